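"""Published prediction equations and model diagnostics.

Two equations link the COP movement battery to the observational General
Movements Assessment of a supine infant:

* a binary logistic classifier for absent vs. normal fidgety movements (FMs),

      P(absent) = 1 / (1 + exp(-(b0 + b_iv * IV_R_std + b_apen * ApEn_R)))

  with b0 = -3.354, b_iv = -0.010 (velocity variability protects), b_apen =
  0.895 (excess complexity raises risk) and a screening-oriented
  classification threshold of 0.15;

* a log-linear estimator of the Motor Optimality Score-Revised (MOS-R,
  range 5-28),

      log10(MOS-R) = 1.294 + 0.172*log10(IV_R_std)
                     - 0.219*log10(IV_R_skew) - 0.265*log10(ApEn_R).

Also here: the correlation-based predictor screening (relevance cutoff 0.25,
collinearity cutoff 0.70), a maximum-likelihood logistic refit (statsmodels)
with likelihood-ratio chi-square and Nagelkerke pseudo-R², and the
Hosmer–Lemeshow calibration test.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .errors import (
    ConvergenceError,
    DegenerateOutcomeError,
    MissingPredictorError,
    PredictorDomainError,
    SeparationError,
)
from .features import CopParameterSet

__all__ = [
    "FmLogisticModel",
    "MosrLinearModel",
    "ClassificationOutcome",
    "fm_probability",
    "fm_classify",
    "mosr_predict",
    "select_candidate_predictors",
    "refit_logistic",
    "hosmer_lemeshow",
    "load_fm_model",
    "load_mosr_model",
]

_DATA_DIR = Path(__file__).parent / "data"


@dataclass(frozen=True)
class FmLogisticModel:
    """Logistic classifier for absent fidgety movements.

    Default coefficients are the published estimates; odds ratios follow as
    exp(coefficient).  standard_errors are kept so the printed OR confidence
    bounds can be re-derived as exp(B ± 1.96·SE).
    """

    beta0: float = -3.354
    beta_iv: float = -0.010
    beta_apen: float = 0.895
    threshold: float = 0.15
    se_iv: float = 0.005
    se_apen: float = 0.294
    se_beta0: float = 1.336

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")

    def odds_ratios(self) -> dict[str, float]:
        return {"iv_std_R": math.exp(self.beta_iv), "apen_R": math.exp(self.beta_apen)}

    def odds_ratio_ci(self, level: float = 0.95) -> dict[str, tuple[float, float]]:
        z = float(_stats.norm.ppf(0.5 + level / 2))
        return {
            "iv_std_R": (
                math.exp(self.beta_iv - z * self.se_iv),
                math.exp(self.beta_iv + z * self.se_iv),
            ),
            "apen_R": (
                math.exp(self.beta_apen - z * self.se_apen),
                math.exp(self.beta_apen + z * self.se_apen),
            ),
        }


@dataclass(frozen=True)
class MosrLinearModel:
    """Log-linear MOS-R estimator; predictions are clamped to the legal
    score range [5, 28].  log_base 10 is the default (an all-ones predictor
    vector then maps to ~19.7, inside the scale; natural log cannot reach the
    legal range) and can be switched to math.e."""

    a0: float = 1.294
    a_iv_std: float = 0.172
    a_iv_skew: float = -0.219
    a_apen: float = -0.265
    log_base: float = 10.0
    score_range: tuple[float, float] = (5.0, 28.0)


@dataclass
class ClassificationOutcome:
    """Result of applying the FMs classifier to one recording."""

    probability: float
    label: str  # "absent_FM" | "normal_FM"
    predictors_used: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def fm_probability(
    iv_std_R: float, apen_R: float, model: FmLogisticModel | None = None
) -> float:
    """P(absent FMs) from resultant velocity variability and approximate
    entropy.  Strictly decreasing in iv_std_R and increasing in apen_R."""
    model = model or FmLogisticModel()
    for name, value in (("iv_std_R", iv_std_R), ("apen_R", apen_R)):
        if not math.isfinite(value):
            raise PredictorDomainError(name, value, f"{name} must be finite")
    lp = model.beta0 + model.beta_iv * iv_std_R + model.beta_apen * apen_R
    return 1.0 / (1.0 + math.exp(-lp))


def fm_classify(
    params: CopParameterSet, model: FmLogisticModel | None = None
) -> ClassificationOutcome:
    """Classify a recording's parameter set as absent_FM or normal_FM.

    A probability exactly at the threshold classifies as absent_FM: in a
    screening context the tie goes to sensitivity.  Unnormalized input is
    accepted with a recorded warning.
    """
    model = model or FmLogisticModel()
    warnings: list[str] = []
    try:
        iv = params.get("instantaneous_velocity_std", "R")
        apen = params.get("approximate_entropy", "R")
    except KeyError as exc:
        raise MissingPredictorError(
            f"parameter set lacks required predictor {exc.args[0]!r}"
        ) from exc
    if not params.normalized:
        warnings.append("parameters are not anthropometrically normalized")
    prob = fm_probability(iv, apen, model)
    label = "absent_FM" if prob >= model.threshold else "normal_FM"
    scheme = params.scheme.kind if params.scheme else None
    return ClassificationOutcome(
        probability=prob,
        label=label,
        predictors_used={
            "instantaneous_velocity_std_R": iv,
            "approximate_entropy_R": apen,
            "normalized": params.normalized,
            "scheme": scheme,
        },
        warnings=warnings,
    )


def mosr_predict(
    iv_std_R: float,
    iv_skew_R: float,
    apen_R: float,
    model: MosrLinearModel | None = None,
    positive_shift: float = 0.0,
) -> dict:
    """Estimate the MOS-R total score from three resultant COP parameters.

    All three predictors must be strictly positive (after the optional
    ``positive_shift``, off by default) because they enter through
    logarithms; a non-positive value — typically negative velocity skewness —
    is a domain error naming the predictor.  The back-transformed estimate is
    clamped to the legal score range with a flag.
    """
    model = model or MosrLinearModel()
    preds = {"iv_std_R": iv_std_R, "iv_skew_R": iv_skew_R, "apen_R": apen_R}
    logs = {}
    for name, value in preds.items():
        shifted = value + positive_shift
        if not math.isfinite(shifted) or shifted <= 0:
            raise PredictorDomainError(
                name, value, f"{name} must be strictly positive for the log "
                f"transform, got {value!r}"
            )
        logs[name] = math.log(shifted, model.log_base)
    log_pred = (
        model.a0
        + model.a_iv_std * logs["iv_std_R"]
        + model.a_iv_skew * logs["iv_skew_R"]
        + model.a_apen * logs["apen_R"]
    )
    raw = model.log_base**log_pred
    lo, hi = model.score_range
    clamped = min(max(raw, lo), hi)
    return {
        "mosr_estimate": clamped,
        "log_prediction": log_pred,
        "unclamped": raw,
        "clamp_applied": clamped != raw,
    }


def _correlation(x: np.ndarray, y: np.ndarray, method: str) -> tuple[float, float]:
    if method == "pearson":
        res = _stats.pearsonr(x, y)
    else:
        res = _stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def select_candidate_predictors(
    feature_table: pd.DataFrame,
    outcome: np.ndarray,
    relevance_cutoff: float = 0.25,
    collinearity_cutoff: float = 0.70,
    alpha: float = 0.05,
    method: str = "spearman",
) -> list[str]:
    """Two-step correlation screening of candidate predictors.

    Step 1 keeps columns whose |correlation with the outcome| exceeds
    ``relevance_cutoff`` at p < ``alpha`` — point-biserial (Pearson against
    the 0/1 indicator) for a dichotomous outcome, rank correlation otherwise.
    Step 2 scans survivors in descending |outcome correlation| and drops any
    candidate whose |correlation| with an already-kept one exceeds
    ``collinearity_cutoff``, so only one of each collinear cluster enters a
    model.  Returns kept column names in scan order.
    """
    outcome = np.asarray(outcome, dtype=float)
    if len(feature_table) != len(outcome):
        raise ValueError("outcome length must match the feature table")
    if len(feature_table) < 3:
        raise ValueError("need at least 3 recordings for screening")
    if np.all(outcome == outcome[0]):
        raise DegenerateOutcomeError("outcome is constant")
    dichotomous = len(np.unique(outcome)) == 2
    outcome_method = "pearson" if dichotomous else method  # point-biserial

    relevance: list[tuple[str, float]] = []
    for col in feature_table.columns:
        x = feature_table[col].to_numpy(dtype=float)
        if np.std(x) == 0:
            continue
        r, p = _correlation(x, outcome, outcome_method)
        if abs(r) > relevance_cutoff and p < alpha:
            relevance.append((col, abs(r)))
    relevance.sort(key=lambda item: -item[1])

    kept: list[str] = []
    for col, _ in relevance:
        x = feature_table[col].to_numpy(dtype=float)
        collinear = False
        for other in kept:
            r, _p = _correlation(
                x, feature_table[other].to_numpy(dtype=float), method
            )
            if abs(r) > collinearity_cutoff:
                collinear = True
                break
        if not collinear:
            kept.append(col)
    return kept


def refit_logistic(
    feature_table: pd.DataFrame,
    labels: np.ndarray,
    predictors: list[str] | None = None,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> tuple[FmLogisticModel, dict]:
    """Maximum-likelihood logistic refit on new data.

    ``predictors`` must name two columns in the order (velocity-variability,
    complexity) to populate a :class:`FmLogisticModel`; the published
    threshold of 0.15 is retained.  Diagnostics: likelihood-ratio chi-square
    -2(LL_null - LL_model) and Nagelkerke pseudo-R².

    Raises :class:`SeparationError` on perfect separation and
    :class:`ConvergenceError` when Newton iterations do not converge.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    labels = np.asarray(labels, dtype=float)
    if set(np.unique(labels)) - {0.0, 1.0}:
        raise ValueError("labels must be 0/1 (1 = absent FMs)")
    if len(np.unique(labels)) < 2:
        raise DegenerateOutcomeError("both outcome classes must be present")
    predictors = list(predictors) if predictors is not None else list(
        feature_table.columns
    )
    n = len(labels)
    if n <= len(predictors) + 1:
        raise ValueError("need n > number of predictors + 1")

    X = sm.add_constant(feature_table[predictors].to_numpy(dtype=float))
    try:
        fit = sm.Logit(labels, X).fit(method="newton", tol=tol, maxiter=maxiter,
                                      disp=False)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        # complete separation makes the likelihood unbounded; depending on the
        # statsmodels version this surfaces as an explicit error or as a
        # singular Hessian after the coefficients diverge
        raise SeparationError(str(exc)) from exc
    if not fit.mle_retvals.get("converged", False):
        raise ConvergenceError(int(fit.mle_retvals.get("iterations", maxiter)))
    params = np.asarray(fit.params, dtype=float)
    bse = np.asarray(fit.bse, dtype=float)
    if np.max(np.abs(params)) > 1e3:
        raise SeparationError("coefficients diverged; labels are likely separable")

    ll_model = float(fit.llf)
    ll_null = float(fit.llnull)
    model_chisq = -2.0 * (ll_null - ll_model)
    # Nagelkerke: Cox-Snell rescaled by its maximum attainable value
    cox_snell = 1.0 - math.exp(2.0 * (ll_null - ll_model) / n)
    max_cs = 1.0 - math.exp(2.0 * ll_null / n)
    nagelkerke = cox_snell / max_cs if max_cs > 0 else 0.0

    if len(predictors) == 2:
        model = FmLogisticModel(
            beta0=params[0], beta_iv=params[1], beta_apen=params[2],
            se_beta0=bse[0], se_iv=bse[1], se_apen=bse[2],
        )
    else:
        model = None
    diagnostics = {
        "model_chisq": model_chisq,
        "model_df": len(predictors),
        "nagelkerke_r2": nagelkerke,
        "loglike": ll_model,
        "loglike_null": ll_null,
        "coefficients": dict(zip(["const", *predictors], params.tolist())),
        "standard_errors": dict(zip(["const", *predictors], bse.tolist())),
        "n": n,
    }
    return model, diagnostics


def hosmer_lemeshow(
    probabilities: np.ndarray, labels: np.ndarray, groups: int = 10
) -> dict:
    """Hosmer–Lemeshow goodness-of-fit test on deciles of predicted risk.

    Observations are sorted by predicted probability (stable, so ties keep
    input order) and split into ``groups`` near-equal groups; the statistic
    sums (O - E)^2 / (E (1 - E/n_g)) over groups, equivalent to the
    two-outcome-level Pearson form, with df = groups - 2.  Groups whose
    expected count is zero are merged with a neighbour and the merge is
    recorded.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels, dtype=float)
    n = len(probabilities)
    if len(labels) != n:
        raise ValueError("labels and probabilities must have equal length")
    if n < 2 * groups:
        raise ValueError(f"need n >= {2 * groups} for {groups} groups")
    if np.any((probabilities <= 0) | (probabilities >= 1)):
        raise ValueError("probabilities must lie strictly in (0, 1)")

    order = np.argsort(probabilities, kind="stable")
    p_sorted = probabilities[order]
    y_sorted = labels[order]
    edges = np.linspace(0, n, groups + 1).round().astype(int)
    group_slices = [slice(edges[i], edges[i + 1]) for i in range(groups)]

    obs = [float(np.sum(y_sorted[s])) for s in group_slices]
    exp = [float(np.sum(p_sorted[s])) for s in group_slices]
    sizes = [s.stop - s.start for s in group_slices]

    merged = 0
    i = 0
    while i < len(obs) and len(obs) > 1:
        if exp[i] == 0.0 or exp[i] == sizes[i]:
            o, e, m = obs.pop(i), exp.pop(i), sizes.pop(i)
            t = i - 1 if i > 0 else 0  # neighbour's post-pop index
            obs[t] += o
            exp[t] += e
            sizes[t] += m
            merged += 1
        else:
            i += 1

    statistic = 0.0
    for o, e, m in zip(obs, exp, sizes):
        statistic += (o - e) ** 2 / (e * (1.0 - e / m))
    df = max(len(obs) - 2, 1)
    p_value = float(_stats.chi2.sf(statistic, df))
    return {
        "statistic": statistic,
        "df": df,
        "p_value": p_value,
        "groups_used": len(obs),
        "groups_merged": merged,
    }


def load_fm_model(path: str | Path | None = None) -> FmLogisticModel:
    """Load an FMs classifier from a JSON model file (default: the shipped
    published coefficients)."""
    path = Path(path) if path else _DATA_DIR / "fm_model.json"
    payload = json.loads(Path(path).read_text())
    fields = {k: payload[k] for k in (
        "beta0", "beta_iv", "beta_apen", "threshold", "se_iv", "se_apen", "se_beta0"
    ) if k in payload}
    return FmLogisticModel(**fields)


def load_mosr_model(path: str | Path | None = None) -> MosrLinearModel:
    """Load a MOS-R estimator from a JSON model file (default: shipped)."""
    path = Path(path) if path else _DATA_DIR / "mosr_model.json"
    payload = json.loads(Path(path).read_text())
    fields = {k: payload[k] for k in (
        "a0", "a_iv_std", "a_iv_skew", "a_apen", "log_base"
    ) if k in payload}
    if "score_range" in payload:
        fields["score_range"] = tuple(payload["score_range"])
    return MosrLinearModel(**fields)


def save_model(model: FmLogisticModel | MosrLinearModel, path: str | Path) -> None:
    """Write a model's coefficients as a human-readable JSON file."""
    payload = asdict(model)
    payload["model_type"] = type(model).__name__
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
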