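"""Diagnostic-accuracy evaluation with exact binomial confidence intervals.

The positive class throughout is ``absent_FM`` — the screening target.
Proportion intervals use the Clopper–Pearson exact method (Beta quantile
form), which is conservative: coverage is at least nominal.  Display
rounding is half-up to integer percent; full precision is kept internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _stats

__all__ = [
    "ConfusionMatrix",
    "ProportionCI",
    "confusion_matrix",
    "diagnostic_metrics",
    "clopper_pearson",
    "percent",
]

POSITIVE_LABEL = "absent_FM"
NEGATIVE_LABEL = "normal_FM"


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 diagnostic counts with absent fidgety movements as positive."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        if self.total < 1:
            raise ValueError("confusion matrix must contain at least one case")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ProportionCI:
    """A proportion with its exact two-sided confidence interval."""

    estimate: float
    lower: float
    upper: float
    level: float = 0.95
    method: str = "clopper-pearson"

    def __post_init__(self) -> None:
        if not 0 <= self.lower <= self.estimate <= self.upper <= 1:
            raise ValueError(
                f"require 0 <= lower <= estimate <= upper <= 1, got "
                f"({self.lower}, {self.estimate}, {self.upper})"
            )


def confusion_matrix(predicted: Sequence[str], actual: Sequence[str]) -> ConfusionMatrix:
    """Tally predicted vs. actual labels ('absent_FM' positive)."""
    if len(predicted) != len(actual):
        raise ValueError(
            f"predicted ({len(predicted)}) and actual ({len(actual)}) lengths differ"
        )
    if len(predicted) == 0:
        raise ValueError("need at least one case")
    allowed = {POSITIVE_LABEL, NEGATIVE_LABEL}
    for lab in (*predicted, *actual):
        if lab not in allowed:
            raise ValueError(f"unknown label {lab!r}; expected one of {sorted(allowed)}")
    pred = np.asarray(predicted) == POSITIVE_LABEL
    act = np.asarray(actual) == POSITIVE_LABEL
    return ConfusionMatrix(
        tp=int(np.sum(pred & act)),
        fp=int(np.sum(pred & ~act)),
        tn=int(np.sum(~pred & ~act)),
        fn=int(np.sum(~pred & act)),
    )


def clopper_pearson(successes: int, n: int, level: float = 0.95) -> ProportionCI:
    """Exact binomial confidence interval via the Beta quantile form.

    lower = BetaInv(alpha/2; s, n-s+1), upper = BetaInv(1-alpha/2; s+1, n-s),
    with the boundary conventions lower=0 at s=0 and upper=1 at s=n.
    """
    if n < 1 or successes < 0 or successes > n:
        raise ValueError(f"invalid counts: {successes}/{n}")
    alpha = 1.0 - level
    s = successes
    lower = 0.0 if s == 0 else float(_stats.beta.ppf(alpha / 2, s, n - s + 1))
    upper = 1.0 if s == n else float(_stats.beta.ppf(1 - alpha / 2, s + 1, n - s))
    return ProportionCI(estimate=s / n, lower=lower, upper=upper, level=level)


def _metric(successes: int, n: int, level: float) -> ProportionCI | None:
    return clopper_pearson(successes, n, level) if n > 0 else None


def diagnostic_metrics(cm: ConfusionMatrix, level: float = 0.95) -> dict:
    """Sensitivity, specificity, accuracy, PPV and NPV, each with an exact CI.

    A metric with a zero denominator (e.g. PPV with no positive predictions)
    is reported as None together with an entry in ``undefined`` explaining
    which denominator was empty, rather than raising.
    """
    out: dict = {
        "sensitivity": _metric(cm.tp, cm.tp + cm.fn, level),
        "specificity": _metric(cm.tn, cm.tn + cm.fp, level),
        "accuracy": _metric(cm.tp + cm.tn, cm.total, level),
        "ppv": _metric(cm.tp, cm.tp + cm.fp, level),
        "npv": _metric(cm.tn, cm.tn + cm.fn, level),
    }
    out["undefined"] = [k for k, v in out.items() if v is None]
    return out


def percent(value: float) -> int:
    """Half-up rounding to integer percent, the report display convention."""
    return int(math.floor(value * 100.0 + 0.5))
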