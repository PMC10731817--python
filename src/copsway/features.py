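"""Posturographic movement-parameter battery for supine infant COP series.

Every parameter is computed per direction: X (medial–lateral), Y
(caudo-cephalic) and R (resultant).  For velocity parameters the R direction
is the magnitude of the planar velocity vector; for displacement parameters
it is the distance from the window-mean COP.  The battery:

==============================  =========  =========================================
parameter                       directions definition
==============================  =========  =========================================
instantaneous_velocity_std      X, Y, R    sample SD of the velocity series (mm/s)
instantaneous_velocity_rms      X, Y, R    RMS of the velocity series (mm/s)
instantaneous_velocity_skewness X, Y, R    adjusted Fisher–Pearson sample skewness
velocity_range                  X, Y, R    max − min of the velocity series (mm/s)
total_distance                  X, Y, R    path length: Σ|Δx|; planar Σ√(Δx²+Δy²) (mm)
instantaneous_distance_rms      X, Y, R    √(mean of squared centered series) (mm)
average_distance                R          mean resultant displacement (mm)
ellipse_area                    R          95% prediction-ellipse area (mm²)
ellipse_major_axis              R          full major axis of that ellipse (mm)
ellipse_minor_axis              R          full minor axis (mm)
ellipse_orientation             R          major-axis angle from the X axis (rad)
approximate_entropy             X, Y, R    Pincus ApEn(m, r·SD) regularity statistic
==============================  =========  =========================================

Velocities use forward differences, so mean resultant speed × window duration
telescopes exactly to the planar path length.  Approximate entropy follows
the Pincus definition with Chebyshev distance and self-matches included, the
de facto standard for physiological series (m=2, r=0.2·SD by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Literal

import numpy as np
from scipy import stats as _stats

from .errors import LengthError, NormalizationError
from .io import SubjectMeta
from .preprocess import ProcessedCop

__all__ = [
    "ApEnConfig",
    "NormalizationScheme",
    "CopParameterSet",
    "instantaneous_velocity",
    "velocity_stats",
    "path_metrics",
    "confidence_ellipse",
    "approximate_entropy",
    "compute_parameters",
    "normalize_parameters",
    "PARAMETER_ORDER",
    "PARAMETER_UNITS",
    "LENGTH_DIMENSION",
]

Direction = Literal["X", "Y", "R"]

#: Frozen battery order: (parameter, direction) pairs, also the output-table
#: column order.
PARAMETER_ORDER: tuple[tuple[str, str], ...] = tuple(
    (name, d)
    for name in (
        "instantaneous_velocity_std",
        "instantaneous_velocity_rms",
        "instantaneous_velocity_skewness",
        "velocity_range",
        "total_distance",
        "instantaneous_distance_rms",
    )
    for d in ("X", "Y", "R")
) + (
    ("average_distance", "R"),
    ("ellipse_area", "R"),
    ("ellipse_major_axis", "R"),
    ("ellipse_minor_axis", "R"),
    ("ellipse_orientation", "R"),
    ("approximate_entropy", "X"),
    ("approximate_entropy", "Y"),
    ("approximate_entropy", "R"),
)

PARAMETER_UNITS: dict[str, str] = {
    "instantaneous_velocity_std": "mm/s",
    "instantaneous_velocity_rms": "mm/s",
    "instantaneous_velocity_skewness": "",
    "velocity_range": "mm/s",
    "total_distance": "mm",
    "instantaneous_distance_rms": "mm",
    "average_distance": "mm",
    "ellipse_area": "mm^2",
    "ellipse_major_axis": "mm",
    "ellipse_minor_axis": "mm",
    "ellipse_orientation": "rad",
    "approximate_entropy": "",
}

#: Power of length carried by each parameter (0 = dimensionless, never
#: rescaled by anthropometric normalization).
LENGTH_DIMENSION: dict[str, int] = {
    "instantaneous_velocity_std": 1,
    "instantaneous_velocity_rms": 1,
    "instantaneous_velocity_skewness": 0,
    "velocity_range": 1,
    "total_distance": 1,
    "instantaneous_distance_rms": 1,
    "average_distance": 1,
    "ellipse_area": 2,
    "ellipse_major_axis": 1,
    "ellipse_minor_axis": 1,
    "ellipse_orientation": 0,
    "approximate_entropy": 0,
}


@dataclass(frozen=True)
class ApEnConfig:
    """Approximate-entropy settings: embedding dimension m and tolerance
    r = r_factor × SD of the series."""

    m: int = 2
    r_factor: float = 0.2

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not self.r_factor > 0:
            raise ValueError("r_factor must be > 0")


@dataclass(frozen=True)
class NormalizationScheme:
    """Anthropometric normalization of length-dimensioned parameters.

    kind=height divides length-dimensioned values by current height (cm),
    kind=weight by current weight (kg), kind=height_weight by both; areas are
    divided by the square of each divisor.  Dimensionless parameters
    (skewness, approximate entropy, orientation) are never rescaled.
    """

    kind: Literal["none", "height", "weight", "height_weight"] = "height_weight"


@dataclass
class CopParameterSet:
    """The computed battery for one recording.

    values maps (parameter_name, direction) to the numeric value; units maps
    parameter_name to its unit string (pre-normalization).  degenerate_ellipse
    flags a rank-deficient planar covariance (area reported as 0).
    """

    values: dict[tuple[str, str], float]
    units: dict[str, str] = field(default_factory=lambda: dict(PARAMETER_UNITS))
    normalized: bool = False
    scheme: NormalizationScheme | None = None
    subject: SubjectMeta = field(default_factory=SubjectMeta)
    degenerate_ellipse: bool = False

    def __getitem__(self, key: tuple[str, str]) -> float:
        return self.values[key]

    def keys(self) -> Iterator[tuple[str, str]]:
        return iter(self.values.keys())

    def get(self, name: str, direction: str = "R") -> float:
        return self.values[(name, direction)]


def instantaneous_velocity(p: ProcessedCop) -> dict[str, np.ndarray]:
    """Forward-difference velocity series per direction (mm/s).

    vx_i = (x_{i+1} − x_i)·fs and likewise for y; the resultant velocity is
    the planar speed sqrt(vx² + vy²), not the derivative of r_disp.
    """
    if len(p) < 2:
        raise LengthError("need at least 2 samples for velocity")
    vx = np.diff(p.x) * p.fs
    vy = np.diff(p.y) * p.fs
    return {"X": vx, "Y": vy, "R": np.hypot(vx, vy)}


def velocity_stats(v: np.ndarray) -> dict[str, float]:
    """Std (N−1 denominator), RMS, adjusted Fisher–Pearson skewness and range
    of a velocity series.  Skewness of a zero-variance series is 0 by
    convention so degenerate fixtures do not crash the battery."""
    v = np.asarray(v, dtype=float)
    if len(v) < 2:
        raise LengthError("need at least 2 velocity samples")
    std = float(np.std(v, ddof=1))
    rms = float(np.sqrt(np.mean(v**2)))
    vrange = float(np.max(v) - np.min(v))
    if std == 0.0 or len(v) < 3:
        skew = 0.0
    else:
        skew = float(_stats.skew(v, bias=False))
    return {"std": std, "rms": rms, "skewness": skew, "range": vrange}


def path_metrics(p: ProcessedCop) -> dict[str, float]:
    """Path-length and displacement metrics.

    total_distance per axis is Σ|Δ|; for R it is the planar path length
    Σ√(Δx²+Δy²).  instantaneous_distance_rms is the RMS of the centered
    series (r_disp for R); average_distance is the mean resultant
    displacement.
    """
    if len(p) < 2:
        raise LengthError("need at least 2 samples for path metrics")
    dx = np.diff(p.x)
    dy = np.diff(p.y)
    return {
        "total_distance_X": float(np.sum(np.abs(dx))),
        "total_distance_Y": float(np.sum(np.abs(dy))),
        "total_distance_R": float(np.sum(np.hypot(dx, dy))),
        "instantaneous_distance_rms_X": float(np.sqrt(np.mean(p.x_c**2))),
        "instantaneous_distance_rms_Y": float(np.sqrt(np.mean(p.y_c**2))),
        "instantaneous_distance_rms_R": float(np.sqrt(np.mean(p.r_disp**2))),
        "average_distance": float(np.mean(p.r_disp)),
    }


def confidence_ellipse(p: ProcessedCop, level: float = 0.95) -> dict[str, float]:
    """Prediction ellipse of the planar COP scatter.

    From the 2×2 sample covariance Σ of (x_c, y_c):

        area = π · χ²₂(level) · sqrt(det Σ)
        axis_k = 2 · sqrt(χ²₂(level) · λ_k)        (full axis lengths)

    with χ²₂(0.95) ≈ 5.991; orientation is the angle of the leading
    eigenvector.  A degenerate (rank-deficient) covariance yields area 0 and
    a ``degenerate`` flag rather than an exception.
    """
    if len(p) < 3:
        raise LengthError("need at least 3 samples for an ellipse")
    chi2 = float(_stats.chi2.ppf(level, df=2))
    cov = np.cov(p.x_c, p.y_c, ddof=1)
    det = float(np.linalg.det(cov))
    eigvals, eigvecs = np.linalg.eigh(cov)  # ascending
    eigvals = np.clip(eigvals, 0.0, None)
    major = 2.0 * math.sqrt(chi2 * eigvals[1])
    minor = 2.0 * math.sqrt(chi2 * eigvals[0])
    lead = eigvecs[:, 1]
    orientation = float(math.atan2(lead[1], lead[0]))
    if orientation < -math.pi / 2 or orientation > math.pi / 2:
        orientation = math.atan2(-lead[1], -lead[0])  # fold to (-pi/2, pi/2]
    degenerate = det <= 0 or eigvals[0] == 0.0
    area = 0.0 if degenerate else math.pi * chi2 * math.sqrt(det)
    return {
        "area": area,
        "major_axis": major,
        "minor_axis": minor,
        "orientation": orientation,
        "degenerate": degenerate,
    }


def _phi(embedded: np.ndarray, r: float, chunk: int = 512) -> float:
    """Mean log correlation sum Φ^k(r) over template vectors (self-matches
    included), Chebyshev distance; chunked to bound memory at long N."""
    n_templates = embedded.shape[0]
    counts = np.empty(n_templates, dtype=np.int64)
    for start in range(0, n_templates, chunk):
        block = embedded[start : start + chunk]  # (c, k)
        # max over the embedding axis of |block_i - template_j|
        dist = np.abs(block[:, None, 0] - embedded[None, :, 0])
        for k in range(1, embedded.shape[1]):
            np.maximum(dist, np.abs(block[:, None, k] - embedded[None, :, k]),
                       out=dist)
        counts[start : start + chunk] = np.count_nonzero(dist <= r, axis=1)
    return float(np.mean(np.log(counts / n_templates)))


def approximate_entropy(series: np.ndarray, cfg: ApEnConfig | None = None) -> float:
    """Pincus approximate entropy ApEn(m, r, N).

    r = r_factor × sample SD of the series; Chebyshev distance; self-matches
    included, so ApEn ≥ 0 always.  A zero-variance series has ApEn 0 by
    definition.  Larger values indicate a less predictable, more irregular
    series.
    """
    cfg = cfg or ApEnConfig()
    series = np.asarray(series, dtype=float)
    n = len(series)
    if n < 10 * (cfg.m + 1):
        raise LengthError(
            f"ApEn(m={cfg.m}) needs at least {10 * (cfg.m + 1)} samples, got {n}"
        )
    sd = float(np.std(series, ddof=1))
    if sd == 0.0:
        return 0.0
    r = cfg.r_factor * sd
    phis = []
    for k in (cfg.m, cfg.m + 1):
        embedded = np.lib.stride_tricks.sliding_window_view(series, k)
        phis.append(_phi(embedded, r))
    return phis[0] - phis[1]


def compute_parameters(
    p: ProcessedCop,
    apen_cfg: ApEnConfig | None = None,
    ellipse_level: float = 0.95,
) -> CopParameterSet:
    """Compute the complete battery for one processed recording.

    Deterministic for fixed input; returns values on the raw (unnormalized)
    scale with ``normalized=False``.
    """
    apen_cfg = apen_cfg or ApEnConfig()
    velocities = instantaneous_velocity(p)
    values: dict[tuple[str, str], float] = {}
    for d in ("X", "Y", "R"):
        vs = velocity_stats(velocities[d])
        values[("instantaneous_velocity_std", d)] = vs["std"]
        values[("instantaneous_velocity_rms", d)] = vs["rms"]
        values[("instantaneous_velocity_skewness", d)] = vs["skewness"]
        values[("velocity_range", d)] = vs["range"]
    paths = path_metrics(p)
    for d in ("X", "Y", "R"):
        values[("total_distance", d)] = paths[f"total_distance_{d}"]
        values[("instantaneous_distance_rms", d)] = paths[
            f"instantaneous_distance_rms_{d}"
        ]
    values[("average_distance", "R")] = paths["average_distance"]
    ell = confidence_ellipse(p, level=ellipse_level)
    values[("ellipse_area", "R")] = ell["area"]
    values[("ellipse_major_axis", "R")] = ell["major_axis"]
    values[("ellipse_minor_axis", "R")] = ell["minor_axis"]
    values[("ellipse_orientation", "R")] = ell["orientation"]
    for d in ("X", "Y", "R"):
        values[("approximate_entropy", d)] = approximate_entropy(p.series(d), apen_cfg)
    ordered = {key: values[key] for key in PARAMETER_ORDER}
    return CopParameterSet(
        values=ordered,
        subject=p.subject,
        degenerate_ellipse=bool(ell["degenerate"]),
    )


def normalize_parameters(
    params: CopParameterSet, scheme: NormalizationScheme | None = None
) -> CopParameterSet:
    """Rescale length-dimensioned parameters by the subject's anthropometrics.

    Height enters in cm, weight in kg (stored weight is in grams); a
    parameter carrying length^d is divided by divisor^d.  Dimensionless
    parameters pass through unchanged under every scheme.
    """
    scheme = scheme or NormalizationScheme()
    divisor = 1.0
    if scheme.kind in ("height", "height_weight"):
        if params.subject.height is None:
            raise NormalizationError(
                f"scheme {scheme.kind!r} requires subject height (cm)"
            )
        divisor *= params.subject.height
    if scheme.kind in ("weight", "height_weight"):
        if params.subject.weight is None:
            raise NormalizationError(
                f"scheme {scheme.kind!r} requires subject weight (g)"
            )
        divisor *= params.subject.weight / 1000.0
    new_values = {
        (name, d): value / divisor ** LENGTH_DIMENSION[name]
        for (name, d), value in params.values.items()
    }
    return replace(params, values=new_values, normalized=True, scheme=scheme)
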