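"""Synthetic supine-infant COP recordings.

No clinical recordings accompany the published models, so this module
generates surrogate stabilograms with the gross properties of the real
protocol: 180 s at 50 Hz, movement energy below 3 Hz, millimetric sway.  Two
regimes mirror the discriminative contrasts of the fidgety-movements
classification:

* ``normal``  — rich amplitude modulation (high velocity variability) and a
  small broadband component (moderate complexity);
* ``absent``  — shallow modulation (reduced velocity variability, the
  monotony of absent fidgety movements) and a larger broadband mix (the
  chaotic, excessive complexity reported for that group).

Per axis the signal is

    cop(t) = base_amplitude * envelope(t) * bandlimited(t)
             + complexity_gain * broadband(t)

where ``bandlimited`` is seeded Gaussian noise band-passed to the movement
band (0.1–3 Hz), ``envelope`` is a slow (0.05–0.2 Hz) random amplitude
modulation whose depth scales with ``velocity_variability_gain``, and
``broadband`` is low-amplitude white noise.  This is an engineering
stand-in, not a biomechanical model: it provides independent knobs for the
two predictors the classifier uses, nothing more.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .io import CopRecording, SubjectMeta

__all__ = ["SimulationConfig", "simulate_cop_recording", "simulate_cohort",
           "write_cohort"]

#: SD (mm) of the raw broadband noise before the complexity weight is
#: applied; small against the 15 mm sway scale so it perturbs regularity,
#: not gross sway amplitude.
_BROADBAND_SD = 2.0

_REGIME_DEFAULTS = {
    "normal": {"velocity_variability_gain": 1.0, "complexity_gain": 0.2},
    "absent": {"velocity_variability_gain": 0.35, "complexity_gain": 0.6},
}


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings.

    ``velocity_variability_gain`` and ``complexity_gain`` default to None and
    are resolved from the regime (normal: 1.0/0.2, absent: 0.35/0.6).
    base_amplitude is the band-limited sway scale in mm; band is the movement
    frequency band in Hz.
    """

    regime: Literal["normal", "absent"] = "normal"
    fs: float = 50.0
    duration: float = 180.0
    seed: int = 0
    band: tuple[float, float] = (0.1, 3.0)
    base_amplitude: float = 15.0
    velocity_variability_gain: float | None = None
    complexity_gain: float | None = None
    n_recordings: int = 1

    def __post_init__(self) -> None:
        if self.regime not in _REGIME_DEFAULTS:
            raise ValueError(f"unknown regime {self.regime!r}")
        if not self.band[1] < self.fs / 2:
            raise ValueError("band upper edge must be below Nyquist")
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration * fs must be integral")
        for g in (self.velocity_variability_gain, self.complexity_gain):
            if g is not None and g < 0:
                raise ValueError("gains must be >= 0")

    @property
    def vv_gain(self) -> float:
        if self.velocity_variability_gain is not None:
            return self.velocity_variability_gain
        return _REGIME_DEFAULTS[self.regime]["velocity_variability_gain"]

    @property
    def cx_gain(self) -> float:
        if self.complexity_gain is not None:
            return self.complexity_gain
        return _REGIME_DEFAULTS[self.regime]["complexity_gain"]


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float,
                       band: tuple[float, float]) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to the movement band."""
    white = rng.standard_normal(n)
    sos = _signal.butter(4, band, btype="band", fs=fs, output="sos")
    shaped = _signal.sosfiltfilt(sos, white)
    sd = np.std(shaped)
    return shaped / sd if sd > 0 else shaped


def _slow_envelope(rng: np.random.Generator, n: int, fs: float,
                   depth: float) -> np.ndarray:
    """Non-negative slow amplitude modulation, mean ~1, depth in [0, 1]."""
    white = rng.standard_normal(n)
    sos = _signal.butter(2, (0.05, 0.2), btype="band", fs=fs, output="sos")
    slow = _signal.sosfiltfilt(sos, white)
    sd = np.std(slow)
    if sd > 0:
        slow = slow / sd
    return np.clip(1.0 + depth * slow, 0.05, None)


def simulate_cop_recording(cfg: SimulationConfig) -> CopRecording:
    """One seeded synthetic recording; bit-identical for identical configs."""
    rng = np.random.default_rng(cfg.seed)
    n = round(cfg.duration * cfg.fs)
    depth = 0.6 * cfg.vv_gain  # envelope depth; 0.6 keeps the envelope positive
    axes = []
    for _axis in range(2):
        carrier = _bandlimited_noise(rng, n, cfg.fs, cfg.band)
        env = _slow_envelope(rng, n, cfg.fs, depth)
        broadband = rng.standard_normal(n) * _BROADBAND_SD
        axes.append(cfg.base_amplitude * env * carrier + cfg.cx_gain * broadband)
    height = float(rng.uniform(55.0, 68.0))
    weight = float(rng.uniform(4500.0, 8000.0))
    subject = SubjectMeta(
        id=f"sim-{cfg.regime}-{cfg.seed}",
        height=round(height, 1),
        weight=round(weight, 0),
        group_label="absent_FM" if cfg.regime == "absent" else "normal_FM",
    )
    return CopRecording(fs=cfg.fs, x=axes[0], y=axes[1], subject=subject)


def simulate_cohort(
    cfg: SimulationConfig, n_normal: int, n_absent: int
) -> list[tuple[CopRecording, str]]:
    """Seeded cohort of labelled recordings.

    Each recording gets an independent child seed spawned deterministically
    from ``cfg.seed``, so the whole cohort is reproducible from the master
    seed.  The published cohort had 88 normal and 13 absent fidgety-movement
    infants.
    """
    if n_normal + n_absent < 2:
        raise ValueError("cohort must contain at least 2 recordings")
    seeds = np.random.SeedSequence(cfg.seed).generate_state(n_normal + n_absent)
    cohort: list[tuple[CopRecording, str]] = []
    for i in range(n_normal + n_absent):
        regime = "normal" if i < n_normal else "absent"
        rec_cfg = replace(cfg, regime=regime, seed=int(seeds[i] % (2**31)))
        label = "normal_FM" if regime == "normal" else "absent_FM"
        cohort.append((simulate_cop_recording(rec_cfg), label))
    return cohort


def write_cohort(cohort: list[tuple[CopRecording, str]], out_dir: str | Path) -> Path:
    """Write each recording as a 'cop'-dialect CSV plus a manifest JSON with
    true labels and anthropometrics; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, (rec, label) in enumerate(cohort):
        fname = f"recording_{i:04d}.csv"
        t = np.arange(len(rec)) / rec.fs
        pd.DataFrame({"time": t, "copx": rec.x, "copy": rec.y}).to_csv(
            out_dir / fname, index=False
        )
        manifest.append({
            "file": fname,
            "label": label,
            "subject_id": rec.subject.id,
            "height_cm": rec.subject.height,
            "weight_g": rec.subject.weight,
            "fs": rec.fs,
        })
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest_path
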