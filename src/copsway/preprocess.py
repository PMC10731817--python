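"""COP signal conditioning: low-pass filtering, acclimation trim, centering.

The supine protocol records 180 s at 50 Hz.  The first 10 s are the infant's
acclimation to the plate and are discarded; the last 170 s form the analysis
window (8500 samples at the default rate).  Noise above the movement band is
removed with a fourth-order 10 Hz low-pass Butterworth filter, applied
zero-phase (forward–backward) by default so velocity estimates carry no phase
lag.  Filtering precedes trimming so startup transients fall in the discarded
lead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .errors import DurationError, LengthError, ParameterError, SamplingRateError
from .io import CopRecording, SubjectMeta

__all__ = ["PreprocessConfig", "ProcessedCop", "butterworth_lowpass",
           "trim_to_analysis_window", "preprocess"]


@dataclass(frozen=True)
class PreprocessConfig:
    """Signal-conditioning parameters.

    Defaults reproduce the published supine-infant protocol: 50 Hz sampling,
    fourth-order 10 Hz low-pass Butterworth, 10 s acclimation lead removed,
    last 170 s analysed.
    """

    expected_fs: float = 50.0
    cutoff: float = 10.0
    order: int = 4
    trim_lead: float = 10.0
    analysis_window: float = 170.0
    zero_phase: bool = True
    allow_short: bool = False

    def __post_init__(self) -> None:
        if not self.cutoff < self.expected_fs / 2:
            raise ParameterError(
                f"cutoff {self.cutoff} Hz must be below Nyquist "
                f"({self.expected_fs / 2} Hz)"
            )
        if self.trim_lead < 0:
            raise ParameterError("trim_lead must be >= 0")
        if not self.analysis_window > 0:
            raise ParameterError("analysis_window must be > 0")


@dataclass
class ProcessedCop:
    """Filtered, trimmed COP series ready for feature extraction.

    x, y are the conditioned series (mm); x_c, y_c are mean-centered copies;
    r_disp is the resultant displacement, the distance of each sample from the
    window-mean COP: r_i = sqrt(x_c_i^2 + y_c_i^2).
    """

    fs: float
    x: np.ndarray
    y: np.ndarray
    x_c: np.ndarray = field(init=False)
    y_c: np.ndarray = field(init=False)
    r_disp: np.ndarray = field(init=False)
    subject: SubjectMeta = field(default_factory=SubjectMeta)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.x) != len(self.y):
            raise ValueError("x and y must have equal length")
        self.x_c = self.x - self.x.mean()
        self.y_c = self.y - self.y.mean()
        self.r_disp = np.hypot(self.x_c, self.y_c)

    def __len__(self) -> int:
        return len(self.x)

    def series(self, direction: str) -> np.ndarray:
        """Centered series for direction 'X' or 'Y', resultant displacement for 'R'."""
        return {"X": self.x_c, "Y": self.y_c, "R": self.r_disp}[direction]


def butterworth_lowpass(
    series: np.ndarray,
    fs: float,
    cutoff: float = 10.0,
    order: int = 4,
    zero_phase: bool = True,
) -> np.ndarray:
    """Low-pass Butterworth filter of the given order.

    ``zero_phase=True`` applies the designed filter forward and backward
    (with reflective edge padding), squaring the magnitude response and
    cancelling phase; ``False`` gives the causal single pass.  DC gain is 1
    either way.
    """
    series = np.asarray(series, dtype=float)
    if len(series) <= 3 * order:
        raise LengthError(
            f"series length {len(series)} must exceed 3*order = {3 * order}"
        )
    if not cutoff < fs / 2:
        raise ParameterError(f"cutoff {cutoff} Hz must be below Nyquist ({fs / 2} Hz)")
    sos = _signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    if zero_phase:
        return _signal.sosfiltfilt(sos, series, padtype="even")
    return _signal.sosfilt(sos, series)


def trim_to_analysis_window(rec: CopRecording, cfg: PreprocessConfig) -> CopRecording:
    """Keep the last ``analysis_window`` seconds of the recording.

    In strict mode the recording must span at least trim_lead +
    analysis_window seconds; with ``allow_short`` everything after trim_lead
    is kept instead and the shortfall is tolerated.
    """
    n_window = round(cfg.analysis_window * rec.fs)
    n_lead = round(cfg.trim_lead * rec.fs)
    n = len(rec)
    if n < n_lead + n_window:
        if not cfg.allow_short:
            raise DurationError(
                f"recording has {n / rec.fs:.2f} s but trim_lead + analysis_window "
                f"requires {cfg.trim_lead + cfg.analysis_window:.2f} s"
            )
        start = min(n_lead, n)
    else:
        start = n - n_window
    return CopRecording(
        fs=rec.fs,
        x=rec.x[start:],
        y=rec.y[start:],
        valid_mask=rec.valid_mask[start:],
        subject=rec.subject,
    )


def preprocess(rec: CopRecording, cfg: PreprocessConfig | None = None) -> ProcessedCop:
    """Full conditioning: rate check, filter, trim, center, resultant.

    Raises :class:`SamplingRateError` when the recording's rate is more than
    1% off the configured ``expected_fs``.
    """
    cfg = cfg or PreprocessConfig()
    if abs(rec.fs - cfg.expected_fs) > 0.01 * cfg.expected_fs:
        raise SamplingRateError(
            f"recording fs {rec.fs:.4g} Hz differs from expected "
            f"{cfg.expected_fs:.4g} Hz by more than 1%"
        )
    x_f = butterworth_lowpass(rec.x, rec.fs, cfg.cutoff, cfg.order, cfg.zero_phase)
    y_f = butterworth_lowpass(rec.y, rec.fs, cfg.cutoff, cfg.order, cfg.zero_phase)
    filtered = replace_series(rec, x_f, y_f)
    trimmed = trim_to_analysis_window(filtered, cfg)
    return ProcessedCop(fs=trimmed.fs, x=trimmed.x, y=trimmed.y, subject=rec.subject)


def replace_series(rec: CopRecording, x: np.ndarray, y: np.ndarray) -> CopRecording:
    """Copy of ``rec`` with new coordinate series (mask and metadata kept)."""
    return CopRecording(fs=rec.fs, x=x, y=y, valid_mask=rec.valid_mask,
                        subject=rec.subject)
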