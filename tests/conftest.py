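import numpy as np
import pytest

from copsway.io import CopRecording, SubjectMeta
from copsway.preprocess import PreprocessConfig, ProcessedCop


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def subject():
    return SubjectMeta(id="test-infant", height=62.0, weight=6340.0)


@pytest.fixture
def short_cfg():
    """Preprocess config for fast tests: 1 s lead + 10 s window at 50 Hz."""
    return PreprocessConfig(trim_lead=1.0, analysis_window=10.0)


def make_recording(x, y, fs=50.0, subject=None):
    return CopRecording(fs=fs, x=np.asarray(x, float), y=np.asarray(y, float),
                        subject=subject or SubjectMeta())


def make_processed(x, y, fs=50.0, subject=None):
    return ProcessedCop(fs=fs, x=np.asarray(x, float), y=np.asarray(y, float),
                        subject=subject or SubjectMeta())


@pytest.fixture
def random_processed(rng, subject):
    """600-sample smooth random planar trajectory (mm scale)."""
    n = 600
    t = np.arange(n) / 50.0
    x = 10 * np.sin(2 * np.pi * 0.7 * t) + rng.normal(0, 1.5, n)
    y = 8 * np.cos(2 * np.pi * 1.1 * t) + rng.normal(0, 1.5, n)
    return make_processed(x, y, subject=subject)
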