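import numpy as np
import pytest

from crowdstress.scoring import PhysioStream, ScoringParams
from crowdstress.synthetic import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def params() -> ScoringParams:
    return ScoringParams()


@pytest.fixture(scope="session")
def small_bundles():
    """Two full sessions of the default protocol (all streams fabricated)."""
    return generate_scenario(ScenarioConfig(n_participants=2, seed=42))


def make_window(
    amplitude: float = 0.0,
    rise_s: float = 3.0,
    st_slope: float = 0.0,
    fs: float = 4.0,
    window_s: int = 8,
    tonic: float = 2.0,
    trough_at_s: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Engineered GSR/ST window: linear GSR rise of ``amplitude`` µS over
    ``rise_s`` seconds starting at ``trough_at_s``, constant-slope ST."""
    n = int(window_s * fs)
    t = np.arange(n) / fs
    gsr = np.full(n, tonic)
    if amplitude > 0:
        frac = np.clip((t - trough_at_s) / rise_s, 0.0, 1.0)
        gsr = tonic + amplitude * frac
    st = 33.0 + st_slope * t
    return gsr, st


def flat_streams(seconds: int = 60, fs: float = 4.0, start: float = 1_636_700_000.0):
    n = int(seconds * fs)
    gsr = PhysioStream("GSR", start, fs, np.full(n, 2.0))
    st = PhysioStream("ST", start, fs, np.full(n, 33.0))
    return gsr, st
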