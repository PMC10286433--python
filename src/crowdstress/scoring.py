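"""Per-second physiological change score from skin conductance and skin temperature.

The change score (CS) quantifies momentary sympathetic arousal from two
wearable channels: galvanic skin response (GSR, µS) rises and skin
temperature (ST, °C) falls when a stress response occurs.  Four rules are
evaluated on a trailing window ending at each second:

* R1 — GSR amplitude increase (trough-to-peak, µS)
* R2 — skin-temperature decrease (least-squares slope, °C/s)
* R3 — GSR rising time (trough-to-peak elapsed time, s)
* R4 — GSR response slope (amplitude / rising time, µS/s)

Each rule is scored on a ternary scale: 1 for complete fulfilment, 0.5 for
partial fulfilment, 0 otherwise.  The change score for the second is the
weighted sum ``CS = Σ wn·sn``; with the default weights of 20 per rule it
is continuous per second and ranges from 0 to 80 (all rules scored 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

from .errors import ConfigError, FormatError

__all__ = [
    "PhysioStream",
    "ScoringParams",
    "RuleScores",
    "preprocess",
    "evaluate_rules",
    "change_score",
    "score_session",
    "score_segments",
]

#: physiologically plausible validity ranges per channel (unit of the channel)
VALID_RANGE = {"GSR": (0.01, 100.0), "ST": (20.0, 40.0)}


@dataclass
class PhysioStream:
    """One raw wearable channel.

    Attributes
    ----------
    channel : str
        ``"GSR"`` (skin conductance, µS) or ``"ST"`` (skin temperature, °C).
    start_epoch : float
        Epoch seconds (UTC) of the first sample.
    fs : float
        Sampling rate in Hz.
    samples : numpy.ndarray
        Ordered sample values; NaN marks a missing sample before preprocessing.
    """

    channel: str
    start_epoch: float
    fs: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.channel not in VALID_RANGE:
            raise ConfigError(f"channel must be one of {sorted(VALID_RANGE)}, got {self.channel!r}")
        if not self.fs > 0:
            raise ConfigError(f"fs must be > 0, got {self.fs}")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ConfigError("samples must be non-empty")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def times(self) -> np.ndarray:
        return self.start_epoch + np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class ScoringParams:
    """Rule thresholds and weights for the change score.

    Defaults: equal weights of 20 per rule (max CS = 80 over four rules),
    an 8 s evaluation window, and amplitude/slope/rise-time thresholds with
    a partial and a stricter complete level per rule.  R2 fires on slopes at
    or below its (negative) thresholds.
    """

    w1: float = 20.0
    w2: float = 20.0
    w3: float = 20.0
    w4: float = 20.0
    window_s: int = 8
    r1_amp_partial: float = 0.05
    r1_amp_full: float = 0.10
    r2_slope_partial: float = -0.002
    r2_slope_full: float = -0.005
    r3_rise_full: tuple[float, float] = (1.0, 5.0)
    r4_slope_partial: float = 0.01
    r4_slope_full: float = 0.02

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ConfigError("window_s must be > 0")
        if not (0 < self.r1_amp_partial < self.r1_amp_full):
            raise ConfigError("r1 thresholds: need 0 < partial < full")
        if not (self.r2_slope_full < self.r2_slope_partial < 0):
            raise ConfigError("r2 thresholds: need full < partial < 0")
        if not (0 < self.r4_slope_partial < self.r4_slope_full):
            raise ConfigError("r4 thresholds: need 0 < partial < full")
        lo, hi = self.r3_rise_full
        if not (0 < lo < hi <= self.window_s):
            raise ConfigError("r3_rise_full must lie within (0, window_s]")

    @property
    def weights(self) -> np.ndarray:
        return np.array([self.w1, self.w2, self.w3, self.w4])

    @property
    def max_score(self) -> float:
        return float(self.weights.sum())

    def to_dict(self) -> dict:
        d = asdict(self)
        d["r3_rise_full"] = list(self.r3_rise_full)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScoringParams":
        d = dict(d)
        if "r3_rise_full" in d:
            d["r3_rise_full"] = tuple(d["r3_rise_full"])
        return cls(**d)


@dataclass(frozen=True)
class RuleScores:
    """Ternary fulfilment scores of R1–R4 at one second."""

    t: float
    s1: float
    s2: float
    s3: float
    s4: float

    def __post_init__(self) -> None:
        for s in (self.s1, self.s2, self.s3, self.s4):
            if s not in (0.0, 0.5, 1.0):
                raise ConfigError(f"rule scores must be in {{0, 0.5, 1}}, got {s}")

    def as_array(self) -> np.ndarray:
        return np.array([self.s1, self.s2, self.s3, self.s4])


# ---------------------------------------------------------------------------
# preprocessing

def _resample(samples: np.ndarray, fs: float, expected_fs: float) -> np.ndarray:
    """Rational-ratio resampling; NaNs are not expected here (only used on raw data
    where gaps are still encoded as NaN — those are interpolated per-segment later,
    so resampling with NaNs present would smear them; we forbid it)."""
    frac = Fraction(expected_fs / fs).limit_denominator(1000)
    if abs(float(frac) - expected_fs / fs) > 1e-9:
        raise FormatError(
            f"cannot resample {fs} Hz to {expected_fs} Hz by a rational factor"
        )
    if np.isnan(samples).any():
        raise FormatError("cannot resample a stream that still contains missing samples")
    return resample_poly(samples, frac.numerator, frac.denominator, padtype="line")


def preprocess(stream: PhysioStream, expected_fs: float) -> list[PhysioStream]:
    """Validate and clean one channel.

    Steps: resample to ``expected_fs`` if needed; blank samples outside the
    channel's physiological validity range (GSR 0.01–100 µS, ST 20–40 °C);
    linearly interpolate gaps of at most 2 s; split the stream at longer
    gaps; apply a 1 s centred moving average.

    Returns a list of contiguous clean segments (usually one).
    """
    x = stream.samples.copy()
    fs = stream.fs
    if not math.isclose(fs, expected_fs, rel_tol=1e-9):
        x = _resample(x, fs, expected_fs)
        fs = expected_fs

    lo, hi = VALID_RANGE[stream.channel]
    x[(x < lo) | (x > hi)] = np.nan
    if np.isnan(x).all():
        raise FormatError(f"{stream.channel} stream entirely out of range [{lo}, {hi}]")

    max_gap = int(round(2 * fs))  # gaps longer than 2 s split the stream
    segments: list[PhysioStream] = []
    isnan = np.isnan(x)
    # split points: runs of NaN longer than max_gap
    boundaries = [0]
    i = 0
    n = x.size
    cut_spans = []
    while i < n:
        if isnan[i]:
            j = i
            while j < n and isnan[j]:
                j += 1
            if j - i > max_gap:
                cut_spans.append((i, j))
            i = j
        else:
            i += 1
    prev = 0
    spans = []
    for a, b in cut_spans:
        if a > prev:
            spans.append((prev, a))
        prev = b
    if prev < n:
        spans.append((prev, n))

    win = max(1, int(round(fs)))  # 1 s smoothing window
    for a, b in spans:
        seg = x[a:b]
        good = ~np.isnan(seg)
        if good.sum() == 0:
            continue
        idx = np.arange(seg.size)
        seg = np.interp(idx, idx[good], seg[good])  # short gaps + edges
        seg = (
            pd.Series(seg).rolling(win, center=True, min_periods=1).mean().to_numpy()
        )
        segments.append(
            PhysioStream(stream.channel, stream.start_epoch + a / fs, fs, seg)
        )
    return segments


# ---------------------------------------------------------------------------
# rule evaluation (vectorised core; scalar API wraps it)

def _ternary(values: np.ndarray, partial: float, full: float) -> np.ndarray:
    """Score 1 where ``values >= full``, 0.5 where ``>= partial``, else 0."""
    return np.where(values >= full, 1.0, np.where(values >= partial, 0.5, 0.0))


def _rule_matrix(gsr_w: np.ndarray, st_w: np.ndarray, fs: float, params: ScoringParams) -> np.ndarray:
    """Evaluate R1–R4 on stacked windows.

    Parameters are (m, L) arrays of m windows of L samples.  Returns an
    (m, 4) array of ternary scores.
    """
    g = np.atleast_2d(np.asarray(gsr_w, dtype=float))
    s = np.atleast_2d(np.asarray(st_w, dtype=float))
    m, L = g.shape
    rows = np.arange(m)

    i_peak = np.argmax(g, axis=1)
    cummin = np.minimum.accumulate(g, axis=1)
    # last index attaining the running minimum (ties -> latest trough, i.e. shortest rise)
    at_min = g <= cummin
    idx = np.where(at_min, np.arange(L)[None, :], -1)
    trough_at = np.maximum.accumulate(idx, axis=1)
    i_trough = trough_at[rows, i_peak]

    amp = g[rows, i_peak] - cummin[rows, i_peak]
    rise = (i_peak - i_trough) / fs

    # least-squares ST slope over the window
    t = np.arange(L) / fs
    tc = t - t.mean()
    ssx = float(tc @ tc)
    slope_st = (s @ tc) / ssx if ssx > 0 else np.zeros(m)

    s1 = _ternary(amp, params.r1_amp_partial, params.r1_amp_full)
    # R2 fires on decreases: slope at or below the (negative) thresholds
    s2 = _ternary(-slope_st, -params.r2_slope_partial, -params.r2_slope_full)
    lo, hi = params.r3_rise_full
    s3 = np.where(
        (rise >= lo) & (rise <= hi),
        1.0,
        np.where((rise > hi) & (rise <= params.window_s), 0.5, 0.0),
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(rise > 0, amp / np.where(rise > 0, rise, 1.0), 0.0)
    s4 = _ternary(ratio, params.r4_slope_partial, params.r4_slope_full)
    return np.column_stack([s1, s2, s3, s4])


def evaluate_rules(
    gsr_window: np.ndarray,
    st_window: np.ndarray,
    params: ScoringParams = ScoringParams(),
    fs: float = 4.0,
    t: float = 0.0,
) -> RuleScores:
    """Score one window of length ``window_s`` seconds at ``fs`` Hz.

    R1 uses the trough-to-peak GSR amplitude, R2 the least-squares ST slope,
    R3 the trough-to-peak elapsed time, R4 the amplitude/rise-time ratio.
    """
    need = int(round(params.window_s * fs))
    gsr_window = np.asarray(gsr_window, dtype=float)
    st_window = np.asarray(st_window, dtype=float)
    if gsr_window.size < need or st_window.size < need:
        raise ConfigError(
            f"window must contain at least {need} samples ({params.window_s} s at {fs} Hz)"
        )
    s1, s2, s3, s4 = _rule_matrix(gsr_window[None, :], st_window[None, :], fs, params)[0]
    return RuleScores(t=t, s1=float(s1), s2=float(s2), s3=float(s3), s4=float(s4))


def change_score(scores: RuleScores, params: ScoringParams = ScoringParams()) -> float:
    """Weighted change score ``CS = Σ wn·sn`` for one second."""
    return float(params.weights @ scores.as_array())


# ---------------------------------------------------------------------------
# session scoring

def score_session(
    gsr: PhysioStream,
    st: PhysioStream,
    params: ScoringParams = ScoringParams(),
) -> pd.DataFrame:
    """Per-second rule scores and change score over the overlap of two streams.

    Both streams must be preprocessed and share a sampling rate.  Each
    second's scores are computed on the trailing window of ``window_s``
    seconds ending at that second; the first ``window_s − 1`` seconds of the
    overlap carry insufficient history and yield no record.

    Returns a DataFrame with columns ``t, s1..s4, CS``.
    """
    if not math.isclose(gsr.fs, st.fs, rel_tol=1e-9):
        raise ConfigError(f"sampling rates differ: GSR {gsr.fs} Hz vs ST {st.fs} Hz")
    fs = gsr.fs
    spp = int(round(fs))
    if abs(spp - fs) > 1e-9:
        raise ConfigError(f"per-second alignment requires an integer rate, got {fs}")

    t0 = max(gsr.start_epoch, st.start_epoch)
    t1 = min(gsr.start_epoch + gsr.duration_s, st.start_epoch + st.duration_s)
    if t1 - t0 < params.window_s:
        raise FusionOverlapError(gsr, st, t0, t1, params.window_s)

    def crop(stream: PhysioStream) -> np.ndarray:
        off = int(round((t0 - stream.start_epoch) * fs))
        length = int(math.floor((t1 - t0) * fs))
        return stream.samples[off : off + length]

    g = crop(gsr)
    s = crop(st)
    n_sec = min(g.size, s.size) // spp
    win = params.window_s
    if n_sec < win:
        raise FusionOverlapError(gsr, st, t0, t1, win)
    L = win * spp
    gw = np.lib.stride_tricks.sliding_window_view(g[: n_sec * spp], L)[::spp]
    sw = np.lib.stride_tricks.sliding_window_view(s[: n_sec * spp], L)[::spp]
    m = n_sec - win + 1
    gw, sw = gw[:m], sw[:m]
    scores = _rule_matrix(gw, sw, fs, params)
    cs = scores @ params.weights
    # record timestamp = the second the trailing window ends at
    tt = t0 + win - 1 + np.arange(m)
    return pd.DataFrame(
        {"t": tt, "s1": scores[:, 0], "s2": scores[:, 1], "s3": scores[:, 2],
         "s4": scores[:, 3], "CS": cs}
    )


class FusionOverlapError(ConfigError):
    def __init__(self, gsr, st, t0, t1, win):
        super().__init__(
            f"streams overlap for {max(0.0, t1 - t0):.1f} s but the scoring window "
            f"needs {win} s (GSR starts {gsr.start_epoch}, ST starts {st.start_epoch})"
        )


def score_segments(
    gsr_segments: list[PhysioStream],
    st_segments: list[PhysioStream],
    params: ScoringParams = ScoringParams(),
) -> pd.DataFrame:
    """Score every overlapping (GSR, ST) segment pair and concatenate."""
    out = []
    for g in gsr_segments:
        for s in st_segments:
            t0 = max(g.start_epoch, s.start_epoch)
            t1 = min(g.start_epoch + g.duration_s, s.start_epoch + s.duration_s)
            if t1 - t0 >= params.window_s:
                out.append(score_session(g, s, params))
    if not out:
        raise ConfigError("no segment pair overlaps long enough to score")
    df = pd.concat(out, ignore_index=True).sort_values("t")
    return df.drop_duplicates(subset="t", keep="first").reset_index(drop=True)
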