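"""Synthetic walk scenarios with known ground truth.

The study protocol this generator emulates: participants walk a guided
route through four urban sites (green, transit, commercial, blue space),
spending 20 minutes at each site — 5 minutes sitting, then 15 minutes
walking — while a wrist sensor records skin conductance and skin
temperature at 4 Hz, a chest camera yields one detection frame per second,
and a phone logs GPS.  The original field data are confidential, so every
stream is simulated here with the statistical structure the downstream
analysis assumes:

* per-frame crowd/object counts are Poisson with site- and zone-specific
  intensities;
* the ground-truth change score follows a linear mixed model —
  ``CS* = μ + Σ βj·countj + b_person + b_timeslot + b_gender + ε`` — with
  configurable true effects and random-intercept standard deviations;
* skin-conductance responses (linear rise, exponential decay) and
  event-locked temperature dips are injected at stressful moments, coupled
  to personal-space intrusions, so the rule-based scorer fires at them.

Everything is driven by one integer seed; identical config + seed yields
bit-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely

from shapely.geometry import Polygon

from .errors import ConfigError
from .fusion import GpsTrack
from .geo import metres_to_degrees
from .proxemics import COUNT_COLUMNS, Detection, FrameDetections, ZoneThresholds
from .scoring import PhysioStream

__all__ = [
    "SiteSpec",
    "ScrEvent",
    "EventCoupling",
    "ScenarioConfig",
    "SessionBundle",
    "SessionTruth",
    "default_site_specs",
    "generate_scenario",
    "simulate_physio",
    "simulate_detections",
]

ZONE_KEYS = ("personal", "close", "medium", "far")
OBJECT_KEYS = ("motor_vehicles", "bikes", "sitting_facilities")

_OBJECT_LABELS = {
    "motor_vehicles": ("car", "bus", "truck", "motorcycle"),
    "bikes": ("bicycle",),
    "sitting_facilities": ("chair", "bench", "dining table"),
}


@dataclass(frozen=True)
class SiteSpec:
    """One study site: polygon, context label and Poisson count intensities.

    ``crowd_intensity`` maps proxemics zone (personal/close/medium/far) to
    the mean number of persons per frame in that zone;
    ``object_intensity`` does the same for the three non-person predictors.
    """

    name: str
    context: str
    polygon: tuple[tuple[float, float], ...]  # (lon, lat) ring
    crowd_intensity: dict
    object_intensity: dict

    def __post_init__(self) -> None:
        if self.context not in {"green", "transit", "commercial", "blue"}:
            raise ConfigError(f"site_specs[{self.name}].context invalid: {self.context!r}")
        for key in ZONE_KEYS:
            if self.crowd_intensity.get(key, 0.0) < 0:
                raise ConfigError(f"site_specs[{self.name}].crowd_intensity[{key}] must be >= 0")
        for key in OBJECT_KEYS:
            if self.object_intensity.get(key, 0.0) < 0:
                raise ConfigError(f"site_specs[{self.name}].object_intensity[{key}] must be >= 0")
        poly = self.shape()
        if not poly.is_valid:
            raise ConfigError(f"site_specs[{self.name}].polygon is not a valid simple ring")

    def shape(self) -> Polygon:
        return Polygon(self.polygon)


@dataclass(frozen=True)
class ScrEvent:
    """One injected skin-conductance response with its temperature dip.

    The phasic kernel rises linearly over ``rise_time`` seconds to
    ``amplitude`` µS above the tonic level and decays exponentially with
    time constant ``decay_tau``; skin temperature dips by ``st_dip`` °C with
    the same time course.
    """

    onset: float
    amplitude: float
    rise_time: float
    decay_tau: float
    st_dip: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ConfigError("ScrEvent.amplitude must be > 0")
        if self.rise_time <= 0:
            raise ConfigError("ScrEvent.rise_time must be > 0")
        if self.decay_tau <= 0:
            raise ConfigError("ScrEvent.decay_tau must be > 0")
        if self.st_dip < 0:
            raise ConfigError("ScrEvent.st_dip must be >= 0")


@dataclass(frozen=True)
class EventCoupling:
    """How personal-space intrusions trigger skin-conductance responses.

    The per-second trigger probability is
    ``min(cap, rate_per_beta · β_personal · count)`` so a zero true effect
    produces no coupled events; spontaneous background responses occur at
    ``background_rate`` per second regardless.
    """

    rate_per_beta: float = 0.06
    cap: float = 0.8
    background_rate: float = 1.0 / 120.0
    amp_range: tuple[float, float] = (0.12, 0.35)
    rise_range: tuple[float, float] = (2.0, 4.0)
    decay_range: tuple[float, float] = (3.0, 6.0)
    dip_range: tuple[float, float] = (0.05, 0.15)


def _default_intensities(context: str) -> tuple[dict, dict]:
    crowd = {
        "green": {"personal": 0.10, "close": 0.20, "medium": 0.60, "far": 1.20},
        "transit": {"personal": 0.20, "close": 0.40, "medium": 1.00, "far": 2.00},
        "commercial": {"personal": 0.30, "close": 0.50, "medium": 1.20, "far": 2.50},
        "blue": {"personal": 0.10, "close": 0.20, "medium": 0.50, "far": 1.00},
    }[context]
    objects = {
        "green": {"motor_vehicles": 0.10, "bikes": 0.20, "sitting_facilities": 0.40},
        "transit": {"motor_vehicles": 0.80, "bikes": 0.30, "sitting_facilities": 0.10},
        "commercial": {"motor_vehicles": 0.30, "bikes": 0.50, "sitting_facilities": 0.30},
        "blue": {"motor_vehicles": 0.20, "bikes": 0.30, "sitting_facilities": 0.20},
    }[context]
    return crowd, objects


def _rect(lat: float, lon: float, half_m: float = 90.0) -> tuple[tuple[float, float], ...]:
    dlat, dlon = metres_to_degrees(half_m, half_m, lat)
    return (
        (lon - dlon, lat - dlat),
        (lon + dlon, lat - dlat),
        (lon + dlon, lat + dlat),
        (lon - dlon, lat + dlat),
        (lon - dlon, lat - dlat),
    )


def default_site_specs() -> list[SiteSpec]:
    """Four sites mirroring the study route through central Salzburg:
    a garden (green), the city centre (transit), a shopping street
    (commercial) and the river bank (blue)."""
    centres = [
        ("mirabellgarten", "green", 47.8053, 13.0420),
        ("city_centre", "transit", 47.8020, 13.0440),
        ("getreidegasse", "commercial", 47.7995, 13.0410),
        ("salzach", "blue", 47.8005, 13.0460),
    ]
    specs = []
    for name, context, lat, lon in centres:
        crowd, objects = _default_intensities(context)
        specs.append(
            SiteSpec(
                name=name,
                context=context,
                polygon=_rect(lat, lon),
                crowd_intensity=crowd,
                object_intensity=objects,
            )
        )
    return specs


def _default_effects() -> dict:
    # personal-space effect defaults to the magnitude the method targets in
    # recovery tests; all other predictors default to no effect
    eff = dict.fromkeys(COUNT_COLUMNS, 0.0)
    eff["persons_personal"] = 3.85
    return eff


@dataclass
class ScenarioConfig:
    """Full specification of a synthetic multi-participant scenario."""

    n_participants: int = 20
    timeslots: tuple[str, ...] = ("9-12", "13-16")
    site_specs: list[SiteSpec] = field(default_factory=default_site_specs)
    physio_fs: float = 4.0
    frame_rate: float = 1.0
    sit_minutes: float = 5.0
    walk_minutes: float = 15.0
    true_effects: dict = field(default_factory=_default_effects)
    cs_baseline: float = 10.0
    random_intercept_sd: dict = field(
        default_factory=lambda: {"person": 5.3, "timeslot": 0.0, "gender": 0.0}
    )
    residual_sd: float = 16.0
    seed: int = 0
    start_epoch: float = 1_637_917_200.0  # 2021-11-26 09:00 UTC
    gps_jitter_m: float = 2.0
    ar1_rho: float = 0.0  # AR(1) on log crowd intensity; 0 = independent frames
    image_size: tuple[int, int] = (1280, 720)
    coupling: EventCoupling = field(default_factory=EventCoupling)

    def validate(self) -> None:
        if self.n_participants < 0:
            raise ConfigError("n_participants must be >= 0")
        if not self.timeslots:
            raise ConfigError("timeslots must be non-empty")
        if not self.site_specs:
            raise ConfigError("site_specs must be non-empty")
        if self.physio_fs <= 0:
            raise ConfigError("physio_fs must be > 0")
        if self.frame_rate <= 0:
            raise ConfigError("frame_rate must be > 0")
        if self.sit_minutes + self.walk_minutes <= 0:
            raise ConfigError("sit_minutes + walk_minutes must be > 0")
        if self.residual_sd < 0:
            raise ConfigError("residual_sd must be >= 0")
        for key, sd in self.random_intercept_sd.items():
            if sd < 0:
                raise ConfigError(f"random_intercept_sd[{key}] must be >= 0")
        for key in self.true_effects:
            if key not in COUNT_COLUMNS:
                raise ConfigError(f"true_effects key {key!r} is not a predictor column")
        if not -1 < self.ar1_rho < 1:
            raise ConfigError("ar1_rho must be in (-1, 1)")

    @property
    def site_seconds(self) -> int:
        return int(round((self.sit_minutes + self.walk_minutes) * 60))

    @property
    def session_seconds(self) -> int:
        return self.site_seconds * len(self.site_specs)

    def beta_vector(self) -> np.ndarray:
        return np.array([self.true_effects.get(c, 0.0) for c in COUNT_COLUMNS])


@dataclass
class SessionTruth:
    """Ground truth of one session: per-second records and injected events.

    ``records`` has one row per frame second with the site label, the seven
    true predictor counts and the model-level change score ``cs_true`` drawn
    from the linear mixed model.  ``intercepts`` stores the realised random
    intercepts; ``events`` every injected skin-conductance response.
    """

    records: pd.DataFrame
    events: list[ScrEvent]
    intercepts: dict
    true_effects: dict


@dataclass
class SessionBundle:
    """Everything one participant's session produced."""

    participant_id: str
    timeslot: str
    gender: str
    gsr: PhysioStream | None
    st: PhysioStream | None
    frames: list[FrameDetections]
    track: GpsTrack
    truth: SessionTruth


# ---------------------------------------------------------------------------
# physiology

def simulate_physio(
    events: list[ScrEvent],
    duration_s: float,
    fs: float,
    tonic_level: float = 2.0,
    drift: float = 0.0,
    noise_sd: float = 0.0,
    st_baseline: float = 33.0,
    start_epoch: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[PhysioStream, PhysioStream]:
    """Simulate a GSR/ST stream pair with phasic responses on a tonic base.

    GSR = tonic + drift·t + Σ event kernels + N(0, noise_sd); each kernel
    rises linearly over the event's rise time to its amplitude, then decays
    exponentially.  ST = baseline − event-locked dips (same time course)
    + noise.  Event onsets are relative to the stream start and must lie in
    ``[0, duration_s]``.
    """
    if fs <= 0:
        raise ConfigError("fs must be > 0")
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    for ev in events:
        if not 0 <= ev.onset <= duration_s:
            raise ConfigError(
                f"event onset {ev.onset} outside the stream duration [0, {duration_s}]"
            )
    gsr = tonic_level + drift * t
    st = np.full(n, st_baseline)
    for ev in events:
        i0 = int(np.ceil((ev.onset) * fs))
        if i0 >= n:
            continue
        tau = t[i0:] - ev.onset
        kern = np.where(
            tau < ev.rise_time,
            tau / ev.rise_time,
            np.exp(-(tau - ev.rise_time) / ev.decay_tau),
        )
        gsr[i0:] += ev.amplitude * kern
        st[i0:] -= ev.st_dip * kern
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        gsr = gsr + rng.normal(0.0, noise_sd, n)
        st = st + rng.normal(0.0, noise_sd, n)
    return (
        PhysioStream("GSR", start_epoch, fs, gsr),
        PhysioStream("ST", start_epoch, fs, st),
    )


# ---------------------------------------------------------------------------
# detections

def _site_index_per_point(x: np.ndarray, y: np.ndarray, specs: list[SiteSpec]) -> np.ndarray:
    """Index of the covering site polygon per (lon, lat) point, −1 for transit."""
    idx = np.full(x.size, -1, dtype=int)
    for i, spec in enumerate(specs):
        hit = shapely.contains_xy(spec.shape(), x, y) | shapely.intersects_xy(
            spec.shape().boundary, x, y
        )
        idx[(idx == -1) & hit] = i
    return idx


def _person_geometry(zone: str, rng: np.random.Generator, W: int, H: int) -> Detection:
    """Fabricate a person box + mask fraction that classify_zone maps back to
    ``zone`` (kept strictly inside the threshold bands)."""
    if zone == "personal":
        frac = rng.uniform(0.12, 0.35)
        height = rng.uniform(0.5, 0.9) * H
        d = rng.uniform(0.0, 4.0)
    else:
        if zone == "close":
            d = rng.uniform(0.5, 4.5)
            height = rng.uniform(0.3, 0.6) * H
        elif zone == "medium":
            d = rng.uniform(6.0, 99.0)
            height = rng.uniform(0.15, 0.4) * H
        else:  # far
            d = rng.uniform(101.0, 290.0)
            height = rng.uniform(0.03, 0.12) * H
        frac = min(0.08, 0.6 * height * 0.4 * height / (W * H))
        frac = max(frac, 0.003)
    height = min(height, H - d)
    y_top = H - d - height
    width = min(0.45 * height, W * 0.4)
    x_left = rng.uniform(0, W - width)
    return Detection(
        label="person",
        box=(x_left, y_top, width, height),
        mask_fraction=frac,
        confidence=rng.uniform(0.6, 0.99),
    )


def _object_detection(column: str, rng: np.random.Generator, W: int, H: int) -> Detection:
    label = rng.choice(_OBJECT_LABELS[column])
    height = rng.uniform(0.05, 0.3) * H
    width = rng.uniform(0.8, 2.0) * height
    width = min(width, W * 0.5)
    y_top = rng.uniform(0.3 * H, H - height)
    x_left = rng.uniform(0, W - width)
    return Detection(
        label=str(label),
        box=(x_left, y_top, width, height),
        mask_fraction=min(0.08, 0.5 * width * height / (W * H)),
        confidence=rng.uniform(0.6, 0.99),
    )


def simulate_detections(
    track: GpsTrack,
    site_specs: list[SiteSpec],
    frame_rate: float,
    coupling_effects: dict | None = None,
    coupling: EventCoupling = EventCoupling(),
    ar1_rho: float = 0.0,
    image_size: tuple[int, int] = (1280, 720),
    rng: np.random.Generator | None = None,
    fabricate: bool = True,
) -> tuple[list[FrameDetections], pd.DataFrame, list[ScrEvent]]:
    """Fabricate per-frame detections along a GPS track.

    Per frame, the covering site's Poisson intensities generate true counts
    per category/zone; geometrically consistent detections are fabricated
    for each count (personal-zone persons get a mask fraction above the
    personal threshold, the other zones get ``|Yi − h|`` inside their pixel
    band).  Frames with personal-space persons trigger skin-conductance
    events with probability scaled by the personal-space true effect.

    Returns ``(frames, truth_counts, events)``; event onsets are seconds
    relative to the first frame.
    """
    if rng is None:
        rng = np.random.default_rng()
    beta_personal = (coupling_effects or {}).get("persons_personal", 0.0)
    W, H = image_size

    t0 = math.ceil(track.t[0])
    n_frames = int(math.floor((track.t[-1] - t0) * frame_rate)) + 1
    times = t0 + np.arange(n_frames) / frame_rate
    lat = np.interp(times, track.t, track.lat)
    lon = np.interp(times, track.t, track.lon)
    site_idx = _site_index_per_point(lon, lat, site_specs)

    n = times.size
    lam = np.zeros((n, 7))
    for i, spec in enumerate(site_specs):
        mask = site_idx == i
        for j, key in enumerate(ZONE_KEYS):
            lam[mask, j] = spec.crowd_intensity.get(key, 0.0)
        for j, key in enumerate(OBJECT_KEYS):
            lam[mask, 4 + j] = spec.object_intensity.get(key, 0.0)
    if ar1_rho != 0.0:
        # optional temporal autocorrelation on the log intensity
        sd = 0.3
        eps = rng.normal(0.0, sd * math.sqrt(1 - ar1_rho**2), size=(n, 7))
        z = np.empty((n, 7))
        z[0] = rng.normal(0.0, sd, size=7)
        for k in range(1, n):
            z[k] = ar1_rho * z[k - 1] + eps[k]
        lam = lam * np.exp(z - sd**2 / 2)
    counts = rng.poisson(lam)

    frames: list[FrameDetections] = []
    events: list[ScrEvent] = []
    for k in range(n if fabricate else 0):
        dets: list[Detection] = []
        for j, zone in enumerate(ZONE_KEYS):
            for _ in range(counts[k, j]):
                dets.append(_person_geometry(zone, rng, W, H))
        for j, col in enumerate(OBJECT_KEYS):
            for _ in range(counts[k, 4 + j]):
                dets.append(_object_detection(col, rng, W, H))
        frames.append(
            FrameDetections(
                frame_id=k, timestamp=float(times[k]), image_width=W, image_height=H,
                detections=dets,
            )
        )
        p_event = coupling.background_rate / frame_rate
        if counts[k, 0] > 0 and beta_personal > 0:
            p_event += min(coupling.cap, coupling.rate_per_beta * beta_personal * counts[k, 0])
        if rng.random() < p_event:
            events.append(
                ScrEvent(
                    onset=float(times[k] - times[0]),
                    amplitude=float(rng.uniform(*coupling.amp_range)),
                    rise_time=float(rng.uniform(*coupling.rise_range)),
                    decay_tau=float(rng.uniform(*coupling.decay_range)),
                    st_dip=float(rng.uniform(*coupling.dip_range)),
                )
            )

    site_names = np.array([s.name for s in site_specs] + ["transit"], dtype=object)
    truth = pd.DataFrame(counts, columns=list(COUNT_COLUMNS))
    truth.insert(0, "t", times)
    truth.insert(1, "site", site_names[site_idx])
    truth["lat"] = lat
    truth["lon"] = lon
    return frames, truth, events


# ---------------------------------------------------------------------------
# route

def _site_waypoints(spec: SiteSpec, sit_s: float, walk_s: float, t0: float) -> list[tuple[float, float, float]]:
    """(t, lon, lat) waypoints: sit at the centroid, then loop an inset ring."""
    poly = spec.shape()
    c = poly.centroid
    ring = poly.buffer(-0.25 * math.sqrt(poly.area)).exterior
    if ring is None or ring.length == 0:
        ring = poly.exterior
    pts = [(t0, c.x, c.y), (t0 + sit_s, c.x, c.y)]
    n_lap = max(4, int(walk_s // 60))
    for i in range(1, n_lap + 1):
        frac = (i / n_lap * 2.0) % 1.0  # two laps around the ring
        p = ring.interpolate(frac, normalized=True)
        pts.append((t0 + sit_s + walk_s * i / n_lap, p.x, p.y))
    return pts


def _session_track(
    config: ScenarioConfig, start: float, rng: np.random.Generator
) -> GpsTrack:
    sit_s = config.sit_minutes * 60
    walk_s = config.walk_minutes * 60
    waypoints: list[tuple[float, float, float]] = []
    t = start
    for spec in config.site_specs:
        waypoints.extend(_site_waypoints(spec, sit_s, walk_s, t))
        t += sit_s + walk_s
    wt = np.array([w[0] for w in waypoints])
    wlon = np.array([w[1] for w in waypoints])
    wlat = np.array([w[2] for w in waypoints])
    tt = np.arange(start, start + config.session_seconds)
    lon = np.interp(tt, wt, wlon)
    lat = np.interp(tt, wt, wlat)
    if config.gps_jitter_m > 0:
        lat0 = float(np.mean(lat))
        dlat, dlon = metres_to_degrees(config.gps_jitter_m, config.gps_jitter_m, lat0)
        lat = lat + rng.normal(0.0, dlat, lat.size)
        lon = lon + rng.normal(0.0, dlon, lon.size)
    return GpsTrack(tt, lat, lon)


# ---------------------------------------------------------------------------
# scenario

def generate_scenario(config: ScenarioConfig, truth_only: bool = False) -> list[SessionBundle]:
    """Generate one bundle per participant with full ground truth.

    Each bundle spans all sites in order with the configured sit/walk
    durations; physiology is sampled at ``physio_fs``, frames at
    ``frame_rate``.  Identical config + seed reproduces bit-identical
    bundles.

    With ``truth_only=True`` only the GPS track and the ground-truth record
    (counts, sites, model-level change score) are produced — physiology and
    detection geometry are skipped.  The random streams are split so the
    ground truth is identical in both modes.
    """
    config.validate()
    if config.n_participants == 0:
        return []
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_participants + 1)
    shared_rng = np.random.default_rng(children[0])

    sd = config.random_intercept_sd
    slot_b = {
        slot: shared_rng.normal(0.0, sd.get("timeslot", 0.0)) for slot in config.timeslots
    }
    gender_b = {g: shared_rng.normal(0.0, sd.get("gender", 0.0)) for g in ("female", "male")}
    beta = config.beta_vector()

    bundles: list[SessionBundle] = []
    for p in range(config.n_participants):
        seq_track, seq_scene, seq_model = children[p + 1].spawn(3)
        rng_track = np.random.default_rng(seq_track)
        rng_scene = np.random.default_rng(seq_scene)
        rng_model = np.random.default_rng(seq_model)
        pid = f"P{p + 1:02d}"
        slot = config.timeslots[p % len(config.timeslots)]
        gender = "female" if p % 2 == 0 else "male"
        slot_idx = config.timeslots.index(slot)
        start = config.start_epoch + slot_idx * 4 * 3600.0

        track = _session_track(config, start, rng_track)
        frames, truth, events = simulate_detections(
            track,
            config.site_specs,
            config.frame_rate,
            coupling_effects=config.true_effects,
            coupling=config.coupling,
            ar1_rho=config.ar1_rho,
            image_size=config.image_size,
            rng=rng_scene,
            fabricate=not truth_only,
        )

        b_person = rng_model.normal(0.0, sd.get("person", 0.0))
        intercepts = {
            "person": float(b_person),
            "timeslot": float(slot_b[slot]),
            "gender": float(gender_b[gender]),
        }
        counts = truth[list(COUNT_COLUMNS)].to_numpy()
        truth = truth.copy()
        truth["cs_true"] = (
            config.cs_baseline
            + counts @ beta
            + b_person
            + slot_b[slot]
            + gender_b[gender]
            + rng_model.normal(0.0, config.residual_sd, len(truth))
        )
        truth["participant_id"] = pid
        truth["timeslot"] = slot
        truth["gender"] = gender

        if truth_only:
            gsr = st = None
        else:
            gsr, st = simulate_physio(
                events,
                duration_s=config.session_seconds,
                fs=config.physio_fs,
                tonic_level=float(rng_scene.uniform(1.5, 4.0)),
                drift=float(rng_scene.uniform(-2e-5, 2e-5)),
                noise_sd=0.005,
                st_baseline=float(rng_scene.uniform(31.0, 34.0)),
                start_epoch=start,
                rng=rng_scene,
            )
        bundles.append(
            SessionBundle(
                participant_id=pid,
                timeslot=slot,
                gender=gender,
                gsr=gsr,
                st=st,
                frames=frames,
                track=track,
                truth=SessionTruth(
                    records=truth,
                    events=events,
                    intercepts=intercepts,
                    true_effects=dict(config.true_effects),
                ),
            )
        )
    return bundles
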