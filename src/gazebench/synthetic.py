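"""Synthetic free-viewing cohorts with known ground truth.

Emulates the museum free-viewing setup: each participant views a single
full-screen scene for 10 s while gaze is logged at 60 Hz with substantial
measurement noise and occasional data loss. The generative model is a
spatial mixture: a central component (early fixations are strongly drawn
to the screen centre, where participants start) plus a set of object-like
clusters over which later fixations disperse. Per-fixation-index mixture
weights implement the early-focal / late-dispersed ordering seen in real
free viewing.

Every participant comes with ground truth (the true fixation schedule and
demographics), so detection, exclusion, scoring and stratification can be
validated end to end without the original dataset.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .geometry import ScreenGeometry, STUDY_GEOMETRY

__all__ = [
    "Cluster",
    "SyntheticCohortConfig",
    "GazeRecording",
    "GroundTruth",
    "default_clusters",
    "draw_demographics",
    "simulate_participant",
    "simulate_cohort",
]


class InvalidConfigError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


# Age-bin composition of the credible-demographics sample: (low, high, count).
# Nine contiguous 6-year bins covering ages 6-59.
AGE_BIN_COUNTS: tuple[tuple[int, int, int], ...] = (
    (6, 11, 58),
    (12, 17, 149),
    (18, 23, 249),
    (24, 29, 431),
    (30, 35, 242),
    (36, 41, 164),
    (42, 47, 175),
    (48, 53, 97),
    (54, 59, 34),
)

GENDERS = ("man", "woman", "nonbinary")


@dataclass(frozen=True)
class Cluster:
    """An object-like attractor: isotropic Gaussian blob in dva units."""

    x_px: float
    y_px: float
    sd_dva: float = 1.5
    weight: float = 1.0


def default_clusters(geometry: ScreenGeometry = STUDY_GEOMETRY) -> tuple[Cluster, ...]:
    """Eight well-separated object clusters spread over the screen.

    Positions are fractions of the screen extents so the layout scales
    with geometry; weights vary to mimic unequally attractive objects.
    Pairwise separations exceed 5 dva on the study geometry, comfortably
    above the 1 dva merge scale of the downstream event post-processing.
    """
    frac = [
        (0.15, 0.25, 1.4),
        (0.40, 0.18, 1.0),
        (0.68, 0.22, 1.2),
        (0.88, 0.35, 0.8),
        (0.12, 0.70, 1.0),
        (0.35, 0.80, 1.3),
        (0.62, 0.72, 1.1),
        (0.85, 0.78, 0.9),
    ]
    return tuple(
        Cluster(fx * geometry.width_px, fy * geometry.height_px, 1.5, w)
        for fx, fy, w in frac
    )


@dataclass
class SyntheticCohortConfig:
    """Generative parameters for one synthetic cohort.

    The ordering schedule gives, for fixation index k = 1, 2, ..., the
    probability that the k-th fixation targets the central component:
    ``floor + w0 * exp(-(k - 1) / decay)``; the complement is shared by
    the clusters in proportion to their weights. ``group_bias`` multiplies
    the central-component odds for participants in the named demographic
    groups (gender values or age-bin labels such as ``"30-35"``).
    """

    n_participants: int = 100
    sample_rate_hz: float = 60.0
    viewing_duration_s: float = 10.0
    clusters: tuple[Cluster, ...] = field(default_factory=default_clusters)
    central_sd_dva: float = 3.0
    ordering_w0: float = 0.85
    ordering_decay: float = 2.0
    ordering_floor: float = 0.10
    fixation_median_ms: float = 250.0
    fixation_shape: float = 0.4
    saccade_samples: int = 3
    min_saccade_amplitude_dva: float = 2.0
    noise_rms_dva: float = 0.68
    loss_run_prob: float = 0.01  # per-second hazard of starting a loss run
    loss_run_length_s: float = 0.5  # mean loss-run length
    gender_proportions: dict[str, float] = field(
        default_factory=lambda: {"man": 0.556, "woman": 0.444}
    )
    age_bin_weights: tuple[tuple[int, int, int], ...] = AGE_BIN_COUNTS
    group_bias: dict[str, float] = field(default_factory=dict)
    survey_year: int = 2022
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise InvalidConfigError("n_participants must be >= 1")
        if self.sample_rate_hz <= 0 or self.viewing_duration_s <= 0:
            raise InvalidConfigError("sample rate and viewing duration must be positive")
        if not self.clusters:
            raise InvalidConfigError("at least one cluster is required")
        if any(c.sd_dva <= 0 for c in self.clusters) or self.central_sd_dva <= 0:
            raise InvalidConfigError("all spatial SDs must be positive")
        if self.fixation_median_ms <= 0 or self.fixation_shape <= 0:
            raise InvalidConfigError("fixation duration law must be positive")
        if self.noise_rms_dva < 0:
            raise InvalidConfigError("noise RMS must be non-negative")
        if not self.gender_proportions:
            raise InvalidConfigError("gender_proportions must not be empty")
        total = sum(self.gender_proportions.values())
        if total <= 0:
            raise InvalidConfigError("gender proportions must sum to a positive value")
        if not self.age_bin_weights:
            raise InvalidConfigError("age_bin_weights must not be empty")

    @classmethod
    def for_geometry(cls, geometry: ScreenGeometry, **kwargs) -> "SyntheticCohortConfig":
        """Config whose default cluster layout is placed on ``geometry``.

        The stock defaults position clusters on the study screen; use
        this when simulating on a different (e.g. down-scaled) screen.
        """
        kwargs.setdefault("clusters", default_clusters(geometry))
        return cls(**kwargs)

    # -- ordering schedule -------------------------------------------------

    def central_weight(self, index: int, bias: float = 1.0) -> float:
        """Central-component probability for fixation index (1-based).

        ``bias`` multiplies the central-vs-clusters odds, so bias = 2
        doubles the relative pull of the centre without leaving [0, 1).
        """
        w = self.ordering_floor + self.ordering_w0 * np.exp(
            -(index - 1) / self.ordering_decay
        )
        w = min(float(w), 0.98)
        if bias != 1.0:
            w = (bias * w) / (bias * w + (1.0 - w))
        return w

    def cluster_probs(self) -> np.ndarray:
        w = np.array([c.weight for c in self.clusters], dtype=float)
        return w / w.sum()

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["clusters"] = [dataclasses.asdict(c) for c in self.clusters]
        d["age_bin_weights"] = [list(b) for b in self.age_bin_weights]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticCohortConfig":
        d = dict(d)
        if "clusters" in d:
            d["clusters"] = tuple(Cluster(**c) for c in d["clusters"])
        if "age_bin_weights" in d:
            d["age_bin_weights"] = tuple(tuple(b) for b in d["age_bin_weights"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticCohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class GazeRecording:
    """One participant's raw gaze stream plus demographics."""

    participant_id: str
    t_ms: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    valid: np.ndarray
    demographics: dict | None = None

    def __post_init__(self) -> None:
        n = len(self.t_ms)
        if not (len(self.x_px) == len(self.y_px) == len(self.valid) == n):
            raise ValueError("sample arrays must have equal length")

    @property
    def sample_period_ms(self) -> float:
        return float(np.median(np.diff(self.t_ms))) if len(self.t_ms) > 1 else np.nan


@dataclass
class GroundTruth:
    """Cohort ground truth: true fixations, demographics, generating mixture."""

    fixations: pd.DataFrame  # participant_id, index, onset_ms, offset_ms, x_px, y_px
    demographics: pd.DataFrame  # participant_id, gender, age, birth_year
    config: SyntheticCohortConfig

    def generating_salience_grid(self, geometry: ScreenGeometry = STUDY_GEOMETRY):
        """The index-averaged generating mixture as a dense salience grid."""
        from .maps import SalienceGrid

        ks = np.arange(1, 19)
        w_central = float(np.mean([self.config.central_weight(int(k)) for k in ks]))
        probs = self.config.cluster_probs() * (1.0 - w_central)
        xc = np.arange(geometry.width_px) + 0.5
        yc = np.arange(geometry.height_px) + 0.5
        grid = np.zeros(geometry.shape)
        comps = [
            (geometry.center_px[0], geometry.center_px[1], self.config.central_sd_dva, w_central)
        ] + [
            (c.x_px, c.y_px, c.sd_dva, p) for c, p in zip(self.config.clusters, probs)
        ]
        for cx, cy, sd_dva, w in comps:
            sx, sy = geometry.dva_to_px(sd_dva)
            gx = np.exp(-0.5 * ((xc - cx) / sx) ** 2)
            gy = np.exp(-0.5 * ((yc - cy) / sy) ** 2)
            grid += w * np.outer(gy, gx) / (2 * np.pi * sx * sy)
        return SalienceGrid(grid, geometry, kind="model_prediction")


# ---------------------------------------------------------------------------
# demographics


def draw_demographics(
    config: SyntheticCohortConfig, rng: np.random.Generator, n: int | None = None
) -> pd.DataFrame:
    """Sample participant demographics from the configured law."""
    config.validate()
    n = config.n_participants if n is None else n
    genders = list(config.gender_proportions)
    gp = np.array([config.gender_proportions[g] for g in genders], dtype=float)
    gp = gp / gp.sum()
    gender = rng.choice(genders, size=n, p=gp)

    bins = config.age_bin_weights
    bw = np.array([b[2] for b in bins], dtype=float)
    bw = bw / bw.sum()
    bin_idx = rng.choice(len(bins), size=n, p=bw)
    age = np.array(
        [rng.integers(bins[i][0], bins[i][1] + 1) for i in bin_idx], dtype=int
    )
    return pd.DataFrame(
        {
            "participant_id": [f"p{i:05d}" for i in range(n)],
            "gender": gender,
            "age": age,
            "birth_year": config.survey_year - age,
        }
    )


def _participant_bias(config: SyntheticCohortConfig, demographics: dict) -> float:
    """Product of group-bias multipliers matching this participant."""
    if not config.group_bias:
        return 1.0
    bias = 1.0
    gender = demographics.get("gender")
    if gender in config.group_bias:
        bias *= config.group_bias[gender]
    age = demographics.get("age")
    if age is not None:
        for lo, hi, _ in config.age_bin_weights:
            if lo <= age <= hi:
                label = f"{lo}-{hi}"
                if label in config.group_bias:
                    bias *= config.group_bias[label]
                break
    return bias


# ---------------------------------------------------------------------------
# gaze generation


def _sample_fixation_target(
    config: SyntheticCohortConfig,
    geometry: ScreenGeometry,
    rng: np.random.Generator,
    index: int,
    bias: float,
    prev_xy: tuple[float, float] | None,
) -> tuple[float, float]:
    """Draw one on-screen fixation target from the index-k mixture.

    Rejection-samples to stay on-screen and, when a previous fixation
    exists, to keep the saccade amplitude above the configured minimum
    (sub-threshold gaze shifts are treated as part of the same fixation,
    not a new one).
    """
    w_central = config.central_weight(index, bias)
    cluster_p = config.cluster_probs()
    for attempt in range(200):
        if rng.random() < w_central:
            cx, cy = geometry.center_px
            sd = config.central_sd_dva
        else:
            c = config.clusters[rng.choice(len(cluster_p), p=cluster_p)]
            cx, cy, sd = c.x_px, c.y_px, c.sd_dva
        sx, sy = geometry.dva_to_px(sd)
        x = cx + rng.normal(0.0, sx)
        y = cy + rng.normal(0.0, sy)
        if not geometry.contains(x, y):
            continue
        if prev_xy is not None and attempt < 150:
            if geometry.distance_dva(prev_xy[0], prev_xy[1], x, y) < config.min_saccade_amplitude_dva:
                continue
        return float(x), float(y)
    # pathological config; clamp to screen as a last resort
    return (
        float(np.clip(x, 0, geometry.width_px - 1e-6)),
        float(np.clip(y, 0, geometry.height_px - 1e-6)),
    )


def _fixation_schedule(
    config: SyntheticCohortConfig,
    geometry: ScreenGeometry,
    rng: np.random.Generator,
    bias: float,
) -> pd.DataFrame:
    """True fixation sequence (onset, offset, x, y) covering the viewing."""
    total_ms = config.viewing_duration_s * 1000.0
    gap_ms = config.saccade_samples / config.sample_rate_hz * 1000.0
    mu = np.log(config.fixation_median_ms)
    rows = []
    t = 0.0
    prev_xy: tuple[float, float] | None = None
    k = 1
    # a tail shorter than this is absorbed into the previous fixation
    min_tail_ms = 100.0
    while t < total_ms:
        dur = float(np.exp(rng.normal(mu, config.fixation_shape)))
        dur = max(dur, 80.0)
        if rows and total_ms - t < min_tail_ms:
            rows[-1]["offset_ms"] = total_ms
            break
        x, y = _sample_fixation_target(config, geometry, rng, k, bias, prev_xy)
        rows.append(
            {"index": k, "onset_ms": t, "offset_ms": min(t + dur, total_ms), "x_px": x, "y_px": y}
        )
        prev_xy = (x, y)
        t = rows[-1]["offset_ms"] + gap_ms
        k += 1
    return pd.DataFrame(rows)


def simulate_participant(
    config: SyntheticCohortConfig,
    demographics: dict,
    rng: np.random.Generator | int,
    geometry: ScreenGeometry = STUDY_GEOMETRY,
) -> tuple[GazeRecording, pd.DataFrame]:
    """Simulate one participant's raw gaze stream.

    Returns the recording (~rate x duration samples) and the true fixation
    table. Samples within a true fixation are its centroid plus isotropic
    Gaussian noise whose per-sample radial RMS is ``noise_rms_dva``;
    samples in inter-fixation gaps interpolate linearly between centroids;
    dropout runs are flagged invalid.
    """
    config.validate()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    bias = _participant_bias(config, demographics)
    truth = _fixation_schedule(config, geometry, rng, bias)

    n = int(round(config.sample_rate_hz * config.viewing_duration_s))
    t_ms = np.arange(n) / config.sample_rate_hz * 1000.0

    # piecewise trace: constant at centroid during fixations, linear in gaps
    knots_t, knots_x, knots_y = [], [], []
    for r in truth.itertuples():
        knots_t += [r.onset_ms, r.offset_ms]
        knots_x += [r.x_px, r.x_px]
        knots_y += [r.y_px, r.y_px]
    x = np.interp(t_ms, knots_t, knots_x)
    y = np.interp(t_ms, knots_t, knots_y)

    if config.noise_rms_dva > 0:
        # isotropic: per-axis SD = rms / sqrt(2) so E[dx^2 + dy^2] = rms^2
        s = config.noise_rms_dva / np.sqrt(2.0)
        x = x + rng.normal(0.0, s * geometry.px_per_deg_x, size=n)
        y = y + rng.normal(0.0, s * geometry.px_per_deg_y, size=n)

    valid = np.ones(n, dtype=bool)
    if config.loss_run_prob > 0:
        p_sample = config.loss_run_prob / config.sample_rate_hz
        starts = np.flatnonzero(rng.random(n) < p_sample)
        mean_len = max(config.loss_run_length_s * config.sample_rate_hz, 1.0)
        for s0 in starts:
            length = 1 + rng.geometric(1.0 / mean_len)
            valid[s0 : s0 + length] = False

    pid = str(demographics.get("participant_id", "p00000"))
    truth = truth.copy()
    truth.insert(0, "participant_id", pid)
    rec = GazeRecording(pid, t_ms, x, y, valid, demographics=dict(demographics))
    return rec, truth


def simulate_cohort(
    config: SyntheticCohortConfig, geometry: ScreenGeometry = STUDY_GEOMETRY
) -> tuple[list[GazeRecording], GroundTruth]:
    """Simulate a full cohort with deterministically derived per-participant seeds."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_participants + 1)
    demo = draw_demographics(config, np.random.default_rng(children[0]))
    recordings: list[GazeRecording] = []
    truths: list[pd.DataFrame] = []
    for i, row in enumerate(demo.to_dict("records")):
        rec, truth = simulate_participant(
            config, row, np.random.default_rng(children[i + 1]), geometry
        )
        recordings.append(rec)
        truths.append(truth)
    truth_df = pd.concat(truths, ignore_index=True)
    return recordings, GroundTruth(truth_df, demo, config)
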