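"""Stratified benchmarking: gender, age bins, and fixation index.

Stratum scores always restrict the fixation set to the group's members
and score the pooled group fixations (matching how group-wise spatial
distribution maps are built) — a group's NSS is never an average of
per-participant or per-subgroup NSS values. Across-age baselines use the
unweighted mean of the nine bin means so that large bins do not dominate
("mean of bin means"), and per-bin deviations are reported against that
baseline. The fixation-index analyses build cumulative (indices 1..k)
and per-index (index exactly k) fixation sets and re-anchor the scores
per k, since the maximally achievable NSS itself changes with k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import ScreenGeometry, STUDY_GEOMETRY
from .maps import MapParams, SalienceGrid, central_bias_map
from .evaluate import (
    fixation_map_upper_bound,
    improvement_pct,
    nss,
    single_observer_score,
)

__all__ = [
    "AgeBinning",
    "DEFAULT_AGE_BINNING",
    "assign_age_bin",
    "attach_age_bins",
    "group_benchmark",
    "bin_deviation_table",
    "explained_pct",
    "cumulative_fixation_benchmark",
    "per_index_fixation_benchmark",
    "mean_pairwise_distance_dva",
    "mean_distance_to_center_dva",
]


@dataclass(frozen=True)
class AgeBinning:
    """Contiguous integer age bins, inclusive on both edges."""

    edges: tuple[tuple[int, int], ...] = tuple(
        (lo, lo + 5) for lo in range(6, 60, 6)
    )

    def __post_init__(self) -> None:
        for (a0, a1), (b0, b1) in zip(self.edges, self.edges[1:]):
            if b0 != a1 + 1:
                raise ValueError("age bins must be contiguous and ordered")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(f"{lo}-{hi}" for lo, hi in self.edges)


#: The study's nine 6-year bins covering ages 6-59.
DEFAULT_AGE_BINNING = AgeBinning()


def assign_age_bin(age: int, binning: AgeBinning = DEFAULT_AGE_BINNING) -> str | None:
    """Bin label for an age, or None for out-of-range (excluded) ages."""
    if age < 0:
        raise ValueError("age must be non-negative")
    for (lo, hi), label in zip(binning.edges, binning.labels):
        if lo <= age <= hi:
            return label
    return None


def attach_age_bins(
    demographics: pd.DataFrame, binning: AgeBinning = DEFAULT_AGE_BINNING
) -> pd.DataFrame:
    """Add an ``age_bin`` column (None where the age falls outside the bins)."""
    out = demographics.copy()
    out["age_bin"] = [assign_age_bin(int(a), binning) for a in out["age"]]
    return out


def group_benchmark(
    grids: dict[str, SalienceGrid],
    fixations: pd.DataFrame,
    groups: pd.Series,
    geometry: ScreenGeometry = STUDY_GEOMETRY,
    params: MapParams | None = None,
    include_single_observer: bool = False,
) -> pd.DataFrame:
    """Score every grid on every group's pooled fixations.

    ``groups`` maps participant_id -> group label (e.g. gender or age
    bin); participants with a null label are left out. Each stratum gets
    its own fixation-map upper bound and central-bias lower anchor.
    Returns tidy rows (map_id, stratum, n_fix, n_participants, nss,
    lower, upper, improvement_pct).
    """
    params = params or MapParams()
    cb = central_bias_map(geometry, params)
    rows = []
    for label in pd.unique(groups.dropna()):
        members = groups[groups == label].index
        sub = fixations[fixations["participant_id"].isin(members)]
        if len(sub) == 0:
            continue
        upper = fixation_map_upper_bound(sub, geometry, params).nss
        lower = nss(cb, sub).nss
        scored = [("fixation_map", upper), ("central_bias", lower)]
        if include_single_observer and sub["participant_id"].nunique() >= 2:
            scored.append(("single_observer", single_observer_score(sub, geometry, params).nss))
        for map_id, grid in grids.items():
            scored.append((map_id, nss(grid, sub).nss))
        for map_id, raw in scored:
            rows.append(
                {
                    "map_id": map_id,
                    "stratum": str(label),
                    "n_fix": len(sub),
                    "n_participants": sub["participant_id"].nunique(),
                    "nss": raw,
                    "lower": lower,
                    "upper": upper,
                    "improvement_pct": improvement_pct(raw, lower, upper).improvement_pct,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class StratifiedBenchmark:
    """Per-model bin scores, imbalance-robust means, and deviations."""

    scores: pd.DataFrame  # models x bins
    across_bin_mean: pd.Series  # per model: unweighted mean of bin scores
    deviations: pd.DataFrame  # scores - across_bin_mean


def bin_deviation_table(per_bin_scores: pd.DataFrame) -> StratifiedBenchmark:
    """Deviations of each model's bin scores from its across-bin mean.

    The across-bin mean is the *unweighted* mean of the bin scores (mean
    of bin means), so bins with many participants do not dominate the
    baseline. Per model, the deviations sum to zero by construction.
    """
    if per_bin_scores.isna().any().any():
        raise ValueError("every model needs a score in every bin")
    mean = per_bin_scores.mean(axis=1)
    dev = per_bin_scores.sub(mean, axis=0)
    return StratifiedBenchmark(per_bin_scores.copy(), mean, dev)


def explained_pct(model_nss: float, single_observer_nss: float, fixation_map_nss: float) -> float:
    """Percentage of the explainable NSS a model attains in one stratum.

    Scales the model's NSS between the stratum's single-observer baseline
    (0%) and its fixation-map upper bound (100%), each computed with
    bin-specific anchors.
    """
    if fixation_map_nss == single_observer_nss:
        raise ValueError("anchors must differ")
    return 100.0 * (model_nss - single_observer_nss) / (fixation_map_nss - single_observer_nss)


def _index_benchmark(
    grids: dict[str, SalienceGrid],
    fixations: pd.DataFrame,
    geometry: ScreenGeometry,
    params: MapParams | None,
    k_max: int,
    cumulative: bool,
) -> pd.DataFrame:
    params = params or MapParams()
    if "index" not in fixations.columns:
        raise ValueError("fixation table needs an 'index' column (1-based)")
    if k_max > int(fixations["index"].max()):
        raise ValueError(f"k_max={k_max} exceeds available fixation indices")
    cb = central_bias_map(geometry, params)
    rows = []
    for k in range(1, k_max + 1):
        sub = fixations[fixations["index"] <= k] if cumulative else fixations[fixations["index"] == k]
        upper = fixation_map_upper_bound(sub, geometry, params).nss
        lower = nss(cb, sub).nss
        for map_id, raw in [("fixation_map", upper), ("central_bias", lower)] + [
            (mid, nss(g, sub).nss) for mid, g in grids.items()
        ]:
            rows.append(
                {
                    "map_id": map_id,
                    "k": k,
                    "cumulative": cumulative,
                    "n_fix": len(sub),
                    "nss": raw,
                    "nss_scaled_to_upper": raw / upper if upper != 0 else np.nan,
                    "lower": lower,
                    "upper": upper,
                    "improvement_pct": improvement_pct(raw, lower, upper).improvement_pct,
                }
            )
    return pd.DataFrame(rows)


def cumulative_fixation_benchmark(
    grids: dict[str, SalienceGrid],
    fixations: pd.DataFrame,
    geometry: ScreenGeometry = STUDY_GEOMETRY,
    params: MapParams | None = None,
    k_max: int = 18,
) -> pd.DataFrame:
    """Benchmark on fixation indices 1..k for each k up to k_max.

    The k = k_max column over 18 indices equals the pooled benchmark.
    Reports raw NSS, NSS scaled to the maximally achievable (fixation
    map) NSS at that k, and improvement with per-k anchors.
    """
    return _index_benchmark(grids, fixations, geometry, params, k_max, cumulative=True)


def per_index_fixation_benchmark(
    grids: dict[str, SalienceGrid],
    fixations: pd.DataFrame,
    geometry: ScreenGeometry = STUDY_GEOMETRY,
    params: MapParams | None = None,
    k_max: int = 18,
) -> pd.DataFrame:
    """Benchmark on exactly the k-th fixation of each participant, per k."""
    return _index_benchmark(grids, fixations, geometry, params, k_max, cumulative=False)


def mean_pairwise_distance_dva(fixations: pd.DataFrame, geometry: ScreenGeometry = STUDY_GEOMETRY) -> float:
    """Dispersion of a fixation set: mean pairwise distance in dva."""
    x = fixations["x_px"].to_numpy(dtype=float) / geometry.px_per_deg_x
    y = fixations["y_px"].to_numpy(dtype=float) / geometry.px_per_deg_y
    if len(x) < 2:
        raise ValueError("need at least 2 fixations")
    dx = x[:, None] - x[None, :]
    dy = y[:, None] - y[None, :]
    d = np.hypot(dx, dy)
    iu = np.triu_indices(len(x), k=1)
    return float(d[iu].mean())


def mean_distance_to_center_dva(
    fixations: pd.DataFrame, geometry: ScreenGeometry = STUDY_GEOMETRY
) -> float:
    """Mean radial distance of fixation centroids from the screen centre."""
    cx, cy = geometry.center_px
    return float(
        np.mean(
            geometry.distance_dva(
                fixations["x_px"].to_numpy(dtype=float),
                fixations["y_px"].to_numpy(dtype=float),
                cx,
                cy,
            )
        )
    )
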