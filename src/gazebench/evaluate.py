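"""NSS scoring and baseline anchors.

Normalized Scanpath Saliency (NSS) of a salience grid against a set of
discrete fixation locations: z-standardise the grid over all pixels
(population SD), read the z-value at every fixated pixel, and average.
Zero is chance level; the self-NSS of the cohort's own smoothed fixation
map is the empirical upper bound for any model, and the screen-centred
Gaussian central bias is the conventional lower anchor. Scores are
commonly rescaled between those anchors ("improvement": central bias =
0%, fixation map = 100%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import ScreenGeometry, STUDY_GEOMETRY
from .maps import (
    MapParams,
    SalienceGrid,
    fixation_count_grid,
    fixation_pixels,
    make_fixation_map,
)

__all__ = [
    "NSSResult",
    "ScaledScore",
    "zscore_grid",
    "nss",
    "fixation_map_upper_bound",
    "single_observer_score",
    "improvement_pct",
    "benchmark_table",
]


@dataclass
class NSSResult:
    nss: float
    n_fixations: int
    map_id: str = ""
    stratum_id: str = ""
    zero_variance: bool = False


@dataclass
class ScaledScore:
    raw_nss: float
    lower_anchor: float
    upper_anchor: float
    improvement_pct: float


def zscore_grid(values: np.ndarray) -> tuple[np.ndarray, bool]:
    """Population z-standardisation; zero-variance grids map to all-zeros."""
    values = np.asarray(values, dtype=float)
    sd = values.std()  # population (n-denominator) SD
    if sd == 0:
        return np.zeros_like(values), True
    return (values - values.mean()) / sd, False


def nss(
    grid: SalienceGrid,
    fixations: pd.DataFrame,
    map_id: str = "",
    stratum_id: str = "",
) -> NSSResult:
    """Pooled-grand-mean NSS of a grid against discrete fixations.

    The mean is taken over all fixations of all participants together
    (not over per-participant means). A zero-variance grid scores 0 by
    convention, with ``zero_variance`` flagged.
    """
    if len(fixations) == 0:
        raise ValueError("NSS requires at least one fixation")
    z, flat = zscore_grid(grid.values)
    x, y = fixation_pixels(fixations, grid.geometry)
    return NSSResult(
        nss=float(z[y, x].mean()),
        n_fixations=len(fixations),
        map_id=map_id,
        stratum_id=stratum_id,
        zero_variance=flat,
    )


def fixation_map_upper_bound(
    fixations: pd.DataFrame,
    geometry: ScreenGeometry = STUDY_GEOMETRY,
    params: MapParams | None = None,
) -> NSSResult:
    """Self-NSS of the smoothed fixation map of the same fixation set."""
    grid = make_fixation_map(fixations, geometry, params)
    out = nss(grid, fixations, map_id="fixation_map")
    return out


def single_observer_score(
    fixations: pd.DataFrame,
    geometry: ScreenGeometry = STUDY_GEOMETRY,
    params: MapParams | None = None,
) -> NSSResult:
    """Leave-one-out inter-observer baseline.

    Each participant's discrete fixations are scored against the blurred
    fixation map of all *other* participants; the per-participant scores
    are averaged with equal weight.
    """
    from scipy import ndimage

    from .maps import blur_sigma_px

    params = params or MapParams()
    pids = fixations["participant_id"].unique()
    if len(pids) < 2:
        raise ValueError("single-observer baseline needs at least 2 participants")
    total_counts = fixation_count_grid(fixations, geometry)
    sigma = blur_sigma_px(geometry, params.blur_sd_dva)
    scores = []
    for pid in pids:
        mine = fixations[fixations["participant_id"] == pid]
        others_counts = total_counts - fixation_count_grid(mine, geometry)
        blurred = ndimage.gaussian_filter(
            others_counts, sigma=sigma, mode="reflect", truncate=params.truncate_sd
        )
        grid = SalienceGrid(blurred, geometry, kind="fixation_map")
        scores.append(nss(grid, mine).nss)
    return NSSResult(
        nss=float(np.mean(scores)),
        n_fixations=len(fixations),
        map_id="single_observer",
    )


def improvement_pct(raw: float, lower: float, upper: float) -> ScaledScore:
    """Rescale a raw NSS between a lower (0%) and upper (100%) anchor.

    May legitimately fall below 0% or above 100% for models worse than
    the lower anchor or (in a stratum) better than the pooled upper one.
    """
    if upper == lower:
        raise ValueError("anchors must differ")
    pct = 100.0 * (raw - lower) / (upper - lower)
    return ScaledScore(raw, lower, upper, float(pct))


def benchmark_table(
    grids: dict[str, SalienceGrid],
    fixations: pd.DataFrame,
    geometry: ScreenGeometry = STUDY_GEOMETRY,
    params: MapParams | None = None,
    stratum_id: str = "all",
    include_single_observer: bool = True,
) -> pd.DataFrame:
    """Tidy benchmark of model grids plus baselines on one fixation set.

    Columns: map_id, stratum, n_fix, nss, lower, upper, improvement_pct.
    The fixation-map row lands at exactly 100 and the central-bias row at
    exactly 0 by construction of the anchors.
    """
    from .maps import central_bias_map

    params = params or MapParams()
    upper = fixation_map_upper_bound(fixations, geometry, params).nss
    lower = nss(central_bias_map(geometry, params), fixations).nss
    rows = [
        ("fixation_map", upper),
        ("central_bias", lower),
    ]
    if include_single_observer and fixations["participant_id"].nunique() >= 2:
        rows.append(("single_observer", single_observer_score(fixations, geometry, params).nss))
    for map_id, grid in grids.items():
        rows.append((map_id, nss(grid, fixations, map_id=map_id).nss))
    records = []
    for map_id, raw in rows:
        records.append(
            {
                "map_id": map_id,
                "stratum": stratum_id,
                "n_fix": len(fixations),
                "nss": raw,
                "lower": lower,
                "upper": upper,
                "improvement_pct": improvement_pct(raw, lower, upper).improvement_pct,
            }
        )
    return pd.DataFrame(records)
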