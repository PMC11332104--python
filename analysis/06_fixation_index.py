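"""Model performance across fixations: cumulative and per-index curves.

For k = 1..18 builds (a) the cumulative fixation set (indices 1..k over
all participants) and (b) the per-index set (index exactly k), scoring
every map with per-k anchors and the ratio to the maximally achievable
(fixation-map) NSS at that k. Early fixations are much more focal, so the
upper bound and the central bias both fall as k grows. Also reports the
per-index dispersion (mean pairwise distance) of the fixation sets.

Writes fixation_index_cumulative.csv / fixation_index_per_index.csv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from gazebench.geometry import STUDY_GEOMETRY as G
from gazebench.maps import load_grid
from gazebench.stratify import (
    cumulative_fixation_benchmark,
    mean_pairwise_distance_dva,
    per_index_fixation_benchmark,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    fixations = pd.read_csv(ROOT / "data" / "default" / "fixations.csv")
    grids = {
        p.stem: load_grid(p)
        for p in sorted((ROOT / "maps").glob("*.npy"))
        if p.stem not in ("fixation_map", "central_bias")
    }
    cum = cumulative_fixation_benchmark(grids, fixations, G)
    per = per_index_fixation_benchmark(grids, fixations, G)
    cum.to_csv(ROOT / "fixation_index_cumulative.csv", index=False)
    per.to_csv(ROOT / "fixation_index_per_index.csv", index=False)

    ub = cum[cum["map_id"] == "fixation_map"].set_index("k")["nss"]
    print("upper bound (cumulative):", {k: round(ub[k], 3) for k in (1, 6, 12, 18)})
    cb = cum[cum["map_id"] == "central_bias"].set_index("k")["nss"]
    print("central bias (cumulative):", {k: round(cb[k], 3) for k in (1, 6, 12, 18)})
    disp = {
        k: round(mean_pairwise_distance_dva(fixations[fixations["index"] == k], G), 2)
        for k in (1, 5, 9, 14, 18)
    }
    print("per-index dispersion (mean pairwise distance, dva):", disp)


if __name__ == "__main__":
    main()
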