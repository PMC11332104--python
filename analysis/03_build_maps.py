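"""Build the spatial maps for benchmarking the default cohort.

Produces, under results/maps/ (lossless .npy grids with JSON sidecars):

* fixation_map      — the cohort's smoothed (1 dva SD) fixation map;
* central_bias      — screen-aspect Gaussian, SD = screen half-dimensions;
* generating_mixture— the synthetic cohort's true generating salience;
* fixture_spectral  — the in-repo spectral-residual fixture model applied
  to the generating mixture treated as a luminance image;
* meaning_map       — aggregation of synthetic patch ratings (raters score
  overlapping patches at 1.5/3/7 dva; ratings here are sampled from the
  generating mixture plus rater noise, standing in for human ratings).
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from gazebench.geometry import STUDY_GEOMETRY as G
from gazebench.maps import (
    MapParams,
    aggregate_meaning_map,
    central_bias_map,
    fixture_saliency,
    make_fixation_map,
    save_grid,
)
from gazebench.synthetic import SyntheticCohortConfig, GroundTruth

ROOT = Path(__file__).resolve().parents[1] / "results"


def synthetic_patch_ratings(truth_grid: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Synthetic meaningfulness ratings: patch grids at three scales,
    rated 1-6 by thresholding the local generating salience plus noise."""
    rows = []
    for diameter in (1.5, 3.0, 7.0):
        step_x = diameter / 2.0 * G.px_per_deg_x
        step_y = diameter / 2.0 * G.px_per_deg_y
        xs = np.arange(step_x / 2, G.width_px, step_x)
        ys = np.arange(step_y / 2, G.height_px, step_y)
        for cy in ys:
            for cx in xs:
                local = truth_grid[int(cy), int(cx)]
                score = local / truth_grid.max() * 5 + rng.normal(0, 0.5)
                rows.append(
                    {
                        "x_px": cx,
                        "y_px": cy,
                        "diameter_dva": diameter,
                        "rating": float(np.clip(1 + score, 1, 6)),
                    }
                )
    return pd.DataFrame(rows)


def main() -> None:
    out = ROOT / "maps"
    out.mkdir(parents=True, exist_ok=True)
    params = MapParams()

    fixations = pd.read_csv(ROOT / "data" / "default" / "fixations.csv")
    cfg = SyntheticCohortConfig.from_yaml(ROOT / "data" / "default" / "cohort_config.yaml")
    demo = pd.read_csv(ROOT / "data" / "default" / "demographics.csv")
    truth = GroundTruth(pd.DataFrame(), demo, cfg)

    grids = {
        "fixation_map": make_fixation_map(fixations, G, params),
        "central_bias": central_bias_map(G, params),
        "generating_mixture": truth.generating_salience_grid(G),
    }
    grids["fixture_spectral"] = fixture_saliency(grids["generating_mixture"].values, G, params)
    rng = np.random.default_rng(20232)
    ratings = synthetic_patch_ratings(grids["generating_mixture"].values, rng)
    ratings.to_csv(out / "patch_ratings.csv", index=False)
    grids["meaning_map"] = aggregate_meaning_map(ratings, G)

    for name, grid in grids.items():
        save_grid(grid, out / f"{name}.npy")
        print(f"{name}: kind={grid.kind}, range [{grid.values.min():.3g}, {grid.values.max():.3g}]")


if __name__ == "__main__":
    main()
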