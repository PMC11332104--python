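"""End-to-end orchestration: simulate/load -> detect -> map -> score -> stratify.

``run_pipeline`` executes the whole benchmarking analysis from a single
:class:`RunConfig` and writes its tables (overall benchmark, per-stratum
benchmarks and deviations, fixation-index curves, exclusion and quality
reports) plus a provenance record into a run directory. All results are
computed in memory first and written at the end, so a failing stage
leaves no partial tables behind.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import ScreenGeometry
from .synthetic import GazeRecording, GroundTruth, SyntheticCohortConfig, simulate_cohort
from .preprocess import DetectionParams, preprocess_cohort
from .maps import MapParams, SalienceGrid, central_bias_map, fixture_saliency, load_grid
from .evaluate import benchmark_table, zscore_grid
from .stratify import (
    DEFAULT_AGE_BINNING,
    attach_age_bins,
    bin_deviation_table,
    cumulative_fixation_benchmark,
    explained_pct,
    group_benchmark,
    per_index_fixation_benchmark,
)
from .stats import bonferroni_contrasts, rm_anova_gg

log = logging.getLogger("gazebench")

__all__ = ["RunConfig", "StageError", "run_pipeline", "difference_map"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    output_dir: str = "results/run"
    cohort: SyntheticCohortConfig = field(default_factory=SyntheticCohortConfig)
    gaze_csv: str | None = None
    demographics_csv: str | None = None
    geometry: ScreenGeometry = field(default_factory=ScreenGeometry)
    detection: DetectionParams = field(default_factory=DetectionParams)
    maps: MapParams = field(default_factory=MapParams)
    model_grids: dict[str, str] = field(default_factory=dict)
    stratify_by: tuple[str, ...] = ("gender", "age")
    fixation_index: bool = True
    k_max: int = 18
    viewing_onset_ms: float = 0.0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d:
            d["cohort"] = SyntheticCohortConfig.from_dict(d["cohort"])
        if "geometry" in d:
            d["geometry"] = ScreenGeometry(**d["geometry"])
        if "detection" in d:
            d["detection"] = DetectionParams(**d["detection"])
        if "maps" in d:
            d["maps"] = MapParams(**d["maps"])
        if "stratify_by" in d:
            d["stratify_by"] = tuple(d["stratify_by"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def difference_map(prediction: SalienceGrid, fixation_map: SalienceGrid) -> np.ndarray:
    """Signed per-pixel delta z(prediction) - z(fixation map).

    Highlights where a model over- (positive) or under-predicts
    (negative) relative to the observed fixation distribution; zero mean
    by construction of the z-scores.
    """
    if prediction.geometry != fixation_map.geometry:
        raise ValueError("grids must share the same geometry")
    zp, _ = zscore_grid(prediction.values)
    zf, _ = zscore_grid(fixation_map.values)
    return zp - zf


def _load_or_simulate(config: RunConfig) -> tuple[list[GazeRecording], GroundTruth | None]:
    if config.gaze_csv:
        from .io import read_demographics_csv, read_gaze_csv

        demo = read_demographics_csv(config.demographics_csv) if config.demographics_csv else None
        return read_gaze_csv(config.gaze_csv, demographics=demo), None
    recordings, truth = simulate_cohort(config.cohort, config.geometry)
    return recordings, truth


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages and write tables + provenance to the run directory."""
    logging.basicConfig(stream=sys.stderr, level=config.log_level)
    outputs: dict[str, pd.DataFrame] = {}

    try:
        recordings, truth = _load_or_simulate(config)
    except Exception as exc:  # noqa: BLE001
        raise StageError("input", str(exc)) from exc
    log.info("input: %d recordings", len(recordings))

    try:
        fixations, exclusions, quality = preprocess_cohort(
            recordings, config.geometry, config.detection, config.viewing_onset_ms
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("preprocess", str(exc)) from exc
    if len(fixations) == 0:
        raise StageError("preprocess", "no participant survived fixation selection")
    outputs["fixations"] = fixations
    outputs["exclusions"] = exclusions
    outputs["quality"] = quality
    log.info(
        "preprocess: %d participants retained, %d excluded",
        fixations["participant_id"].nunique(),
        int(exclusions["excluded"].sum()),
    )

    # model grids: external predictions plus, for synthetic runs, the
    # generating mixture and the in-repo fixture model applied to it
    try:
        grids: dict[str, SalienceGrid] = {
            name: load_grid(path) for name, path in config.model_grids.items()
        }
        if truth is not None:
            gen = truth.generating_salience_grid(config.geometry)
            grids.setdefault("generating_mixture", gen)
            grids.setdefault("fixture_spectral", fixture_saliency(gen.values, config.geometry, config.maps))
    except Exception as exc:  # noqa: BLE001
        raise StageError("maps", str(exc)) from exc

    try:
        outputs["benchmark_overall"] = benchmark_table(
            grids,
            fixations,
            config.geometry,
            config.maps,
            include_single_observer=fixations["participant_id"].nunique() >= 2,
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("evaluate", str(exc)) from exc

    demo = truth.demographics if truth is not None else None
    if config.gaze_csv and config.demographics_csv:
        from .io import read_demographics_csv

        demo = read_demographics_csv(config.demographics_csv)

    retained = set(fixations["participant_id"])
    if "gender" in config.stratify_by or "age" in config.stratify_by:
        if demo is None:
            raise StageError("stratify", "stratification requires demographics")
        if fixations["participant_id"].nunique() < 2:
            raise StageError(
                "stratify",
                "demographic stratification requires at least 2 retained participants",
            )
        demo = demo[demo["participant_id"].isin(retained)]

    if "gender" in config.stratify_by:
        groups = demo.set_index("participant_id")["gender"]
        outputs["benchmark_gender"] = group_benchmark(
            grids, fixations, groups, config.geometry, config.maps, include_single_observer=True
        )

    if "age" in config.stratify_by:
        binned = attach_age_bins(demo)
        groups = binned.set_index("participant_id")["age_bin"]
        bench = group_benchmark(
            grids, fixations, groups, config.geometry, config.maps, include_single_observer=True
        )
        outputs["benchmark_age_bins"] = bench
        wide = bench.pivot(index="map_id", columns="stratum", values="nss")
        if wide.notna().all().all() and wide.shape[1] >= 2:
            strat = bin_deviation_table(wide)
            outputs["age_bin_deviations"] = strat.deviations.reset_index()
            # percentage explained NSS of the explainable NSS, per bin
            if "single_observer" in set(bench["map_id"]):
                expl_rows = []
                for stratum, sub in bench.groupby("stratum"):
                    so = float(sub.loc[sub["map_id"] == "single_observer", "nss"].iloc[0])
                    fm = float(sub.loc[sub["map_id"] == "fixation_map", "nss"].iloc[0])
                    for _, r in sub.iterrows():
                        if r["map_id"] in ("fixation_map", "central_bias", "single_observer"):
                            continue
                        expl_rows.append(
                            {
                                "map_id": r["map_id"],
                                "stratum": stratum,
                                "explained_pct": explained_pct(r["nss"], so, fm),
                            }
                        )
                expl = pd.DataFrame(expl_rows)
                outputs["age_bin_explained_pct"] = expl
                wide_expl = expl.pivot(index="map_id", columns="stratum", values="explained_pct")
                if wide_expl.shape[0] >= 2 and wide_expl.shape[1] >= 2:
                    res = rm_anova_gg(wide_expl.to_numpy())
                    outputs["age_anova"] = pd.DataFrame(
                        [dataclasses.asdict(res)]
                    )
                    outputs["age_contrasts"] = bonferroni_contrasts(wide_expl)

    if config.fixation_index:
        try:
            k_max = min(config.k_max, int(fixations["index"].max()))
            outputs["fixation_index_cumulative"] = cumulative_fixation_benchmark(
                grids, fixations, config.geometry, config.maps, k_max
            )
            outputs["fixation_index_per_index"] = per_index_fixation_benchmark(
                grids, fixations, config.geometry, config.maps, k_max
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError("fixation_index", str(exc)) from exc

    # all stages succeeded: write everything
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, df in outputs.items():
        df.to_csv(out_dir / f"{name}.csv", index=False)
    config_json = json.dumps(config.to_dict(), sort_keys=True, default=str)
    provenance = {
        "gazebench_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "config": json.loads(config_json),
        "tables": sorted(outputs),
    }
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    log.info("wrote %d tables to %s", len(outputs), out_dir)
    return out_dir
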