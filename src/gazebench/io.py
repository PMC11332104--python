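"""Tabular I/O for gaze recordings, demographics and fixation tables.

Formats are plain CSV:

* gaze:        participant_id, t_ms, x_px, y_px, valid
* demographics: participant_id, gender, age, birth_year
* fixations:   participant_id, index, onset_ms, offset_ms, x_px, y_px

``read_gaze_csv`` accepts a column-name mapping so externally exported
tables (different header conventions) can be ingested without rewriting.
"""

from __future__ import annotations

import pandas as pd

from .synthetic import GazeRecording

GAZE_COLUMNS = ["participant_id", "t_ms", "x_px", "y_px", "valid"]
FIXATION_COLUMNS = ["participant_id", "index", "onset_ms", "offset_ms", "x_px", "y_px"]


def write_gaze_csv(recordings: list[GazeRecording], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "participant_id": rec.participant_id,
                "t_ms": rec.t_ms,
                "x_px": rec.x_px,
                "y_px": rec.y_px,
                "valid": rec.valid.astype(int),
            }
        )
        for rec in recordings
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_gaze_csv(
    path,
    demographics: pd.DataFrame | None = None,
    column_map: dict[str, str] | None = None,
) -> list[GazeRecording]:
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = set(GAZE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gaze CSV missing columns: {sorted(missing)}")
    demo_by_pid = {}
    if demographics is not None:
        demo_by_pid = {str(r["participant_id"]): dict(r) for _, r in demographics.iterrows()}
    recordings = []
    for pid, group in df.groupby("participant_id", sort=False):
        group = group.sort_values("t_ms")
        recordings.append(
            GazeRecording(
                participant_id=str(pid),
                t_ms=group["t_ms"].to_numpy(float),
                x_px=group["x_px"].to_numpy(float),
                y_px=group["y_px"].to_numpy(float),
                valid=group["valid"].to_numpy().astype(bool),
                demographics=demo_by_pid.get(str(pid)),
            )
        )
    return recordings


def write_demographics_csv(demographics: pd.DataFrame, path) -> None:
    demographics.to_csv(path, index=False)


def read_demographics_csv(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    return df


def write_fixations_csv(fixations: pd.DataFrame, path) -> None:
    fixations.to_csv(path, index=False)


def read_fixations_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(FIXATION_COLUMNS) - set(df.columns) - {"index"}
    if missing:
        raise ValueError(f"fixation CSV missing columns: {sorted(missing)}")
    return df
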