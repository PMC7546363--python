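"""Readers and writers for the pipeline's plain-text formats.

All tabular files are UTF-8, comma-separated CSV with a mandatory header
row and '.' decimals; lines starting with '#' are header comments (every
file written here embeds the config hash and seed that produced it).
Coordinates are pixels with origin top-left; times are milliseconds.

Formats
-------
fixation CSV   participant_id, stimulus_id, onset_ms, duration_ms, x_px,
               y_px [, tracking_ratio]
raw-sample CSV participant_id, stimulus_id, timestamp_ms, x_px, y_px, valid
cohort CSV     participant_id, group
stimulus CSV   stimulus_id, stimulus_class
ROI label CSV  state_index, category [, name]
variable CSV   participant, group, stimulus, actors, variable, category,
               value
model files    JSON text (round-trips floats exactly)
"""

from __future__ import annotations

import json
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .types import (GROUPS, STIMULUS_CLASSES, CATEGORIES, BhmmModel,
                    FeatureTransform, FormatError, Scanpath, ValidationError)

log = logging.getLogger("gazehmm")

FIXATION_COLUMNS = ["participant_id", "stimulus_id", "onset_ms",
                    "duration_ms", "x_px", "y_px"]
RAW_COLUMNS = ["participant_id", "stimulus_id", "timestamp_ms", "x_px",
               "y_px", "valid"]
VARIABLE_COLUMNS = ["participant", "group", "stimulus", "actors",
                    "variable", "category", "value"]


def _header_comment(config=None, seed=None) -> str:
    parts = []
    if config is not None:
        parts.append(f"config_hash={config.config_hash()}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return "# gazehmm " + " ".join(parts) + "\n" if parts else ""


def _require_columns(df: pd.DataFrame, required: Sequence[str],
                     path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_fixation_table(path, config=None, min_duration_ms: float | None = None
                        ) -> list[Scanpath]:
    """Parse a fixation-event CSV into one Scanpath per participant x stimulus.

    Rows must be sorted by onset within each recording and fixation
    intervals must not overlap; violations raise :class:`ValidationError`
    naming the offending participant.  Durations below the configured
    minimum (60 ms by default) are rejected as malformed with their line
    numbers.
    """
    if min_duration_ms is None:
        min_duration_ms = config.min_fixation_ms if config is not None else 60.0
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    _require_columns(df, FIXATION_COLUMNS, path)
    bad = df.index[df["duration_ms"] < min_duration_ms]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:10]]
        raise ValidationError(
            f"{path}: {len(bad)} fixation(s) shorter than {min_duration_ms} ms"
            f" (data lines {lines}{'...' if len(bad) > 10 else ''})")
    scanpaths = []
    for (pid, sid), g in df.groupby(["participant_id", "stimulus_id"],
                                    sort=True):
        g = g  # already onset-sorted per contract; Scanpath validates
        scanpaths.append(Scanpath(str(pid), str(sid),
                                  g["onset_ms"].to_numpy(),
                                  g["duration_ms"].to_numpy(),
                                  g["x_px"].to_numpy(),
                                  g["y_px"].to_numpy()))
    log.info("stage=read_fixations n_rows=%d n_scanpaths=%d path=%s",
             len(df), len(scanpaths), path)
    return scanpaths


def write_fixation_table(scanpaths: Sequence[Scanpath], path,
                         config=None, seed=None,
                         tracking_ratio: dict | None = None) -> None:
    rows = []
    for sp in scanpaths:
        for i in range(len(sp)):
            row = {"participant_id": sp.participant_id,
                   "stimulus_id": sp.stimulus_id,
                   "onset_ms": sp.onset_ms[i],
                   "duration_ms": sp.duration_ms[i],
                   "x_px": sp.x[i], "y_px": sp.y[i]}
            if tracking_ratio is not None:
                row["tracking_ratio"] = tracking_ratio.get(
                    (sp.participant_id, sp.stimulus_id), np.nan)
            rows.append(row)
    df = pd.DataFrame(rows)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_header_comment(config, seed))
        df.to_csv(fh, index=False)


def read_raw_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    _require_columns(df, RAW_COLUMNS, path)
    df["valid"] = df["valid"].astype(bool)
    return df


def write_raw_samples(df: pd.DataFrame, path, config=None, seed=None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_header_comment(config, seed))
        df.to_csv(fh, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ["participant_id", "group"], path)
    if df["participant_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate participant rows")
    bad = set(df["group"]) - set(GROUPS)
    if bad:
        raise ValidationError(
            f"{path}: unknown group label(s) {sorted(bad)}; "
            f"expected one of {GROUPS}")
    df["participant_id"] = df["participant_id"].astype(str)
    return df


def read_stimuli(path) -> dict:
    """Map stimulus_id -> stimulus class ('four_actor' / 'one_actor')."""
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ["stimulus_id", "stimulus_class"], path)
    bad = set(df["stimulus_class"]) - set(STIMULUS_CLASSES)
    if bad:
        raise ValidationError(f"{path}: unknown stimulus class {sorted(bad)}")
    return dict(zip(df["stimulus_id"].astype(str), df["stimulus_class"]))


def read_roi_labels(path) -> dict:
    """Map state_index -> semantic category (face/body/nonsocial/excluded)."""
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ["state_index", "category"], path)
    allowed = set(CATEGORIES) | {"excluded"}
    bad = set(df["category"]) - allowed
    if bad:
        raise ValidationError(f"{path}: unknown categories {sorted(bad)}")
    return dict(zip(df["state_index"].astype(int), df["category"]))


def write_roi_labels(labels: dict, path, config=None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_header_comment(config))
        fh.write("state_index,category\n")
        for k in sorted(labels):
            fh.write(f"{k},{labels[k]}\n")


def write_variable_table(table: pd.DataFrame, path, config=None,
                         seed=None) -> None:
    """Write the long-format gaze-variable table with a stable row order."""
    if table is None or len(table) == 0:
        raise ValidationError("refusing to write an empty variable table")
    _require_columns(table, VARIABLE_COLUMNS, "variable table")
    out = table.sort_values(["participant", "stimulus", "variable",
                             "category"], kind="mergesort")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_header_comment(config, seed))
        out.to_csv(fh, index=False, columns=VARIABLE_COLUMNS)


def read_variable_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    _require_columns(df, VARIABLE_COLUMNS, path)
    return df


# ---------------------------------------------------------------------------
# model serialisation (JSON; float repr round-trips exactly)

def model_to_dict(model: BhmmModel) -> dict:
    d = {"n_states": model.n_states,
         "prior": model.prior.tolist(),
         "transition": model.transition.tolist(),
         "means": model.means.tolist(),
         "covariances": model.covariances.tolist()}
    if model.transform is not None:
        d["transform"] = {"mean": model.transform.mean.tolist(),
                          "scale": model.transform.scale.tolist(),
                          "log_duration": model.transform.log_duration}
    return d


def model_from_dict(d: dict) -> BhmmModel:
    tf = None
    if "transform" in d:
        t = d["transform"]
        tf = FeatureTransform(np.array(t["mean"]), np.array(t["scale"]),
                              bool(t["log_duration"]))
    return BhmmModel(np.array(d["prior"]), np.array(d["transition"]),
                     np.array(d["means"]), np.array(d["covariances"]),
                     transform=tf)


def write_model(model: BhmmModel, path, config=None, seed=None) -> None:
    payload = {"format": "gazehmm-model-v1"}
    if config is not None:
        payload["config_hash"] = config.config_hash()
    if seed is not None:
        payload["seed"] = seed
    payload.update(model_to_dict(model))
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def read_model(path) -> BhmmModel:
    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    if d.get("format") != "gazehmm-model-v1":
        raise FormatError(f"{path}: not a gazehmm model file")
    return model_from_dict(d)
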