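"""Fixation detection from raw gaze samples and recording-quality control.

Fixations are detected with a dispersion-threshold (I-DT) algorithm: a
maximal window of consecutive valid samples whose spatial dispersion
(range in x plus range in y) stays below the pixel equivalent of the
configured visual angle, lasting at least the minimum duration (60 ms by
default, matching common eye-tracker defaults).  Invalid samples (blinks,
off-screen) break candidate windows.

Quality control excludes a recording unless its tracking ratio exceeds
75% AND its total fixation time exceeds 50% of the stimulus duration,
both strictly.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .types import (RecordingQuality, Scanpath, ScreenGeometry,
                    ValidationError)

log = logging.getLogger("gazehmm")


def degrees_to_pixels(angle_deg: float, geometry: ScreenGeometry) -> float:
    """Width on screen, in pixels, subtending ``angle_deg`` of visual angle.

    Uses the exact chord 2 * d * tan(angle/2) at viewing distance d, then
    converts centimetres to pixels with the horizontal pixel pitch.
    """
    if angle_deg <= 0:
        raise ValueError("visual angle must be positive")
    width_cm = 2.0 * geometry.viewing_distance_cm * math.tan(
        math.radians(angle_deg) / 2.0)
    return width_cm * geometry.px_per_cm


def detect_fixations_idt(samples: pd.DataFrame, min_duration_ms: float,
                         dispersion_deg: float, geometry: ScreenGeometry,
                         participant_id: str = "", stimulus_id: str = "",
                         sampling_rate_hz: float = 120.0) -> pd.DataFrame:
    """Dispersion-threshold fixation detection on one recording.

    Parameters
    ----------
    samples
        Raw samples with columns timestamp_ms, x_px, y_px, valid; timestamps
        strictly increasing.
    Returns
    -------
    DataFrame with columns onset_ms, duration_ms, x_px, y_px (centroids),
    sorted and non-overlapping.  An empty stream yields an empty frame.
    """
    if len(samples) == 0:
        return pd.DataFrame(columns=["onset_ms", "duration_ms", "x_px",
                                     "y_px"])
    t = samples["timestamp_ms"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValidationError("raw sample timestamps must strictly increase")
    x = samples["x_px"].to_numpy(dtype=float)
    y = samples["y_px"].to_numpy(dtype=float)
    valid = samples["valid"].to_numpy(dtype=bool)
    dt = 1000.0 / sampling_rate_hz
    disp_px = degrees_to_pixels(dispersion_deg, geometry)

    fixations = []
    # contiguous valid runs; invalid samples break candidate windows
    runs = []
    start = None
    for i, v in enumerate(valid):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(valid)))

    def span(i, j):  # duration covered by samples i..j-1
        return t[j - 1] - t[i] + dt

    for lo, hi in runs:
        i = lo
        while i < hi:
            # grow to the minimum-duration window
            j = i + 1
            while j < hi and span(i, j) < min_duration_ms:
                j += 1
            if span(i, j) < min_duration_ms:
                break
            disp = (x[i:j].max() - x[i:j].min()) + (y[i:j].max() - y[i:j].min())
            if disp <= disp_px:
                while j < hi:
                    nd = (x[i:j + 1].max() - x[i:j + 1].min()) + \
                         (y[i:j + 1].max() - y[i:j + 1].min())
                    if nd > disp_px:
                        break
                    j += 1
                fixations.append({"onset_ms": t[i],
                                  "duration_ms": span(i, j),
                                  "x_px": x[i:j].mean(),
                                  "y_px": y[i:j].mean()})
                i = j
            else:
                i += 1
    out = pd.DataFrame(fixations, columns=["onset_ms", "duration_ms",
                                           "x_px", "y_px"])
    log.debug("stage=idt participant=%s stimulus=%s n_samples=%d n_fix=%d",
              participant_id, stimulus_id, len(samples), len(out))
    return out


def compute_quality(samples: pd.DataFrame | None, fixations: pd.DataFrame,
                    stimulus_duration_ms: float,
                    sampling_rate_hz: float = 120.0,
                    tracking_ratio: float | None = None,
                    tracking_ratio_min: float = 0.75,
                    fixation_time_fraction_min: float = 0.50,
                    _warn: bool = True) -> RecordingQuality:
    """Tracking ratio and fixation-time checks for one recording.

    tracking_ratio = valid samples / expected samples (rate x duration).
    When only fixation events are available (no raw samples), an externally
    reported tracking ratio may be supplied; if neither exists the ratio
    test is skipped with a logged warning.
    """
    if stimulus_duration_ms <= 0:
        raise ValueError("stimulus duration must be positive")
    expected = sampling_rate_hz * stimulus_duration_ms / 1000.0
    if expected <= 0:
        raise ValueError("expected sample count is zero")
    if samples is not None and len(samples) > 0:
        ratio = float(samples["valid"].sum()) / expected
    elif tracking_ratio is not None:
        ratio = float(tracking_ratio)
    else:
        ratio = float("nan")
        if _warn:
            log.warning("stage=qc no raw samples and no reported tracking"
                        " ratio; skipping the ratio test")
    total_fix = float(fixations["duration_ms"].sum()) if len(fixations) else 0.0
    fix_frac = total_fix / stimulus_duration_ms

    reasons = []
    ratio_ok = True
    if not math.isnan(ratio):
        ratio_ok = ratio > tracking_ratio_min
        if not ratio_ok:
            reasons.append(f"tracking_ratio {ratio:.3f} <= "
                           f"{tracking_ratio_min}")
    time_ok = fix_frac > fixation_time_fraction_min
    if not time_ok:
        reasons.append(f"fixation_time_fraction {fix_frac:.3f} <= "
                       f"{fixation_time_fraction_min}")
    return RecordingQuality(tracking_ratio=ratio,
                            total_fixation_time_ms=total_fix,
                            stimulus_duration_ms=stimulus_duration_ms,
                            passed=ratio_ok and time_ok,
                            reason="; ".join(reasons))


def exclude_invalid_fixations(fixations: pd.DataFrame,
                              geometry: ScreenGeometry) -> pd.DataFrame:
    """Drop fixations whose centroid lies outside [0, resolution) on x or y."""
    if len(fixations) == 0:
        return fixations
    keep = ((fixations["x_px"] >= 0) &
            (fixations["x_px"] < geometry.resolution_x) &
            (fixations["y_px"] >= 0) &
            (fixations["y_px"] < geometry.resolution_y))
    return fixations.loc[keep].reset_index(drop=True)


def apply_qc(scanpaths, config, tracking_ratios: dict | None = None,
             stimulus_duration_ms: float = 120_000.0):
    """Filter a scanpath collection by the recording-quality rules.

    Returns (passing scanpaths, QC report DataFrame).
    """
    kept, rows = [], []
    warned = False
    for sp in scanpaths:
        ratio = None
        if tracking_ratios is not None:
            ratio = tracking_ratios.get((sp.participant_id, sp.stimulus_id))
        if ratio is None and not warned:
            log.info("stage=qc no tracking ratios supplied; the ratio test"
                     " is skipped for event-only input")
            warned = True
        fx = pd.DataFrame({"duration_ms": sp.duration_ms})
        q = compute_quality(None, fx, stimulus_duration_ms,
                            config.sampling_rate_hz, _warn=False,
                            tracking_ratio=ratio,
                            tracking_ratio_min=config.tracking_ratio_min,
                            fixation_time_fraction_min=
                            config.fixation_time_fraction_min)
        rows.append({"participant": sp.participant_id,
                     "stimulus": sp.stimulus_id,
                     "tracking_ratio": q.tracking_ratio,
                     "fixation_time_fraction":
                         q.total_fixation_time_ms / q.stimulus_duration_ms,
                     "passed": q.passed, "reason": q.reason})
        if q.passed:
            kept.append(sp)
    report = pd.DataFrame(rows)
    log.info("stage=qc n_in=%d n_out=%d", len(scanpaths), len(kept))
    return kept, report
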