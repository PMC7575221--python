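"""Calibration, window summaries, orthostatic-hypotension classification.

The analysis contract: finger pressure is rescaled to brachial cuff values
with a two-point (affine) calibration; the supine baseline is the mean over
the 5 min preceding the sit-onset; the seated period is summarised as
consecutive 1-min means; orthostatic hypotension (OH) is a fall of >= 20
mmHg systolic and/or >= 10 mmHg diastolic within the first 3 min upright
(thresholds inclusive), delayed OH the same fall first met after 3 min; and
the per-subject feature vector is (dSBP, dDBP, dHR) between the lowest
seated 1-min mean and the supine mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .beats import BeatSeries
from .waveforms import Annotations, CuffReading

__all__ = [
    "CalibrationModel",
    "WindowSummary",
    "OHCriteria",
    "OHResult",
    "OrthostaticFeatures",
    "fit_two_point_calibration",
    "apply_calibration",
    "summarize_windows",
    "classify_oh",
    "extract_features",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CalibrationModel:
    """Affine map mmHg -> mmHg: calibrated = gain * finger + offset."""

    gain: float
    offset: float
    calibration_window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError(f"calibration gain must be positive, got {self.gain}")


@dataclass
class WindowSummary:
    """Mean hemodynamics over one analysis window ('supine' or 'seated_k')."""

    label: str
    start_s: float
    end_s: float
    mean_sbp: float
    mean_dbp: float
    mean_hr: float
    n_valid_beats: int
    missing: bool = False


@dataclass(frozen=True)
class OHCriteria:
    """Consensus OH definition: drops in mmHg, window limit in minutes."""

    sbp_drop: float = 20.0
    dbp_drop: float = 10.0
    window_limit: int = 3

    def __post_init__(self) -> None:
        if self.sbp_drop <= 0 or self.dbp_drop <= 0 or self.window_limit <= 0:
            raise ValueError("OH criteria must all be positive")


@dataclass
class OHResult:
    oh: bool
    delayed_oh: bool
    qualifying_window: str | None
    sbp_drop_observed: float
    dbp_drop_observed: float
    assessable: bool = True
    reason: str = ""


@dataclass
class OrthostaticFeatures:
    """(dSBP, dDBP, dHR): selected seated 1-min mean minus supine mean."""

    d_sbp: float
    d_dbp: float
    d_hr: float
    source_window: str


def fit_two_point_calibration(
    beats: BeatSeries,
    cuffs: list[CuffReading],
    window: tuple[float, float],
) -> CalibrationModel:
    """Fit the affine map sending window-mean finger SBP/DBP to cuff SBP/DBP.

    The two calibration points are (finger mean SBP -> cuff mean SBP) and
    (finger mean DBP -> cuff mean DBP), which determine gain and offset
    exactly (a 2x2 linear system).
    """
    lo, hi = window
    in_cuffs = [c for c in cuffs if lo <= c.time_s < hi]
    if not in_cuffs:
        raise ValueError(f"no cuff readings inside calibration window [{lo}, {hi})")
    sel = (beats.r_time >= lo) & (beats.r_time < hi) & beats.valid
    if int(np.sum(sel)) < 10:
        raise ValueError(
            f"need >= 10 valid beats in calibration window, found {int(np.sum(sel))}"
        )
    f_sbp = float(np.mean(beats.sbp[sel]))
    f_dbp = float(np.mean(beats.dbp[sel]))
    c_sbp = float(np.mean([c.sbp for c in in_cuffs]))
    c_dbp = float(np.mean([c.dbp for c in in_cuffs]))
    if abs(f_sbp - f_dbp) < 1e-9:
        raise ValueError("degenerate calibration: finger SBP and DBP means coincide")
    gain = (c_sbp - c_dbp) / (f_sbp - f_dbp)
    offset = c_sbp - gain * f_sbp
    return CalibrationModel(gain=gain, offset=offset, calibration_window=(lo, hi))


def apply_calibration(beats: BeatSeries, model: CalibrationModel) -> BeatSeries:
    """Return a copy with SBP/DBP mapped through the calibration (gain > 0
    preserves the DBP < SBP ordering)."""
    return BeatSeries(
        beats.r_time.copy(), beats.rr.copy(), beats.hr.copy(),
        model.gain * beats.sbp + model.offset,
        model.gain * beats.dbp + model.offset,
        beats.valid.copy(), beats.reason.copy(),
    )


def _window_mean(beats: BeatSeries, lo: float, hi: float, label: str,
                 min_beats: int) -> WindowSummary:
    sel = (beats.r_time >= lo) & (beats.r_time < hi) & beats.valid
    n = int(np.sum(sel))
    if n < min_beats:
        return WindowSummary(label, lo, hi, np.nan, np.nan, np.nan, n, missing=True)
    hr = beats.hr[sel]
    hr = hr[np.isfinite(hr)]
    return WindowSummary(
        label, lo, hi,
        float(np.mean(beats.sbp[sel])),
        float(np.mean(beats.dbp[sel])),
        float(np.mean(hr)) if len(hr) else np.nan,
        n,
        missing=len(hr) == 0,
    )


def summarize_windows(
    beats: BeatSeries,
    annotations: Annotations,
    min_beats: int = 10,
    min_partial_s: float = 30.0,
) -> list[WindowSummary]:
    """Supine 5-min mean plus consecutive seated 1-min means.

    The supine window is the 300 s before sit-onset (shorter with a warning
    if the recording starts late); the transition is excluded; seated windows
    are half-open [60(k-1), 60k) intervals from the seated start.  A partial
    final window is kept if it spans at least ``min_partial_s``.
    """
    sup_start = annotations.sit_onset_s - 300.0
    if sup_start < annotations.supine_start_s:
        logger.warning(
            "supine span is %.0f s (< 300 s); supine mean computed over available data",
            annotations.sit_onset_s - annotations.supine_start_s,
        )
        sup_start = annotations.supine_start_s
    out = [_window_mean(beats, sup_start, annotations.sit_onset_s, "supine", min_beats)]
    t0 = annotations.seated_start_s
    k = 1
    while t0 + 60.0 * (k - 1) < annotations.seated_end_s - 1e-9:
        a = t0 + 60.0 * (k - 1)
        b = min(t0 + 60.0 * k, annotations.seated_end_s)
        if b - a < min_partial_s:
            break
        out.append(_window_mean(beats, a, b, f"seated_{k}", min_beats))
        k += 1
    return out


def _seated(windows: list[WindowSummary]) -> list[WindowSummary]:
    return [w for w in windows if w.label.startswith("seated_")]


def _drops(supine: WindowSummary, wins: list[WindowSummary]):
    """Max observed SBP/DBP drops (supine minus window mean) and argmin windows."""
    usable = [w for w in wins if not w.missing]
    if not usable:
        return None
    sbp_w = min(usable, key=lambda w: w.mean_sbp)
    dbp_w = min(usable, key=lambda w: w.mean_dbp)
    return (supine.mean_sbp - sbp_w.mean_sbp, supine.mean_dbp - dbp_w.mean_dbp, sbp_w, dbp_w)


def classify_oh(
    supine: WindowSummary,
    seated: list[WindowSummary],
    criteria: OHCriteria | None = None,
) -> OHResult:
    """Classify orthostatic hypotension and delayed OH from window means.

    OH: the largest SBP (or DBP) fall over seated windows 1..window_limit
    meets the inclusive thresholds.  Delayed OH: OH is absent but the same
    criteria are met over the windows after window_limit.
    """
    criteria = criteria or OHCriteria()
    if supine.missing or not np.isfinite(supine.mean_sbp):
        return OHResult(False, False, None, np.nan, np.nan, False, "supine mean undefined")
    seated = _seated(seated)
    early = [w for w in seated if int(w.label.split("_")[1]) <= criteria.window_limit]
    late = [w for w in seated if int(w.label.split("_")[1]) > criteria.window_limit]
    d = _drops(supine, early)
    if d is None:
        return OHResult(False, False, None, np.nan, np.nan, False,
                        f"no usable seated windows within {criteria.window_limit} min")
    sbp_drop, dbp_drop, sbp_w, dbp_w = d
    if sbp_drop >= criteria.sbp_drop or dbp_drop >= criteria.dbp_drop:
        qw = sbp_w.label if sbp_drop >= criteria.sbp_drop else dbp_w.label
        return OHResult(True, False, qw, sbp_drop, dbp_drop)
    dl = _drops(supine, late)
    if dl is not None:
        l_sbp, l_dbp, l_sbp_w, l_dbp_w = dl
        if l_sbp >= criteria.sbp_drop or l_dbp >= criteria.dbp_drop:
            qw = l_sbp_w.label if l_sbp >= criteria.sbp_drop else l_dbp_w.label
            return OHResult(False, True, qw, l_sbp, l_dbp)
    return OHResult(False, False, None, sbp_drop, dbp_drop)


def extract_features(
    supine: WindowSummary,
    seated: list[WindowSummary],
    convention: str = "coherent-window",
) -> OrthostaticFeatures:
    """Orthostatic response features from window summaries.

    'coherent-window' (default): all three deltas come from the single
    seated window with the lowest 1-min mean SBP.  'per-variable-extremum':
    dSBP from the min-SBP window, dDBP from the min-DBP window, dHR from the
    max-HR window (windows may differ).
    """
    if supine.missing or not np.isfinite(supine.mean_sbp):
        raise ValueError("supine summary undefined; cannot extract features")
    usable = [w for w in _seated(seated) if not w.missing]
    if not usable:
        raise ValueError("no usable seated windows; cannot extract features")
    if convention == "coherent-window":
        w = min(usable, key=lambda w: w.mean_sbp)
        return OrthostaticFeatures(
            w.mean_sbp - supine.mean_sbp,
            w.mean_dbp - supine.mean_dbp,
            w.mean_hr - supine.mean_hr,
            w.label,
        )
    if convention == "per-variable-extremum":
        ws = min(usable, key=lambda w: w.mean_sbp)
        wd = min(usable, key=lambda w: w.mean_dbp)
        wh = max(usable, key=lambda w: w.mean_hr)
        return OrthostaticFeatures(
            ws.mean_sbp - supine.mean_sbp,
            wd.mean_dbp - supine.mean_dbp,
            wh.mean_hr - supine.mean_hr,
            f"sbp:{ws.label},dbp:{wd.label},hr:{wh.label}",
        )
    raise ValueError(f"unknown feature convention {convention!r}")


def windows_to_frame(windows: list[WindowSummary], subject_id: str = "") -> pd.DataFrame:
    rows = [{
        "subject_id": subject_id,
        "label": w.label,
        "start_s": w.start_s,
        "end_s": w.end_s,
        "mean_sbp": w.mean_sbp,
        "mean_dbp": w.mean_dbp,
        "mean_hr": w.mean_hr,
        "n_valid_beats": w.n_valid_beats,
        "missing": w.missing,
    } for w in windows]
    return pd.DataFrame(rows)
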