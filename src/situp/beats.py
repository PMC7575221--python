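"""Waveform -> validated per-beat series.

R peaks are found with a classical band-pass / differentiate / square /
moving-window-integrate scheme with an adaptive threshold and a 250-ms
refractory period, then refined to the local maximum of the raw ECG.  All
thresholds are relative to the signal's own scale, so detection is invariant
to uniform amplitude scaling.  Blood-pressure systolic peaks and diastolic
troughs are located beat-by-beat relative to each R peak and their values
read off a parabolic fit to suppress sample noise.

Artifactual beats are flagged, never deleted; downstream window means use
valid beats only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "BeatSeries",
    "PhysiologicLimits",
    "detect_r_peaks",
    "detect_bp_extrema",
    "build_beat_series",
    "screen_artifacts",
]

logger = logging.getLogger(__name__)

REFRACTORY_S = 0.25  # minimum distance between accepted R peaks


@dataclass
class PhysiologicLimits:
    """Plausibility limits used by screen_artifacts."""

    hr_min: float = 20.0
    hr_max: float = 220.0
    sbp_min: float = 40.0
    sbp_max: float = 260.0
    dbp_min: float = 20.0
    dbp_max: float = 160.0
    max_sbp_step: float = 25.0  # |beat-to-beat SBP change|
    rr_rel_dev: float = 0.4  # relative deviation from local median RR


@dataclass
class BeatSeries:
    """Per-beat series: times, RR/HR and per-beat SBP/DBP with validity flags.

    ``rr[i]`` is the interval ending at beat i (NaN for the first beat);
    ``hr = 60/rr``.  ``reason`` holds comma-joined flag codes for invalid
    beats and '' for valid ones.
    """

    r_time: np.ndarray
    rr: np.ndarray
    hr: np.ndarray
    sbp: np.ndarray
    dbp: np.ndarray
    valid: np.ndarray
    reason: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.r_time)
        for name in ("rr", "hr", "sbp", "dbp", "valid", "reason"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"BeatSeries field {name} length mismatch")
        if n > 1 and not np.all(np.diff(self.r_time) > 0):
            raise ValueError("r_time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.r_time)

    def flag(self, idx: np.ndarray | int, code: str) -> None:
        idx = np.atleast_1d(idx)
        for i in idx:
            self.valid[i] = False
            self.reason[i] = code if not self.reason[i] else f"{self.reason[i]},{code}"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "r_time_s": self.r_time,
            "rr_s": self.rr,
            "hr_bpm": self.hr,
            "sbp_mmhg": self.sbp,
            "dbp_mmhg": self.dbp,
            "valid": self.valid,
            "reason": self.reason,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BeatSeries":
        required = ["r_time_s", "rr_s", "hr_bpm", "sbp_mmhg", "dbp_mmhg", "valid", "reason"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"beat table missing column(s): {', '.join(missing)}")
        return cls(
            r_time=df["r_time_s"].to_numpy(float),
            rr=df["rr_s"].to_numpy(float),
            hr=df["hr_bpm"].to_numpy(float),
            sbp=df["sbp_mmhg"].to_numpy(float),
            dbp=df["dbp_mmhg"].to_numpy(float),
            valid=df["valid"].to_numpy(bool),
            reason=df["reason"].fillna("").to_numpy(object),
        )


def _bandpass(x: np.ndarray, fs: float, lo: float = 5.0, hi: float = 25.0) -> np.ndarray:
    nyq = fs / 2.0
    hi = min(hi, 0.95 * nyq)
    b, a = sps.butter(2, [lo / nyq, hi / nyq], btype="band")
    return sps.filtfilt(b, a, x)


def detect_r_peaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """Detect R-peak times (s) in an ECG channel.

    Returns an empty array (with a logged warning) for flat or empty input
    rather than raising.
    """
    ecg = np.asarray(ecg, dtype=float)
    if len(ecg) < fs:  # < 1 s of signal
        logger.warning("ECG too short for R-peak detection (%d samples)", len(ecg))
        return np.array([])
    scale = float(np.std(ecg))
    if scale == 0.0 or not np.isfinite(scale):
        logger.warning("ECG channel is flat; no R peaks detected")
        return np.array([])

    filt = _bandpass(ecg, fs)
    energy = np.gradient(filt) ** 2
    win = max(1, int(round(0.12 * fs)))
    integ = np.convolve(energy, np.ones(win) / win, mode="same")

    dist = max(1, int(round(REFRACTORY_S * fs)))
    cand, _ = sps.find_peaks(integ, distance=dist)
    if len(cand) == 0:
        logger.warning("no candidate R peaks found")
        return np.array([])

    # adaptive signal/noise running estimates (Pan-Tompkins style)
    spki = float(np.percentile(integ[cand], 90))
    npki = float(np.percentile(integ, 50))
    accepted = []
    for c in cand:
        thr = npki + 0.25 * (spki - npki)
        if integ[c] >= thr:
            accepted.append(c)
            spki = 0.125 * integ[c] + 0.875 * spki
        else:
            npki = 0.125 * integ[c] + 0.875 * npki
    if not accepted:
        logger.warning("adaptive threshold rejected all candidates")
        return np.array([])

    # refine to local maximum of the raw ECG
    half = int(round(0.05 * fs))
    refined = []
    for c in accepted:
        a, b = max(0, c - half), min(len(ecg), c + half + 1)
        refined.append(a + int(np.argmax(ecg[a:b])))
    refined = np.unique(refined)
    # enforce refractory period after refinement
    keep = [refined[0]]
    for r in refined[1:]:
        if r - keep[-1] >= dist:
            keep.append(r)
        elif ecg[r] > ecg[keep[-1]]:
            keep[-1] = r
    return np.asarray(keep) / fs


def _parabolic_extremum(x: np.ndarray, fs: float, center: int) -> float:
    """Extremum value from a +-40 ms least-squares parabola around ``center``.

    Fitting the raw samples around the smoothed-signal extremum suppresses
    additive sample noise without the peak flattening that a heavy low-pass
    filter would cause.
    """
    half = max(2, int(round(0.04 * fs)))
    a, b = max(0, center - half), min(len(x), center + half + 1)
    if b - a < 3:
        return float(x[center])
    tt = (np.arange(a, b) - center) / fs
    try:
        coef = np.polyfit(tt, x[a:b], 2)
    except np.linalg.LinAlgError:
        return float(x[center])
    if coef[0] == 0:
        return float(x[center])
    tv = float(np.clip(-coef[1] / (2 * coef[0]), tt[0], tt[-1]))
    return float(np.polyval(coef, tv))


def detect_bp_extrema(
    bp: np.ndarray, fs: float, r_times: np.ndarray,
    min_pulse_pressure: float = 10.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-beat (sbp, dbp, resolvable) aligned with r_times.

    For each R peak the systolic peak is the maximum in (R, R + 0.6*RR] and
    the diastolic trough the minimum between the preceding systolic peak (or
    R - 0.4*RR for the first beat) and the systolic peak.  Beats whose
    peak-trough amplitude falls below ``min_pulse_pressure`` are marked
    unresolvable.
    """
    bp = np.asarray(bp, dtype=float)
    r_times = np.asarray(r_times, dtype=float)
    n = len(r_times)
    sbp = np.full(n, np.nan)
    dbp = np.full(n, np.nan)
    ok = np.zeros(n, dtype=bool)
    if n == 0:
        return sbp, dbp, ok
    rr = np.diff(r_times)
    rr = np.append(rr, rr[-1] if len(rr) else 1.0)
    # smoothing only to *locate* extrema; values come from parabola fits
    win = max(1, int(round(0.04 * fs)))
    smooth = np.convolve(bp, np.ones(win) / win, mode="same")

    prev_peak_i = None
    flat_beats = 0
    for i, (rt, rri) in enumerate(zip(r_times, rr)):
        i_r = int(round(rt * fs))
        i_hi = min(len(bp), int(round((rt + 0.6 * rri) * fs)) + 1)
        if i_hi <= i_r + 2:
            continue
        seg = smooth[i_r + 1:i_hi]
        j_peak = i_r + 1 + int(np.argmax(seg))
        s_val = _parabolic_extremum(bp, fs, j_peak)
        lo = prev_peak_i if prev_peak_i is not None else max(0, int(round((rt - 0.4 * rri) * fs)))
        if j_peak <= lo + 1:
            continue
        j_tr = lo + int(np.argmin(smooth[lo:j_peak]))
        d_val = _parabolic_extremum(bp, fs, j_tr)
        prev_peak_i = j_peak
        sbp[i], dbp[i] = s_val, d_val
        if np.isfinite(s_val) and np.isfinite(d_val) and (s_val - d_val) >= min_pulse_pressure:
            ok[i] = True
        else:
            flat_beats += 1
    if flat_beats > 0.5 * n:
        logger.warning("BP channel looks non-pulsatile: %d/%d beats unresolvable", flat_beats, n)
    return sbp, dbp, ok


def build_beat_series(r_times: np.ndarray, sbp: np.ndarray, dbp: np.ndarray,
                      resolvable: np.ndarray | None = None) -> BeatSeries:
    """Assemble a BeatSeries; RR assigned to the later beat of each pair."""
    r_times = np.asarray(r_times, dtype=float)
    order = np.argsort(r_times)
    r_times = r_times[order]
    sbp = np.asarray(sbp, dtype=float)[order]
    dbp = np.asarray(dbp, dtype=float)[order]
    n = len(r_times)
    rr = np.full(n, np.nan)
    if n > 1:
        rr[1:] = np.diff(r_times)
    with np.errstate(divide="ignore", invalid="ignore"):
        hr = 60.0 / rr
    valid = np.ones(n, dtype=bool)
    reason = np.array([""] * n, dtype=object)
    beats = BeatSeries(r_times, rr, hr, sbp, dbp, valid, reason)
    if n > 0:
        beats.flag(0, "no_rr")
    if resolvable is not None:
        resolvable = np.asarray(resolvable, dtype=bool)[order]
        beats.flag(np.nonzero(~resolvable)[0], "bp_unresolved")
    bad_bp = np.nonzero(np.isnan(sbp) | np.isnan(dbp) | (dbp >= sbp))[0]
    for i in bad_bp:
        if "bp_unresolved" not in beats.reason[i]:
            beats.flag(i, "pressure_order")
    return beats


def screen_artifacts(beats: BeatSeries, limits: PhysiologicLimits | None = None) -> BeatSeries:
    """Flag physiologically implausible beats (copy; input unchanged)."""
    limits = limits or PhysiologicLimits()
    out = BeatSeries(
        beats.r_time.copy(), beats.rr.copy(), beats.hr.copy(),
        beats.sbp.copy(), beats.dbp.copy(), beats.valid.copy(), beats.reason.copy(),
    )
    hr, sbp, dbp, rr = out.hr, out.sbp, out.dbp, out.rr
    with np.errstate(invalid="ignore"):
        out.flag(np.nonzero((hr < limits.hr_min) | (hr > limits.hr_max))[0], "hr_range")
        out.flag(np.nonzero((sbp < limits.sbp_min) | (sbp > limits.sbp_max))[0], "sbp_range")
        out.flag(np.nonzero((dbp < limits.dbp_min) | (dbp > limits.dbp_max))[0], "dbp_range")
        if len(out) > 1:
            step = np.abs(np.diff(sbp))
            out.flag(np.nonzero(step > limits.max_sbp_step)[0] + 1, "sbp_step")
        if len(out) >= 5:
            med = pd.Series(rr).rolling(11, center=True, min_periods=3).median().to_numpy()
            with np.errstate(invalid="ignore"):
                dev = np.abs(rr - med) / med
            out.flag(np.nonzero(dev > limits.rr_rel_dev)[0], "rr_outlier")
    return out
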