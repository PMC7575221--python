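"""Synthetic ECG / finger-pressure waveform generation with embedded truth.

A sit-up test recording is emulated as a 5-min supine baseline, a 10-s
passive transition, and a seated period of 4 or 15 min.  Beat-to-beat SBP,
DBP and heart rate follow piecewise-constant per-window trajectories joined
by short cosine ramps; the seated nadir window carries exactly the subject's
target orthostatic deltas, and later windows recover partially so that the
nadir window is the unique lowest-SBP window.  The rendered channels are a
simplified ECG (dominant R spike with small P/Q/S/T deflections — only
R-peak timing matters downstream) and a pulsatile arterial pressure wave
(trough -> systolic upstroke -> peak -> decay with optional dicrotic bump).

Ground truth (beat times, per-beat SBP/DBP, programmed window means) is
stored in the record's metadata so detectors can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .templates import SubjectProfile

__all__ = [
    "CuffReading",
    "Annotations",
    "SignalRecord",
    "synthesize_signals",
    "apply_finger_distortion",
    "render_ecg",
    "render_bp",
]

SUPINE_DURATION = 300.0  # s of supine rest summarised by the 5-min mean
DEFAULT_TRANSITION = 10.0  # s of passive supine->seated transition
RAMP_S = 5.0  # s cosine ramp joining consecutive window levels


@dataclass(frozen=True)
class CuffReading:
    """A brachial cuff measurement used for two-point calibration."""

    time_s: float
    sbp: float
    dbp: float

    def __post_init__(self) -> None:
        if not self.dbp < self.sbp:
            raise ValueError(f"cuff reading at {self.time_s}s: DBP {self.dbp} >= SBP {self.sbp}")


@dataclass(frozen=True)
class Annotations:
    """Protocol timing marks, seconds from recording start."""

    supine_start_s: float
    sit_onset_s: float
    seated_end_s: float
    transition_s: float = DEFAULT_TRANSITION

    def __post_init__(self) -> None:
        if not (self.supine_start_s < self.sit_onset_s < self.seated_end_s):
            raise ValueError("annotations must satisfy supine_start < sit_onset < seated_end")

    @property
    def seated_start_s(self) -> float:
        return self.sit_onset_s + self.transition_s


@dataclass
class SignalRecord:
    """A multichannel recording: ECG (mV) and finger pressure (mmHg)."""

    fs: float
    ecg: np.ndarray
    bp: np.ndarray
    annotations: Annotations
    cuff_readings: list[CuffReading] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.bp = np.asarray(self.bp, dtype=float)
        if self.ecg.shape != self.bp.shape:
            raise ValueError("ECG and BP channels must have equal length")

    @property
    def duration(self) -> float:
        return len(self.ecg) / self.fs

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.ecg)) / self.fs


def _window_levels(profile: SubjectProfile, nadir_window: int,
                   margin_base: float, margin_slope: float, recovery_frac: float):
    """Programmed (SBP, DBP, HR) level for each seated 1-min window.

    The nadir window sits exactly at supine + target; every other window sits
    ``margin_base + margin_slope * |w - nadir|`` mmHg above the nadir SBP
    (half that for DBP) with an attenuated HR response, making the nadir the
    unique lowest-SBP window regardless of the sign of the target deltas.
    """
    n_win = int(round(profile.seated_duration / 60.0))
    if not 1 <= nadir_window <= n_win:
        raise ValueError(f"nadir_window {nadir_window} outside 1..{n_win}")
    if (profile.target_dsbp, profile.target_ddbp, profile.target_dhr) == (0.0, 0.0, 0.0):
        # null responder: perfectly flat seated period at supine levels
        margin_base = margin_slope = 0.0
        recovery_frac = 1.0
    levels = []
    for w in range(1, n_win + 1):
        if w == nadir_window:
            levels.append((
                profile.supine_sbp + profile.target_dsbp,
                profile.supine_dbp + profile.target_ddbp,
                profile.supine_hr + profile.target_dhr,
            ))
        else:
            m = margin_base + margin_slope * abs(w - nadir_window)
            levels.append((
                profile.supine_sbp + profile.target_dsbp + m,
                profile.supine_dbp + profile.target_ddbp + m / 2.0,
                profile.supine_hr + recovery_frac * profile.target_dhr,
            ))
    return levels


class _Trajectory:
    """Piecewise-constant levels joined by short cosine ramps.

    ``ramp_side[i]`` places the ramp around internal breakpoint i+1 either in
    the earlier segment ("before", the default) or the later one ("after").
    Segments flagged protected on both sides (the seated nadir window) are
    therefore exactly at their level throughout.
    """

    def __init__(self, breakpoints: list[float], levels: list[float],
                 ramp_side: list[str] | None = None):
        # levels[i] holds on [breakpoints[i], breakpoints[i+1]) modulo ramps
        self.bp = np.asarray(breakpoints, dtype=float)
        self.levels = np.asarray(levels, dtype=float)
        n_internal = len(self.levels) - 1
        ramp_side = ramp_side or ["before"] * n_internal
        self.ramps: list[tuple[float, float, float, float]] = []  # t0, t1, v0, v1
        for i in range(n_internal):
            v0, v1 = self.levels[i], self.levels[i + 1]
            if v0 == v1:
                continue
            b = self.bp[i + 1]
            if ramp_side[i] == "after":
                seg_len = self.bp[i + 2] - b
                self.ramps.append((b, b + min(RAMP_S, seg_len), v0, v1))
            else:
                seg_len = b - self.bp[i]
                self.ramps.append((b - min(RAMP_S, seg_len), b, v0, v1))

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        t_in = np.asarray(t, dtype=float)
        tt = np.atleast_1d(t_in)
        idx = np.clip(np.searchsorted(self.bp, tt, side="right") - 1, 0, len(self.levels) - 1)
        out = self.levels[idx].astype(float).copy()
        for t0, t1, v0, v1 in self.ramps:
            m = (tt >= t0) & (tt < t1)
            if m.any():
                w = 0.5 * (1 - np.cos(np.pi * (tt[m] - t0) / (t1 - t0)))
                out[m] = v0 + w * (v1 - v0)
        return out if t_in.ndim else float(out[0])

    def window_mean(self, start: float, end: float, dt: float = 0.05) -> float:
        t = np.arange(start, end, dt) + dt / 2
        return float(np.mean(self(t)))


def _build_trajectories(profile: SubjectProfile, nadir_window: int,
                        margin_base: float, margin_slope: float, recovery_frac: float):
    ann = Annotations(
        supine_start_s=0.0,
        sit_onset_s=SUPINE_DURATION,
        seated_end_s=SUPINE_DURATION + DEFAULT_TRANSITION + profile.seated_duration,
    )
    levels = _window_levels(profile, nadir_window, margin_base, margin_slope, recovery_frac)
    breaks = [ann.supine_start_s, ann.sit_onset_s]  # supine, transition
    sbp_l = [profile.supine_sbp, profile.supine_sbp]
    dbp_l = [profile.supine_dbp, profile.supine_dbp]
    hr_l = [profile.supine_hr, profile.supine_hr]
    for w, (s, d, h) in enumerate(levels):
        breaks.append(ann.seated_start_s + 60.0 * w)
        sbp_l.append(s)
        dbp_l.append(d)
        hr_l.append(h)
    breaks.append(ann.seated_end_s)
    # Ramps default to the earlier segment (so each window reaches its level
    # by its first moment; the supine->seated ramp sits in the transition,
    # which no window includes).  The ramp leaving the nadir window is pushed
    # into the following window so the nadir's 1-min mean is exactly
    # supine + target.
    n_internal = len(sbp_l) - 1
    ramp_side = ["before"] * n_internal
    nadir_seg = 2 + (nadir_window - 1)
    if nadir_seg < n_internal:
        ramp_side[nadir_seg] = "after"
    return (ann,
            _Trajectory(breaks, sbp_l, ramp_side),
            _Trajectory(breaks, dbp_l, ramp_side),
            _Trajectory(breaks, hr_l, ramp_side))


def _beat_schedule(hr_traj: _Trajectory, t_end: float, rng: np.random.Generator,
                   rr_jitter: float) -> np.ndarray:
    times = []
    t = 0.4
    while t < t_end - 0.5:
        times.append(t)
        rr = 60.0 / float(hr_traj(t))
        if rr_jitter > 0:
            rr *= 1.0 + rng.normal(0.0, rr_jitter)
        t += max(rr, 0.25)
    return np.asarray(times)


def _add_gaussians(signal: np.ndarray, fs: float, centers: np.ndarray,
                   amps: np.ndarray, sigma_s: float) -> None:
    """Add amp * exp(-(t-c)^2 / 2 sigma^2) bumps in place (4-sigma support)."""
    half = max(1, int(round(4 * sigma_s * fs)))
    n = len(signal)
    offsets = np.arange(-half, half + 1)
    for c, a in zip(centers, np.broadcast_to(amps, centers.shape)):
        ci = int(round(c * fs))
        idx = ci + offsets
        ok = (idx >= 0) & (idx < n)
        tt = idx[ok] / fs - c
        signal[idx[ok]] += a * np.exp(-0.5 * (tt / sigma_s) ** 2)


def render_ecg(beat_times: np.ndarray, fs: float, duration: float,
               r_amplitude: float = 1.0, noise_sd_frac: float = 0.05,
               rng: np.random.Generator | None = None) -> np.ndarray:
    """Render a simplified ECG with R spikes at the given beat times."""
    rng = rng or np.random.default_rng()
    n = int(round(duration * fs))
    ecg = np.zeros(n)
    bt = np.asarray(beat_times, dtype=float)
    rr = np.diff(bt, append=bt[-1] + (bt[-1] - bt[-2] if len(bt) > 1 else 1.0)) if len(bt) else bt
    a = r_amplitude
    _add_gaussians(ecg, fs, bt, np.full_like(bt, a), 0.008)            # R
    _add_gaussians(ecg, fs, bt - 0.025, np.full_like(bt, -0.15 * a), 0.008)  # Q
    _add_gaussians(ecg, fs, bt + 0.025, np.full_like(bt, -0.20 * a), 0.008)  # S
    if len(bt):
        t_off = np.minimum(0.30 * rr, 0.28)
        _add_gaussians(ecg, fs, bt + t_off, np.full_like(bt, 0.25 * a), 0.04)  # T
        _add_gaussians(ecg, fs, bt - 0.18, np.full_like(bt, 0.10 * a), 0.025)  # P
    if noise_sd_frac > 0:
        ecg += rng.normal(0.0, noise_sd_frac * a, n)
    return ecg


def render_bp(beat_times: np.ndarray, beat_sbp: np.ndarray, beat_dbp: np.ndarray,
              fs: float, duration: float, foot_delay: float = 0.15,
              dicrotic: bool = True, noise_sd: float = 1.0,
              rng: np.random.Generator | None = None) -> np.ndarray:
    """Render a pulsatile pressure wave hitting the per-beat SBP/DBP exactly.

    For beat i the diastolic trough (value ``beat_dbp[i]``) falls at the
    pulse foot ``beat_times[i] + foot_delay``; the wave then rises to the
    systolic peak ``beat_sbp[i]`` and decays monotonically to the next foot.
    """
    rng = rng or np.random.default_rng()
    n = int(round(duration * fs))
    bp = np.zeros(n)
    bt = np.asarray(beat_times, dtype=float)
    if len(bt) == 0:
        return bp + noise_sd * rng.normal(size=n) if noise_sd > 0 else bp
    feet = bt + foot_delay
    rr = np.diff(bt)
    rr = np.append(rr, rr[-1] if len(rr) else 1.0)
    peak_delay = np.minimum(0.15, 0.35 * rr)  # rise time foot -> peak
    peaks = feet + peak_delay
    t = np.arange(n) / fs
    bp[t < feet[0]] = beat_dbp[0]
    for i in range(len(bt)):
        f0, p0 = feet[i], peaks[i]
        f1 = feet[i + 1] if i + 1 < len(bt) else min(duration, f0 + rr[i])
        d_next = beat_dbp[i + 1] if i + 1 < len(bt) else beat_dbp[i]
        i0, i1, i2 = (int(math.ceil(f0 * fs)), int(math.ceil(p0 * fs)),
                      min(int(math.ceil(f1 * fs)), n))
        if i1 > i0:  # systolic upstroke: half-cosine rise
            tt = (t[i0:i1] - f0) / (p0 - f0)
            bp[i0:i1] = beat_dbp[i] + (beat_sbp[i] - beat_dbp[i]) * np.sin(0.5 * np.pi * tt) ** 2
        if i2 > i1:  # decay to next foot
            tt = (t[i1:i2] - p0) / max(f1 - p0, 1e-6)
            seg = d_next + (beat_sbp[i] - d_next) * np.cos(0.5 * np.pi * tt) ** 2
            if dicrotic:
                pulse = beat_sbp[i] - beat_dbp[i]
                seg += 0.06 * pulse * np.exp(-0.5 * ((tt - 0.35) / 0.08) ** 2) * (1 - tt)
            bp[i1:i2] = seg
    last = int(math.ceil(feet[-1] * fs))
    if last < n and feet[-1] + rr[-1] < duration:
        bp[int(math.ceil((feet[-1] + rr[-1]) * fs)):] = beat_dbp[-1]
    if noise_sd > 0:
        bp += rng.normal(0.0, noise_sd, n)
    return bp


def synthesize_signals(
    profile: SubjectProfile,
    seed: int = 0,
    nadir_window: int = 2,
    margin_base: float = 3.0,
    margin_slope: float = 1.5,
    recovery_frac: float = 0.7,
    ecg_noise_frac: float = 0.05,
    bp_noise_sd: float = 1.0,
    beat_bp_sd: float = 0.5,
    rr_jitter: float = 0.01,
    dicrotic: bool = True,
) -> SignalRecord:
    """Synthesize one subject's sit-up-test recording with ground truth.

    Noise defaults: ECG SD = 5% of the R amplitude, BP sample SD = 1 mmHg,
    per-beat SBP/DBP variability SD = 0.5 mmHg, RR jitter CV = 1%.  Set all
    four to 0 for noise-free records.
    """
    rng = np.random.default_rng(seed)
    ann, sbp_traj, dbp_traj, hr_traj = _build_trajectories(
        profile, nadir_window, margin_base, margin_slope, recovery_frac
    )
    duration = ann.seated_end_s
    beat_times = _beat_schedule(hr_traj, duration, rng, rr_jitter)
    beat_sbp = np.asarray(sbp_traj(beat_times), dtype=float)
    beat_dbp = np.asarray(dbp_traj(beat_times), dtype=float)
    if beat_bp_sd > 0:
        beat_sbp = beat_sbp + rng.normal(0.0, beat_bp_sd, len(beat_times))
        beat_dbp = beat_dbp + rng.normal(0.0, beat_bp_sd, len(beat_times))

    ecg = render_ecg(beat_times, profile.fs, duration,
                     noise_sd_frac=ecg_noise_frac, rng=rng)
    bp = render_bp(beat_times, beat_sbp, beat_dbp, profile.fs, duration,
                   dicrotic=dicrotic, noise_sd=bp_noise_sd, rng=rng)

    cuffs = [
        CuffReading(60.0, round(profile.supine_sbp, 1), round(profile.supine_dbp, 1)),
        CuffReading(240.0, round(profile.supine_sbp, 1), round(profile.supine_dbp, 1)),
    ]
    n_win = int(round(profile.seated_duration / 60.0))
    win_means = {
        "supine": {
            "sbp": sbp_traj.window_mean(ann.sit_onset_s - 300.0, ann.sit_onset_s),
            "dbp": dbp_traj.window_mean(ann.sit_onset_s - 300.0, ann.sit_onset_s),
            "hr": hr_traj.window_mean(ann.sit_onset_s - 300.0, ann.sit_onset_s),
        }
    }
    for w in range(1, n_win + 1):
        a, b = ann.seated_start_s + 60.0 * (w - 1), ann.seated_start_s + 60.0 * w
        win_means[f"seated_{w}"] = {
            "sbp": sbp_traj.window_mean(a, b),
            "dbp": dbp_traj.window_mean(a, b),
            "hr": hr_traj.window_mean(a, b),
        }
    metadata = {
        "subject_id": profile.subject_id,
        "seed": seed,
        "nadir_window": nadir_window,
        "ground_truth": {
            "beat_times_s": beat_times.tolist(),
            "beat_sbp": np.round(beat_sbp, 4).tolist(),
            "beat_dbp": np.round(beat_dbp, 4).tolist(),
            "programmed_window_means": win_means,
            "target_dsbp": profile.target_dsbp,
            "target_ddbp": profile.target_ddbp,
            "target_dhr": profile.target_dhr,
        },
    }
    return SignalRecord(fs=profile.fs, ecg=ecg, bp=bp, annotations=ann,
                        cuff_readings=cuffs, metadata=metadata)


def apply_finger_distortion(record: SignalRecord, gain: float, offset: float) -> SignalRecord:
    """Return a copy whose BP channel is gain*bp + offset (cuffs untouched).

    Emulates the systematic miscalibration of finger arterial pressure
    relative to brachial pressure that two-point calibration must undo.
    """
    if gain <= 0:
        raise ValueError(f"distortion gain must be positive, got {gain}")
    meta = dict(record.metadata)
    meta["distortion"] = {"gain": gain, "offset": offset}
    return SignalRecord(
        fs=record.fs,
        ecg=record.ecg.copy(),
        bp=gain * record.bp + offset,
        annotations=record.annotations,
        cuff_readings=list(record.cuff_readings),
        metadata=meta,
    )
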