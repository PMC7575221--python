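"""Cohort synthesis from printed cluster summary templates.

The study cohort's raw recordings are not public; what is public is the
per-cluster summary of the three orthostatic response features — the change
in systolic blood pressure (dSBP), diastolic blood pressure (dDBP) and heart
rate (dHR) between the lowest seated 1-min mean and the supine mean — as
median (min, max) for eight clusters of 159 people with spinal cord injury.
This module turns those printed summaries into a reproducible synthetic
cohort with known cluster membership, so the downstream pipeline can be
exercised and validated end to end.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

__all__ = [
    "ClusterTemplate",
    "SubjectProfile",
    "make_cluster_templates",
    "generate_cohort",
    "cohort_to_frame",
    "frame_to_cohort",
]

LEVEL_GROUPS = ("cervical", "high_thoracic", "low_cord")
AIS_GRADES = ("A", "B", "C", "D")

#: Default dispersion divisor: within-template SD = range / spread.  The
#: templates' printed ranges overlap between the central clusters, so the
#: generator defaults to a tight dispersion that keeps the embedded cluster
#: structure recoverable; see docs/methods.md for the reasoning.
DEFAULT_SPREAD = 8.0


@dataclass(frozen=True)
class ClusterTemplate:
    """Median (min, max) of the three orthostatic features for one cluster."""

    cluster_id: int
    n: int
    sbp_med: float
    sbp_min: float
    sbp_max: float
    dbp_med: float
    dbp_min: float
    dbp_max: float
    hr_med: float
    hr_min: float
    hr_max: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"template {self.cluster_id}: n must be >= 1, got {self.n}")
        for var in ("sbp", "dbp", "hr"):
            lo = getattr(self, f"{var}_min")
            med = getattr(self, f"{var}_med")
            hi = getattr(self, f"{var}_max")
            if not (lo <= med <= hi):
                raise ValueError(
                    f"template {self.cluster_id}: require {var}_min <= {var}_med <= "
                    f"{var}_max, got ({lo}, {med}, {hi})"
                )

    def ranges(self) -> dict[str, tuple[float, float, float]]:
        """(min, median, max) per feature, keyed 'sbp'/'dbp'/'hr'."""
        return {
            var: (
                getattr(self, f"{var}_min"),
                getattr(self, f"{var}_med"),
                getattr(self, f"{var}_max"),
            )
            for var in ("sbp", "dbp", "hr")
        }


@dataclass
class SubjectProfile:
    """Ground-truth description of one synthetic subject.

    ``target_*`` are the orthostatic response deltas the waveform synthesizer
    embeds (lowest seated 1-min mean minus supine mean); the downstream
    pipeline should recover them.
    """

    subject_id: str
    cluster_id: int
    level_group: str
    ais: str
    supine_sbp: float
    supine_dbp: float
    supine_hr: float
    target_dsbp: float
    target_ddbp: float
    target_dhr: float
    seated_duration: float = 240.0
    fs: float = 500.0

    def __post_init__(self) -> None:
        if self.seated_duration not in (240.0, 900.0):
            raise ValueError(f"seated_duration must be 240 or 900 s, got {self.seated_duration}")
        if self.fs not in (500.0, 1000.0):
            raise ValueError(f"fs must be 500 or 1000 Hz, got {self.fs}")
        if self.level_group not in LEVEL_GROUPS:
            raise ValueError(f"unknown level_group {self.level_group!r}")
        if self.ais not in AIS_GRADES:
            raise ValueError(f"unknown AIS grade {self.ais!r}")
        if not self.supine_dbp < self.supine_sbp:
            raise ValueError("supine DBP must be below supine SBP")


# Printed per-cluster summaries: (cluster_id, n,
#   sbp med, min, max,  dbp med, min, max,  hr med, min, max)
_TEMPLATE_ROWS = [
    (1, 24, -23, -40, -13, -11, -22, -2, 7, -6, 16),
    (2, 2, -55, -58, -51, -34, -36, -32, 23, 11, 35),
    (3, 20, -19, -35, -8, -11, -25, 2, 25, 17, 40),
    (4, 33, -3, -12, 8, 0, -6, 8, 13, 8, 22),
    (5, 23, -7, -14, -3, -1, -7, 5, 4, -1, 8),
    (6, 3, 23, 22, 25, 16, 15, 20, 2, -6, 5),
    (7, 28, 8, 0, 22, 2, -10, 10, 3, -10, 8),
    (8, 26, -1, -6, 14, 8, 0, 23, 4, -2, 12),
]

# Injury-level composition of the cohort (85 cervical C2-C8, 21 high thoracic
# T1-T5, 53 low cord T6-L3) and AIS severity composition (60/35/41/23 A-D).
_LEVEL_PROBS = np.array([85, 21, 53], dtype=float) / 159.0
_AIS_PROBS = np.array([60, 35, 41, 23], dtype=float) / 159.0
#: Fraction of subjects tested with the long (15-min seated, 1 kHz) protocol.
_LONG_PROTOCOL_FRAC = 76.0 / 159.0


def make_cluster_templates() -> list[ClusterTemplate]:
    """The eight built-in cluster templates (sizes 24, 2, 20, 33, 23, 3, 28, 26)."""
    return [ClusterTemplate(*row) for row in _TEMPLATE_ROWS]


def _sample_feature(
    rng: np.random.Generator, n: int, lo: float, med: float, hi: float, spread: float
) -> np.ndarray:
    """Draw n values in [lo, hi] centred on the printed median.

    For n <= 3 the printed summary determines the sample exactly (min/median/
    max are order statistics of the sample), so those values are returned
    verbatim.  For larger n, draws come from a normal centred on the median
    with SD = (hi - lo)/spread, truncated to [lo, hi].
    """
    if lo > hi:
        raise ValueError(f"feature range inverted: min {lo} > max {hi}")
    if n == 1:
        return np.array([med], dtype=float)
    if n == 2:
        return np.array([lo, hi], dtype=float)
    if n == 3:
        return np.array([lo, med, hi], dtype=float)
    if hi == lo:
        return np.full(n, med, dtype=float)
    sd = (hi - lo) / spread
    a, b = (lo - med) / sd, (hi - med) / sd
    return np.asarray(truncnorm.rvs(a, b, loc=med, scale=sd, size=n, random_state=rng))


def generate_cohort(
    templates: list[ClusterTemplate] | None = None,
    seed: int = 0,
    spread: float = DEFAULT_SPREAD,
    long_protocol_frac: float = _LONG_PROTOCOL_FRAC,
) -> list[SubjectProfile]:
    """Sample a cohort of subject profiles from cluster templates.

    Each template contributes exactly ``template.n`` subjects whose target
    (dSBP, dDBP, dHR) lie within the template's printed ranges.  Supine
    baselines are drawn from population-typical distributions.  Seated
    protocol duration/sampling rate are assigned at the study's site mix
    (240 s @ 500 Hz vs 900 s @ 1000 Hz).  Identical seed -> identical cohort.
    """
    if templates is None:
        templates = make_cluster_templates()
    rng = np.random.default_rng(seed)
    profiles: list[SubjectProfile] = []
    sid = 0
    for tpl in templates:
        rng_t = np.random.default_rng(rng.integers(0, 2**31 - 1))
        r = tpl.ranges()
        dsbp = _sample_feature(rng_t, tpl.n, *r["sbp"], spread)
        ddbp = _sample_feature(rng_t, tpl.n, *r["dbp"], spread)
        dhr = _sample_feature(rng_t, tpl.n, *r["hr"], spread)
        for i in range(tpl.n):
            sup_sbp = float(np.clip(rng_t.normal(120.0, 10.0), 100.0, 145.0))
            pulse = float(np.clip(rng_t.normal(45.0, 6.0), 30.0, 60.0))
            sup_hr = float(np.clip(rng_t.normal(68.0, 8.0), 52.0, 92.0))
            long_proto = rng_t.random() < long_protocol_frac
            profiles.append(
                SubjectProfile(
                    subject_id=f"S{sid:03d}",
                    cluster_id=tpl.cluster_id,
                    level_group=LEVEL_GROUPS[rng_t.choice(3, p=_LEVEL_PROBS)],
                    ais=AIS_GRADES[rng_t.choice(4, p=_AIS_PROBS)],
                    supine_sbp=round(sup_sbp, 1),
                    supine_dbp=round(sup_sbp - pulse, 1),
                    supine_hr=round(sup_hr, 1),
                    target_dsbp=float(dsbp[i]),
                    target_ddbp=float(ddbp[i]),
                    target_dhr=float(dhr[i]),
                    seated_duration=900.0 if long_proto else 240.0,
                    fs=1000.0 if long_proto else 500.0,
                )
            )
            sid += 1
    return profiles


def cohort_to_frame(profiles: list[SubjectProfile]) -> pd.DataFrame:
    """One row per subject, columns = SubjectProfile fields."""
    return pd.DataFrame([asdict(p) for p in profiles])


def frame_to_cohort(df: pd.DataFrame) -> list[SubjectProfile]:
    names = [f.name for f in fields(SubjectProfile)]
    missing = [c for c in names if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing column(s): {', '.join(missing)}")
    return [SubjectProfile(**{k: row[k] for k in names}) for row in df.to_dict("records")]
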