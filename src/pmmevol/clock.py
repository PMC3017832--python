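"""Molecular-clock calibration and divergence dating.

A per-year synonymous substitution rate is calibrated from a dated species
split as k = dS / 2t, then other splits are dated as T = dS / 2k with the
standard error propagated linearly (se_T = se_dS / 2k).

Conventions chosen to match classical published tables of this kind:
averaged dS carries the arithmetic mean of the member SEs (not the SE of the
mean), and dating uses the rate rounded to 2 significant figures by default
(the rounded rate is what such papers print and then reuse).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .distances import DistanceEstimate


class ClockError(ValueError):
    pass


def round_sig(x: float, sig: int = 2) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


@dataclass
class AveragedDistance:
    """Arithmetic mean of a group of pairwise dS estimates."""

    value: float
    se: float
    members: list = field(default_factory=list)
    label: str = ""

    def __str__(self):
        return f"{self.value:.4f} ± {self.se:.4f}"


def average_ds(estimates, label: str = "", member_labels=None) -> AveragedDistance:
    """Average a group of dS estimates: mean of values, mean of SEs."""
    ests = list(estimates)
    if not ests:
        raise ClockError("cannot average an empty group")
    vals, ses = [], []
    for e in ests:
        if isinstance(e, DistanceEstimate):
            if not e.applicable:
                raise ClockError("inapplicable estimate in averaging group")
            vals.append(e.value)
            ses.append(e.se)
        else:  # (value, se) tuple
            v, s = e
            vals.append(v)
            ses.append(s)
    return AveragedDistance(
        value=sum(vals) / len(vals),
        se=sum(ses) / len(ses),
        members=list(member_labels or []),
        label=label,
    )


@dataclass
class ClockCalibration:
    """A substitution rate tied to a dated calibration split."""

    rate_k: float  # substitutions / synonymous site / year
    calibration_time_t: float  # years
    rounded_rate: float
    label: str = ""

    def __post_init__(self):
        if self.rate_k > 0:
            assert abs(self.rounded_rate - self.rate_k) <= 0.05 * self.rate_k


def calibrate_rate(avg_ds: AveragedDistance, t_years: float,
                   label: str = "") -> ClockCalibration:
    """k = dS / 2t from an averaged dS and a known split time in years."""
    if t_years <= 0:
        raise ClockError(f"calibration time must be positive, got {t_years}")
    k = avg_ds.value / (2.0 * t_years)
    return ClockCalibration(
        rate_k=k,
        calibration_time_t=t_years,
        rounded_rate=round_sig(k, 2),
        label=label or avg_ds.label,
    )


@dataclass
class DivergenceEstimate:
    """A dated split: T = dS/2k, se_T = se_dS/2k (years)."""

    time_T: float
    se_T: float
    ds_label: str = ""
    rate_label: str = ""
    rate_used: float = 0.0

    @property
    def mya(self) -> float:
        return self.time_T / 1e6

    @property
    def se_mya(self) -> float:
        return self.se_T / 1e6

    def __str__(self):
        return f"{self.mya:.1f} ± {self.se_mya:.1f} MY"


def divergence_time(ds: AveragedDistance, calibration: ClockCalibration,
                    use_rounded: bool = True) -> DivergenceEstimate:
    """Date a split from an (averaged) dS and a calibrated rate."""
    k = calibration.rounded_rate if use_rounded else calibration.rate_k
    if k <= 0:
        if ds.value == 0:
            return DivergenceEstimate(0.0, 0.0, ds.label, calibration.label, k)
        raise ClockError("calibration rate is zero")
    return DivergenceEstimate(
        time_T=ds.value / (2.0 * k),
        se_T=ds.se / (2.0 * k),
        ds_label=ds.label,
        rate_label=calibration.label,
        rate_used=k,
    )


def dating_table(rows) -> str:
    """TSV dating report: comparison, time ± se (MY, 1 decimal), dS used."""
    lines = ["comparison\tdivergence_time_MYA\taveraged_dS"]
    for label, est, ds in rows:
        lines.append(
            f"{label}\t{est.mya:.1f} ± {est.se_mya:.1f}\t"
            f"{ds.value:.4f} ± {ds.se:.4f}"
        )
    return "\n".join(lines) + "\n"
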