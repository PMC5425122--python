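"""Mean z-score trajectories, crossing-age and acceleration analysis.

After the screen, the increasing and decreasing probe sets each get a
summary trajectory: the unweighted mean of their members' z-scored
window-mean series, plotted against window mean age.  Two quantities
formalize what is usually read off such a figure by eye:

* the *crossing age* — where the increasing and decreasing trajectories
  meet, found as the interpolated root of their difference; and
* the *acceleration interval* — the age span over which the trajectories
  separate fastest, found as the longest contiguous run of windows whose
  central-difference slope of the trajectory difference is at or above a
  chosen quantile of all slopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ValidationError


@dataclass
class TrajectoryPair:
    """Mean z-score trajectories of the increasing and decreasing sets."""

    ages: np.ndarray
    mean_z_increasing: np.ndarray
    mean_z_decreasing: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.mean_z_increasing = np.asarray(self.mean_z_increasing, dtype=float)
        self.mean_z_decreasing = np.asarray(self.mean_z_decreasing, dtype=float)
        if not (
            len(self.ages)
            == len(self.mean_z_increasing)
            == len(self.mean_z_decreasing)
        ):
            raise ValidationError("trajectory series lengths differ")

    def difference(self) -> np.ndarray:
        return self.mean_z_increasing - self.mean_z_decreasing

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_mean_age": self.ages,
                "mean_z_inc": self.mean_z_increasing,
                "mean_z_dec": self.mean_z_decreasing,
            }
        )


@dataclass
class CrossingReport:
    """Crossing ages and (optionally) the acceleration interval."""

    crossing_ages: list[float]
    primary_crossing: float | None = None
    acceleration_interval: tuple[float, float] | None = None
    flat_slope: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.crossing_ages and self.primary_crossing is None:
            self.primary_crossing = self.crossing_ages[0]


def mean_trajectories(
    zscores: pd.DataFrame, trend_table: pd.DataFrame, mean_ages
) -> TrajectoryPair:
    """Unweighted mean z-trajectory of each trend class.

    Raises when either class is empty — a trajectory of nothing is
    meaningless and usually signals thresholds that retained no probes.
    """
    labels = trend_table.set_index("probeset")["trend"]
    out = {}
    for cls in ("increasing", "decreasing"):
        members = labels.index[labels == cls]
        if len(members) == 0:
            raise ValidationError(f"no probes in class {cls!r}")
        out[cls] = zscores.loc[members].to_numpy(dtype=float).mean(axis=0)
    return TrajectoryPair(np.asarray(mean_ages, dtype=float), out["increasing"], out["decreasing"])


def crossing_age(pair: TrajectoryPair) -> CrossingReport:
    """All ages where the two trajectories cross, by linear interpolation.

    A crossing is reported at each sign change of
    ``d = mean_z_increasing - mean_z_decreasing``, located by linear
    interpolation between the bracketing window mean ages; an exact zero
    reports that window's age itself.  No sign change gives an empty list.
    The first (youngest) crossing is the primary one.
    """
    if len(pair.ages) < 2:
        raise ValidationError("need >= 2 windows to find a crossing")
    d = pair.difference()
    ages = pair.ages
    crossings: list[float] = []
    for k, dk in enumerate(d):
        if dk == 0.0:
            crossings.append(float(ages[k]))
    for k in range(len(d) - 1):
        if d[k] * d[k + 1] < 0:
            frac = d[k] / (d[k] - d[k + 1])
            crossings.append(float(ages[k] + frac * (ages[k + 1] - ages[k])))
    crossings.sort()
    return CrossingReport(crossings)


def steepest_change_interval(
    pair: TrajectoryPair, quantile: float = 0.75
) -> tuple[tuple[float, float], bool]:
    """Age span where the trajectories separate fastest.

    Central-difference slopes ``|d'(age)|`` are computed on the trajectory
    difference; the interval is the age span of the longest contiguous run
    of windows whose slope is at or above the given quantile of all
    slopes.  When every slope is equal (a linear difference) there is no
    distinguished run: the full age range is returned with the flag set.

    Returns ``((age_lo, age_hi), flat)``.
    """
    if len(pair.ages) < 3:
        raise ValidationError("need >= 3 windows for slope analysis")
    if not 0 <= quantile < 1:
        raise ValidationError("quantile must lie in [0, 1)")
    d = pair.difference()
    ages = pair.ages
    slopes = np.abs(np.gradient(d, ages))
    if np.allclose(slopes, slopes[0]):
        return (float(ages[0]), float(ages[-1])), True
    cut = np.quantile(slopes, quantile)
    above = slopes >= cut
    best_start, best_len = 0, 0
    k = 0
    while k < len(above):
        if above[k]:
            j = k
            while j < len(above) and above[j]:
                j += 1
            if j - k > best_len:
                best_start, best_len = k, j - k
            k = j
        else:
            k += 1
    lo = float(ages[best_start])
    hi = float(ages[best_start + best_len - 1])
    return (lo, hi), False


def analyze_trajectories(
    zscores: pd.DataFrame,
    trend_table: pd.DataFrame,
    mean_ages,
    quantile: float = 0.75,
) -> tuple[TrajectoryPair, CrossingReport]:
    """Trajectories, crossings and acceleration interval in one call."""
    pair = mean_trajectories(zscores, trend_table, mean_ages)
    report = crossing_age(pair)
    (lo, hi), flat = steepest_change_interval(pair, quantile=quantile)
    report.acceleration_interval = (lo, hi)
    report.flat_slope = flat
    return pair, report
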