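"""Measured interactions from two-density plate-reader growth curves.

The intraspecific interaction of a culture with itself is estimated by
inoculating the same condition at two densities (ratio R, default 4:1).
The low-density wells act as a monoculture-like reference for a matched
subpopulation of the high-density wells, so after background correction the
*measured interaction* at each timepoint is

    m(t) = OD_high(t)/R - OD_low(t),

positive when the extra cells in the high-density wells helped the matched
subpopulation (e.g., by detoxifying the medium faster), negative when they
hindered it (e.g., by depleting the nutrient sooner).

Background correction first estimates the true initial OD contribution of
cells in the high-density wells,

    kappa = R/(R-1) * (<OD_h0> - <OD_l0>),

from the plate-wide mean initial readings of the two classes (at R=4 this is
the familiar 4/3 prefactor), then shifts every well to zero by the mean of
its first three readings and re-adds kappa (high) or kappa/R (low).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "WellSeries",
    "PlateData",
    "MeasuredInteractionCurve",
    "InteractionSummary",
    "read_plate_csv",
    "write_plate_csv",
    "background_correct",
    "measured_interaction",
    "summarize",
    "sign_switch_time",
]

PLATE_COLUMNS = ["time_h", "well", "condition", "density_class", "replicate", "od"]
DENSITY_CLASSES = ("high", "low")


@dataclass
class WellSeries:
    """One well's OD600 timecourse."""

    well: str
    condition: str
    density_class: str
    replicate: int
    times: np.ndarray
    od: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.density_class not in DENSITY_CLASSES:
            raise ValidationError(
                f"well {self.well}: density_class must be one of {DENSITY_CLASSES}, "
                f"got {self.density_class!r}"
            )
        if self.times.shape != self.od.shape or self.times.ndim != 1:
            raise ValidationError(f"well {self.well}: times/od shape mismatch")
        if not np.all(np.diff(self.times) > 0):
            raise ValidationError(f"well {self.well}: times must be strictly increasing")
        if not np.all(np.isfinite(self.od)):
            raise ValidationError(f"well {self.well}: non-finite OD readings")


@dataclass
class PlateData:
    """A collection of well series sharing a common time grid.

    ``ratio`` is the high:low inoculation density ratio R.  Series on
    different time grids are linearly interpolated onto the intersection
    grid at construction (with a warning).
    """

    series: list
    ratio: float = 4.0
    metadata: dict = field(default_factory=dict)
    corrected: bool = False

    def __post_init__(self):
        if self.ratio <= 1:
            raise ValidationError(f"inoculation ratio must exceed 1, got {self.ratio}")
        if not self.series:
            raise ValidationError("plate contains no well series")
        self._align_time_grids()
        missing = []
        for cond in self.conditions:
            classes = {w.density_class for w in self.series if w.condition == cond}
            if set(DENSITY_CLASSES) - classes:
                missing.append((cond, sorted(set(DENSITY_CLASSES) - classes)))
        if missing:
            raise ValidationError(
                "conditions missing a density class: "
                + "; ".join(f"{c} lacks {m}" for c, m in missing)
            )

    def _align_time_grids(self):
        grids = {tuple(w.times) for w in self.series}
        if len(grids) == 1:
            return
        lo = max(w.times[0] for w in self.series)
        hi = min(w.times[-1] for w in self.series)
        if hi <= lo:
            raise ValidationError("well time ranges do not overlap")
        finest = min(np.diff(w.times).min() for w in self.series)
        common = np.arange(lo, hi + finest / 2, finest)
        warnings.warn(
            f"wells use {len(grids)} different time grids; resampling onto the "
            f"common range [{lo:g}, {hi:g}] h",
            stacklevel=3,
        )
        for w in self.series:
            w.od = np.interp(common, w.times, w.od)
            w.times = common

    @property
    def times(self) -> np.ndarray:
        return self.series[0].times

    @property
    def conditions(self) -> list:
        seen = dict.fromkeys(w.condition for w in self.series)
        return list(seen)

    def wells(self, condition: str, density_class: Optional[str] = None) -> list:
        out = [w for w in self.series if w.condition == condition]
        if density_class is not None:
            out = [w for w in out if w.density_class == density_class]
        return out

    def class_average(self, condition: str, density_class: str) -> np.ndarray:
        wells = self.wells(condition, density_class)
        if not wells:
            raise ValidationError(f"no {density_class} wells for condition {condition!r}")
        return np.mean([w.od for w in wells], axis=0)


@dataclass
class MeasuredInteractionCurve:
    """Normalised high-density minus low-density OD difference over time."""

    condition: str
    times: np.ndarray
    values: np.ndarray
    smoothed: Optional[np.ndarray] = None


@dataclass(frozen=True)
class InteractionSummary:
    """Peak and final values of a measured-interaction curve.

    Peak and final are reported independently; a monotone-negative curve has
    its peak at t=0.
    """

    condition: str
    peak: float
    peak_time: float
    final: float


def read_plate_csv(path) -> PlateData:
    """Read a long-format plate CSV: time_h, well, condition, density_class, replicate, od."""
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"plate CSV {path} lacks columns {missing}")
    bad = df[~np.isfinite(pd.to_numeric(df["od"], errors="coerce"))]
    if len(bad):
        lines = (bad.index + 2).tolist()[:10]  # +2: header and 1-based numbering
        raise ValidationError(f"malformed od values at CSV lines {lines}")
    series = []
    for (well, cond, dclass, rep), grp in df.groupby(
        ["well", "condition", "density_class", "replicate"], sort=False
    ):
        grp = grp.sort_values("time_h")
        series.append(
            WellSeries(
                well=str(well),
                condition=str(cond),
                density_class=str(dclass),
                replicate=int(rep),
                times=grp["time_h"].to_numpy(dtype=float),
                od=grp["od"].to_numpy(dtype=float),
            )
        )
    ratio = 4.0
    meta = {}
    return PlateData(series=series, ratio=ratio, metadata=meta)


def write_plate_csv(plate: PlateData, path) -> None:
    """Write a PlateData back to the long-format CSV read by read_plate_csv."""
    rows = []
    for w in plate.series:
        rows.append(
            pd.DataFrame(
                {
                    "time_h": w.times,
                    "well": w.well,
                    "condition": w.condition,
                    "density_class": w.density_class,
                    "replicate": w.replicate,
                    "od": w.od,
                }
            )
        )
    pd.concat(rows, ignore_index=True)[PLATE_COLUMNS].to_csv(path, index=False)


def background_correct(plate: PlateData, n_initial: int = 3) -> PlateData:
    """Remove well backgrounds and restore the true inoculum OD signal.

    kappa = R/(R-1) * (<OD_h0> - <OD_l0>) estimates the initial cell OD in
    the high-density wells from the plate-wide means of the first
    ``n_initial`` readings per class.  Each series is zeroed by its own
    initial mean, then shifted up by kappa (high) or kappa/R (low).
    """
    if plate.times.size < n_initial:
        raise ValidationError(f"need at least {n_initial} timepoints per series")
    R = plate.ratio

    def class_initial_mean(dclass):
        vals = [w.od[:n_initial].mean() for w in plate.series if w.density_class == dclass]
        return float(np.mean(vals))

    diff = class_initial_mean("high") - class_initial_mean("low")
    if diff <= 0:
        warnings.warn(
            f"high-class initial OD does not exceed low-class (difference {diff:.4g}); "
            "no detectable inoculum signal, clipping kappa at 0",
            stacklevel=2,
        )
        diff = 0.0
    kappa = R / (R - 1.0) * diff
    new_series = []
    for w in plate.series:
        offset = kappa if w.density_class == "high" else kappa / R
        new_series.append(
            replace(w, times=w.times.copy(), od=w.od - w.od[:n_initial].mean() + offset)
        )
    return PlateData(
        series=new_series,
        ratio=R,
        metadata={**plate.metadata, "kappa": kappa},
        corrected=True,
    )


def _loess_smooth(times: np.ndarray, values: np.ndarray, span: float) -> np.ndarray:
    from statsmodels.nonparametric.smoothers_lowess import lowess

    return lowess(values, times, frac=span, return_sorted=False)


def measured_interaction(
    plate: PlateData,
    condition: str,
    *,
    smooth: bool = False,
    span: float = 0.2,
    method: str = "difference",
) -> MeasuredInteractionCurve:
    """Replicate-averaged measured interaction of one condition.

    ``method`` selects the comparison between the normalised high curve
    h(t)/R and the low curve l(t): ``difference`` (default, h/R - l),
    ``ratio`` ((h/R)/l) or ``log_ratio`` (log of the ratio).  The abundance
    difference tracks the shape of the underlying cumulative interaction
    while staying robust to measurement noise; the alternatives are exposed
    for comparison only.
    """
    if not plate.corrected:
        warnings.warn(
            "plate has not been background-corrected; interactions will include "
            "background offsets",
            stacklevel=2,
        )
    high = plate.class_average(condition, "high")
    low = plate.class_average(condition, "low")
    norm_high = high / plate.ratio
    if method == "difference":
        values = norm_high - low
    elif method == "ratio":
        values = norm_high / np.where(low != 0, low, np.nan)
    elif method == "log_ratio":
        with np.errstate(divide="ignore", invalid="ignore"):
            values = np.log(norm_high / np.where(low != 0, low, np.nan))
    else:
        raise ValidationError(f"unknown method {method!r}")
    smoothed = _loess_smooth(plate.times, values, span) if smooth else None
    return MeasuredInteractionCurve(
        condition=condition, times=plate.times.copy(), values=values, smoothed=smoothed
    )


def summarize(curve: MeasuredInteractionCurve, *, use_smoothed: bool = False) -> InteractionSummary:
    """Peak value (with its time) and final value of an interaction curve."""
    v = curve.smoothed if (use_smoothed and curve.smoothed is not None) else curve.values
    if v.size == 0:
        raise ValidationError("empty interaction curve")
    i = int(np.argmax(v))
    return InteractionSummary(
        condition=curve.condition,
        peak=float(v[i]),
        peak_time=float(curve.times[i]),
        final=float(v[-1]),
    )


def sign_switch_time(curve: MeasuredInteractionCurve, *, threshold: float = 0.0) -> Optional[float]:
    """First positive-to-negative crossing of the measured interaction.

    ``threshold`` requires the curve to have exceeded +threshold before the
    crossing counts (guards against noise-level wiggles around zero).
    Returns None if the curve never switches.
    """
    v = curve.values
    armed = False
    for i in range(1, v.size):
        if v[i - 1] > threshold:
            armed = True
        if armed and v[i - 1] > 0 and v[i] <= 0:
            t0, t1 = curve.times[i - 1], curve.times[i]
            return float(t0 + (t1 - t0) * v[i - 1] / (v[i - 1] - v[i]))
    return None
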