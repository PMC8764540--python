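"""Measured strain physiology and its conversion into model-ready rates.

The measured channels of a nitrogen-limited octanoate batch culture are
total biomass (g/L), PHA content (% of cell dry weight), free
(R)-3-hydroxyalkanoate concentration (g/L), residual octanoate (mM) and,
optionally, viable-cell counts and MicroResp OD570 readings.

Because the polymer fraction inflates both dry weight and turbidity, growth
rates are computed on *residual biomass* — cell dry weight free of PHA —
as the least-squares slope of log10(residual biomass) against time,
converted to natural-log units (h^-1).

Specific rates (mmol gCDW^-1 h^-1) divide a concentration change by its
molar mass, the interval length, and the mean residual biomass over the
interval, which is what a constraint-based model expects as an exchange
bound.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

#: Conversion between log10 and natural-log slopes.  The 4-figure value
#: 2.303 commonly printed in physiology methods is this constant rounded.
LOG10_TO_LN = math.log(10.0)

#: Default phase boundaries (h): phase I [0,5), II [5,10), III [10,24].
DEFAULT_PHASE_BOUNDARIES = (5.0, 10.0)

# CSV schema (External interface): header row with these columns; the
# optional ones may be absent.
CSV_REQUIRED_COLUMNS = [
    "time_h", "total_biomass_gL", "pha_pct_cdw", "ha_gL", "octanoate_mM",
]
CSV_OPTIONAL_COLUMNS = ["viable_cells_1e8ml", "od570"]


class InsufficientDataError(ValueError):
    """Fewer usable data points than an operation requires."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Phase:
    """A growth phase: half-open interval [t_start, t_end) in hours.

    The last phase of a segmentation is closed at its right edge so the
    final sample (24 h) belongs to phase III.
    """

    label: str
    t_start: float
    t_end: float
    closed_right: bool = False

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError(
                f"phase {self.label!r}: t_start {self.t_start} >= t_end {self.t_end}"
            )

    def contains(self, t: float) -> bool:
        if self.closed_right:
            return self.t_start <= t <= self.t_end
        return self.t_start <= t < self.t_end

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class CalibrationCurve:
    """MicroResp rectangular hyperbola  %CO2 = A*x / (B + x), x = OD570.

    Packaged defaults A = 1.73 %CO2 and B = -0.13 OD570 units.  With B < 0
    the curve has a vertical asymptote at x = -B = 0.13: readings are valid
    only for x > 0.13, where the curve is monotone *decreasing* toward the
    horizontal asymptote A (more CO2 acidifies the cresol-red dye and lowers
    the absorbance).
    """

    A: float = 1.73
    B: float = -0.13

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError(f"calibration asymptote A must be > 0, got {self.A}")


@dataclass
class MonomerMassTable:
    """Molar masses (g/mmol) used to convert g/L deltas to mmol.

    PHA is quantified as the dehydrated C8 repeat unit (3-hydroxyoctanoate
    in chain, 142.20 g/mol); free (R)-HA as 3-hydroxyoctanoic acid
    (160.21 g/mol).  Octanoate is measured in mM so its mass is unused by
    the standard pipeline but kept for completeness (octanoic acid,
    144.21 g/mol).
    """

    pha_repeat_unit: float = 0.14220
    ha_free_acid: float = 0.16021
    octanoate: float = 0.14421

    def __post_init__(self) -> None:
        for name in ("pha_repeat_unit", "ha_free_acid", "octanoate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"molar mass {name} must be > 0")


@dataclass
class PhysioTimeCourse:
    """One strain's measured trajectories in physical units."""

    strain: str
    times: np.ndarray                  # h, strictly increasing from 0
    total_biomass: np.ndarray          # g/L
    pha_pct_cdw: np.ndarray            # % of CDW
    ha_conc: np.ndarray                # g/L
    octanoate: np.ndarray              # mM
    viable_cells: Optional[np.ndarray] = None   # 10^8 / ml
    od570: Optional[np.ndarray] = None          # MicroResp absorbance

    def __post_init__(self) -> None:
        arrays = {
            "times": self.times,
            "total_biomass": self.total_biomass,
            "pha_pct_cdw": self.pha_pct_cdw,
            "ha_conc": self.ha_conc,
            "octanoate": self.octanoate,
        }
        for name, arr in arrays.items():
            setattr(self, name, np.asarray(arr, dtype=float))
        n = len(self.times)
        for name in ("total_biomass", "pha_pct_cdw", "ha_conc", "octanoate"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name} length != times length")
        if n and self.times[0] != 0.0:
            raise ValueError("time course must start at t = 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for name in ("total_biomass", "ha_conc", "octanoate"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"negative values in {name}")
        if np.any((self.pha_pct_cdw < 0) | (self.pha_pct_cdw > 100)):
            raise ValueError("pha_pct_cdw outside [0, 100]")
        for name in ("viable_cells", "od570"):
            val = getattr(self, name)
            if val is not None:
                val = np.asarray(val, dtype=float)
                if len(val) != n:
                    raise ValueError(f"channel {name} length != times length")
                setattr(self, name, val)

    # -- derived channels -------------------------------------------------
    @property
    def residual_biomass_series(self) -> np.ndarray:
        return self.total_biomass * (1.0 - self.pha_pct_cdw / 100.0)

    @property
    def pha_conc_series(self) -> np.ndarray:
        return self.total_biomass * self.pha_pct_cdw / 100.0

    def interp(self, channel: str, t: float) -> float:
        """Linear interpolation of a (derived) channel at time ``t``."""
        series = {
            "residual_biomass": self.residual_biomass_series,
            "pha_conc": self.pha_conc_series,
            "total_biomass": self.total_biomass,
            "ha_conc": self.ha_conc,
            "octanoate": self.octanoate,
        }[channel]
        return float(np.interp(t, self.times, series))

    # -- CSV I/O ----------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        data = {
            "time_h": self.times,
            "total_biomass_gL": self.total_biomass,
            "pha_pct_cdw": self.pha_pct_cdw,
            "ha_gL": self.ha_conc,
            "octanoate_mM": self.octanoate,
        }
        if self.viable_cells is not None:
            data["viable_cells_1e8ml"] = self.viable_cells
        if self.od570 is not None:
            data["od570"] = self.od570
        return pd.DataFrame(data)

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str, strain: Optional[str] = None) -> "PhysioTimeCourse":
        df = pd.read_csv(path)
        missing = [c for c in CSV_REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
        kwargs = {}
        for col, attr in (("viable_cells_1e8ml", "viable_cells"), ("od570", "od570")):
            if col in df.columns:
                kwargs[attr] = df[col].to_numpy(dtype=float)
        return cls(
            strain=strain or str(path),
            times=df["time_h"].to_numpy(dtype=float),
            total_biomass=df["total_biomass_gL"].to_numpy(dtype=float),
            pha_pct_cdw=df["pha_pct_cdw"].to_numpy(dtype=float),
            ha_conc=df["ha_gL"].to_numpy(dtype=float),
            octanoate=df["octanoate_mM"].to_numpy(dtype=float),
            **kwargs,
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def residual_biomass(total: float, pha_pct: float) -> float:
    """Residual (PHA-free) biomass in g/L: ``total * (1 - pha_pct/100)``."""
    if total < 0:
        raise ValueError(f"total biomass must be >= 0, got {total}")
    if not 0.0 <= pha_pct <= 100.0:
        raise ValueError(f"pha_pct must be in [0, 100], got {pha_pct}")
    return total * (1.0 - pha_pct / 100.0)


def pha_conc(total: float, pha_pct: float) -> float:
    """PHA concentration in g/L: ``total * pha_pct/100``."""
    if total < 0:
        raise ValueError(f"total biomass must be >= 0, got {total}")
    if not 0.0 <= pha_pct <= 100.0:
        raise ValueError(f"pha_pct must be in [0, 100], got {pha_pct}")
    return total * pha_pct / 100.0


def compute_growth_rate(tc: PhysioTimeCourse, window: Phase) -> float:
    """Specific growth rate (h^-1) over ``window``.

    Least-squares slope of log10(residual biomass) versus time over the
    samples the window contains, converted to natural-log units.  Points
    with non-positive residual biomass are excluded with a warning rather
    than raising; fewer than two usable points raises
    :class:`InsufficientDataError`.
    """
    residual = tc.residual_biomass_series
    in_window = np.array([window.contains(t) for t in tc.times])
    usable = in_window & (residual > 0)
    n_dropped = int(in_window.sum() - usable.sum())
    if n_dropped:
        warnings.warn(
            f"{tc.strain}: excluded {n_dropped} non-positive residual-biomass "
            f"point(s) from the growth-rate fit in phase {window.label}",
            stacklevel=2,
        )
    if usable.sum() < 2:
        raise InsufficientDataError(
            f"{tc.strain}: phase {window.label} has {int(usable.sum())} usable "
            "point(s); need >= 2 for a growth-rate fit"
        )
    t = tc.times[usable]
    y = np.log10(residual[usable])
    slope = np.polyfit(t, y, 1)[0]
    return float(slope * LOG10_TO_LN)


def specific_rate(
    delta_mass: float,
    interval: float,
    mean_residual_biomass: float,
    molar_mass: float,
) -> float:
    """Specific conversion rate in mmol gCDW^-1 h^-1.

    ``(delta_mass / molar_mass) / (interval * mean_residual_biomass)``;
    the sign follows ``delta_mass`` (consumption negative).  ``delta_mass``
    in g/L, ``interval`` in h, biomass in g/L, ``molar_mass`` in g/mmol.
    """
    if interval <= 0:
        raise ValueError(f"interval must be > 0, got {interval}")
    if molar_mass <= 0:
        raise ValueError(f"molar mass must be > 0, got {molar_mass}")
    if mean_residual_biomass <= 0:
        raise ZeroDivisionError(
            "mean residual biomass must be > 0 to normalize a specific rate "
            f"(got {mean_residual_biomass} g/L)"
        )
    return (delta_mass / molar_mass) / (interval * mean_residual_biomass)


def mean_residual_biomass(
    tc: PhysioTimeCourse, phase: Phase, strategy: str = "endpoint-mean"
) -> float:
    """Interval-mean residual biomass (g/L) used to normalize rates.

    ``endpoint-mean`` (default) is the arithmetic mean of the interpolated
    endpoint values; ``log-mean`` is their logarithmic mean, which is exact
    for exponential growth between the endpoints.
    """
    x0 = tc.interp("residual_biomass", phase.t_start)
    x1 = tc.interp("residual_biomass", phase.t_end)
    if strategy == "endpoint-mean":
        return 0.5 * (x0 + x1)
    if strategy == "log-mean":
        if x0 <= 0 or x1 <= 0:
            raise ValueError("log-mean needs positive endpoint biomasses")
        if math.isclose(x0, x1):
            return x0
        return (x1 - x0) / math.log(x1 / x0)
    raise ValueError(f"unknown biomass-averaging strategy {strategy!r}")


def segment_phases(
    tc: PhysioTimeCourse,
    boundaries: Sequence[float] = DEFAULT_PHASE_BOUNDARIES,
) -> List[Phase]:
    """Cut the time course into ordered, non-overlapping phases.

    Default boundaries (5, 10) on a 0-24 h course yield phase I [0,5),
    II [5,10) and III [10,24] (last phase closed).  Boundaries beyond the
    final sampling time are dropped, so a course ending before the first
    boundary yields a single phase I.
    """
    bounds = list(boundaries)
    if bounds != sorted(bounds):
        raise ValueError(f"phase boundaries must be sorted, got {boundaries}")
    t_end = float(tc.times[-1])
    bounds = [b for b in bounds if 0.0 < b < t_end]
    edges = [0.0] + bounds + [t_end]
    labels = ["I", "II", "III", "IV", "V"]
    phases = []
    for k in range(len(edges) - 1):
        phases.append(
            Phase(
                label=labels[k] if k < len(labels) else str(k + 1),
                t_start=edges[k],
                t_end=edges[k + 1],
                closed_right=(k == len(edges) - 2),
            )
        )
    return phases


def microresp_percent_co2(od570: float, calib: CalibrationCurve) -> float:
    """Convert a MicroResp OD570 reading to %CO2 via the calibration
    hyperbola ``A*x / (B + x)``.

    Valid only right of the vertical asymptote (``od570 + B > 0``); there
    the packaged calibration is monotone decreasing in the absorbance and
    approaches A from above as the reading grows.
    """
    if od570 + calib.B <= 0:
        raise ValueError(
            f"OD570 reading {od570} is on or left of the calibration asymptote "
            f"at {-calib.B}; the hyperbola is undefined there"
        )
    return calib.A * od570 / (calib.B + od570)


def relative_co2(samples: Dict[str, float], reference: str) -> Dict[str, float]:
    """Normalize per-strain %CO2 values to a reference strain (fold units)."""
    if reference not in samples:
        raise KeyError(f"reference strain {reference!r} not among samples")
    ref = samples[reference]
    if ref <= 0:
        raise ValueError(f"reference {reference!r} has non-positive CO2 {ref}")
    return {strain: value / ref for strain, value in samples.items()}
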