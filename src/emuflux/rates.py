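"""Specific-rate estimation from batch-culture time courses.

During balanced exponential growth, extracellular mass balances read
d[glucose]/dt = -nu*X and d[acetate]/dt = rho*X, with X the biomass
concentration (g-DCW/l) and nu, rho the biomass-specific rates
(mmol/g-DCW/h).  Integrating once gives concentration as a *linear*
function of the time-integrated biomass, so nu and rho fall out as ordinary
regression slopes of concentration against integral(X dt) — robust to the
exponential shape of X and insensitive to the absolute time origin.  The
growth rate mu is the slope of ln X against time over a user-chosen
exponential window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.stats import linregress

__all__ = [
    "TimeCourse",
    "SpecificRates",
    "integrated_biomass",
    "fit_specific_rate",
    "growth_rate",
    "estimate_rates",
]


@dataclass
class TimeCourse:
    """Sampled culture: times (h), biomass (g-DCW/l) and analyte
    concentrations (mmol/l).

    When the instrument records OD, convert with an explicit OD-to-DCW
    factor before constructing; the factor is culture-specific and must not
    be silently assumed.
    """

    time: np.ndarray
    biomass: np.ndarray
    concentrations: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.biomass = np.asarray(self.biomass, float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time points must be strictly increasing")
        if len(self.biomass) != len(self.time):
            raise ValueError("biomass length does not match time")
        if np.any(self.biomass < 0):
            raise ValueError("biomass must be nonnegative")
        self.concentrations = {
            k: np.asarray(v, float) for k, v in self.concentrations.items()}
        for k, v in self.concentrations.items():
            if len(v) != len(self.time):
                raise ValueError(f"analyte {k!r} length does not match time")

    @classmethod
    def from_csv(cls, path, od_to_dcw: float | None = None) -> "TimeCourse":
        """Columns: ``time_h``, ``biomass`` (or ``od`` with a conversion
        factor), then one column per analyte."""
        df = pd.read_csv(path)
        if "biomass" in df.columns:
            biomass = df["biomass"].to_numpy(float)
            drop = ["time_h", "biomass"]
        elif "od" in df.columns:
            if od_to_dcw is None:
                raise ValueError("OD biomass requires an od_to_dcw factor")
            biomass = df["od"].to_numpy(float) * od_to_dcw
            drop = ["time_h", "od"]
        else:
            raise ValueError("need a 'biomass' or 'od' column")
        conc = {c: df[c].to_numpy(float) for c in df.columns if c not in drop}
        return cls(df["time_h"].to_numpy(float), biomass, conc)


@dataclass
class SpecificRates:
    """Fitted rates: mu (1/h) and per-analyte specific rates
    (mmol/g-DCW/h, consumption reported as positive uptake)."""

    mu: float
    mu_se: float
    rates: dict[str, float]
    rate_se: dict[str, float]
    r_squared: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"quantity": "growth_rate", "value": self.mu, "se": self.mu_se,
                 "r_squared": self.r_squared.get("growth_rate", np.nan)}]
        for k in self.rates:
            rows.append({"quantity": k, "value": self.rates[k],
                         "se": self.rate_se[k],
                         "r_squared": self.r_squared.get(k, np.nan)})
        return pd.DataFrame(rows)


def integrated_biomass(tc: TimeCourse) -> np.ndarray:
    """Cumulative trapezoidal integral of X over time (g-DCW h / l),
    starting at 0."""
    if len(tc.time) < 2:
        raise ValueError("need at least two time points")
    return cumulative_trapezoid(tc.biomass, tc.time, initial=0.0)


def fit_specific_rate(
    integ: np.ndarray,
    conc: np.ndarray,
    sign: str = "production",
) -> tuple[float, float, float]:
    """Slope of concentration vs integrated biomass.

    Returns ``(rate, se, r_squared)``; ``sign='consumption'`` negates the
    slope so that uptake of a falling analyte is reported positive.
    """
    integ = np.asarray(integ, float)
    conc = np.asarray(conc, float)
    if len(integ) != len(conc) or len(integ) < 3:
        raise ValueError("need >= 3 paired points")
    if np.ptp(integ) == 0:
        raise ValueError("integrated biomass has zero variance")
    if sign not in ("production", "consumption"):
        raise ValueError(f"unknown sign {sign!r}")
    res = linregress(integ, conc)
    slope = -res.slope if sign == "consumption" else res.slope
    return float(slope), float(res.stderr), float(res.rvalue ** 2)


def growth_rate(
    tc: TimeCourse,
    window: tuple[float, float] | None = None,
) -> tuple[float, float, float]:
    """Exponential growth rate: slope of ln X vs t inside ``window``
    (default: all points).  Returns ``(mu, se, r_squared)``."""
    if window is None:
        mask = np.ones_like(tc.time, bool)
    else:
        mask = (tc.time >= window[0]) & (tc.time <= window[1])
    t = tc.time[mask]
    x = tc.biomass[mask]
    if len(t) < 3:
        raise ValueError("need >= 3 points in the window")
    if np.any(x <= 0):
        raise ValueError("nonpositive biomass in the growth window")
    res = linregress(t, np.log(x))
    return float(res.slope), float(res.stderr), float(res.rvalue ** 2)


def estimate_rates(
    tc: TimeCourse,
    consumed: tuple[str, ...] = ("glucose",),
    window: tuple[float, float] | None = None,
) -> SpecificRates:
    """Full workflow: mu from ln X, then one regression per analyte against
    the integrated biomass; analytes named in ``consumed`` are reported as
    uptake rates."""
    mu, mu_se, mu_r2 = growth_rate(tc, window)
    integ = integrated_biomass(tc)
    rates: dict[str, float] = {}
    ses: dict[str, float] = {}
    r2: dict[str, float] = {"growth_rate": mu_r2}
    for analyte, conc in tc.concentrations.items():
        sign = "consumption" if analyte in consumed else "production"
        rates[analyte], ses[analyte], r2[analyte] = fit_specific_rate(
            integ, conc, sign)
    return SpecificRates(mu, mu_se, rates, ses, r2)
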