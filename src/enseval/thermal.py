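"""Melting-curve construction and apparent melting temperature extraction.

An observable f (folded-state fraction or secondary-structure preservation)
is computed per ensemble across temperatures and fitted with the sigmoid

    f(T) = y_min + (y_max - y_min) / (1 + exp(-(T - Tm) / k_slope))

where y_min and y_max are fixed to the series minimum and maximum and only
(Tm, k_slope) are optimized by nonlinear least squares.  As printed, the
curve rises with T; decreasing observables are handled by a negative fitted
k_slope rather than by flipping the series.  The apparent melting
temperature Tm is the inflection point.

The fit is exposed statsmodels-style: :class:`MeltCurveModel` wraps one
series, ``fit()`` returns a :class:`MeltCurveResults` carrying estimates,
residuals and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .core import Conformation, Ensemble
from .scores import (
    folded_state_fraction,
    native_contacts,
    native_sse,
    ssep,
)

__all__ = [
    "MeltSeries",
    "MeltFit",
    "MeltCurveModel",
    "MeltCurveResults",
    "build_melt_series",
    "fit_sigmoid",
    "melting_temperature",
    "delta_tm",
]

OBSERVABLES = ("FSF", "SSEP")


@dataclass(frozen=True)
class MeltSeries:
    """An observable-vs-temperature series (temperatures strictly increasing)."""

    temperatures: np.ndarray  # K
    values: np.ndarray  # [0, 1]
    observable: str  # "FSF" or "SSEP"

    def __post_init__(self):
        t = np.asarray(self.temperatures, float)
        v = np.asarray(self.values, float)
        if t.shape != v.shape or t.ndim != 1 or t.size < 4:
            raise ValueError("series needs >= 4 matching (T, value) points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly increasing and unique")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class MeltFit:
    """Fitted sigmoid parameters: Tm and slope, with y-range fixed to the series."""

    tm: float  # K
    k_slope: float  # K; negative for observables decreasing in T
    y_min: float
    y_max: float
    rss: float
    converged: bool

    def predict(self, temperatures) -> np.ndarray:
        t = np.asarray(temperatures, float)
        return self.y_min + (self.y_max - self.y_min) / (
            1.0 + np.exp(-(t - self.tm) / self.k_slope)
        )


class MeltCurveModel:
    """Sigmoid melting-curve model for one observable-vs-temperature series."""

    def __init__(self, series: MeltSeries):
        self.series = series

    @classmethod
    def from_arrays(cls, temperatures, values, observable="FSF") -> "MeltCurveModel":
        return cls(MeltSeries(
            temperatures=np.asarray(temperatures, float),
            values=np.asarray(values, float),
            observable=observable,
        ))

    @classmethod
    def from_ensembles(
        cls, ensembles: Sequence[Ensemble], native: Conformation, observable: str
    ) -> "MeltCurveModel":
        return cls(build_melt_series(ensembles, native, observable))

    def fit(self) -> "MeltCurveResults":
        """Nonlinear least squares over (Tm, k_slope); y-range fixed to the data."""
        t = self.series.temperatures
        y = self.series.values
        y_min, y_max = float(y.min()), float(y.max())
        if y_max - y_min <= 0:
            raise ValueError("no transition detected: series is flat")
        # initial Tm: first crossing of the half height (linear interpolation)
        half = 0.5 * (y_min + y_max)
        tm0 = _half_crossing(t, y, half)
        increasing = y[-1] >= y[0]
        k0 = 20.0 if increasing else -20.0

        def residuals(params):
            tm, k = params
            return y_min + (y_max - y_min) / (1.0 + np.exp(-(t - tm) / k)) - y

        res = least_squares(
            residuals,
            x0=[tm0, k0],
            bounds=([t.min() - 100.0, -np.inf], [t.max() + 100.0, np.inf]),
            xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
        tm, k = res.x
        fit = MeltFit(
            tm=float(tm),
            k_slope=float(k),
            y_min=y_min,
            y_max=y_max,
            rss=float(np.sum(res.fun**2)),
            converged=bool(res.success and np.isfinite(res.x).all() and k != 0),
        )
        return MeltCurveResults(model=self, params=fit)


def _half_crossing(t, y, half) -> float:
    s = np.sign(y - half)
    for i in range(len(t) - 1):
        if s[i] == 0:
            return float(t[i])
        if s[i] != s[i + 1]:
            y0, y1 = y[i], y[i + 1]
            if y1 == y0:
                return float(0.5 * (t[i] + t[i + 1]))
            w = (half - y0) / (y1 - y0)
            return float(t[i] + w * (t[i + 1] - t[i]))
    return float(t[len(t) // 2])


@dataclass(frozen=True)
class MeltCurveResults:
    """Results of a melting-curve fit; the estimates live in ``params``."""

    model: MeltCurveModel
    params: MeltFit

    @property
    def tm(self) -> float:
        return self.params.tm

    @property
    def k_slope(self) -> float:
        return self.params.k_slope

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.params.predict(self.model.series.temperatures)

    @property
    def resid(self) -> np.ndarray:
        return self.model.series.values - self.fittedvalues

    def summary(self) -> str:
        s = self.model.series
        p = self.params
        lines = [
            "Melting-curve sigmoid fit",
            "=" * 41,
            f"observable        {s.observable}",
            f"n temperatures    {len(s.temperatures)}",
            f"T range (K)       {s.temperatures.min():.1f} - {s.temperatures.max():.1f}",
            f"y_min / y_max     {p.y_min:.4f} / {p.y_max:.4f}  (fixed to series)",
            f"Tm (K)            {p.tm:.2f}",
            f"k_slope (K)       {p.k_slope:.2f}",
            f"RSS               {p.rss:.3e}",
            f"converged         {p.converged}",
        ]
        return "\n".join(lines)


def build_melt_series(
    ensembles: Sequence[Ensemble],
    native: Conformation,
    observable: str,
) -> MeltSeries:
    """Compute FSF or SSEP per ensemble and sort by temperature."""
    if observable not in OBSERVABLES:
        raise ValueError(f"observable must be one of {OBSERVABLES}")
    temps = []
    for e in ensembles:
        if e.temperature is None:
            raise ValueError(f"ensemble {e.label!r} has no temperature")
        temps.append(e.temperature)
    if len(set(temps)) != len(temps):
        raise ValueError("duplicate ensemble temperatures")
    topo = ensembles[0].topology
    if observable == "FSF":
        contacts = native_contacts(native, topo)
        values = [folded_state_fraction(e, contacts) for e in ensembles]
    else:
        states = native_sse(native, topo)
        values = [ssep(e, native, native_states=states) for e in ensembles]
    order = np.argsort(temps)
    return MeltSeries(
        temperatures=np.asarray(temps, float)[order],
        values=np.asarray(values, float)[order],
        observable=observable,
    )


def fit_sigmoid(series: MeltSeries) -> MeltFit:
    """Functional wrapper around :meth:`MeltCurveModel.fit`."""
    return MeltCurveModel(series).fit().params


def melting_temperature(
    ensembles: Sequence[Ensemble],
    native: Conformation,
    observable: str = "both",
) -> dict:
    """Apparent Tm from FSF and/or SSEP melting curves.

    Returns a dict with per-observable :class:`MeltFit` entries plus, when
    both are requested, the |Tm(FSF) - Tm(SSEP)| consistency diagnostic.
    """
    wanted = OBSERVABLES if observable == "both" else (observable,)
    out: dict = {}
    for obs in wanted:
        series = build_melt_series(ensembles, native, obs)
        out[obs] = fit_sigmoid(series)
        out[f"{obs}_series"] = series
    if len(wanted) == 2:
        out["tm_difference"] = abs(out["FSF"].tm - out["SSEP"].tm)
    return out


def delta_tm(fit_a: MeltFit, fit_b: MeltFit) -> float:
    """Tm(a) - Tm(b) in Kelvin; both fits must have converged."""
    if not (fit_a.converged and fit_b.converged):
        raise ValueError("delta Tm requires two converged fits")
    return fit_a.tm - fit_b.tm
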