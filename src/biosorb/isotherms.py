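"""Langmuir and Freundlich isotherm fitting with interval-valued parameters.

Both isotherms are fitted on their classical linearizations:

* Langmuir  Qe = q0 b Ce / (1 + b Ce)   ->   Ce/Qe = 1/(q0 b) + Ce/q0
* Freundlich qe = Kf Ce^(1/n)           ->   log10 qe = log10 Kf + (1/n) log10 Ce

The linearized data are fitted by possibilistic fuzzy regression
(:func:`biosorb.fuzzy.fit_tanaka`), and physical parameters are read off
the *support* of each fuzzy coefficient [center - spread, center + spread]
by monotone (endpoint) interval arithmetic:

* q0 = 1/slope, decreasing         ->  q0 = [1/s_hi, 1/s_lo]
* b  = slope/intercept             ->  b  = [s_lo/i_hi, s_hi/i_lo]
* n  = 1/slope (log-log)           ->  n  = [1/s_hi, 1/s_lo]
* Kf = 10^intercept-center, crisp (the heterogeneity constant is
  conventionally quoted as a single value alongside an interval n)

Goodness of fit is the crisp OLS R^2 on the same linearized data.  The
dimensionless Langmuir separation factor R_L = 1/(1 + b C0) (antitone in
b) flags a favorable isotherm when it lies inside (0, 1); a Freundlich
intensity n inside [1, 10] flags efficient sorption.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegeneratePointError, DomainError, NonInvertibleFitError, ParseError
from .errors import UndefinedR2Error
from .fuzzy import FuzzyLinearModel, RegressionData, fit_tanaka, ols_r_squared
from .units import METALS, MetalSpec

__all__ = [
    "IsothermDataset",
    "IntervalParam",
    "LangmuirFit",
    "FreundlichFit",
    "langmuir_linearize",
    "freundlich_linearize",
    "fit_langmuir",
    "fit_freundlich",
    "separation_factor",
    "favorability_report",
    "read_isotherm_csv",
    "write_isotherm_csv",
    "summary_table",
]

ISO_COLUMNS = ["Ce_mg_L", "Qe_mg_g"]


@dataclass(frozen=True)
class IntervalParam:
    """A closed interval [low, high] with a unit annotation."""

    low: float
    high: float
    units: str = ""

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise DomainError(f"interval low > high: [{self.low}, {self.high}]")

    @property
    def width(self) -> float:
        return self.high - self.low

    @property
    def mid(self) -> float:
        return 0.5 * (self.low + self.high)

    def contains(self, v: float, tol: float = 0.0) -> bool:
        return self.low - tol <= v <= self.high + tol

    def within(self, lo: float, hi: float, closed: bool = True) -> bool:
        """Whether the whole interval lies inside [lo, hi] (or (lo, hi))."""
        if closed:
            return lo <= self.low and self.high <= hi
        return lo < self.low and self.high < hi

    def to_list(self) -> list[float]:
        return [self.low, self.high]


@dataclass(frozen=True)
class IsothermDataset:
    """Equilibrium (Ce, Qe) pairs for one metal, in mg/L and mg/g."""

    points: tuple[tuple[float, float], ...]
    metal: MetalSpec
    label: str = ""

    def __post_init__(self) -> None:
        pts = tuple((float(c), float(q)) for c, q in self.points)
        object.__setattr__(self, "points", pts)
        if len(pts) < 3:
            raise DegeneratePointError(f"need >= 3 isotherm points, got {len(pts)}")
        ce = [p[0] for p in pts]
        if len(set(ce)) < 2:
            raise DegeneratePointError("Ce values must not all be identical")

    @property
    def ce(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def qe(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


@dataclass(frozen=True)
class LangmuirFit:
    """Interval-valued Langmuir parameters from a fuzzy fit."""

    q0: IntervalParam       # monolayer capacity, mg/g
    b: IntervalParam        # affinity (absorption energy), L/mg
    r2: float               # OLS R^2 on Ce/Qe vs Ce
    H: float
    model: FuzzyLinearModel
    RL: IntervalParam | None = field(default=None)  # set when C0 is known

    def with_RL(self, C0: float) -> "LangmuirFit":
        return LangmuirFit(self.q0, self.b, self.r2, self.H, self.model,
                           separation_factor(self.b, C0))


@dataclass(frozen=True)
class FreundlichFit:
    """Freundlich parameters: crisp Kf, interval intensity n."""

    Kf: float               # (mg/g)(L/mg)^(1/n)
    n: IntervalParam        # dimensionless
    r2: float
    H: float
    model: FuzzyLinearModel


def _check_positive_points(ds: IsothermDataset) -> None:
    for ce, qe in ds.points:
        if ce <= 0 or qe <= 0:
            raise DegeneratePointError(
                f"isotherm point (Ce={ce}, Qe={qe}) not strictly positive"
            )


def langmuir_linearize(ds: IsothermDataset) -> RegressionData:
    """Map (Ce, Qe) to the Langmuir line: x = Ce, y = Ce/Qe (g/L)."""
    _check_positive_points(ds)
    return RegressionData.from_xy(ds.ce, ds.ce / ds.qe)


def freundlich_linearize(ds: IsothermDataset) -> RegressionData:
    """Map (Ce, Qe) to the Freundlich line: x = log10 Ce, y = log10 Qe."""
    _check_positive_points(ds)
    return RegressionData.from_xy(np.log10(ds.ce), np.log10(ds.qe))


def fit_langmuir(
    ds: IsothermDataset, H: float = 0.0, C0: float | None = None
) -> LangmuirFit:
    """Fuzzy-fit the linearized Langmuir model and invert to (q0, b) intervals.

    Slope support [s_lo, s_hi] gives q0 = [1/s_hi, 1/s_lo]; with intercept
    support [i_lo, i_hi], b = slope/intercept = [s_lo/i_hi, s_hi/i_lo].
    Either support touching zero makes the inversion undefined and raises
    :class:`NonInvertibleFitError` (the fuzzy model rides on the exception).
    If ``C0`` (mg/L) is given, the separation factor interval is attached.
    """
    lin = langmuir_linearize(ds)
    model = fit_tanaka(lin, H=H)
    i_lo, i_hi = model.coefficients[0].support
    s_lo, s_hi = model.coefficients[1].support
    if s_lo <= 0:
        raise NonInvertibleFitError(
            f"slope support [{s_lo:.4g}, {s_hi:.4g}] touches zero", model=model
        )
    if i_lo <= 0:
        raise NonInvertibleFitError(
            f"intercept support [{i_lo:.4g}, {i_hi:.4g}] touches zero", model=model
        )
    q0 = IntervalParam(1.0 / s_hi, 1.0 / s_lo, units="mg/g")
    b = IntervalParam(s_lo / i_hi, s_hi / i_lo, units="L/mg")
    try:
        r2 = ols_r_squared(lin)
    except UndefinedR2Error as exc:
        # constant Ce/Qe: the line degenerates, no meaningful inversion
        raise NonInvertibleFitError(f"degenerate linearized data: {exc}",
                                    model=model) from exc
    fit = LangmuirFit(q0, b, r2, float(H), model)
    return fit.with_RL(C0) if C0 is not None else fit


def fit_freundlich(ds: IsothermDataset, H: float = 0.0) -> FreundlichFit:
    """Fuzzy-fit the log-log Freundlich model.

    Kf = 10^(intercept center); n = 1/slope inverted over the slope support.
    """
    lin = freundlich_linearize(ds)
    model = fit_tanaka(lin, H=H)
    a0 = model.coefficients[0].center
    s_lo, s_hi = model.coefficients[1].support
    if s_lo <= 0:
        raise NonInvertibleFitError(
            f"slope support [{s_lo:.4g}, {s_hi:.4g}] touches zero", model=model
        )
    n = IntervalParam(1.0 / s_hi, 1.0 / s_lo, units="")
    try:
        r2 = ols_r_squared(lin)
    except UndefinedR2Error as exc:
        raise NonInvertibleFitError(f"degenerate log-log data: {exc}",
                                    model=model) from exc
    return FreundlichFit(10.0 ** a0, n, r2, float(H), model)


def separation_factor(b: IntervalParam, C0: float) -> IntervalParam:
    """Langmuir separation factor R_L = 1/(1 + b C0), endpoint-wise.

    R_L is decreasing in b, so the endpoints swap:
    [1/(1 + b_hi C0), 1/(1 + b_lo C0)].  C0 is the initial concentration
    of the experimental design, mg/L.
    """
    if C0 <= 0:
        raise DomainError(f"C0 must be positive, got {C0}")
    if b.low < 0:
        raise DomainError(f"b must be non-negative, got low={b.low}")
    return IntervalParam(1.0 / (1.0 + b.high * C0), 1.0 / (1.0 + b.low * C0), units="")


def favorability_report(
    l: LangmuirFit, f: FreundlichFit, C0: float
) -> dict:
    """Diagnostic flags for a fitted metal.

    * ``effective``: the R_L interval at C0 lies strictly inside (0, 1)
      (favorable Langmuir sorption);
    * ``efficient``: the Freundlich n interval lies inside [1, 10];
    * ``preferred_model``: whichever linearized fit has the higher OLS R^2.
    """
    RL = separation_factor(l.b, C0)
    return {
        "C0_mg_L": C0,
        "RL": RL.to_list(),
        "effective": RL.within(0.0, 1.0, closed=False),
        "n": f.n.to_list(),
        "efficient": f.n.within(1.0, 10.0),
        "r2_langmuir": l.r2,
        "r2_freundlich": f.r2,
        "preferred_model": "langmuir" if l.r2 >= f.r2 else "freundlich",
    }


def read_isotherm_csv(
    path: str | Path, metal: MetalSpec | str = "Cd", label: str = ""
) -> IsothermDataset:
    """Read equilibrium points from a CSV with columns Ce_mg_L, Qe_mg_g."""
    if isinstance(metal, str):
        if metal not in METALS:
            raise DomainError(f"unknown metal {metal!r}; known: {sorted(METALS)}")
        metal = METALS[metal]
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in ISO_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if df[ISO_COLUMNS].isna().any().any():
        bad = int(df[ISO_COLUMNS].isna().any(axis=1).idxmax()) + 1
        raise ParseError(f"{path}: non-numeric or missing value", line=bad)
    pts = tuple(zip(df["Ce_mg_L"].astype(float), df["Qe_mg_g"].astype(float)))
    return IsothermDataset(pts, metal=metal, label=label or str(path))


def write_isotherm_csv(ds: IsothermDataset, path: str | Path) -> None:
    pd.DataFrame(list(ds.points), columns=ISO_COLUMNS).to_csv(path, index=False)


def summary_table(
    langmuir: LangmuirFit | None = None, freundlich: FreundlichFit | None = None
) -> pd.DataFrame:
    """Flat (parameter, low, high) table mirroring the conventional report layout."""
    rows: list[dict] = []
    if langmuir is not None:
        rows.append({"model": "Langmuir", "parameter": "q0_mg_g",
                     "low": langmuir.q0.low, "high": langmuir.q0.high})
        rows.append({"model": "Langmuir", "parameter": "b_L_mg",
                     "low": langmuir.b.low, "high": langmuir.b.high})
        if langmuir.RL is not None:
            rows.append({"model": "Langmuir", "parameter": "RL",
                         "low": langmuir.RL.low, "high": langmuir.RL.high})
        rows.append({"model": "Langmuir", "parameter": "R2",
                     "low": langmuir.r2, "high": langmuir.r2})
    if freundlich is not None:
        rows.append({"model": "Freundlich", "parameter": "Kf",
                     "low": freundlich.Kf, "high": freundlich.Kf})
        rows.append({"model": "Freundlich", "parameter": "n",
                     "low": freundlich.n.low, "high": freundlich.n.high})
        rows.append({"model": "Freundlich", "parameter": "R2",
                     "low": freundlich.r2, "high": freundlich.r2})
    return pd.DataFrame(rows, columns=["model", "parameter", "low", "high"])


def fit_to_dict(fit: LangmuirFit | FreundlichFit) -> dict:
    """JSON-serializable view of a fit (intervals, R^2, H, fuzzy model)."""
    if isinstance(fit, LangmuirFit):
        return {
            "isotherm": "langmuir",
            "q0_mg_g": fit.q0.to_list(),
            "b_L_mg": fit.b.to_list(),
            "RL": fit.RL.to_list() if fit.RL is not None else None,
            "r2": fit.r2,
            "H": fit.H,
            "model": fit.model.to_dict(),
        }
    return {
        "isotherm": "freundlich",
        "Kf": fit.Kf,
        "n": fit.n.to_list(),
        "r2": fit.r2,
        "H": fit.H,
        "model": fit.model.to_dict(),
    }
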