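"""Synthetic batch-sorption experiments under a known isotherm.

Stands in for the wet lab: a graded series of initial metal
concentrations is equilibrated against a fixed biosorbent dose, the
equilibrium (Ce, Qe) is obtained by coupling the batch mass balance

    Qe = (Ci - Ce) V / M

with the chosen isotherm law Q(Ce), and a multiplicative lognormal
measurement error (emulating atomic-absorption readout noise, which
scales with signal) perturbs Qe.  Ce is then recomputed from the mass
balance so every noisy record remains internally consistent — the
property the downstream fitting stages assume.

The default design mirrors the study system: 50 mL test solutions,
1 g/L dry biomass, cadmium series from 0.5 mM and manganese series from
3 mM, both reaching 20 mM.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .errors import DomainError, SolverError
from .isotherms import IsothermDataset, write_isotherm_csv
from .units import METALS, BatchRecord, MetalSpec, molar_to_mass_conc

__all__ = [
    "TrueIsotherm",
    "BatchDesign",
    "NoiseSpec",
    "equilibrium_solve",
    "generate_isotherm",
    "generate_batch_records",
    "paper_like_design",
    "write_truth_sidecar",
]


@dataclass(frozen=True)
class TrueIsotherm:
    """Ground-truth isotherm: 'langmuir' (q0 mg/g, b L/mg) or 'freundlich' (Kf, n)."""

    kind: str
    params: tuple[float, float]

    def __post_init__(self) -> None:
        if self.kind not in ("langmuir", "freundlich"):
            raise DomainError(f"unknown isotherm kind {self.kind!r}")
        p1, p2 = self.params
        if p1 <= 0 or p2 <= 0:
            raise DomainError(f"isotherm parameters must be positive, got {self.params}")
        if self.kind == "freundlich" and p2 < 1:
            raise DomainError(f"freundlich intensity n must be >= 1, got {p2}")

    def uptake(self, Ce: float) -> float:
        """Equilibrium uptake Q(Ce), mg/g, at solution concentration Ce mg/L."""
        if Ce < 0:
            raise DomainError(f"Ce must be >= 0, got {Ce}")
        if self.kind == "langmuir":
            q0, b = self.params
            return q0 * b * Ce / (1.0 + b * Ce)
        Kf, n = self.params
        return Kf * Ce ** (1.0 / n)


@dataclass(frozen=True)
class BatchDesign:
    """Experimental design: initial concentrations (mM), volume, dose, metal."""

    initial_concs_mM: tuple[float, ...]
    V: float                 # L
    biomass_dose: float      # g/L
    metal: MetalSpec

    def __post_init__(self) -> None:
        concs = tuple(float(c) for c in self.initial_concs_mM)
        object.__setattr__(self, "initial_concs_mM", concs)
        if not concs or any(c <= 0 for c in concs):
            raise DomainError("initial concentrations must be positive")
        if any(b <= a for a, b in zip(concs, concs[1:])):
            raise DomainError("initial concentrations must be strictly increasing")
        if self.V <= 0 or self.biomass_dose <= 0:
            raise DomainError("volume and biomass dose must be positive")

    @property
    def M(self) -> float:
        """Dry biomass per batch, g."""
        return self.biomass_dose * self.V

    @property
    def initial_concs_mg_L(self) -> tuple[float, ...]:
        return tuple(molar_to_mass_conc(c, self.metal) for c in self.initial_concs_mM)


@dataclass(frozen=True)
class NoiseSpec:
    """Relative (fractional) measurement noise on Qe and the master seed."""

    relative_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relative_sd < 0:
            raise DomainError(f"relative_sd must be >= 0, got {self.relative_sd}")


def equilibrium_solve(
    Ci: float, V: float, M: float, iso: TrueIsotherm
) -> tuple[float, float]:
    """Unique equilibrium (Ce, Qe) of one batch: mass balance meets isotherm.

    Solves (Ci - Ce) V / M = Q(Ce) for Ce in [0, Ci].  The Langmuir case
    reduces to a quadratic in Ce (positive root taken in closed form);
    the Freundlich case is solved by bracketed root-finding to
    |residual| < 1e-10 Ci.  Qe is recovered from the mass balance, so
    Qe M = (Ci - Ce) V holds exactly.
    """
    if Ci <= 0 or V <= 0 or M <= 0:
        raise DomainError(f"require Ci, V, M > 0, got Ci={Ci}, V={V}, M={M}")
    rho = M / V  # dose, g/L
    if iso.kind == "langmuir":
        q0, b = iso.params
        # b Ce^2 + (1 - b Ci + b rho q0) Ce - Ci = 0
        A, B, C = b, 1.0 - b * Ci + b * rho * q0, -Ci
        disc = B * B - 4.0 * A * C
        if disc < 0:
            raise SolverError("Langmuir quadratic has no real root")
        # positive root in the cancellation-stable form -2C/(B + sqrt(disc)),
        # which stays accurate in the weak-affinity limit b -> 0 (Ce -> Ci)
        Ce = 2.0 * Ci / (B + np.sqrt(disc))
    else:
        def residual(ce: float) -> float:
            return (Ci - ce) * V / M - iso.uptake(ce)

        # residual(0) = Ci/rho > 0, residual(Ci) = -Q(Ci) < 0: bracketed
        Ce = brentq(residual, 0.0, Ci, xtol=1e-14, rtol=8.9e-16, maxiter=200)
        if abs(residual(Ce)) > 1e-10 * Ci:
            raise SolverError(f"equilibrium residual too large at Ce={Ce}")
    if not (0.0 <= Ce <= Ci * (1.0 + 1e-9)):
        raise SolverError(f"equilibrium Ce={Ce} outside [0, Ci={Ci}]")
    Ce = min(max(Ce, 0.0), Ci)
    Qe = (Ci - Ce) * V / M
    return float(Ce), float(Qe)


def _lognormal_factor(rng: np.random.Generator, relative_sd: float) -> float:
    """Unit-mean lognormal multiplier with exact relative sd."""
    if relative_sd == 0.0:
        return 1.0
    sigma2 = np.log1p(relative_sd**2)
    return float(rng.lognormal(mean=-0.5 * sigma2, sigma=np.sqrt(sigma2)))


def _noisy_record(
    Ci: float, V: float, M: float, iso: TrueIsotherm,
    rng: np.random.Generator, relative_sd: float, max_attempts: int = 100,
) -> tuple[float, float]:
    """One noisy (Ce, Qe) with mass balance restored; resamples if Ce leaves (0, Ci)."""
    Ce0, Qe0 = equilibrium_solve(Ci, V, M, iso)
    for _ in range(max_attempts):
        Qe = Qe0 * _lognormal_factor(rng, relative_sd)
        Ce = Ci - Qe * M / V
        if 0.0 < Ce < Ci:
            return Ce, Qe
    raise SolverError(
        f"noise rejection cap ({max_attempts}) reached at Ci={Ci}; "
        f"relative_sd={relative_sd} too large for this design"
    )


def generate_isotherm(
    design: BatchDesign, iso: TrueIsotherm, noise: NoiseSpec
) -> IsothermDataset:
    """Simulate one isotherm experiment series; deterministic given the seed.

    The master seed expands into independent per-record streams
    (``numpy.random.SeedSequence.spawn``), so the dataset for any one
    concentration does not depend on how many other concentrations are run.
    """
    children = np.random.SeedSequence(noise.seed).spawn(len(design.initial_concs_mM))
    pts = []
    for Ci, child in zip(design.initial_concs_mg_L, children):
        rng = np.random.default_rng(child)
        pts.append(_noisy_record(Ci, design.V, design.M, iso, rng, noise.relative_sd))
    return IsothermDataset(
        tuple((ce, qe) for ce, qe in pts),
        metal=design.metal,
        label=f"synthetic {iso.kind} {design.metal.symbol} seed={noise.seed}",
    )


def generate_batch_records(
    design: BatchDesign, iso: TrueIsotherm, noise: NoiseSpec
) -> list[BatchRecord]:
    """Same simulation, returned as raw batch records (Ci, Cf=Ce, V, M)."""
    ds = generate_isotherm(design, iso, noise)
    return [
        BatchRecord(Ci=ci, Cf=ce, V=design.V, M=design.M)
        for ci, (ce, _) in zip(design.initial_concs_mg_L, ds.points)
    ]


#: Isotherm-series concentration grids, mM.  The cadmium single-factor series
#: (0.5–4 mM) is extended to the design's 20 mM ceiling for isotherm runs;
#: manganese runs 3–20 mM.
_CD_SERIES_MM = (0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 10.0, 15.0, 20.0)
_MN_SERIES_MM = (3.0, 5.0, 10.0, 15.0, 20.0)


def paper_like_design(metal: MetalSpec | str) -> BatchDesign:
    """The study-like batch design for Cd or Mn: 50 mL, 1 g/L dry biomass."""
    symbol = metal if isinstance(metal, str) else metal.symbol
    if symbol not in METALS:
        raise DomainError(f"no built-in design for metal {symbol!r}")
    series = _CD_SERIES_MM if symbol == "Cd" else _MN_SERIES_MM
    return BatchDesign(series, V=0.05, biomass_dose=1.0, metal=METALS[symbol])


def write_truth_sidecar(
    path: str | Path, iso: TrueIsotherm, design: BatchDesign, noise: NoiseSpec
) -> None:
    """Ground-truth JSON sidecar so test harnesses can score recovery."""
    Path(path).write_text(
        json.dumps(
            {
                "isotherm": iso.kind,
                "params": list(iso.params),
                "metal": design.metal.symbol,
                "initial_concs_mM": list(design.initial_concs_mM),
                "V_L": design.V,
                "biomass_dose_g_L": design.biomass_dose,
                "relative_sd": noise.relative_sd,
                "seed": noise.seed,
            },
            indent=2,
        )
    )


def write_dataset(
    ds: IsothermDataset, path: str | Path, *,
    iso: TrueIsotherm | None = None,
    design: BatchDesign | None = None,
    noise: NoiseSpec | None = None,
) -> None:
    """Write the dataset CSV, plus a `.truth.json` sidecar when truth is given."""
    write_isotherm_csv(ds, path)
    if iso is not None and design is not None and noise is not None:
        write_truth_sidecar(Path(path).with_suffix(".truth.json"), iso, design, noise)
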