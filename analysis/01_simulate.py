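"""Simulate the batch biosorption experiment series for both metals.

Generates the synthetic stand-in for the wet-lab measurements: a graded
series of initial concentrations equilibrated against 1 g/L dry biomass
in 50 mL, under a known Langmuir ground truth per metal, with 2%
relative measurement noise on the uptake.  Writes the equilibrium
datasets plus ground-truth sidecars under results/data/.

Ground truths echo the scale of the study system: cadmium saturating
near 170 mg/g with moderate affinity, manganese near 114 mg/g with weak
affinity.
"""

from pathlib import Path

from biosorb import NoiseSpec, TrueIsotherm, generate_isotherm, paper_like_design
from biosorb.simulate import write_dataset

OUT = Path(__file__).resolve().parent.parent / "results" / "data"

TRUTHS = {
    "Cd": TrueIsotherm("langmuir", (170.0, 0.01)),
    "Mn": TrueIsotherm("langmuir", (114.0, 0.0015)),
}
SEED = {"Cd": 1, "Mn": 2}
SD = 0.02


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for metal, truth in TRUTHS.items():
        design = paper_like_design(metal)
        noise = NoiseSpec(relative_sd=SD, seed=SEED[metal])
        ds = generate_isotherm(design, truth, noise)
        path = OUT / f"{metal.lower()}_isotherm.csv"
        write_dataset(ds, path, iso=truth, design=design, noise=noise)
        q0, b = truth.params
        print(
            f"{metal}: {len(ds.points)} equilibrium points "
            f"(Ci {design.initial_concs_mg_L[0]:.1f}-"
            f"{design.initial_concs_mg_L[-1]:.0f} mg/L), "
            f"truth q0={q0} mg/g, b={b} L/mg, sd={SD:.0%}, seed={SEED[metal]} "
            f"-> {path.relative_to(OUT.parent.parent)}"
        )
        print(
            "   Qe range "
            f"{min(q for _, q in ds.points):.1f}-{max(q for _, q in ds.points):.1f} mg/g"
        )


if __name__ == "__main__":
    main()
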