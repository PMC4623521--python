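"""Favorability diagnostics and model comparison across metals.

Re-fits both isotherms from the stored datasets, evaluates the
separation-factor and intensity criteria, and writes a combined
diagnostic table: sorption is called *effective* when the R_L interval
sits strictly inside (0, 1) and *efficient* when the Freundlich n
interval sits inside [1, 10]; the model with the higher crisp R^2 on its
linearized data is preferred.
"""

import json
from pathlib import Path

from biosorb import (
    favorability_report,
    fit_freundlich,
    fit_langmuir,
    molar_to_mass_conc,
    paper_like_design,
    read_isotherm_csv,
)

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"
OUT = ROOT / "results" / "fits"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    combined = {}
    for metal in ("Cd", "Mn"):
        ds = read_isotherm_csv(DATA / f"{metal.lower()}_isotherm.csv", metal=metal)
        design = paper_like_design(metal)
        C0 = molar_to_mass_conc(design.initial_concs_mM[0], design.metal)
        rep = favorability_report(fit_langmuir(ds), fit_freundlich(ds), C0)
        combined[metal] = rep
        print(
            f"{metal}: RL = [{rep['RL'][0]:.3f}, {rep['RL'][1]:.3f}] at "
            f"C0 = {C0:.1f} mg/L -> effective={rep['effective']}; "
            f"n = [{rep['n'][0]:.2f}, {rep['n'][1]:.2f}] -> "
            f"efficient={rep['efficient']}; preferred: {rep['preferred_model']} "
            f"(R2 {rep['r2_langmuir']:.4f} vs {rep['r2_freundlich']:.4f})"
        )
    (OUT / "favorability.json").write_text(json.dumps(combined, indent=2))
    print(f"wrote {OUT.relative_to(ROOT) / 'favorability.json'}")


if __name__ == "__main__":
    main()
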