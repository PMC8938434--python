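#!/usr/bin/env python
"""Desk calculations for the perfect GLFG repeat constructs.

Computes, for the 52-repeat protein and the 7-repeat fragment: molecular mass,
FG-motif count, hydrated Stokes radius (vbar 0.73 cm^3/g + 3.2 A shell), the
rigid-sphere rotational correlation time and diffusion coefficient at 24 degC,
and the condensed-phase concentration bookkeeping (mg/ml, motif molarity,
sphere-confined local motif concentration, enrichment over the input).
Writes results/hydrodynamics.csv and results/concentrations.csv.
"""

from pathlib import Path

import pandas as pd

from fgphase import phase_assay
from fgphase import seqthermo as st

OUT = Path(__file__).resolve().parents[1] / "results"
UNIT = "GGLFGGNTQPAT"


def main():
    OUT.mkdir(exist_ok=True)
    cond = st.SolutionConditions.water(24.0)

    rows = []
    for name, n in [("prf_52x12", 52), ("prf_7x12", 7)]:
        spec = st.MoleculeSpec(sequence=st.build_repeat_sequence(UNIT, n))
        r_h = st.hydrated_radius(spec)
        rows.append({
            "construct": name,
            "length_res": len(spec.sequence),
            "mw_da": round(spec.mw, 1),
            "fg_motifs": spec.motifs_per_chain,
            "hydrated_radius_a": round(r_h, 2),
            "tau_c_ns": round(st.sed_tau_c(r_h, cond), 2),
            "d_um2_s": round(st.stokes_einstein_D(r_h / 10.0, cond), 2),
        })
    hydro = pd.DataFrame(rows)
    hydro.to_csv(OUT / "hydrodynamics.csv", index=False)

    full = st.MoleculeSpec(sequence=st.build_repeat_sequence(UNIT, 52))
    mgml = st.molar_to_mass_conc(4.5e-3, full.mw)
    conc = pd.DataFrame([
        {"quantity": "condensed_phase_protein", "value": round(mgml, 1), "units": "mg/ml"},
        {"quantity": "condensed_phase_protein", "value": 4.5, "units": "mM"},
        {"quantity": "condensed_phase_fg_motifs",
         "value": round(st.motif_molarity(4.5, full.motifs_per_chain), 1), "units": "mM"},
        {"quantity": "single_chain_local_fg_motifs",
         "value": round(st.sphere_local_concentration(52, 5.0) * 1e3, 1), "units": "mM"},
        {"quantity": "enrichment_over_20uM_input",
         "value": round(phase_assay.enrichment_factor(mgml, 1.2), 1), "units": "fold"},
    ])
    conc.to_csv(OUT / "concentrations.csv", index=False)

    print(hydro.to_string(index=False))
    print()
    print(conc.to_string(index=False))
    print("\nRigid-sphere tumbling predicts ~22 ns for the full-length chain; the"
          "\nmeasured aqueous-state value (~1.4 ns) shows the chain does not tumble"
          "\nas a compact sphere: segmental motion dominates.")


if __name__ == "__main__":
    main()
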