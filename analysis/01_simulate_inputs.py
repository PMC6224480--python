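#!/usr/bin/env python
"""Generate every synthetic input consumed by the downstream analyses.

Writes to results/data/: four ITC isotherms simulated from the published
sequential-model parameters with per-experiment concentration errors,
direct and competition anisotropy titrations, a toy helix-dimer
structure, and an ortholog sequence set with a controlled fraction of
disrupted motifs.
"""

from pathlib import Path

import numpy as np

from tprbind import io as tio
from tprbind import structure as struc
from tprbind import synthetic as synth
from tprbind.conservation import MotifDefinition
from tprbind.recovery import REFERENCE_PARAMS, simulate_isotherm_set

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 20260926


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    experiments, nuisances = simulate_isotherm_set(SEED, truth=REFERENCE_PARAMS)
    for i, expt in enumerate(experiments):
        tio.write_itc_csv(expt, OUT / f"itc_isotherm_{i}.csv")
    print(f"wrote {len(experiments)} isotherms "
          f"(true K1={REFERENCE_PARAMS.k1} uM^-1, dH1={REFERENCE_PARAMS.dh1} kcal/mol; "
          f"nuisance f_cell={[round(n.f_cell, 3) for n in nuisances]})")

    direct = synth.simulate_direct_curve(seed=SEED)
    tio.write_anisotropy_csv(direct, OUT / "anisotropy_direct.csv")
    comp = synth.simulate_competition_curve(synth.SyntheticAnisotropySpec(seed=SEED))
    tio.write_anisotropy_csv(comp, OUT / "anisotropy_competition.csv")
    null = synth.simulate_competition_curve(
        synth.SyntheticAnisotropySpec(k_i=1e6, seed=SEED))
    tio.write_anisotropy_csv(null, OUT / "anisotropy_null_competitor.csv")
    print("wrote direct (true K_d=37 uM), competition (true K_I=11.3 uM) and "
          "non-binding competitor titrations")

    h1 = synth.build_toy_helix(20, "A")
    h2 = struc.translate(synth.build_toy_helix(20, "B"), (7.0, 0.0, 0.0))
    struc.write_pdb(struc.merge([h1, h2]), OUT / "toy_dimer.pdb")
    far = struc.translate(synth.build_toy_helix(20, "B"), (50.0, 0.0, 0.0))
    struc.write_pdb(struc.merge([h1, far]), OUT / "toy_separated.pdb")
    print("wrote toy helix dimer (7 A apart) and separated pair (50 A)")

    rng = np.random.default_rng(SEED)
    ref = "".join(rng.choice(list(synth.AMINO_ACIDS), size=300))
    (OUT / "reference.fasta").write_text(f">REF\n{ref}\n")
    motif = MotifDefinition(
        "jip3_binding_site_on_klc", "REF",
        frozenset({200, 201, 204, 208, 213, 215, 216, 219, 220, 223, 227}))
    records = synth.generate_ortholog_set(synth.SyntheticOrthologSpec(
        reference_seq=ref, motif=motif,
        n_species_per_clade={"Bilateria": 59, "non-Bilateria": 42},
        background_substitution_rate=0.02,
        motif_break_fraction={"Bilateria": 0.0, "non-Bilateria": 0.5},
        seed=SEED))
    tio.write_fasta(records, OUT / "orthologs.fasta")
    tio.write_taxonomy_tsv(records, OUT / "taxa.tsv")
    n_broken = sum(not r.ground_truth_conserved for r in records)
    print(f"wrote {len(records)} ortholog sequences ({n_broken} with a "
          "disrupted motif, all in non-Bilateria)")


if __name__ == "__main__":
    main()
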