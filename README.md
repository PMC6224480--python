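# tprbind

Quantitative analysis of how kinesin-1 light chain (KLC) TPR domains
recognise the JIP3 leucine-zipper (LZ) cargo adaptor: the binding
thermodynamics of a dimeric ligand engaging two receptor domains, the
competition behaviour of the autoregulatory LFP-motif peptide, the
geometry of the TPR1:LZ interface, and the conservation of the
interface motifs across metazoan orthologs.

The package is organised as an analysis project: every computation
lives in the library under `src/tprbind/`, and the numbered scripts
under `analysis/` drive the stages end to end on synthetic data with
known ground truth, writing their tables to `results/`.

## The models

**Sequential two-site ITC binding** (`tprbind.itc`).  A leucine-zipper
dimer A binds two TPR domains B in two macroscopic stages,

    A + B + B  →  BA + B  →  BAB

with association constants K₁, K₂ (μM⁻¹) and stage enthalpies ΔH₁, ΔH₂
(kcal/mol).  Species concentrations come from the mass-action closure

    [BA] = K₁[A][B],  [BAB] = K₁K₂[A][B]²,

solved by bracketed root-finding on the monotone mass balance.
Injection heats follow the perfusion-cell displacement convention
(`predict_heats`), and several titrations are fitted globally
(`global_fit`): K₁, K₂, ΔH₁, ΔH₂ and active fractions shared, local
concentration-correction factors and baselines per experiment.
Because the heats are exactly invariant under rescaling all
concentrations by s with K → K/s and ΔH → ΔH/s, the local factors carry
a lognormal prior (10% sd — the accuracy of routine protein
quantification).  `thermo_decompose` converts (K, ΔH) into ΔG and −TΔS
at a 1 M standard state; `n_app` computes the apparent stoichiometry
from the locally fitted factors.

**Anisotropy competition** (`tprbind.anisotropy`).  A fluorescent
LFP-motif tracer (0.3 μM) reports receptor occupancy.  Direct mode: a
slope-1 dose-response with dissociation constant K_d.  Competition
mode, at fixed receptor concentration [KLC], uses the trace-tracer
closed form

    R_free = ([KLC] − [C] − K_I + √((K_I+[KLC]+[C])² − 4[KLC][C])) / 2
    A = A_min + (A_max − A_min) · R_free / (K_LFP + R_free)

**Interface geometry** (`tprbind.structure`).  Contact residues at a
4.2 Å heavy-atom cutoff, putative hydrogen bonds as N/O pairs within
3.4 Å, buried accessible surface area by Shrake–Rupley sampling
(probe 1.4 Å), Kabsch superposition/RMSD over Cα selections, crystal
neighbours at a 10 Å Cα cutoff, an i→i+4 backbone-hydrogen-bond helix
assignment, and the concentration of n molecules confined to a sphere
(two tethered TPR domains in a 150 Å sphere ≈ 235 μM).

**Motif conservation** (`tprbind.conservation`).  Global pairwise
alignment (BLOSUM62, affine gaps, free end gaps); a motif is conserved
in a homolog iff every non-exempt motif position aligns to an identical
residue; per-clade (Bilateria / non-Bilateria) percentages.

**Synthetic data** (`tprbind.synthetic`) generates every input with
known ground truth: isotherms from the sequential model, anisotropy
curves from the closed forms, parametric ideal poly-alanine helices,
and ortholog sets with a controlled fraction of disrupted motifs.

## Worked example

```sh
python analysis/01_simulate_inputs.py
python analysis/02_fit_itc.py
```

prints (four simulated isotherms, global sequential fit):

```
global fit over 76 retained injections, rss = 87.7 ucal^2
  K1 (uM^-1)       fitted    0.2002   truth    0.1317   (+52.0%)
  K2 (uM^-1)       fitted    0.1879   truth    0.1315   (+42.9%)
  dH1 (kcal/mol)   fitted  -17.8021   truth  -18.7560   (-5.1%)
  dH2 (kcal/mol)   fitted    0.3523   truth    0.9520   (-63.0%)
  stage 1: dG =  -7.233, dH = -17.802, -TdS =  10.569 kcal/mol
  stage 2: dG =  -7.195, dH =   0.352, -TdS =  -7.547 kcal/mol
  apparent stoichiometry N_app = 0.942 (local concentration factors near 1 by construction)
```

The single-realisation K₁/K₂ deviations are expected: at these
concentrations and noise the stage split is strongly correlated with
the enthalpies (see `analysis/06_recovery_study.py`, which repeats the
experiment twenty times — the medians land within a few percent of the
truth while individual repetitions scatter widely).  The fitted −TΔS
columns always equal ΔG − ΔH by construction.

`python analysis/03_fit_anisotropy.py` fits the tracer titration
(K_d ≈ 37 μM), holds it fixed for the competition fit (K_I ≈ 11.3 μM),
and shows that a non-binding competitor is reported as a lower bound
rather than an estimate.  `04_structure_analysis.py` and
`05_conservation.py` run the geometric and conservation stages on the
toy structures and ortholog set.

A `tprbind` CLI wraps the same operations
(`tprbind demo --outdir out`, `tprbind fit-itc --isotherms a.csv b.csv
--out fit.json`, `tprbind interface --structure x.pdb --side-a A
--side-b C,D --out iface.json`, ...).

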