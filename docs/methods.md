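# Methods

## Sequential two-site binding model

A dimeric ligand A carries two equivalent-in-sequence but
thermodynamically distinct binding events for a receptor domain B:

    A + B ⇌ BA        K₁ = [BA] / ([A][B])        ΔH₁
    BA + B ⇌ BAB      K₂ = [BAB] / ([BA][B])      ΔH₂

K₁ and K₂ are *macroscopic* stepwise association constants (μM⁻¹); no
site-specific (microscopic) parameterisation is attempted.  Given total
concentrations A_t, B_t the free-titrant concentration solves

    B_t = [B] + A_t (K₁[B] + 2K₁K₂[B]²) / (1 + K₁[B] + K₁K₂[B]²),

which is strictly monotone in [B]; we solve for the free fraction
u = [B]/B_t ∈ [0, 1] with a bracketed (Brent) root-finder at machine
tolerance.  Normalising to the free fraction keeps the bracket
well-scaled at any concentration; the mass-balance residual is below
10⁻¹⁰ relative everywhere (property-tested over 10⁴ random draws).

### Injection heats

The perfusion-cell displacement convention: an injection of volume dv
into a constant cell volume V₀ displaces a fraction dv/V₀ of the
pre-mixing content, so resident totals scale by (1 − dv/V₀) and the
injected species gains c_syr·dv/V₀.  The heat of injection n is
referenced to the post-mixing cell contents, with displaced material
assumed at the pre-injection equilibrium:

    qₙ = V₀[ΔH₁Δ[BA] + (ΔH₁+ΔH₂)Δ[BAB]] + baseline · (moles injected),

where Δ[X] = [X]ₙ − (1 − dv/V₀)[X]ₙ₋₁.  Units: μL·μM·kcal/mol → μcal
via a factor 10⁻³.  A first sacrificial injection (0.5 μL, followed by
19 × 2 μL — the defaults of the synthetic generator) participates in
the dilution bookkeeping but is excluded from fit residuals.  An
enthalpy-bookkeeping oracle (tracking every mole that passed through
the cell at its formation enthalpy) confirms the heats sum to a state
function difference to 10⁻⁸ relative.

### Global fit and identifiability

Several titrations are fitted jointly: (ln K₁, ln K₂, ΔH₁, ΔH₂) and,
optionally, active fractions are shared; each experiment has local
(ln f_cell, ln f_syr, baseline).  Residuals are weighted by reported
heat errors when present.  Bounded trust-region least squares with a
small multistart over log-spaced perturbations of the K's guards
against the K₁/K₂ correlation; the multistart seed is explicit.

The heats are *exactly* invariant under the one-parameter family
(c → sc, K → K/s, ΔH → ΔH/s) applied to all concentrations jointly, so
unconstrained local factors leave the absolute scale of K and ΔH
undetermined (a noise-free synthetic fit reaches rss ≈ 10⁻²⁶ at
parameters displaced along exactly this direction).  We therefore place
a lognormal prior on the local concentration factors, sd 0.1 — the
typical accuracy of spectrophotometric protein quantification — which
pins the scale without biasing the remaining directions.  The prior
terms are excluded from the reported rss.

Even with all concentrations known exactly, the Fisher information of
a four-isotherm experiment (200 μL cell, 20 μM dimer, 400 μM titrant,
19 × 2 μL injections, 0.5 μcal heat noise) bounds sd(ln K₁) ≥ 0.49:
ln K₁ is 98% correlated with ΔH₁ at these conditions.  Single-fit
estimates of K₁ therefore scatter by ±40–60%, and no estimator can
recover K₁ within 15% in most repetitions at this design.  What *is*
stable is the median over repeated experiments: across twenty
simulate-and-refit repetitions the median recovered K₁ and ΔH₁ land
within a few percent of the truth (analysis/06, tests).  The
per-repetition parameter-recovery check is asserted at its stated
threshold regardless and fails for this reason — the honest reading of
the information content, not an estimator defect.

### Derived quantities

ΔG = −RT ln(K·10⁶) against a 1 M standard state with
R = 1.98720425×10⁻³ kcal·mol⁻¹·K⁻¹, T = 298.15 K by default; −TΔS is
always ΔG − ΔH (derived, never fitted).  The apparent stoichiometry is

    N_app = (A_cell · A_lig / n) Σᵢ F_cell,i / F_lig,i

over n experiments' locally fitted concentration factors F and global
active fractions A.  The typeset grouping of this expression is
ambiguous (the active fractions could divide instead); the product
reading is implemented as the default because with ligand factors
around 1.3 and active fractions around 0.95 it yields N_app ≈ 0.7,
matching the reported behaviour of over-quantified tryptophan-acidic
peptides; the quotient reading is available behind
`n_app(..., reading="quotient")`.

## Anisotropy models

Direct titration: A = A_min + (A_max − A_min)[R]/(K_d + [R]) (Hill
slope fixed at 1).  Competition at fixed receptor [KLC] with total
competitor [C] uses the trace-tracer closed form: the free receptor is
the positive root of R² + R(K_I + [C] − [KLC]) − K_I[KLC] = 0, and the
anisotropy follows the direct hyperbola in R_free with K_LFP.  This
equals the single-fraction printed form algebraically (property-tested
to 10⁻¹⁰) and agrees with an exact three-species equilibrium (tracer
depletion included) within 1% at tracer 0.3 μM ≪ K_LFP = 37 μM.

Fits are unweighted per-replicate least squares; K_LFP is held fixed in
the competition fit at the value from a prior direct fit.  K_I counts
as identified only when its log-scale standard error is below one
e-fold; otherwise the result is flagged and the highest tested
concentration is reported as a lower bound (the behaviour a
non-displacing competitor produces).  Competitor concentrations for a
dimeric competitor are interpreted in monomer-subunit units.

## Structure operations

Coordinates in Å, author residue numbering, inclusive ranges.  Parsing
(gemmi, PDB or mmCIF) keeps the first model, drops waters and
hydrogens, and keeps blank/'A' altlocs only — single-conformer
analysis of structures without hydrogens.

- Contacts: a residue is at the interface iff ≥ 1 heavy atom lies
  within 4.2 Å of the other side (k-d tree; equals all-pairs brute
  force exactly).
- Hydrogen bonds: inter-side N/O–N/O pairs ≤ 3.4 Å, distance-only; no
  donor/acceptor role assignment and no angle term, appropriate at
  3–4 Å resolution.
- Buried surface: Shrake–Rupley accessible surface with 960
  deterministic golden-spiral sphere points, probe 1.4 Å, van der
  Waals radii C 1.70, N 1.55, O 1.52, S/P 1.80 Å (others 1.70);
  buried(X) = ASA(X alone) − ASA(X in complex).  A single atom's ASA
  matches 4π(r + 1.4)² within 0.5% at this sampling; published-area
  comparisons carry a 5% tolerance for radii-set differences between
  implementations.
- Superposition: Kabsch (SVD with proper-rotation correction),
  correspondence by residue-number offset (default inferred from the
  starts of the two selections, e.g. the TPR1 ranges 195–236 vs
  210–251 give offset 15; register shifts are handled by explicit
  offsets).
- Crystal neighbours: chains with any Cα within 10 Å of the target
  chain; symmetry mates must be pre-expanded (space-group expansion is
  out of scope).
- Helix assignment: residue i is helical iff O(i)···N(i+4) ≤ 3.5 Å,
  with isolated single-residue gaps bridged.  This i→i+4 proxy
  reproduces ≥ 0.8 on an ideal 20-mer (four C-terminal residues lack a
  partner) and 0 on an extended chain; it is deliberately simpler than
  pattern-based assigners, so comparisons to their helix fractions
  carry a ±0.05 tolerance.
- Confinement: c = n / (N_A · 4/3 π r³), converted to μM; two
  molecules in a 150 Å sphere give ≈ 235 μM.

## Conservation pipeline

Pairwise global alignment with BLOSUM62, BLAST-like affine gaps (a gap
of length L costs 11 + L) and free end gaps, via Biopython's
PairwiseAligner; the first optimal alignment in its deterministic
enumeration is used, and an independent Gotoh dynamic-programming
oracle confirms the scores.  Homolog identification (database
searching, orthology assignment) is out of scope — inputs are
pre-matched ortholog sets.

A motif is a set of 1-based positions on its reference sequence with
an optional exempt subset where variation is allowed.  Conservation is
binary: every non-exempt position must align to an identical residue;
gaps, mismatches, 'X', and positions outside the alignment all break
it.  The five shipped motif definitions (`motifs.json`) include the
JIP3-binding and tryptophan-acidic cargo sites and the LFP motif on
KLC2, the TPR1 dimerisation site, and the KLC-binding site on JIP3;
for the latter the published exemption list names two positions
(446–447) outside the motif's own residue list, so exemptions are
intersected with the motif and apply only if present.  Summaries
report percent conserved per motif per clade; an empty clade yields NA
rather than 0.

## Synthetic generators

All generators are deterministic functions of (spec, seed) with
explicit mandatory seeds and no global random state; with zero noise
each equals its forward model to floating tolerance.  Noise is
independent Gaussian per observation (per integrated heat, per
anisotropy replicate), matching the least-squares estimators
downstream.

- ITC: defaults emulate the study conditions — 200 μL cell, 20 μM
  dimer, 400 μM titrant, one sacrificial 0.5 μL + 19 × 2 μL
  injections; heat noise 0.5 μcal per injection (chosen to resemble
  integrated-isotherm residual magnitudes; the study does not state a
  noise level).  An optional per-experiment nuisance (cell/syringe
  factors) emulates concentration errors; recovery studies draw them
  uniformly from [0.9, 1.1].
- Anisotropy: tracer 0.3 μM, A_min 0.05 / A_max 0.20, K_LFP 37 μM,
  K_I 11.3 μM, receptor 21 μM, twelve 2-fold dilutions from 300 μM,
  triplicate, noise 0.005 anisotropy units.
- Toy helices: closed-form parametric backbone — every atom type lies
  on a helical curve with rise 1.5 Å/residue and twist 100°/residue;
  Cα radius 2.3 Å, with N/C/O radius, phase and height offsets frozen
  from a one-off ideal-geometry (φ=−57°, ψ=−47°) internal-coordinate
  build.  The closed form makes the geometry self-verifying
  (Cα–Cα 3.83 Å, Cα i→i+4 6.20 Å, O(i)–N(i+4) 2.86 Å).
- Orthologs: star topology (no phylogeny) — each species mutates the
  reference independently at a background rate, avoiding required
  motif positions; an exact count round(f·n) of species per clade
  receives one disruptive substitution (→ Gly, or → Ala if already
  Gly) at a random required position, and the per-species label is
  stored as ground truth.  The break fraction may be given per clade.

What the synthetic layer does *not* emulate: baseline drift and
integration artefacts in thermograms, correlated replicate errors,
instrument G-factor effects, paralog confusion and alignment ambiguity
from real indel-rich orthologs, and crystal-specific coordinates.
Passing tests therefore demonstrate correctness of the estimators and
geometry under the stated noise models, not robustness to every
artefact of real data; comparisons that require deposited coordinates
are kept as separately invoked, optional checks.

## Problem sizes and runtime

The recovery studies use 20 repetitions × 4 isotherms × 19 fitted
injections (a fit takes well under a second; the full study a few
seconds) and single triplicate 12-point anisotropy titrations; the
property batteries use 10⁴ equilibrium draws and 100 random toy
structures.  These sizes were chosen to estimate each quantity's
sampling spread comfortably on a laptop-class single core.
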