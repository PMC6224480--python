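"""Synthetic-data generators with known ground truth.

Every input the analysis consumes can be generated here: ITC isotherms
from the sequential binding model, direct and competition anisotropy
titrations from their closed forms, ideal poly-alanine helices (and
dimers built from them) for the geometric operations, and ortholog
sequence sets with controlled conservation at motif positions.  All
generators are deterministic functions of (spec, seed); with zero noise
their output equals the corresponding forward model exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .anisotropy import AnisotropyDataset, CompetitionParams, competition_model, \
    direct_binding_model
from .conservation import MotifDefinition, OrthologRecord
from .itc import Injection, ITCExperiment, LocalNuisance, SequentialBindingParams, \
    predict_heats
from .structure import StructureModel

__all__ = [
    "SyntheticITCSpec",
    "SyntheticAnisotropySpec",
    "SyntheticOrthologSpec",
    "DEFAULT_INJECTION_SCHEDULE",
    "simulate_itc",
    "simulate_competition_curve",
    "simulate_direct_curve",
    "build_toy_helix",
    "generate_ortholog_set",
]

# one sacrificial 0.5 uL injection followed by 19 x 2 uL
DEFAULT_INJECTION_SCHEDULE = (0.5,) + (2.0,) * 19

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Ideal alpha-helix backbone as closed-form cylindrical curves, one per
# atom type: (radius A, phase offset deg, z offset A) relative to the
# C-alpha curve (radius 2.3 A, rise 1.5 A/residue, twist 100 deg/residue).
# Offsets frozen from a one-off ideal-geometry (phi=-57, psi=-47) build.
HELIX_RISE = 1.5
HELIX_TWIST = 100.0
HELIX_ATOM_PARAMS = {
    "N": (1.552, -26.77, -0.919),
    "CA": (2.30, 0.0, 0.0),
    "C": (1.666, 26.74, 1.069),
    "O": (1.924, 20.17, 2.255),
}


@dataclass(frozen=True)
class SyntheticITCSpec:
    """Conditions of one simulated titration.

    Defaults follow the study conditions: a MicroCal iTC200-scale cell
    (200 uL), dimer at 20 uM in the cell, titrant at 400 uM, one
    sacrificial 0.5 uL injection then 19 x 2 uL, Gaussian heat noise of
    0.5 ucal per injection.
    """

    true_params: SequentialBindingParams
    cell_conc_a: float = 20.0  # uM dimer
    syringe_conc_b: float = 400.0  # uM
    cell_volume_ul: float = 200.0
    injection_volumes: tuple = DEFAULT_INJECTION_SCHEDULE
    noise_sd: float = 0.5  # ucal
    seed: int = 0
    nuisance: LocalNuisance = field(default_factory=LocalNuisance)

    def __post_init__(self) -> None:
        if self.cell_conc_a <= 0 or self.syringe_conc_b <= 0:
            raise ValueError("concentrations must be positive")
        if self.cell_volume_ul <= 0:
            raise ValueError("cell volume must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if len(self.injection_volumes) < 1:
            raise ValueError("need at least one injection")
        if any(v <= 0 for v in self.injection_volumes):
            raise ValueError("injection volumes must be positive")


@dataclass(frozen=True)
class SyntheticAnisotropySpec:
    """Conditions of one simulated competition titration.

    Defaults follow the competition assay: tracer 0.3 uM, receptor fixed
    at 21 uM, tracer dissociation constant 37 uM, competitor
    dissociation constant 11.3 uM, two-fold competitor dilutions,
    triplicate, anisotropy noise 0.005.
    """

    a_min: float = 0.05
    a_max: float = 0.20
    k_lfp: float = 37.0  # uM
    k_i: float = 11.3  # uM
    klc_conc: float = 21.0  # uM
    competitor_concs: tuple = tuple(300.0 / 2 ** i for i in range(12))
    noise_sd: float = 0.005
    replicates: int = 3
    seed: int = 0
    tracer_conc: float = 0.3

    def __post_init__(self) -> None:
        if self.a_max <= self.a_min:
            raise ValueError("a_max must exceed a_min")
        if self.k_lfp <= 0 or self.k_i <= 0:
            raise ValueError("dissociation constants must be positive")
        if self.klc_conc < 0 or any(c < 0 for c in self.competitor_concs):
            raise ValueError("concentrations must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


@dataclass(frozen=True)
class SyntheticOrthologSpec:
    """Star-topology ortholog set with controlled motif conservation.

    Species sequences derive from the reference by background
    substitutions that avoid required motif positions; a
    ``motif_break_fraction`` of species (exact count per clade,
    round(f * n)) additionally receive one disruptive substitution at a
    randomly chosen required motif position.  ``motif_break_fraction``
    may be a single fraction or a mapping clade -> fraction.
    """

    reference_seq: str
    motif: MotifDefinition
    n_species_per_clade: dict
    background_substitution_rate: float = 0.02
    motif_break_fraction: float | dict = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.reference_seq:
            raise ValueError("reference sequence must be non-empty")
        if max(self.motif.residue_indices) > len(self.reference_seq):
            raise ValueError("motif indices exceed reference length")
        if not (0.0 <= self.background_substitution_rate <= 1.0):
            raise ValueError("background rate must lie in [0, 1]")
        for frac in self._fractions().values():
            if not (0.0 <= frac <= 1.0):
                raise ValueError("break fractions must lie in [0, 1]")
        if any(n < 0 for n in self.n_species_per_clade.values()):
            raise ValueError("species counts must be non-negative")

    def _fractions(self) -> dict:
        if isinstance(self.motif_break_fraction, dict):
            return dict(self.motif_break_fraction)
        return {c: self.motif_break_fraction for c in self.n_species_per_clade}


def simulate_itc(spec: SyntheticITCSpec) -> ITCExperiment:
    """Simulate one titration from the sequential model plus Gaussian noise."""
    schedule = tuple(Injection(v) for v in spec.injection_volumes)
    blank = ITCExperiment(
        cell_conc_a=spec.cell_conc_a, syringe_conc_b=spec.syringe_conc_b,
        cell_volume_ul=spec.cell_volume_ul, injections=schedule,
        sacrificial_first=len(spec.injection_volumes) > 1,
    )
    clean = predict_heats(spec.true_params, blank, spec.nuisance)
    rng = np.random.default_rng(spec.seed)
    noisy = clean + rng.normal(0.0, spec.noise_sd, size=len(clean)) \
        if spec.noise_sd > 0 else clean
    err = spec.noise_sd if spec.noise_sd > 0 else float("nan")
    injections = tuple(
        Injection(v, float(q), err)
        for v, q in zip(spec.injection_volumes, noisy)
    )
    return replace(blank, injections=injections)


def simulate_competition_curve(spec: SyntheticAnisotropySpec) -> AnisotropyDataset:
    """Simulate a competition titration from the closed form plus noise."""
    params = CompetitionParams(spec.a_min, spec.a_max, spec.k_lfp, spec.k_i,
                               spec.klc_conc)
    clean = competition_model(params, np.array(spec.competitor_concs))
    rng = np.random.default_rng(spec.seed)
    points = []
    for rep in range(spec.replicates):
        noise = rng.normal(0.0, spec.noise_sd, size=len(clean)) \
            if spec.noise_sd > 0 else np.zeros(len(clean))
        for c, a, e in zip(spec.competitor_concs, clean, noise):
            points.append((float(c), float(a + e), rep))
    return AnisotropyDataset(tuple(points), mode="competition",
                             klc_conc=spec.klc_conc, tracer_conc=spec.tracer_conc)


def simulate_direct_curve(
    a_min: float = 0.05, a_max: float = 0.20, k_d: float = 37.0,
    klc_concs=tuple(300.0 / 2 ** i for i in range(12)),
    noise_sd: float = 0.005, replicates: int = 3, seed: int = 0,
    tracer_conc: float = 0.3,
) -> AnisotropyDataset:
    """Simulate a direct receptor titration of the tracer (slope-1 model)."""
    if a_max <= a_min:
        raise ValueError("a_max must exceed a_min")
    clean = direct_binding_model(np.array(klc_concs), a_min, a_max, k_d)
    rng = np.random.default_rng(seed)
    points = []
    for rep in range(replicates):
        noise = rng.normal(0.0, noise_sd, size=len(clean)) \
            if noise_sd > 0 else np.zeros(len(clean))
        for c, a, e in zip(klc_concs, clean, noise):
            points.append((float(c), float(a + e), rep))
    return AnisotropyDataset(tuple(points), mode="direct", tracer_conc=tracer_conc)


def build_toy_helix(n_residues: int, chain_id: str = "A",
                    origin=(0.0, 0.0, 0.0)) -> StructureModel:
    """Ideal poly-alanine alpha-helical backbone (N, CA, C, O per residue).

    Closed-form parametric construction: each backbone atom type lies on
    a helical curve about the z axis with rise 1.5 A/residue and twist
    100 deg/residue (C-alpha radius 2.3 A), so the geometry is
    self-verifying from the parameters.
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues")
    origin = np.asarray(origin, dtype=float)
    chains, resnums, icodes, resnames, atnames, elements, coords = \
        [], [], [], [], [], [], []
    for i in range(n_residues):
        for name in ("N", "CA", "C", "O"):
            r, dphi, dz = HELIX_ATOM_PARAMS[name]
            theta = np.radians(HELIX_TWIST * i + dphi)
            coords.append(origin + np.array([
                r * np.cos(theta), r * np.sin(theta), HELIX_RISE * i + dz]))
            chains.append(chain_id)
            resnums.append(i + 1)
            icodes.append("")
            resnames.append("ALA")
            atnames.append(name)
            elements.append(name[0])
    return StructureModel(
        chain_ids=chains, residue_numbers=np.array(resnums),
        insertion_codes=icodes, residue_names=resnames, atom_names=atnames,
        elements=elements, coords=np.array(coords),
        metadata={"entry_id": "toy-helix"},
    )


def generate_ortholog_set(spec: SyntheticOrthologSpec) -> list:
    """Generate ortholog records with known per-species conservation labels."""
    rng = np.random.default_rng(spec.seed)
    ref = spec.reference_seq
    required = sorted(spec.motif.required_positions)
    required_set = set(required)
    fractions = spec._fractions()
    phyla = {
        "Bilateria": ("Chordata", "Arthropoda", "Nematoda",
                      "Annelida", "Platyhelminthes", "Mollusca"),
        "non-Bilateria": ("Porifera", "Ctenophora", "Cnidaria"),
    }
    records = []
    for clade, n in spec.n_species_per_clade.items():
        n_break = int(round(fractions.get(clade, 0.0) * n))
        broken = set(rng.choice(n, size=n_break, replace=False)) if n_break else set()
        for j in range(n):
            seq = list(ref)
            for pos in range(1, len(ref) + 1):
                if pos in required_set:
                    continue
                if rng.random() < spec.background_substitution_rate:
                    choices = [a for a in AMINO_ACIDS if a != seq[pos - 1]]
                    seq[pos - 1] = choices[rng.integers(len(choices))]
            is_broken = j in broken
            if is_broken and required:
                pos = required[rng.integers(len(required))]
                # disruptive: glycine, or alanine if already glycine
                seq[pos - 1] = "A" if ref[pos - 1] == "G" else "G"
            clade_phyla = phyla.get(clade, (clade,))
            records.append(OrthologRecord(
                species=f"sp_{clade.replace('-', '_')}_{j:03d}",
                phylum=clade_phyla[j % len(clade_phyla)],
                clade=clade,
                sequence="".join(seq),
                ground_truth_conserved=not is_broken,
            ))
    return records
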