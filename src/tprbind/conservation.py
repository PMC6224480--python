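"""Residue-motif conservation across ortholog sequences.

Each motif is a named set of 1-based positions on a reference sequence
(e.g. the JIP3-binding surface of a kinesin light chain TPR domain, or
the KLC-binding heptads of the JIP3 leucine zipper).  A motif counts as
conserved in a homolog when every required (non-exempt) position aligns
to an identical residue in a global pairwise alignment; any gap,
mismatch, or unaligned position breaks conservation.  Per-species calls
are aggregated into percent-conserved per clade (Bilateria versus
non-Bilateria).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "MotifDefinition",
    "OrthologRecord",
    "PairwiseAlignment",
    "MotifCall",
    "load_motifs",
    "align_pair",
    "classify_motif",
    "classify_records",
    "summarise",
]

CLADES = ("Bilateria", "non-Bilateria")


@dataclass(frozen=True)
class MotifDefinition:
    name: str
    reference_id: str
    residue_indices: frozenset
    exempt_positions: frozenset = frozenset()

    def __post_init__(self) -> None:
        if any(i < 1 for i in self.residue_indices):
            raise ValueError("residue indices are 1-based (>= 1)")
        if not self.exempt_positions <= self.residue_indices:
            raise ValueError("exempt positions must be a subset of the motif")

    @property
    def required_positions(self) -> frozenset:
        return self.residue_indices - self.exempt_positions


@dataclass(frozen=True)
class OrthologRecord:
    species: str
    phylum: str
    clade: str
    sequence: str
    ground_truth_conserved: bool | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")


@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_ref: str
    aligned_hom: str
    score: float
    ref_to_hom: dict  # 1-based reference position -> 1-based homolog position | None


@dataclass(frozen=True)
class MotifCall:
    conserved: bool
    per_position: tuple  # of (ref_pos, ref_aa, hom_pos|None, hom_aa|None, required, match)
    unmapped: tuple = ()


def load_motifs(path=None) -> dict:
    """Load motif definitions (name -> MotifDefinition) from JSON.

    With no path, the packaged definitions of the study's five motifs
    are loaded.  The JIP3 KLC-binding motif's published exemption list
    names two positions (446, 447) outside the printed residue set;
    exemptions are intersected with the motif, so they apply only if
    present.
    """
    if path is None:
        text = resources.files("tprbind").joinpath("motifs.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = json.loads(text)
    motifs = {}
    for name, entry in raw["motifs"].items():
        indices = frozenset(_expand(entry["residues"]))
        exempt = frozenset(_expand(entry.get("exempt", []))) & indices
        motifs[name] = MotifDefinition(name, entry["reference"], indices, exempt)
    return motifs


def _expand(items) -> list:
    out = []
    for item in items:
        if isinstance(item, str) and "-" in item:
            lo, _, hi = item.partition("-")
            out.extend(range(int(lo), int(hi) + 1))
        else:
            out.append(int(item))
    return out


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    # BLAST-style affine gaps: a gap of length L costs 11 + L
    aligner.open_gap_score = -12.0
    aligner.extend_gap_score = -1.0
    # end gaps free (the homolog may be a fragment or carry extensions)
    try:
        aligner.open_end_insertion_score = 0.0
        aligner.extend_end_insertion_score = 0.0
        aligner.open_end_deletion_score = 0.0
        aligner.extend_end_deletion_score = 0.0
    except AttributeError:  # older attribute names
        aligner.target_end_open_gap_score = 0.0
        aligner.target_end_extend_gap_score = 0.0
        aligner.query_end_open_gap_score = 0.0
        aligner.query_end_extend_gap_score = 0.0
    return aligner


def align_pair(reference: str, homolog: str) -> PairwiseAlignment:
    """Global pairwise alignment (BLOSUM62, affine gaps, free end gaps).

    Returns the gapped strings, the score, and a map from 1-based
    reference positions to 1-based homolog positions (None where the
    reference residue aligns to a gap).  The first optimal alignment in
    the aligner's deterministic enumeration order is used.
    """
    if not reference or not homolog:
        raise ValueError("sequences must be non-empty")
    aligner = _make_aligner()
    aln = aligner.align(reference, homolog)[0]
    ref_to_hom = {i: None for i in range(1, len(reference) + 1)}
    for (rs, re_), (hs, he) in zip(*aln.aligned):
        for k in range(re_ - rs):
            ref_to_hom[rs + k + 1] = hs + k + 1
    aligned_ref, aligned_hom = _gapped_strings(aln)
    return PairwiseAlignment(aligned_ref, aligned_hom, float(aln.score), ref_to_hom)


def _gapped_strings(aln):
    # Biopython's Alignment exposes gapped rows via indexing
    return str(aln[0]), str(aln[1])


def classify_motif(motif: MotifDefinition, reference: str, homolog: str,
                   alignment: PairwiseAlignment | None = None) -> MotifCall:
    """Call a motif conserved/not-conserved in one homolog.

    Conserved iff every required position aligns to an identical
    residue.  Exempt positions are reported but never break the call;
    'X' in the homolog counts as a mismatch; motif positions that fall
    outside the alignment are flagged and count as not conserved.
    """
    if max(motif.residue_indices) > len(reference):
        raise ValueError("motif indices exceed reference length")
    if alignment is None:
        alignment = align_pair(reference, homolog)
    rows = []
    unmapped = []
    conserved = True
    for pos in sorted(motif.residue_indices):
        ref_aa = reference[pos - 1]
        hom_pos = alignment.ref_to_hom.get(pos)
        required = pos in motif.required_positions
        if hom_pos is None:
            rows.append((pos, ref_aa, None, None, required, False))
            unmapped.append(pos)
            if required:
                conserved = False
            continue
        hom_aa = homolog[hom_pos - 1]
        match = hom_aa == ref_aa and hom_aa != "X"
        rows.append((pos, ref_aa, hom_pos, hom_aa, required, match))
        if required and not match:
            conserved = False
    return MotifCall(conserved, tuple(rows), tuple(unmapped))


def classify_records(records, motif: MotifDefinition, reference: str) -> pd.DataFrame:
    """Per-species conservation calls for one motif."""
    rows = []
    for rec in records:
        call = classify_motif(motif, reference, rec.sequence)
        rows.append({
            "species": rec.species, "phylum": rec.phylum, "clade": rec.clade,
            "motif": motif.name, "conserved": call.conserved,
        })
    return pd.DataFrame(rows)


def summarise(records, motifs, reference_map) -> pd.DataFrame:
    """Percent of species per clade in which each motif is conserved.

    ``reference_map`` maps motif name -> reference sequence.  Clades
    with no species report NaN (undefined), not 0.  Rows are sorted by
    motif then clade.
    """
    records = list(records)
    for rec in records:
        if rec.clade not in CLADES:
            raise ValueError(f"unknown clade {rec.clade!r} for {rec.species}")
    rows = []
    for motif in motifs:
        calls = classify_records(records, motif, reference_map[motif.name])
        for clade in CLADES:
            sub = calls[calls["clade"] == clade] if len(calls) else calls
            n = int(len(sub))
            n_cons = int(sub["conserved"].sum()) if n else 0
            rows.append({
                "motif": motif.name, "clade": clade,
                "n_species": n, "n_conserved": n_cons,
                "percentage": 100.0 * n_cons / n if n else np.nan,
            })
    out = pd.DataFrame(rows).sort_values(["motif", "clade"]).reset_index(drop=True)
    return out
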