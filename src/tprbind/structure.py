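"""Geometric analysis of macromolecular structures.

Covers the structural operations of the study: interface contact
residues (4.2 A heavy-atom cutoff), putative hydrogen bonds (3.4 A
between N/O atoms across the interface), buried accessible surface area
(Shrake-Rupley sphere sampling, 1.4 A probe), Kabsch superposition and
RMSD over C-alpha selections, crystal-contact neighbour enumeration
(10 A C-alpha cutoff), a backbone-hydrogen-bond helix assignment, and
the confinement-concentration estimate for tethered domains.

Coordinates are in Angstrom, residue numbering is author numbering
(inclusive ranges).  Waters and hydrogens are dropped at parse time;
only blank or 'A' altlocs are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
from scipy.spatial import cKDTree

import gemmi

AVOGADRO = 6.02214076e23

# van der Waals radii (A) used for accessible-surface computations
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}
VDW_DEFAULT = 1.70
PROBE_RADIUS = 1.4

__all__ = [
    "StructureModel",
    "AtomRecord",
    "ResidueSelection",
    "SelectionUnion",
    "InterfaceReport",
    "SuperpositionResult",
    "parse_structure",
    "write_pdb",
    "merge",
    "translate",
    "contact_residues",
    "hydrogen_bonds",
    "buried_surface_area",
    "shrake_rupley_asa",
    "superpose",
    "crystal_neighbours",
    "helix_fraction",
    "confinement_concentration",
]


class AtomRecord(NamedTuple):
    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    element: str
    x: float
    y: float
    z: float
    altloc: str = ""
    occupancy: float = 1.0


@dataclass
class StructureModel:
    """Flat atom table with numpy-backed coordinates."""

    chain_ids: list
    residue_numbers: np.ndarray
    insertion_codes: list
    residue_names: list
    atom_names: list
    elements: list
    coords: np.ndarray  # (n, 3) in A
    altlocs: list = field(default_factory=list)
    occupancies: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.chain_ids)
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (n, 3):
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if not self.altlocs:
            self.altlocs = [""] * n
        if self.occupancies is None:
            self.occupancies = np.ones(n)
        keys = set(zip(self.chain_ids, self.residue_numbers.tolist(),
                       self.insertion_codes, self.atom_names, self.altlocs))
        if len(keys) != n:
            raise ValueError("duplicate (chain, residue, insertion, atom, altloc) key")

    def __len__(self) -> int:
        return len(self.chain_ids)

    @property
    def atoms(self) -> list[AtomRecord]:
        return [
            AtomRecord(c, int(r), i, rn, an, el, *xyz, al, float(oc))
            for c, r, i, rn, an, el, xyz, al, oc in zip(
                self.chain_ids, self.residue_numbers, self.insertion_codes,
                self.residue_names, self.atom_names, self.elements,
                self.coords, self.altlocs, self.occupancies)
        ]

    def chain_set(self) -> set:
        return set(self.chain_ids)

    def select(self, selection: "ResidueSelection | None" = None,
               atom_name: str | None = None,
               elements: Iterable[str] | None = None) -> np.ndarray:
        """Indices of atoms matching a residue selection and atom filters."""
        mask = np.ones(len(self), dtype=bool)
        if selection is not None:
            mask &= np.array([
                selection.contains(c, int(r))
                for c, r in zip(self.chain_ids, self.residue_numbers)
            ])
        if atom_name is not None:
            mask &= np.array([a == atom_name for a in self.atom_names])
        if elements is not None:
            wanted = set(elements)
            mask &= np.array([e in wanted for e in self.elements])
        return np.nonzero(mask)[0]

    def residue_keys(self, indices: np.ndarray) -> list:
        """Sorted unique (chain, resnum, icode, resname) for atom indices."""
        seen = {}
        for i in indices:
            key = (self.chain_ids[i], int(self.residue_numbers[i]),
                   self.insertion_codes[i])
            seen.setdefault(key, self.residue_names[i])
        return sorted((c, r, ic, seen[(c, r, ic)]) for (c, r, ic) in seen)


@dataclass(frozen=True)
class ResidueSelection:
    """Chain plus inclusive author-numbered residue ranges (empty = whole chain)."""

    chain_id: str
    ranges: tuple = ()

    def __post_init__(self) -> None:
        for lo, hi in self.ranges:
            if lo > hi:
                raise ValueError(f"ill-ordered range {lo}-{hi}")

    def contains(self, chain: str, resnum: int) -> bool:
        if chain != self.chain_id:
            return False
        if not self.ranges:
            return True
        return any(lo <= resnum <= hi for lo, hi in self.ranges)

    @classmethod
    def parse(cls, text: str) -> "ResidueSelection":
        """Parse "A:195-236,240" or "A" into a selection."""
        if ":" not in text:
            return cls(text)
        chain, _, rest = text.partition(":")
        ranges = []
        for part in rest.split(","):
            if "-" in part:
                lo, _, hi = part.partition("-")
                ranges.append((int(lo), int(hi)))
            else:
                ranges.append((int(part), int(part)))
        return cls(chain, tuple(ranges))


@dataclass(frozen=True)
class SelectionUnion:
    """Union of several residue selections (e.g. both chains of a dimer)."""

    selections: tuple

    def contains(self, chain: str, resnum: int) -> bool:
        return any(s.contains(chain, resnum) for s in self.selections)


@dataclass(frozen=True)
class HydrogenBond:
    atom_a: tuple  # (chain, resnum, resname, atom_name)
    atom_b: tuple
    distance: float


@dataclass(frozen=True)
class InterfaceReport:
    contact_residues_a: tuple
    contact_residues_b: tuple
    hydrogen_bonds: tuple = ()
    buried_area_a: float | None = None
    buried_area_b: float | None = None
    cutoff: float | None = None


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int


class ParseError(ValueError):
    pass


_WATERS = {"HOH", "DOD", "WAT"}


def parse_structure(path, fmt: str | None = None,
                    keep_waters: bool = False,
                    keep_hydrogens: bool = False) -> StructureModel:
    """Read a PDB or mmCIF file into a StructureModel (first model only).

    Waters and hydrogens are excluded by default, and only blank/'A'
    altlocs are retained (single-conformer analysis).
    """
    path = str(path)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(path)
        elif fmt == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(path)[0])
        else:
            st = gemmi.read_structure(path)
    except (RuntimeError, ValueError, IndexError) as exc:
        raise ParseError(f"failed to parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: no models")
    model = st[0]
    chains, resnums, icodes, resnames = [], [], [], []
    atnames, elements, altlocs, occs, xyz = [], [], [], [], []
    for chain in model:
        for res in chain:
            if not keep_waters and res.name in _WATERS:
                continue
            for atom in res:
                el = atom.element.name
                if not keep_hydrogens and el in ("H", "D"):
                    continue
                if atom.altloc not in ("\0", "", "A"):
                    continue
                chains.append(chain.name)
                resnums.append(res.seqid.num)
                icodes.append(res.seqid.icode.strip())
                resnames.append(res.name)
                atnames.append(atom.name)
                elements.append(el)
                altlocs.append("" if atom.altloc in ("\0", "") else atom.altloc)
                occs.append(atom.occ)
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not chains:
        raise ParseError(f"{path}: no atoms after filtering")
    return StructureModel(
        chain_ids=chains, residue_numbers=np.array(resnums),
        insertion_codes=icodes, residue_names=resnames,
        atom_names=atnames, elements=elements,
        coords=np.array(xyz), altlocs=altlocs,
        occupancies=np.array(occs),
        metadata={"entry_id": st.name, "model": model.num},
    )


def write_pdb(model: StructureModel, path) -> None:
    """Write a minimal PDB file (ATOM records + TER/END)."""
    with open(path, "w") as fh:
        serial = 0
        prev_chain = None
        for a in model.atoms:
            if prev_chain is not None and a.chain_id != prev_chain:
                fh.write("TER\n")
            serial += 1
            name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name:<3}"
            fh.write(
                f"ATOM  {serial:>5} {name}{a.altloc or ' '}{a.residue_name:<3} "
                f"{a.chain_id:1}{a.residue_number:>4}{a.insertion_code or ' '}   "
                f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
                f"          {a.element:>2}\n"
            )
            prev_chain = a.chain_id
        fh.write("TER\nEND\n")


def merge(models: Iterable[StructureModel]) -> StructureModel:
    """Concatenate several models into one (chain ids must not collide)."""
    models = list(models)
    chains = [c for m in models for c in m.chain_ids]
    return StructureModel(
        chain_ids=chains,
        residue_numbers=np.concatenate([m.residue_numbers for m in models]),
        insertion_codes=[i for m in models for i in m.insertion_codes],
        residue_names=[r for m in models for r in m.residue_names],
        atom_names=[a for m in models for a in m.atom_names],
        elements=[e for m in models for e in m.elements],
        coords=np.vstack([m.coords for m in models]),
        altlocs=[a for m in models for a in m.altlocs],
        occupancies=np.concatenate([m.occupancies for m in models]),
    )


def translate(model: StructureModel, vector) -> StructureModel:
    """Rigidly translate a copy of the model."""
    out = StructureModel(
        chain_ids=list(model.chain_ids),
        residue_numbers=model.residue_numbers.copy(),
        insertion_codes=list(model.insertion_codes),
        residue_names=list(model.residue_names),
        atom_names=list(model.atom_names),
        elements=list(model.elements),
        coords=model.coords + np.asarray(vector, dtype=float),
        altlocs=list(model.altlocs),
        occupancies=model.occupancies.copy(),
        metadata=dict(model.metadata),
    )
    return out


def _check_disjoint(model, idx_a, idx_b):
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError("selections must be non-empty")
    if set(idx_a.tolist()) & set(idx_b.tolist()):
        raise ValueError("selections overlap")


def contact_residues(model: StructureModel, side_a: ResidueSelection,
                     side_b: ResidueSelection, cutoff: float = 4.2) -> InterfaceReport:
    """Interface residues: any residue with >= 1 heavy atom within ``cutoff``
    of the other side (the interatomic-distance definition of an interface)."""
    idx_a = model.select(side_a)
    idx_b = model.select(side_b)
    _check_disjoint(model, idx_a, idx_b)
    tree_b = cKDTree(model.coords[idx_b])
    pairs = tree_b.query_ball_point(model.coords[idx_a], cutoff)
    hit_a = np.array([len(p) > 0 for p in pairs])
    hit_b_idx = sorted({idx_b[j] for p in pairs for j in p})
    res_a = model.residue_keys(idx_a[hit_a])
    res_b = model.residue_keys(np.array(hit_b_idx, dtype=int))
    return InterfaceReport(tuple(res_a), tuple(res_b), cutoff=cutoff)


def hydrogen_bonds(model: StructureModel, side_a: ResidueSelection,
                   side_b: ResidueSelection, cutoff: float = 3.4) -> list:
    """Putative hydrogen bonds: inter-side N/O pairs within ``cutoff``.

    Distance-only criterion between donor/acceptor-capable elements;
    donor and acceptor roles are not distinguished.
    """
    idx_a = model.select(side_a, elements=("N", "O"))
    idx_b = model.select(side_b, elements=("N", "O"))
    if len(idx_a) == 0 or len(idx_b) == 0:
        return []
    _check_disjoint(model, model.select(side_a), model.select(side_b))
    tree_b = cKDTree(model.coords[idx_b])
    bonds = []
    for ia, neigh in zip(idx_a, tree_b.query_ball_point(model.coords[idx_a], cutoff)):
        for j in neigh:
            ib = idx_b[j]
            d = float(np.linalg.norm(model.coords[ia] - model.coords[ib]))
            bonds.append(HydrogenBond(
                (model.chain_ids[ia], int(model.residue_numbers[ia]),
                 model.residue_names[ia], model.atom_names[ia]),
                (model.chain_ids[ib], int(model.residue_numbers[ib]),
                 model.residue_names[ib], model.atom_names[ib]),
                d,
            ))
    return sorted(bonds, key=lambda b: (b.atom_a, b.atom_b))


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def shrake_rupley_asa(coords: np.ndarray, elements, probe: float = PROBE_RADIUS,
                      n_points: int = 960) -> np.ndarray:
    """Per-atom accessible surface area (A^2) by sphere-point sampling."""
    coords = np.asarray(coords, dtype=float)
    radii = np.array([VDW_RADII.get(e, VDW_DEFAULT) for e in elements]) + probe
    n = len(coords)
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    asa = np.zeros(n)
    rmax = radii.max()
    for i in range(n):
        ri = radii[i]
        pts = coords[i] + ri * unit
        neigh = [j for j in tree.query_ball_point(coords[i], ri + rmax) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neigh:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > radii[j] ** 2
        asa[i] = 4.0 * np.pi * ri * ri * accessible.sum() / n_points
    return asa


def buried_surface_area(model: StructureModel, side_a: ResidueSelection,
                        side_b: ResidueSelection, probe: float = PROBE_RADIUS,
                        n_points: int = 960):
    """Buried area per side: ASA(side alone) - ASA(side in the complex)."""
    idx_a = model.select(side_a)
    idx_b = model.select(side_b)
    _check_disjoint(model, idx_a, idx_b)
    el = np.array(model.elements, dtype=object)
    asa_a_alone = shrake_rupley_asa(model.coords[idx_a], el[idx_a], probe, n_points)
    asa_b_alone = shrake_rupley_asa(model.coords[idx_b], el[idx_b], probe, n_points)
    idx_ab = np.concatenate([idx_a, idx_b])
    asa_ab = shrake_rupley_asa(model.coords[idx_ab], el[idx_ab], probe, n_points)
    na = len(idx_a)
    buried_a = float(asa_a_alone.sum() - asa_ab[:na].sum())
    buried_b = float(asa_b_alone.sum() - asa_ab[na:].sum())
    return buried_a, buried_b


def _matched_coords(model_a, sel_a, model_b, sel_b, atom_name, offset):
    idx_a = model_a.select(sel_a, atom_name=atom_name)
    idx_b = model_b.select(sel_b, atom_name=atom_name)
    by_res_b = {int(model_b.residue_numbers[i]): i for i in idx_b}
    pa, pb = [], []
    for i in idx_a:
        j = by_res_b.get(int(model_a.residue_numbers[i]) + offset)
        if j is not None:
            pa.append(model_a.coords[i])
            pb.append(model_b.coords[j])
    return np.array(pa), np.array(pb)


def kabsch(moving: np.ndarray, target: np.ndarray):
    """Least-squares rotation/translation mapping ``moving`` onto ``target``."""
    cm = moving.mean(axis=0)
    ct = target.mean(axis=0)
    h = (moving - cm).T @ (target - ct)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ct - rot @ cm
    return rot, trans


def superpose(model_a: StructureModel, sel_a: ResidueSelection,
              model_b: StructureModel, sel_b: ResidueSelection,
              atom_name: str = "CA", offset: int | None = None) -> SuperpositionResult:
    """Kabsch superposition of selection A onto selection B.

    Atom correspondence is by residue number with an additive ``offset``
    (residue r in A pairs with residue r + offset in B).  By default the
    offset is inferred from the starts of the two selections' first
    ranges, e.g. TPR1 ranges 195-236 vs 210-251 give offset 15.
    """
    if offset is None:
        start_a = sel_a.ranges[0][0] if sel_a.ranges else 0
        start_b = sel_b.ranges[0][0] if sel_b.ranges else 0
        offset = start_b - start_a
    pa, pb = _matched_coords(model_a, sel_a, model_b, sel_b, atom_name, offset)
    if len(pa) < 3:
        raise ValueError(f"need >= 3 matched atoms, got {len(pa)}")
    rot, trans = kabsch(pa, pb)
    moved = pa @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - pb) ** 2, axis=1))))
    return SuperpositionResult(rot, trans, rmsd, len(pa))


def crystal_neighbours(model: StructureModel, target_chain: str,
                       cutoff: float = 10.0, atom_name: str = "CA") -> list:
    """Chains with >= 1 C-alpha within ``cutoff`` of the target chain.

    Symmetry mates must already be expanded into distinct chains in the
    input model.
    """
    if target_chain not in model.chain_set():
        raise ValueError(f"chain {target_chain!r} not in model")
    idx_t = model.select(ResidueSelection(target_chain), atom_name=atom_name)
    if len(idx_t) == 0:
        raise ValueError(f"chain {target_chain!r} has no {atom_name} atoms")
    tree = cKDTree(model.coords[idx_t])
    neighbours = []
    for chain in sorted(model.chain_set() - {target_chain}):
        idx_c = model.select(ResidueSelection(chain), atom_name=atom_name)
        if len(idx_c) == 0:
            continue
        d, _ = tree.query(model.coords[idx_c], k=1)
        if np.min(d) <= cutoff:
            neighbours.append(chain)
    return neighbours


def helix_fraction(model: StructureModel, selection: ResidueSelection | None = None,
                   hbond_cutoff: float = 3.5) -> float:
    """Fraction of selected residues assigned alpha-helical.

    Residue i is helical when its backbone O forms an i -> i+4 hydrogen
    bond (O(i)...N(i+4) <= cutoff); isolated single-residue gaps inside
    helical runs are bridged.  Residues without backbone O (or with no
    i+4 partner, e.g. chain termini) are non-helical by this rule.
    """
    # collect backbone O and N per (chain, resnum)
    o_pos, n_pos = {}, {}
    for i in range(len(model)):
        key = (model.chain_ids[i], int(model.residue_numbers[i]))
        if model.atom_names[i] == "O":
            o_pos[key] = model.coords[i]
        elif model.atom_names[i] == "N":
            n_pos[key] = model.coords[i]
    residues = sorted({
        (model.chain_ids[i], int(model.residue_numbers[i]))
        for i in (model.select(selection) if selection is not None
                  else range(len(model)))
    })
    if not residues:
        raise ValueError("empty selection")
    helical = {}
    for chain, rnum in residues:
        o = o_pos.get((chain, rnum))
        n4 = n_pos.get((chain, rnum + 4))
        helical[(chain, rnum)] = (
            o is not None and n4 is not None
            and float(np.linalg.norm(o - n4)) <= hbond_cutoff
        )
    # bridge single-residue gaps between helical neighbours
    for chain, rnum in residues:
        if not helical[(chain, rnum)]:
            if helical.get((chain, rnum - 1)) and helical.get((chain, rnum + 1)):
                helical[(chain, rnum)] = True
    return sum(helical.values()) / len(residues)


def confinement_concentration(n_molecules: int, radius: float) -> float:
    """Concentration (uM) of n molecules confined to a sphere of given
    radius (A): c = n / (N_A * 4/3 pi r^3)."""
    if n_molecules < 0:
        raise ValueError("molecule count must be non-negative")
    if radius <= 0:
        raise ValueError("radius must be positive")
    volume_l = (4.0 / 3.0) * np.pi * radius ** 3 * 1e-27
    return n_molecules / (AVOGADRO * volume_l) * 1e6
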