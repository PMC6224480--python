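"""Plain-text readers and writers for the pipeline's tabular formats.

Isotherms and anisotropy titrations travel as CSV with ``# key: value``
header comments carrying the experiment-level constants; ortholog sets
as FASTA plus a taxonomy TSV; structures as minimal PDB (see
``structure.write_pdb``).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .anisotropy import AnisotropyDataset
from .conservation import OrthologRecord
from .itc import Injection, ITCExperiment

__all__ = [
    "write_itc_csv", "read_itc_csv",
    "write_anisotropy_csv", "read_anisotropy_csv",
    "write_fasta", "read_fasta",
    "write_taxonomy_tsv", "read_ortholog_set",
]


def _read_header_comments(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
    return meta


def write_itc_csv(expt: ITCExperiment, path) -> None:
    cum_b = 0.0
    a_tot = expt.cell_conc_a
    v0 = expt.cell_volume_ul
    rows = []
    for i, inj in enumerate(expt.injections):
        dil = 1.0 - inj.volume_ul / v0
        a_tot *= dil
        cum_b = cum_b * dil + expt.syringe_conc_b * inj.volume_ul / v0
        rows.append({
            "injection_index": i,
            "volume_uL": inj.volume_ul,
            "molar_ratio": cum_b / a_tot,
            "heat_ucal": inj.heat_ucal,
            "heat_error_ucal": inj.heat_error_ucal,
        })
    with open(path, "w") as fh:
        fh.write(f"# cell_conc_A_uM: {expt.cell_conc_a!r}\n")
        fh.write(f"# syringe_conc_B_uM: {expt.syringe_conc_b!r}\n")
        fh.write(f"# cell_volume_uL: {expt.cell_volume_ul!r}\n")
        fh.write(f"# temperature_K: {expt.temperature!r}\n")
        fh.write(f"# sacrificial_first: {expt.sacrificial_first}\n")
        pd.DataFrame(rows).to_csv(fh, index=False)


def read_itc_csv(path) -> ITCExperiment:
    meta = _read_header_comments(path)
    df = pd.read_csv(path, comment="#")
    injections = tuple(
        Injection(float(r.volume_uL), float(r.heat_ucal),
                  float(r.heat_error_ucal) if math.isfinite(r.heat_error_ucal)
                  else float("nan"))
        for r in df.itertuples()
    )
    return ITCExperiment(
        cell_conc_a=float(meta["cell_conc_A_uM"]),
        syringe_conc_b=float(meta["syringe_conc_B_uM"]),
        cell_volume_ul=float(meta["cell_volume_uL"]),
        injections=injections,
        temperature=float(meta.get("temperature_K", 298.15)),
        sacrificial_first=meta.get("sacrificial_first", "True") == "True",
    )


def write_anisotropy_csv(data: AnisotropyDataset, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# mode: {data.mode}\n")
        if data.klc_conc is not None:
            fh.write(f"# klc_conc_uM: {data.klc_conc!r}\n")
        fh.write(f"# tracer_conc_uM: {data.tracer_conc!r}\n")
        pd.DataFrame(
            [{"competitor_uM": x, "replicate": rep, "anisotropy": a}
             for x, a, rep in data.points]
        ).to_csv(fh, index=False)


def read_anisotropy_csv(path) -> AnisotropyDataset:
    meta = _read_header_comments(path)
    df = pd.read_csv(path, comment="#")
    points = tuple(
        (float(r.competitor_uM), float(r.anisotropy), int(r.replicate))
        for r in df.itertuples()
    )
    klc = meta.get("klc_conc_uM")
    return AnisotropyDataset(
        points, mode=meta.get("mode", "direct"),
        klc_conc=float(klc) if klc is not None else None,
        tracer_conc=float(meta.get("tracer_conc_uM", 0.3)),
    )


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.species}\n")
            seq = rec.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def read_fasta(path) -> dict:
    """Read a FASTA file into {identifier: sequence} (order-preserving)."""
    seqs: dict = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            else:
                if name is None:
                    raise ValueError(f"{path}: sequence before first header")
                seqs[name].append(line)
    return {k: "".join(v) for k, v in seqs.items()}


def write_taxonomy_tsv(records, path) -> None:
    pd.DataFrame([
        {"species": r.species, "phylum": r.phylum, "clade": r.clade,
         "ground_truth_conserved": r.ground_truth_conserved}
        for r in records
    ]).to_csv(path, sep="\t", index=False)


def read_ortholog_set(fasta_path, taxonomy_path) -> list:
    """Join a FASTA file and taxonomy TSV into OrthologRecords."""
    seqs = read_fasta(fasta_path)
    taxa = pd.read_csv(taxonomy_path, sep="\t")
    records = []
    for row in taxa.itertuples():
        if row.species not in seqs:
            raise ValueError(f"species {row.species!r} missing from FASTA")
        gt = getattr(row, "ground_truth_conserved", None)
        records.append(OrthologRecord(
            species=row.species, phylum=row.phylum, clade=row.clade,
            sequence=seqs[row.species],
            ground_truth_conserved=bool(gt) if gt is not None and not (
                isinstance(gt, float) and np.isnan(gt)) else None,
        ))
    return records
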