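"""Readers and writers for the pipeline's plain-text formats.

Formats: PDB backbones (Bio.PDB), PB sequences as FASTA over ``a..p``/``Z``,
substitution matrices as labelled whitespace tables, dendrograms as Newick,
paired-FASTA alignment datasets with a metadata TSV and a per-column
distance track, and JSON truth bundles from the synthetic generator.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .pb_core import BackboneStructure
from .substitution import DomainPairAlignment, SubstitutionCounts, SubstitutionMatrix

GAP = "-"


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def read_pdb(path: str | Path, id: str | None = None) -> BackboneStructure:
    """Backbone (N, CA, C) of the first model; altloc blank or 'A' only."""
    from Bio.Data.PDBData import protein_letters_3to1
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(id or Path(path).stem, str(path))
    model = next(structure.get_models())
    chain_ids, numbers, aas = [], [], []
    n_xyz, ca_xyz, c_xyz = [], [], []
    for chain in model:
        for res in chain:
            if res.id[0] != " ":
                continue  # skip HETATM/water
            coords = {}
            for name in ("N", "CA", "C"):
                if name in res:
                    atom = res[name]
                    if atom.is_disordered():
                        atom = atom.disordered_get("A") if atom.disordered_has_id("A") else None
                    if atom is not None:
                        coords[name] = atom.get_coord()
            chain_ids.append(chain.id)
            numbers.append(res.id[1])
            aas.append(protein_letters_3to1.get(res.get_resname(), "X"))
            for name, dest in (("N", n_xyz), ("CA", ca_xyz), ("C", c_xyz)):
                dest.append(coords.get(name, np.full(3, np.nan)))
    return BackboneStructure(
        chain_ids=chain_ids,
        res_numbers=np.asarray(numbers),
        aa="".join(aas),
        n=np.asarray(n_xyz, float),
        ca=np.asarray(ca_xyz, float),
        c=np.asarray(c_xyz, float),
        id=id or Path(path).stem,
    )


def write_pdb(s: BackboneStructure, path: str | Path) -> None:
    """Write backbone ATOM records (poly-ALA residue names carry the 1-letter
    code only implicitly; amino acid identity lives in the FASTA outputs)."""
    three = {
        "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
        "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
        "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
        "Y": "TYR", "V": "VAL", "X": "UNK",
    }
    lines = []
    serial = 1
    ok = s.has_backbone()
    for i in range(len(s)):
        if not ok[i]:
            continue
        res = three.get(s.aa[i], "UNK")
        for name, xyz, element in (("N", s.n[i], "N"), ("CA", s.ca[i], "C"), ("C", s.c[i], "C")):
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s} {res} {s.chain_ids[i]:1s}"
                f"{int(s.res_numbers[i]):4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {element:>2s}"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA (PB alphabet)
# ---------------------------------------------------------------------------

def write_pb_fasta(records: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for k in range(0, len(seq), width):
                fh.write(seq[k: k + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    records: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            if name is not None:
                records[name] = "".join(chunks)
            name = line[1:].strip()
            chunks = []
        elif line.strip():
            chunks.append(line.strip())
    if name is not None:
        records[name] = "".join(chunks)
    return records


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------

def write_matrix(m: SubstitutionMatrix | SubstitutionCounts, path: str | Path,
                 decimals: int = 2) -> None:
    values = m.scores if isinstance(m, SubstitutionMatrix) else m.counts
    labels = m.labels
    header = "pb " + " ".join(labels)
    rows = [header]
    if isinstance(m, SubstitutionMatrix):
        rows.insert(0, f"# class={m.scop_class} stratum={m.stratum} "
                       f"pseudocount={m.pseudocount} normalization={m.normalization}")
    for lab, row in zip(labels, values):
        rows.append(lab + " " + " ".join(f"{v:.{decimals}f}" for v in row))
    Path(path).write_text("\n".join(rows) + "\n")


def read_matrix(path: str | Path) -> SubstitutionMatrix:
    meta: dict[str, str] = {}
    labels: list[str] = []
    rows: list[list[float]] = []
    header: list[str] | None = None
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            for tok in line[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
            continue
        parts = line.split()
        if not parts:
            continue
        if header is None:
            header = parts[1:]
            continue
        labels.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    if header is None or labels != header:
        raise ValueError(f"malformed matrix file {path}")
    return SubstitutionMatrix(
        labels=labels,
        scores=np.asarray(rows, float),
        scop_class=meta.get("class", "global"),
        stratum=meta.get("stratum", "all"),
        pseudocount=float(meta.get("pseudocount", 1.0)),
        normalization=meta.get("normalization", "family"),
    )


# ---------------------------------------------------------------------------
# Paired alignments + metadata + distances
# ---------------------------------------------------------------------------

def write_alignment_dataset(
    pairs: list[DomainPairAlignment], prefix: str | Path
) -> tuple[Path, Path, Path]:
    """Write ``<prefix>.pbfa`` (paired FASTA), ``<prefix>.meta.tsv`` and
    ``<prefix>.dist.tsv``; returns the three paths."""
    prefix = Path(prefix)
    fasta = prefix.with_suffix(".pbfa")
    meta = prefix.with_suffix(".meta.tsv")
    dist = prefix.with_suffix(".dist.tsv")
    with open(fasta, "w") as fh:
        for k, p in enumerate(pairs):
            aa1, aa2 = p.gapped("aa")
            pb1, pb2 = p.gapped("pb")
            fh.write(f">pair{k}|{p.id1}|aa\n{aa1}\n>pair{k}|{p.id2}|aa\n{aa2}\n")
            fh.write(f">pair{k}|{p.id1}|pb\n{pb1}\n>pair{k}|{p.id2}|pb\n{pb2}\n")
    with open(meta, "w") as fh:
        fh.write("pair\tid1\tid2\tfamily\tclass\tidentity\tresolution\n")
        for k, p in enumerate(pairs):
            res = "" if p.resolution is None else f"{p.resolution:.3f}"
            fh.write(f"pair{k}\t{p.id1}\t{p.id2}\t{p.family}\t{p.scop_class}"
                     f"\t{p.identity:.3f}\t{res}\n")
    with open(dist, "w") as fh:
        for k, p in enumerate(pairs):
            vals = ",".join("-" if np.isnan(d) else f"{d:.4f}" for d in p.distances)
            fh.write(f"pair{k}\t{vals}\n")
    return fasta, meta, dist


def read_alignment_dataset(prefix: str | Path) -> list[DomainPairAlignment]:
    prefix = Path(prefix)
    records = read_fasta(prefix.with_suffix(".pbfa"))
    meta_lines = prefix.with_suffix(".meta.tsv").read_text().splitlines()
    dists: dict[str, np.ndarray] = {}
    for line in prefix.with_suffix(".dist.tsv").read_text().splitlines():
        key, vals = line.split("\t")
        dists[key] = np.array([np.nan if v == "-" else float(v) for v in vals.split(",")])
    pairs: list[DomainPairAlignment] = []
    for line in meta_lines[1:]:
        key, id1, id2, family, cls, identity, resolution = line.split("\t")
        aa1g = records[f"{key}|{id1}|aa"]
        aa2g = records[f"{key}|{id2}|aa"]
        pb1g = records[f"{key}|{id1}|pb"]
        pb2g = records[f"{key}|{id2}|pb"]
        columns: list[tuple[int, int]] = []
        i = j = 0
        for a, b in zip(pb1g, pb2g):
            ii = i if a != GAP else -1
            jj = j if b != GAP else -1
            columns.append((ii, jj))
            i += a != GAP
            j += b != GAP
        pairs.append(
            DomainPairAlignment(
                id1=id1,
                id2=id2,
                family=family,
                scop_class=cls,
                columns=columns,
                distances=dists[key],
                aa1=aa1g.replace(GAP, ""),
                aa2=aa2g.replace(GAP, ""),
                pb1=pb1g.replace(GAP, ""),
                pb2=pb2g.replace(GAP, ""),
                identity=float(identity),
                resolution=float(resolution) if resolution else None,
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# Truth bundles
# ---------------------------------------------------------------------------

def write_truth_bundle(truth, path: str | Path) -> None:
    payload = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(truth.config).items()
            if k != "processes"
        },
        "processes": {cls: np.asarray(P).tolist() for cls, P in truth.processes.items()},
        "pairs": [
            {
                "family": t.family,
                "scop_class": t.scop_class,
                "intended1": t.intended1,
                "intended2": t.intended2,
                "realized1": t.realized1,
                "realized2": t.realized2,
                "aligned_columns": [list(c) for c in t.aligned_columns],
                "substituted_positions": t.substituted_positions,
                "indels": [
                    {
                        "carrier": s.carrier,
                        "length": s.length,
                        "left_index": s.left_index,
                        "di_pb": list(s.di_pb),
                    }
                    for s in t.indels
                ],
            }
            for t in truth.pairs
        ],
    }
    Path(path).write_text(json.dumps(payload))
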