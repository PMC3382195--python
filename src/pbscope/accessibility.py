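"""Solvent accessibility of PB positions and burial-stratified substitutions.

Per-residue relative solvent accessibility (RSA, % of a fully exposed
reference maximum) comes either from an imported NACCESS-style ``.rsa``
table or from an internal Shrake-Rupley calculation (Bio.PDB, 960 sphere
points, 1.4 angstrom probe, Chothia-type radii, Tien et al. theoretical
reference maxima; absolute values differ slightly from NACCESS output).

A PB position is *exposed* when at least 3 of the 5 residues in its window
are accessible, a residue being accessible when its RSA exceeds the chosen
cutoff (7, 15 or 25%).  Stratifying each PB into exposed/buried doubles the
alphabet to 32 labels (``m_e``, ``m_b``, ...) and the substitution pipeline
runs unchanged on it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .pb_core import PB_LABELS, UNASSIGNED, BackboneStructure
from .substitution import (
    CONSERVED_DISTANCE_DEFAULT,
    DomainPairAlignment,
    SubstitutionCounts,
    count_substitutions,
)

logger = logging.getLogger(__name__)

ACCESSIBILITY_CUTOFFS = (7.0, 15.0, 25.0)
STRATIFIED_CUTOFF_DEFAULT = 25.0
#: residues (out of the 5-residue PB window) that must be accessible
EXPOSED_MIN_RESIDUES = 3

PROBE_RADIUS = 1.4
SPHERE_POINTS = 960

#: Chothia-type van der Waals radii by element, angstrom
ATOM_RADII = {"C": 1.87, "N": 1.65, "O": 1.40, "S": 1.85, "P": 1.90, "H": 1.0}

#: Tien et al. (2013) theoretical maximum accessible surface areas, A^2
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

STRATA = ("e", "b")  # exposed, buried
STRATIFIED_LABELS = [f"{pb}_{s}" for pb in PB_LABELS for s in STRATA]


# ---------------------------------------------------------------------------
# RSA computation / import
# ---------------------------------------------------------------------------

def rsa_from_biopdb(model, probe: float = PROBE_RADIUS, n_points: int = SPHERE_POINTS) -> np.ndarray:
    """Relative all-atom accessibility (%) per residue of a Bio.PDB model."""
    from Bio.Data.PDBData import protein_letters_3to1
    from Bio.PDB.SASA import ShrakeRupley

    sr = ShrakeRupley(probe_radius=probe, n_points=n_points, radii_dict=ATOM_RADII)
    sr.compute(model, level="R")
    out = []
    for chain in model:
        for res in chain:
            aa = protein_letters_3to1.get(res.get_resname(), "X")
            ref = MAX_ASA.get(aa)
            out.append(100.0 * res.sasa / ref if ref else np.nan)
    return np.asarray(out)


def _to_biopdb(s: BackboneStructure):
    from Bio.PDB.StructureBuilder import StructureBuilder

    builder = StructureBuilder()
    builder.init_structure(s.id)
    builder.init_model(0)
    current_chain = None
    ok = s.has_backbone()
    for i in range(len(s)):
        if s.chain_ids[i] != current_chain:
            current_chain = s.chain_ids[i]
            builder.init_chain(current_chain)
            builder.init_seg("    ")
        if not ok[i]:
            continue
        builder.init_residue("GLY" if s.aa[i] == "G" else "ALA", " ", int(s.res_numbers[i]), " ")
        for name, coords, element in (("N", s.n[i], "N"), ("CA", s.ca[i], "C"), ("C", s.c[i], "C")):
            builder.init_atom(name, np.asarray(coords, float), 0.0, 1.0, " ", name, element=element)
    return builder.get_structure()[0]


def compute_accessibility(
    s: BackboneStructure, probe: float = PROBE_RADIUS, n_points: int = SPHERE_POINTS
) -> np.ndarray:
    """Shrake-Rupley RSA (%) per residue of a backbone structure.

    Only the atoms actually present contribute, so backbone-only synthetic
    chains yield backbone accessibility relative to the full-residue
    reference maxima.  Residues lacking backbone atoms are NaN.
    """
    rsa = np.full(len(s), np.nan)
    ok = s.has_backbone()
    if ok.any():
        model = _to_biopdb(s)
        vals = rsa_from_biopdb(model, probe=probe, n_points=n_points)
        # reference maxima follow the true amino acids, not the placeholder resnames
        k = 0
        for i in range(len(s)):
            if not ok[i]:
                continue
            ref = MAX_ASA.get(s.aa[i])
            # rsa_from_biopdb normalized by placeholder residue; renormalize
            raw = vals[k] * MAX_ASA["G" if s.aa[i] == "G" else "A"] / 100.0
            rsa[i] = 100.0 * raw / ref if ref else np.nan
            k += 1
    return rsa


def read_rsa(path: str | Path) -> np.ndarray:
    """Import a NACCESS-style per-residue relative accessibility table.

    Accepts either NACCESS ``RES`` lines (all-atom relative value, column 5)
    or a two-column whitespace table ``residue_number  rsa_percent``; values
    pass through unchanged.
    """
    values: list[float] = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "RES" and len(parts) >= 6:
            values.append(float(parts[5]))
        elif len(parts) == 2 and not parts[0].startswith(("#", "RE", "TO")):
            values.append(float(parts[1]))
    if not values:
        raise ValueError(f"no accessibility rows found in {path}")
    return np.asarray(values)


# ---------------------------------------------------------------------------
# Burial classification
# ---------------------------------------------------------------------------

@dataclass
class BurialLabels:
    """Per-residue exposed/buried call for each assigned PB position."""

    labels: list[str | None]  # 'e', 'b', or None (unassigned PB / missing RSA)
    cutoff: float


def classify_pb_burial(
    pb: str, rsa: np.ndarray, cutoff: float = STRATIFIED_CUTOFF_DEFAULT
) -> BurialLabels:
    """Exposed/buried call per PB position.

    A residue is accessible iff its RSA is strictly above ``cutoff``; a PB
    position is exposed iff at least 3 of the 5 residues of its window are
    accessible.  Positions with 'Z' or with undefined RSA anywhere in the
    window stay unlabeled.
    """
    rsa = np.asarray(rsa, float)
    if rsa.shape[0] != len(pb):
        raise ValueError("one RSA value per residue required")
    out: list[str | None] = []
    n_skipped = 0
    for i, lab in enumerate(pb):
        if lab == UNASSIGNED or i < 2 or i > len(pb) - 3:
            out.append(None)
            continue
        window = rsa[i - 2: i + 3]
        if np.isnan(window).any():
            out.append(None)
            n_skipped += 1
            continue
        accessible = int((window > cutoff).sum())
        out.append("e" if accessible >= EXPOSED_MIN_RESIDUES else "b")
    if n_skipped:
        logger.warning("%d PB position(s) left unlabeled: undefined RSA in window", n_skipped)
    return BurialLabels(labels=out, cutoff=float(cutoff))


def exposure_ratio(labelled: list[tuple[str, BurialLabels]]) -> pd.Series:
    """Ratio of exposed to buried occurrences per PB over a dataset.

    ``labelled`` pairs each PB sequence with its burial labels.  PBs absent
    from the dataset are omitted (with a warning); PBs never buried get
    ``inf``.
    """
    exposed = {pb: 0 for pb in PB_LABELS}
    buried = {pb: 0 for pb in PB_LABELS}
    for pb_seq, bl in labelled:
        for lab, stratum in zip(pb_seq, bl.labels):
            if stratum == "e":
                exposed[lab] += 1
            elif stratum == "b":
                buried[lab] += 1
    out = {}
    for pb in PB_LABELS:
        tot = exposed[pb] + buried[pb]
        if tot == 0:
            logger.warning("PB %r absent from the labelled dataset; omitted", pb)
            continue
        out[pb] = exposed[pb] / buried[pb] if buried[pb] else np.inf
    return pd.Series(out, name="exposed_to_buried")


# ---------------------------------------------------------------------------
# Stratified substitution counts
# ---------------------------------------------------------------------------

def stratified_counts(
    pairs: list[DomainPairAlignment],
    cutoff: float = STRATIFIED_CUTOFF_DEFAULT,
    distance_cutoff: float = CONSERVED_DISTANCE_DEFAULT,
) -> SubstitutionCounts:
    """32x32 substitution counts over the doubled (PB x burial) alphabet.

    Requires ``rsa1``/``rsa2`` on every pair.  Columns where either side
    lacks a burial label are skipped; marginalizing the result over strata
    reproduces the plain 16x16 counts of the same labelled columns.
    """
    burial: dict[tuple[str, int], BurialLabels] = {}
    for p in pairs:
        if p.rsa1 is None or p.rsa2 is None:
            raise ValueError(f"pair {p.pair_id} lacks accessibility profiles")
        burial[(p.pair_id, 0)] = classify_pb_burial(p.pb1, p.rsa1, cutoff)
        burial[(p.pair_id, 1)] = classify_pb_burial(p.pb2, p.rsa2, cutoff)

    def symbol_of(pair: DomainPairAlignment, side: int, i: int) -> str | None:
        pb = (pair.pb1 if side == 0 else pair.pb2)[i]
        stratum = burial[(pair.pair_id, side)].labels[i]
        if pb == UNASSIGNED or stratum is None:
            return None
        return f"{pb}_{stratum}"

    return count_substitutions(
        pairs, distance_cutoff, labels=list(STRATIFIED_LABELS), symbol_of=symbol_of
    )


def marginalize_strata(c: SubstitutionCounts) -> SubstitutionCounts:
    """Collapse 32x32 stratified counts to plain 16x16 PB counts."""
    if c.labels != list(STRATIFIED_LABELS):
        raise ValueError("expected stratified 32-label counts")
    collapsed = c.counts.reshape(16, 2, 16, 2).sum(axis=(1, 3))
    per_family = {
        fam: (mat.reshape(16, 2, 16, 2).sum(axis=(1, 3)), n)
        for fam, (mat, n) in c.per_family.items()
    }
    return SubstitutionCounts(labels=list(PB_LABELS), counts=collapsed, per_family=per_family)
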