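"""Protein Block (PB) encoding of protein backbones.

A Protein Block is one of 16 pentapeptide backbone prototypes, each described
by a series of 8 consecutive dihedral angles
(psi_{i-2}, phi_{i-1}, psi_{i-1}, phi_i, psi_i, phi_{i+1}, psi_{i+1}, phi_{i+2})
and labelled ``a`` through ``p``.  A backbone is encoded one residue at a time
by measuring that 8-angle window and taking the prototype with the smallest
angular RMSD (RMSDA).  Positions whose window is incomplete (chain termini,
chain breaks, missing atoms) receive the conventional placeholder ``Z``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

PB_LABELS: str = "abcdefghijklmnop"
UNASSIGNED: str = "Z"

#: maximum peptide-bond C(i)-N(i+1) length before a chain break is declared, in angstrom
CHAIN_BREAK_DISTANCE: float = 2.0


class DegenerateGeometryError(ValueError):
    """Raised when a torsion is requested for collinear or coincident atoms."""


# ---------------------------------------------------------------------------
# Backbone container
# ---------------------------------------------------------------------------

@dataclass
class BackboneStructure:
    """Ordered backbone (N, CA, C) coordinates for one or more chains.

    Parameters
    ----------
    chain_ids : sequence of str, one per residue
    res_numbers : integer author numbering, strictly increasing within a chain
    aa : one-letter amino acid codes, one per residue
    n, ca, c : (n_res, 3) float arrays of atom coordinates in angstrom.
        Missing atoms are NaN rows.
    """

    chain_ids: list[str]
    res_numbers: np.ndarray
    aa: str
    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    id: str = "struct"

    def __post_init__(self) -> None:
        self.res_numbers = np.asarray(self.res_numbers, dtype=int)
        for name in ("n", "ca", "c"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (len(self), 3):
                raise ValueError(f"{name} coordinates must be ({len(self)}, 3)")
            setattr(self, name, arr)
        if len(self.chain_ids) != len(self) or len(self.aa) != len(self):
            raise ValueError("per-residue fields must have equal length")
        for cid in set(self.chain_ids):
            nums = self.res_numbers[[i == cid for i in self.chain_ids]]
            if np.any(np.diff(nums) <= 0):
                raise ValueError(f"residue numbers not strictly increasing in chain {cid}")

    def __len__(self) -> int:
        return self.res_numbers.shape[0]

    def has_backbone(self) -> np.ndarray:
        """Boolean mask of residues with all three backbone atoms present."""
        return ~(
            np.isnan(self.n).any(axis=1)
            | np.isnan(self.ca).any(axis=1)
            | np.isnan(self.c).any(axis=1)
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "BackboneStructure":
        """Return a rigidly moved copy (x -> R x + t)."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        return BackboneStructure(
            chain_ids=list(self.chain_ids),
            res_numbers=self.res_numbers.copy(),
            aa=self.aa,
            n=self.n @ rotation.T + translation,
            ca=self.ca @ rotation.T + translation,
            c=self.c @ rotation.T + translation,
            id=self.id,
        )


# ---------------------------------------------------------------------------
# Torsions
# ---------------------------------------------------------------------------

def torsions_from_points(
    p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray
) -> np.ndarray:
    """Vectorized IUPAC torsion angles, in degrees in (-180, 180].

    Inputs are (..., 3) arrays of four points per torsion.  Degenerate
    quadruplets (coincident points or collinear bonds) yield NaN.
    """
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        x = np.sum(n1 * n2, axis=-1)
        y = np.sum(np.cross(n1, n2) * b2 / np.where(b2n == 0, np.nan, b2n)[..., None], axis=-1)
        ang = np.degrees(np.arctan2(y, x))
    bad = (np.linalg.norm(n1, axis=-1) < 1e-9) | (np.linalg.norm(n2, axis=-1) < 1e-9)
    ang = np.where(bad, np.nan, ang)
    # map -180 -> 180 so the range is (-180, 180]
    return np.where(np.isclose(ang, -180.0), 180.0, ang)


def compute_torsion(p1, p2, p3, p4) -> float:
    """IUPAC torsion angle of four points, degrees in (-180, 180].

    Positive sense is a clockwise rotation of the p3->p4 bond relative to the
    p1->p2 bond when viewed from p2 towards p3 (so trans/anti is 180).

    Raises
    ------
    DegenerateGeometryError
        if consecutive points coincide or the bond vectors are collinear.
    """
    ang = float(torsions_from_points(p1, p2, p3, p4))
    if np.isnan(ang):
        raise DegenerateGeometryError("collinear or coincident points define no torsion")
    return ang


# ---------------------------------------------------------------------------
# Dihedral series
# ---------------------------------------------------------------------------

@dataclass
class DihedralSeries:
    """Per-residue backbone phi/psi in degrees; NaN marks undefined angles."""

    phi: np.ndarray
    psi: np.ndarray
    chain_ids: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return self.phi.shape[0]


def _chain_continuity(s: BackboneStructure) -> np.ndarray:
    """Mask over i = 0..n-2: True where residues i, i+1 form a continuous peptide.

    Continuity requires the same chain id, consecutive author numbering and a
    C(i)-N(i+1) distance within CHAIN_BREAK_DISTANCE.
    """
    n = len(s)
    if n < 2:
        return np.zeros(0, dtype=bool)
    same_chain = np.array([s.chain_ids[i] == s.chain_ids[i + 1] for i in range(n - 1)])
    consecutive = np.diff(s.res_numbers) == 1
    with np.errstate(invalid="ignore"):
        dist = np.linalg.norm(s.n[1:] - s.c[:-1], axis=1)
    bonded = np.nan_to_num(dist, nan=np.inf) <= CHAIN_BREAK_DISTANCE
    return same_chain & consecutive & bonded


def compute_dihedrals(s: BackboneStructure) -> DihedralSeries:
    """Backbone phi/psi series of a structure.

    phi_i uses C(i-1), N(i), CA(i), C(i); psi_i uses N(i), CA(i), C(i), N(i+1).
    Angles spanning a chain terminus, a chain break or a residue with missing
    backbone atoms are NaN.
    """
    n = len(s)
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    if n >= 2:
        cont = _chain_continuity(s)
        with np.errstate(invalid="ignore"):
            phi_all = torsions_from_points(s.c[:-1], s.n[1:], s.ca[1:], s.c[1:])
            psi_all = torsions_from_points(s.n[:-1], s.ca[:-1], s.c[:-1], s.n[1:])
        phi[1:] = np.where(cont, phi_all, np.nan)
        psi[:-1] = np.where(cont, psi_all, np.nan)
        n_missing = int((~s.has_backbone()).sum())
        if n_missing:
            logger.warning("%d residue(s) lack backbone atoms; dependent angles undefined", n_missing)
    return DihedralSeries(phi=phi, psi=psi, chain_ids=list(s.chain_ids))


# ---------------------------------------------------------------------------
# Prototype table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PBPrototypeTable:
    """The 16 reference 8-angle vectors, one per PB label a..p."""

    labels: str
    angles: np.ndarray  # (16, 8), degrees

    def __post_init__(self) -> None:
        if len(self.labels) != 16 or self.angles.shape != (16, 8):
            raise ValueError("prototype table must have 16 labels x 8 angles")

    def vector(self, label: str) -> np.ndarray:
        return self.angles[self.labels.index(label)]

    def central_pair(self, label: str) -> tuple[float, float]:
        """(phi_i, psi_i) of a prototype: the 4th and 5th angles of its series."""
        v = self.vector(label)
        return float(v[3]), float(v[4])


def load_prototype_table(path: str | Path | None = None) -> PBPrototypeTable:
    """Load the shipped (or a user-supplied) plain-text prototype table."""
    if path is None:
        ref = resources.files("pbscope").joinpath("data/pb_prototypes.txt")
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    labels: list[str] = []
    rows: list[list[float]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        labels.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    table = PBPrototypeTable(labels="".join(labels), angles=np.asarray(rows, float))
    if table.labels != PB_LABELS:
        raise ValueError(f"expected labels {PB_LABELS!r}, got {table.labels!r}")
    return table


_DEFAULT_TABLE: PBPrototypeTable | None = None


def default_prototype_table() -> PBPrototypeTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_prototype_table()
    return _DEFAULT_TABLE


# ---------------------------------------------------------------------------
# RMSDA and assignment
# ---------------------------------------------------------------------------

def circular_difference(a, b) -> np.ndarray:
    """Smallest absolute angular difference in degrees, elementwise."""
    d = np.abs(np.asarray(a, float) - np.asarray(b, float)) % 360.0
    return np.minimum(d, 360.0 - d)


def rmsda(v1: Sequence[float], v2: Sequence[float]) -> float:
    """Root mean square deviation over angles with circular differences."""
    v1 = np.asarray(v1, float)
    v2 = np.asarray(v2, float)
    if v1.shape != (8,) or v2.shape != (8,):
        raise ValueError("rmsda expects two 8-angle vectors")
    if np.isnan(v1).any() or np.isnan(v2).any():
        raise ValueError("rmsda requires fully defined angle vectors")
    return float(np.sqrt(np.mean(circular_difference(v1, v2) ** 2)))


def dihedral_windows(d: DihedralSeries) -> np.ndarray:
    """(n, 8) matrix of per-residue PB windows; NaN where undefined.

    Window for residue i is (psi_{i-2}, phi_{i-1}, psi_{i-1}, phi_i, psi_i,
    phi_{i+1}, psi_{i+1}, phi_{i+2}).
    """
    n = len(d)
    w = np.full((n, 8), np.nan)
    if n == 0:
        return w
    phi, psi = d.phi, d.psi

    def shifted(arr: np.ndarray, k: int) -> np.ndarray:
        out = np.full(n, np.nan)
        if k >= 0:
            out[: n - k if k else n] = arr[k:]
        else:
            out[-k:] = arr[: n + k]
        return out

    w[:, 0] = shifted(psi, -2)
    w[:, 1] = shifted(phi, -1)
    w[:, 2] = shifted(psi, -1)
    w[:, 3] = phi
    w[:, 4] = psi
    w[:, 5] = shifted(phi, 1)
    w[:, 6] = shifted(psi, 1)
    w[:, 7] = shifted(phi, 2)
    # windows must not mix chains: blank any window whose +-2 neighbourhood
    # crosses a chain-id boundary (breaks within a chain already give NaN phi/psi)
    if d.chain_ids:
        cids = np.asarray(d.chain_ids)
        for off in (-2, -1, 1, 2):
            idx = np.arange(n) + off
            valid = (idx >= 0) & (idx < n)
            mixed = np.zeros(n, dtype=bool)
            mixed[valid] = cids[np.clip(idx[valid], 0, n - 1)] != cids[valid]
            w[mixed] = np.nan
    return w


def assign_windows(windows: np.ndarray, table: PBPrototypeTable | None = None) -> str:
    """Assign a PB label to each fully defined 8-angle window, else 'Z'.

    Ties in RMSDA (within 1e-9 degrees) resolve to the alphabetically first
    label.
    """
    table = table or default_prototype_table()
    windows = np.asarray(windows, float)
    defined = ~np.isnan(windows).any(axis=1)
    out = np.full(windows.shape[0], UNASSIGNED, dtype="U1")
    if defined.any():
        diffs = circular_difference(
            windows[defined][:, None, :], table.angles[None, :, :]
        )
        scores = np.sqrt(np.mean(diffs**2, axis=2))
        # argmin takes the first minimum, and labels are in alphabetical order
        best = np.argmin(np.where(scores <= scores.min(axis=1, keepdims=True) + 1e-9,
                                  scores.min(axis=1, keepdims=True), scores), axis=1)
        out[defined] = np.array(list(table.labels))[best]
    return "".join(out)


def assign_pbs(d: DihedralSeries, table: PBPrototypeTable | None = None) -> str:
    """PB sequence of a dihedral series (one symbol per residue, 'Z' padding)."""
    return assign_windows(dihedral_windows(d), table)


def encode_structure(s: BackboneStructure, table: PBPrototypeTable | None = None) -> str:
    """Convenience: backbone coordinates -> PB string."""
    return assign_pbs(compute_dihedrals(s), table)


# ---------------------------------------------------------------------------
# Sequence identity
# ---------------------------------------------------------------------------

def percent_identity(aligned_aa_pairs: Iterable[tuple[str, str]]) -> float:
    """Percent identical residues among aligned (non-gap) amino acid pairs."""
    pairs = list(aligned_aa_pairs)
    if not pairs:
        raise ValueError("percent identity of an empty alignment is undefined")
    same = sum(1 for a, b in pairs if a == b)
    return 100.0 * same / len(pairs)
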