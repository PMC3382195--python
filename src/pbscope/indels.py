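"""Indel sites in pairwise alignments and di-PB hotspot enrichment.

A maximal run of gaps of length n in one row of a structural alignment is an
insertion/deletion site when it is flanked on both sides by at least 3
consecutive aligned residue pairs, each within 3 angstrom.  The site is
described by the ordered pair of PB labels (di-PB) of the *un-inserted*
sequence immediately bounding the gap, plus a 6-symbol PB context (two PBs
on each side of the di-PB).  Per insert-length class (1, 2, 3, 4, 5+),
observed di-PB counts are compared to the background di-PB frequencies of
the whole dataset with a one-sample binomial-proportion Z statistic,

    Z_d = (O_d - T p_d) / sqrt(T p_d (1 - p_d)),

and di-PBs with Z > 2 are flagged as preferred insertion sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pb_core import PB_LABELS, UNASSIGNED
from .substitution import CONSERVED_DISTANCE_DEFAULT, DomainPairAlignment

logger = logging.getLogger(__name__)

MIN_FLANK_DEFAULT = 3
IDENTITY_CUTOFF_INDELS = 80.0
Z_THRESHOLD_DEFAULT = 2.0

LENGTH_CLASSES = ("1", "2", "3", "4", "5+")


def length_class(n: int) -> str:
    """Insert-length class: 1..4 literal, everything >= 5 pooled as '5+'."""
    if n < 1:
        raise ValueError("gap length must be at least 1")
    return str(n) if n < 5 else "5+"


@dataclass
class IndelSite:
    """One accepted insertion/deletion site."""

    pair_id: str
    carrier: int  # 1 or 2: domain with the extra residues
    length: int
    di_pb: tuple[str, str]  # bounding PBs of the un-inserted sequence, N->C
    context: str  # 6 PB symbols: 2 upstream + di-PB + 2 downstream
    left_flank_ok: bool = True
    right_flank_ok: bool = True

    @property
    def insert_class(self) -> str:
        return length_class(self.length)


def find_indel_sites(
    a: DomainPairAlignment,
    min_flank: int = MIN_FLANK_DEFAULT,
    distance_cutoff: float = CONSERVED_DISTANCE_DEFAULT,
) -> list[IndelSite]:
    """Accepted indel sites of one alignment.

    Each maximal gap run in either row qualifies iff the ``min_flank``
    columns immediately left and right of the run are aligned pairs within
    ``distance_cutoff``.  Sites whose di-PB or 6-symbol context contains 'Z'
    (or falls off the chain) are rejected.
    """
    if np.isnan(a.distances[[i >= 0 and j >= 0 for i, j in a.columns]]).any():
        raise ValueError(f"pair {a.pair_id} lacks distances for aligned columns")
    cols = a.columns
    n_cols = len(cols)
    aligned = np.array([i >= 0 and j >= 0 for i, j in cols])
    good = aligned & ~np.isnan(np.where(aligned, a.distances, np.nan)) & (
        np.nan_to_num(a.distances, nan=np.inf) <= distance_cutoff
    )
    sites: list[IndelSite] = []
    for row in (0, 1):
        gap_here = np.array([(cols[c][row] < 0) for c in range(n_cols)])
        c = 0
        while c < n_cols:
            if not gap_here[c]:
                c += 1
                continue
            start = c
            while c < n_cols and gap_here[c]:
                c += 1
            end = c  # run is [start, end)
            left_ok = start >= min_flank and bool(good[start - min_flank: start].all())
            right_ok = end + min_flank <= n_cols and bool(good[end: end + min_flank].all())
            if not (left_ok and right_ok):
                continue
            # the un-inserted domain is the one with the gap in this row
            if row == 0:
                seq, li = a.pb1, cols[start - 1][0]
                carrier = 2
            else:
                seq, li = a.pb2, cols[start - 1][1]
                carrier = 1
            if li < 2 or li + 3 >= len(seq):
                continue
            context = seq[li - 2: li + 4]
            if UNASSIGNED in context:
                continue
            sites.append(
                IndelSite(
                    pair_id=a.pair_id,
                    carrier=carrier,
                    length=end - start,
                    di_pb=(seq[li], seq[li + 1]),
                    context=context,
                )
            )
    return sites


def collect_indel_sites(
    pairs: list[DomainPairAlignment],
    max_identity: float = IDENTITY_CUTOFF_INDELS,
    min_flank: int = MIN_FLANK_DEFAULT,
    distance_cutoff: float = CONSERVED_DISTANCE_DEFAULT,
) -> list[IndelSite]:
    """Sites pooled over a dataset, after the identity filter (strict <)."""
    sites: list[IndelSite] = []
    for p in pairs:
        if p.identity >= max_identity:
            continue
        sites.extend(find_indel_sites(p, min_flank, distance_cutoff))
    return sites


# ---------------------------------------------------------------------------
# Background distribution
# ---------------------------------------------------------------------------

@dataclass
class DiPBDistribution:
    """Counts and frequencies over the 256 ordered di-PBs."""

    counts: np.ndarray  # (16, 16)
    total: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, float)
        self.total = int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    def frequency(self, di: tuple[str, str]) -> float:
        return float(self.frequencies[PB_LABELS.index(di[0]), PB_LABELS.index(di[1])])


def dipb_background(sequences: list[str]) -> DiPBDistribution:
    """Background di-PB distribution: all consecutive non-Z ordered pairs."""
    counts = np.zeros((16, 16))
    idx = {lab: k for k, lab in enumerate(PB_LABELS)}
    for seq in sequences:
        for a, b in zip(seq, seq[1:]):
            if a in idx and b in idx:
                counts[idx[a], idx[b]] += 1
    if counts.sum() == 0:
        raise ValueError("no valid di-PBs in the input sequences")
    return DiPBDistribution(counts=counts)


# ---------------------------------------------------------------------------
# Z statistics
# ---------------------------------------------------------------------------

@dataclass
class IndelZReport:
    """Per length class and di-PB: enrichment of indel sites over background."""

    table: pd.DataFrame
    z_threshold: float = Z_THRESHOLD_DEFAULT
    statistic: str = "one-sample binomial-proportion Z vs dataset di-PB background"
    n_sites: dict[str, int] = field(default_factory=dict)

    def preferred(self, insert_class: str | None = None) -> pd.DataFrame:
        t = self.table[self.table["preferred"]]
        if insert_class is not None:
            t = t[t["insert_class"] == insert_class]
        return t


def z_scores(
    sites: list[IndelSite],
    background: DiPBDistribution,
    z_threshold: float = Z_THRESHOLD_DEFAULT,
) -> IndelZReport:
    """Di-PB enrichment per insert-length class.

    For a class with T sites and a di-PB of background frequency p, the
    expected count is T*p and Z = (O - T*p)/sqrt(T*p*(1-p)); the di-PB is
    preferred iff Z > ``z_threshold``.  Background frequencies of exactly 0
    or 1 leave Z undefined (NaN, flagged in the ``note`` column).  The modal
    6-symbol context of each di-PB is reported with its percentage among
    that di-PB's sites in the class.
    """
    if not sites:
        raise ValueError("no indel sites to score")
    freqs = background.frequencies
    rows = []
    n_sites: dict[str, int] = {}
    by_class: dict[str, list[IndelSite]] = {}
    for s in sites:
        by_class.setdefault(s.insert_class, []).append(s)
    for cls in LENGTH_CLASSES:
        members = by_class.get(cls)
        if not members:
            continue
        T = len(members)
        n_sites[cls] = T
        tallies: dict[tuple[str, str], list[IndelSite]] = {}
        for s in members:
            tallies.setdefault(s.di_pb, []).append(s)
        for di, di_sites in sorted(tallies.items()):
            obs = len(di_sites)
            p = float(freqs[PB_LABELS.index(di[0]), PB_LABELS.index(di[1])])
            expected = T * p
            if p <= 0.0 or p >= 1.0:
                z = np.nan
                note = "background frequency degenerate; Z undefined"
            else:
                z = (obs - expected) / np.sqrt(T * p * (1.0 - p))
                note = ""
            contexts = pd.Series([s.context for s in di_sites])
            top = contexts.value_counts()
            modal = sorted(top[top == top.max()].index)[0]
            rows.append(
                {
                    "insert_class": cls,
                    "di_pb": "".join(di),
                    "observed": obs,
                    "expected": expected,
                    "z": z,
                    "preferred": bool(z > z_threshold) if np.isfinite(z) else False,
                    "modal_context": modal,
                    "context_pct": 100.0 * top.max() / obs,
                    "note": note,
                }
            )
    table = pd.DataFrame(rows)
    return IndelZReport(table=table, z_threshold=z_threshold, n_sites=n_sites)
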