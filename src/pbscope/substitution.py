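"""PB substitution statistics over structurally conserved aligned regions.

Substitutions are counted column-by-column from pairwise structural
alignments of homologous domains: a column contributes iff both sides carry a
real PB (not 'Z') and the aligned C-alpha atoms lie within a distance cutoff
(default 3 angstrom, the "conserved core").  Counts are accumulated per
family and each family's matrix is divided by its number of contributing
domain pairs before pooling, so large families do not dominate.  Pooled
counts become log-odds scores in the BLOSUM sense

    S_ij = log2( q_ij / (p_i p_j) )

where q is the symmetrized ordered-pair frequency and p its marginals; a
pseudocount keeps every score finite.  The same pipeline runs globally, per
SCOP class, and (in :mod:`pbscope.accessibility`) per burial stratum.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

from .pb_core import PB_LABELS, UNASSIGNED

logger = logging.getLogger(__name__)

CONSERVED_DISTANCE_DEFAULT: float = 3.0
IDENTITY_CUTOFF_MATRIX: float = 40.0
PSEUDOCOUNT_DEFAULT: float = 1.0

SCOP_CLASSES = ("all-alpha", "all-beta", "alpha/beta", "alpha+beta")


# ---------------------------------------------------------------------------
# Alignment container
# ---------------------------------------------------------------------------

@dataclass
class DomainPairAlignment:
    """A pairwise structural alignment of two homologous domains.

    ``columns`` lists (i, j) residue indices with -1 for a gap; ``distances``
    gives the post-superposition C-alpha distance per column (NaN at gap
    columns).  PB and amino acid sequences are *ungapped*, indexed by the
    residue indices in ``columns``.
    """

    id1: str
    id2: str
    family: str
    scop_class: str
    columns: list[tuple[int, int]]
    distances: np.ndarray
    aa1: str
    aa2: str
    pb1: str
    pb2: str
    identity: float
    resolution: float | None = None
    structure1: object | None = None
    structure2: object | None = None
    rsa1: np.ndarray | None = None
    rsa2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, float)
        if len(self.columns) != self.distances.shape[0]:
            raise ValueError("one distance per alignment column required")
        for i, j in self.columns:
            if i < 0 and j < 0:
                raise ValueError("alignment column with gaps on both sides")

    @property
    def pair_id(self) -> str:
        return f"{self.id1}|{self.id2}"

    def gapped(self, which: str = "pb") -> tuple[str, str]:
        """Gapped sequence pair ('pb' or 'aa') spelled from the columns."""
        s1, s2 = (self.pb1, self.pb2) if which == "pb" else (self.aa1, self.aa2)
        g1 = "".join(s1[i] if i >= 0 else "-" for i, _ in self.columns)
        g2 = "".join(s2[j] if j >= 0 else "-" for _, j in self.columns)
        return g1, g2


# ---------------------------------------------------------------------------
# Dataset filtering
# ---------------------------------------------------------------------------

def filter_dataset(
    pairs: list[DomainPairAlignment],
    max_identity: float = IDENTITY_CUTOFF_MATRIX,
    min_resolution: float | None = None,
) -> list[DomainPairAlignment]:
    """Keep pairs with identity strictly below ``max_identity`` (%) and, when
    requested, resolution strictly better (smaller) than ``min_resolution``."""
    kept = []
    warned = False
    for p in pairs:
        if p.identity >= max_identity:
            continue
        if min_resolution is not None:
            if p.resolution is None:
                if not warned:
                    logger.warning("pairs without resolution metadata pass the filter")
                    warned = True
            elif p.resolution >= min_resolution:
                continue
        kept.append(p)
    return kept


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

@dataclass
class SubstitutionCounts:
    """Raw (possibly family-normalized) substitution frequencies."""

    labels: list[str]
    counts: np.ndarray
    per_family: dict[str, tuple[np.ndarray, int]] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def _label_index(labels: list[str]) -> dict[str, int]:
    return {lab: k for k, lab in enumerate(labels)}


def count_substitutions(
    pairs: list[DomainPairAlignment],
    distance_cutoff: float = CONSERVED_DISTANCE_DEFAULT,
    labels: list[str] | None = None,
    symbol_of=None,
) -> SubstitutionCounts:
    """Tally PB pairs in conserved aligned columns, accumulated per family.

    A column counts iff both sides are non-gap, neither symbol is 'Z', and
    the C-alpha distance is <= ``distance_cutoff``.  ``symbol_of`` may remap
    (pair, side, residue_index) -> label to support stratified alphabets; by
    default the PB symbol itself is used.
    """
    labels = labels or list(PB_LABELS)
    idx = _label_index(labels)
    m = len(labels)
    per_family: dict[str, tuple[np.ndarray, int]] = {}
    for p in pairs:
        if np.isnan(p.distances[[i >= 0 and j >= 0 for i, j in p.columns]]).any():
            raise ValueError(f"pair {p.pair_id} lacks distances for aligned columns")
        mat = np.zeros((m, m))
        for col, (i, j) in enumerate(p.columns):
            if i < 0 or j < 0:
                continue
            if p.distances[col] > distance_cutoff:
                continue
            if symbol_of is None:
                a, b = p.pb1[i], p.pb2[j]
            else:
                a, b = symbol_of(p, 0, i), symbol_of(p, 1, j)
            if a is None or b is None or UNASSIGNED in (a, b):
                continue
            if a in idx and b in idx:
                mat[idx[a], idx[b]] += 1
        fam_mat, fam_n = per_family.get(p.family, (np.zeros((m, m)), 0))
        per_family[p.family] = (fam_mat + mat, fam_n + 1)
    pooled = sum((mat for mat, _ in per_family.values()), np.zeros((m, m)))
    return SubstitutionCounts(labels=labels, counts=pooled, per_family=per_family)


def normalize_by_family(c: SubstitutionCounts) -> SubstitutionCounts:
    """Divide each family's counts by its pair count, then pool.

    Every family then contributes with equal per-pair weight, removing the
    bias from unbalanced family sizes.
    """
    if not c.per_family:
        raise ValueError("no families to normalize")
    m = len(c.labels)
    pooled = np.zeros((m, m))
    norm_fams: dict[str, tuple[np.ndarray, int]] = {}
    for fam, (mat, n_pairs) in c.per_family.items():
        if n_pairs == 0:
            logger.warning("family %s has no pairs; skipped", fam)
            continue
        pooled += mat / n_pairs
        norm_fams[fam] = (mat / n_pairs, n_pairs)
    return SubstitutionCounts(labels=c.labels, counts=pooled, per_family=norm_fams)


# ---------------------------------------------------------------------------
# Log-odds
# ---------------------------------------------------------------------------

@dataclass
class SubstitutionMatrix:
    """Symmetric log-odds substitution scores with provenance metadata."""

    labels: list[str]
    scores: np.ndarray
    scop_class: str = "global"
    stratum: str = "all"
    pseudocount: float = PSEUDOCOUNT_DEFAULT
    normalization: str = "family"
    source: str = ""
    id: str = ""

    def row(self, label: str) -> np.ndarray:
        return self.scores[self.labels.index(label)]


def log_odds(
    c: SubstitutionCounts,
    pseudocount: float = PSEUDOCOUNT_DEFAULT,
    base: float = 2.0,
    scale: float = 1.0,
    **meta,
) -> SubstitutionMatrix:
    """Symmetrized log-odds scores from raw substitution frequencies.

    Counts are symmetrized (N'_ij = N_ij + N_ji off-diagonal, N'_ii = 2 N_ii)
    and a pseudocount is added to every cell.  With q the ordered-pair
    frequencies (q = N'/sum N') and p_i = sum_j q_ij the marginals,

        S_ij = scale * log_base( q_ij / (p_i p_j) ).

    This is the standard symmetric observed-over-expected weight (equivalent
    to the unordered-pair convention with its factor-2 off-diagonal expected
    frequency); a uniform count table yields all-zero scores and diagonal
    concentration yields positive diagonal scores.
    """
    counts = np.asarray(c.counts, float)
    if (counts < 0).any():
        raise ValueError("negative substitution counts")
    if len(c.labels) < 2:
        raise ValueError("need an alphabet of at least 2 symbols")
    sym = counts + counts.T
    sym = sym + float(pseudocount)
    q = sym / sym.sum()
    p = q.sum(axis=1)
    scores = scale * (np.log(q / np.outer(p, p)) / np.log(base))
    return SubstitutionMatrix(
        labels=list(c.labels),
        scores=scores,
        pseudocount=float(pseudocount),
        **meta,
    )


def class_matrices(
    pairs: list[DomainPairAlignment],
    distance_cutoff: float = CONSERVED_DISTANCE_DEFAULT,
    pseudocount: float = PSEUDOCOUNT_DEFAULT,
) -> dict[str, SubstitutionMatrix]:
    """One substitution matrix per SCOP class present in the dataset.

    Each class runs the same count -> family-normalize -> log-odds pipeline
    on its own pairs only.
    """
    out: dict[str, SubstitutionMatrix] = {}
    for cls in sorted({p.scop_class for p in pairs}):
        subset = [p for p in pairs if p.scop_class == cls]
        counts = count_substitutions(subset, distance_cutoff)
        if counts.total == 0:
            logger.warning("class %s has no conserved columns; scores are pure pseudocount", cls)
        normed = normalize_by_family(counts)
        out[cls] = log_odds(normed, pseudocount, scop_class=cls, id=cls)
    return out


def build_matrix(
    pairs: list[DomainPairAlignment],
    distance_cutoff: float = CONSERVED_DISTANCE_DEFAULT,
    pseudocount: float = PSEUDOCOUNT_DEFAULT,
    **meta,
) -> SubstitutionMatrix:
    """Global count -> family-normalize -> log-odds pipeline."""
    counts = count_substitutions(pairs, distance_cutoff)
    return log_odds(normalize_by_family(counts), pseudocount, **meta)


# ---------------------------------------------------------------------------
# Matrix comparison
# ---------------------------------------------------------------------------

def compare_rows(
    a: SubstitutionMatrix, b: SubstitutionMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson correlations and the elementwise difference a - b.

    Correlations include all 16 row entries (the diagonal is not excluded);
    a constant row yields NaN, reported rather than raised.
    """
    if a.labels != b.labels:
        raise ValueError("matrices must share shape and label order")
    diff = a.scores - b.scores
    corr = np.full(len(a.labels), np.nan)
    for k in range(len(a.labels)):
        ra, rb = a.scores[k], b.scores[k]
        if np.ptp(ra) == 0 or np.ptp(rb) == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            corr[k] = pearsonr(ra, rb)[0]
    return corr, diff


def outlier_substitutions(row_differences: np.ndarray) -> np.ndarray:
    """Boolean mask of 1.5*IQR outliers among one row of |score differences|.

    Quartiles use linear interpolation (type-7).  When the IQR is zero the
    rule degenerates to flagging any value different from the median.
    """
    vals = np.asarray(row_differences, float)
    q1, q3 = np.percentile(vals, [25, 75])
    iqr = q3 - q1
    if iqr == 0:
        return vals != np.median(vals)
    return (vals < q1 - 1.5 * iqr) | (vals > q3 + 1.5 * iqr)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

@dataclass
class PBDendrogram:
    """Agglomerative merge tree over the PB labels."""

    labels: list[str]
    linkage: np.ndarray  # scipy linkage matrix, (n-1, 4)

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def fmt(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            return f"({fmt(node.left)},{fmt(node.right)}):{node.dist:.6g}"

        inner = fmt(tree)
        return inner + ";"

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def correlation_distance_matrix(m: SubstitutionMatrix) -> np.ndarray:
    """d(i, j) = 1 - Pearson r(row_i, row_j); errors on constant rows."""
    scores = np.asarray(m.scores, float)
    for k, lab in enumerate(m.labels):
        if np.ptp(scores[k]) == 0:
            raise ValueError(f"substitution row for PB {lab!r} is constant")
    r = np.corrcoef(scores)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return np.maximum(d, 0.0)


def cluster_pbs(m: SubstitutionMatrix, method: str = "complete") -> PBDendrogram:
    """Hierarchical clustering of PBs on correlation distance.

    Complete linkage by default.  scipy's deterministic ordering provides
    label-order tie-breaking.
    """
    d = correlation_distance_matrix(m)
    link = hierarchy.linkage(squareform(d, checks=False), method=method)
    return PBDendrogram(labels=list(m.labels), linkage=link)
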