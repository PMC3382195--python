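"""PB-sequence alignment and rigid-body superposition.

Two backbones are compared by encoding each as a PB string, aligning the
strings with Smith-Waterman local dynamic programming under a PB substitution
matrix and a linear gap penalty (default -5.0 per gap position), and then
performing a least-squares rigid fit (Kabsch) of the C-alpha atoms of the
aligned residue pairs.  The fit rmsd is the figure of merit used to compare
substitution matrices against each other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .pb_core import UNASSIGNED, BackboneStructure

logger = logging.getLogger(__name__)

GAP_PENALTY_DEFAULT: float = -5.0
#: |delta rmsd| at or below which two alignments count as "same" in benchmarks
TIE_TOLERANCE_DEFAULT: float = 0.01


@dataclass
class PBAlignment:
    """A local alignment of two PB strings."""

    gapped1: str
    gapped2: str
    pairs: list[tuple[int, int]]  # aligned residue index pairs (0-based)
    score: float
    gap_penalty: float
    matrix_id: str = ""

    def recomputed_score(self, score_of) -> float:
        """Score re-derived from the gapped strings (symbol pairs + gaps)."""
        total = 0.0
        for a, b in zip(self.gapped1, self.gapped2):
            if a == "-" or b == "-":
                total += self.gap_penalty
            else:
                total += score_of(a, b)
        return total


def _score_lookup(matrix) -> tuple[dict[str, int], np.ndarray]:
    """Map a SubstitutionMatrix (or (labels, scores)) to an indexed table.

    The placeholder 'Z' scores 0 against everything.
    """
    labels = list(matrix.labels)
    scores = np.asarray(matrix.scores, float)
    if UNASSIGNED not in labels:
        m = len(labels)
        ext = np.zeros((m + 1, m + 1))
        ext[:m, :m] = scores
        scores = ext
        labels = labels + [UNASSIGNED]
    index = {lab: i for i, lab in enumerate(labels)}
    return index, scores


def align_pb_sequences(
    s1: str,
    s2: str,
    matrix,
    gap_penalty: float = GAP_PENALTY_DEFAULT,
) -> PBAlignment:
    """Optimal Smith-Waterman local alignment of two PB strings.

    Linear gap model (``gap_penalty`` per gap position).  The traceback is
    deterministic: on ties it prefers diagonal over up (gap in ``s2``) over
    left (gap in ``s1``), and ends at the first (lowest i, then j) maximal
    cell.  'Z' symbols score 0 against everything.
    """
    if not s1 or not s2:
        raise ValueError("cannot align empty PB sequences")
    index, table = _score_lookup(matrix)
    try:
        a = np.array([index[ch] for ch in s1])
        b = np.array([index[ch] for ch in s2])
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"symbol {exc} not covered by the substitution matrix") from exc

    n, m = len(s1), len(s2)
    H = np.zeros((n + 1, m + 1))
    g = float(gap_penalty)
    jdx = np.arange(m)
    for i in range(1, n + 1):
        sub = table[a[i - 1], b]
        cand = np.maximum(H[i - 1, :-1] + sub, H[i - 1, 1:] + g)
        cand = np.maximum(cand, 0.0)
        # fold in the within-row (left) dependency:
        # H[i,j] = max(cand_j, max_{k<j} cand_k + g*(j-k))
        run = np.maximum.accumulate(cand - g * jdx) + g * jdx
        H[i, 1:] = np.maximum(cand, run)

    best = float(H.max())
    if best <= 0.0:
        return PBAlignment("", "", [], 0.0, g, getattr(matrix, "id", ""))
    end_i, end_j = np.unravel_index(int(np.argmax(H)), H.shape)

    # traceback, tie order: diagonal > up > left
    i, j = int(end_i), int(end_j)
    g1: list[str] = []
    g2: list[str] = []
    pairs: list[tuple[int, int]] = []
    eps = 1e-9
    while i > 0 and j > 0 and H[i, j] > eps:
        h = H[i, j]
        if abs(h - (H[i - 1, j - 1] + table[a[i - 1], b[j - 1]])) <= eps:
            g1.append(s1[i - 1])
            g2.append(s2[j - 1])
            pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif abs(h - (H[i - 1, j] + g)) <= eps:
            g1.append(s1[i - 1])
            g2.append("-")
            i -= 1
        else:
            g1.append("-")
            g2.append(s2[j - 1])
            j -= 1
    pairs.reverse()
    return PBAlignment(
        gapped1="".join(reversed(g1)),
        gapped2="".join(reversed(g2)),
        pairs=pairs,
        score=best,
        gap_penalty=g,
        matrix_id=getattr(matrix, "id", ""),
    )


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

@dataclass
class SuperpositionResult:
    """Optimal rigid transform of structure 2 onto structure 1."""

    rotation: np.ndarray  # (3, 3), proper
    translation: np.ndarray  # (3,)
    rmsd: float
    n_fitted: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


def kabsch_fit(x_ref: np.ndarray, x_mov: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid fit of ``x_mov`` onto ``x_ref`` (paired points).

    Uses the SVD-based Kabsch solution (proper rotation; reflections are
    excluded).  Requires at least 3 point pairs.
    """
    x_ref = np.asarray(x_ref, float)
    x_mov = np.asarray(x_mov, float)
    if x_ref.shape != x_mov.shape or x_ref.ndim != 2 or x_ref.shape[1] != 3:
        raise ValueError("expected matching (n, 3) coordinate arrays")
    n = x_ref.shape[0]
    if n < 3:
        raise ValueError("rigid fit requires at least 3 aligned pairs")
    c_ref = x_ref.mean(axis=0)
    c_mov = x_mov.mean(axis=0)
    rot, rssd = Rotation.align_vectors(x_ref - c_ref, x_mov - c_mov)
    R = rot.as_matrix()
    t = c_ref - R @ c_mov
    rmsd = float(rssd) / np.sqrt(n)
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_fitted=n)


def superpose(
    s1: BackboneStructure, s2: BackboneStructure, a: PBAlignment
) -> SuperpositionResult:
    """Kabsch fit of the aligned C-alpha pairs of two structures."""
    if len(a.pairs) < 3:
        raise ValueError("superposition requires at least 3 aligned pairs")
    idx1 = [i for i, _ in a.pairs]
    idx2 = [j for _, j in a.pairs]
    return kabsch_fit(s1.ca[idx1], s2.ca[idx2])


# ---------------------------------------------------------------------------
# Matrix benchmarking
# ---------------------------------------------------------------------------

def benchmark_matrices(
    test_pairs,
    candidate,
    reference,
    gap_penalty: float = GAP_PENALTY_DEFAULT,
    tie_tolerance: float = TIE_TOLERANCE_DEFAULT,
) -> dict[str, float]:
    """Compare two substitution matrices by alignment-then-fit rmsd.

    ``test_pairs`` iterates over objects carrying ``structure1``,
    ``structure2``, ``pb1`` and ``pb2`` (e.g. synthetic DomainPairAlignment
    records).  For each pair both matrices produce an alignment and a fit;
    the pair is classified better/same/worse for the candidate by comparing
    rmsds with ``tie_tolerance``.  Returns percentages summing to 100, plus
    the number of pairs evaluated under ``"n"``.
    """
    better = same = worse = 0
    skipped = 0
    for pair in test_pairs:
        try:
            r_cand = _rmsd_under(pair, candidate, gap_penalty)
            r_ref = _rmsd_under(pair, reference, gap_penalty)
        except ValueError as exc:
            logger.warning("benchmark pair skipped: %s", exc)
            skipped += 1
            continue
        delta = r_cand - r_ref
        if abs(delta) <= tie_tolerance:
            same += 1
        elif delta < 0:
            better += 1
        else:
            worse += 1
    n = better + same + worse
    if n == 0:
        raise ValueError("no benchmark pair could be aligned under both matrices")
    return {
        "better": 100.0 * better / n,
        "same": 100.0 * same / n,
        "worse": 100.0 * worse / n,
        "n": n,
        "skipped": skipped,
    }


def _rmsd_under(pair, matrix, gap_penalty: float) -> float:
    aln = align_pb_sequences(pair.pb1, pair.pb2, matrix, gap_penalty)
    fit = superpose(pair.structure1, pair.structure2, aln)
    return fit.rmsd
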