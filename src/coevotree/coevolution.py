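"""Co-evolution scoring: mirrortree, profile-correlation and context-mirror.

The three scorers quantify the similarity of evolutionary histories of
protein-family pairs from their inter-ortholog distance matrices.

mirrortree (MT)
    Pearson correlation between the two families' pairwise-distance
    vectors, restricted to organisms present in both families and taken
    over the upper triangle in canonical organism-pair order.  A minimum
    number of common organisms (default 15) is required, and only
    correlations whose P-value passes a cutoff (default 1e-5) count as
    significant.  The P-value uses the two-sided t approximation for a
    Pearson coefficient, treating the distance pairs as independent
    observations — the classic convention of the method, kept here even
    though pairs sharing a leaf are not truly independent.

profile-correlation (PC)
    A protein's co-evolutionary profile is its row in the genome-wide
    matrix of significant MT correlations.  PC re-scores a pair as the
    Pearson correlation between the two profiles over positions where both
    are available (pairwise-complete; a zero-fill compatibility mode
    treats unavailable entries as 0 instead).  Profiles implicitly encode
    the co-evolutionary context and buffer artifacts such as phylogenetic
    redundancy that inflate raw tree correlations.

context-mirror (CM)
    Partial-correlation re-scoring that removes the influence of third
    proteins.  For a pair (A, B), candidate controller proteins are ranked
    by |r_AC * r_BC| and the top ``level`` controllers are partialled out
    via inversion of the corresponding correlation submatrix, separating
    co-evolution specific to the pair from genome-wide trends.  Higher
    levels demand a denser network of significant correlations, which is
    why CM coverage collapses when few organisms are available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .phylo import DistanceMatrix

__all__ = [
    "CoevolutionScore",
    "ScoreMatrix",
    "common_organisms",
    "mirrortree_score",
    "build_score_matrix",
    "profile_correlation",
    "partial_correlation",
    "context_mirror",
    "scored_pairs_from_matrix",
    "scored_pairs_from_table",
]

DEFAULT_MIN_COMMON = 15
DEFAULT_P_MAX = 1e-5
DEFAULT_MIN_JOINT = 3


@dataclass(frozen=True)
class CoevolutionScore:
    """One pair's correlation with its support and significance call."""

    r: float
    n_common: int
    n_pairs: int
    p_value: float
    significant: bool
    evaluable: bool
    reason: str = ""


def _not_evaluable(n_common: int, reason: str) -> CoevolutionScore:
    n_pairs = n_common * (n_common - 1) // 2
    return CoevolutionScore(
        r=float("nan"),
        n_common=n_common,
        n_pairs=n_pairs,
        p_value=1.0,
        significant=False,
        evaluable=False,
        reason=reason,
    )


def pearson_pvalue(r: float, n: int) -> float:
    """Two-sided P-value for a Pearson coefficient on ``n`` observations
    (t statistic with n - 2 degrees of freedom)."""
    df = n - 2
    if df <= 0:
        return 1.0
    if 1.0 - r * r <= 0.0:
        return 0.0
    t = abs(r) * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * stats.t.sf(t, df))


def common_organisms(dmA: DistanceMatrix, dmB: DistanceMatrix) -> list[str]:
    """Sorted list of organisms present in both distance matrices."""
    return sorted(set(dmA.labels) & set(dmB.labels))


def mirrortree_score(
    dmA: DistanceMatrix,
    dmB: DistanceMatrix,
    min_common: int = DEFAULT_MIN_COMMON,
    p_max: float = DEFAULT_P_MAX,
) -> CoevolutionScore:
    """Mirrortree correlation between two families' distance matrices.

    The two vectors are the upper triangles (canonical organism-pair
    order) of both matrices restricted to the common organisms.  Pairs
    with fewer than ``min_common`` shared organisms are not evaluable;
    zero variance in either vector yields a masked (not evaluable) score
    rather than an exception.
    """
    if dmA.labels == dmB.labels:
        m = dmA.n
        if m < min_common:
            return _not_evaluable(m, "fewer common organisms than min_common")
        x = dmA.condensed()
        y = dmB.condensed()
    else:
        common = common_organisms(dmA, dmB)
        m = len(common)
        if m < min_common:
            return _not_evaluable(m, "fewer common organisms than min_common")
        x = dmA.restrict(common).condensed()
        y = dmB.restrict(common).condensed()
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return _not_evaluable(m, "zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    n_pairs = len(x)
    p = pearson_pvalue(r, n_pairs)
    return CoevolutionScore(
        r=r,
        n_common=m,
        n_pairs=n_pairs,
        p_value=p,
        significant=p <= p_max,
        evaluable=True,
    )


class ScoreMatrix:
    """Genome-wide matrix of significant tree correlations.

    ``r[i, j]`` holds the MT correlation of proteins i and j where
    ``available[i, j]`` is True (evaluable and significant); the diagonal
    is masked.  Rows are co-evolutionary profiles.
    """

    def __init__(self, proteins, r: np.ndarray, available: np.ndarray):
        self.proteins = tuple(proteins)
        self.index = {p: i for i, p in enumerate(self.proteins)}
        r = np.asarray(r, dtype=float)
        available = np.asarray(available, dtype=bool)
        n = len(self.proteins)
        if r.shape != (n, n) or available.shape != (n, n):
            raise ValueError("score matrix shape mismatch")
        if not np.array_equal(available, available.T):
            raise ValueError("availability mask must be symmetric")
        r = np.where(available, 0.5 * (r + r.T), np.nan)
        np.fill_diagonal(available, False)
        np.fill_diagonal(r, np.nan)
        self.r = r
        self.available = available

    @property
    def n(self) -> int:
        return len(self.proteins)

    def profile(self, protein: str) -> tuple[np.ndarray, np.ndarray]:
        """(correlations, availability) row for ``protein``."""
        i = self.index[protein]
        return self.r[i], self.available[i]

    def get(self, a: str, b: str) -> float | None:
        i, j = self.index[a], self.index[b]
        return float(self.r[i, j]) if self.available[i, j] else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.proteins, columns=self.proteins)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.6f", na_rep="NA")


def build_score_matrix(
    family_matrices: Mapping[str, DistanceMatrix],
    min_common: int = DEFAULT_MIN_COMMON,
    p_max: float = DEFAULT_P_MAX,
) -> ScoreMatrix:
    """Score all unordered family pairs with MT and keep significant entries.

    ``evaluable_pairs`` / ``significant_pairs`` counters are exposed as
    attributes of the returned matrix for coverage bookkeeping.
    """
    proteins = sorted(family_matrices)
    if len(proteins) < 2:
        raise ValueError("need at least 2 families")
    n = len(proteins)
    r = np.full((n, n), np.nan)
    avail = np.zeros((n, n), dtype=bool)
    evaluable = 0
    for i in range(n):
        for j in range(i + 1, n):
            sc = mirrortree_score(
                family_matrices[proteins[i]],
                family_matrices[proteins[j]],
                min_common=min_common,
                p_max=p_max,
            )
            if sc.evaluable:
                evaluable += 1
            if sc.significant:
                r[i, j] = r[j, i] = sc.r
                avail[i, j] = avail[j, i] = True
    sm = ScoreMatrix(proteins, np.nan_to_num(r), avail)
    sm.evaluable_pairs = evaluable
    sm.significant_pairs = int(avail.sum() // 2)
    return sm


def profile_correlation(
    score_matrix: ScoreMatrix,
    a: str,
    b: str,
    min_joint: int = DEFAULT_MIN_JOINT,
    zero_fill: bool = False,
) -> CoevolutionScore:
    """Correlation between the co-evolutionary profiles of ``a`` and ``b``.

    Profile positions corresponding to ``a`` and ``b`` themselves are
    excluded.  By default only positions available in *both* profiles are
    used (pairwise-complete); ``zero_fill=True`` instead treats
    unavailable entries as 0 over all other positions.  Fewer than
    ``min_joint`` joint positions yields a not-evaluable score.
    """
    if a == b:
        raise ValueError("profile correlation requires two distinct proteins")
    ra, aa = score_matrix.profile(a)
    rb, ab = score_matrix.profile(b)
    ia, ib = score_matrix.index[a], score_matrix.index[b]
    others = np.ones(score_matrix.n, dtype=bool)
    others[[ia, ib]] = False
    if zero_fill:
        joint = others
        x = np.where(aa, np.nan_to_num(ra), 0.0)[joint]
        y = np.where(ab, np.nan_to_num(rb), 0.0)[joint]
    else:
        joint = others & aa & ab
        x = ra[joint]
        y = rb[joint]
    m = int(joint.sum())
    if m < min_joint:
        return _not_evaluable(m, "fewer joint profile positions than min_joint")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return _not_evaluable(m, "zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    p = pearson_pvalue(r, m)
    return CoevolutionScore(
        r=r, n_common=m, n_pairs=m, p_value=p, significant=p <= DEFAULT_P_MAX,
        evaluable=True,
    )


def partial_correlation(r_ab: float, r_ac: float, r_bc: float) -> float:
    """First-order partial correlation of A and B controlling for C.

    Returns ``(r_ab - r_ac * r_bc) / sqrt((1 - r_ac^2)(1 - r_bc^2))``;
    NaN when the denominator vanishes (|r_ac| or |r_bc| = 1).
    """
    for v in (r_ab, r_ac, r_bc):
        if not -1.0 <= v <= 1.0:
            raise ValueError("correlations must lie in [-1, 1]")
    denom = (1.0 - r_ac * r_ac) * (1.0 - r_bc * r_bc)
    if denom <= 0.0:
        return float("nan")
    return (r_ab - r_ac * r_bc) / np.sqrt(denom)


def _partial_from_submatrix(M: np.ndarray) -> float | None:
    """Partial correlation of variables 0 and 1 given the rest, via the
    precision matrix; None if the submatrix is (near-)singular."""
    if not np.isfinite(M).all():
        return None
    if np.linalg.cond(M) > 1e12:
        return None
    P = np.linalg.inv(M)
    denom = P[0, 0] * P[1, 1]
    if denom <= 0:
        return None
    return float(-P[0, 1] / np.sqrt(denom))


def context_mirror(score_matrix: ScoreMatrix, level: int) -> pd.DataFrame:
    """Context-mirror scores at a given specificity level.

    For every pair (A, B) with an available correlation, the candidate
    controllers are proteins C with available r_AC and r_BC, ranked by
    |r_AC * r_BC| (descending; ties broken lexicographically).  The top
    ``min(level, available)`` controllers are partialled out through
    inversion of the (k+2) x (k+2) correlation submatrix; unavailable
    controller-controller entries are taken as 0.  Singular submatrices
    fall back to the largest non-singular leading controller subset.
    Pairs with no controllers degrade to the raw correlation and are
    flagged.

    Returns a DataFrame with columns ``protein_a, protein_b, r, order,
    flagged`` where ``order`` is the number of controllers actually used.
    """
    if level < 1:
        raise ValueError("level must be >= 1")
    prots = score_matrix.proteins
    R = np.nan_to_num(score_matrix.r)
    A = score_matrix.available
    rows = []
    n = score_matrix.n
    for i in range(n):
        for j in range(i + 1, n):
            if not A[i, j]:
                continue
            cand = np.flatnonzero(A[i] & A[j])
            cand = cand[(cand != i) & (cand != j)]
            if cand.size == 0:
                rows.append((prots[i], prots[j], float(R[i, j]), 0, True))
                continue
            strength = np.abs(R[i, cand] * R[j, cand])
            order_idx = sorted(
                range(cand.size), key=lambda k: (-strength[k], prots[cand[k]])
            )
            S = [int(cand[k]) for k in order_idx[: min(level, cand.size)]]
            score, used = None, 0
            while S:
                sel = [i, j] + S
                M = R[np.ix_(sel, sel)].copy()
                np.fill_diagonal(M, 1.0)
                score = _partial_from_submatrix(M)
                if score is not None:
                    used = len(S)
                    break
                S = S[:-1]
            if score is None:
                rows.append((prots[i], prots[j], float(R[i, j]), 0, True))
            else:
                score = float(np.clip(score, -1.0, 1.0))
                rows.append((prots[i], prots[j], score, used, False))
    return pd.DataFrame(
        rows, columns=["protein_a", "protein_b", "r", "order", "flagged"]
    )


# ---------------------------------------------------------------------------
# helpers for evaluation
# ---------------------------------------------------------------------------

def scored_pairs_from_matrix(score_matrix: ScoreMatrix) -> dict[tuple[str, str], float]:
    """Significant MT pairs as a {pair: r} mapping."""
    out = {}
    n = score_matrix.n
    for i in range(n):
        for j in range(i + 1, n):
            if score_matrix.available[i, j]:
                out[(score_matrix.proteins[i], score_matrix.proteins[j])] = float(
                    score_matrix.r[i, j]
                )
    return out


def scored_pairs_from_table(table: pd.DataFrame) -> dict[tuple[str, str], float]:
    """A context-mirror table as a {pair: r} mapping."""
    out = {}
    for row in table.itertuples(index=False):
        a, b = sorted((row.protein_a, row.protein_b))
        out[(a, b)] = float(row.r)
    return out


def write_scores_tsv(
    scores: Mapping[tuple[str, str], CoevolutionScore] | pd.DataFrame, path, method: str, level: int = 0
) -> None:
    """Write pair scores as TSV (protein_a, protein_b, method, level, r,
    n_common, p_value, significant)."""
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\tmethod\tlevel\tr\tn_common\tp_value\tsignificant\n")
        if isinstance(scores, pd.DataFrame):
            for row in scores.itertuples(index=False):
                fh.write(
                    f"{row.protein_a}\t{row.protein_b}\t{method}\t{level}\t"
                    f"{row.r:.6f}\t\t\t\n"
                )
            return
        for (a, b), sc in sorted(scores.items()):
            fh.write(
                f"{a}\t{b}\t{method}\t{level}\t{sc.r:.6f}\t{sc.n_common}\t"
                f"{sc.p_value:.3e}\t{sc.significant}\n"
            )
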