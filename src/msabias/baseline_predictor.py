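"""Self-contained coevolution baseline: mutual information with APC.

Covarying alignment columns hint at spatial contact. The baseline scores
every query-column pair by the plug-in mutual information (bits) of the
two columns' joint amino-acid distribution, then subtracts the
average-product correction (APC) to remove the background coupling that
high-entropy columns show against everything:

    score(i, j) = MI(i, j) − MI̅(i, ·) · MI̅(·, j) / MI̅(·, ·)

where MI̅ are off-diagonal row/overall means. Like the heavyweight
predictors it stands in for, this score improves with alignment depth —
which is exactly the property the depth-bias experiments exercise.

Limitations (deliberate): pairwise-complete gap handling (rows gapped at
either column are dropped for that pair only), no sequence weighting,
no pseudocounts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cp_evaluation import PredictionList, canonical_order
from .msa_metrics import Alignment


class ShallowAlignmentError(ValueError):
    """Alignment too shallow or narrow for coevolution scoring."""


@dataclass(frozen=True)
class ScoreMatrix:
    """Symmetric pairwise score matrix over the query's residues."""

    L: int
    scores: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        s = self.scores
        if s.shape != (self.L, self.L):
            raise ValueError(f"score matrix shape {s.shape} != ({self.L}, {self.L})")
        if not np.all(np.isfinite(s)):
            raise ValueError("score matrix contains non-finite entries")
        if not np.allclose(s, s.T):
            raise ValueError("score matrix must be symmetric")


def mutual_information(aln: Alignment) -> ScoreMatrix:
    """Plug-in pairwise mutual information (bits) between query columns.

    For each column pair only rows canonical at both positions enter the
    joint distribution; marginals are recomputed on that same row subset
    so MI is a proper (non-negative) information."""
    qcols = aln.query_columns
    L = len(qcols)
    if len(aln.rows) < 2:
        raise ShallowAlignmentError("need at least 2 sequences")
    if L < 2:
        raise ShallowAlignmentError("need at least 2 query columns")
    mat = aln.to_matrix()[:, list(qcols)]  # rows × L, codes 0..19 or -1
    mi = np.zeros((L, L))
    for i in range(L):
        ci = mat[:, i]
        for j in range(i + 1, L):
            cj = mat[:, j]
            ok = (ci >= 0) & (cj >= 0)
            n = int(ok.sum())
            if n == 0:
                continue
            joint = np.bincount(
                (ci[ok].astype(np.int64) * 20 + cj[ok]), minlength=400
            ).reshape(20, 20) / n
            fi = joint.sum(axis=1)
            fj = joint.sum(axis=0)
            nz = joint > 0
            mi[i, j] = mi[j, i] = float(
                (joint[nz] * np.log2(joint[nz] / np.outer(fi, fj)[nz])).sum()
            )
    return ScoreMatrix(L=L, scores=mi)


def apc_correct(mi: ScoreMatrix) -> ScoreMatrix:
    """Average-product correction of a symmetric coupling matrix."""
    L = mi.L
    s = mi.scores
    off = ~np.eye(L, dtype=bool)
    row_mean = (s * off).sum(axis=1) / (L - 1)
    overall = (s * off).sum() / (L * (L - 1))
    if overall == 0:
        corrected = s.copy()
    else:
        corrected = s - np.outer(row_mean, row_mean) / overall
    np.fill_diagonal(corrected, 0.0)
    return ScoreMatrix(L=L, scores=corrected)


def mi_apc_scores(aln: Alignment) -> ScoreMatrix:
    """Mutual information with average-product correction."""
    return apc_correct(mutual_information(aln))


def predict_contacts(aln: Alignment, target_id: str | None = None) -> PredictionList:
    """Rank all upper-triangle MI+APC scores into a prediction list in the
    query residue frame (1-based positions among the query's residues)."""
    sm = mi_apc_scores(aln)
    entries = [
        (i + 1, j + 1, float(sm.scores[i, j]))
        for i in range(sm.L)
        for j in range(i + 1, sm.L)
    ]
    return PredictionList(
        target_id=target_id or aln.query_id,
        entries=tuple(canonical_order(entries)),
    )
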