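"""Scoring of ranked contact predictions against ground truth.

The headline statistic is top-L precision (PPV): keep predicted pairs
with sequence separation |i−j| ≥ 5 ("greater than 4 residues"), take the
L best-scored survivors (L = chain length), and report the fraction that
are real contacts. Dataset-level summaries report the median and the
25th/40th/60th/75th percentile band, plus the mean.

Ranking is made deterministic by the canonical tie-break: score
descending, then i ascending, then j ascending.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .contact_maps import ContactMap


@dataclass(frozen=True)
class PredictionList:
    """Ranked residue-pair predictions, 1-based, i < j, score descending."""

    target_id: str
    entries: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        seen = set()
        for i, j, _ in self.entries:
            if not i < j:
                raise ValueError(f"pair ({i}, {j}) must have i < j")
            if (i, j) in seen:
                raise ValueError(f"duplicate pair ({i}, {j})")
            seen.add((i, j))
        if list(self.entries) != canonical_order(self.entries):
            raise ValueError("entries not in canonical order (score desc, i, j)")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class EvalResult:
    """Top-K precision of one prediction list against one contact map."""

    target_id: str
    L: int
    n_considered: int
    n_correct: int
    ppv: float
    min_separation: int


@dataclass(frozen=True)
class PerformanceSummary:
    n: int
    mean: float
    median: float
    p25: float
    p40: float
    p60: float
    p75: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def canonical_order(
    entries: Sequence[tuple[int, int, float]],
) -> list[tuple[int, int, float]]:
    """Sort by score descending, ties broken by (i, j) ascending."""
    return sorted(entries, key=lambda e: (-e[2], e[0], e[1]))


# ---------------------------------------------------------------------------
# readers


def read_predictions(
    path: str | Path,
    format: str = "rr",
    L: int | None = None,
    target_id: str | None = None,
) -> PredictionList:
    """Read predictions from CASP RR lines (``i j d1 d2 prob``) or from a
    whitespace-separated L×L score matrix (upper triangle used)."""
    path = Path(path)
    fmt = format.lower()
    if fmt == "rr":
        entries = _read_rr(path)
    elif fmt == "matrix":
        entries = _read_matrix(path, L)
    else:
        raise ValueError(f"unknown prediction format {format!r}")
    if L is not None:
        for i, j, _ in entries:
            if j > L:
                raise ValueError(f"pair ({i}, {j}) exceeds L={L}")
    return PredictionList(
        target_id=target_id or path.stem, entries=tuple(canonical_order(entries))
    )


def _read_rr(path: Path) -> list[tuple[int, int, float]]:
    entries: list[tuple[int, int, float]] = []
    seen: set[tuple[int, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.upper().startswith(
                ("PFRMAT", "TARGET", "AUTHOR", "METHOD", "MODEL", "REMARK", "END")
            ):
                continue
            fields = line.split()
            # sequence line of the RR header (letters only)
            if len(fields) == 1 and fields[0].isalpha():
                continue
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: malformed RR line {line!r}")
            i, j = int(fields[0]), int(fields[1])
            prob = float(fields[4])
            i, j = min(i, j), max(i, j)
            if i == j:
                raise ValueError(f"{path}:{lineno}: self-pair ({i}, {j})")
            if (i, j) in seen:
                raise ValueError(f"{path}:{lineno}: duplicate pair ({i}, {j})")
            seen.add((i, j))
            entries.append((i, j, prob))
    if not entries:
        raise ValueError(f"{path}: no prediction lines")
    return entries


def _read_matrix(path: Path, L: int | None) -> list[tuple[int, int, float]]:
    mat = np.loadtxt(path)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{path}: score matrix must be square, got {mat.shape}")
    if L is not None and mat.shape[0] != L:
        raise ValueError(f"{path}: matrix is {mat.shape[0]}×{mat.shape[0]}, L={L}")
    n = mat.shape[0]
    return [
        (i + 1, j + 1, float(mat[i, j])) for i in range(n) for j in range(i + 1, n)
    ]


def write_rr(preds: PredictionList, path: str | Path, sequence: str | None = None) -> None:
    """Write predictions in CASP RR format (d1=0, d2=8)."""
    with open(path, "w") as fh:
        fh.write("PFRMAT RR\n")
        fh.write(f"TARGET {preds.target_id}\n")
        fh.write("MODEL 1\n")
        if sequence:
            fh.write(sequence + "\n")
        for i, j, score in preds.entries:
            fh.write(f"{i} {j} 0 8 {score:.6f}\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# scoring


def top_l_precision(
    preds: PredictionList,
    truth: ContactMap,
    fraction: float = 1.0,
    min_separation: int = 5,
) -> EvalResult:
    """Precision of the best ``floor(fraction × L)`` predicted pairs after
    discarding pairs with |i − j| < min_separation.

    If the filtered list is shorter than the budget, the denominator is the
    number of pairs actually taken (``n_considered``) and a warning is
    raised: the statistic then measures precision over a short list rather
    than silently penalising the predictor.
    """
    if fraction <= 0:
        raise ValueError("fraction must be positive")
    L = truth.length
    kept = [
        (i, j) for i, j, _ in preds.entries if abs(i - j) >= min_separation
    ]
    if not kept:
        raise ValueError("no predictions survive the separation filter")
    budget = math.floor(fraction * L)
    taken = kept[:budget]
    if len(taken) < budget:
        warnings.warn(
            f"{preds.target_id}: only {len(taken)} predictions available for a "
            f"top-{budget} evaluation; PPV denominator is {len(taken)}",
            stacklevel=2,
        )
    n_correct = sum(1 for p in taken if p in truth)
    return EvalResult(
        target_id=preds.target_id,
        L=L,
        n_considered=len(taken),
        n_correct=n_correct,
        ppv=n_correct / len(taken),
        min_separation=min_separation,
    )


def summarize_performance(
    results: Sequence[EvalResult] | Sequence[float],
) -> PerformanceSummary:
    """Median, quartile/central-quintile band and mean of a set of PPVs.

    Percentiles use linear interpolation, matching the usual box/band plot
    convention.
    """
    if len(results) == 0:
        raise ValueError("no results to summarise")
    values = np.array(
        [r.ppv if isinstance(r, EvalResult) else float(r) for r in results]
    )
    p25, p40, p50, p60, p75 = np.percentile(values, [25, 40, 50, 60, 75])
    return PerformanceSummary(
        n=len(values),
        mean=float(values.mean()),
        median=float(p50),
        p25=float(p25),
        p40=float(p40),
        p60=float(p60),
        p75=float(p75),
    )
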