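"""Multiple sequence alignment parsing and information-content metrics.

An MSA's evolutionary information is summarised by three quantities that
track how much a homology search found for a query protein:

* the **homolog count** (alignment depth minus the query itself),
* **NEFF**, the mean over alignment columns of the number of *distinct*
  canonical amino-acid types observed in that column (1 when all rows are
  identical, 20 when every column shows complete variability), and
* the **mean per-residue Shannon entropy** (bits) of the column
  distributions aligned to the query's residues.

Gaps and ambiguity codes (X, B, Z, U, O, J) never count as amino-acid
types and are excluded from frequency distributions: the 1-20 NEFF range
only holds over the canonical alphabet.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO, SeqIO

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_AA)
AMBIGUOUS_AA = frozenset("XBZUOJ")
GAP_CHARS = frozenset("-.")
MAX_ENTROPY_BITS = float(np.log2(20.0))

#: letter -> integer code; canonical residues 0..19, everything else -1
AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}


class AlignmentError(ValueError):
    """Raised when an alignment file violates the MSA invariants."""


@dataclass(frozen=True)
class Alignment:
    """An MSA in the query's column frame.

    Row 0 is the query. All rows have identical length; letters are
    uppercase canonical amino acids, ambiguity codes, or ``-``.
    """

    query_id: str
    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentError("empty alignment")
        ncol = len(self.rows[0])
        if ncol == 0:
            raise AlignmentError("alignment has zero columns")
        for rid, row in zip(self.ids, self.rows):
            if len(row) != ncol:
                raise AlignmentError(
                    f"ragged alignment: row {rid!r} has length {len(row)}, "
                    f"expected {ncol}"
                )
            bad = set(row) - _CANONICAL_SET - AMBIGUOUS_AA - {"-"}
            if bad:
                raise AlignmentError(
                    f"row {rid!r} contains invalid letters {sorted(bad)!r}"
                )
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids/rows length mismatch")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def homolog_count(self) -> int:
        """Number of non-query rows (the alignment depth)."""
        return len(self.rows) - 1

    @property
    def query(self) -> str:
        return self.rows[0]

    @property
    def query_columns(self) -> tuple[int, ...]:
        """0-based indices of columns where the query has a residue."""
        return tuple(i for i, c in enumerate(self.rows[0]) if c != "-")

    def to_matrix(self) -> np.ndarray:
        """Integer-coded alignment, shape (n_rows, n_columns).

        Canonical residues map to 0..19; gaps and ambiguity codes to -1.
        """
        out = np.full((len(self.rows), self.n_columns), -1, dtype=np.int8)
        for r, row in enumerate(self.rows):
            for c, letter in enumerate(row):
                out[r, c] = AA_INDEX.get(letter, -1)
        return out


@dataclass(frozen=True)
class MetricReport:
    """Per-alignment information-content summary."""

    query_id: str
    homolog_count: int
    neff: float
    mean_entropy_bits: float
    per_column_entropy_bits: tuple[float, ...] = field(repr=False)


# ---------------------------------------------------------------------------
# readers


def _normalise_a3m_row(seq: str) -> str:
    # lowercase letters are insert states relative to the query profile and
    # live outside the shared column frame; '.' is an alternate gap glyph
    return "".join("-" if c == "." else c for c in seq if not c.islower())


def read_alignment(
    path: str | Path,
    format: str = "fasta",
    query_id: str | None = None,
) -> Alignment:
    """Read an MSA from ``fasta``, ``a3m`` or ``stockholm`` into an Alignment.

    The query is the first record unless ``query_id`` names another row,
    which is then moved to row 0. A3M lowercase insertions are dropped so
    every row shares the query's column frame.
    """
    path = Path(path)
    fmt = format.lower()
    if fmt == "fasta":
        records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(path, "fasta")]
    elif fmt == "a3m":
        records = [
            (r.id, _normalise_a3m_row(str(r.seq)).upper())
            for r in SeqIO.parse(path, "fasta")
        ]
    elif fmt == "stockholm":
        aln = AlignIO.read(path, "stockholm")
        records = [(r.id, str(r.seq).upper().replace(".", "-")) for r in aln]
    else:
        raise ValueError(f"unknown alignment format {format!r}")

    if not records:
        raise AlignmentError(f"no sequences found in {path}")
    if query_id is not None:
        idx = next((i for i, (rid, _) in enumerate(records) if rid == query_id), None)
        if idx is None:
            raise AlignmentError(f"query id {query_id!r} not found in {path}")
        records.insert(0, records.pop(idx))
    ids, rows = zip(*records)
    return Alignment(query_id=ids[0], ids=tuple(ids), rows=tuple(rows))


def write_alignment(aln: Alignment, path: str | Path) -> None:
    """Write an Alignment as aligned FASTA."""
    with open(path, "w") as fh:
        for rid, row in zip(aln.ids, aln.rows):
            fh.write(f">{rid}\n{row}\n")


# ---------------------------------------------------------------------------
# metrics


def neff(aln: Alignment) -> float:
    """Mean over *all* alignment columns of the count of distinct canonical
    amino-acid types in the column.

    Ranges from 1 (all sequences identical) to 20 (complete variability in
    every column). Gaps and ambiguity codes do not count as types; a column
    containing only gaps contributes 0 and triggers a warning.
    """
    mat = aln.to_matrix()
    n_allgap = 0
    col_types = np.zeros(aln.n_columns)
    for c in range(aln.n_columns):
        col = mat[:, c]
        types = np.unique(col[col >= 0])
        if types.size == 0:
            n_allgap += 1
        col_types[c] = types.size
    if n_allgap:
        warnings.warn(
            f"{n_allgap} all-gap column(s) contribute 0 to NEFF", stacklevel=2
        )
    return float(col_types.mean())


def column_entropy_bits(letters: Iterable[str]) -> float:
    """Shannon entropy (bits) of the canonical-residue distribution in one
    column; gaps/ambiguity excluded, plug-in frequencies, 0·log 0 = 0."""
    counts = np.zeros(20)
    for c in letters:
        i = AA_INDEX.get(c, -1)
        if i >= 0:
            counts[i] += 1
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def per_column_entropies(aln: Alignment) -> np.ndarray:
    """Entropy (bits) of each query-mapped column."""
    mat = aln.to_matrix()
    out = []
    for c in aln.query_columns:
        col = mat[:, c]
        col = col[col >= 0]
        if col.size == 0:
            out.append(0.0)
            continue
        counts = np.bincount(col, minlength=20).astype(float)
        p = counts[counts > 0] / counts.sum()
        out.append(float(-(p * np.log2(p)).sum()))
    return np.asarray(out)


def mean_entropy(aln: Alignment) -> float:
    """Mean per-residue entropy: average of the query-column entropies."""
    if not aln.query_columns:
        raise AlignmentError("query row is all gaps; no residue columns")
    return float(per_column_entropies(aln).mean())


def metric_report(aln: Alignment) -> MetricReport:
    """Compute all information-content metrics for one alignment."""
    ents = per_column_entropies(aln)
    return MetricReport(
        query_id=aln.query_id,
        homolog_count=aln.homolog_count,
        neff=neff(aln),
        mean_entropy_bits=float(ents.mean()) if ents.size else 0.0,
        per_column_entropy_bits=tuple(float(e) for e in ents),
    )


# ---------------------------------------------------------------------------
# depth control


def subsample_msa(aln: Alignment, n_homologs: int, seed: int) -> Alignment:
    """Truncate an MSA to ``n_homologs`` homolog rows drawn uniformly
    without replacement; the query row is always kept.

    This is the depth-control primitive: artificially cutting MSA size to
    match the homolog budget of a shallower dataset. Deterministic for a
    fixed seed.
    """
    if n_homologs < 0:
        raise ValueError("n_homologs must be non-negative")
    if n_homologs > aln.homolog_count:
        raise ValueError(
            f"requested {n_homologs} homologs but alignment has only "
            f"{aln.homolog_count}"
        )
    rng = np.random.default_rng(seed)
    picked = np.sort(rng.choice(aln.homolog_count, size=n_homologs, replace=False))
    keep = [0] + [int(i) + 1 for i in picked]
    return Alignment(
        query_id=aln.query_id,
        ids=tuple(aln.ids[i] for i in keep),
        rows=tuple(aln.rows[i] for i in keep),
    )


def metrics_table(alignments: Sequence[Alignment]):
    """MetricReports for several alignments as a pandas DataFrame."""
    import pandas as pd

    reps = [metric_report(a) for a in alignments]
    return pd.DataFrame(
        {
            "id": [r.query_id for r in reps],
            "homolog_count": [r.homolog_count for r in reps],
            "neff": [r.neff for r in reps],
            "mean_entropy_bits": [r.mean_entropy_bits for r in reps],
        }
    )
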