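"""Construction of bias-free validation sets.

Benchmark sets drawn from solved structures over-represent proteins with
unusually many homologs. This module removes that bias by (1) filtering
per-protein records on length and contact coverage (the classic
contact-prediction benchmark filters: 50 ≤ L ≤ 275 and at least L
contacts), (2) sampling a benchmark subset whose homolog-count
distribution matches a reference population drawn without the structure
condition, and (3) prescribing MSA truncation depths so an existing
benchmark can be re-evaluated at the homolog budget of the reference.

Distribution matching is quantile matching on log1p homolog counts:
counts span orders of magnitude, so nearest-neighbour assignment in log
space keeps the whole shape of the distribution, not just its centre.
The two-sample Kolmogorov–Smirnov statistic between the selected and the
target counts is reported as the closeness diagnostic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .msa_metrics import Alignment, subsample_msa

logger = logging.getLogger(__name__)

RECORD_COLUMNS = [
    "id",
    "length",
    "homolog_count",
    "neff",
    "mean_entropy_bits",
    "n_contacts",
    "group",
    "disorder_fraction",
    "msa_path",
    "pdb_path",
    "pred_path",
]


@dataclass(frozen=True)
class DatasetRecord:
    """One protein's precomputed annotations."""

    id: str
    length: int
    homolog_count: int
    neff: float | None = None
    mean_entropy_bits: float | None = None
    n_contacts: int | None = None
    group: str | None = None
    disorder_fraction: float | None = None
    msa_path: str | None = None
    pdb_path: str | None = None
    pred_path: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"{self.id}: length must be ≥ 1")
        if self.homolog_count < 0:
            raise ValueError(f"{self.id}: homolog_count must be ≥ 0")
        if self.disorder_fraction is not None and not (
            0.0 <= self.disorder_fraction <= 1.0
        ):
            raise ValueError(f"{self.id}: disorder_fraction must be in [0, 1]")


@dataclass(frozen=True)
class MatchResult:
    """Outcome of distribution-matched sampling."""

    selected_ids: tuple[str, ...]
    n: int
    ks_statistic: float
    seed: int
    log_transform: bool = True

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


@dataclass(frozen=True)
class DepthPrescription:
    """Truncation order for one record's MSA."""

    record_id: str
    depth: int
    seed: int


# ---------------------------------------------------------------------------
# record I/O


def read_records(path: str | Path) -> list[DatasetRecord]:
    """Read per-protein records from a headered TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "group": str})
    missing = {"id", "length", "homolog_count"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()

        def opt(key, cast):
            v = d.get(key)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                return None
            return cast(v)

        records.append(
            DatasetRecord(
                id=str(d["id"]),
                length=int(d["length"]),
                homolog_count=int(d["homolog_count"]),
                neff=opt("neff", float),
                mean_entropy_bits=opt("mean_entropy_bits", float),
                n_contacts=opt("n_contacts", int),
                group=opt("group", str),
                disorder_fraction=opt("disorder_fraction", float),
                msa_path=opt("msa_path", str),
                pdb_path=opt("pdb_path", str),
                pred_path=opt("pred_path", str),
            )
        )
    return records


def write_records(records: Sequence[DatasetRecord], path: str | Path) -> None:
    df = pd.DataFrame([dataclasses.asdict(r) for r in records], columns=RECORD_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# filters


def filter_records(
    records: Sequence[DatasetRecord],
    min_length: int,
    max_length: int,
    require_L_contacts: bool = False,
) -> list[DatasetRecord]:
    """Keep records with min_length ≤ length ≤ max_length and, when
    requested, at least L contacts (L = the record's own length).

    Order is preserved and the filter is idempotent. The contact count
    used for the ≥ L filter includes pairs at any sequence separation.
    """
    if min_length > max_length:
        raise ValueError("min_length must not exceed max_length")
    kept: list[DatasetRecord] = []
    n_len = n_contact = 0
    for r in records:
        if not (min_length <= r.length <= max_length):
            n_len += 1
            continue
        if require_L_contacts:
            if r.n_contacts is None:
                raise ValueError(f"{r.id}: contact filter requested but n_contacts absent")
            if r.n_contacts < r.length:
                n_contact += 1
                continue
        kept.append(r)
    logger.info(
        "filter_records: kept %d / %d (removed %d on length, %d on contacts)",
        len(kept), len(records), n_len, n_contact,
    )
    return kept


# ---------------------------------------------------------------------------
# distribution-matched sampling


def match_distribution(
    candidates: Sequence[DatasetRecord],
    target_counts: Sequence[int],
    n: int,
    seed: int,
) -> MatchResult:
    """Select ``n`` candidates whose homolog-count distribution matches the
    target counts as closely as possible.

    Target empirical quantiles are computed at probabilities (k − 0.5)/n
    on log1p-transformed counts; the quantiles are visited in seeded
    random order and each claims the still-unused candidate with the
    nearest log1p count. The selection depends only on (seed, candidate
    multiset): candidates are canonicalised by (count, id) first, so
    permuting the input order changes nothing.
    """
    if n < 1:
        raise ValueError("n must be ≥ 1")
    if len(candidates) < n:
        raise ValueError(f"need at least n={n} candidates, have {len(candidates)}")
    if len(target_counts) == 0:
        raise ValueError("target_counts must be non-empty")

    ordered = sorted(candidates, key=lambda r: (r.homolog_count, r.id))
    cand_log = np.log1p(np.array([r.homolog_count for r in ordered], dtype=float))
    tgt_log = np.log1p(np.asarray(target_counts, dtype=float))

    probs = (np.arange(1, n + 1) - 0.5) / n
    quantiles = np.quantile(tgt_log, probs)

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)

    used = np.zeros(len(ordered), dtype=bool)
    chosen = np.empty(n, dtype=int)
    for k in order:
        diff = np.abs(cand_log - quantiles[k])
        diff[used] = np.inf
        pick = int(np.argmin(diff))  # first index wins ties -> deterministic
        used[pick] = True
        chosen[k] = pick

    selected = [ordered[i] for i in chosen]
    ks = ks_2samp(
        [r.homolog_count for r in selected], np.asarray(target_counts, dtype=float)
    ).statistic
    return MatchResult(
        selected_ids=tuple(r.id for r in selected),
        n=n,
        ks_statistic=float(ks),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# MSA-depth matching (the truncation control)


def _derive_seed(seed: int, record_id: str) -> int:
    digest = hashlib.blake2s(f"{seed}:{record_id}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def match_msa_depths(
    records: Sequence[DatasetRecord],
    target_counts: Sequence[int],
    seed: int,
) -> list[DepthPrescription]:
    """Pair records with target homolog counts rank-to-rank and prescribe a
    truncation depth of min(own count, paired target) for each.

    Records sorted by homolog count are matched against sorted targets, so
    the deepest MSA is cut to the largest target budget and so on down the
    ranks; homologs can only be removed, never added. Each prescription
    carries a per-record seed derived from (seed, record id) so that the
    actual subsampling is reproducible record by record.
    """
    if len(records) != len(target_counts):
        raise ValueError(
            f"records ({len(records)}) and target_counts ({len(target_counts)}) "
            "must pair one-to-one"
        )
    ordered = sorted(records, key=lambda r: (r.homolog_count, r.id))
    targets = sorted(int(t) for t in target_counts)
    return [
        DepthPrescription(
            record_id=r.id,
            depth=min(r.homolog_count, t),
            seed=_derive_seed(seed, r.id),
        )
        for r, t in zip(ordered, targets)
    ]


def apply_msa_depths(
    prescriptions: Sequence[DepthPrescription],
    alignments: Mapping[str, Alignment],
) -> dict[str, Alignment]:
    """Execute depth prescriptions: subsample each record's alignment to its
    prescribed depth with its per-record seed."""
    out: dict[str, Alignment] = {}
    for p in prescriptions:
        aln = alignments[p.record_id]
        out[p.record_id] = subsample_msa(aln, p.depth, seed=p.seed)
    return out
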