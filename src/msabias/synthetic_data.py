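"""Synthetic inputs with known ground truth for the whole pipeline.

Every generator is a pure function of its configuration (seed included):
the same config produces byte-identical output. The generators emulate
the statistical structure of the real pipeline inputs —

* ``gen_msa``: alignments with controlled per-column diversity, so the
  expected NEFF and column entropies are known in closed form;
* ``gen_coupled_msa``: alignments with planted covarying column pairs
  (bijective recoding with probability c), whose mutual information has
  a closed form (MI = column entropy at c = 1) — the planted pairs act
  as ground-truth contacts;
* ``gen_structure``: compact self-avoiding 3D chains with derivable
  contact maps (Cα spacing 3.8 Å, pseudo-Cβ offset 1.5 Å);
* ``gen_predictions``: ranked prediction lists with an exactly
  controlled precision;
* ``gen_count_populations``: two heavy-tailed (log-normal) homolog-count
  populations whose means differ 6-fold by default, emulating the gap
  between proteins with solved structures and sequence-only proteins.

What these do *not* emulate: phylogenetic correlation between rows,
gap structure of real alignments, and real side-chain geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .contact_maps import ChainCoords, ContactMap, Residue, contact_map
from .cp_evaluation import PredictionList, canonical_order
from .msa_metrics import CANONICAL_AA, Alignment

MIN_PLANTED_SEPARATION = 5
CA_SPACING = 3.8  # Å between consecutive Cα
MIN_APPROACH = 4.0  # Å minimum non-consecutive Cα approach (self-avoidance)
CB_OFFSET = 1.5  # Å pseudo-Cβ offset from Cα


@dataclass(frozen=True)
class CountModel:
    """Log-normal homolog-count populations.

    Defaults give a heavy-tailed reference ("sequence-only") population
    with median ~55 homologs and a structure-biased population whose mean
    is 6× larger (same σ, Δμ = ln 6)."""

    mu_nostruct: float = 4.0
    sigma_nostruct: float = 1.5
    n_nostruct: int = 5000
    mu_struct: float = 4.0 + float(np.log(6.0))
    sigma_struct: float = 1.5
    n_struct: int = 5000


@dataclass(frozen=True)
class SimConfig:
    """Configuration shared by the generators.

    ``diversity`` is either one integer k (every column uniform over a
    seeded k-letter subset) or a per-column sequence of k values.
    ``planted_pairs`` are 1-based (i, j) column pairs, i < j, separation
    ≥ 5, no shared columns; ``coupling`` is the recoding probability c.
    """

    seed: int = 0
    length: int = 60
    depth: int = 500
    diversity: int | Sequence[int] = 20
    planted_pairs: tuple[tuple[int, int], ...] = ()
    coupling: float = 0.9
    gap_fraction: float = 0.0
    count_model: CountModel = field(default_factory=CountModel)

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must be in [0, 1]")
        ks = self.column_diversities()
        if any(not 1 <= k <= 20 for k in ks):
            raise ValueError("diversity values must be in [1, 20]")
        cols: set[int] = set()
        for i, j in self.planted_pairs:
            if not (1 <= i < j <= self.length):
                raise ValueError(f"planted pair ({i}, {j}) out of range")
            if j - i < MIN_PLANTED_SEPARATION:
                raise ValueError(
                    f"planted pair ({i}, {j}) closer than separation "
                    f"{MIN_PLANTED_SEPARATION}"
                )
            if i in cols or j in cols:
                raise ValueError(f"planted pair ({i}, {j}) shares a column")
            cols.update((i, j))

    def column_diversities(self) -> list[int]:
        if isinstance(self.diversity, (int, np.integer)):
            return [int(self.diversity)] * self.length
        ks = [int(k) for k in self.diversity]
        if len(ks) != self.length:
            raise ValueError(
                f"diversity has {len(ks)} entries for length {self.length}"
            )
        return ks


# ---------------------------------------------------------------------------
# alignments


def _column_supports(cfg: SimConfig, rng: np.random.Generator) -> list[np.ndarray]:
    """Per-column letter supports: a seeded k-subset of the 20 codes."""
    return [
        rng.permutation(20)[:k].astype(np.int8) for k in cfg.column_diversities()
    ]


def _rows_to_alignment(codes: np.ndarray, gap_mask: np.ndarray | None) -> Alignment:
    letters = np.array(list(CANONICAL_AA))
    rows = []
    for r in range(codes.shape[0]):
        row = letters[codes[r]]
        if gap_mask is not None:
            row = np.where(gap_mask[r], "-", row)
        rows.append("".join(row))
    ids = ("query",) + tuple(f"hom_{k}" for k in range(1, codes.shape[0]))
    return Alignment(query_id="query", ids=ids, rows=tuple(rows))


def gen_msa(cfg: SimConfig) -> Alignment:
    """Alignment of ``depth`` homolog rows plus a query, letters drawn iid
    per column uniformly over that column's k-letter support.

    The query (row 0) is always gap-free; homolog rows carry independent
    gaps at rate ``gap_fraction``. Expected NEFF and entropies follow in
    closed form from the per-column supports.
    """
    if cfg.depth < 0 or cfg.length < 1:
        raise ValueError("depth must be ≥ 0 and length ≥ 1")
    rng = np.random.default_rng(cfg.seed)
    supports = _column_supports(cfg, rng)
    n_rows = cfg.depth + 1
    codes = np.empty((n_rows, cfg.length), dtype=np.int8)
    for c, sup in enumerate(supports):
        codes[:, c] = rng.choice(sup, size=n_rows)
    gap_mask = None
    if cfg.gap_fraction > 0:
        gap_mask = rng.random((n_rows, cfg.length)) < cfg.gap_fraction
        gap_mask[0] = False  # query stays gap-free
    return _rows_to_alignment(codes, gap_mask)


def gen_coupled_msa(cfg: SimConfig) -> tuple[Alignment, ContactMap]:
    """Alignment with planted covarying column pairs, plus the planted
    pairs as a ground-truth ContactMap.

    For each planted pair (i, j): with probability ``coupling`` the row's
    letter at j is a fixed bijective recoding of its letter at i,
    otherwise it is drawn independently. At c = 1 the pair's mutual
    information equals column i's entropy exactly.
    """
    if cfg.depth < 1:
        raise ValueError("coupled MSA needs depth ≥ 1")
    rng = np.random.default_rng(cfg.seed)
    supports = _column_supports(cfg, rng)
    # coupled columns must share a support size for the recoding bijection
    for i, j in cfg.planted_pairs:
        supports[j - 1] = rng.permutation(20)[: len(supports[i - 1])].astype(np.int8)
    n_rows = cfg.depth + 1
    codes = np.empty((n_rows, cfg.length), dtype=np.int8)
    for c, sup in enumerate(supports):
        codes[:, c] = rng.choice(sup, size=n_rows)
    for i, j in cfg.planted_pairs:
        si, sj = supports[i - 1], supports[j - 1]
        # fixed bijection: position p in support i maps to position p of a
        # seeded shuffle of support j
        recode = sj[rng.permutation(len(sj))]
        pos_of = np.full(20, -1, dtype=np.int64)
        pos_of[si] = np.arange(len(si))
        couple = rng.random(n_rows) < cfg.coupling
        codes[couple, j - 1] = recode[pos_of[codes[couple, i - 1]]]
    aln = _rows_to_alignment(codes, None)
    planted = ContactMap(
        length=cfg.length,
        pairs=frozenset(cfg.planted_pairs),
        threshold_angstrom=float("nan"),
    )
    return aln, planted


# ---------------------------------------------------------------------------
# structures


def _grow_chain(
    L: int, rng: np.random.Generator, compaction: float, max_tries: int = 200
) -> np.ndarray | None:
    ca = np.empty((L, 3))
    ca[0] = 0.0
    for k in range(1, L):
        centroid = ca[:k].mean(axis=0)
        for _ in range(max_tries):
            step = rng.normal(size=3)
            pull = centroid - ca[k - 1]
            norm_pull = np.linalg.norm(pull)
            if norm_pull > 1e-9:
                step = step + compaction * pull / norm_pull
            step /= np.linalg.norm(step)
            cand = ca[k - 1] + CA_SPACING * step
            if k >= 2:
                d = np.linalg.norm(ca[: k - 1] - cand, axis=1)
                if d.min() < MIN_APPROACH:
                    continue
            ca[k] = cand
            break
        else:
            return None
    return ca


def gen_structure(cfg: SimConfig) -> ChainCoords:
    """Compact self-avoiding Cα walk with pseudo-Cβ atoms.

    Consecutive Cα are exactly 3.8 Å apart; non-consecutive Cα never
    come closer than 4.0 Å; each residue gets a pseudo-Cβ 1.5 Å from its
    Cα in a random direction (glycines carry no Cβ, exercising the Cα
    fallback of the contact rule). The inward pull of the walk keeps the
    chain compact enough that chains of length ≥ 30 are guaranteed at
    least one contact at sequence separation ≥ 5; the generator retries
    with derived seeds until that holds.
    """
    L = cfg.length
    if L < 2:
        raise ValueError("need length ≥ 2")
    for attempt in range(50):
        rng = np.random.default_rng((cfg.seed, attempt))
        ca = _grow_chain(L, rng, compaction=1.0)
        if ca is None:
            continue
        aas = [CANONICAL_AA[i] for i in rng.integers(0, 20, size=L)]
        residues = []
        for k in range(L):
            if aas[k] == "G":
                cb = None
            else:
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                cb = tuple(float(x) for x in (ca[k] + CB_OFFSET * direction))
            residues.append(
                Residue(
                    index=k + 1,
                    aa=aas[k],
                    ca_xyz=tuple(float(x) for x in ca[k]),
                    cb_xyz=cb,
                )
            )
        coords = ChainCoords(chain_id="A", residues=tuple(residues))
        if L < 30:
            return coords
        cmap = contact_map(coords)
        if any(j - i >= MIN_PLANTED_SEPARATION for i, j in cmap.pairs):
            return coords
    raise RuntimeError(f"failed to grow a self-avoiding chain of length {L}")


def write_pdb(coords: ChainCoords, path) -> None:
    """Write ChainCoords as a minimal single-chain PDB file (CA + CB)."""
    from Bio.PDB.Polypeptide import protein_letters_3to1

    letters_1to3 = {v: k for k, v in protein_letters_3to1.items()}
    with open(path, "w") as fh:
        serial = 1
        for r in coords.residues:
            res3 = letters_1to3.get(r.aa, "UNK")
            for name, xyz in (("CA", r.ca_xyz), ("CB", r.cb_xyz)):
                if xyz is None:
                    continue
                fh.write(
                    f"ATOM  {serial:5d}  {name:<3s}{res3:>4s} "
                    f"{coords.chain_id}{r.index:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          "
                    f"{name[0]:>2s}\n"
                )
                serial += 1
        fh.write("END\n")


# ---------------------------------------------------------------------------
# predictions of controlled precision


def gen_predictions(
    truth: ContactMap, target_ppv: float, K: int, seed: int
) -> PredictionList:
    """Ranked prediction list whose top K contains exactly
    round(target_ppv × K) true contacts at separation ≥ 5, the rest
    non-contacts, in seeded random rank order with strictly decreasing
    scores."""
    if not 0.0 <= target_ppv <= 1.0:
        raise ValueError("target_ppv must be in [0, 1]")
    if K < 1:
        raise ValueError("K must be ≥ 1")
    rng = np.random.default_rng(seed)
    eligible = [
        (i, j)
        for i in range(1, truth.length + 1)
        for j in range(i + MIN_PLANTED_SEPARATION, truth.length + 1)
        if i not in truth.missing_residues and j not in truth.missing_residues
    ]
    true_pool = [p for p in eligible if p in truth.pairs]
    false_pool = [p for p in eligible if p not in truth.pairs]
    n_true = round(target_ppv * K)
    n_false = K - n_true
    if n_true > len(true_pool) or n_false > len(false_pool):
        raise ValueError(
            f"cannot plant {n_true} true + {n_false} false pairs: pools have "
            f"{len(true_pool)} true / {len(false_pool)} false eligible pairs"
        )
    chosen = [true_pool[i] for i in rng.choice(len(true_pool), n_true, replace=False)]
    chosen += [
        false_pool[i] for i in rng.choice(len(false_pool), n_false, replace=False)
    ]
    order = rng.permutation(K)
    scores = np.linspace(1.0, 0.5, K)
    entries = [
        (chosen[order[r]][0], chosen[order[r]][1], float(scores[r]))
        for r in range(K)
    ]
    return PredictionList(
        target_id="synthetic", entries=tuple(canonical_order(entries))
    )


# ---------------------------------------------------------------------------
# homolog-count populations


def gen_count_populations(cfg: SimConfig) -> tuple[list[int], list[int]]:
    """Seeded integer homolog counts for a structure-biased population and
    a sequence-only-like reference population.

    Returns (struct_like, nostruct_like). With the default CountModel the
    population mean ratio is 6 (log-normal mean exp(μ + σ²/2), identical
    σ, Δμ = ln 6)."""
    cm = cfg.count_model
    if cm.n_struct < 1 or cm.n_nostruct < 1:
        raise ValueError("population sizes must be positive")
    rng = np.random.default_rng(cfg.seed)
    struct = rng.lognormal(cm.mu_struct, cm.sigma_struct, cm.n_struct)
    nostruct = rng.lognormal(cm.mu_nostruct, cm.sigma_nostruct, cm.n_nostruct)
    return (
        [int(x) for x in np.rint(struct)],
        [int(x) for x in np.rint(nostruct)],
    )


def load_sim_config(mapping: Mapping) -> SimConfig:
    """Build a SimConfig from a plain mapping (e.g. parsed YAML)."""
    m = dict(mapping)
    if "planted_pairs" in m:
        m["planted_pairs"] = tuple(tuple(p) for p in m["planted_pairs"])
    if "count_model" in m:
        m["count_model"] = CountModel(**m["count_model"])
    return SimConfig(**m)
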