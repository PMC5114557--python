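"""Ground-truth residue contacts from protein coordinates.

Two residues are in contact when their representative atoms lie strictly
closer than a distance threshold, 8 Å by default. The representative atom
is Cβ, or Cα for glycine (which has no Cβ); this is the contact
definition used by CASP assessments. Non-glycine residues missing their
Cβ (incomplete side chains are common in deposited structures) fall back
to Cα with a warning rather than being dropped.

Residues are indexed 1-based by their order along the parsed chain;
insertion codes collapse into sequential positions. Contacts are stored
at *all* sequence separations — the evaluation layer applies its own
separation filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1
from scipy.spatial.distance import pdist, squareform


class StructureError(ValueError):
    """Raised for unusable coordinate files."""


@dataclass(frozen=True)
class Residue:
    index: int  # 1-based position along the chain
    aa: str  # one-letter code, 'X' for unknown
    ca_xyz: tuple[float, float, float] | None
    cb_xyz: tuple[float, float, float] | None

    @property
    def representative_xyz(self) -> tuple[float, float, float] | None:
        """Cβ if present, else Cα (exact for glycine, fallback otherwise)."""
        if self.cb_xyz is not None:
            return self.cb_xyz
        return self.ca_xyz


@dataclass(frozen=True)
class ChainCoords:
    """Ordered residue coordinates for a single protein chain."""

    chain_id: str
    residues: tuple[Residue, ...]

    def __post_init__(self) -> None:
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise StructureError("residue indices must be strictly increasing")

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def missing_residues(self) -> frozenset[int]:
        """Indices with neither Cβ nor Cα — excluded from contact derivation."""
        return frozenset(
            r.index for r in self.residues if r.representative_xyz is None
        )


@dataclass(frozen=True)
class ContactMap:
    """Symmetric set of contacting residue pairs for a chain of length L."""

    length: int
    pairs: frozenset[tuple[int, int]]  # (i, j), 1-based, i < j
    threshold_angstrom: float = 8.0
    missing_residues: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for i, j in self.pairs:
            if not (1 <= i < j <= self.length):
                raise ValueError(f"pair ({i}, {j}) out of range for L={self.length}")
            if i in self.missing_residues or j in self.missing_residues:
                raise ValueError(f"pair ({i}, {j}) touches a missing residue")

    def __contains__(self, pair: tuple[int, int]) -> bool:
        i, j = pair
        return (min(i, j), max(i, j)) in self.pairs

    @property
    def n_contacts(self) -> int:
        return len(self.pairs)

    def to_matrix(self) -> np.ndarray:
        """Dense boolean L×L matrix (symmetric, zero diagonal), 0-based."""
        m = np.zeros((self.length, self.length), dtype=bool)
        for i, j in self.pairs:
            m[i - 1, j - 1] = m[j - 1, i - 1] = True
        return m


# ---------------------------------------------------------------------------
# PDB reading


def read_structure(path: str | Path, chain: str | None = None) -> ChainCoords:
    """Parse one chain of a PDB-format file into ChainCoords.

    Alternate locations resolve to the highest-occupancy conformer
    (Bio.PDB's disorder handling, first-seen on ties). If ``chain`` is
    None the file must contain exactly one chain. Only standard ATOM
    residues are kept; waters/ligands are ignored.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("s", str(path))
    except Exception as exc:  # Bio.PDB raises several unrelated types
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    model = next(structure.get_models(), None)
    if model is None:
        raise StructureError(f"no coordinate model in {path}")
    chains = {c.id: c for c in model}
    if not chains:
        raise StructureError(f"no ATOM records in {path}")
    if chain is None:
        if len(chains) > 1:
            raise StructureError(
                f"{path} has chains {sorted(chains)}; specify one"
            )
        chain_obj = next(iter(chains.values()))
    else:
        if chain not in chains:
            raise StructureError(f"chain {chain!r} not in {path} ({sorted(chains)})")
        chain_obj = chains[chain]

    residues: list[Residue] = []
    pos = 0
    n_cb_fallback = 0
    for res in chain_obj:
        if res.id[0] != " ":  # skip HETATM / water
            continue
        pos += 1
        resname = res.get_resname().strip()
        aa = protein_letters_3to1.get(resname, "X")
        ca = res["CA"].get_coord() if "CA" in res else None
        cb = res["CB"].get_coord() if "CB" in res else None
        if cb is None and aa != "G" and ca is not None:
            n_cb_fallback += 1
        residues.append(
            Residue(
                index=pos,
                aa=aa,
                ca_xyz=tuple(map(float, ca)) if ca is not None else None,
                cb_xyz=tuple(map(float, cb)) if cb is not None else None,
            )
        )
    if not residues:
        raise StructureError(f"chain {chain_obj.id!r} in {path} has no residues")
    if n_cb_fallback:
        warnings.warn(
            f"{n_cb_fallback} non-glycine residue(s) missing Cβ; using Cα",
            stacklevel=2,
        )
    return ChainCoords(chain_id=chain_obj.id, residues=tuple(residues))


# ---------------------------------------------------------------------------
# contact derivation


def contact_map(coords: ChainCoords, threshold: float = 8.0) -> ContactMap:
    """All residue pairs whose representative atoms are strictly closer
    than ``threshold`` Å. Pairs involving residues with no representative
    atom are excluded and listed in ``missing_residues``."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    usable = [r for r in coords.residues if r.representative_xyz is not None]
    if len(usable) < 2:
        raise StructureError("fewer than 2 residues with usable coordinates")
    xyz = np.array([r.representative_xyz for r in usable])
    idx = np.array([r.index for r in usable])
    dmat = squareform(pdist(xyz))
    ii, jj = np.nonzero(np.triu(dmat < threshold, k=1))
    pairs = frozenset((int(idx[a]), int(idx[b])) for a, b in zip(ii, jj))
    return ContactMap(
        length=coords.length,
        pairs=pairs,
        threshold_angstrom=threshold,
        missing_residues=coords.missing_residues,
    )


def contact_density(cmap: ContactMap) -> float:
    """Number of contacts divided by chain length."""
    if cmap.length < 1:
        raise ValueError("empty chain")
    return cmap.n_contacts / cmap.length


# ---------------------------------------------------------------------------
# writers / readers for contact lists


def write_contacts_tsv(
    cmap: ContactMap, coords: ChainCoords | None, path: str | Path
) -> None:
    """Contact list as TSV: i, j, distance (Å, blank if coords absent)."""
    dist = {}
    if coords is not None:
        rep = {
            r.index: np.asarray(r.representative_xyz)
            for r in coords.residues
            if r.representative_xyz is not None
        }
        for i, j in cmap.pairs:
            dist[(i, j)] = float(np.linalg.norm(rep[i] - rep[j]))
    with open(path, "w") as fh:
        fh.write("i\tj\tdistance\n")
        for i, j in sorted(cmap.pairs):
            d = f"{dist[(i, j)]:.3f}" if (i, j) in dist else ""
            fh.write(f"{i}\t{j}\t{d}\n")


def read_contacts_tsv(path: str | Path, length: int) -> ContactMap:
    """Read a TSV contact list (header i, j[, distance]) into a ContactMap."""
    pairs = set()
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("i"):
            raise ValueError(f"{path}: expected header starting with 'i'")
        for line in fh:
            if not line.strip():
                continue
            fields = line.split("\t")
            i, j = int(fields[0]), int(fields[1])
            pairs.add((min(i, j), max(i, j)))
    return ContactMap(length=length, pairs=frozenset(pairs))
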