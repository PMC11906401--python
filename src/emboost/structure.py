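"""Atomic structure parsing.

Exposes atoms as flat numpy arrays (element, atomic number, Cartesian Å
coordinates, chain id) — exactly what density simulation and molecular
masking need.  All ATOM and HETATM records are kept, including hydrogens,
waters, ligands and nucleic acids; for alternate locations only the
highest-occupancy conformer of each atom is retained so every atom has a
single position.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import gemmi
import numpy as np

__all__ = ["AtomicStructure", "read_structure", "select_chain"]


@dataclasses.dataclass
class AtomicStructure:
    """A flat list of atoms.

    Fields are parallel arrays: ``elements`` (symbols), ``atomic_numbers``
    (int, ≥ 1), ``coords`` (n×3 float64 Å), ``chains`` (chain ids).
    """

    elements: np.ndarray
    atomic_numbers: np.ndarray
    coords: np.ndarray
    chains: np.ndarray

    def __post_init__(self) -> None:
        self.elements = np.asarray(self.elements, dtype=object)
        self.atomic_numbers = np.asarray(self.atomic_numbers, dtype=np.int64)
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        self.chains = np.asarray(self.chains, dtype=object)
        n = len(self.coords)
        if not (len(self.elements) == len(self.atomic_numbers) == len(self.chains) == n):
            raise ValueError("atom arrays have inconsistent lengths")
        if n == 0:
            raise ValueError("structure contains no atoms")
        if (self.atomic_numbers < 1).any():
            raise ValueError("atomic numbers must be >= 1")
        if not np.isfinite(self.coords).all():
            raise ValueError("atom coordinates must be finite")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chains:
            seen.setdefault(str(c))
        return list(seen)

    def concat(self, other: "AtomicStructure") -> "AtomicStructure":
        return AtomicStructure(
            np.concatenate([self.elements, other.elements]),
            np.concatenate([self.atomic_numbers, other.atomic_numbers]),
            np.concatenate([self.coords, other.coords]),
            np.concatenate([self.chains, other.chains]),
        )


# Minimal fallback table for legacy PDB files with a blank element column;
# keyed by the first alphabetic character of the atom name.
_NAME_FALLBACK = {"C": 6, "N": 7, "O": 8, "S": 16, "H": 1, "P": 15}
_SYMBOL = {1: "H", 6: "C", 7: "N", 8: "O", 15: "P", 16: "S"}


def _element_from_name(atom_name: str) -> tuple[str, int]:
    for ch in atom_name:
        if ch.isalpha():
            z = _NAME_FALLBACK.get(ch.upper())
            if z is not None:
                return _SYMBOL[z], z
            break
    raise ValueError(f"cannot resolve element for atom record {atom_name!r}")


def read_structure(path: str | Path, keep_waters: bool = True) -> AtomicStructure:
    """Parse a PDB or mmCIF file into an :class:`AtomicStructure`.

    Every ATOM/HETATM record contributes one atom; elements are resolved to
    atomic numbers via the periodic table, with an atom-name heuristic (and
    a warning) for legacy files lacking the element column.  For altloc
    groups only the highest-occupancy conformer is kept.  Waters are kept
    by default (``keep_waters=False`` drops them).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"{path}: cannot parse structure ({exc})") from exc

    elements: list[str] = []
    numbers: list[int] = []
    coords: list[tuple[float, float, float]] = []
    chains: list[str] = []
    if len(st) == 0:
        raise ValueError(f"{path}: structure contains no models")
    model = st[0]
    for chain in model:
        for res in chain:
            if not keep_waters and res.is_water():
                continue
            # Resolve altlocs: keep the highest-occupancy conformer per atom name.
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                cur = best.get(atom.name)
                if cur is None or atom.occ > cur.occ:
                    best[atom.name] = atom
            for atom in best.values():
                el = atom.element
                if el.atomic_number >= 1:
                    sym, z = el.name, el.atomic_number
                else:
                    warnings.warn(
                        f"{path}: blank element for atom {atom.name!r} in "
                        f"{chain.name}/{res.name}; inferring from atom name",
                        stacklevel=2,
                    )
                    sym, z = _element_from_name(atom.name)
                elements.append(sym)
                numbers.append(z)
                coords.append((atom.pos.x, atom.pos.y, atom.pos.z))
                chains.append(chain.name)
    if not coords:
        raise ValueError(f"{path}: structure contains no atoms")
    return AtomicStructure(elements, numbers, coords, chains)


def select_chain(s: AtomicStructure, chain: str) -> AtomicStructure:
    """Restrict ``s`` to the atoms of one chain."""
    mask = np.array([str(c) == str(chain) for c in s.chains])
    if not mask.any():
        raise KeyError(
            f"chain {chain!r} not found; available chains: {s.chain_ids}"
        )
    return AtomicStructure(
        s.elements[mask], s.atomic_numbers[mask], s.coords[mask], s.chains[mask]
    )
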