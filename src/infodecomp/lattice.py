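"""The redundancy (antichain) lattice and Möbius inversion.

The decompositions in this package distribute an information quantity over
"atoms": antichains of sources, where a source is a nonempty subset of the
system's variables and an antichain is a collection of sources none of which
contains another. The atoms are partially ordered (alpha below beta iff every
source of beta contains some source of alpha), forming the redundancy lattice
of Williams and Beer, with the all-singletons atom (full redundancy) at the
bottom and the single full-set source (full synergy) at the top.

Cumulative redundancy values assigned to each atom are converted into unique
per-atom ("partial") values by Möbius inversion over this order.

The number of atoms grows as the Dedekind numbers minus two
(1, 4, 18, 166, 7579, ... for n = 1, 2, 3, 4, 5), which is why full-lattice
work is capped at four variables.
"""

from __future__ import annotations

import itertools
from functools import lru_cache
from typing import Iterable, Iterator, Mapping, Sequence

MAX_VARIABLES = 4

#: atom counts for n = 1..4 (Dedekind number of n minus the empty antichain
#: and the empty source)
ATOM_COUNTS = {1: 1, 2: 4, 3: 18, 4: 166}


class UnsupportedSizeError(ValueError):
    """Lattice size outside the supported 1..4 variable range."""


class IncompleteTableError(ValueError):
    """A cumulative table does not cover every atom of the lattice."""


def default_names(n: int) -> tuple[str, ...]:
    return tuple(f"X{i + 1}" for i in range(n))


class Source(frozenset):
    """A nonempty set of variable indices treated as one observable."""

    __slots__ = ()

    def __new__(cls, indices: Iterable[int]) -> "Source":
        self = super().__new__(cls, indices)
        if not self:
            raise ValueError("a source must contain at least one variable index")
        for i in self:
            if not isinstance(i, int) or i < 0:
                raise ValueError(f"source indices must be non-negative ints, got {i!r}")
        return self

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(sorted(self))

    def label(self, names: Sequence[str] | None = None) -> str:
        if names is None:
            names = default_names(max(self) + 1)
        return "{" + ",".join(names[i] for i in self.indices) + "}"

    def __repr__(self) -> str:
        return f"Source({self.indices})"


class Antichain(frozenset):
    """A lattice atom: a set of pairwise inclusion-incomparable sources."""

    __slots__ = ()

    def __new__(cls, sources: Iterable[Iterable[int]]) -> "Antichain":
        srcs = [s if isinstance(s, Source) else Source(s) for s in sources]
        self = super().__new__(cls, srcs)
        if not self:
            raise ValueError("an antichain must contain at least one source")
        for a, b in itertools.combinations(self, 2):
            if a <= b or b <= a:
                raise ValueError(
                    f"sources {sorted(a)} and {sorted(b)} are comparable; not an antichain"
                )
        return self

    @property
    def sources(self) -> tuple[Source, ...]:
        """Sources in canonical order: by cardinality, then index order."""
        return tuple(sorted(self, key=lambda s: (len(s), s.indices)))

    def label(self, names: Sequence[str] | None = None) -> str:
        if names is None:
            names = default_names(max(max(s) for s in self) + 1)
        return "".join(s.label(names) for s in self.sources)

    def __repr__(self) -> str:
        return f"Antichain({self.label()})"


def atom_leq(alpha: Antichain, beta: Antichain) -> bool:
    """Lattice order: alpha is below beta iff every source of beta contains
    some source of alpha (redundancy at the bottom, synergy at the top)."""
    return all(any(a <= b for a in alpha) for b in beta)


def enumerate_antichains(n: int) -> list[Antichain]:
    """All antichains of nonempty subsets of {0..n-1}, the empty antichain
    excluded. Generated by depth-first extension with incomparability
    pruning; counts are pinned to the known sequence 1, 4, 18, 166."""
    if not (1 <= n <= MAX_VARIABLES):
        raise UnsupportedSizeError(
            f"n={n} is outside 1..{MAX_VARIABLES}: the atom count follows the "
            "Dedekind numbers (7579 atoms at n=5) and full-lattice "
            "decompositions beyond four variables are intractable"
        )
    sources = [
        frozenset(c)
        for size in range(1, n + 1)
        for c in itertools.combinations(range(n), size)
    ]
    out: list[Antichain] = []
    chosen: list[frozenset] = []

    def extend(start: int) -> None:
        for i in range(start, len(sources)):
            s = sources[i]
            if all(not (s <= c or c <= s) for c in chosen):
                chosen.append(s)
                out.append(Antichain(chosen))
                extend(i + 1)
                chosen.pop()

    extend(0)
    assert len(out) == ATOM_COUNTS[n]
    return out


class RedundancyLattice:
    """All atoms for ``n_variables`` plus the partial order, with atoms held
    in a fixed topological order (bottom first) and strict down-sets cached."""

    def __init__(self, n_variables: int, atoms: Sequence[Antichain]) -> None:
        self.n_variables = n_variables
        down: dict[Antichain, tuple[Antichain, ...]] = {}
        for a in atoms:
            down[a] = tuple(b for b in atoms if b is not a and atom_leq(b, a))
        self.atoms: tuple[Antichain, ...] = tuple(
            sorted(atoms, key=lambda a: (len(down[a]), a.label(default_names(n_variables))))
        )
        self._down = down
        self._index = {a: i for i, a in enumerate(self.atoms)}
        self._by_label: dict[str, Antichain] = {
            a.label(default_names(n_variables)): a for a in self.atoms
        }

    @property
    def bottom(self) -> Antichain:
        return self.atoms[0]

    @property
    def top(self) -> Antichain:
        return self.atoms[-1]

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[Antichain]:
        return iter(self.atoms)

    def leq(self, alpha: Antichain, beta: Antichain) -> bool:
        return atom_leq(alpha, beta)

    def down_set(self, atom: Antichain, strict: bool = True) -> tuple[Antichain, ...]:
        """Atoms below ``atom``; includes ``atom`` itself unless ``strict``."""
        d = self._down[atom]
        return d if strict else d + (atom,)

    def index(self, atom: Antichain) -> int:
        return self._index[atom]

    def atom_from_label(self, label: str) -> Antichain:
        """Resolve a canonical default-named label like '{X1}{X2,X3}'."""
        try:
            return self._by_label[label]
        except KeyError:
            raise KeyError(f"no atom with canonical label {label!r}") from None

    def __repr__(self) -> str:
        return f"RedundancyLattice(n={self.n_variables}, atoms={len(self)})"


@lru_cache(maxsize=None)
def build_lattice(n: int) -> RedundancyLattice:
    """Construct (and cache) the redundancy lattice on ``n`` variables."""
    lat = RedundancyLattice(n, enumerate_antichains(n))
    if n >= 1:
        assert lat.bottom == Antichain([(i,) for i in range(n)])
        assert lat.top == Antichain([tuple(range(n))])
    return lat


class AtomTable(Mapping):
    """A value in bits for every atom of a lattice.

    Keys are exactly the lattice's atoms. Lookup also accepts a canonical
    label string rendered either with the table's variable ``names`` or with
    the default X1..Xn names. Tables over the same lattice support atomwise
    addition, subtraction and scalar multiplication.
    """

    __slots__ = ("lattice", "names", "_values", "_label_map")

    def __init__(
        self,
        lattice: RedundancyLattice,
        values: Mapping[Antichain, float],
        names: Sequence[str] | None = None,
    ) -> None:
        if set(values) != set(lattice.atoms):
            raise IncompleteTableError(
                f"table holds {len(values)} atoms, lattice has {len(lattice)}"
            )
        for a, v in values.items():
            v = float(v)
            if v != v or v in (float("inf"), float("-inf")):
                raise ValueError(f"non-finite value {v} for atom {a.label()}")
        self.lattice = lattice
        self.names = tuple(names) if names is not None else default_names(lattice.n_variables)
        if len(self.names) != lattice.n_variables:
            raise ValueError("need one name per lattice variable")
        self._values = {a: float(values[a]) for a in lattice.atoms}
        label_map = {}
        for a in lattice.atoms:
            label_map[a.label(self.names)] = a
            label_map.setdefault(a.label(default_names(lattice.n_variables)), a)
        self._label_map = label_map

    @classmethod
    def zeros(
        cls, lattice: RedundancyLattice, names: Sequence[str] | None = None
    ) -> "AtomTable":
        return cls(lattice, {a: 0.0 for a in lattice.atoms}, names)

    def _resolve(self, key) -> Antichain:
        if isinstance(key, str):
            try:
                return self._label_map[key]
            except KeyError:
                raise KeyError(f"no atom labelled {key!r}") from None
        if not isinstance(key, Antichain):
            key = Antichain(key)
        return key

    def __getitem__(self, key) -> float:
        return self._values[self._resolve(key)]

    def __iter__(self) -> Iterator[Antichain]:
        return iter(self.lattice.atoms)

    def __len__(self) -> int:
        return len(self._values)

    def total(self) -> float:
        """Sum of all atoms — the reconstructed aggregate quantity."""
        import math

        return math.fsum(self._values.values())

    def label(self, atom: Antichain) -> str:
        return atom.label(self.names)

    # -- arithmetic ------------------------------------------------------

    def _binop(self, other: "AtomTable", op) -> "AtomTable":
        if self.lattice is not other.lattice and self.lattice.atoms != other.lattice.atoms:
            raise ValueError("atom tables are over different lattices")
        return AtomTable(
            self.lattice,
            {a: op(self._values[a], other._values[a]) for a in self.lattice.atoms},
            self.names,
        )

    def __add__(self, other: "AtomTable") -> "AtomTable":
        return self._binop(other, lambda x, y: x + y)

    def __sub__(self, other: "AtomTable") -> "AtomTable":
        return self._binop(other, lambda x, y: x - y)

    def __mul__(self, w: float) -> "AtomTable":
        return AtomTable(
            self.lattice, {a: v * w for a, v in self._values.items()}, self.names
        )

    __rmul__ = __mul__

    def allclose(self, other: "AtomTable", atol: float = 1e-9) -> bool:
        return all(
            abs(self._values[a] - other._values[a]) <= atol for a in self.lattice.atoms
        )

    # -- output ----------------------------------------------------------

    def to_frame(self):
        """Two-column pandas DataFrame (atom, bits) in lattice topological order."""
        import pandas as pd

        return pd.DataFrame(
            {
                "atom": [a.label(self.names) for a in self.lattice.atoms],
                "bits": [self._values[a] for a in self.lattice.atoms],
            }
        )

    def to_tsv(self, path) -> None:
        """Atom-table TSV: columns 'atom' and 'bits', topological row order,
        floats rendered with 10 significant digits."""
        lines = ["atom\tbits"]
        for a in self.lattice.atoms:
            lines.append(f"{a.label(self.names)}\t{self._values[a]:.10g}")
        from pathlib import Path

        Path(path).write_text("\n".join(lines) + "\n")

    def __repr__(self) -> str:
        return f"AtomTable(n={self.lattice.n_variables}, total={self.total():.6g} bits)"


def mobius_inversion(
    lattice: RedundancyLattice,
    cumulative: Mapping[Antichain, float],
    names: Sequence[str] | None = None,
) -> AtomTable:
    """Invert a cumulative redundancy table into partial atom values.

    Processing the atoms in topological order, each partial value is the
    cumulative value minus the sum of partial values over the atom's strict
    down-set, so every atom is resolved exactly once and the inclusive
    down-set sum of the result reproduces the cumulative input.
    """
    missing = [a for a in lattice.atoms if a not in cumulative]
    if missing:
        raise IncompleteTableError(
            f"cumulative table missing {len(missing)} atoms, e.g. {missing[0].label()}"
        )
    partial: dict[Antichain, float] = {}
    for atom in lattice.atoms:
        below = sum(partial[b] for b in lattice.down_set(atom, strict=True))
        partial[atom] = float(cumulative[atom]) - below
    return AtomTable(lattice, partial, names)
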