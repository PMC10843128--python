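"""Partial entropy decomposition (PED).

Decomposes the local surprisal h(x) = -log2 P(x) of each outcome over the
redundancy lattice, then (optionally) averages the local tables under P to
decompose the Shannon entropy. The decomposition is driven by a pluggable
*redundancy function* h_cap(x, alpha, P): the entropy shared by all sources
of the antichain alpha at the outcome x. The shipped default is h_min — the
minimum local surprisal across the antichain's sources — which is localizable
and yields non-negative local atoms.
"""

from __future__ import annotations

from typing import Callable, Mapping, Sequence

from .distributions import (
    JointDistribution,
    Realization,
    SupportError,
    _as_state,
    local_surprisal,
)
from .lattice import Antichain, AtomTable, RedundancyLattice, build_lattice, mobius_inversion

#: contract: (realization, antichain, distribution) -> local redundant entropy
#: in bits. Must be symmetric in the antichain's sources and localizable
#: (defined per outcome, not only in expectation).
RedundancyFunction = Callable[[Realization, Antichain, JointDistribution], float]


def h_min(
    x: "Realization | Sequence", alpha: Antichain, P: JointDistribution
) -> float:
    """Minimum over the antichain's sources of the local surprisal of that
    source's projection of ``x``. Ties need no breaking: only the minimum
    value is used."""
    state = _as_state(x)
    return min(local_surprisal(P, state, sorted(src)) for src in alpha)


REDUNDANCY_FUNCTIONS: dict[str, RedundancyFunction] = {"hmin": h_min}


def register_redundancy_function(
    name: str, fn: RedundancyFunction, overwrite: bool = False
) -> None:
    """Register an alternative redundancy function (e.g. a differentiable
    shared-exclusion variant) under ``name`` for use by the CLI and callers
    that select functions by name."""
    if name in REDUNDANCY_FUNCTIONS and not overwrite:
        raise ValueError(f"redundancy function {name!r} already registered")
    REDUNDANCY_FUNCTIONS[name] = fn


def get_redundancy_function(name: str) -> RedundancyFunction:
    try:
        return REDUNDANCY_FUNCTIONS[name]
    except KeyError:
        raise KeyError(
            f"unknown redundancy function {name!r}; registered: "
            f"{sorted(REDUNDANCY_FUNCTIONS)}"
        ) from None


def cumulative_table(
    P: JointDistribution,
    x: "Realization | Sequence",
    rf: RedundancyFunction = h_min,
    lattice: RedundancyLattice | None = None,
) -> Mapping[Antichain, float]:
    """The raw (cumulative) redundancy values rf(x, alpha, P) per atom."""
    if lattice is None:
        lattice = build_lattice(P.n_variables)
    return {alpha: rf(x, alpha, P) for alpha in lattice.atoms}


def local_ped(
    P: JointDistribution,
    x: "Realization | Sequence",
    rf: RedundancyFunction = h_min,
    lattice: RedundancyLattice | None = None,
) -> AtomTable:
    """Decompose the local surprisal of outcome ``x`` under ``P``.

    Möbius inversion of the cumulative redundancy values; the atom values sum
    to h(x) because the cumulative value at the top atom is the full-state
    surprisal.
    """
    state = _as_state(x)
    if P.prob(state) <= 0.0:
        raise SupportError(f"state {state!r} is outside the support of P")
    if lattice is None:
        lattice = build_lattice(P.n_variables)
    return mobius_inversion(lattice, cumulative_table(P, state, rf, lattice), P.variables)


def expected_ped(
    P: JointDistribution,
    rf: RedundancyFunction = h_min,
    lattice: RedundancyLattice | None = None,
) -> AtomTable:
    """Probability-weighted average of the local decompositions over supp(P);
    the atom values sum to the Shannon entropy H(P).

    The order of operations is decompose-locally-then-average, not the
    decomposition of averaged cumulative values.
    """
    if lattice is None:
        lattice = build_lattice(P.n_variables)
    acc = {alpha: 0.0 for alpha in lattice.atoms}
    for state, p in P.pmf.items():
        local = local_ped(P, state, rf, lattice)
        for alpha in lattice.atoms:
            acc[alpha] += p * local[alpha]
    return AtomTable(lattice, acc, P.variables)
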