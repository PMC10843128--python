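"""Generalized information decomposition (GID).

Decomposes the Kullback-Leibler divergence D(P || Q) between an arbitrary
prior Q and posterior P over the redundancy lattice: each atom receives the
expected difference, under the posterior, between the local partial-entropy
atoms computed against the prior and against the posterior. The atoms sum to
D(P || Q) but — unlike the total — individual atoms may be negative: a
negative atom marks information that was "lost" in the belief update (the
observer holding the posterior would be *more* surprised by that combination
of sources than one holding the prior).

The cross-entropy decomposition aggregates the prior's local partial-entropy
atoms under the posterior's weights, so that, atomwise,
cross-entropy table = GID table + expected PED of the posterior.
"""

from __future__ import annotations

from typing import Sequence

from .distributions import (
    JointDistribution,
    Realization,
    _as_state,
    _check_same_space,
    apply_support_policy,
)
from .lattice import AtomTable, RedundancyLattice, build_lattice
from .ped import RedundancyFunction, h_min, local_ped


def local_gid(
    P: JointDistribution,
    Q: JointDistribution,
    x: "Realization | Sequence",
    rf: RedundancyFunction = h_min,
    lattice: RedundancyLattice | None = None,
) -> AtomTable:
    """Atomwise difference local_ped(Q, x) - local_ped(P, x) for a single
    outcome ``x`` in the support of both distributions. The atom sum equals
    hQ(x) - hP(x) = log2 [P(x)/Q(x)]."""
    _check_same_space(P, Q)
    state = _as_state(x)
    if lattice is None:
        lattice = build_lattice(P.n_variables)
    return local_ped(Q, state, rf, lattice) - local_ped(P, state, rf, lattice)


def gid(
    P: JointDistribution,
    Q: JointDistribution,
    rf: RedundancyFunction = h_min,
    policy: str = "strict",
    eps: float = 1e-6,
) -> AtomTable:
    """Decompose D(P || Q) into redundancy-lattice atoms.

    Parameters
    ----------
    P, Q:
        Posterior and prior over identical variable lists and alphabets.
        Alignment is by state tuple, never by row order.
    rf:
        Localizable redundancy function (default h_min).
    policy, eps:
        Support policy reconciling supp(P) with supp(Q); the default is
        strict (mismatches raise) because both pseudocount and restrict bias
        the divergence. Expectation weights come exclusively from P over
        supp(P); prior-only states carry zero weight.
    """
    _check_same_space(P, Q)
    P, Q = apply_support_policy(P, Q, policy, eps)
    lattice = build_lattice(P.n_variables)
    acc = {alpha: 0.0 for alpha in lattice.atoms}
    for state, p in P.pmf.items():
        local = local_gid(P, Q, state, rf, lattice)
        for alpha in lattice.atoms:
            acc[alpha] += p * local[alpha]
    return AtomTable(lattice, acc, P.variables)


def cross_entropy_decomposition(
    P: JointDistribution,
    Q: JointDistribution,
    rf: RedundancyFunction = h_min,
    policy: str = "strict",
    eps: float = 1e-6,
) -> AtomTable:
    """Decompose the cross entropy E_P[-log2 Q(x)]: the prior's local
    partial-entropy tables, aggregated across states with the posterior's
    probabilities. In a learning setting this is a "partial loss
    decomposition" over the feature combinations."""
    _check_same_space(P, Q)
    P, Q = apply_support_policy(P, Q, policy, eps)
    lattice = build_lattice(P.n_variables)
    acc = {alpha: 0.0 for alpha in lattice.atoms}
    for state, p in P.pmf.items():
        local = local_ped(Q, state, rf, lattice)
        for alpha in lattice.atoms:
            acc[alpha] += p * local[alpha]
    return AtomTable(lattice, acc, P.variables)
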