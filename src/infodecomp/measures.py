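"""Derived decompositions and identities.

Special cases of the generalized information decomposition obtained by fixing
the prior:

- total correlation   TC(X) = D(P || product of marginals),
- negentropy          D(P || uniform over the declared alphabets),
- single-target mutual information, recovered either as an expectation of
  conditional-vs-marginal divergences over the target (the classic
  redundancy/unique/synergy decomposition) or as one joint divergence on the
  full lattice (an 18-atom decomposition for two inputs and one target).

Also the two total-correlation-derived summary statistics — the O-information
(redundancy- vs synergy-dominance) and the Tononi-Sporns-Edelman (TSE)
integration/segregation complexity — each computed both directly from subset
total correlations and as a fixed linear combination of the 18 partial-TC
atoms at n=3.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

from .distributions import (
    JointDistribution,
    condition,
    kl_divergence,
    marginalize,
    product_of_marginals,
    uniform_prior,
)
from .gid import gid
from .lattice import AtomTable, build_lattice
from .ped import RedundancyFunction, h_min


def total_correlation(P: JointDistribution) -> float:
    """TC(X) = D(P(X) || prod_i P(X_i)): the deviation of the joint from the
    maximum-entropy model with the same marginals. Zero iff the variables are
    independent; equals sum_i H(X_i) - H(X) in bits."""
    return kl_divergence(P, product_of_marginals(P))


def tc_decomposition(P: JointDistribution, rf: RedundancyFunction = h_min) -> AtomTable:
    """Partial total correlation: the GID with the product-of-marginals
    prior. That prior always covers supp(P), so no support policy is needed;
    the atoms sum to TC(P)."""
    return gid(P, product_of_marginals(P), rf)


def negentropy_decomposition(
    P: JointDistribution, rf: RedundancyFunction = h_min
) -> AtomTable:
    """GID against the uniform prior on the full alphabet product; the atoms
    sum to the negentropy sum_i log2 |A_i| - H(P)."""
    return gid(P, uniform_prior(P), rf)


# -- O-information -------------------------------------------------------


def o_information(P: JointDistribution) -> float:
    """O-information of a system of n >= 3 variables:

        Omega(X) = (2 - n) TC(X) + sum_i TC(X without X_i)

    Positive values indicate redundancy-dominated structure, negative values
    synergy-dominated structure."""
    n = P.n_variables
    if n < 3:
        raise ValueError(f"O-information needs at least 3 variables, got {n}")
    tc_full = total_correlation(P)
    loo = [
        total_correlation(marginalize(P, [j for j in range(n) if j != i]))
        for i in range(n)
    ]
    return (2 - n) * tc_full + math.fsum(loo)


# Coefficients of the partial-TC atoms in the three-variable expansion of the
# O-information, keyed by canonical atom label. Bivariate single-source atoms
# carry coefficient zero: the O-information is blind to pairwise dependency,
# and only the top (triple-synergy) atom ever counts towards synergy.
O_INFORMATION_COEFFS_3 = {
    "{X1}{X2}{X3}": 2.0,
    "{X1}{X2}": 2.0,
    "{X1}{X3}": 2.0,
    "{X2}{X3}": 2.0,
    "{X1}{X2,X3}": 2.0,
    "{X2}{X1,X3}": 2.0,
    "{X3}{X1,X2}": 2.0,
    "{X1}": 1.0,
    "{X2}": 1.0,
    "{X3}": 1.0,
    "{X1,X2}{X1,X3}{X2,X3}": 2.0,
    "{X1,X2}{X1,X3}": 1.0,
    "{X1,X2}{X2,X3}": 1.0,
    "{X1,X3}{X2,X3}": 1.0,
    "{X1,X2}": 0.0,
    "{X1,X3}": 0.0,
    "{X2,X3}": 0.0,
    "{X1,X2,X3}": -1.0,
}

# Coefficients of the partial-TC atoms in the three-variable expansion of the
# TSE complexity. Atoms low on the lattice (widely shared information) are
# penalized in 1/3 increments, atoms high on the lattice rewarded, with the
# triple synergy contributing fully.
TSE_COEFFS_3 = {
    "{X1}{X2}{X3}": -1.0,
    "{X1}{X2}": -2.0 / 3.0,
    "{X1}{X3}": -2.0 / 3.0,
    "{X2}{X3}": -2.0 / 3.0,
    "{X1}{X2,X3}": -1.0 / 3.0,
    "{X2}{X1,X3}": -1.0 / 3.0,
    "{X3}{X1,X2}": -1.0 / 3.0,
    "{X1}": 0.0,
    "{X2}": 0.0,
    "{X3}": 0.0,
    "{X1,X2}{X1,X3}{X2,X3}": 0.0,
    "{X1,X2}{X1,X3}": 1.0 / 3.0,
    "{X1,X2}{X2,X3}": 1.0 / 3.0,
    "{X1,X3}{X2,X3}": 1.0 / 3.0,
    "{X1,X2}": 2.0 / 3.0,
    "{X1,X3}": 2.0 / 3.0,
    "{X2,X3}": 2.0 / 3.0,
    "{X1,X2,X3}": 1.0,
}


def _combine_atoms_3(tc_atoms: AtomTable, coeffs: dict[str, float]) -> float:
    if tc_atoms.lattice.n_variables != 3:
        raise ValueError(
            f"atom-combination coefficients are defined for 3 variables, "
            f"table has {tc_atoms.lattice.n_variables}"
        )
    default = build_lattice(3)
    return math.fsum(
        coeffs[atom.label()] * tc_atoms[atom] for atom in default.atoms
    )


def o_information_from_atoms(tc_atoms: AtomTable) -> float:
    """The O-information as a linear combination of the 18 partial-TC atoms
    of a three-variable system. Exact for the product-of-marginals prior,
    whatever localizable redundancy function produced the atoms."""
    return _combine_atoms_3(tc_atoms, O_INFORMATION_COEFFS_3)


# -- TSE complexity -------------------------------------------------------


def tse_complexity(P: JointDistribution) -> float:
    """TSE(X) = sum_{i=1}^{n} [ (i/n) TC(X) - <TC over size-i subsets> ].

    High when subsets look independent on average while the whole system
    deviates strongly from independence. The total correlation of a single
    variable is zero (its product-of-marginals prior is itself), so size-1
    subsets contribute only the (1/n) TC(X) term.
    """
    n = P.n_variables
    if n < 2:
        raise ValueError(f"TSE complexity needs at least 2 variables, got {n}")
    tc_full = total_correlation(P)
    out = 0.0
    for i in range(1, n + 1):
        subs = list(itertools.combinations(range(n), i))
        mean_tc = math.fsum(
            total_correlation(marginalize(P, s)) if len(s) > 1 else 0.0 for s in subs
        ) / len(subs)
        out += (i / n) * tc_full - mean_tc
    return out


def tse_from_atoms(tc_atoms: AtomTable) -> float:
    """The TSE complexity as a linear combination of the 18 partial-TC atoms
    of a three-variable system."""
    return _combine_atoms_3(tc_atoms, TSE_COEFFS_3)


# -- single-target mutual information -------------------------------------


def pid_single_target(
    P: JointDistribution,
    target_index: int,
    rf: RedundancyFunction = h_min,
) -> AtomTable:
    """Classic single-target partial information decomposition recovered from
    the GID:

        I(inputs; T) = E_T[ D( P(inputs | T=t) || P(inputs) ) ]

    Each conditional-vs-marginal divergence is decomposed on the *input*
    lattice and the atoms averaged under P(T). Atoms sum to I(inputs; T) and
    the down-set sums at single-input atoms reproduce the per-input mutual
    informations (redundancy + unique_i = I(X_i; T)). With h_min the result
    matches the pointwise informative/misinformative (I±) decomposition, so
    individual atoms can be negative.

    Target values of zero probability are excluded from the support at
    construction and therefore carry zero weight.
    """
    target_index = int(target_index)
    n = P.n_variables
    if not (0 <= target_index < n):
        raise ValueError(f"target index {target_index} out of range")
    inputs = [i for i in range(n) if i != target_index]
    if len(inputs) not in (2, 3):
        raise ValueError(f"single-target decomposition supports 2 or 3 inputs, got {len(inputs)}")
    prior = marginalize(P, inputs)
    lattice = build_lattice(len(inputs))
    acc = AtomTable.zeros(lattice, prior.variables)
    for (t,), pt in P.marginal_probs((target_index,)).items():
        posterior = condition(P, target_index, t)
        acc = acc + pt * gid(posterior, prior, rf)
    return acc


def mi_joint_decomposition(
    P: JointDistribution,
    target_index: int,
    rf: RedundancyFunction = h_min,
) -> AtomTable:
    """Alternative mutual-information decomposition on the *full* lattice:

        I(inputs; T) = D( P(inputs, T) || P(inputs) x P(T) )

    decomposed by the GID over all inputs+target atoms (18 atoms for two
    inputs and one target). The atoms still sum to I(inputs; T), but there is
    no known linear bridge between these atoms and the four atoms of
    :func:`pid_single_target`."""
    target_index = int(target_index)
    n = P.n_variables
    if not (0 <= target_index < n):
        raise ValueError(f"target index {target_index} out of range")
    inputs = [i for i in range(n) if i != target_index]
    inputs_marg = P.marginal_probs(tuple(inputs))
    target_marg = P.marginal_probs((target_index,))
    pmf: dict[tuple, float] = {}
    for in_state, p_in in inputs_marg.items():
        for (t,), p_t in target_marg.items():
            state = [None] * n
            for pos, i in enumerate(inputs):
                state[i] = in_state[pos]
            state[target_index] = t
            pmf[tuple(state)] = p_in * p_t
    Q = JointDistribution(P.variables, P.alphabets, pmf, normalize=True)
    return gid(P, Q, rf)
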