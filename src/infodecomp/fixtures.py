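"""Deterministic generators for reference distributions.

Logic gates with equiprobable binary inputs, uniform and giant-bit
distributions, seeded Dirichlet-random distributions, and the harness that
reproduces the reference three-column decomposition of the XOR system
(expected PED of the maximum-entropy prior, expected PED of the XOR
distribution, and the partial total correlation between them).

Binary symbols are rendered as the strings "0"/"1" so that the file dialects
round-trip exactly.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from .distributions import JointDistribution, uniform_prior
from .lattice import Antichain, AtomTable
from .measures import tc_decomposition
from .ped import RedundancyFunction, expected_ped, h_min

_GATES = {
    "XOR": lambda a, b: a ^ b,
    "AND": lambda a, b: a & b,
    "OR": lambda a, b: a | b,
    "COPY": lambda a, b: a,
}


def logic_gate(gate: str) -> JointDistribution:
    """Three binary variables (X1, X2, T): equiprobable inputs and a
    deterministic target T = gate(X1, X2). COPY sets T identical to X1."""
    try:
        fn = _GATES[gate.upper()]
    except KeyError:
        raise ValueError(f"unknown gate {gate!r}; choose from {sorted(_GATES)}") from None
    pmf = {
        (str(a), str(b), str(fn(a, b))): 0.25
        for a in (0, 1)
        for b in (0, 1)
    }
    return JointDistribution(("X1", "X2", "T"), (("0", "1"),) * 3, pmf)


def uniform(n: int, alphabet_size: int = 2) -> JointDistribution:
    """Maximum-entropy distribution: all alphabet_size**n states equiprobable."""
    if n < 1 or alphabet_size < 2:
        raise ValueError("need n >= 1 variables and an alphabet of size >= 2")
    alphabet = tuple(str(k) for k in range(alphabet_size))
    p = 1.0 / alphabet_size**n
    pmf = {state: p for state in itertools.product(alphabet, repeat=n)}
    return JointDistribution(
        [f"X{i + 1}" for i in range(n)], (alphabet,) * n, pmf, normalize=True
    )


def giant_bit(n: int = 3) -> JointDistribution:
    """All n variables copy one fair bit: two states (all-0, all-1) at one
    half each — the canonical redundancy extreme."""
    if n < 2:
        raise ValueError("a giant bit needs at least 2 variables")
    pmf = {("0",) * n: 0.5, ("1",) * n: 0.5}
    return JointDistribution(
        [f"X{i + 1}" for i in range(n)], (("0", "1"),) * n, pmf
    )


def random_distribution(
    n: int,
    alphabet_size: int = 2,
    seed: int | None = None,
    concentration: float = 1.0,
) -> JointDistribution:
    """Joint pmf drawn from a symmetric Dirichlet over all states.

    ``seed`` is mandatory (no hidden global randomness); the same seed always
    yields the same pmf. Large concentrations approach the uniform
    distribution; states whose mass falls below the zero tolerance are
    dropped and the rest renormalized.
    """
    if seed is None:
        raise ValueError("random_distribution requires an explicit seed")
    if concentration <= 0:
        raise ValueError("Dirichlet concentration must be positive")
    rng = np.random.default_rng(seed)
    alphabet = tuple(str(k) for k in range(alphabet_size))
    states = list(itertools.product(alphabet, repeat=n))
    probs = rng.dirichlet([concentration] * len(states))
    pmf = {s: float(p) for s, p in zip(states, probs)}
    return JointDistribution(
        [f"X{i + 1}" for i in range(n)], (alphabet,) * n, pmf, normalize=True
    )


#: row order of the reference XOR report (names X1, X2, T)
TABLE1_ATOM_ORDER: tuple[Antichain, ...] = tuple(
    Antichain(srcs)
    for srcs in [
        [(0,), (1,), (2,)],
        [(0,), (1,)],
        [(0,), (2,)],
        [(1,), (2,)],
        [(0,), (1, 2)],
        [(1,), (0, 2)],
        [(2,), (0, 1)],
        [(0,)],
        [(1,)],
        [(2,)],
        [(0, 1), (0, 2), (1, 2)],
        [(0, 1), (0, 2)],
        [(0, 1), (1, 2)],
        [(0, 2), (1, 2)],
        [(0, 1)],
        [(0, 2)],
        [(1, 2)],
        [(0, 1, 2)],
    ]
)


def reproduce_table1(
    rf: RedundancyFunction = h_min,
) -> tuple[AtomTable, AtomTable, AtomTable]:
    """The reference XOR worked example, as three 18-atom tables:

    1. expected PED of the maximum-entropy distribution Q on (X1, X2, T),
    2. expected PED of the XOR distribution P (T = X1 xor X2, equiprobable
       inputs),
    3. the partial total correlation of P (the GID from Q to P).

    Use :data:`TABLE1_ATOM_ORDER` to iterate the rows in the reference order.
    """
    xor = logic_gate("XOR")
    q = uniform_prior(xor)
    return expected_ped(q, rf), expected_ped(xor, rf), tc_decomposition(xor, rf)


def table1_frame(rf: RedundancyFunction = h_min):
    """The worked example as a pandas DataFrame with columns
    (atom, H_Q, H_P, TC), rows in the reference order."""
    import pandas as pd

    h_q, h_p, tc = reproduce_table1(rf)
    names = h_p.names
    return pd.DataFrame(
        {
            "atom": [a.label(names) for a in TABLE1_ATOM_ORDER],
            "H_Q": [h_q[a] for a in TABLE1_ATOM_ORDER],
            "H_P": [h_p[a] for a in TABLE1_ATOM_ORDER],
            "TC": [tc[a] for a in TABLE1_ATOM_ORDER],
        }
    )
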