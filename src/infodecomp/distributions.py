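"""Discrete joint-distribution algebra.

Joint probability mass functions over small sets of named, finite-alphabet
variables, together with the primitive information-theoretic quantities the
rest of the package is built from: marginalization, conditioning,
product-of-marginals and uniform priors, local surprisal, Shannon entropy and
the Kullback-Leibler (KL) divergence.

All information quantities are reported in bits (logarithm base 2).
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Hashable, Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

Symbol = Hashable
State = tuple

#: absolute tolerance below which a probability is treated as exactly zero
PROB_ATOL = 1e-15
#: tolerance on the total mass at construction time
NORM_ATOL = 1e-12
#: looser tolerance applied when ingesting distributions from files
INGEST_ATOL = 1e-6


class InvalidDistributionError(ValueError):
    """The supplied state table does not describe a valid distribution."""


class SupportError(ValueError):
    """A state (or conditioning value) has zero probability where positive
    probability is required, e.g. supp(P) is not contained in supp(Q)."""


@dataclass(frozen=True)
class Realization:
    """A single outcome: one symbol per variable (or per projected variable).

    Most functions in this package also accept a bare tuple wherever a
    :class:`Realization` is expected.
    """

    state: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "state", tuple(self.state))

    def __iter__(self):
        return iter(self.state)

    def __len__(self) -> int:
        return len(self.state)

    def project(self, subset: Sequence[int]) -> "Realization":
        return Realization(tuple(self.state[i] for i in subset))


def _as_state(x: "Realization | Sequence[Symbol]") -> tuple:
    return x.state if isinstance(x, Realization) else tuple(x)


class JointDistribution:
    """A joint pmf over named variables with finite alphabets.

    Parameters
    ----------
    variables:
        Ordered variable names. Order is significant and preserved; subsets
        of variables are always communicated as index lists against it.
    alphabets:
        Per-variable symbol sets, aligned with ``variables``. If omitted, the
        alphabet of each variable is inferred as the sorted set of symbols
        observed in the support.
    pmf:
        Mapping from full state tuples to probabilities. States with
        probability within ``PROB_ATOL`` of zero are dropped from the stored
        support; probabilities must sum to one within ``NORM_ATOL`` (or
        ``INGEST_ATOL`` when ``normalize=True``, in which case the pmf is
        renormalized).
    """

    __slots__ = ("variables", "alphabets", "pmf", "_marginal_cache")

    def __init__(
        self,
        variables: Sequence[str],
        alphabets: Sequence[Sequence[Symbol]] | None,
        pmf: Mapping[tuple, float],
        *,
        normalize: bool = False,
    ) -> None:
        variables = tuple(str(v) for v in variables)
        if len(set(variables)) != len(variables) or not variables:
            raise InvalidDistributionError("variable names must be nonempty and unique")

        cleaned: dict[tuple, float] = {}
        for state, p in pmf.items():
            state = tuple(state)
            p = float(p)
            if p < -PROB_ATOL:
                raise InvalidDistributionError(f"negative probability {p} for state {state!r}")
            if p <= PROB_ATOL:
                continue
            if len(state) != len(variables):
                raise InvalidDistributionError(
                    f"state {state!r} has arity {len(state)}, expected {len(variables)}"
                )
            if state in cleaned:
                raise InvalidDistributionError(f"duplicate state {state!r}")
            cleaned[state] = p
        if not cleaned:
            raise InvalidDistributionError("distribution has empty support")

        total = math.fsum(cleaned.values())
        tol = INGEST_ATOL if normalize else NORM_ATOL
        if abs(total - 1.0) > tol:
            raise InvalidDistributionError(f"probabilities sum to {total}, not 1")
        if abs(total - 1.0) > NORM_ATOL:
            logger.warning("pmf summed to %.12g; renormalizing", total)
        if total != 1.0:
            cleaned = {s: p / total for s, p in cleaned.items()}

        if alphabets is None:
            alphabets = [
                tuple(sorted({s[i] for s in cleaned}, key=str))
                for i in range(len(variables))
            ]
        alphabets = tuple(tuple(a) for a in alphabets)
        if len(alphabets) != len(variables):
            raise InvalidDistributionError("need one alphabet per variable")
        for i, alpha in enumerate(alphabets):
            if len(set(alpha)) != len(alpha) or not alpha:
                raise InvalidDistributionError(f"alphabet of {variables[i]!r} must be nonempty and unique")
        for state in cleaned:
            for i, sym in enumerate(state):
                if sym not in alphabets[i]:
                    raise InvalidDistributionError(
                        f"symbol {sym!r} not in alphabet of variable {variables[i]!r}"
                    )

        object.__setattr__(self, "variables", variables)
        object.__setattr__(self, "alphabets", alphabets)
        object.__setattr__(self, "pmf", cleaned)
        object.__setattr__(self, "_marginal_cache", {})

    def __setattr__(self, name: str, value: Any) -> None:  # pragma: no cover
        raise AttributeError("JointDistribution is immutable")

    # -- basic queries ---------------------------------------------------

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    def support(self) -> Iterable[tuple]:
        return self.pmf.keys()

    def prob(self, state: "Realization | Sequence[Symbol]") -> float:
        return self.pmf.get(_as_state(state), 0.0)

    def index_of(self, variable: str) -> int:
        try:
            return self.variables.index(variable)
        except ValueError:
            raise KeyError(f"unknown variable {variable!r}") from None

    def marginal_probs(self, subset: Sequence[int]) -> Mapping[tuple, float]:
        """Marginal pmf over ``subset`` (indices, in the given order), cached."""
        key = tuple(subset)
        _validate_subset(self, key)
        cached = self._marginal_cache.get(key)
        if cached is None:
            cached = {}
            for state, p in self.pmf.items():
                proj = tuple(state[i] for i in key)
                cached[proj] = cached.get(proj, 0.0) + p
            self._marginal_cache[key] = cached
        return cached

    def same_space(self, other: "JointDistribution") -> bool:
        return self.variables == other.variables and self.alphabets == other.alphabets

    def allclose(self, other: "JointDistribution", atol: float = 1e-12) -> bool:
        if not self.same_space(other):
            return False
        states = set(self.pmf) | set(other.pmf)
        return all(abs(self.prob(s) - other.prob(s)) <= atol for s in states)

    def __repr__(self) -> str:
        return (
            f"JointDistribution(variables={self.variables!r}, "
            f"support={len(self.pmf)} states)"
        )


def _validate_subset(P: JointDistribution, subset: Sequence[int]) -> None:
    if len(subset) == 0:
        raise ValueError("variable subset must be nonempty")
    if len(set(subset)) != len(subset):
        raise ValueError(f"variable subset {subset!r} has duplicates")
    for i in subset:
        if not (0 <= int(i) < P.n_variables):
            raise ValueError(f"variable index {i} out of range for {P.n_variables} variables")


# -- structural operations ----------------------------------------------


def marginalize(P: JointDistribution, subset: Sequence[int]) -> JointDistribution:
    """Project ``P`` onto the variables at ``subset`` (order preserved as given)."""
    subset = tuple(int(i) for i in subset)
    probs = P.marginal_probs(subset)
    return JointDistribution(
        [P.variables[i] for i in subset],
        [P.alphabets[i] for i in subset],
        dict(probs),
    )


def condition(P: JointDistribution, index: int, value: Symbol) -> JointDistribution:
    """Condition on ``variables[index] == value``; returns a distribution over
    the remaining variables. Conditioning on a zero-probability value is a
    :class:`SupportError`."""
    index = int(index)
    _validate_subset(P, (index,))
    pv = P.marginal_probs((index,)).get((value,), 0.0)
    if pv <= PROB_ATOL:
        raise SupportError(
            f"cannot condition on {P.variables[index]}={value!r}: zero marginal probability"
        )
    rest = [i for i in range(P.n_variables) if i != index]
    pmf = {
        tuple(state[i] for i in rest): p / pv
        for state, p in P.pmf.items()
        if state[index] == value
    }
    return JointDistribution(
        [P.variables[i] for i in rest], [P.alphabets[i] for i in rest], pmf
    )


def product_of_marginals(P: JointDistribution) -> JointDistribution:
    """The maximum-entropy distribution preserving every single-variable
    marginal of ``P`` — the implicit prior of the total correlation."""
    marginals = [P.marginal_probs((i,)) for i in range(P.n_variables)]
    pmf: dict[tuple, float] = {}
    for combo in itertools.product(*(m.items() for m in marginals)):
        state = tuple(kv[0][0] for kv in combo)
        p = math.prod(kv[1] for kv in combo)
        if p > PROB_ATOL:
            pmf[state] = p
    return JointDistribution(P.variables, P.alphabets, pmf, normalize=True)


def uniform_prior(P: JointDistribution) -> JointDistribution:
    """Uniform distribution over the full Cartesian product of ``P``'s
    declared alphabets (the maximum-entropy prior of the negentropy)."""
    n_states = math.prod(len(a) for a in P.alphabets)
    p = 1.0 / n_states
    pmf = {state: p for state in itertools.product(*P.alphabets)}
    return JointDistribution(P.variables, P.alphabets, pmf, normalize=True)


# -- information primitives ----------------------------------------------


def local_surprisal(
    P: JointDistribution,
    x: "Realization | Sequence[Symbol]",
    subset: Sequence[int] | None = None,
) -> float:
    """h(x) = -log2 P(x), optionally of the projection of ``x`` onto
    ``subset``. ``x`` must be a full state; the projection is taken here."""
    state = _as_state(x)
    if len(state) != P.n_variables:
        raise ValueError(f"state {state!r} has arity {len(state)}, expected {P.n_variables}")
    if subset is None:
        subset = tuple(range(P.n_variables))
    else:
        subset = tuple(int(i) for i in subset)
    proj = tuple(state[i] for i in subset)
    p = P.marginal_probs(subset).get(proj, 0.0)
    if p <= PROB_ATOL:
        names = ",".join(P.variables[i] for i in subset)
        raise SupportError(f"state ({names})={proj!r} has zero probability")
    return -math.log2(p)


def shannon_entropy(P: JointDistribution) -> float:
    """H(P) = E_P[-log2 P(x)], in bits."""
    return -math.fsum(p * math.log2(p) for p in P.pmf.values())


def cross_entropy(P: JointDistribution, Q: JointDistribution) -> float:
    """E_P[-log2 Q(x)]; requires supp(P) within supp(Q)."""
    _check_same_space(P, Q)
    acc = []
    for state, p in P.pmf.items():
        q = Q.prob(state)
        if q <= PROB_ATOL:
            raise SupportError(f"state {state!r} has positive P but zero Q probability")
        acc.append(-p * math.log2(q))
    return math.fsum(acc)


def kl_divergence(P: JointDistribution, Q: JointDistribution) -> float:
    """D(P || Q) = sum_x P(x) log2 [P(x)/Q(x)], the information gained when
    updating from the prior ``Q`` to the posterior ``P``. Requires that the
    support of ``P`` is contained in the support of ``Q``."""
    _check_same_space(P, Q)
    acc = []
    for state, p in P.pmf.items():
        q = Q.prob(state)
        if q <= PROB_ATOL:
            raise SupportError(f"state {state!r} has positive P but zero Q probability")
        acc.append(p * math.log2(p / q))
    return math.fsum(acc)


def _check_same_space(P: JointDistribution, Q: JointDistribution) -> None:
    if not P.same_space(Q):
        raise InvalidDistributionError(
            "distributions must share identical variable lists and alphabets"
        )


# -- support policies ----------------------------------------------------

SUPPORT_POLICIES = ("strict", "pseudocount", "restrict")


def apply_support_policy(
    P: JointDistribution,
    Q: JointDistribution,
    policy: str = "strict",
    eps: float = 1e-6,
) -> tuple[JointDistribution, JointDistribution]:
    """Reconcile the supports of a posterior ``P`` and prior ``Q`` ahead of a
    KL-divergence computation.

    strict
        Raise :class:`SupportError` if any state has P(x) > 0 but Q(x) = 0;
        otherwise return the inputs unchanged.
    pseudocount
        Add ``eps`` to Q on every state of the full alphabet product and
        renormalize Q. Biased: the inflated prior surprisal of the previously
        impossible states can dominate the divergence.
    restrict
        Drop states of P outside supp(Q) and renormalize P. Also biased:
        probability mass of P is discarded.
    """
    _check_same_space(P, Q)
    if policy == "strict":
        missing = [s for s in P.support() if Q.prob(s) <= PROB_ATOL]
        if missing:
            raise SupportError(
                f"supp(P) not contained in supp(Q); e.g. state {missing[0]!r} "
                "(strict policy)"
            )
        return P, Q
    if policy == "pseudocount":
        if not eps > 0:
            raise ValueError(f"pseudocount eps must be > 0, got {eps}")
        pmf = {
            state: Q.prob(state) + eps
            for state in itertools.product(*Q.alphabets)
        }
        total = math.fsum(pmf.values())
        pmf = {s: p / total for s, p in pmf.items()}
        return P, JointDistribution(Q.variables, Q.alphabets, pmf)
    if policy == "restrict":
        kept = {s: p for s, p in P.pmf.items() if Q.prob(s) > PROB_ATOL}
        if not kept:
            raise SupportError("supports of P and Q are disjoint; cannot restrict")
        total = math.fsum(kept.values())
        kept = {s: p / total for s, p in kept.items()}
        return JointDistribution(P.variables, P.alphabets, kept), Q
    raise ValueError(f"unknown support policy {policy!r}; choose from {SUPPORT_POLICIES}")


# -- file dialects -------------------------------------------------------
#
# Tabular dialect: header row of variable names plus a final column "p";
# one row per state; symbols are strings. JSON dialect:
# {"variables": [...], "alphabets": {...}, "pmf": [{"state": [...], "p": ...}]}


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_table(path: str | Path) -> JointDistribution:
    """Read a distribution from TSV/CSV (by extension) or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return read_json(path)
    return read_tsv(path)


def read_tsv(path: str | Path) -> JointDistribution:
    path = Path(path)
    sep = _sep_for(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise InvalidDistributionError(f"{path}: empty distribution file")
    header = lines[0].split(sep)
    if len(header) < 2 or header[-1] != "p":
        raise InvalidDistributionError(
            f"{path}: header must list variable names followed by a final 'p' column"
        )
    variables = header[:-1]
    pmf: dict[tuple, float] = {}
    for ln in lines[1:]:
        cells = ln.split(sep)
        if len(cells) != len(header):
            raise InvalidDistributionError(f"{path}: malformed row {ln!r}")
        try:
            p = float(cells[-1])
        except ValueError:
            raise InvalidDistributionError(f"{path}: bad probability {cells[-1]!r}") from None
        state = tuple(cells[:-1])
        pmf[state] = pmf.get(state, 0.0) + p
    return JointDistribution(variables, None, pmf, normalize=True)


def write_tsv(P: JointDistribution, path: str | Path) -> None:
    path = Path(path)
    sep = _sep_for(path)
    rows = [sep.join([*P.variables, "p"])]
    for state in sorted(P.pmf, key=lambda s: tuple(map(str, s))):
        rows.append(sep.join([*(str(sym) for sym in state), repr(P.pmf[state])]))
    path.write_text("\n".join(rows) + "\n")


def read_json(path: str | Path) -> JointDistribution:
    with open(path) as fh:
        doc = json.load(fh)
    try:
        variables = list(doc["variables"])
        alphabets = [list(doc["alphabets"][v]) for v in variables]
        pmf = {tuple(entry["state"]): float(entry["p"]) for entry in doc["pmf"]}
    except (KeyError, TypeError) as exc:
        raise InvalidDistributionError(f"{path}: malformed JSON dialect ({exc})") from exc
    return JointDistribution(variables, alphabets, pmf, normalize=True)


def write_json(P: JointDistribution, path: str | Path) -> None:
    doc = {
        "variables": list(P.variables),
        "alphabets": {v: [str(s) for s in a] for v, a in zip(P.variables, P.alphabets)},
        "pmf": [
            {"state": [str(sym) for sym in state], "p": P.pmf[state]}
            for state in sorted(P.pmf, key=lambda s: tuple(map(str, s)))
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")
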