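"""Gating schemes for ligand-gated channels and their generator matrices.

A :class:`KineticScheme` is a declarative description of a continuous-time
Markov gating model: a set of named states (closed, open, desensitized or
deep-desensitized, each with 0-4 agonist molecules bound), a set of
reversible transitions carrying rate-constant names and statistical
multiplicities, the rate constants themselves, and a conductance rule.
Schemes are data, not code: the AMPA-receptor schemes used throughout the
package ("scheme 1", the full gating model with conducting desensitized
states, and "scheme 2", its desensitized-only restriction mimicking a
cross-linked receptor) ship as plain-text definition files and are loaded
with :func:`load_scheme`.

The generator (Q) matrix at a given glutamate concentration has off-diagonal
entries ``multiplicity * rate * (conc if binding step)`` and diagonal entries
set so that every row sums to zero; state occupancies evolve as
``dp/dt = p Q``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.sparse.csgraph import connected_components

__all__ = [
    "State",
    "Transition",
    "RateSet",
    "ConductanceModel",
    "KineticScheme",
    "SchemeConfigError",
    "MicroReversibilityError",
    "build_generator",
    "steady_state",
    "enforce_microscopic_reversibility",
    "restrict_to_desensitized",
    "load_scheme",
    "scheme1",
    "scheme2",
]

STATE_CLASSES = ("closed", "open", "desensitized", "deep_desensitized")
_DESENSITIZED = ("desensitized", "deep_desensitized")

RATE_NAMES = (
    "k1",
    "k_minus1",
    "alpha",
    "beta",
    "gamma1",
    "delta1",
    "gamma2",
    "delta2",
    "gamma0",
    "delta0",
    "k_minus2",
)


class SchemeConfigError(ValueError):
    """A scheme definition is malformed or internally inconsistent."""


class MicroReversibilityError(ValueError):
    """Cycle balance cannot be achieved by adjusting the free rate."""


@dataclass(frozen=True)
class State:
    """A single kinetic state.

    ``conductance_fraction`` is ``n_bound / 4`` for conducting states and 0
    otherwise; closed states never conduct, and only agonist-bound open or
    desensitized states do.
    """

    name: str
    n_bound: int
    state_class: str
    conducting: bool = field(default=None)  # type: ignore[assignment]
    conductance_fraction: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.state_class not in STATE_CLASSES:
            raise SchemeConfigError(
                f"state {self.name!r}: unknown class {self.state_class!r}"
            )
        if not 0 <= self.n_bound <= 4:
            raise SchemeConfigError(f"state {self.name!r}: n_bound must be 0-4")
        conducting = self.state_class != "closed" and self.n_bound > 0
        if self.conducting is None:
            object.__setattr__(self, "conducting", conducting)
        if self.state_class == "closed" and self.conducting:
            raise SchemeConfigError(f"closed state {self.name!r} cannot conduct")
        frac = self.n_bound / 4.0 if self.conducting else 0.0
        if self.conductance_fraction is None:
            object.__setattr__(self, "conductance_fraction", frac)
        elif abs(self.conductance_fraction - frac) > 1e-12:
            raise SchemeConfigError(
                f"state {self.name!r}: conductance_fraction must be "
                f"n_bound/4 for conducting states, 0 otherwise"
            )


@dataclass(frozen=True)
class Transition:
    """A directed transition ``source -> target``.

    ``multiplicity`` is the statistical factor (e.g. 4 for the first binding
    step of a receptor with four identical empty sites);
    ``concentration_dependent`` marks agonist-binding steps whose rate is
    multiplied by the free agonist concentration.
    """

    source: str
    target: str
    rate_name: str
    multiplicity: int = 1
    concentration_dependent: bool = False

    def __post_init__(self):
        if self.source == self.target:
            raise SchemeConfigError(f"self-transition on {self.source!r}")
        if self.multiplicity < 1:
            raise SchemeConfigError("multiplicity must be >= 1")


@dataclass
class RateSet:
    """The rate constants of the AMPA-receptor gating model.

    Units: ``k1`` in M^-1 s^-1 (association), everything else in s^-1.
    ``alpha``/``beta`` are channel closing/opening, ``delta``-named rates
    enter desensitization, ``gamma``-named rates leave it (the 0-suffixed
    pair governs the unliganded receptor), and ``k_minus2`` is glutamate
    dissociation within the desensitized rows.
    """

    k1: float = 1.3e6
    k_minus1: float = 350.0
    alpha: float = 3100.0
    beta: float = 1000.0
    gamma1: float = 88.0
    delta1: float = 110.0
    gamma2: float = 36.0
    delta2: float = 39.0
    gamma0: float = 8.0
    delta0: float = 0.48
    k_minus2: float = 870.0

    def __post_init__(self):
        for name in RATE_NAMES:
            if getattr(self, name) <= 0:
                raise SchemeConfigError(f"rate {name} must be strictly positive")

    def __getitem__(self, name: str) -> float:
        if name not in RATE_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in RATE_NAMES}


@dataclass
class ConductanceModel:
    """Occupancy-proportional unitary conductances.

    A fully occupied open state has conductance ``g_open_max`` (default
    3.9 pS) and a fully occupied desensitized state ``g_des_max`` (default
    670 fS); partially occupied conducting states scale as ``n_bound / 4``.
    """

    g_open_max: float = 3.9e-12
    g_des_max: float = 670e-15

    def __post_init__(self):
        if self.g_open_max < 0 or self.g_des_max < 0:
            raise SchemeConfigError("conductances must be non-negative")

    def unitary_conductance(self, state: State) -> float:
        if not state.conducting:
            return 0.0
        if state.state_class == "open":
            return state.conductance_fraction * self.g_open_max
        return state.conductance_fraction * self.g_des_max


@dataclass
class KineticScheme:
    states: list
    transitions: list
    rates: RateSet
    conductances: ConductanceModel
    name: str = "scheme"
    # Optional closed-form reversibility constraint: maps the other rates to
    # the constrained one, e.g. "k_minus2 = k_minus1*alpha*gamma1/(beta*delta1)".
    reversibility_constraint: str | None = None

    def __post_init__(self):
        names = [s.name for s in self.states]
        if len(set(names)) != len(names):
            raise SchemeConfigError("state names must be unique")
        self._index = {n: i for i, n in enumerate(names)}
        for t in self.transitions:
            for endpoint in (t.source, t.target):
                if endpoint not in self._index:
                    raise SchemeConfigError(f"transition endpoint {endpoint!r} undefined")
            if t.rate_name not in RATE_NAMES:
                raise SchemeConfigError(f"unknown rate name {t.rate_name!r}")
        if not self._connected(conc=1e-3):
            raise SchemeConfigError(f"scheme {self.name!r}: transition graph not connected")

    # -- basic introspection ------------------------------------------------

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def state_names(self) -> list:
        return [s.name for s in self.states]

    def state_index(self, name: str) -> int:
        return self._index[name]

    def states_of_class(self, *classes: str) -> list:
        return [s.name for s in self.states if s.state_class in classes]

    def conductance_vector(self) -> np.ndarray:
        """Unitary conductance (S) of each state, in state order."""
        return np.array([self.conductances.unitary_conductance(s) for s in self.states])

    def unitary_currents(self, voltage: float, reversal: float = 0.0) -> np.ndarray:
        return self.conductance_vector() * (voltage - reversal)

    def _connected(self, conc: float) -> bool:
        n = len(self.states)
        adj = np.zeros((n, n), dtype=bool)
        for t in self.transitions:
            if t.concentration_dependent and conc == 0:
                continue
            adj[self._index[t.source], self._index[t.target]] = True
        ncomp, _ = connected_components(adj, directed=True, connection="strong")
        return ncomp == 1

    # -- generator and stationary distribution ------------------------------

    def generator(self, conc: float) -> np.ndarray:
        return build_generator(self, conc)

    def stationary(self, conc: float) -> np.ndarray:
        return steady_state(self, conc)

    def constrained_k_minus2(self) -> float:
        """Evaluate the scheme's declared reversibility constraint for k_minus2.

        The shipped AMPA-receptor scheme fixes glutamate dissociation from
        desensitized receptors by balancing the monoliganded
        activation/desensitization/dissociation loop, which gives
        ``k_minus2 = k_minus1 * alpha * gamma1 / (beta * delta1)``.
        """
        if not self.reversibility_constraint:
            raise SchemeConfigError(f"scheme {self.name!r} declares no reversibility constraint")
        lhs, expr = [s.strip() for s in self.reversibility_constraint.split("=", 1)]
        if lhs != "k_minus2":
            raise SchemeConfigError("only k_minus2 constraints are supported")
        return _eval_rate_expression(expr, self.rates.as_dict())

    def with_rates(self, rates: RateSet) -> "KineticScheme":
        return replace(self, rates=rates)


def _eval_rate_expression(expr: str, rates: dict) -> float:
    if not re.fullmatch(r"[\w\s+\-*/().0-9eE]+", expr):
        raise SchemeConfigError(f"unsafe rate expression: {expr!r}")
    return float(eval(expr, {"__builtins__": {}}, dict(rates)))  # noqa: S307


def build_generator(scheme: KineticScheme, conc: float) -> np.ndarray:
    """Generator (Q) matrix of ``scheme`` at agonist concentration ``conc`` (M).

    Off-diagonal entry (i, j) is the total rate of i -> j transitions;
    diagonal entries are minus the row sums, so every row sums to zero.
    """
    if conc < 0:
        raise ValueError("concentration must be non-negative")
    n = scheme.n_states
    Q = np.zeros((n, n))
    idx = scheme._index
    rates = scheme.rates
    for t in scheme.transitions:
        rate = rates[t.rate_name] * t.multiplicity
        if t.concentration_dependent:
            rate *= conc
        Q[idx[t.source], idx[t.target]] += rate
    Q[np.diag_indices(n)] -= Q.sum(axis=1)
    return Q


def steady_state(scheme: KineticScheme, conc: float) -> np.ndarray:
    """Stationary occupancy vector at ``conc``, by null-space solve.

    Solves ``pi Q = 0`` with ``sum(pi) = 1``.  Raises if the chain is not
    irreducible at this concentration (the stationary distribution would not
    be unique), naming the unreachable states.
    """
    classes = _recurrent_classes(scheme, conc)
    if len(classes) != 1:
        raise SchemeConfigError(
            f"stationary distribution not unique at conc={conc!r}: "
            f"multiple closed communicating classes: {classes}"
        )
    Q = build_generator(scheme, conc)
    n = Q.shape[0]
    A = np.vstack([Q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def _recurrent_classes(scheme, conc):
    """Closed communicating classes at the given concentration, as name lists."""
    n = scheme.n_states
    adj = np.zeros((n, n), dtype=bool)
    for t in scheme.transitions:
        if t.concentration_dependent and conc == 0:
            continue
        adj[scheme._index[t.source], scheme._index[t.target]] = True
    ncomp, labels = connected_components(adj, directed=True, connection="strong")
    open_classes = set()
    for i in range(n):
        for j in range(n):
            if adj[i, j] and labels[i] != labels[j]:
                open_classes.add(labels[i])
    return [
        [scheme.state_names[i] for i in range(n) if labels[i] == c]
        for c in range(ncomp)
        if c not in open_classes
    ]


# -- microscopic reversibility ---------------------------------------------


def _reversible_edge_pairs(scheme: KineticScheme):
    """Map frozenset({a, b}) -> (fwd Transition, rev Transition)."""
    directed = {}
    for t in scheme.transitions:
        directed[(t.source, t.target)] = t
    pairs = {}
    for (a, b), t in directed.items():
        if (b, a) not in directed:
            raise MicroReversibilityError(
                f"transition {a} -> {b} has no reverse; cycle balance undefined"
            )
        key = frozenset((a, b))
        if key not in pairs:
            pairs[key] = (t, directed[(b, a)])
    return pairs


def _fundamental_cycles(scheme: KineticScheme):
    """Fundamental cycles (as state-name lists) of the undirected edge graph."""
    pairs = _reversible_edge_pairs(scheme)
    adjacency = {s: [] for s in scheme.state_names}
    for key in pairs:
        a, b = tuple(key)
        adjacency[a].append(b)
        adjacency[b].append(a)
    root = scheme.state_names[0]
    parent = {root: None}
    order = [root]
    seen = {root}
    qi = 0
    while qi < len(order):
        u = order[qi]
        qi += 1
        for v in adjacency[u]:
            if v not in seen:
                seen.add(v)
                parent[v] = u
                order.append(v)
    tree_edges = {frozenset((v, p)) for v, p in parent.items() if p is not None}
    cycles = []
    for key in pairs:
        if key in tree_edges:
            continue
        a, b = tuple(key)
        path_a = _path_to_root(a, parent)
        path_b = _path_to_root(b, parent)
        common = set(path_a) & set(path_b)
        ia = next(i for i, s in enumerate(path_a) if s in common)
        ib = next(i for i, s in enumerate(path_b) if s in common)
        # cycle: a .. ancestor .. b, then edge b-a closes it
        cycle = path_a[: ia + 1] + path_b[:ib][::-1]
        cycles.append(cycle)
    return cycles


def _path_to_root(node, parent):
    path = [node]
    while parent[path[-1]] is not None:
        path.append(parent[path[-1]])
    return path


def _cycle_balance(scheme, cycle, rates: dict, free_rate: str):
    """Return (power a, log-imbalance b) so that balance reads a*ln(x) + b = 0
    where x is the free rate value."""
    directed = {(t.source, t.target): t for t in scheme.transitions}
    a = 0
    b = 0.0
    m = len(cycle)
    for k in range(m):
        u, v = cycle[k], cycle[(k + 1) % m]
        fwd, rev = directed[(u, v)], directed[(v, u)]
        for t, sign in ((fwd, +1), (rev, -1)):
            if t.rate_name == free_rate:
                a += sign
                b += sign * math.log(t.multiplicity)
            else:
                b += sign * math.log(rates[t.rate_name] * t.multiplicity)
    return a, b


def enforce_microscopic_reversibility(
    scheme: KineticScheme, free_rate: str = "k_minus2", rtol: float = 1e-9
) -> RateSet:
    """Solve cycle balance for ``free_rate`` and return the balanced rate set.

    For every independent cycle of the scheme graph the product of rates one
    way round must equal the product the other way (binding steps contribute
    equally to both directions of any physical cycle, so concentration drops
    out).  Only ``free_rate`` is adjusted.  If two cycles imply conflicting
    values, or a cycle not involving ``free_rate`` is out of balance, a
    :class:`MicroReversibilityError` lists the offending cycles.
    """
    if free_rate not in RATE_NAMES:
        raise SchemeConfigError(f"unknown rate name {free_rate!r}")
    rates = scheme.rates.as_dict()
    cycles = _fundamental_cycles(scheme)
    solutions = []
    conflicts = []
    for cycle in cycles:
        a, b = _cycle_balance(scheme, cycle, rates, free_rate)
        if a == 0:
            if abs(b) > 1e-6:
                conflicts.append((cycle, None, b))
            continue
        solutions.append((cycle, math.exp(-b / a)))
    if not solutions and not conflicts:
        raise MicroReversibilityError(
            f"{free_rate!r} does not participate in any cycle of scheme {scheme.name!r}"
        )
    if solutions:
        values = [v for _, v in solutions]
        ref = values[0]
        for (cyc, v) in solutions[1:]:
            if abs(v - ref) > rtol * max(ref, v) + 1e-300:
                conflicts.append((cyc, v, None))
    if conflicts:
        lines = []
        for cyc, v, b in conflicts:
            if v is not None:
                lines.append(f"cycle {'-'.join(cyc)} implies {free_rate}={v:.6g}")
            else:
                lines.append(
                    f"cycle {'-'.join(cyc)} does not contain {free_rate} and has "
                    f"log-imbalance {b:.3g}"
                )
        ref = solutions[0][1] if solutions else None
        head = f"(first solution {free_rate}={ref:.6g}) " if ref is not None else ""
        raise MicroReversibilityError(
            f"cycle balance over-constrained in scheme {scheme.name!r} {head}:\n  "
            + "\n  ".join(lines)
        )
    value = solutions[0][1]
    return replace(scheme.rates, **{free_rate: value})


# -- desensitized-only restriction (cross-linked receptor) -------------------


def restrict_to_desensitized(scheme: KineticScheme) -> KineticScheme:
    """Restrict a scheme to its desensitized states.

    Mimics a receptor whose cysteine cross-link traps the ligand-binding
    domain dimer in the desensitized (relaxed-dimer) arrangement: closed and
    open states are removed, and only transitions among desensitized and
    deep-desensitized states (agonist binding within those rows, and
    entry/exit of the deep row) remain.  Applying the restriction twice is a
    no-op.
    """
    keep = {s.name for s in scheme.states if s.state_class in _DESENSITIZED}
    if not keep:
        raise SchemeConfigError("scheme has no desensitized states")
    states = [s for s in scheme.states if s.name in keep]
    transitions = [
        t for t in scheme.transitions if t.source in keep and t.target in keep
    ]
    name = scheme.name if scheme.name.endswith("-desensitized") else scheme.name + "-desensitized"
    try:
        return KineticScheme(
            states=states,
            transitions=transitions,
            rates=scheme.rates,
            conductances=scheme.conductances,
            name=name,
            reversibility_constraint=None,
        )
    except SchemeConfigError as exc:
        raise SchemeConfigError(f"desensitized restriction is disconnected: {exc}") from exc


# -- scheme definition files -------------------------------------------------


def load_scheme(source) -> KineticScheme:
    """Load a scheme from a definition file (path or text).

    The format is line-based with ``[section]`` headers::

        name = scheme1
        [rates]
        k1 = 1.3e6
        [states]
        C0 0 closed
        [transitions]
        C0 C1 k1 4 c
        [conductances]
        g_open_max = 3.9e-12
        [reversibility]
        k_minus2 = k_minus1 * alpha * gamma1 / (beta * delta1)

    In ``[transitions]`` the fields are source, target, rate name,
    multiplicity, and a flag (``c`` for concentration-dependent binding
    steps, ``-`` otherwise).
    """
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source):
        text = Path(source).read_text()
    else:
        text = str(source)
    section = None
    name = "scheme"
    rates = {}
    states = []
    transitions = []
    conduct = {}
    constraint = None
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1].strip().lower()
            if section not in ("rates", "states", "transitions", "conductances", "reversibility"):
                raise SchemeConfigError(f"line {lineno}: unknown section {section!r}")
            continue
        if section is None:
            key, _, value = line.partition("=")
            if key.strip() == "name":
                name = value.strip()
            else:
                raise SchemeConfigError(f"line {lineno}: unexpected content before sections")
        elif section == "rates":
            key, _, value = line.partition("=")
            rates[key.strip()] = float(value)
        elif section == "states":
            parts = line.split()
            if len(parts) != 3:
                raise SchemeConfigError(f"line {lineno}: states need 'name n_bound class'")
            states.append(State(parts[0], int(parts[1]), parts[2]))
        elif section == "transitions":
            parts = line.split()
            if len(parts) != 5:
                raise SchemeConfigError(
                    f"line {lineno}: transitions need 'source target rate mult flag'"
                )
            transitions.append(
                Transition(
                    source=parts[0],
                    target=parts[1],
                    rate_name=parts[2],
                    multiplicity=int(parts[3]),
                    concentration_dependent=parts[4].lower() == "c",
                )
            )
        elif section == "conductances":
            key, _, value = line.partition("=")
            conduct[key.strip()] = float(value)
        elif section == "reversibility":
            constraint = line
    try:
        rateset = RateSet(**rates)
    except TypeError as exc:
        raise SchemeConfigError(f"bad [rates] section: {exc}") from exc
    return KineticScheme(
        states=states,
        transitions=transitions,
        rates=rateset,
        conductances=ConductanceModel(**conduct),
        name=name,
        reversibility_constraint=constraint,
    )


def _packaged(filename: str) -> KineticScheme:
    text = resources.files("desensgate").joinpath("schemes", filename).read_text()
    return load_scheme(text)


def scheme1() -> KineticScheme:
    """The full AMPA-receptor gating scheme with conducting desensitized states."""
    return _packaged("scheme1.cfg")


def scheme2() -> KineticScheme:
    """The desensitized-only scheme (cross-linked receptor)."""
    return restrict_to_desensitized(scheme1())
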