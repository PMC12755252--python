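"""Reaction networks with a mix of instantaneous and delayed reactions.

A :class:`ReactionNetwork` is the static description consumed by the exact
delay stochastic simulation algorithm (:mod:`grnswitch.simulate`): an ordered
species list, an initial count vector and a list of :class:`Reaction` objects.
Each reaction carries a propensity (a declarative form plus parameters, so
that networks round-trip through plain config dictionaries and can be
compiled for the fast event loop), an integer state-change vector, and a
``delayed`` flag.  Delayed reactions are *non-consuming*: nothing happens at
initiation, the full state-change vector is applied at completion.  This is
the right convention for the networks shipped here, whose delayed reactions
are all catalytic production reactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "evaluate_propensities",
]

# Propensity forms understood by both the Python evaluator and the compiled
# event loop.  params/species usage:
#   constant      a(x) = k                                  params=(k,)
#   linear        a(x) = k * x[i]                           params=(k,), species=(i,)
#   dimerize      a(x) = k * x[i] * (x[i]-1) / 2            params=(k,), species=(i,)
#   bimolecular   a(x) = k * x[i] * x[j]                    params=(k,), species=(i, j)
#   hill_repress  a(x) = beta * kappa / (kappa + x[j]**2)   params=(beta, kappa), species=(j,)
#   hill_activate a(x) = alpha + beta*x[j]**b/(c**b+x[j]**b) params=(alpha, beta, b, c), species=(j,)
PROP_CONSTANT = 0
PROP_LINEAR = 1
PROP_DIMERIZE = 2
PROP_BIMOLECULAR = 3
PROP_HILL_REPRESS = 4
PROP_HILL_ACTIVATE = 5

_KIND_NAMES = {
    "constant": PROP_CONSTANT,
    "linear": PROP_LINEAR,
    "dimerize": PROP_DIMERIZE,
    "bimolecular": PROP_BIMOLECULAR,
    "hill_repress": PROP_HILL_REPRESS,
    "hill_activate": PROP_HILL_ACTIVATE,
}
_KIND_CODES = {v: k for k, v in _KIND_NAMES.items()}

_N_SPECIES_REQUIRED = {
    PROP_CONSTANT: 0,
    PROP_LINEAR: 1,
    PROP_DIMERIZE: 1,
    PROP_BIMOLECULAR: 2,
    PROP_HILL_REPRESS: 1,
    PROP_HILL_ACTIVATE: 1,
}
_N_PARAMS_REQUIRED = {
    PROP_CONSTANT: 1,
    PROP_LINEAR: 1,
    PROP_DIMERIZE: 1,
    PROP_BIMOLECULAR: 1,
    PROP_HILL_REPRESS: 2,
    PROP_HILL_ACTIVATE: 4,
}


def _propensity_value(kind: int, params: np.ndarray, species: np.ndarray, x: np.ndarray) -> float:
    if kind == PROP_CONSTANT:
        return params[0]
    if kind == PROP_LINEAR:
        return params[0] * x[species[0]]
    if kind == PROP_DIMERIZE:
        n = x[species[0]]
        return params[0] * n * (n - 1) / 2.0
    if kind == PROP_BIMOLECULAR:
        return params[0] * x[species[0]] * x[species[1]]
    if kind == PROP_HILL_REPRESS:
        beta, kappa = params[0], params[1]
        q = x[species[0]]
        return beta * kappa / (kappa + q * q)
    if kind == PROP_HILL_ACTIVATE:
        alpha, beta, b, c = params[0], params[1], params[2], params[3]
        q = x[species[0]]
        if q <= 0:
            return alpha
        u = (q / c) ** b
        return alpha + beta * u / (1.0 + u)
    raise ValueError(f"unknown propensity kind code {kind}")


@dataclass
class Reaction:
    """One channel of a reaction network.

    Parameters
    ----------
    name : str
        Human-readable label, e.g. ``"production_Q1"``.
    kind : str
        Propensity form; one of ``constant``, ``linear``, ``dimerize``,
        ``bimolecular``, ``hill_repress``, ``hill_activate``.
    params : tuple of float
        Rate parameters of the propensity form (see module notes).
    species : tuple of int
        Indices of the species entering the propensity.
    state_change : tuple of int
        Net change of each species count when the reaction completes.
    delayed : bool
        If True the state change is applied a random delay after firing.
    kernel_ref : str
        Name of the delay kernel used when ``delayed``; looked up in the
        kernel table passed to the simulator.
    """

    name: str
    kind: str
    params: tuple
    species: tuple
    state_change: tuple
    delayed: bool = False
    kernel_ref: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _KIND_NAMES:
            raise ValueError(f"unknown propensity kind {self.kind!r}")
        code = _KIND_NAMES[self.kind]
        if len(self.species) != _N_SPECIES_REQUIRED[code]:
            raise ValueError(
                f"{self.name}: kind {self.kind!r} needs "
                f"{_N_SPECIES_REQUIRED[code]} species index(es), got {len(self.species)}"
            )
        if len(self.params) != _N_PARAMS_REQUIRED[code]:
            raise ValueError(
                f"{self.name}: kind {self.kind!r} needs "
                f"{_N_PARAMS_REQUIRED[code]} parameter(s), got {len(self.params)}"
            )
        if any(not np.isfinite(p) for p in self.params):
            raise ValueError(f"{self.name}: non-finite propensity parameter")
        if self.delayed and not self.kernel_ref:
            raise ValueError(f"{self.name}: delayed reaction needs a kernel_ref")

    @property
    def kind_code(self) -> int:
        return _KIND_NAMES[self.kind]

    def propensity(self, x) -> float:
        """Evaluate the propensity at count vector ``x``."""
        return _propensity_value(
            self.kind_code,
            np.asarray(self.params, dtype=float),
            np.asarray(self.species, dtype=np.int64),
            np.asarray(x, dtype=float),
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "kind": self.kind,
            "params": list(self.params),
            "species": list(self.species),
            "state_change": list(self.state_change),
            "delayed": bool(self.delayed),
            "kernel_ref": self.kernel_ref,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Reaction":
        return cls(
            name=d["name"],
            kind=d["kind"],
            params=tuple(d["params"]),
            species=tuple(d["species"]),
            state_change=tuple(d["state_change"]),
            delayed=bool(d.get("delayed", False)),
            kernel_ref=d.get("kernel_ref", ""),
        )


@dataclass
class ReactionNetwork:
    """Species, reactions and initial state of a biochemical network."""

    species: list
    reactions: list
    initial_state: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.initial_state = np.asarray(self.initial_state, dtype=np.int64)
        if len(self.reactions) == 0:
            raise ValueError("network needs at least one reaction")
        if self.initial_state.shape != (len(self.species),):
            raise ValueError("initial_state length must match species list")
        if (self.initial_state < 0).any():
            raise ValueError("initial counts must be non-negative")
        j = len(self.species)
        for rx in self.reactions:
            if len(rx.state_change) != j:
                raise ValueError(
                    f"{rx.name}: state_change has length {len(rx.state_change)}, "
                    f"expected {j}"
                )
            if any(s >= j or s < 0 for s in rx.species):
                raise ValueError(f"{rx.name}: species index out of range")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_index(self, name: str) -> int:
        return self.species.index(name)

    def kernel_refs(self) -> list:
        """Names of kernels referenced by delayed reactions (deduplicated)."""
        seen: list = []
        for rx in self.reactions:
            if rx.delayed and rx.kernel_ref not in seen:
                seen.append(rx.kernel_ref)
        return seen

    # -- arrays consumed by the compiled event loop ---------------------

    def encode(self):
        """Pack propensity forms and state changes into flat arrays."""
        r, j = self.n_reactions, self.n_species
        kinds = np.zeros(r, dtype=np.int64)
        params = np.zeros((r, 4), dtype=np.float64)
        species = np.zeros((r, 2), dtype=np.int64)
        changes = np.zeros((r, j), dtype=np.int64)
        delayed = np.zeros(r, dtype=np.bool_)
        for i, rx in enumerate(self.reactions):
            kinds[i] = rx.kind_code
            params[i, : len(rx.params)] = rx.params
            species[i, : len(rx.species)] = rx.species
            changes[i] = rx.state_change
            delayed[i] = rx.delayed
        return kinds, params, species, changes, delayed

    def to_dict(self) -> dict:
        return {
            "species": list(self.species),
            "reactions": [rx.to_dict() for rx in self.reactions],
            "initial_state": [int(v) for v in self.initial_state],
            "metadata": dict(self.metadata),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReactionNetwork":
        return cls(
            species=list(d["species"]),
            reactions=[Reaction.from_dict(r) for r in d["reactions"]],
            initial_state=np.asarray(d["initial_state"], dtype=np.int64),
            metadata=dict(d.get("metadata", {})),
        )


def evaluate_propensities(network: ReactionNetwork, state) -> np.ndarray:
    """Propensity of every reaction at ``state``.

    ``state`` may be an integer count vector or a real (mean-field)
    concentration vector; the same algebraic forms are used in both cases.
    Values are clamped at zero (the combinatorial factor ``x(x-1)/2`` dips
    below zero for real ``x`` in (0, 1)).
    """
    x = np.asarray(state, dtype=float)
    if x.shape != (network.n_species,):
        raise ValueError(
            f"state has shape {x.shape}, expected ({network.n_species},)"
        )
    out = np.empty(network.n_reactions)
    for i, rx in enumerate(network.reactions):
        out[i] = _propensity_value(
            rx.kind_code,
            np.asarray(rx.params, dtype=float),
            np.asarray(rx.species, dtype=np.int64),
            x,
        )
    return np.maximum(out, 0.0)
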