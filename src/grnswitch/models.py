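"""Builders for three bistable gene regulatory networks.

* **Co-repressive toggle switch** — two genes whose products repress each
  other's production.  Production of each protein is delayed, dilution is
  instantaneous.  Propensities: ``beta*kappa/(kappa + Q_other**2)`` and
  ``gamma*Q``.
* **Single-gene positive feedback loop (PFL)** — one gene whose product
  up-regulates its own (delayed) production through a steep Hill function:
  ``alpha + beta*Q**b/(c**b + Q**b)``; dilution ``gamma*Q``.
* **Lambda-phage lysis/lysogeny switch** — the reduced Warren–ten Wolde
  model: two transcription factors A and B produced (with delay) from a
  shared operator, dimerizing and competing for operator binding.  Seven
  species, fourteen reactions; bistability is visible in the projection
  ``A_T = A + 2*A2 + 2*OA2``, ``B_T = B + 2*B2 + 2*OB2``.

Delay enters only through the history argument of the production terms, so
the fixed points of the delay-free rate equations locate the metastable
states for every delay distribution; :func:`find_steady_states` finds and
classifies them by multi-start root finding.

Toggle parameter disambiguation
-------------------------------
The printed source values of the toggle parameters ``beta`` and ``kappa``
are typographically corrupted (lost superscripts / fraction bars).  The
builder therefore ships a list of candidate readings and certifies each
against the hard structural requirement that the delay-free toggle ODE be
bistable, which for this symmetric repression form reduces to
``beta/gamma > 2*sqrt(kappa)``.  The chosen reading is recorded in the
network metadata.  See :data:`TOGGLE_CANDIDATE_PARSINGS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, root

from .network import Reaction, ReactionNetwork, evaluate_propensities

__all__ = [
    "ToggleParams",
    "PFLParams",
    "PhageParams",
    "make_toggle",
    "make_pfl",
    "make_phage",
    "phage_projection",
    "find_steady_states",
    "toggle_candidates",
]

LOG2 = float(np.log(2.0))

# Candidate readings of the corrupted toggle parameters, in preference
# order.  Each is (label, beta, kappa).  The first reading that certifies
# bistability of the delay-free ODE is used.  The preferred reading takes
# the beta cell literally as a product and the kappa cell as a collapsed
# fraction 1000/21.6404; it is the only candidate that both certifies
# bistability and reproduces the reported fixed-delay mean residence times
# of the toggle (e.g. ~1.9e4 at fixed delay 2).
TOGGLE_CANDIDATE_PARSINGS = [
    ("beta=31.6404*log2, kappa=1000/21.6404", 31.6404 * LOG2, 1000.0 / 21.6404),
    ("beta=31.6404*log2, kappa=1000/2^1.6404", 31.6404 * LOG2, 1000.0 / 2**1.6404),
    ("beta=31.6404*log2, kappa=1000*2^1.6404", 31.6404 * LOG2, 1000.0 * 2**1.6404),
    ("beta=3^1.6404*log2, kappa=1000/2^1.6404", 3**1.6404 * LOG2, 1000.0 / 2**1.6404),
    ("beta=3^1.6404*log2, kappa=1000*2^1.6404", 3**1.6404 * LOG2, 1000.0 * 2**1.6404),
]


def _toggle_bistable(beta: float, kappa: float, gamma: float) -> bool:
    """Bistability of q1' = beta*kappa/(kappa+q2^2) - gamma*q1 (symmetric).

    The symmetric fixed point q* solves (beta/gamma)*kappa = q*(kappa+q*^2);
    the pitchfork criterion |f'(q*)| > 1 reduces to q*^2 > kappa, i.e.
    beta/gamma > 2*sqrt(kappa).
    """
    return beta / gamma > 2.0 * np.sqrt(kappa)


def toggle_candidates(gamma: float = LOG2) -> list:
    """Candidate (label, beta, kappa, bistable) rows for the toggle readings."""
    return [
        (label, b, k, _toggle_bistable(b, k, gamma))
        for label, b, k in TOGGLE_CANDIDATE_PARSINGS
    ]


def _resolve_toggle(gamma: float) -> tuple[str, float, float]:
    for label, b, k in TOGGLE_CANDIDATE_PARSINGS:
        if _toggle_bistable(b, k, gamma):
            return label, b, k
    raise ValueError("no candidate toggle parameter reading is bistable")


@dataclass
class ToggleParams:
    """Co-repressive toggle parameters.

    ``beta``: maximal production rate; ``kappa``: repression constant
    (count^2 units — production is half-maximal at Q_other = sqrt(kappa));
    ``gamma``: dilution rate.  With ``beta`` or ``kappa`` left as None the
    certified default reading is used (see module docstring).
    """

    beta: float | None = None
    kappa: float | None = None
    gamma: float = LOG2
    kernel_ref: str = "production"
    parsing_label: str = field(default="", repr=False)

    def __post_init__(self) -> None:
        if self.beta is None or self.kappa is None:
            label, b, k = _resolve_toggle(self.gamma)
            self.beta = b if self.beta is None else self.beta
            self.kappa = k if self.kappa is None else self.kappa
            self.parsing_label = label
        if min(self.beta, self.kappa, self.gamma) <= 0:
            raise ValueError("toggle parameters must be positive")


@dataclass
class PFLParams:
    """Positive-feedback-loop parameters (defaults give a bistable ODE)."""

    alpha: float = 5.0
    beta: float = 20.0
    b: float = 10.0
    c: float = 19.0
    gamma: float = LOG2
    kernel_ref: str = "production"

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.c, self.gamma) <= 0:
            raise ValueError("PFL parameters must be positive")
        if self.b < 1:
            raise ValueError("Hill coefficient b must be >= 1")


@dataclass
class PhageParams:
    """Reduced lambda-phage switch parameters (defaults from the source model)."""

    kA: float = 1.0
    kB: float = 1.0
    muA: float = 0.3
    muB: float = 0.3
    kf: float = 5.0
    kb: float = 5.0
    kon: float = 5.0
    koff: float = 1.0
    operator_copies: int = 1
    kernel_ref: str = "production"

    def __post_init__(self) -> None:
        vals = [self.kA, self.kB, self.muA, self.muB, self.kf, self.kb, self.kon, self.koff]
        if min(vals) <= 0:
            raise ValueError("phage parameters must be positive")
        if self.operator_copies < 1:
            raise ValueError("operator copy number must be >= 1")


def make_toggle(params: ToggleParams | None = None, validate: bool = True) -> ReactionNetwork:
    """Co-repressive toggle switch network (2 species, 4 reactions)."""
    p = params or ToggleParams()
    net = ReactionNetwork(
        species=["Q1", "Q2"],
        reactions=[
            Reaction("production_Q1", "hill_repress", (p.beta, p.kappa), (1,), (1, 0),
                     delayed=True, kernel_ref=p.kernel_ref),
            Reaction("production_Q2", "hill_repress", (p.beta, p.kappa), (0,), (0, 1),
                     delayed=True, kernel_ref=p.kernel_ref),
            Reaction("dilution_Q1", "linear", (p.gamma,), (0,), (-1, 0)),
            Reaction("dilution_Q2", "linear", (p.gamma,), (1,), (0, -1)),
        ],
        initial_state=np.zeros(2, dtype=np.int64),
        metadata={
            "model": "toggle",
            "beta": p.beta,
            "kappa": p.kappa,
            "gamma": p.gamma,
            "parsing": p.parsing_label,
        },
    )
    if validate:
        stable = find_steady_states(net)
        if len(stable) != 2:
            raise ValueError(
                f"toggle parameters beta={p.beta}, kappa={p.kappa}, gamma={p.gamma} "
                f"give {len(stable)} stable fixed point(s); bistability is required"
            )
        # start in one metastable state
        net.initial_state = np.round(stable[0]).astype(np.int64)
    return net


def make_pfl(params: PFLParams | None = None, validate: bool = True) -> ReactionNetwork:
    """Single-gene positive feedback loop network (1 species, 2 reactions)."""
    p = params or PFLParams()
    net = ReactionNetwork(
        species=["Q"],
        reactions=[
            Reaction("production", "hill_activate", (p.alpha, p.beta, p.b, p.c), (0,), (1,),
                     delayed=True, kernel_ref=p.kernel_ref),
            Reaction("dilution", "linear", (p.gamma,), (0,), (-1,)),
        ],
        initial_state=np.zeros(1, dtype=np.int64),
        metadata={"model": "pfl", "alpha": p.alpha, "beta": p.beta, "b": p.b,
                  "c": p.c, "gamma": p.gamma},
    )
    if validate:
        stable = find_steady_states(net)
        if len(stable) != 2:
            raise ValueError("PFL parameters do not give a bistable delay-free ODE")
        net.initial_state = np.round(stable[0]).astype(np.int64)
    return net


def make_phage(params: PhageParams | None = None, validate: bool = True) -> ReactionNetwork:
    """Reduced lambda-phage switch (7 species, 14 reactions).

    Species order: A, B, A2, B2, O, OA2, OB2.  The four production
    reactions (monomer expression from the free or self-bound operator) are
    delayed; dimerization, dissociation, operator (un)binding and monomer
    degradation are instantaneous.  ``O + OA2 + OB2`` is conserved.
    """
    p = params or PhageParams()
    A, B, A2, B2, O, OA2, OB2 = range(7)
    z = [0] * 7

    def ch(**kw):
        v = list(z)
        for name, val in kw.items():
            v[{"A": A, "B": B, "A2": A2, "B2": B2, "O": O, "OA2": OA2, "OB2": OB2}[name]] = val
        return tuple(v)

    rxs = [
        Reaction("express_A_from_O", "linear", (p.kA,), (O,), ch(A=1),
                 delayed=True, kernel_ref=p.kernel_ref),
        Reaction("express_A_from_OA2", "linear", (p.kA,), (OA2,), ch(A=1),
                 delayed=True, kernel_ref=p.kernel_ref),
        Reaction("express_B_from_O", "linear", (p.kB,), (O,), ch(B=1),
                 delayed=True, kernel_ref=p.kernel_ref),
        Reaction("express_B_from_OB2", "linear", (p.kB,), (OB2,), ch(B=1),
                 delayed=True, kernel_ref=p.kernel_ref),
        Reaction("degrade_A", "linear", (p.muA,), (A,), ch(A=-1)),
        Reaction("degrade_B", "linear", (p.muB,), (B,), ch(B=-1)),
        Reaction("dimerize_A", "dimerize", (p.kf,), (A,), ch(A=-2, A2=1)),
        Reaction("dissociate_A2", "linear", (p.kb,), (A2,), ch(A=2, A2=-1)),
        Reaction("dimerize_B", "dimerize", (p.kf,), (B,), ch(B=-2, B2=1)),
        Reaction("dissociate_B2", "linear", (p.kb,), (B2,), ch(B=2, B2=-1)),
        Reaction("bind_A2", "bimolecular", (p.kon,), (O, A2), ch(O=-1, A2=-1, OA2=1)),
        Reaction("unbind_A2", "linear", (p.koff,), (OA2,), ch(O=1, A2=1, OA2=-1)),
        Reaction("bind_B2", "bimolecular", (p.kon,), (O, B2), ch(O=-1, B2=-1, OB2=1)),
        Reaction("unbind_B2", "linear", (p.koff,), (OB2,), ch(O=1, B2=1, OB2=-1)),
    ]
    x0 = np.zeros(7, dtype=np.int64)
    x0[O] = p.operator_copies
    net = ReactionNetwork(
        species=["A", "B", "A2", "B2", "O", "OA2", "OB2"],
        reactions=rxs,
        initial_state=x0,
        metadata={"model": "phage", **{k: getattr(p, k) for k in
                  ("kA", "kB", "muA", "muB", "kf", "kb", "kon", "koff", "operator_copies")}},
    )
    if validate:
        stable = find_steady_states(net)
        if len(stable) != 2:
            raise ValueError("phage parameters do not give a bistable mean-field system")
        net.initial_state = np.maximum(np.round(stable[0]), 0).astype(np.int64)
        net.initial_state[O] = (
            p.operator_copies - net.initial_state[OA2] - net.initial_state[OB2]
        )
    return net


def phage_projection(state) -> tuple[float, float]:
    """Total monomer-equivalents ``(A_T, B_T)`` of the 7-species phage state.

    ``A_T = A + 2*A2 + 2*OA2`` and symmetrically for B.
    """
    s = np.asarray(state, dtype=float)
    if s.shape[-1] != 7:
        raise ValueError("phage state needs 7 species (A, B, A2, B2, O, OA2, OB2)")
    a_t = s[..., 0] + 2 * s[..., 2] + 2 * s[..., 5]
    b_t = s[..., 1] + 2 * s[..., 3] + 2 * s[..., 6]
    return a_t, b_t


# ----------------------------------------------------------------------
# delay-free fixed points


def _ode_rhs(network: ReactionNetwork):
    _, _, _, changes, _ = network.encode()

    def rhs(x):
        return evaluate_propensities(network, np.maximum(x, 0.0)) @ changes

    return rhs


def _phage_reduced(network: ReactionNetwork):
    """Eliminate O = copies - OA2 - OB2 to remove the conserved direction."""
    copies = float(network.metadata.get("operator_copies", 1))
    rhs7 = _ode_rhs(network)

    def to7(y):
        A, B, A2, B2, OA2, OB2 = y
        return np.array([A, B, A2, B2, copies - OA2 - OB2, OA2, OB2])

    def rhs6(y):
        full = rhs7(to7(y))
        return np.array([full[0], full[1], full[2], full[3], full[5], full[6]])

    return rhs6, to7


def find_steady_states(
    network: ReactionNetwork, tol: float = 1e-9, return_unstable: bool = False
):
    """Stable fixed points of the delay-free rate equations of a model.

    The deterministic rate equations use the same propensity forms as the
    stochastic model, with the counts treated as real.  Delay does not move
    fixed points (it only enters history arguments), so these are the
    metastable-state locations for every delay kernel.

    Returns the stable fixed points as count vectors ordered by the first
    coordinate (toggle/PFL) so that index 0 is a deterministic choice; with
    ``return_unstable=True`` returns ``(stable, unstable)``.
    """
    model = network.metadata.get("model", "")
    if model == "pfl":
        alpha = network.metadata["alpha"]
        beta = network.metadata["beta"]
        gamma = network.metadata["gamma"]
        rhs = _ode_rhs(network)
        f = lambda q: rhs(np.array([q]))[0]
        hi = 1.2 * (alpha + beta) / gamma
        grid = np.linspace(0.0, hi, 4001)
        vals = np.array([f(q) for q in grid])
        roots = []
        for i in range(len(grid) - 1):
            if vals[i] == 0.0:
                roots.append(grid[i])
            elif vals[i] * vals[i + 1] < 0:
                roots.append(brentq(f, grid[i], grid[i + 1], xtol=1e-12))
        stable, unstable = [], []
        for q in roots:
            d = (f(q + 1e-6) - f(q - 1e-6)) / 2e-6
            (stable if d < 0 else unstable).append(np.array([q]))
        stable.sort(key=lambda v: v[0])
        return (stable, unstable) if return_unstable else stable

    if model == "phage":
        # locate attractors by relaxing the ODE from representative starts,
        # then polish with a root solver; the conserved operator total is
        # eliminated first.  The saddle lies on the A<->B symmetry plane and
        # is found by root-finding from the symmetric start.
        from scipy.integrate import solve_ivp

        rhs6, to7 = _phage_reduced(network)
        scale = (
            4.0
            * max(network.metadata["kA"], network.metadata["kB"])
            / min(network.metadata["muA"], network.metadata["muB"])
        )
        starts = [
            np.array([scale, 0.1, scale / 2, 0.0, 0.9, 0.0]),
            np.array([0.1, scale, 0.0, scale / 2, 0.0, 0.9]),
            np.full(6, 0.3),
        ]
        found = []
        for s0 in starts:
            sol = solve_ivp(lambda t, y: rhs6(y), (0.0, 2000.0), s0,
                            rtol=1e-10, atol=1e-12)
            y = sol.y[:, -1]
            pol = root(rhs6, y, method="hybr", tol=1e-12)
            if pol.success and np.max(np.abs(rhs6(pol.x))) < 1e-8:
                y = pol.x
            if (y < -1e-6).any():
                continue
            y = np.maximum(y, 0.0)
            if not any(np.allclose(y, z, atol=1e-5 * (1 + scale)) for z in found):
                found.append(y)
        # symmetric saddle (if present) via root from the symmetric relaxed mean
        sym0 = np.mean([found[0], found[1]], axis=0) if len(found) >= 2 else np.full(6, 1.0)
        pol = root(rhs6, sym0, method="hybr", tol=1e-12)
        if pol.success and np.max(np.abs(rhs6(pol.x))) < 1e-8 and not (pol.x < -1e-6).any():
            y = np.maximum(pol.x, 0.0)
            if not any(np.allclose(y, z, atol=1e-5 * (1 + scale)) for z in found):
                found.append(y)
        stable, unstable = [], []
        for y in found:
            jac = np.empty((6, 6))
            h = 1e-6 * (1.0 + np.abs(y))
            for j in range(6):
                e = np.zeros(6)
                e[j] = h[j]
                jac[:, j] = (rhs6(y + e) - rhs6(y - e)) / (2 * h[j])
            ev = np.linalg.eigvals(jac)
            (stable if np.max(ev.real) < -tol else unstable).append(to7(y))
        stable.sort(key=lambda v: tuple(v))
        unstable.sort(key=lambda v: tuple(v))
        return (stable, unstable) if return_unstable else stable
    else:
        f = _ode_rhs(network)
        dim, wrap = network.n_species, lambda y: np.asarray(y)
        if model == "toggle":
            scale = 1.2 * network.metadata["beta"] / network.metadata["gamma"]
        else:
            scale = 10.0 + 2.0 * float(network.initial_state.max())

    rng = np.random.default_rng(12345)  # deterministic multi-start
    starts = [np.zeros(dim), np.full(dim, 0.5 * scale)]
    if model == "toggle":
        starts += [np.array([scale, 0.0]), np.array([0.0, scale])]
    if model == "phage":
        base = np.full(dim, 0.1)
        hiA = np.array([scale, 0.1, scale / 2, 0.1, 0.9, 0.05])
        hiB = np.array([0.1, scale, 0.1, scale / 2, 0.05, 0.9])
        starts += [base, hiA, hiB]
    starts += list(rng.uniform(0, scale, size=(60, dim)))

    found = []
    for s0 in starts:
        sol = root(f, s0, method="hybr", tol=1e-12)
        if not sol.success:
            continue
        y = sol.x
        if (y < -1e-6).any() or np.max(np.abs(f(y))) > 1e-7:
            continue
        y = np.maximum(y, 0.0)
        if any(np.allclose(y, z, atol=1e-5 * (1 + scale)) for z in found):
            continue
        found.append(y)

    stable, unstable = [], []
    for y in found:
        jac = np.empty((dim, dim))
        h = 1e-6 * (1.0 + np.abs(y))
        for j in range(dim):
            e = np.zeros(dim)
            e[j] = h[j]
            jac[:, j] = (f(y + e) - f(y - e)) / (2 * h[j])
        ev = np.linalg.eigvals(jac)
        (stable if np.max(ev.real) < -tol else unstable).append(wrap(y))
    stable.sort(key=lambda v: tuple(v))
    unstable.sort(key=lambda v: tuple(v))
    return (stable, unstable) if return_unstable else stable
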