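"""Closed-form analysis of the three-states symbolic model of bistability.

The phase space of a bistable network is coded by three symbols: H and L
(neighborhoods of the metastable states) and I (a thickening of the
separating set).  Transitions j -> k occur at rates ``lambda^i_{j->k}``
that depend on the symbol i occupied ``tau`` time units ago — the delay
enters the symbolic model only through this memory.  Direct H <-> L jumps
are forbidden; I must be visited along the way.

Standing assumptions:

* RM1 — the delay ``tau`` is small compared to residence times in H and L;
* RM2 — rates out of I are large compared to rates out of H and L;
* RM3 — with ``p^i_{I->j} = lambda^i_{I->j} / (lambda^i_{I->H} +
  lambda^i_{I->L})``, memory of H biases the excursion back toward H:
  ``p^H_{I->H} > p^I_{I->H}`` (and symmetrically for L).

Under these assumptions the probability ``f_H`` that a transition attempt
from H fails is a convex combination

    f_H(tau) = (1 - Z_H(tau)) p^H_{I->H} + Z_H(tau) p^I_{I->H},
    Z_H(tau) = exp(-(lambda^H_{I->H} + lambda^H_{I->L}) tau),

the number of failed attempts before a success is geometric with mean
``f_H/(1-f_H)``, and the expected residence time follows from the loop/
sequence durations F_H, S_H:

    E[R_H] ~ (f_H/(1-f_H)) (E[F_H] + 1/lambda^H_{H->I})
             + (E[S_H] + 1/lambda^H_{H->I}).

The *extended* model redraws the delay after each attempt from the
symmetric two-point distribution on {mu - sigma, mu + sigma}; with
``p0 = f_H(mu - sigma)`` and ``p1 = f_H(mu + sigma)`` the expected number
of failures becomes ``m/(1-m)`` with ``m = (p0+p1)/2``, and convexity of
``Z_H`` (Jensen) forces the averaged failure ratio — hence the residence
time — to *decrease* with sigma.  This is the slow-switching
destabilization mechanism seen in the delay-switching simulations.

Every closed form here is validated in the test suite against a
brute-force simulation of the discretized memory chain (``tau = K Delta``,
memory vector re-initialized to all-H before each attempt).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

__all__ = [
    "RMRates",
    "rm_fail_probability",
    "rm_loop_time_density",
    "rm_success_time_density",
    "rm_expected_loop_time",
    "rm_expected_success_time",
    "rm_residence_estimate",
    "rm_loop_steps_pmf",
    "rm_discrete_simulate",
    "ext_expected_failures",
    "ext_residence_estimate",
    "ext_failures_simulate",
    "averaged_fail_ratio",
    "check_rm_assumptions",
    "sample_rm3_rates",
]

_STATES = ("H", "I", "L")


@dataclass(frozen=True)
class RMRates:
    """The twelve memory-dependent rates ``lambda^i_{j->k}``.

    Each field maps the memory state i (symbol occupied ``tau`` ago) to a
    rate; the four allowed moves are H->I, I->H, I->L and L->I.
    """

    H_to_I: dict
    I_to_H: dict
    I_to_L: dict
    L_to_I: dict

    def __post_init__(self) -> None:
        for name in ("H_to_I", "I_to_H", "I_to_L", "L_to_I"):
            d = getattr(self, name)
            if set(d) != set(_STATES):
                raise ValueError(f"{name} must give a rate for each memory state H, I, L")
            if any(v < 0 for v in d.values()):
                raise ValueError(f"{name} rates must be non-negative")
        for i in _STATES:
            if self.I_to_H[i] + self.I_to_L[i] <= 0:
                raise ValueError(f"rates out of I with memory {i} must not both vanish")

    # -- derived quantities --------------------------------------------

    def exit_rate_I(self, memory: str) -> float:
        """Total rate out of I given memory state: Lambda_i."""
        return self.I_to_H[memory] + self.I_to_L[memory]

    def p_I_to(self, memory: str, target: str) -> float:
        """Splitting probability p^i_{I->j} (Eq.-style normalized rate)."""
        lam = {"H": self.I_to_H, "L": self.I_to_L}[target][memory]
        return lam / self.exit_rate_I(memory)

    def Z(self, memory: str, tau) -> np.ndarray | float:
        """Survival factor Z_i(tau) = exp(-Lambda_i tau)."""
        return np.exp(-self.exit_rate_I(memory) * np.asarray(tau, dtype=float))


def rm_fail_probability(rates: RMRates, tau: float) -> float:
    """Probability f_H that a transition attempt from H fails.

    Convex combination of the memory-H and memory-I splitting
    probabilities, with weight Z_H(tau) on the memory-I branch; hence
    f_H(0) = p^I_{I->H} and f_H(inf) = p^H_{I->H}, and f_H increases with
    tau exactly when RM3 holds.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    z = rates.Z("H", tau)
    return float((1.0 - z) * rates.p_I_to("H", "H") + z * rates.p_I_to("I", "H"))


def _two_branch_density(rates: RMRates, tau: float, t, target: str, norm: float):
    """Shared two-branch exponential density for loop (I->H) / sequence (I->L)."""
    t = np.asarray(t, dtype=float)
    lam_h = {"H": rates.I_to_H, "L": rates.I_to_L}[target]["H"]
    lam_i = {"H": rates.I_to_H, "L": rates.I_to_L}[target]["I"]
    big_h = rates.exit_rate_I("H")
    big_i = rates.exit_rate_I("I")
    early = lam_h * np.exp(-big_h * t)
    late = lam_i * np.exp(-big_h * tau - big_i * (t - tau))
    out = np.where(t <= tau, early, late) / norm
    return np.where(t > 0, out, 0.0)


def rm_loop_time_density(rates: RMRates, tau: float, t):
    """Density P(t) of the H->I->H loop time F_H, given the attempt failed.

    Exponential at the memory-H exit rate up to the delay horizon ``tau``,
    switching to the memory-I exit rate beyond it; normalized by f_H.
    """
    return _two_branch_density(rates, tau, t, "H", rm_fail_probability(rates, tau))


def rm_success_time_density(rates: RMRates, tau: float, t):
    """Density of the H->I->L sequence time S_H, given the attempt succeeded."""
    return _two_branch_density(
        rates, tau, t, "L", 1.0 - rm_fail_probability(rates, tau)
    )


def _expected_two_branch(rates: RMRates, tau: float, target: str, norm: float) -> float:
    p_h = rates.p_I_to("H", target)
    p_i = rates.p_I_to("I", target)
    big_h = rates.exit_rate_I("H")
    big_i = rates.exit_rate_I("I")
    z = rates.Z("H", tau)
    early = p_h / big_h * (1.0 - z * (big_h * tau + 1.0))
    late = p_i / big_i * z * (big_i * tau + 1.0)
    return (early + late) / norm


def rm_expected_loop_time(rates: RMRates, tau: float) -> float:
    """E[F_H], the expected H->I->H loop time given failure (closed form)."""
    return _expected_two_branch(rates, tau, "H", rm_fail_probability(rates, tau))


def rm_expected_success_time(rates: RMRates, tau: float) -> float:
    """E[S_H], the expected H->I->L sequence time given success.

    Same two-branch integral as E[F_H] with the I->L numerator rates and
    normalization 1 - f_H.
    """
    return _expected_two_branch(
        rates, tau, "L", 1.0 - rm_fail_probability(rates, tau)
    )


def rm_expected_loop_time_quadrature(rates: RMRates, tau: float) -> float:
    """E[F_H] by adaptive quadrature of t P(t); cross-check of the closed form."""
    f = lambda t: t * rm_loop_time_density(rates, tau, t)
    a, _ = quad(f, 0.0, tau) if tau > 0 else (0.0, 0.0)
    b, _ = quad(f, tau, np.inf)
    return a + b


def rm_residence_estimate(rates: RMRates, tau: float) -> float:
    """Expected residence time in H for the fixed-delay three-states model.

    ``(f_H/(1-f_H)) (E[F_H] + 1/lambda^H_{H->I}) + E[S_H] + 1/lambda^H_{H->I}``,
    the geometric number of failed loops times the cost of a loop plus the
    cost of the final successful sequence.
    """
    f_h = rm_fail_probability(rates, tau)
    if f_h >= 1.0:
        raise ValueError("f_H = 1: expected residence time diverges")
    wait = 1.0 / rates.H_to_I["H"]
    return (
        f_h / (1.0 - f_h) * (rm_expected_loop_time(rates, tau) + wait)
        + rm_expected_success_time(rates, tau)
        + wait
    )


# ----------------------------------------------------------------------
# discretized memory chain: closed-form pmf and brute-force oracle


def _step_probs(rates: RMRates, tau: float, K: int):
    if K < 1:
        raise ValueError("K must be >= 1")
    delta = tau / K
    a_h = rates.I_to_H["H"] * delta
    b_h = rates.I_to_L["H"] * delta
    a_i = rates.I_to_H["I"] * delta
    b_i = rates.I_to_L["I"] * delta
    if a_h + b_h >= 1.0 or a_i + b_i >= 1.0:
        raise ValueError(
            f"per-step jump probability >= 1 at K={K}; increase K (finer Delta)"
        )
    return delta, a_h, b_h, a_i, b_i


def rm_loop_steps_pmf(rates: RMRates, tau: float, K: int, k_max: int | None = None):
    """Pmf P(k) of the number of steps to complete the H->I->H loop.

    The delay is discretized as ``tau = K Delta``; during the first K steps
    of an attempt the memory (the symbol K steps in the past) is H, beyond
    that it is I.  Returns ``(k, pmf)`` up to ``k_max`` (default: enough
    mass for a 1e-12 tail) normalized by the discrete failure probability,
    plus the tail mass beyond ``k_max`` as the third element.
    """
    _, a_h, b_h, a_i, b_i = _step_probs(rates, tau, K)
    rho_h = 1.0 - a_h - b_h
    rho_i = 1.0 - a_i - b_i
    p_h = a_h / (a_h + b_h)
    p_i = a_i / (a_i + b_i)
    z_k = rho_h**K
    f_disc = (1.0 - z_k) * p_h + z_k * p_i  # discrete analogue of f_H
    if k_max is None:
        tail = 1e-12
        k_max = K + max(int(np.ceil(np.log(tail) / np.log(max(rho_i, 1e-300)))), 10)
    k = np.arange(1, k_max + 1)
    early = rho_h ** (k - 1.0) * (1.0 - rho_h) * p_h
    late = z_k * rho_i ** (k - K - 1.0) * (1.0 - rho_i) * p_i
    pmf = np.where(k <= K, early, late) / f_disc
    # geometric tail beyond k_max (exact summation)
    if k_max > K:
        tail_mass = z_k * rho_i ** (k_max - K) * p_i / f_disc
    else:
        tail_mass = (
            (rho_h**k_max - z_k) * p_h + z_k * p_i
        ) / f_disc  # remaining early + all late mass
    return k, pmf, float(tail_mass)


def rm_discrete_simulate(
    rates: RMRates, tau: float, K: int, n: int, seed: int = 0
) -> dict:
    """Brute-force Monte Carlo of the discretized attempt chain.

    Each episode starts with the memory vector all-H and the current symbol
    just arrived in I (the attempt has begun).  Per step the symbol jumps
    to H or L with the per-step probabilities of the memory state (H for
    the first K steps, I afterwards — once in I the chain stays in I until
    the attempt completes, so the look-back is deterministic in the step
    index).  Returns the empirical failure probability, loop/sequence time
    samples (in continuous units ``k * Delta``) and completion step counts.
    """
    delta, a_h, b_h, a_i, b_i = _step_probs(rates, tau, K)
    rng = np.random.default_rng(seed)
    steps = np.zeros(n, dtype=np.int64)
    failed = np.zeros(n, dtype=bool)
    active = np.ones(n, dtype=bool)
    m = 0
    while active.any():
        m += 1
        a, b = (a_h, b_h) if m <= K else (a_i, b_i)
        u = rng.random(int(active.sum()))
        jump_h = u < a
        jump_l = (u >= a) & (u < a + b)
        done = jump_h | jump_l
        idx = np.flatnonzero(active)
        steps[idx[done]] = m
        failed[idx[jump_h]] = True
        active[idx[done]] = False
        if m > 10**7:
            raise RuntimeError("discrete chain failed to complete; rates too small")
    return {
        "fail_probability": float(failed.mean()),
        "fail_se": float(np.sqrt(failed.mean() * (1 - failed.mean()) / n)),
        "loop_steps": steps[failed],
        "loop_times": steps[failed] * delta,
        "success_times": steps[~failed] * delta,
        "delta": delta,
    }


# ----------------------------------------------------------------------
# extended model: delay redrawn per attempt from {mu - sigma, mu + sigma}


def ext_expected_failures(p0: float, p1: float) -> float:
    """E[N_s]: expected failed attempts when each attempt's failure
    probability is p0 or p1 with a fair coin.

    Equals ``m/(1-m)`` with ``m = (p0+p1)/2`` — the same geometric mean
    formula as the fixed-delay model evaluated at the averaged failure
    probability.
    """
    for p in (p0, p1):
        if not 0.0 <= p < 1.0:
            raise ValueError("failure probabilities must lie in [0, 1)")
    m = 0.5 * (p0 + p1)
    if m >= 1.0:
        raise ValueError("mean failure probability >= 1: diverges")
    return m / (1.0 - m)


def ext_failures_simulate(p0: float, p1: float, n: int, seed: int = 0) -> dict:
    """Brute-force sampling of the per-attempt coin + failure process."""
    rng = np.random.default_rng(seed)
    counts = np.zeros(n, dtype=np.int64)
    active = np.ones(n, dtype=bool)
    while active.any():
        k = int(active.sum())
        p = np.where(rng.random(k) < 0.5, p0, p1)
        fail = rng.random(k) < p
        idx = np.flatnonzero(active)
        counts[idx[fail]] += 1
        active[idx[fail]] = True
        active[idx[~fail]] = False
    return {
        "expected_failures": float(counts.mean()),
        "se": float(counts.std(ddof=1) / np.sqrt(n)),
        "counts": counts,
    }


def averaged_fail_ratio(rates: RMRates, mu: float, sigma: float) -> float:
    """The failure ratio m/(1-m) with m = (f_H(mu-sigma)+f_H(mu+sigma))/2.

    Under RM3 this is strictly decreasing in sigma (Jensen's inequality
    applied to the convex survival factor Z_H), which is the analytic
    destabilization mechanism of slow delay switching.
    """
    if not 0.0 <= sigma < mu:
        raise ValueError("need 0 <= sigma < mu")
    p0 = rm_fail_probability(rates, mu - sigma)
    p1 = rm_fail_probability(rates, mu + sigma)
    return ext_expected_failures(p0, p1)


def ext_residence_estimate(rates: RMRates, mu: float, sigma: float) -> float:
    """Expected residence time in H for the delay-switching extension.

    Substitutes E[N_s] for the geometric count in the fixed-delay estimate;
    E[F_H] and E[S_H] are delay-insensitive under RM2 and are evaluated at
    the mean delay ``mu``.  Reduces exactly to the fixed-delay estimate at
    ``sigma = 0``.
    """
    if not 0.0 <= sigma < mu:
        raise ValueError("need 0 <= sigma < mu")
    e_ns = averaged_fail_ratio(rates, mu, sigma)
    wait = 1.0 / rates.H_to_I["H"]
    return (
        e_ns * (rm_expected_loop_time(rates, mu) + wait)
        + rm_expected_success_time(rates, mu)
        + wait
    )


# ----------------------------------------------------------------------
# assumption checks and rate sampling


def check_rm_assumptions(rates: RMRates, tau: float, rm2_min_ratio: float = 10.0) -> dict:
    """Evaluate the standing assumptions RM1-RM3 with margins.

    RM1 compares ``tau`` with the estimated residence time; RM2 the
    smallest exit rate from I with the largest rate out of H or L; RM3 the
    splitting-probability inequalities.
    """
    rm3_h = rates.p_I_to("H", "H") - rates.p_I_to("I", "H")
    rm3_l = rates.p_I_to("L", "L") - rates.p_I_to("I", "L")
    i_exit = min(rates.exit_rate_I(i) for i in _STATES)
    hl_exit = max(max(rates.H_to_I.values()), max(rates.L_to_I.values()))
    rm2_ratio = i_exit / hl_exit if hl_exit > 0 else np.inf
    try:
        res = rm_residence_estimate(rates, tau)
        rm1_ratio = res / tau if tau > 0 else np.inf
    except ValueError:
        res, rm1_ratio = np.inf, np.inf
    return {
        "rm1_ratio": rm1_ratio,
        "rm1_pass": bool(rm1_ratio > 10.0),
        "rm2_ratio": rm2_ratio,
        "rm2_pass": bool(rm2_ratio >= rm2_min_ratio),
        "rm3_margin_H": rm3_h,
        "rm3_margin_L": rm3_l,
        "rm3_pass": bool(rm3_h > 0 and rm3_l > 0),
        "residence_estimate": res,
    }


def sample_rm3_rates(
    rng: np.random.Generator, rm2_separation: float = 100.0
) -> RMRates:
    """Draw a random rate set satisfying RM2 (scale separation) and RM3.

    Exit rates from I are of order ``rm2_separation`` times the H/L exit
    rates; splitting probabilities are drawn with clear RM3 margins
    (memory of H biases I -> H, memory of L biases I -> L, and the
    memory-I chain is roughly unbiased).
    """
    slow = rng.uniform(0.5, 1.5, size=6)
    fast = rm2_separation * rng.uniform(0.5, 1.5, size=3)
    p_ih_i = rng.uniform(0.25, 0.45)  # memory I: mildly sub-fair toward H
    p_ih_h = p_ih_i + rng.uniform(0.1, 0.95 - p_ih_i)  # RM3 margin for H
    p_il_l = (1.0 - p_ih_i) + rng.uniform(0.05, p_ih_i * 0.9)  # RM3 margin for L
    big_h, big_i, big_l = fast
    return RMRates(
        H_to_I={"H": slow[0], "I": slow[1], "L": slow[2]},
        L_to_I={"H": slow[3], "I": slow[4], "L": slow[5]},
        I_to_H={"H": p_ih_h * big_h, "I": p_ih_i * big_i, "L": (1 - p_il_l) * big_l},
        I_to_L={"H": (1 - p_ih_h) * big_h, "I": (1 - p_ih_i) * big_i, "L": p_il_l * big_l},
    )
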