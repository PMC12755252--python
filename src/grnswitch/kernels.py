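"""Delay kernels: the probability distributions governing transcriptional delay.

A delayed reaction does not change the state when it fires.  Instead, a delay
``tau`` is drawn from the reaction's kernel and the state change is applied
``tau`` time units later.  Kernels are parameterized by their mean ``E[tau]``
and coefficient of variation ``cv[tau] = sd[tau]/E[tau]``, so that experiments
can hold the mean fixed while sweeping the noise level of the delay.

Supported families
------------------
``fixed``
    Point mass at ``mean`` (cv must be 0).
``gamma``
    Gamma distribution with shape ``cv**-2`` and scale ``mean * cv**2``,
    which has exactly the requested mean and CV.
``bernoulli``
    Symmetric two-point distribution ``(1/2) d_{mu-sigma} + (1/2) d_{mu+sigma}``
    with ``sigma = cv * mean``; requires ``cv < 1`` so both support points
    are positive.

Any family with ``cv == 0`` collapses to a point mass at ``mean``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DelayKernel", "make_kernel", "sample_delays"]

_FAMILIES = ("fixed", "gamma", "bernoulli")

# integer codes used by the compiled simulation engine
KERNEL_NONE = 0
KERNEL_FIXED = 1
KERNEL_GAMMA = 2
KERNEL_BERNOULLI = 3


@dataclass(frozen=True)
class DelayKernel:
    """A delay distribution with prescribed mean and coefficient of variation.

    Attributes
    ----------
    family : str
        One of ``fixed``, ``gamma``, ``bernoulli``.
    mean : float
        Analytic mean of the delay, in simulation time units.  Must be > 0.
    cv : float
        Analytic coefficient of variation (dimensionless).  Must be >= 0,
        and < 1 for the Bernoulli family.
    """

    family: str
    mean: float
    cv: float

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(
                f"unknown delay family {self.family!r}; expected one of {_FAMILIES}"
            )
        if not np.isfinite(self.mean) or self.mean <= 0:
            raise ValueError(f"delay mean must be positive, got {self.mean}")
        if not np.isfinite(self.cv) or self.cv < 0:
            raise ValueError(f"delay cv must be non-negative, got {self.cv}")
        if self.family == "fixed" and self.cv != 0:
            raise ValueError("fixed kernel requires cv == 0")
        if self.family == "bernoulli" and self.cv >= 1:
            raise ValueError(
                "bernoulli kernel requires cv < 1 so that mean - sigma > 0 "
                "(delays must be strictly positive)"
            )

    # -- derived parameterizations -------------------------------------

    @property
    def is_degenerate(self) -> bool:
        """True when the kernel is a point mass at ``mean``."""
        return self.cv == 0

    @property
    def shape(self) -> float:
        """Gamma shape parameter ``cv**-2`` (gamma family, cv > 0 only)."""
        self._require("gamma")
        if self.cv == 0:
            raise ValueError("degenerate gamma kernel (cv=0) has no finite shape")
        return self.cv**-2

    @property
    def scale(self) -> float:
        """Gamma scale parameter ``mean * cv**2`` (gamma family, cv > 0 only)."""
        self._require("gamma")
        if self.cv == 0:
            raise ValueError("degenerate gamma kernel (cv=0) has no finite scale")
        return self.mean * self.cv**2

    @property
    def sigma(self) -> float:
        """Half-width ``cv * mean`` of the symmetric Bernoulli kernel."""
        self._require("bernoulli")
        return self.cv * self.mean

    @property
    def support(self) -> tuple[float, float]:
        """Support ``(mean - sigma, mean + sigma)`` of the Bernoulli kernel."""
        self._require("bernoulli")
        return (self.mean - self.sigma, self.mean + self.sigma)

    def _require(self, family: str) -> None:
        if self.family != family:
            raise AttributeError(f"attribute only defined for {family} kernels")

    # -- engine encoding ------------------------------------------------

    def encode(self) -> tuple[int, float, float]:
        """(code, p0, p1) triple consumed by the compiled event loop."""
        if self.is_degenerate or self.family == "fixed":
            return (KERNEL_FIXED, self.mean, 0.0)
        if self.family == "gamma":
            return (KERNEL_GAMMA, self.shape, self.scale)
        lo, hi = self.support
        return (KERNEL_BERNOULLI, lo, hi)

    def to_dict(self) -> dict:
        return {"family": self.family, "mean": self.mean, "cv": self.cv}


def make_kernel(family: str, mean: float, cv: float = 0.0) -> DelayKernel:
    """Construct a :class:`DelayKernel`, validating parameters.

    Parameters
    ----------
    family : {"fixed", "gamma", "bernoulli"}
        Delay family.  ``bernoulli`` is the symmetric two-point distribution
        ``(1/2) d_{mu-sigma} + (1/2) d_{mu+sigma}``.
    mean : float
        Requested analytic mean (> 0).
    cv : float
        Requested analytic coefficient of variation (>= 0; < 1 for
        ``bernoulli``).  ``fixed`` accepts only ``cv == 0``.
    """
    if family == "fixed" and cv != 0:
        raise ValueError("fixed kernel requires cv == 0")
    return DelayKernel(family=family, mean=float(mean), cv=float(cv))


def sample_delays(
    kernel: DelayKernel, n: int, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Draw ``n`` i.i.d. delays from ``kernel``.

    Every draw is strictly positive.  For a fixed seed the draws are
    reproducible.  This sampler is used for kernel-level statistics and
    testing; inside a simulation the event loop draws delays from its own
    single per-run stream so that whole runs replay from one seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if kernel.is_degenerate:
        return np.full(n, kernel.mean)
    if kernel.family == "gamma":
        draws = rng.gamma(kernel.shape, kernel.scale, size=n)
        # a draw of exactly 0 (possible by floating-point underflow at very
        # small shape) is disallowed: completions must follow initiations
        bad = draws <= 0
        while bad.any():
            draws[bad] = rng.gamma(kernel.shape, kernel.scale, size=int(bad.sum()))
            bad = draws <= 0
        return draws
    lo, hi = kernel.support
    return np.where(rng.random(n) < 0.5, lo, hi)
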