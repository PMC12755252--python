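"""Metastable-region geometry: neighborhoods U0/U1 and the H/I/L coding.

Residence times are measured by thresholding: neighborhoods U0 and U1 of
the two stable fixed points are fixed in advance, and the residence clock
for U0 runs from entry into U0 until the trajectory *first enters U1* —
intermediate exits and re-entries of U0 do not stop it.  For the symbolic
three-states analysis the same geometry also defines H (= U0), L (= U1)
and I, a thickening of the separating set.

The source analyses do not pin down the neighborhood shapes, so this module
makes a concrete, config-exposed choice.  All models here admit a scalar
reaction coordinate ``d(x) = w . x + offset``:

* toggle: ``d = Q1 - Q2`` (the symmetry line is ``d = 0``);
* lambda-phage: ``d = A_T - B_T`` in the total-monomer projection;
* PFL: ``d = Q - q_unstable`` (distance past the unstable fixed point).

Regions are half-planes/bands in ``d``:  ``H = {d >= theta_pos}``,
``L = {d <= -theta_neg}``, ``I = {-w_neg <= d <= w_pos}``.  By default the
thresholds sit close to the fixed points (``radius_frac = 0.85`` of the
distance from the separatrix) and the I band is half as wide as the
thresholds (``iband_frac = 0.5``), so H, I, L are pairwise disjoint with a
gap between them.

The tight default neighborhoods matter: switching transients of delayed
circuits *ring* (delayed feedback initiated before the switch completes
after it), and with looser thresholds a single physical transition can be
scored as several spurious back-and-forth transitions, contaminating the
residence statistics with artifacts a few delay times long.  With
``radius_frac`` in the 0.8-0.9 range the measured means sit on a plateau,
insensitive to the exact value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import find_steady_states, phage_projection
from .network import ReactionNetwork

__all__ = ["RegionSpec", "make_regions"]


@dataclass
class RegionSpec:
    """Half-plane/band regions along a scalar projection of the state.

    ``H`` is the metastable neighborhood on the positive side of the
    projection, ``L`` the one on the negative side, ``I`` the band around 0.
    ``state_labels`` maps the symbols to model-specific descriptions (e.g.
    for the PFL, H is the high-protein state).
    """

    weights: np.ndarray
    offset: float
    theta_pos: float
    theta_neg: float
    iband_pos: float
    iband_neg: float
    state_labels: dict = field(default_factory=dict)
    fixed_points: tuple = ()

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.theta_pos <= 0 or self.theta_neg <= 0:
            raise ValueError("thresholds must be positive")
        if self.iband_pos < 0 or self.iband_neg < 0:
            raise ValueError("I-band half-widths must be non-negative")
        if self.iband_pos >= self.theta_pos or self.iband_neg >= self.theta_neg:
            raise ValueError("I band must not overlap the metastable neighborhoods")

    def projection(self, state) -> float:
        return float(np.dot(self.weights, np.asarray(state, dtype=float)) + self.offset)

    def classify(self, state) -> str:
        """Deterministic region label of a count vector.

        Returns one of ``"H"`` (= U0), ``"L"`` (= U1), ``"I"``, ``"gap"``.
        """
        d = self.projection(state)
        if d >= self.theta_pos:
            return "H"
        if d <= -self.theta_neg:
            return "L"
        if -self.iband_neg <= d <= self.iband_pos:
            return "I"
        return "gap"


def make_regions(
    network: ReactionNetwork,
    radius_frac: float = 0.85,
    iband_frac: float = 0.5,
) -> RegionSpec:
    """Default region geometry for a certified-bistable model network.

    Parameters
    ----------
    network : ReactionNetwork
        A network built by one of the model builders (its metadata
        identifies the model and parameters).
    radius_frac : float in (0, 1)
        Threshold position as a fraction of the distance from the
        separatrix to each fixed point along the projection.
    iband_frac : float in (0, 1)
        I-band half-width as a fraction of the threshold on each side.
    """
    if not (0 < radius_frac < 1) or not (0 < iband_frac < 1):
        raise ValueError("radius_frac and iband_frac must lie in (0, 1)")
    model = network.metadata.get("model", "")
    if model == "toggle":
        stable = find_steady_states(network)
        if len(stable) != 2:
            raise ValueError("toggle network is not bistable")
        lo, hi = stable[0]  # stable[0] = (Q1 low, Q2 high)
        d_star = abs(hi - lo)
        theta = radius_frac * d_star
        return RegionSpec(
            weights=np.array([1.0, -1.0]),
            offset=0.0,
            theta_pos=theta,
            theta_neg=theta,
            iband_pos=iband_frac * theta,
            iband_neg=iband_frac * theta,
            state_labels={"H": "Q1 high / Q2 low", "L": "Q1 low / Q2 high"},
            fixed_points=(np.array([hi, lo]), np.array([lo, hi])),
        )
    if model == "phage":
        stable = find_steady_states(network)
        if len(stable) != 2:
            raise ValueError("phage network is not bistable")
        at0, bt0 = phage_projection(stable[0])
        d_star = abs(float(at0) - float(bt0))
        theta = radius_frac * d_star
        return RegionSpec(
            weights=np.array([1.0, -1.0, 2.0, -2.0, 0.0, 2.0, -2.0]),
            offset=0.0,
            theta_pos=theta,
            theta_neg=theta,
            iband_pos=iband_frac * theta,
            iband_neg=iband_frac * theta,
            state_labels={"H": "A_T high / B_T low", "L": "A_T low / B_T high"},
            fixed_points=tuple(stable[::-1]),
        )
    if model == "pfl":
        stable, unstable = find_steady_states(network, return_unstable=True)
        if len(stable) != 2 or not unstable:
            raise ValueError("PFL network is not bistable")
        q_lo, q_hi = float(stable[0][0]), float(stable[1][0])
        q_u = float(unstable[0][0])
        theta_pos = radius_frac * (q_hi - q_u)
        theta_neg = radius_frac * (q_u - q_lo)
        return RegionSpec(
            weights=np.array([1.0]),
            offset=-q_u,
            theta_pos=theta_pos,
            theta_neg=theta_neg,
            iband_pos=iband_frac * theta_pos,
            iband_neg=iband_frac * theta_neg,
            state_labels={"H": "Q high", "L": "Q low"},
            fixed_points=(np.array([q_hi]), np.array([q_lo])),
        )
    raise ValueError(
        f"no default region geometry for model {model!r}; construct a RegionSpec directly"
    )
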