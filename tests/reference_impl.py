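"""Plain-Python delay-Gillespie reference implementation.

Deliberately simple and independent of the package's compiled event loop:
a heapq pending queue, propensities via ``evaluate_propensities``, and a
numpy Generator.  Used only as a statistical oracle in tests.
"""

import heapq

import numpy as np

from grnswitch.kernels import DelayKernel
from grnswitch.network import ReactionNetwork, evaluate_propensities


def reference_dssa(
    network: ReactionNetwork,
    kernels: dict | None,
    t_max: float,
    rng: np.random.Generator,
    grid: np.ndarray,
):
    """Simulate and return species counts sampled on a time grid."""
    x = network.initial_state.astype(np.int64).copy()
    changes = np.array([rx.state_change for rx in network.reactions], dtype=np.int64)
    pending: list = []
    counter = 0
    t = 0.0
    out = np.empty((len(grid), len(x)), dtype=np.int64)
    gi = 0

    def record_until(tnew):
        nonlocal gi
        while gi < len(grid) and grid[gi] < tnew:
            out[gi] = x
            gi += 1

    while t < t_max:
        props = evaluate_propensities(network, x)
        a0 = props.sum()
        t_rx = t + rng.exponential(1.0 / a0) if a0 > 0 else np.inf
        t_comp = pending[0][0] if pending else np.inf
        if t_comp <= t_rx:
            record_until(t_comp)
            t = t_comp
            _, _, rxi = heapq.heappop(pending)
            x += changes[rxi]
        else:
            if not np.isfinite(t_rx) or t_rx >= t_max:
                break
            record_until(t_rx)
            t = t_rx
            rxi = int(rng.choice(len(props), p=props / a0))
            rx = network.reactions[rxi]
            if rx.delayed:
                kern: DelayKernel = kernels[rx.kernel_ref]
                if kern.is_degenerate:
                    tau = kern.mean
                elif kern.family == "gamma":
                    tau = rng.gamma(kern.shape, kern.scale)
                else:
                    lo, hi = kern.support
                    tau = lo if rng.random() < 0.5 else hi
                heapq.heappush(pending, (t + tau, counter, rxi))
                counter += 1
            else:
                x += changes[rxi]
    record_until(t_max)
    while gi < len(grid):
        out[gi] = x
        gi += 1
    return out
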