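"""Residence-time and transition-attempt analysis of metastable switching.

The residence clock follows the thresholding definition: with neighborhoods
U0 (= H) and U1 (= L) fixed, the n-th transition time is
``G_n = inf{t > G_{n-1} : X(t) in U_i}`` with the target region alternating,
and residence times are ``R_n = G_{n+1} - G_n``.  A trajectory may leave and
re-enter its current neighborhood many times; the clock only stops on first
entry into the *other* neighborhood.

Transition attempts refine this picture through the three-states coding:
an attempt is an excursion H -> I; it fails if the trajectory next returns
to H (loop H -> I -> H) and succeeds if it reaches L.  A residence in H then
decomposes into N failed attempts followed by one success, giving the
estimate

    E[R_H] ~ E[N] * (E[wait H->I] + E[I->H]) + (E[wait H->I] + E[I->L]),

whose two dominant terms are the expected number of failed attempts and the
expected waiting time before an attempt.  Attempt statistics measured here
feed the comparison with the closed-form three-states analysis in
:mod:`grnswitch.reduced`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kernels import make_kernel
from .regions import RegionSpec, make_regions
from .simulate import HybridConfig, SymbolTrace, Trajectory, simulate_dssa, simulate_hybrid

__all__ = [
    "ResidenceRecord",
    "AttemptRecord",
    "residence_times",
    "attempt_statistics",
    "run_residence_cell",
    "cv_sweep",
    "hybrid_cv_sweep",
]

_CODE_TO_STATE = {0: "H", 1: "L"}


def _get_trace(traj, regions: RegionSpec | None) -> SymbolTrace:
    if isinstance(traj, SymbolTrace):
        return traj
    if isinstance(traj, Trajectory):
        if traj.symbols is not None:
            return traj.symbols
        if regions is None:
            raise ValueError(
                "trajectory has no recorded region trace; pass a RegionSpec"
            )
        times, counts = traj.counts_path()
        proj = counts @ regions.weights + regions.offset
        codes = np.where(
            proj >= regions.theta_pos,
            0,
            np.where(
                proj <= -regions.theta_neg,
                1,
                np.where(
                    (proj >= -regions.iband_neg) & (proj <= regions.iband_pos), 2, 3
                ),
            ),
        ).astype(np.int8)
        keep = np.concatenate(([True], codes[1:] != codes[:-1]))
        return SymbolTrace(times[keep], codes[keep])
    raise TypeError("expected a Trajectory or SymbolTrace")


@dataclass
class ResidenceRecord:
    """Transition times ``G_n`` and the residence times they delimit."""

    transition_times: np.ndarray  # G_n, including G_0 (first metastable entry)
    states: np.ndarray  # state ("H"/"L") occupied on [G_n, G_n+1)

    @property
    def durations(self) -> np.ndarray:
        return np.diff(self.transition_times)

    @property
    def n_residences(self) -> int:
        return max(len(self.transition_times) - 1, 0)

    def to_frame(self, discard_first: bool = False) -> pd.DataFrame:
        d = self.durations
        df = pd.DataFrame(
            {
                "index": np.arange(len(d)),
                "state": self.states[: len(d)],
                "start": self.transition_times[:-1],
                "duration": d,
            }
        )
        return df.iloc[1:].reset_index(drop=True) if discard_first else df

    def mean(self, state: str | None = None, discard_first: bool = True) -> float:
        df = self.to_frame(discard_first=discard_first)
        if state is not None:
            df = df[df["state"] == state]
        return float(df["duration"].mean()) if len(df) else np.nan


def residence_times(traj, regions: RegionSpec | None = None) -> ResidenceRecord:
    """Measure residence times of a trajectory by the thresholding clock.

    Accepts a :class:`Trajectory` (using its recorded region trace, or
    classifying its event log with ``regions``) or a raw
    :class:`SymbolTrace`.  The first recorded metastable entry opens the
    clock; callers concerned with initial-condition bias should discard the
    first residence (:meth:`ResidenceRecord.to_frame` supports this).
    """
    trace = _get_trace(traj, regions)
    times, codes = trace.metastable_entries()
    if len(times) < 2:
        warnings.warn(
            "trajectory never completed a metastable transition; "
            "empty residence record (run longer)",
            stacklevel=2,
        )
    return ResidenceRecord(
        transition_times=times,
        states=np.array([_CODE_TO_STATE[int(c)] for c in codes]),
    )


@dataclass
class AttemptRecord:
    """Per-attempt decomposition of residencies into failed loops + success.

    ``attempts`` has one row per H->I (or L->I) excursion with columns
    ``residency`` (index of the enclosing residency), ``state`` (the
    metastable state attempting to leave), ``wait`` (sojourn in the
    metastable neighborhood before entering I), ``excursion`` (sojourn in I)
    and ``outcome`` ("fail"/"success").
    """

    attempts: pd.DataFrame
    n_residencies: int

    def summary(self, state: str | None = None) -> dict:
        """Pooled (or per-state) attempt statistics.

        ``attempts_per_residency`` counts failed loops plus the final
        success; ``expected_failures`` estimates E[N].
        """
        df = self.attempts
        if state is not None:
            df = df[df["state"] == state]
        n_succ = int((df["outcome"] == "success").sum())
        n_fail = int((df["outcome"] == "fail").sum())
        fails = df[df["outcome"] == "fail"]
        succs = df[df["outcome"] == "success"]
        if n_succ == 0:
            return {
                "n_attempts": len(df), "n_failed": n_fail, "n_successful": 0,
                "attempts_per_residency": np.nan, "expected_failures": np.nan,
                "mean_wait": float(df["wait"].mean()) if len(df) else np.nan,
                "mean_excursion_fail": np.nan, "mean_excursion_success": np.nan,
                "eq_residence_estimate": np.nan,
            }
        en = n_fail / n_succ
        mean_wait = float(df["wait"].mean())
        m_exc_f = float(fails["excursion"].mean()) if n_fail else 0.0
        m_exc_s = float(succs["excursion"].mean())
        return {
            "n_attempts": len(df),
            "n_failed": n_fail,
            "n_successful": n_succ,
            "attempts_per_residency": (n_fail + n_succ) / n_succ,
            "expected_failures": en,
            "mean_wait": mean_wait,
            "mean_excursion_fail": m_exc_f,
            "mean_excursion_success": m_exc_s,
            # decomposition estimate of the mean residence time
            "eq_residence_estimate": en * (mean_wait + m_exc_f) + (mean_wait + m_exc_s),
        }

    def attempt_time_histogram(self, bins="fd", state: str | None = None):
        """Histogram (density) of attempt waiting times (the H->I times)."""
        df = self.attempts
        if state is not None:
            df = df[df["state"] == state]
        return np.histogram(df["wait"].to_numpy(), bins=bins, density=True)


def attempt_statistics(
    traj, regions: RegionSpec | None = None, discard_first: bool = True
) -> AttemptRecord:
    """Parse a trajectory's H/I/L symbol sequence into transition attempts.

    Failed attempts are H->I->H loops, the final successful attempt is
    H->I->L (and symmetrically from L).  With ``discard_first`` the
    residency containing the initial condition is excluded.
    """
    trace = _get_trace(traj, regions)
    t, c = trace.core_sequence()
    meta_t, meta_c = trace.metastable_entries()
    if len(meta_t) == 0 or not np.any(c == 2):
        warnings.warn("trajectory has no I-entry events; empty attempt record",
                      stacklevel=2)
        return AttemptRecord(
            attempts=pd.DataFrame(
                columns=["residency", "state", "wait", "excursion", "outcome"]
            ),
            n_residencies=0,
        )
    start_t = meta_t[1] if (discard_first and len(meta_t) > 1) else meta_t[0]
    # residency index = number of completed metastable changes so far
    rows = []
    residency = 0
    meta_ptr = 0
    for i in range(1, len(c) - 1):
        # advance residency counter past metastable entries up to t[i]
        while meta_ptr < len(meta_t) and meta_t[meta_ptr] <= t[i]:
            residency = meta_ptr
            meta_ptr += 1
        if c[i] != 2:
            continue
        prev_c, next_c = c[i - 1], c[i + 1]
        if prev_c == 2 or next_c == 2:  # cannot happen after dedup; safety
            continue
        if t[i - 1] < start_t:
            continue
        rows.append(
            {
                "residency": residency,
                "state": _CODE_TO_STATE[int(prev_c)],
                "wait": t[i] - t[i - 1],
                "excursion": t[i + 1] - t[i],
                "outcome": "fail" if next_c == prev_c else "success",
            }
        )
    df = pd.DataFrame(rows, columns=["residency", "state", "wait", "excursion", "outcome"])
    n_res = int(df["residency"].nunique()) if len(df) else 0
    return AttemptRecord(attempts=df, n_residencies=n_res)


# ----------------------------------------------------------------------
# experiment cells and sweeps


def _cell_seed(base: int, *salt: int) -> int:
    ss = np.random.SeedSequence([int(base), *[int(s) for s in salt]])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def run_residence_cell(
    network,
    *,
    kernels: dict | None = None,
    hybrid: HybridConfig | None = None,
    regions: RegionSpec,
    min_residences: int = 100,
    seeds=(0, 1),
    max_events: int = 4 * 10**9,
    want_attempts: bool = False,
) -> dict:
    """Simulate one experiment cell until enough pooled residences accrue.

    The target number of residences is split across the given seeds; each
    seed's first residence (initial-condition burn-in) is discarded.
    Returns a dict with the tidy residence table, per-state and pooled
    means with batch-means standard errors over seeds, and (optionally)
    pooled attempt statistics.
    """
    seeds = list(seeds)
    if len(seeds) < 1:
        raise ValueError("need at least one seed")
    per_seed = -(-min_residences // len(seeds))  # ceil
    frames = []
    attempts = []
    n_residencies = 0
    complete = True
    for s in seeds:
        kwargs = dict(
            t_max=np.inf,
            seed=s,
            regions=regions,
            stop_after_entries=per_seed + 2,  # burn-in + fencepost
            max_events=max_events,
            record_events=False,
        )
        if hybrid is not None:
            traj = simulate_hybrid(network, hybrid, **kwargs)
        else:
            traj = simulate_dssa(network, kernels, **kwargs)
        if traj.n_region_entries < per_seed + 2:
            complete = False
        rec = residence_times(traj)
        df = rec.to_frame(discard_first=True)
        df.insert(0, "seed", s)
        frames.append(df)
        if want_attempts:
            ar = attempt_statistics(traj, discard_first=True)
            attempts.append(ar.attempts)
            n_residencies += ar.n_residencies
    residences = pd.concat(frames, ignore_index=True)

    def _stats(df: pd.DataFrame) -> dict:
        seed_means = df.groupby("seed")["duration"].mean()
        m = float(df["duration"].mean()) if len(df) else np.nan
        se = (
            float(seed_means.std(ddof=1) / np.sqrt(len(seed_means)))
            if len(seed_means) > 1
            else np.nan
        )
        return {"n": int(len(df)), "mean": m, "se": se}

    out = {
        "residences": residences,
        "pooled": _stats(residences),
        "by_state": {
            st: _stats(residences[residences["state"] == st]) for st in ("H", "L")
        },
        "complete": complete,
    }
    if want_attempts:
        all_attempts = pd.concat(attempts, ignore_index=True)
        out["attempts"] = AttemptRecord(all_attempts, n_residencies)
    return out


def _kernel_table(network, family: str, mean: float, cv: float) -> dict:
    return {ref: make_kernel(family, mean, cv) for ref in network.kernel_refs()}


def cv_sweep(
    network,
    family: str = "gamma",
    mean: float = 3.0,
    cv_grid=(0.0, 0.3, 1.0, 3.0),
    min_residences: int = 100,
    seeds=(0, 1),
    regions: RegionSpec | None = None,
    per_state: bool = False,
    max_events: int = 4 * 10**9,
) -> pd.DataFrame:
    """Mean residence time versus delay CV at fixed delay mean.

    For each CV in the grid the network is simulated until ``min_residences``
    pooled residences accrue (split over ``seeds``); the mean residence time
    is normalized by its value at CV = 0 (fixed delay).  Symmetric models
    pool the two metastable states (``per_state=False``); for the
    asymmetric PFL pass ``per_state=True`` to get low/high rows.

    Returns a tidy frame with columns ``cv, state, n_residences,
    mean_residence, se, norm_mean, norm_se, complete``.
    """
    cv_grid = list(cv_grid)
    if 0.0 not in cv_grid:
        raise ValueError("cv grid must include 0 (the normalization baseline)")
    regions = regions or make_regions(network)
    rows = []
    for icv, cv in enumerate(cv_grid):
        cell_seeds = [_cell_seed(s, 1, icv) for s in seeds]
        cell = run_residence_cell(
            network,
            kernels=_kernel_table(network, family, mean, cv),
            regions=regions,
            min_residences=min_residences,
            seeds=cell_seeds,
            max_events=max_events,
        )
        states = ("H", "L") if per_state else ("pooled",)
        for st in states:
            stats = cell["pooled"] if st == "pooled" else cell["by_state"][st]
            rows.append(
                {
                    "cv": cv,
                    "state": st,
                    "n_residences": stats["n"],
                    "mean_residence": stats["mean"],
                    "se": stats["se"],
                    "complete": cell["complete"],
                }
            )
    df = pd.DataFrame(rows)
    base = df[df["cv"] == 0.0].set_index("state")["mean_residence"]
    base_se = df[df["cv"] == 0.0].set_index("state")["se"]
    df["norm_mean"] = [
        r["mean_residence"] / base[r["state"]] for _, r in df.iterrows()
    ]
    df["norm_se"] = [
        r["norm_mean"]
        * np.sqrt(
            (r["se"] / r["mean_residence"]) ** 2
            + (base_se[r["state"]] / base[r["state"]]) ** 2
        )
        if r["cv"] != 0.0
        else 0.0
        for _, r in df.iterrows()
    ]
    return df


def hybrid_cv_sweep(
    network,
    mu: float = 3.0,
    r_grid=(1.0, 16.0, 256.0),
    cv_grid=(0.0, 0.3, 0.6),
    min_residences: int = 100,
    seeds=(0, 1),
    regions: RegionSpec | None = None,
    max_events: int = 4 * 10**9,
    want_attempts: bool = False,
) -> pd.DataFrame:
    """Residence-time heatmap of the delay-switching (unfolded) model.

    Sweeps switching rate ``r`` (rows) and Bernoulli CV ``sigma/mu``
    (columns) with the delay mean held at ``mu``.  The CV = 0 baseline is
    independent of ``r`` (the two modes coincide), so it is simulated once
    as a fixed-delay run and shared by every row for normalization.

    With ``want_attempts`` each cell also reports pooled transition-attempt
    statistics (mean attempts per residency, mean attempt waiting time and
    the decomposition estimate of the residence time).
    """
    cv_grid = list(cv_grid)
    if 0.0 not in cv_grid:
        raise ValueError("cv grid must include 0 (the normalization baseline)")
    regions = regions or make_regions(network)

    base_seeds = [_cell_seed(s, 2, 0) for s in seeds]
    base_cell = run_residence_cell(
        network,
        kernels=_kernel_table(network, "fixed", mu, 0.0),
        regions=regions,
        min_residences=min_residences,
        seeds=base_seeds,
        max_events=max_events,
        want_attempts=want_attempts,
    )
    rows = []

    def _row(r, cv, cell):
        stats = cell["pooled"]
        row = {
            "r": r,
            "cv": cv,
            "n_residences": stats["n"],
            "mean_residence": stats["mean"],
            "se": stats["se"],
            "complete": cell["complete"],
        }
        if want_attempts:
            s = cell["attempts"].summary()
            row.update(
                {
                    "attempts_per_residency": s["attempts_per_residency"],
                    "mean_attempt_wait": s["mean_wait"],
                    "eq_residence_estimate": s["eq_residence_estimate"],
                }
            )
        return row

    for r in r_grid:
        for icv, cv in enumerate(cv_grid):
            if cv == 0.0:
                rows.append(_row(r, 0.0, base_cell))
                continue
            cell_seeds = [_cell_seed(s, 2, int(r * 2**20), icv) for s in seeds]
            cell = run_residence_cell(
                network,
                hybrid=HybridConfig(mu=mu, sigma=cv * mu, r=r),
                regions=regions,
                min_residences=min_residences,
                seeds=cell_seeds,
                max_events=max_events,
                want_attempts=want_attempts,
            )
            rows.append(_row(r, cv, cell))
    df = pd.DataFrame(rows)
    base = base_cell["pooled"]
    df["norm_mean"] = df["mean_residence"] / base["mean"]
    df["norm_se"] = np.where(
        df["cv"] == 0.0,
        0.0,
        df["norm_mean"]
        * np.sqrt(
            (df["se"] / df["mean_residence"]) ** 2 + (base["se"] / base["mean"]) ** 2
        ),
    )
    return df
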