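"""Shared fixtures: pooled simulation statistics at the study conditions.

Simulations are run once per session at the grid of (mu, theta) values the
analyses use — interval length 100,000, twenty replicates per grid point —
and reduced to pooled count Series so that individual tests stay cheap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fracstats import SimulationConfig, run_simulation
from fracstats.runstats import _RunArrays, classify_events, summarize_state

N_INTERVAL = 100_000
N_REPLICATES = 20
MU_GRID = (2.0, 3.0, 6.0, 11.0)
THETA_GRID = (0.5, 0.3, 0.1)


def _base_seed(mu: float, theta: float) -> int:
    return int(mu * 1000 + theta * 100) * 1000


def _pool(acc: pd.Series | None, new: pd.Series) -> pd.Series:
    return new if acc is None else acc.add(new, fill_value=0)


@pytest.fixture(scope="session")
def grid_stats():
    """Pooled one-sided run statistics over the (mu, theta) grid.

    Per grid point: pooled f/rho/pi counts, per-replicate empirical means,
    and (for the points that need them) joint per-run (r, length) arrays,
    per-event (r, realized length) arrays, and event-type classifications.
    """
    out = {}
    for mu in MU_GRID:
        for theta in THETA_GRID:
            f_counts = rho_counts = pi_counts = None
            totals = []
            run_r, run_l = [], []
            ev_r, ev_len = [], []
            classified = []
            for rep in range(N_REPLICATES):
                cfg = SimulationConfig(
                    N=N_INTERVAL, mu=mu, theta_target=theta,
                    seed=_base_seed(mu, theta) + rep,
                )
                state = run_simulation(cfg)
                summ = summarize_state(state)
                f_counts = _pool(f_counts, summ.f_counts)
                rho_counts = _pool(rho_counts, summ.rho_counts)
                pi_counts = _pool(pi_counts, summ.pi_counts)
                totals.append(
                    (summ.theta,
                     float((summ.f_counts * summ.f_counts.index).sum()), summ.n_single_runs,
                     float((summ.rho_counts * summ.rho_counts.index).sum()), summ.n_duplicated_runs)
                )
                ra = _RunArrays(state)
                keep = ra.included(True) & (ra.kinds == 1)
                if (mu, theta) in ((2.0, 0.5), (3.0, 0.3)):
                    run_r.append(ra.r[keep])
                    run_l.append(ra.lengths[keep])
                    keep_ev = ra.included(True)[ra.event_run]
                    ev_r.append(ra.r[ra.event_run][keep_ev])
                    ev_len.append(np.asarray(state.events.realized)[keep_ev])
                if mu == 2.0 and theta == 0.1:
                    classified.append(classify_events(state))
            entry = {
                "f_counts": f_counts.astype(int),
                "rho_counts": rho_counts.astype(int),
                "pi_counts": pi_counts.astype(int),
                "totals": pd.DataFrame(
                    totals,
                    columns=["theta", "single_len", "single_n", "dup_len", "dup_n"],
                ),
            }
            if run_r:
                entry["run_r"] = np.concatenate(run_r)
                entry["run_l"] = np.concatenate(run_l)
                entry["event_r"] = np.concatenate(ev_r)
                entry["event_len"] = np.concatenate(ev_len)
            if classified:
                entry["classified"] = pd.concat(classified, ignore_index=True)
            out[(mu, theta)] = entry
    return out


@pytest.fixture(scope="session")
def mu1_pooled_f():
    """Pooled single-copy run-length counts for gene-by-gene deletion (mu=1)."""
    counts = None
    for rep in range(N_REPLICATES):
        cfg = SimulationConfig(N=N_INTERVAL, mu=1.0, theta_target=0.5, seed=7000 + rep)
        counts = _pool(counts, summarize_state(run_simulation(cfg)).f_counts)
    return counts.astype(int)


@pytest.fixture(scope="session")
def large_interval_f():
    """Pooled f counts at a tripled interval (edge-effect control), mu=2, theta=0.5."""
    counts = None
    for rep in range(N_REPLICATES):
        cfg = SimulationConfig(N=3 * N_INTERVAL, mu=2.0, theta_target=0.5, seed=8000 + rep)
        counts = _pool(counts, summarize_state(run_simulation(cfg)).f_counts)
    return counts.astype(int)


@pytest.fixture(scope="session")
def onesided_surface():
    from fracstats import build_response_surface

    return build_response_surface(
        "one_sided", [1, 2, 3, 4, 5, 6, 8], [0.3, 0.5],
        N=N_INTERVAL, replicates=3, seed=42,
    )


@pytest.fixture(scope="session")
def twosided_surface():
    from fracstats import build_response_surface

    return build_response_surface(
        "two_sided", [1, 2, 3, 4, 6], [0.2, 0.3, 0.4],
        N=50_000, replicates=2, seed=77,
    )


def counts_to_sample(counts: pd.Series) -> np.ndarray:
    return np.repeat(counts.index.to_numpy(), counts.to_numpy().astype(int))
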