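"""Run extraction and empirical statistics of fractionated sequences.

The consolidated sequence ``G + H`` alternates between runs of single-copy
loci (value 1) and runs of surviving duplicate pairs (value 2).  This module
extracts those runs, attributes each deletion event to the unique final
single-copy run containing it (giving the per-run event count ``r``), and
computes the empirical distributions used throughout:

``f(l)``   lengths of single-copy runs,
``rho(l)`` lengths of duplicated (undeleted) runs,
``pi(r)``  number of deletion events composing each single-copy run.

By default the two runs abutting the interval boundary, and runs containing
an event truncated at the boundary, are excluded from the distributions so
that finite-interval statistics estimate the boundary-free process; the
exclusion is a flag so the (negligible) edge effect can be checked
explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import TRUNC_BOUNDARY, GenomePairState

__all__ = [
    "RunRecord",
    "RunSummary",
    "extract_runs",
    "summarize",
    "summarize_state",
    "empirical_pi",
    "event_length_by_r",
    "classify_events",
]

SINGLE_COPY = "single_copy"
DUPLICATED = "duplicated"


@dataclass
class RunRecord:
    """A maximal run of the consolidated sequence.

    ``r`` is the number of deletion events composing the run (single-copy
    runs only; 0 for duplicated runs).
    """

    start: int
    length: int
    kind: str
    r: int = 0
    event_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    is_boundary: bool = False
    has_truncated_event: bool = False

    @property
    def end(self) -> int:
        return self.start + self.length


class _RunArrays:
    """Vectorized run decomposition of a state (internal fast path)."""

    def __init__(self, state: GenomePairState):
        cons = state.consolidated()
        N = state.N
        change = np.flatnonzero(np.diff(cons))
        starts = np.concatenate(([0], change + 1))
        ends = np.concatenate((change + 1, [N]))
        self.N = N
        self.starts = starts
        self.lengths = ends - starts
        self.kinds = cons[starts]  # 1 = single copy, 2 = duplicated
        self.is_boundary = np.zeros(starts.size, dtype=bool)
        self.is_boundary[0] = True
        self.is_boundary[-1] = True

        n_events = len(state.events)
        self.event_run = np.empty(0, dtype=np.int64)
        self.r = np.zeros(starts.size, dtype=np.int64)
        self.has_trunc = np.zeros(starts.size, dtype=bool)
        if n_events:
            first = state.events.first_positions()
            self.event_run = np.searchsorted(starts, first, side="right") - 1
            self.r = np.bincount(self.event_run, minlength=starts.size)
            trunc = np.asarray(state.events.truncated) == TRUNC_BOUNDARY
            if trunc.any():
                self.has_trunc = (
                    np.bincount(self.event_run[trunc], minlength=starts.size) > 0
                )

    def included(self, exclude_boundary: bool) -> np.ndarray:
        if not exclude_boundary:
            return np.ones(self.starts.size, dtype=bool)
        return ~(self.is_boundary | self.has_trunc)


def extract_runs(state: GenomePairState, *, validate: bool = False) -> list[RunRecord]:
    """Decompose a state into maximal alternating runs with ``r`` labels.

    Every deletion event lies within exactly one final single-copy run (its
    deleted and skipped positions form one contiguous single-copy block), so
    ``r`` is obtained by counting the events whose first deleted position
    falls inside the run; for the two-sided model this counts events from
    both homeologs.
    """
    if validate:
        state.validate()
    ra = _RunArrays(state)
    records: list[RunRecord] = []
    if ra.event_run.size:
        order = np.argsort(ra.event_run, kind="stable")
        bounds = np.cumsum(ra.r)
        sorted_ids = order
    for i in range(ra.starts.size):
        kind = SINGLE_COPY if ra.kinds[i] == 1 else DUPLICATED
        if kind == SINGLE_COPY and ra.event_run.size:
            lo = bounds[i - 1] if i else 0
            ids = np.sort(sorted_ids[lo:bounds[i]])
        else:
            ids = np.empty(0, dtype=np.int64)
        records.append(
            RunRecord(
                start=int(ra.starts[i]),
                length=int(ra.lengths[i]),
                kind=kind,
                r=int(ra.r[i]),
                event_ids=ids,
                is_boundary=bool(ra.is_boundary[i]),
                has_truncated_event=bool(ra.has_trunc[i]),
            )
        )
    return records


@dataclass
class RunSummary:
    """Empirical run statistics of one state.

    ``theta`` is the proportion of unreduced (duplicated) positions over the
    whole interval; distributions and means are over the included runs only.
    ``f``, ``rho`` and ``pi`` are normalized; the ``*_counts`` Series carry
    the raw counts for pooling across replicates.
    """

    N: int
    theta: float
    f_counts: pd.Series
    rho_counts: pd.Series
    pi_counts: pd.Series
    mean_single: float
    mean_duplicated: float
    n_single_runs: int
    n_duplicated_runs: int

    @property
    def f(self) -> pd.Series:
        return self.f_counts / max(self.f_counts.sum(), 1)

    @property
    def rho(self) -> pd.Series:
        return self.rho_counts / max(self.rho_counts.sum(), 1)

    @property
    def pi(self) -> pd.Series:
        return self.pi_counts / max(self.pi_counts.sum(), 1)


def _counts(values: np.ndarray, name: str) -> pd.Series:
    if values.size == 0:
        return pd.Series(dtype=np.int64, index=pd.Index([], name=name))
    c = np.bincount(values)
    idx = np.flatnonzero(c)
    return pd.Series(c[idx], index=pd.Index(idx, name=name))


def _summary_from_arrays(ra: _RunArrays, theta: float, exclude_boundary: bool) -> RunSummary:
    if ra.starts.size == 0:
        raise ValueError("empty run list")
    keep = ra.included(exclude_boundary)
    sc = keep & (ra.kinds == 1)
    dp = keep & (ra.kinds == 2)
    sc_len = ra.lengths[sc]
    dp_len = ra.lengths[dp]
    return RunSummary(
        N=ra.N,
        theta=theta,
        f_counts=_counts(sc_len, "l"),
        rho_counts=_counts(dp_len, "l"),
        pi_counts=_counts(ra.r[sc], "r"),
        mean_single=float(sc_len.mean()) if sc_len.size else float("nan"),
        mean_duplicated=float(dp_len.mean()) if dp_len.size else float("nan"),
        n_single_runs=int(sc.sum()),
        n_duplicated_runs=int(dp.sum()),
    )


def summarize_state(state: GenomePairState, *, exclude_boundary: bool = True) -> RunSummary:
    """Summarize a state directly (fast path; see :func:`summarize`)."""
    return _summary_from_arrays(_RunArrays(state), state.theta(), exclude_boundary)


def summarize(runs: list[RunRecord], N: int, *, exclude_boundary: bool = True) -> RunSummary:
    """Empirical theta, f(l), rho(l), pi(r) and mean run lengths.

    ``theta`` is computed from the full tiling; distributions honour the
    boundary-exclusion flag.  The mean lengths of duplicated and single-copy
    runs satisfy the conservation relation
    ``mean_single ~ (1 - theta)/theta * mean_duplicated`` up to sampling and
    boundary effects (the run counts on an interval differ by at most one).
    """
    if not runs:
        raise ValueError("empty run list")
    if sum(rec.length for rec in runs) != N:
        raise ValueError("runs do not tile the interval")
    dup = sum(rec.length for rec in runs if rec.kind == DUPLICATED)
    theta = dup / N

    def keep(rec: RunRecord) -> bool:
        return not exclude_boundary or not (rec.is_boundary or rec.has_truncated_event)

    sc_len = np.array([r.length for r in runs if r.kind == SINGLE_COPY and keep(r)])
    dp_len = np.array([r.length for r in runs if r.kind == DUPLICATED and keep(r)])
    rs = np.array([r.r for r in runs if r.kind == SINGLE_COPY and keep(r)], dtype=np.int64)
    return RunSummary(
        N=N,
        theta=theta,
        f_counts=_counts(sc_len.astype(np.int64), "l"),
        rho_counts=_counts(dp_len.astype(np.int64), "l"),
        pi_counts=_counts(rs, "r"),
        mean_single=float(sc_len.mean()) if sc_len.size else float("nan"),
        mean_duplicated=float(dp_len.mean()) if dp_len.size else float("nan"),
        n_single_runs=int(sc_len.size),
        n_duplicated_runs=int(dp_len.size),
    )


def empirical_pi(runs: list[RunRecord], *, exclude_boundary: bool = True) -> pd.Series:
    """Normalized distribution of the per-run deletion-event count ``r``."""
    rs = [
        r.r
        for r in runs
        if r.kind == SINGLE_COPY
        and (not exclude_boundary or not (r.is_boundary or r.has_truncated_event))
    ]
    if not rs:
        raise ValueError("no single-copy runs")
    counts = _counts(np.asarray(rs, dtype=np.int64), "r")
    return counts / counts.sum()


def event_length_by_r(state: GenomePairState, *, exclude_boundary: bool = True) -> pd.DataFrame:
    """Mean realized deletion length per run-composition class ``r``.

    Longer deletion events have a greater chance of engulfing neighbouring
    runs, so events in high-``r`` runs are, on average, longer — the events
    composing a run are not independent draws from the length distribution.
    """
    if len(state.events) == 0:
        raise ValueError("event log is empty")
    ra = _RunArrays(state)
    keep_run = ra.included(exclude_boundary)
    realized = np.asarray(state.events.realized, dtype=np.int64)
    keep_ev = keep_run[ra.event_run]
    r_of_event = ra.r[ra.event_run][keep_ev]
    length = realized[keep_ev]
    frame = pd.DataFrame({"r": r_of_event, "length": length})
    out = frame.groupby("r")["length"].agg(mean_length="mean", count="size").reset_index()
    return out


_EVENT_TYPES = np.array(["A", "B", "C", "D", "E", "other"])


def classify_events(state: GenomePairState) -> pd.DataFrame:
    """Classify each logged event by how it reshaped the deleted runs.

    Types (one-sided semantics; for two-sided states the classification is
    with respect to the target homeolog):

    - ``A``: new run, touching no pre-existing deleted run;
    - ``B``: extends the deleted run to the left of the anchor's run only;
    - ``C``: reaches the deleted run on the right (possibly eating into the
      following undeleted run) without crossing it entirely;
    - ``D``: merges the deleted run on the right with the one beyond it;
    - ``E``: merges the deleted runs on both sides of the anchor's run;
    - ``other``: merges three or more pre-existing runs.

    Returns one row per event with its ``theta_before`` and truncation flag.
    """
    if len(state.events) == 0:
        return pd.DataFrame(columns=["event_id", "theta_before", "event_type", "truncated"])
    touched = np.asarray(state.events.runs_touched, dtype=int)
    left = np.asarray(state.events.touched_left, dtype=bool)
    kind = np.full(touched.size, 5, dtype=int)  # other
    kind[touched == 0] = 0
    kind[(touched == 1) & left] = 1
    kind[(touched == 1) & ~left] = 2
    kind[(touched == 2) & ~left] = 3
    kind[(touched == 2) & left] = 4
    return pd.DataFrame(
        {
            "event_id": np.arange(touched.size),
            "theta_before": np.asarray(state.events.theta_before, dtype=float),
            "event_type": _EVENT_TYPES[kind],
            "truncated": np.asarray(state.events.truncated, dtype=int),
        }
    )
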