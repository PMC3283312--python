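"""Stochastic simulation of one-sided and two-sided fractionation.

Deletion events are applied sequentially: an anchor is drawn uniformly over
currently eligible positions (one-sided: ``g(i) = 1``; two-sided: positions
still duplicated), a target homeolog is drawn with probability ``phi``
(two-sided only) and an excision length is drawn from the geometric
deletion-length distribution.  The scan converts 1s to 0s rightward from the
anchor, skipping positions already deleted in the target sequence; in the
two-sided model the scan stops at the first position that is single copy on
the other homeolog, truncating the event.  Simulation stops after the first
event that brings the proportion of unreduced positions down to the target
``theta``.

Per-event draw order is fixed (anchor rejection attempts, then target, then
length) from a single ``random.Random(seed)`` stream, so a configuration and
seed reproduce the event log exactly.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass

import numpy as np

from .core import (
    ONE_SIDED,
    TRUNC_BOUNDARY,
    TRUNC_NONE,
    TRUNC_SINGLE_COPY,
    TWO_SIDED,
    DeletionEvent,
    DeletionLengthModel,
    GenomePairState,
)

__all__ = [
    "SimulationConfig",
    "apply_one_sided_event",
    "apply_two_sided_event",
    "run_simulation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one fractionation simulation.

    ``theta_target`` is the proportion of unreduced positions at which to
    stop (the final event completes, so a slight overshoot is accepted).
    ``phi`` is the probability of targeting sequence G per event (two-sided
    only); 0.5 is unbiased fractionation.
    """

    N: int = 100_000
    mu: float = 2.0
    theta_target: float = 0.5
    model: str = ONE_SIDED
    phi: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.mu < 1:
            raise ValueError("mu must be >= 1")
        if not (0.0 < self.theta_target <= 1.0):
            raise ValueError("theta_target must be in (0, 1]")
        if not (0.0 <= self.phi <= 1.0):
            raise ValueError("phi must be in [0, 1]")
        if self.model not in (ONE_SIDED, TWO_SIDED):
            raise ValueError(f"unknown model {self.model!r}")


def _scan_one_sided(g, N: int, anchor: int, a: int):
    """Convert ``a`` ones to zeros rightward of ``anchor`` in ``g``, skipping 0s.

    Mutates ``g`` (any mutable integer sequence).  Returns
    ``(deleted, truncated, runs_touched, touched_left)`` where ``runs_touched``
    counts the distinct pre-existing zero runs the event extends or merges.
    """
    touched_left = anchor > 0 and g[anchor - 1] == 0
    touched = 1 if touched_left else 0
    deleted: list[int] = []
    need = a
    pos = anchor
    in_zero = False
    while need and pos < N:
        if g[pos] == 1:
            g[pos] = 0
            deleted.append(pos)
            need -= 1
            in_zero = False
        else:
            if not in_zero:
                touched += 1
                in_zero = True
        pos += 1
    truncated = TRUNC_BOUNDARY if need else TRUNC_NONE
    if not need and pos < N and g[pos] == 0:
        touched += 1  # right-adjacent pre-existing run
    return deleted, truncated, touched, touched_left


def _scan_two_sided(t, o, N: int, anchor: int, a: int):
    """Like :func:`_scan_one_sided` on target ``t``, stopping where ``o`` is 0."""
    touched_left = anchor > 0 and t[anchor - 1] == 0
    touched = 1 if touched_left else 0
    deleted: list[int] = []
    need = a
    pos = anchor
    in_zero = False
    truncated = TRUNC_NONE
    while need:
        if pos >= N:
            truncated = TRUNC_BOUNDARY
            break
        if t[pos] == 0:
            if not in_zero:
                touched += 1
                in_zero = True
            pos += 1
            continue
        if o[pos] == 0:
            truncated = TRUNC_SINGLE_COPY  # deleting here would kill a single-copy gene
            break
        t[pos] = 0
        deleted.append(pos)
        need -= 1
        in_zero = False
        pos += 1
    if not need and pos < N and t[pos] == 0:
        touched += 1
    return deleted, truncated, touched, touched_left


def apply_one_sided_event(state: GenomePairState, anchor: int, a: int) -> DeletionEvent:
    """Apply one deletion event of requested length ``a`` anchored at ``anchor``.

    The anchor must currently carry a duplicate (``g(anchor) = 1``).  Zeros are
    skipped; the event is truncated (and flagged) only at the interval
    boundary.
    """
    if state.model != ONE_SIDED:
        raise ValueError("state is not in one_sided mode")
    if a < 1:
        raise ValueError("deletion length a must be >= 1")
    if not (0 <= anchor < state.N) or state.g[anchor] != 1:
        raise ValueError(f"anchor {anchor} is not an undeleted position")
    theta_before = state.theta()
    deleted, trunc, touched, left = _scan_one_sided(state.g, state.N, anchor, a)
    i = state.events.append(0, anchor, a, deleted, trunc, theta_before, touched, left)
    return state.events[i]


def apply_two_sided_event(state: GenomePairState, target: str, anchor: int, a: int) -> DeletionEvent:
    """Apply one two-sided deletion event on homeolog ``target`` ("G" or "H")."""
    if state.model != TWO_SIDED:
        raise ValueError("state is not in two_sided mode")
    if a < 1:
        raise ValueError("deletion length a must be >= 1")
    if target not in ("G", "H"):
        raise ValueError("target must be 'G' or 'H'")
    if not (0 <= anchor < state.N) or state.g[anchor] + state.h[anchor] != 2:
        raise ValueError(f"anchor {anchor} is not a duplicated position")
    theta_before = state.theta()
    t, o = (state.g, state.h) if target == "G" else (state.h, state.g)
    deleted, trunc, touched, left = _scan_two_sided(t, o, state.N, anchor, a)
    code = 0 if target == "G" else 1
    i = state.events.append(code, anchor, a, deleted, trunc, theta_before, touched, left)
    return state.events[i]


def run_simulation(config: SimulationConfig) -> GenomePairState:
    """Run a fractionation simulation down to ``config.theta_target``.

    Returns the final :class:`GenomePairState` with its full event log.  The
    same configuration and seed yield a byte-identical log.
    """
    rng = random.Random(config.seed)
    model = DeletionLengthModel(config.mu)
    N = config.N
    two = config.model == TWO_SIDED
    g = [1] * N
    h = [1] * N
    state = GenomePairState(N=N, model=config.model)
    log = state.events

    unreduced = N  # g==1 count (one-sided) or duplicated count (two-sided)
    threshold = config.theta_target * N
    inv_n = 1.0 / N
    randrange = rng.randrange
    rand = rng.random
    phi = config.phi

    while unreduced > threshold:
        if unreduced == 0:  # pragma: no cover - unreachable while threshold >= 0
            logger.warning("no eligible anchors left; stopping early at theta=0")
            break
        # anchor: rejection sampling is uniform over eligible positions
        if two:
            while True:
                i = randrange(N)
                if g[i] == 1 and h[i] == 1:
                    break
            target = 0 if rand() < phi else 1
        else:
            while True:
                i = randrange(N)
                if g[i] == 1:
                    break
            target = 0
        a = model.sample(rng)
        theta_before = unreduced * inv_n
        if two:
            t, o = (g, h) if target == 0 else (h, g)
            deleted, trunc, touched, left = _scan_two_sided(t, o, N, i, a)
        else:
            deleted, trunc, touched, left = _scan_one_sided(g, N, i, a)
        unreduced -= len(deleted)
        log.append(target, i, a, deleted, trunc, theta_before, touched, left)

    state.g = np.asarray(g, dtype=np.int8)
    state.h = np.asarray(h, dtype=np.int8) if two else state.h
    achieved = unreduced * inv_n
    if achieved > config.theta_target and len(log) == 0 and config.theta_target < 1.0:
        logger.warning("stopped before reaching theta target; achieved theta=%.4f", achieved)
    return state
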