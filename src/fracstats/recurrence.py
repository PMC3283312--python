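"""Deterministic recurrence for the deletion-run composition pi(r).

One-sided model.  As the proportion ``theta`` of undeleted loci falls, each
deletion event reshapes the population of deleted runs in one of five ways
(plus a neglected remainder):

- ``A``  falls strictly inside an undeleted run: a new deleted run, r = 1;
- ``B``  starts at the left edge of an undeleted run: extends the deleted run
         on the left from r to r + 1 events;
- ``C``  reaches the deleted run on the right (possibly eating into the next
         undeleted run, but not through it): r to r + 1;
- ``D``  crosses the deleted run on the right and the whole next undeleted
         run, reaching the deleted run beyond: merges two runs of r and s
         events into one of r + s + 1;
- ``E``  consumes its whole undeleted run, bridging the deleted runs on both
         sides: likewise r + s + 1;
- ``other`` merges three or more deleted runs; its probability mass is
  tracked but, by design, not fed back into the recurrence, so the model is
  accurate until ``theta`` becomes small and multi-run mergers common.

The probabilities are computed under the model's own assumptions: undeleted
run lengths ``rho`` are geometric with mean ``E_rho = theta * N / R`` (each
event drops a uniform demarcation among the surviving loci), an event anchors
inside a run of length ``l`` with probability ``l * rho(l) / E_rho`` and at a
uniform offset within it, and the deletion length is geometric with mean
``mu``.  Under the geometric ``rho`` all sums collapse to closed forms, so no
series cutoff is needed; a brute-force truncated summation is kept as a test
oracle.

Writing ``p = 1/E_rho``, ``s = 1 - p``, ``q = 1/mu``, ``t = 1 - q``:

    p_A = (E_rho - 2 - t/(1-t) + p/((1-t)(1-st))) / E_rho
    p_B = (1 - p/(1-st)) / E_rho
    p_C = p_B / (1-st)
    p_D = p_C * p t/(1-st)
    p_E = p q / (E_rho (1-st)^2)

Each step applies ``Lambda`` events at once: ``R' = R + Lambda*sum(delta)``,
``pi' = (R pi + Lambda delta)/R'``, ``theta' = theta - Lambda*mu/N`` (each
event deletes ``mu`` loci in expectation) and ``E_rho' = theta' N / R'``,
which keeps the deleted/undeleted mean-run-length conservation identity
satisfied after every step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "RecurrenceState",
    "EventTypeProbabilities",
    "event_type_probabilities",
    "delta_runs",
    "step",
    "run_recurrence",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EventTypeProbabilities:
    p_A: float
    p_B: float
    p_C: float
    p_D: float
    p_E: float

    @property
    def p_other(self) -> float:
        return max(0.0, 1.0 - (self.p_A + self.p_B + self.p_C + self.p_D + self.p_E))

    def as_tuple(self) -> tuple[float, float, float, float, float, float]:
        return (self.p_A, self.p_B, self.p_C, self.p_D, self.p_E, self.p_other)


@dataclass(frozen=True)
class RecurrenceState:
    """State of the recurrence at one value of theta.

    ``R`` is the number of deleted runs per reference interval of length
    ``N``; ``pi[k]`` is the probability of r = k + 1.  ``other_mass`` is the
    accumulated expected fraction of events that merged three or more runs
    (tracked, never fed back).
    """

    theta: float
    R: float
    pi: np.ndarray
    mu: float
    N: float
    other_mass: float = 0.0
    pi_tail_lost: float = 0.0

    @property
    def mean_rho(self) -> float:
        """Mean undeleted run length E_rho = theta N / R."""
        return self.theta * self.N / self.R

    @property
    def mean_deleted(self) -> float:
        """(1 - theta)/theta * E_rho, the conservation identity."""
        return (1.0 - self.theta) * self.N / self.R

    def validate(self) -> None:
        if not (0.0 < self.theta <= 1.0):
            raise ValueError("theta must be in (0, 1]")
        if abs(self.pi.sum() - 1.0) > 1e-9:
            raise ValueError("pi must sum to 1")
        if np.any(self.pi < -1e-12):
            raise ValueError("pi has negative mass")


def event_type_probabilities(state: RecurrenceState) -> EventTypeProbabilities:
    """Closed-form probabilities of event types A..E at the current state."""
    E = state.mean_rho
    if E < 1.0:
        raise ValueError(f"mean undeleted run length {E:.3f} < 1: inconsistent state")
    p = 1.0 / E
    s = 1.0 - p
    q = 1.0 / state.mu
    t = 1.0 - q
    st = s * t
    if t > 0:
        p_A = (E - 2.0 - t / (1.0 - t) + p / ((1.0 - t) * (1.0 - st))) / E
    else:  # mu = 1: gene-by-gene deletion
        p_A = (E - 2.0 + p) / E
    b_num = 1.0 - p / (1.0 - st)
    p_B = b_num / E
    p_C = b_num / (E * (1.0 - st))
    p_D = p_C * p * t / (1.0 - st)
    p_E = p * q / (E * (1.0 - st) ** 2)
    probs = EventTypeProbabilities(max(p_A, 0.0), p_B, p_C, p_D, p_E)
    total = sum(probs.as_tuple()[:5])
    if total > 1.0 + 1e-9:
        raise ValueError(f"event-type probabilities sum to {total} > 1")
    return probs


def delta_runs(state: RecurrenceState, probs: EventTypeProbabilities) -> np.ndarray:
    """Expected signed change per event in the count of runs with each r.

    Type A adds a run with r = 1; B and C move a pi-distributed run from r to
    r + 1; D and E remove two independent pi-distributed runs r, s and add one
    with r + s + 1.  The total satisfies
    ``sum(delta) = p_A - (p_D + p_E)`` up to the mass lost beyond ``r_max``.
    """
    pi = state.pi
    r_max = pi.size
    p_bc = probs.p_B + probs.p_C
    p_de = probs.p_D + probs.p_E
    delta = np.zeros(r_max)
    delta[0] += probs.p_A
    # lengthen: r -> r+1
    delta -= p_bc * pi
    delta[1:] += p_bc * pi[:-1]
    # merge two runs: (r, s) -> r + s + 1
    if p_de > 0:
        conv = np.convolve(pi, pi)  # conv[k] = P(r + s = k + 2)
        gain = np.zeros(r_max)
        # r + s + 1 = k  =>  index k-1 gains conv[k-3]
        hi = min(r_max, conv.size + 2)
        gain[2:hi] = conv[: hi - 2]
        delta += p_de * gain
        delta -= 2.0 * p_de * pi
    return delta


def step(state: RecurrenceState, lam: float, probs: EventTypeProbabilities | None = None) -> RecurrenceState:
    """Apply ``lam`` deletion events' worth of expected change."""
    if lam < 0:
        raise ValueError("Lambda must be >= 0")
    if lam == 0:
        return state
    if probs is None:
        probs = event_type_probabilities(state)
    delta = delta_runs(state, probs)
    # mass pushed past r_max by the B/C shift and D/E mergers
    tail_bc = (probs.p_B + probs.p_C) * state.pi[-1]
    conv_tail = 0.0
    if probs.p_D + probs.p_E > 0:
        conv = np.convolve(state.pi, state.pi)
        conv_tail = (probs.p_D + probs.p_E) * conv[state.pi.size - 2 :].sum()
    lost = lam * (tail_bc + conv_tail)

    r_new = state.R + lam * float(delta.sum()) + lost
    if r_new <= 0:
        raise ValueError("Lambda too large: run count driven non-positive")
    counts = state.R * state.pi + lam * delta
    if counts.min() < -1e-9 * state.R:
        raise ValueError("Lambda too large: pi mass driven negative")
    counts = np.clip(counts, 0.0, None)
    pi_new = counts / counts.sum()

    theta_new = state.theta - lam * state.mu / state.N
    if theta_new <= 0:
        raise ValueError("Lambda too large: theta driven non-positive")
    other_new = state.other_mass + lam * probs.p_other
    return replace(
        state,
        theta=theta_new,
        R=r_new,
        pi=pi_new,
        other_mass=other_new,
        pi_tail_lost=state.pi_tail_lost + lost / max(r_new, 1.0),
    )


def initial_state(mu: float, N: float = 100_000.0, r_max: int = 200, burn_in_runs: float = 10.0) -> RecurrenceState:
    """Burn-in start just below theta = 1, where every event is type A."""
    pi = np.zeros(r_max)
    pi[0] = 1.0
    theta0 = 1.0 - burn_in_runs * mu / N
    if theta0 <= 0:
        raise ValueError("N too small for the burn-in initialisation")
    return RecurrenceState(theta=theta0, R=burn_in_runs, pi=pi, mu=mu, N=N)


def run_recurrence(
    mu: float,
    theta_stop: float,
    lam: float | None = None,
    r_max: int = 200,
    N: float = 100_000.0,
) -> tuple[pd.DataFrame, RecurrenceState]:
    """Iterate the recurrence from theta ~ 1 down to ``theta_stop``.

    ``lam`` is the number of events per step; the default deletes 0.1% of the
    remaining undeleted mass per step (adaptive), favouring accuracy — large
    steps make the trajectory lag behind the stochastic process.  Returns the
    per-step trajectory (theta, R, event-type probabilities, mean run
    lengths) and the final state.
    """
    if mu < 1:
        raise ValueError("mu must be >= 1")
    if not (0.0 < theta_stop < 1.0):
        raise ValueError("theta_stop must be in (0, 1)")
    state = initial_state(mu, N=N, r_max=r_max)
    if theta_stop >= state.theta:
        raise ValueError("theta_stop is above the burn-in starting theta")
    rows = []
    while state.theta > theta_stop:
        probs = event_type_probabilities(state)
        step_lam = lam if lam is not None else max(1.0, 0.001 * state.theta * N / mu)
        # do not overshoot theta_stop by more than one step
        max_lam = (state.theta - theta_stop) * N / mu
        step_lam = min(step_lam, max_lam) if max_lam > 0 else step_lam
        rows.append(
            {
                "theta": state.theta,
                "R": state.R,
                "p_A": probs.p_A,
                "p_B": probs.p_B,
                "p_C": probs.p_C,
                "p_D": probs.p_D,
                "p_E": probs.p_E,
                "p_other": probs.p_other,
                "mean_rho": state.mean_rho,
                "mean_deleted": state.mean_deleted,
                "lambda": step_lam,
            }
        )
        state = step(state, step_lam, probs)
    if state.pi_tail_lost > 1e-6:
        logger.warning(
            "pi support cutoff r_max=%d lost %.2e probability mass; increase r_max",
            r_max, state.pi_tail_lost,
        )
    state.validate()
    return pd.DataFrame(rows), state
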