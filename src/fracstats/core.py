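"""Shared data model for fractionation statistics.

After a whole genome duplication (WGD) every ancestral locus is present in
two copies, one on each homeologous chromosome.  Fractionation — the loss of
one member of each duplicate pair — is modelled here on a finite interval of
``N`` loci as a pair of binary sequences ``(G, H)`` with the functional
constraint ``g(i) + h(i) >= 1``: both copies of a gene are never lost.

Deletion events excise a geometrically distributed number of genes
(mean ``mu``) from one homeolog.  This module holds the deletion-length
distribution, the negative-binomial mixture that approximates single-copy
run lengths, and the :class:`GenomePairState` container with its auditable
event log.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DeletionLengthModel",
    "DeletionEvent",
    "EventLog",
    "GenomePairState",
    "negative_binomial_mixture_pmf",
]

ONE_SIDED = "one_sided"
TWO_SIDED = "two_sided"

#: truncation codes stored in the event log
TRUNC_NONE = 0
TRUNC_BOUNDARY = 1  # ran off the end of the finite interval
TRUNC_SINGLE_COPY = 2  # two-sided stop at a single-copy gene

_TRUNC_LABELS = {TRUNC_NONE: None, TRUNC_BOUNDARY: "boundary", TRUNC_SINGLE_COPY: "single_copy"}


class DeletionLengthModel:
    """Geometric distribution of genes excised per deletion event.

    ``gamma(a) = (1/mu) * (1 - 1/mu)**(a - 1)`` for ``a >= 1``; the mean is
    ``mu``.  ``mu = 1`` degenerates to a point mass at ``a = 1`` (gene-by-gene
    deletion).
    """

    def __init__(self, mu: float):
        if mu < 1:
            raise ValueError(f"mean deletion length mu must be >= 1, got {mu}")
        self.mu = float(mu)
        self.q = 1.0 / self.mu  # geometric success probability

    def pmf(self, a) -> np.ndarray | float:
        a = np.asarray(a)
        out = np.where(a >= 1, self.q * (1.0 - self.q) ** (np.maximum(a, 1) - 1), 0.0)
        return out if out.ndim else float(out)

    def support_cutoff(self, tail: float = 1e-12) -> int:
        """Smallest A with P(a > A) < ``tail``."""
        if self.mu == 1.0:
            return 1
        # P(a > A) = (1 - q)**A
        return max(1, math.ceil(math.log(tail) / math.log(1.0 - self.q)))

    def sample(self, rng) -> int:
        """Draw one length from ``gamma`` using inversion on ``rng.random()``.

        ``rng`` is a ``random.Random``-like object with a ``random()`` method.
        """
        if self.mu == 1.0:
            return 1
        u = rng.random()
        while u <= 0.0:  # pragma: no cover - random() is [0, 1)
            u = rng.random()
        return max(1, math.ceil(math.log(u) / math.log(1.0 - self.q)))

    def __repr__(self) -> str:  # pragma: no cover
        return f"DeletionLengthModel(mu={self.mu})"


def negative_binomial_mixture_pmf(pi, mu: float, tail: float = 1e-12) -> pd.Series:
    """Mixture of negative binomials approximating single-copy run lengths.

    A run produced by ``r`` deletion events has length distributed (under the
    independence approximation) as the sum of ``r`` geometric(1/mu) variables,
    i.e. negative binomial on support ``l >= r`` with mean ``r * mu``.  Given a
    distribution ``pi`` over ``r >= 1`` this returns
    ``p(l) = sum_r pi(r) * NB(l; r, 1/mu)`` as a Series indexed by ``l``.

    ``pi`` may be a mapping ``{r: prob}`` or a sequence whose first entry is
    ``pi(1)``.  The support is cut where the cumulative tail mass drops below
    ``tail``; the returned pmf sums to 1 within that tolerance.
    """
    if mu < 1:
        raise ValueError("mu must be >= 1")
    if hasattr(pi, "items"):
        items = sorted(pi.items())
        rs = np.array([r for r, _ in items], dtype=int)
        ws = np.array([w for _, w in items], dtype=float)
    else:
        ws = np.asarray(pi, dtype=float)
        rs = np.arange(1, ws.size + 1)
    if rs.size == 0:
        raise ValueError("pi has empty support")
    if np.any(rs < 1) or np.any(ws < 0):
        raise ValueError("pi must be supported on r >= 1 with non-negative mass")
    total = ws.sum()
    if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-8):
        raise ValueError(f"pi must be normalized (sums to {total})")

    q = 1.0 / mu
    # support cutoff: the heaviest-tailed component is the largest r
    r_hi = int(rs.max())
    if mu == 1.0:
        l_max = r_hi
    else:
        l_max = r_hi
        while stats.nbinom.sf(l_max - r_hi, r_hi, q) > tail:
            l_max = max(l_max + 16, int(l_max * 1.5))
    ls = np.arange(1, l_max + 1)
    p = np.zeros(ls.size)
    for r, w in zip(rs, ws):
        if w == 0:
            continue
        mask = ls >= r
        p[mask] += w * stats.nbinom.pmf(ls[mask] - r, r, q)
    return pd.Series(p, index=pd.Index(ls, name="l"), name="p")


@dataclass
class DeletionEvent:
    """A single excision event, as recorded in the log.

    ``realized < requested`` only when the event was truncated, either at the
    interval boundary or (two-sided model) at a single-copy gene it was
    forbidden to delete.
    """

    event_id: int
    target: str  # "G" or "H"
    anchor: int
    requested: int
    realized: int
    deleted_positions: np.ndarray
    truncated: str | None  # None | "boundary" | "single_copy"
    theta_before: float = math.nan
    runs_touched: int = -1  # pre-existing deleted runs merged/extended (-1: not tracked)
    touched_left: bool = False

    def __post_init__(self):
        pos = np.asarray(self.deleted_positions, dtype=np.int64)
        if pos.size and (np.any(np.diff(pos) <= 0) or pos[0] < self.anchor):
            raise ValueError("deleted_positions must be strictly increasing, all >= anchor")
        if self.realized != pos.size:
            raise ValueError("realized must equal |deleted_positions|")
        if self.realized < self.requested and self.truncated is None:
            raise ValueError("realized < requested requires a truncation flag")
        self.deleted_positions = pos


class EventLog:
    """Columnar, append-only log of deletion events.

    Stores one row per event plus a flat array of deleted positions with
    offsets, which keeps million-event simulations cheap.  Indexing returns a
    :class:`DeletionEvent` view.
    """

    def __init__(self):
        self.target: list[int] = []  # 0 = G, 1 = H
        self.anchor: list[int] = []
        self.requested: list[int] = []
        self.realized: list[int] = []
        self.truncated: list[int] = []
        self.theta_before: list[float] = []
        self.runs_touched: list[int] = []
        self.touched_left: list[bool] = []
        self._flat: list[int] = []
        self._offsets: list[int] = [0]

    def append(self, target: int, anchor: int, requested: int, positions: Sequence[int],
               truncated: int, theta_before: float = math.nan,
               runs_touched: int = -1, touched_left: bool = False) -> int:
        self.target.append(target)
        self.anchor.append(anchor)
        self.requested.append(requested)
        self.realized.append(len(positions))
        self.truncated.append(truncated)
        self.theta_before.append(theta_before)
        self.runs_touched.append(runs_touched)
        self.touched_left.append(touched_left)
        self._flat.extend(positions)
        self._offsets.append(len(self._flat))
        return len(self.target) - 1

    def __len__(self) -> int:
        return len(self.target)

    def positions(self, i: int) -> np.ndarray:
        return np.asarray(self._flat[self._offsets[i]:self._offsets[i + 1]], dtype=np.int64)

    def first_positions(self) -> np.ndarray:
        """First deleted position of every event (its events all share a run)."""
        off = np.asarray(self._offsets[:-1], dtype=np.int64)
        return np.asarray(self._flat, dtype=np.int64)[off] if self._flat else np.empty(0, np.int64)

    def all_positions(self) -> np.ndarray:
        return np.asarray(self._flat, dtype=np.int64)

    def __getitem__(self, i: int) -> DeletionEvent:
        if i < 0:
            i += len(self)
        return DeletionEvent(
            event_id=i,
            target="GH"[self.target[i]],
            anchor=self.anchor[i],
            requested=self.requested[i],
            realized=self.realized[i],
            deleted_positions=self.positions(i),
            truncated=_TRUNC_LABELS[self.truncated[i]],
            theta_before=self.theta_before[i],
            runs_touched=self.runs_touched[i],
            touched_left=self.touched_left[i],
        )

    def __iter__(self) -> Iterator[DeletionEvent]:
        return (self[i] for i in range(len(self)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "event_id": np.arange(len(self)),
                "target": np.where(np.asarray(self.target, dtype=int) == 0, "G", "H"),
                "anchor": np.asarray(self.anchor, dtype=np.int64),
                "requested": np.asarray(self.requested, dtype=np.int64),
                "realized": np.asarray(self.realized, dtype=np.int64),
                "truncated": [_TRUNC_LABELS[t] or "" for t in self.truncated],
                "theta_before": np.asarray(self.theta_before, dtype=float),
                "runs_touched": np.asarray(self.runs_touched, dtype=int),
                "touched_left": np.asarray(self.touched_left, dtype=bool),
            }
        )


@dataclass
class GenomePairState:
    """Paired binary gene-presence sequences on the interval ``[0, N)``.

    ``g[i] + h[i] >= 1`` always holds (both copies of a duplicate pair are
    never deleted).  In the one-sided model ``h`` stays all ones.  The event
    log records every excision so any state is auditable against it.
    """

    N: int
    model: str = ONE_SIDED
    g: np.ndarray = None
    h: np.ndarray = None
    events: EventLog = field(default_factory=EventLog)

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("interval length N must be >= 1")
        if self.model not in (ONE_SIDED, TWO_SIDED):
            raise ValueError(f"unknown model {self.model!r}")
        if self.g is None:
            self.g = np.ones(self.N, dtype=np.int8)
        else:
            self.g = np.asarray(self.g, dtype=np.int8)
        if self.h is None:
            self.h = np.ones(self.N, dtype=np.int8)
        else:
            self.h = np.asarray(self.h, dtype=np.int8)
        if self.g.shape != (self.N,) or self.h.shape != (self.N,):
            raise ValueError("g and h must have length N")

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        """Raise if any structural invariant is violated."""
        if np.any(self.g + self.h < 1):
            raise ValueError("invariant violated: g(i) + h(i) >= 1")
        if self.model == ONE_SIDED and np.any(self.h != 1):
            raise ValueError("one-sided model requires h == 1 everywhere")
        zeros = set(np.flatnonzero(self.g == 0)) | {
            self.N + int(i) for i in np.flatnonzero(self.h == 0)
        }
        logged: set[int] = set()
        for i in range(len(self.events)):
            off = self.N if self.events.target[i] == 1 else 0
            for p in self.events.positions(i):
                key = off + int(p)
                if key in logged:
                    raise ValueError(f"position {p} deleted twice in the log")
                logged.add(key)
        if logged != zeros:
            raise ValueError("event log does not account exactly for the zero entries")

    # -- observables ------------------------------------------------------
    def theta(self) -> float:
        """Proportion of unreduced positions.

        One-sided: fraction with ``g(i) = 1``; two-sided: fraction still
        duplicated, ``g(i) + h(i) = 2``.
        """
        if self.model == ONE_SIDED:
            return float(np.mean(self.g == 1))
        return float(np.mean(self.g + self.h == 2))

    def consolidated(self) -> np.ndarray:
        """``G + H``: 1 marks a single-copy locus, 2 a surviving duplicate pair."""
        return (self.g + self.h).astype(np.int8)

    # -- serialization ----------------------------------------------------
    def to_tsv(self, prefix: str | Path, header_comment: str = "") -> tuple[Path, Path]:
        """Write ``<prefix>.state.tsv`` and ``<prefix>.events.tsv``."""
        prefix = Path(prefix)
        state_path = prefix.with_name(prefix.name + ".state.tsv")
        events_path = prefix.with_name(prefix.name + ".events.tsv")
        state = pd.DataFrame({"position": np.arange(self.N), "g": self.g, "h": self.h})
        ev = self.events.to_frame()
        ev["deleted_positions"] = [
            ",".join(map(str, self.events.positions(i))) for i in range(len(self.events))
        ]
        for path, frame in ((state_path, state), (events_path, ev)):
            with open(path, "w") as fh:
                if header_comment:
                    for line in header_comment.splitlines():
                        fh.write(f"# {line}\n")
                fh.write(f"# model={self.model} N={self.N}\n")
                frame.to_csv(fh, sep="\t", index=False)
        return state_path, events_path

    @classmethod
    def from_tsv(cls, prefix: str | Path) -> "GenomePairState":
        prefix = Path(prefix)
        state_path = prefix.with_name(prefix.name + ".state.tsv")
        events_path = prefix.with_name(prefix.name + ".events.tsv")
        model = ONE_SIDED
        with open(state_path) as fh:
            for line in fh:
                if line.startswith("# model="):
                    model = line.split("model=")[1].split()[0]
                if not line.startswith("#"):
                    break
        state = pd.read_csv(state_path, sep="\t", comment="#")
        ev = pd.read_csv(events_path, sep="\t", comment="#", keep_default_na=False)
        obj = cls(N=len(state), model=model,
                  g=state["g"].to_numpy(), h=state["h"].to_numpy())
        trunc_codes = {v or "": k for k, v in _TRUNC_LABELS.items()}
        for _, row in ev.iterrows():
            pos = [int(x) for x in str(row["deleted_positions"]).split(",") if x != ""]
            obj.events.append(
                target=0 if row["target"] == "G" else 1,
                anchor=int(row["anchor"]),
                requested=int(row["requested"]),
                positions=pos,
                truncated=trunc_codes[str(row["truncated"])],
                theta_before=float(row["theta_before"]),
                runs_touched=int(row["runs_touched"]),
                touched_left=bool(row["touched_left"]),
            )
        return obj
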