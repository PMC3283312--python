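"""Estimating the mean excision length mu from observed run statistics.

The excision length itself is never observable in a fractionated genome —
only the accumulation of events into single-copy runs.  What can be measured
are the proportion ``theta`` of ancestral loci still present as duplicate
pairs and the mean single-copy run length ``u_bar``.  Because the mean run
length at a given ``theta`` increases monotonically with ``mu``, a
Monte-Carlo response surface of mean run length over a (mu, theta) grid can
be inverted at the observed ``u_bar`` to give an estimate of ``mu``.

For real genomes the observable runs (analytical units, AUs) are additionally
biased short: a rearrangement breakpoint anywhere in an AU of length ``u``
(``u + 1`` internal adjacencies including the two flanking ones) destroys it.
With per-adjacency disruption probability ``alpha * D`` (``D`` rearrangements
per gene since the WGD, ``alpha <= 1`` a proportionality constant, 0.5 by
experience) an AU survives with probability ``(1 - alpha*D)**(u + 1)``, so
``f(u) / (1 - alpha*D)**(u + 1)`` estimates the rearrangement-free run-length
frequencies.  Treating ``f`` as geometric with mean ``u_bar``, the corrected
distribution is again geometric with ratio
``z = (1 - 1/u_bar) / (1 - alpha*D)`` and mean ``nu = 1/(1 - z)``; the
correction diverges when ``alpha*D >= 1/u_bar`` (the corrected series is no
longer summable), which is why the procedure is sensitive to ``alpha``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ONE_SIDED, TWO_SIDED
from .runstats import summarize_state
from .simulate import SimulationConfig, run_simulation

__all__ = [
    "GenomeSummary",
    "ResponseSurface",
    "MuEstimate",
    "theta_from_counts",
    "load_wgd_descendants",
    "build_response_surface",
    "estimate_mu",
    "rearrangement_correction",
    "CorrectionDivergenceError",
]

logger = logging.getLogger(__name__)


def theta_from_counts(n: int, m: int, *, allow_odd: bool = False) -> tuple[float, float]:
    """Proportion of unreduced duplicate pairs from gene counts.

    With ``n`` total genes and ``m`` single-copy genes, the surviving
    duplicate pairs number ``P = (n - m)/2`` and the ancestral post-WGD loci
    ``L = P + m``; then ``theta = P / L``.  Returns ``(theta, 1 - theta)``.
    ``n - m`` must be even (pairs are whole) unless ``allow_odd`` floors it
    with a warning.
    """
    if m < 0 or n <= m:
        raise ValueError("need n > m >= 0")
    if (n - m) % 2:
        if not allow_odd:
            raise ValueError(f"n - m = {n - m} is odd: duplicate pairs are not whole")
        logger.warning("n - m = %d is odd; flooring the pair count", n - m)
    pairs = (n - m) // 2
    loci = pairs + m
    theta = pairs / loci
    return theta, m / loci


@dataclass
class GenomeSummary:
    """Per-genome summary row: counts, derived theta, and run statistics.

    ``d`` (rearrangement distance) is user-supplied when available; it is
    never computed here.
    """

    name: str
    n: int
    m: int
    u_bar: float = math.nan
    d: float = math.nan
    t_mya: float = math.nan

    @property
    def pairs(self) -> int:
        return (self.n - self.m) // 2

    @property
    def loci(self) -> int:
        return self.pairs + self.m

    @property
    def theta(self) -> float:
        return theta_from_counts(self.n, self.m)[0]

    @property
    def one_minus_theta(self) -> float:
        return theta_from_counts(self.n, self.m)[1]

    @property
    def D(self) -> float:
        """Rearrangements per gene since the WGD, d / (n - m)."""
        return self.d / (self.n - self.m)


def load_wgd_descendants() -> pd.DataFrame:
    """The packaged 15-genome summary table (6 distinct WGD events).

    Columns: genome, t_mya, n, m, one_minus_theta (as printed in the source
    survey, for regression checks), u_bar.
    """
    with resources.files("fracstats").joinpath("data/wgd_descendants.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


@dataclass
class ResponseSurface:
    """Monte-Carlo map (mu, theta) -> expected mean single-copy run length.

    ``table`` has columns mu, theta, mean_run_length, se, replicates.  The
    mean run length is strictly increasing in mu at fixed theta and grows as
    theta decreases, which is what makes the inversion well posed.
    """

    model: str
    table: pd.DataFrame
    N: int = 100_000

    @property
    def mu_grid(self) -> np.ndarray:
        return np.sort(self.table["mu"].unique())

    @property
    def theta_grid(self) -> np.ndarray:
        return np.sort(self.table["theta"].unique())

    def slice_at_theta(self, theta: float, edge_tol: float = 1e-3) -> pd.DataFrame:
        """Linear interpolation of the surface at one theta, per mu.

        ``edge_tol`` absorbs the small overshoot of simulated stopping thetas
        just past a grid edge; anything farther outside the grid is an error.
        """
        tg = self.theta_grid
        if not (tg.min() - edge_tol <= theta <= tg.max() + edge_tol):
            raise ValueError(f"theta={theta} outside surface range [{tg.min()}, {tg.max()}]")
        theta = float(np.clip(theta, tg.min(), tg.max()))
        rows = []
        for mu, grp in self.table.groupby("mu"):
            grp = grp.sort_values("theta")
            mean = float(np.interp(theta, grp["theta"], grp["mean_run_length"]))
            se = float(np.interp(theta, grp["theta"], grp["se"]))
            rows.append({"mu": mu, "mean_run_length": mean, "se": se})
        return pd.DataFrame(rows).sort_values("mu").reset_index(drop=True)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# response surface model={self.model} N={self.N}\n")
            self.table.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ResponseSurface":
        model, N = TWO_SIDED, 100_000
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("# response surface"):
                parts = dict(p.split("=") for p in first.split()[3:])
                model = parts.get("model", model)
                N = int(parts.get("N", N))
        return cls(model=model, table=pd.read_csv(path, sep="\t", comment="#"), N=N)


def build_response_surface(
    model: str,
    mu_grid,
    theta_grid,
    N: int = 100_000,
    replicates: int = 3,
    seed: int = 0,
    phi: float = 0.5,
) -> ResponseSurface:
    """Simulate the mean single-copy run length over a (mu, theta) grid.

    Per grid point the mean over ``replicates`` independent simulations is
    recorded together with its standard error.  At very small theta the
    process percolates (runs merge at a rapidly increasing rate) and the
    standard errors grow accordingly; they are reported, not hidden.
    """
    if model not in (ONE_SIDED, TWO_SIDED):
        raise ValueError(f"unknown model {model!r}")
    if replicates < 1 or len(list(mu_grid)) == 0 or len(list(theta_grid)) == 0:
        raise ValueError("need non-empty grids and replicates >= 1")
    rows = []
    counter = 0
    for mu in mu_grid:
        for theta in theta_grid:
            means = []
            for rep in range(replicates):
                cfg = SimulationConfig(
                    N=N, mu=float(mu), theta_target=float(theta), model=model,
                    phi=phi, seed=seed + 1_000_003 * counter + rep,
                )
                summ = summarize_state(run_simulation(cfg))
                means.append(summ.mean_single)
            counter += 1
            means = np.asarray(means)
            se = float(means.std(ddof=1) / math.sqrt(replicates)) if replicates > 1 else 0.0
            rows.append(
                {"mu": float(mu), "theta": float(theta),
                 "mean_run_length": float(means.mean()), "se": se,
                 "replicates": replicates}
            )
    return ResponseSurface(model=model, table=pd.DataFrame(rows), N=N)


@dataclass
class MuEstimate:
    """Point estimate of mu with a heuristic +/- 1 SE interval.

    ``flag`` is None for an interior estimate, ``"le_min"`` when the observed
    run length is at or below the smallest grid mu's curve (so only an upper
    bound ``mu <= mu_hat`` is supported), ``"ge_max"`` symmetrically.
    """

    mu_hat: float
    lo: float
    hi: float
    flag: str | None = None


def estimate_mu(u_bar_observed: float, theta_observed: float, surface: ResponseSurface) -> MuEstimate:
    """Invert the response surface at an observed mean run length.

    The theta slice of the surface gives a curve mean-run-length(mu),
    monotone increasing; linear interpolation inverts it at
    ``u_bar_observed``.  The interval propagates +/- 1 SE of the surface
    through the same inversion (heuristic: no formal inferential procedure is
    attached to the run statistics).
    """
    if u_bar_observed < 1.0:
        raise ValueError("mean run length below 1 is inconsistent with the model")
    sl = surface.slice_at_theta(theta_observed)
    mus = sl["mu"].to_numpy()
    means = sl["mean_run_length"].to_numpy()
    ses = sl["se"].to_numpy()
    if np.any(np.diff(means) <= 0):
        logger.warning("response surface slice is not strictly increasing in mu")

    def invert(target: float) -> float:
        return float(np.interp(target, means, mus))

    if u_bar_observed <= means[0]:
        return MuEstimate(mu_hat=float(mus[0]), lo=float(mus[0]), hi=float(mus[0]), flag="le_min")
    if u_bar_observed >= means[-1]:
        return MuEstimate(mu_hat=float(mus[-1]), lo=float(mus[-1]), hi=float(mus[-1]), flag="ge_max")
    mu_hat = invert(u_bar_observed)
    # +/- 1 SE bands: shifting the curve up lowers the inverted mu
    lo = float(np.interp(u_bar_observed, means + ses, mus))
    hi = float(np.interp(u_bar_observed, means - ses, mus))
    return MuEstimate(mu_hat=mu_hat, lo=min(lo, hi), hi=max(lo, hi), flag=None)


class CorrectionDivergenceError(ValueError):
    """The rearrangement correction diverges: alpha*D >= 1/u_bar.

    The corrected geometric ratio z reaches 1 and the corrected run-length
    distribution is no longer summable — the procedure is very sensitive to
    the arbitrary proportionality constant alpha.
    """


def rearrangement_correction(u_bar: float, D: float, alpha: float = 0.5) -> float:
    """Rearrangement-survival-corrected mean run length nu.

    Assumes the observed run-length distribution is geometric with mean
    ``u_bar`` and that an AU of length ``u`` survived rearrangement with
    probability ``(1 - alpha*D)**(u+1)``.  Dividing out the survival and
    renormalizing leaves a geometric with ratio
    ``z = (1 - 1/u_bar)/(1 - alpha*D)`` and mean ``nu = 1/(1 - z) >= u_bar``.
    """
    if u_bar <= 1.0:
        raise ValueError("u_bar must exceed 1")
    aD = alpha * D
    if not (0.0 <= aD < 1.0):
        raise ValueError("alpha*D must lie in [0, 1)")
    z = (1.0 - 1.0 / u_bar) / (1.0 - aD)
    if z >= 1.0:
        raise CorrectionDivergenceError(
            f"alpha*D = {aD:.4f} >= 1/u_bar = {1.0 / u_bar:.4f}: corrected distribution diverges"
        )
    return 1.0 / (1.0 - z)
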