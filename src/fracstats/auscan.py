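"""Analytical-unit detection in annotated gene orders.

In a real WGD descendant most single-copy runs cannot be attributed to
fractionation because rearrangements have shuffled the homeologous regions.
An *analytical unit* (AU) is a two-sided single-copy run that demonstrably
escaped disruption: it is flanked at both ends by an intact duplicate pair,
the two flanking genes on each chromosome share orientation, and no interior
gene has a paralog outside the unit's two regions.  The AU's observable run
length is ``u = s1 + s2``, the single-copy genes pooled over the two regions.

The module also generates synthetic rearranged descendants (two-sided
fractionation laid out on two chromosomes, followed by random inversions) so
the detection and the rearrangement-survival correction can be validated
end to end against known parameters.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass
from collections import Counter, defaultdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core import TWO_SIDED
from .simulate import SimulationConfig, run_simulation

__all__ = [
    "GeneRecord",
    "AURecord",
    "read_gene_order",
    "write_gene_order",
    "find_analytical_units",
    "au_length_fit",
    "generate_synthetic_descendant",
]

logger = logging.getLogger(__name__)

GENE_ORDER_COLUMNS = ["genome", "chromosome", "index", "gene_id", "orientation", "family_id"]


@dataclass(frozen=True)
class GeneRecord:
    """One gene in an annotated order: 0-based position along its chromosome.

    ``family_id`` is empty/None for singletons; paralogy is taken as given,
    never inferred.
    """

    genome: str
    chromosome: str
    index: int
    gene_id: str
    orientation: str
    family_id: str | None = None


@dataclass
class AURecord:
    """An analytical unit: two homeologous single-copy regions.

    ``region1``/``region2`` are ``(chromosome, start, end)`` half-open index
    ranges of the interior single-copy genes; ``u = s1 + s2`` may be 0
    (adjacent duplicate pairs).  ``same_chromosome`` flags units whose two
    regions lie on one chromosome (remote regions of a single chromosome).
    """

    flank_left: tuple[str, str]
    flank_right: tuple[str, str]
    region1: tuple[str, int, int]
    region2: tuple[str, int, int]
    s1: int
    s2: int

    @property
    def u(self) -> int:
        return self.s1 + self.s2

    @property
    def same_chromosome(self) -> bool:
        return self.region1[0] == self.region2[0]


def read_gene_order(path: str | Path) -> list[GeneRecord]:
    """Read a gene-order TSV (columns: genome, chromosome, index, gene_id,
    orientation, family_id; family_id empty for singletons)."""
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False, dtype=str)
    missing = set(GENE_ORDER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene-order file missing columns: {sorted(missing)}")
    records = []
    seen = set()
    for row in df.itertuples(index=False):
        if row.orientation not in ("+", "-"):
            raise ValueError(f"malformed orientation {row.orientation!r} for {row.gene_id}")
        key = (row.genome, row.chromosome, int(row.index))
        if key in seen:
            raise ValueError(f"duplicate position {key}")
        seen.add(key)
        records.append(
            GeneRecord(
                genome=row.genome,
                chromosome=row.chromosome,
                index=int(row.index),
                gene_id=row.gene_id,
                orientation=row.orientation,
                family_id=row.family_id or None,
            )
        )
    for (genome, chrom), group in _by_chromosome(records).items():
        idx = sorted(g.index for g in group)
        if idx != list(range(len(idx))):
            raise ValueError(f"indices on {genome}/{chrom} are not contiguous from 0")
    return records


def write_gene_order(records: list[GeneRecord], path: str | Path, header_comment: str = "") -> None:
    df = pd.DataFrame(
        [
            {
                "genome": g.genome, "chromosome": g.chromosome, "index": g.index,
                "gene_id": g.gene_id, "orientation": g.orientation,
                "family_id": g.family_id or "",
            }
            for g in sorted(records, key=lambda g: (g.genome, g.chromosome, g.index))
        ],
        columns=GENE_ORDER_COLUMNS,
    )
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def _by_chromosome(records: list[GeneRecord]) -> dict[tuple[str, str], list[GeneRecord]]:
    out: dict[tuple[str, str], list[GeneRecord]] = defaultdict(list)
    for g in records:
        out[(g.genome, g.chromosome)].append(g)
    for group in out.values():
        group.sort(key=lambda g: g.index)
    return out


def family_sizes(records: list[GeneRecord]) -> Counter:
    return Counter(g.family_id for g in records if g.family_id)


def find_analytical_units(records: list[GeneRecord]) -> list[AURecord]:
    """All maximal AUs in a single genome's gene order.

    Anchors are the members of two-member paralog families (only those can
    form intact post-WGD duplicate pairs; larger families are flagged and
    excluded).  A candidate segment is the stretch between two *consecutive*
    anchors on a chromosome whose flanking anchors share orientation and
    whose interior genes have no paralog anywhere (interior members of larger
    families disqualify the segment — their paralogs lie outside the unit).
    Two segments bounded by the same pair of families, using all four family
    members, form one AU.
    """
    genomes = {g.genome for g in records}
    if len(genomes) > 1:
        raise ValueError(f"records span multiple genomes: {sorted(genomes)}")
    sizes = family_sizes(records)
    big = {f for f, c in sizes.items() if c != 2}
    if big:
        logger.warning("%d families with size != 2 excluded from the pair index", len(big))
    pair_families = {f for f, c in sizes.items() if c == 2}

    # candidate segments between consecutive anchors, keyed by family pair
    segments: dict[frozenset, list[dict]] = defaultdict(list)
    for (_, chrom), genes in _by_chromosome(records).items():
        anchors = [g for g in genes if g.family_id in pair_families]
        for left, right in zip(anchors, anchors[1:]):
            interior = genes[left.index + 1 : right.index]
            if any(g.family_id and sizes[g.family_id] >= 2 for g in interior):
                continue  # an interior gene has a paralog outside the unit
            if left.orientation != right.orientation:
                continue  # flanking genes on a chromosome must share orientation
            segments[frozenset((left.family_id, right.family_id))].append(
                {
                    "chrom": chrom,
                    "left": left,
                    "right": right,
                    "s": len(interior),
                    "start": left.index + 1,
                    "end": right.index,
                }
            )

    aus: list[AURecord] = []
    for fams, segs in segments.items():
        if len(fams) != 2 or len(segs) < 2:
            continue
        for i in range(len(segs)):
            for j in range(i + 1, len(segs)):
                a, b = segs[i], segs[j]
                flanks = {a["left"].gene_id, a["right"].gene_id,
                          b["left"].gene_id, b["right"].gene_id}
                if len(flanks) != 4:
                    continue  # the two segments must use all four family members
                aus.append(
                    AURecord(
                        flank_left=(a["left"].gene_id, b["left"].gene_id),
                        flank_right=(a["right"].gene_id, b["right"].gene_id),
                        region1=(a["chrom"], a["start"], a["end"]),
                        region2=(b["chrom"], b["start"], b["end"]),
                        s1=a["s"],
                        s2=b["s"],
                    )
                )
    return aus


def au_length_fit(aus: list[AURecord]) -> tuple[pd.Series, float, float]:
    """Fit a geometric distribution to AU lengths ``u >= 1``.

    Zero-length units (adjacent duplicate pairs) are excluded from the fit.
    Returns ``(f, u_bar, gof_p)``: the empirical frequency counts of u >= 1,
    the maximum-likelihood geometric mean (the sample mean), and the p-value
    of a chi-square goodness-of-fit test with tail cells pooled to expected
    counts >= 5.
    """
    lengths = np.array([au.u for au in aus if au.u >= 1], dtype=int)
    if lengths.size == 0:
        raise ValueError("no analytical units with u >= 1")
    counts = pd.Series(Counter(lengths)).sort_index()
    counts.index.name = "u"
    u_bar = float(lengths.mean())
    gof_p = geometric_gof_pvalue(counts, 1.0 / u_bar)
    return counts, u_bar, gof_p


def geometric_gof_pvalue(counts: pd.Series, p: float, estimated_params: int = 1,
                         min_expected: float = 5.0) -> float:
    """Chi-square GOF of observed length counts against geometric(p) on u >= 1.

    Cells are pooled from the tail until every expected count is at least
    ``min_expected``; degrees of freedom are cells - 1 - ``estimated_params``.
    Returns NaN when fewer than 2 cells remain.
    """
    n = counts.sum()
    u_max = int(counts.index.max())
    expected = np.array([n * p * (1 - p) ** (u - 1) for u in range(1, u_max + 1)])
    expected_tail = n * (1 - p) ** u_max  # mass above u_max
    observed = np.zeros(u_max)
    observed[counts.index.to_numpy() - 1] = counts.to_numpy()
    # pool from the right so each cell's expectation >= min_expected
    obs_cells, exp_cells = [], []
    acc_o, acc_e = 0.0, expected_tail
    for u in range(u_max, 0, -1):
        acc_o += observed[u - 1]
        acc_e += expected[u - 1]
        if acc_e >= min_expected:
            obs_cells.append(acc_o)
            exp_cells.append(acc_e)
            acc_o, acc_e = 0.0, 0.0
    if acc_e > 0 or acc_o > 0:
        if obs_cells:
            obs_cells[-1] += acc_o
            exp_cells[-1] += acc_e
        else:
            return float("nan")
    if len(obs_cells) < 2 + estimated_params:
        return float("nan")
    obs_arr = np.array(obs_cells)
    exp_arr = np.array(exp_cells)
    exp_arr *= obs_arr.sum() / exp_arr.sum()
    chi2 = float(((obs_arr - exp_arr) ** 2 / exp_arr).sum())
    dof = len(obs_cells) - 1 - estimated_params
    return float(stats.chi2.sf(chi2, dof))


def generate_synthetic_descendant(
    n_genes: int,
    mu: float,
    theta: float,
    phi: float = 0.5,
    n_inversions: int = 0,
    seed: int = 0,
    genome: str = "synthetic",
) -> list[GeneRecord]:
    """Simulate a two-sided fractionated genome disrupted by inversions.

    Runs the two-sided simulator on ``n_genes`` ancestral loci, lays the
    surviving genes of G on chromosome ``c1`` and of H on ``c2`` (deleted
    genes are removed and survivors re-indexed — excised DNA is invisible),
    assigns two-member families to surviving duplicate pairs, then applies
    ``n_inversions`` random segment inversions (uniform endpoints on a
    uniformly chosen chromosome, gene orientations flipped).  Deterministic
    for a given seed.
    """
    if n_inversions < 0:
        raise ValueError("n_inversions must be >= 0")
    cfg = SimulationConfig(N=n_genes, mu=mu, theta_target=theta, model=TWO_SIDED,
                           phi=phi, seed=seed)
    state = run_simulation(cfg)
    chrom_genes: dict[str, list[tuple[str, str, str | None]]] = {"c1": [], "c2": []}
    for i in range(n_genes):
        fam = f"f{i}" if state.g[i] and state.h[i] else None
        if state.g[i]:
            chrom_genes["c1"].append((f"g{i}a", "+", fam))
        if state.h[i]:
            chrom_genes["c2"].append((f"g{i}b", "+", fam))

    rng = random.Random(seed + 0x5F5E1)
    chroms = ["c1", "c2"]
    for _ in range(n_inversions):
        chrom = chroms[rng.randrange(2)]
        genes = chrom_genes[chrom]
        if len(genes) < 2:
            continue
        i = rng.randrange(len(genes))
        j = rng.randrange(len(genes))
        lo, hi = min(i, j), max(i, j)
        flipped = [
            (gid, "-" if orient == "+" else "+", fam)
            for gid, orient, fam in reversed(genes[lo : hi + 1])
        ]
        chrom_genes[chrom] = genes[:lo] + flipped + genes[hi + 1 :]

    records = []
    for chrom, genes in chrom_genes.items():
        for idx, (gid, orient, fam) in enumerate(genes):
            records.append(
                GeneRecord(genome=genome, chromosome=chrom, index=idx,
                           gene_id=gid, orientation=orient, family_id=fam)
            )
    return records
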