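"""Analytical-unit detection and the synthetic rearranged-descendant generator."""

from collections import defaultdict

import numpy as np
import pytest

from fracstats import (
    GeneRecord,
    SimulationConfig,
    au_length_fit,
    estimate_mu,
    find_analytical_units,
    generate_synthetic_descendant,
    rearrangement_correction,
    read_gene_order,
    run_simulation,
    summarize_state,
    theta_from_counts,
    write_gene_order,
)


def make_genes(chrom_layout, genome="toy"):
    """chrom_layout: {chrom: [(gene_id, orientation, family_id or None), ...]}"""
    records = []
    for chrom, genes in chrom_layout.items():
        for idx, (gid, orient, fam) in enumerate(genes):
            records.append(
                GeneRecord(genome=genome, chromosome=chrom, index=idx,
                           gene_id=gid, orientation=orient, family_id=fam)
            )
    return records


@pytest.fixture
def toy_au_layout():
    """24 genes: anchors fA/fB on c1 and c2 with 3 + 2 interior single-copy genes."""
    return {
        "c1": [("x0", "+", None), ("a1", "+", "fA"), ("s1", "+", None), ("s2", "-", None),
               ("s3", "+", None), ("b1", "+", "fB"), ("x1", "+", None), ("x2", "+", None),
               ("x3", "+", None), ("x4", "+", None), ("x5", "+", None), ("x6", "+", None)],
        "c2": [("y0", "+", None), ("y1", "+", None), ("a2", "-", "fA"), ("t1", "+", None),
               ("t2", "+", None), ("b2", "-", "fB"), ("y2", "+", None), ("y3", "+", None),
               ("y4", "+", None), ("y5", "+", None), ("y6", "+", None), ("y7", "+", None)],
    }


class TestFindAnalyticalUnits:
    def test_toy_two_region_unit(self, toy_au_layout):
        aus = find_analytical_units(make_genes(toy_au_layout))
        assert len(aus) == 1
        au = aus[0]
        assert {au.s1, au.s2} == {3, 2}
        assert au.u == 5
        assert not au.same_chromosome

    def test_external_paralog_excludes_candidate(self, toy_au_layout):
        # an interior gene with a paralog on a third chromosome disqualifies the unit
        layout = {k: list(v) for k, v in toy_au_layout.items()}
        layout["c1"][3] = ("s2", "-", "fX")
        layout["c3"] = [("z0", "+", "fX")]
        aus = find_analytical_units(make_genes(layout))
        assert aus == []

    def test_discordant_flank_orientation_excludes_candidate(self, toy_au_layout):
        layout = {k: list(v) for k, v in toy_au_layout.items()}
        layout["c1"][5] = ("b1", "-", "fB")  # a1 is "+": orientations differ on c1
        assert find_analytical_units(make_genes(layout)) == []

    def test_unfractionated_doubling_yields_zero_length_units(self):
        layout = {
            "c1": [(f"g{i}a", "+", f"f{i}") for i in range(5)],
            "c2": [(f"g{i}b", "+", f"f{i}") for i in range(5)],
        }
        aus = find_analytical_units(make_genes(layout))
        assert len(aus) == 4
        assert all(au.u == 0 for au in aus)

    def test_chromosome_relabeling_symmetry(self, toy_au_layout):
        swapped = {"c1": toy_au_layout["c2"], "c2": toy_au_layout["c1"]}
        a = find_analytical_units(make_genes(toy_au_layout))[0]
        b = find_analytical_units(make_genes(swapped))[0]
        assert {a.s1, a.s2} == {b.s1, b.s2}
        assert a.u == b.u

    def test_multiple_genomes_rejected(self):
        records = make_genes({"c1": [("g", "+", None)]}, genome="a") + make_genes(
            {"c1": [("g2", "+", None)]}, genome="b"
        )
        with pytest.raises(ValueError):
            find_analytical_units(records)


class TestGeneOrderIO:
    def test_round_trip(self, tmp_path):
        records = generate_synthetic_descendant(200, mu=2, theta=0.5, n_inversions=5, seed=3)
        path = tmp_path / "genome.tsv"
        write_gene_order(records, path, header_comment="synthetic fixture")
        back = read_gene_order(path)
        assert sorted(back, key=lambda g: (g.chromosome, g.index)) == sorted(
            records, key=lambda g: (g.chromosome, g.index)
        )

    def test_family_of_three_excluded_with_warning(self, tmp_path, caplog):
        layout = {
            "c1": [("a", "+", "f1"), ("b", "+", None), ("c", "+", "f1")],
            "c2": [("d", "+", "f1")],
        }
        aus = find_analytical_units(make_genes(layout))
        assert aus == []

    def test_malformed_orientation_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "genome\tchromosome\tindex\tgene_id\torientation\tfamily_id\n"
            "g\tc1\t0\tx\t>\t\n"
        )
        with pytest.raises(ValueError):
            read_gene_order(path)

    def test_duplicate_position_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "genome\tchromosome\tindex\tgene_id\torientation\tfamily_id\n"
            "g\tc1\t0\tx\t+\t\ng\tc1\t0\ty\t+\t\n"
        )
        with pytest.raises(ValueError):
            read_gene_order(path)


class TestAULengthFit:
    def test_sample_mean_is_geometric_mle(self):
        aus = find_analytical_units_from_lengths([1, 1, 2])
        counts, u_bar, _ = au_length_fit(aus)
        assert u_bar == pytest.approx(4 / 3)
        assert counts.to_dict() == {1: 2, 2: 1}

    def test_recovers_geometric_mean(self):
        rng = np.random.default_rng(5)
        lengths = rng.geometric(1 / 6, size=500)
        aus = find_analytical_units_from_lengths(lengths)
        _, u_bar, gof_p = au_length_fit(aus)
        assert 5.3 <= u_bar <= 6.7
        assert gof_p > 0.01

    def test_all_zero_lengths_rejected(self):
        with pytest.raises(ValueError):
            au_length_fit(find_analytical_units_from_lengths([0, 0]))


def find_analytical_units_from_lengths(lengths):
    from fracstats.auscan import AURecord

    return [
        AURecord(flank_left=("a", "b"), flank_right=("c", "d"),
                 region1=("c1", 0, int(u)), region2=("c2", 0, 0), s1=int(u), s2=0)
        for u in lengths
    ]


class TestSyntheticDescendant:
    def test_unrearranged_scan_matches_simulator_runs(self):
        # without inversions the AU lengths u >= 1 are exactly the interior
        # consolidated single-copy runs of the underlying simulation
        seed, n = 11, 3000
        records = generate_synthetic_descendant(n, mu=3, theta=0.4, n_inversions=0, seed=seed)
        aus = find_analytical_units(records)
        state = run_simulation(
            SimulationConfig(N=n, mu=3, theta_target=0.4, model="two_sided", seed=seed)
        )
        summ = summarize_state(state, exclude_boundary=True)
        au_lengths = sorted(au.u for au in aus if au.u >= 1)
        run_lengths = sorted(
            np.repeat(summ.f_counts.index.to_numpy(), summ.f_counts.to_numpy())
        )
        assert au_lengths == [int(x) for x in run_lengths]

    def test_zero_length_units_count_adjacent_pairs(self):
        records = generate_synthetic_descendant(10, mu=2, theta=1.0, n_inversions=0, seed=0)
        by_chrom = defaultdict(list)
        for g in records:
            by_chrom[g.chromosome].append(g)
        assert {len(v) for v in by_chrom.values()} == {10}
        aus = find_analytical_units(records)
        assert len(aus) == 9 and all(au.u == 0 for au in aus)

    def test_determinism(self):
        a = generate_synthetic_descendant(500, mu=2, theta=0.5, n_inversions=20, seed=4)
        b = generate_synthetic_descendant(500, mu=2, theta=0.5, n_inversions=20, seed=4)
        assert a == b

    def test_inversions_destroy_units_monotonically(self):
        counts = []
        for n_inv in (0, 40, 160, 640):
            total = 0
            for seed in range(3):
                recs = generate_synthetic_descendant(
                    3000, mu=3, theta=0.4, n_inversions=n_inv, seed=seed
                )
                total += len(find_analytical_units(recs))
            counts.append(total)
        assert all(a > b for a, b in zip(counts, counts[1:]))


def _adjacencies(records):
    by_chrom = defaultdict(list)
    for g in records:
        by_chrom[g.chromosome].append((g.index, g.gene_id))
    adj = set()
    for genes in by_chrom.values():
        genes.sort()
        for (_, a), (_, b) in zip(genes, genes[1:]):
            adj.add(frozenset((a, b)))
    return adj


def test_end_to_end_mu_recovery_through_rearrangement(twosided_surface):
    """Simulate, rearrange, scan, correct, invert: recovered mu within +/-1.

    The per-adjacency disruption probability is measured directly from the
    generator's before/after adjacency sets and used in place of alpha*D, so
    the check isolates the correction and inversion pathway rather than the
    choice of alpha.
    """
    mu_true, errors = 3.0, []
    for seed in range(20):
        pristine = generate_synthetic_descendant(
            20_000, mu=mu_true, theta=0.3, n_inversions=0, seed=seed
        )
        rearranged = generate_synthetic_descendant(
            20_000, mu=mu_true, theta=0.3, n_inversions=600, seed=seed
        )
        before, after = _adjacencies(pristine), _adjacencies(rearranged)
        p_break = 1 - len(before & after) / len(before)
        _, u_bar, _ = au_length_fit(find_analytical_units(rearranged))
        nu = rearrangement_correction(u_bar, p_break, alpha=1.0)
        n = len(rearranged)
        m = sum(1 for g in rearranged if not g.family_id)
        theta_obs = theta_from_counts(n, m)[0]
        est = estimate_mu(nu, theta_obs, twosided_surface)
        errors.append(abs(est.mu_hat - mu_true))
    assert np.median(errors) <= 1.0
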