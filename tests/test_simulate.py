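import numpy as np
import pytest
from scipy import stats

from hapscna import (
    ParentalKaryotype,
    RenderConfig,
    apply_bfb_amplification,
    apply_bfb_break,
    apply_chromothripsis,
    apply_missegregation,
    apply_paracentric_or_pericentric,
    apply_upd,
    apply_wgd,
    render_bulk,
    render_single_cell,
    render_sloping_population,
    simulate_clone_tree,
    simulate_genome,
)
import hapscna.simulate as sim
from hapscna.simulate import PRE_TP53_KINDS, segment_arm_class


class TestBfbBreak:
    def test_reciprocal_terminal_loss_and_gain(self, genome, diploid):
        d1, d2 = apply_bfb_break(diploid, "chr1", "A", 60_000_000)
        assert d1.cn_at("chr1", 30_000_000, "A") == 1
        assert d1.cn_at("chr1", 100_000_000, "A") == 0
        assert d2.cn_at("chr1", 100_000_000, "A") == 2

    def test_boundary_breakpoints_rejected(self, genome, diploid):
        for bp in (0, genome.lengths["chr1"]):
            with pytest.raises(ValueError):
                apply_bfb_break(diploid, "chr1", "A", bp)

    def test_zero_cn_region_rejected(self, genome, diploid):
        lost, _ = apply_bfb_break(diploid, "chr1", "A", 60_000_000)
        with pytest.raises(ValueError):
            apply_bfb_break(lost, "chr1", "A", 100_000_000)

    def test_conservation_on_random_breaks(self, genome):
        # per-bin audit: daughters always sum to twice the parent
        rng = np.random.default_rng(0)
        k = ParentalKaryotype.diploid(genome)
        k.add_cn("chr1", 20_000_000, 80_000_000, "A", 1)  # non-trivial parent
        for _ in range(100):
            bp = int(rng.integers(1, genome.lengths["chr1"] - 1))
            hom = "A" if rng.random() < 0.5 else "B"
            try:
                d1, d2 = apply_bfb_break(k, "chr1", hom, bp)
            except ValueError:
                continue
            for chrom in genome.chromosomes:
                pa, pb = k.cn_per_bin(chrom)
                a1, b1 = d1.cn_per_bin(chrom)
                a2, b2 = d2.cn_per_bin(chrom)
                assert np.allclose(a1 + a2, 2 * pa)
                assert np.allclose(b1 + b2, 2 * pb)


class TestInternalEvents:
    def test_paracentric_loss_definition(self, genome, diploid):
        k = apply_paracentric_or_pericentric(diploid, "chr1", "A", 30_000_000, 50_000_000, -1)
        assert k.cn_at("chr1", 40_000_000, "A") == 0
        assert k.cn_at("chr1", 20_000_000, "A") == 1
        assert segment_arm_class(genome, "chr1", 30_000_000, 50_000_000) == "paracentric"

    def test_pericentric_spans_centromere(self, genome):
        assert segment_arm_class(genome, "chr1", 40_000_000, 90_000_000) == "pericentric"

    def test_loss_at_zero_cn_rejected(self, genome, diploid):
        k = apply_paracentric_or_pericentric(diploid, "chr1", "A", 30_000_000, 50_000_000, -1)
        with pytest.raises(ValueError):
            apply_paracentric_or_pericentric(k, "chr1", "A", 35_000_000, 45_000_000, -1)

    def test_telomere_touching_segment_rejected(self, genome, diploid):
        with pytest.raises(ValueError):
            apply_paracentric_or_pericentric(diploid, "chr1", "A", 0, 50_000_000, 1)


class TestChromothripsis:
    def test_expected_retained_fraction(self, genome, diploid):
        # with 10 fragments at retention 0.5, lost length ~ Binomial mean
        lost_fracs = []
        for seed in range(30):
            k = apply_chromothripsis(diploid, "chr1", "A", (40_000_000, 140_000_000), 10, 0.5, seed)
            a, _ = k.cn_per_bin("chr1")
            edges = genome.bin_edges("chr1")
            centers = (edges[:-1] + edges[1:]) / 2
            m = (centers >= 40_000_000) & (centers < 140_000_000)
            lost_fracs.append(np.mean(a[m] < 1))
        assert abs(np.mean(lost_fracs) - 0.5) < 0.1
        # oscillation between exactly two adjacent states
        assert set(np.round(a[m]).astype(int)) <= {0, 1}

    def test_retention_one_is_identity(self, genome, diploid):
        k = apply_chromothripsis(diploid, "chr1", "A", (40_000_000, 140_000_000), 10, 1.0, 0)
        assert k == diploid

    def test_retention_zero_is_contiguous_loss(self, genome, diploid):
        k = apply_chromothripsis(diploid, "chr1", "A", (40_000_000, 140_000_000), 10, 0.0, 0)
        assert k.cn_at("chr1", 90_000_000, "A") == 0
        assert len(k.copy().simplify().segments["chr1"]) == 3

    def test_too_few_fragments_rejected(self, genome, diploid):
        with pytest.raises(ValueError):
            apply_chromothripsis(diploid, "chr1", "A", (0, 50_000_000), 3, 0.5, 0)


class TestAmplificationAndKaryotypeOps:
    def test_three_rounds_from_single_copy_reach_threshold(self, genome, diploid):
        k = apply_bfb_amplification(diploid, "chr1", "A", (100_000_000, 102_000_000), 3)
        assert k.cn_at("chr1", 101_000_000, "A") == 8
        assert k.cn_at("chr1", 120_000_000, "A") == 0  # broken terminus lost

    def test_zero_rounds_is_identity(self, genome, diploid):
        assert apply_bfb_amplification(diploid, "chr1", "A", (100_000_000, 102_000_000), 0) == diploid

    def test_two_rounds_from_two_copies(self, genome, diploid):
        k2 = diploid.copy()
        k2.add_cn("chr1", 100_000_000, 102_000_000, "A", 1)
        k = apply_bfb_amplification(k2, "chr1", "A", (100_000_000, 102_000_000), 2)
        assert k.cn_at("chr1", 101_000_000, "A") == 8

    def test_wgd_doubles_everything(self, genome, diploid):
        k = diploid.copy()
        k.add_cn("chr2", 0, 60_000_000, "B", 1)
        w = apply_wgd(k)
        assert w.cn_at("chr2", 30_000_000, "B") == 4
        assert w.cn_at("chr2", 30_000_000, "A") == 2

    def test_upd_is_copy_neutral(self, genome, diploid):
        k = apply_upd(diploid, "chr1", (0, 40_000_000), "A")
        s = k.segments["chr1"][0]
        assert (s.cnA, s.cnB) == (2, 0)
        a, b = k.cn_per_bin("chr1")
        assert np.allclose(a + b, 2.0)

    def test_missegregation_of_absent_homolog_rejected(self, genome, diploid):
        k = apply_missegregation(diploid, "chr3", "B", -1)
        with pytest.raises(ValueError):
            apply_missegregation(k, "chr3", "B", -1)


class TestCloneTree:
    def test_tp53_gating_restricts_pre_loss_events(self, genome):
        tree = simulate_clone_tree(genome, n_leaves=6, seed=4, events_per_branch=3.0)
        for name, nd in tree.nodes.items():
            if name == tree.root or nd.tp53_lost:
                continue
            for e in nd.events:
                assert e.kind in PRE_TP53_KINDS

    def test_tp53_branch_carries_loh(self, genome):
        # biallelic TP53 inactivation is accompanied by arm-scale LOH
        tree = simulate_clone_tree(genome, n_leaves=4, seed=8)
        first = [n for n in tree.nodes.values() if n.parent == tree.root][0]
        kinds = {e.kind for e in first.events}
        assert kinds & {"UPD", "bfb_terminal"}

    def test_child_equals_parent_plus_events(self, genome):
        from hapscna.simulate import apply_event

        tree = simulate_clone_tree(genome, n_leaves=4, seed=11, min_events_per_branch=1)
        for name, nd in tree.nodes.items():
            if nd.parent is None:
                continue
            k = tree.nodes[nd.parent].karyotype.copy()
            for spec in nd.events:
                k = apply_event(k, spec)
            assert k == nd.karyotype

    def test_no_events_keeps_leaves_identical_to_root(self, genome):
        tree = simulate_clone_tree(
            genome, n_leaves=2, seed=0, events_per_branch=0.0, wgd_prob=0.0, tp53_rules=False
        )
        for leaf in tree.leaves:
            assert tree.nodes[leaf].karyotype == tree.nodes[tree.root].karyotype

    def test_deterministic_given_seed(self, genome):
        a = simulate_clone_tree(genome, n_leaves=5, seed=21)
        b = simulate_clone_tree(genome, n_leaves=5, seed=21)
        assert a.newick() == b.newick()
        for n in a.nodes:
            assert a.nodes[n].karyotype == b.nodes[n].karyotype


class TestRendering:
    def test_switch_count_matches_poisson_mean(self, genome):
        rng = np.random.default_rng(0)
        counts = [
            len(sim.draw_switch_points(150_000_000, 1 / 250_000, rng)) for _ in range(100)
        ]
        mean = 150_000_000 / 250_000
        # chi-square GOF of observed counts against the Poisson model
        counts = np.asarray(counts)
        interior = np.linspace(mean - 2.5 * np.sqrt(mean), mean + 2.5 * np.sqrt(mean), 7)
        edges = np.r_[-np.inf, interior, np.inf]
        obs = np.histogram(counts, bins=np.r_[-0.5, interior, np.inf])[0]
        cdf = stats.poisson(mean).cdf
        exp = np.diff(cdf(np.r_[-1, interior, 1e9])) * len(counts)
        chi2 = np.sum((obs - exp) ** 2 / exp)
        assert chi2 < stats.chi2(len(obs) - 1).ppf(0.99)

    def test_zero_switch_rate_preserves_phase(self, small_genome):
        k = ParentalKaryotype.diploid(small_genome)
        cfg = RenderConfig(purity=1.0, switch_rate=0.0, seed=0)
        rng = np.random.default_rng(0)
        parity = sim.simulate_switch_parity(small_genome, 0.0, rng)
        assert all(np.all(parity[c] == 1) for c in small_genome.chromosomes)

    def test_pure_loh_gives_zero_minor_fraction(self, small_genome):
        k = apply_upd(ParentalKaryotype.diploid(small_genome), "chr1", (0, 80_000_000), "A")
        cfg = RenderConfig(purity=1.0, mean_depth=200, site_depth=8, switch_rate=0.0)
        rng = np.random.default_rng(3)
        _, t, _ = sim._render_observation(small_genome, [(k, 1.0)], cfg, "s", rng, None, None)
        assert t.depth_b["chr1"].sum() == 0

    def test_rendering_unbiased(self, small_genome):
        # mean normalized coverage over replicates ~ purity-weighted CN
        k = ParentalKaryotype.diploid(small_genome)
        k.add_cn("chr1", 0, 40_000_000, "A", 1)  # total CN 3 on half of chr1
        cfg = RenderConfig(purity=0.6, mean_depth=100, site_depth=0.0, ffpe_sigma=0.0)
        rng = np.random.default_rng(5)
        acc = None
        n_rep = 200
        for _ in range(n_rep):
            counts = []
            bins_cn, _ = sim._mixture_cn(small_genome, [(k, 0.6)])
            for chrom in small_genome.chromosomes:
                a, b = bins_cn[chrom]
                mu = cfg.mean_depth * (a + b) / 2.0
                counts.append(sim._nbinom(mu, cfg.depth_dispersion, rng))
            v = np.concatenate(counts) / cfg.mean_depth
            acc = v if acc is None else acc + v
        mean_cov = acc / n_rep
        expect = np.concatenate(
            [np.add(*sim._mixture_cn(small_genome, [(k, 0.6)])[0][c]) / 2 for c in small_genome.chromosomes]
        )
        assert np.mean(np.abs(mean_cov - expect) / expect) < 0.02

    def test_sloping_population_monotone_expectation(self, small_genome):
        base = ParentalKaryotype.diploid(small_genome)
        bounds = [40_000_000 + i * 3_000_000 for i in range(10)]
        comps = []
        for bp in bounds:
            s = base.copy()
            s.add_cn("chr1", bp, 80_000_000, "A", -1)
            comps.append((s.simplify(), 0.05))
        bins_cn, _ = sim._mixture_cn(small_genome, comps)
        a, b = bins_cn["chr1"]
        edges = small_genome.bin_edges("chr1")
        centers = (edges[:-1] + edges[1:]) / 2
        arm = a[(centers > 35_000_000)]
        assert np.all(np.diff(arm) <= 1e-9)  # monotone non-increasing toward telomere
        assert np.allclose(b, b[0])  # other homolog flat

    def test_single_subclone_is_plain_step(self, small_genome):
        base = ParentalKaryotype.diploid(small_genome)
        cfg = RenderConfig(purity=0.5, mean_depth=300, site_depth=5, seed=1)
        d, _, _ = render_sloping_population(base, "chr1", "A", [50_000_000], [0.5], cfg)
        sub = d[d["chrom"] == "chr1"]["count"].to_numpy(float)
        edges = small_genome.bin_edges("chr1")
        centers = (edges[:-1] + edges[1:]) / 2
        left = sub[(centers > 30_000_000) & (centers < 50_000_000)].mean()
        right = sub[centers > 50_000_000].mean()
        assert right / left == pytest.approx(0.75, abs=0.03)  # 2 -> 1.5 copies at 0.5 fraction

    def test_single_cell_deterministic_and_ratio_degenerate(self, small_genome):
        diploid = ParentalKaryotype.diploid(small_genome)
        tetra = apply_wgd(diploid)
        d1, _ = render_single_cell(diploid, seed=5)
        d1b, _ = render_single_cell(diploid, seed=5)
        assert d1.equals(d1b)
        d2, _ = render_single_cell(tetra, seed=5)
        # (2,2) vs (1,1): identical expected profile at equal sequencing depth
        assert np.allclose(d1["count"].mean(), d2["count"].mean(), rtol=0.05)
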