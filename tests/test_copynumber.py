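import numpy as np
import pandas as pd
import pytest

from hapscna import (
    ParentalKaryotype,
    RenderConfig,
    apply_missegregation,
    apply_upd,
    apply_wgd,
    call_integer_cn,
    denoise_with_eigensamples,
    estimate_purity_ploidy,
    haplotype_coverage,
    normalize_bulk,
    segment_profile,
    single_cell_chrom_cn,
    single_cell_normalize,
)
import hapscna.simulate as sim
from hapscna.copynumber import PipelineConfig, depth_matrix
from hapscna.phasing import AllelicDepthTable


class TestNormalizeBulk:
    def _panel(self, n_bins, n, rng, bias=None):
        mu = 200 * np.exp(bias if bias is not None else 0.0)
        return rng.poisson(np.broadcast_to(mu, (n, n_bins)).T * 1.0)

    def test_flat_data_centers_at_one(self):
        rng = np.random.default_rng(0)
        panel = self._panel(2000, 5, rng)
        counts = rng.poisson(np.full(2000, 300.0))
        out = normalize_bulk(counts, panel)
        assert np.nanmean(out) == pytest.approx(1.0, abs=1e-6)
        assert np.nanstd(out) < 0.12

    def test_shared_bias_removed(self):
        rng = np.random.default_rng(1)
        bias = 0.4 * np.sin(np.linspace(0, 12, 3000))
        panel = self._panel(3000, 6, rng, bias)
        counts = rng.poisson(400 * np.exp(bias))
        out = normalize_bulk(counts, panel)
        # residual correlation with the injected bias is negligible
        assert abs(np.corrcoef(out, bias)[0, 1]) < 0.08
        assert np.nanstd(out) < 0.12

    def test_gc_trend_removed(self):
        rng = np.random.default_rng(2)
        gc = np.clip(0.45 + 0.05 * rng.standard_normal(3000), 0.3, 0.6)
        gc_bias = -8 * (gc - 0.45) ** 2
        panel = self._panel(3000, 5, rng, gc_bias)
        counts = rng.poisson(350 * np.exp(gc_bias))
        out = normalize_bulk(counts, panel, gc)
        assert np.nanstd(out) < 0.12

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        panel = self._panel(1000, 4, rng)
        counts = rng.poisson(np.full(1000, 250.0))
        a = normalize_bulk(counts, panel)
        b = normalize_bulk(counts * 7.0, panel)
        assert np.allclose(a, b, equal_nan=True)

    def test_zero_panel_bins_masked(self):
        rng = np.random.default_rng(4)
        panel = self._panel(500, 4, rng)
        panel[100] = 0
        counts = rng.poisson(np.full(500, 250.0))
        out = normalize_bulk(counts, panel)
        assert np.isnan(out[100])

    def test_requires_three_panel_samples(self):
        with pytest.raises(ValueError):
            normalize_bulk(np.ones(100), np.ones((100, 2)))


class TestEigensampleDenoising:
    def setup_method(self):
        rng = np.random.default_rng(5)
        self.basis = rng.normal(0, 1, (2000, 3))
        self.panel = np.exp(
            self.basis @ rng.normal(0, 0.1, (3, 15)) + rng.normal(0, 0.01, (2000, 15))
        )

    def test_k_zero_is_identity(self):
        cov = np.exp(np.random.default_rng(0).normal(0, 0.1, 2000))
        assert np.allclose(denoise_with_eigensamples(cov, self.panel, 0), cov)

    def test_rank_k_bias_fully_removed(self):
        bias = self.basis @ np.array([0.3, -0.2, 0.1])
        out = denoise_with_eigensamples(np.exp(bias), self.panel, 10)
        assert np.log(out).std() < 0.02

    def test_orthogonal_signal_preserved(self):
        signal = np.zeros(2000)
        signal[500:900] = np.log(1.5)
        out = denoise_with_eigensamples(np.exp(signal), self.panel, 10)
        step = np.log(out[550:850]).mean() - np.log(out[:450]).mean()
        assert step == pytest.approx(np.log(1.5), rel=0.01)

    def test_k_beyond_panel_rejected(self):
        with pytest.raises(ValueError):
            denoise_with_eigensamples(np.ones(2000), self.panel, 16)


class TestHaplotypeCoverage:
    def _table(self, genome, k, purity, seed=0, switch_rate=0.0):
        rng = np.random.default_rng(seed)
        cfg = RenderConfig(purity=purity, mean_depth=400, site_depth=8, switch_rate=switch_rate)
        parity = sim.simulate_switch_parity(genome, switch_rate, rng)
        _, t, _ = sim._render_observation(genome, [(k, purity)], cfg, "s", rng, None, parity)
        return t

    def test_haplotypes_sum_to_total(self, small_genome):
        k = ParentalKaryotype.diploid(small_genome)
        t = self._table(small_genome, k, 0.8)
        total = {c: np.ones(small_genome.n_bins(c)) for c in small_genome.chromosomes}
        prof = haplotype_coverage(total, t, small_genome)
        for c in small_genome.chromosomes:
            assert np.allclose(prof.hap_a[c] + prof.hap_b[c], prof.total[c])

    def test_pure_loh_zeroes_one_haplotype(self, small_genome):
        k = apply_upd(ParentalKaryotype.diploid(small_genome), "chr1", (0, 80_000_000), "A")
        t = self._table(small_genome, k, 1.0)
        total = {c: np.ones(small_genome.n_bins(c)) for c in small_genome.chromosomes}
        prof = haplotype_coverage(total, t, small_genome)
        assert np.nanmax(prof.hap_b["chr1"]) < 0.02

    def test_half_purity_loh_fraction(self, small_genome):
        # (2,0) truth at purity 0.5: B fraction (0*0.5+0.5)/2 = 0.25
        k = apply_upd(ParentalKaryotype.diploid(small_genome), "chr1", (0, 80_000_000), "A")
        t = self._table(small_genome, k, 0.5)
        total = {c: np.ones(small_genome.n_bins(c)) for c in small_genome.chromosomes}
        prof = haplotype_coverage(total, t, small_genome)
        assert np.nanmedian(prof.hap_b["chr1"]) == pytest.approx(0.25, abs=0.02)

    def test_uninformative_bins_inherit_and_flag(self, small_genome):
        k = ParentalKaryotype.diploid(small_genome)
        t = self._table(small_genome, k, 0.8)
        # wipe het sites in a window of chr2
        m = (t.positions["chr2"] > 10_000_000) & (t.positions["chr2"] < 12_000_000)
        t.depth_a["chr2"][m] = 0
        t.depth_b["chr2"][m] = 0
        total = {c: np.ones(small_genome.n_bins(c)) for c in small_genome.chromosomes}
        prof = haplotype_coverage(total, t, small_genome)
        assert not prof.informative["chr2"].all()
        assert np.isfinite(prof.hap_a["chr2"]).all()


class TestPurityPloidy:
    def test_exact_recovery_from_noiseless_segments(self):
        purity, ploidy = 0.6, 2.4
        D = purity * ploidy + 2 * (1 - purity)
        states = [(1, 1, 100e6), (2, 1, 60e6), (2, 0, 40e6), (3, 1, 40e6)]
        rows = []
        pos = 0
        for a, b, ln in states:
            rows.append(
                {
                    "chrom": "chr1",
                    "start": pos,
                    "end": pos + ln,
                    "cov_a": (purity * a + (1 - purity)) / D,
                    "cov_b": (purity * b + (1 - purity)) / D,
                }
            )
            pos += ln
        fit = estimate_purity_ploidy(pd.DataFrame(rows))
        assert fit.status == "ok"
        assert fit.purity == pytest.approx(purity, abs=0.01)
        assert fit.ploidy == pytest.approx(ploidy, abs=0.02)

    def test_balanced_diploid_is_indeterminate(self):
        rows = [
            {"chrom": "chr1", "start": 0, "end": 150e6, "cov_a": 0.5, "cov_b": 0.5},
            {"chrom": "chr2", "start": 0, "end": 120e6, "cov_a": 0.501, "cov_b": 0.499},
        ]
        fit = estimate_purity_ploidy(pd.DataFrame(rows))
        assert fit.status == "indeterminate"

    def test_candidate_table_reports_ladder(self):
        purity, ploidy = 0.8, 2.0
        D = purity * ploidy + 2 * (1 - purity)
        rows = []
        for i, (a, b, ln) in enumerate([(1, 1, 120e6), (2, 0, 50e6), (2, 1, 30e6)]):
            rows.append(
                {
                    "chrom": "chr1",
                    "start": i * 200e6,
                    "end": i * 200e6 + ln,
                    "cov_a": (purity * a + (1 - purity)) / D,
                    "cov_b": (purity * b + (1 - purity)) / D,
                }
            )
        fit = estimate_purity_ploidy(pd.DataFrame(rows))
        assert fit.candidates is not None and len(fit.candidates) > 10
        assert {"purity", "ploidy", "objective", "n_subclonal"} <= set(fit.candidates.columns)


class TestCallIntegerCn:
    def test_exact_inputs_give_exact_truth(self, small_genome):
        purity, ploidy = 0.7, 2.0
        D = purity * ploidy + 2 * (1 - purity)
        truth = apply_upd(ParentalKaryotype.diploid(small_genome), "chr1", (0, 30_000_000), "A")
        rows = []
        for chrom in small_genome.chromosomes:
            for s in truth.segments[chrom]:
                rows.append(
                    {
                        "chrom": chrom,
                        "start": s.start,
                        "end": s.end,
                        "cov_a": (purity * s.cnA + (1 - purity)) / D,
                        "cov_b": (purity * s.cnB + (1 - purity)) / D,
                    }
                )
        called, table = call_integer_cn(pd.DataFrame(rows), purity, ploidy, small_genome)
        assert called == truth
        assert not table["subclonal"].any()

    def test_subclonal_mixture_flagged(self, small_genome):
        purity, ploidy = 0.8, 2.0
        D = purity * ploidy + 2 * (1 - purity)
        # a 50/50 subclonal single-copy gain: effective CN 1.5
        rows = [
            {"chrom": "chr1", "start": 0, "end": 80_000_000,
             "cov_a": (purity * 1.5 + (1 - purity)) / D, "cov_b": (purity * 1 + (1 - purity)) / D},
            {"chrom": "chr2", "start": 0, "end": 60_000_000,
             "cov_a": (purity * 2 + (1 - purity)) / D, "cov_b": (purity * 0 + (1 - purity)) / D},
        ]
        _, table = call_integer_cn(pd.DataFrame(rows), purity, ploidy, small_genome)
        assert bool(table.loc[0, "subclonal"]) is True
        assert bool(table.loc[1, "subclonal"]) is False

    def test_calls_never_negative(self, small_genome):
        rows = [
            {"chrom": c, "start": 0, "end": small_genome.lengths[c], "cov_a": 0.0, "cov_b": 0.01}
            for c in small_genome.chromosomes
        ]
        called, _ = call_integer_cn(pd.DataFrame(rows), 0.9, 2.0, small_genome)
        for _, s in called.iter_segments():
            assert s.cnA >= 0 and s.cnB >= 0


class TestSegmentProfile:
    def test_boundary_recovery_at_depth(self, small_genome):
        rng = np.random.default_rng(7)
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            true_bp = 40_000_000
            n1 = small_genome.n_bins("chr1")
            edges = small_genome.bin_edges("chr1")
            centers = (edges[:-1] + edges[1:]) / 2
            a = np.where(centers < true_bp, 0.5, 0.25) + rng.normal(0, 0.07, n1)
            b = np.full(n1, 0.5) + rng.normal(0, 0.07, n1)
            prof_total = {"chr1": a + b, "chr2": np.ones(small_genome.n_bins("chr2"))}
            from hapscna.copynumber import HaplotypeProfile

            prof = HaplotypeProfile(
                small_genome,
                prof_total,
                {"chr1": a, "chr2": np.full(small_genome.n_bins("chr2"), 0.5)},
                {"chr1": b, "chr2": np.full(small_genome.n_bins("chr2"), 0.5)},
            )
            segs = segment_profile(prof, penalty_factor=1.8)
            bps = segs[segs["chrom"] == "chr1"]["start"].tolist()[1:]
            if any(abs(bp - true_bp) <= 2 * 25_000 for bp in bps):
                hits += 1
        assert hits >= 18  # within 2 bins in >= 90% of replicates

    def test_no_signal_gives_single_segment(self, small_genome):
        from hapscna.copynumber import HaplotypeProfile

        rng = np.random.default_rng(8)
        tot = {c: 1 + rng.normal(0, 0.05, small_genome.n_bins(c)) for c in small_genome.chromosomes}
        prof = HaplotypeProfile(
            small_genome, tot, {c: v / 2 for c, v in tot.items()}, {c: v / 2 for c, v in tot.items()}
        )
        segs = segment_profile(prof)
        assert len(segs) == len(small_genome.chromosomes)


class TestSingleCellOps:
    def test_cubic_bias_removed(self, small_genome):
        rng = np.random.default_rng(9)
        med = {}
        counts = {}
        for c in small_genome.chromosomes:
            n = -(-small_genome.lengths[c] // 10_000)
            m = np.exp(rng.normal(0, 0.25, n))
            med[c] = m
            lm = np.log(m)
            bias = 0.3 * lm + 0.1 * lm**2 - 0.05 * lm**3
            counts[c] = 60 * np.exp(bias)  # exactly cubic in log median coverage
        coarse, info = single_cell_normalize(counts, med, small_genome)
        flat = np.concatenate([v[np.isfinite(v)] for v in coarse.values()])
        assert np.abs(flat - 1).max() < 0.01

    def test_diploid_cell_flat_profile(self, small_genome):
        from hapscna import render_single_cell

        diploid = ParentalKaryotype.diploid(small_genome)
        profs = []
        for i in range(8):
            d, _ = render_single_cell(diploid, seed=50 + i, amp_noise=0.1)
            profs.append({c: d[d["chrom"] == c]["count"].to_numpy(float) for c in small_genome.chromosomes})
        med = {
            c: np.median(np.vstack([p[c] / np.concatenate(list(p.values())).mean() for p in profs]), axis=0)
            for c in small_genome.chromosomes
        }
        coarse, _ = single_cell_normalize(profs[0], med, small_genome)
        flat = np.concatenate([v[np.isfinite(v)] for v in coarse.values()])
        assert abs(np.median(flat) - 1) < 0.06
        assert flat.std() < 0.2

    def test_aneuploid_cell_falls_back_to_lowest_sd_arm(self, small_genome):
        rng = np.random.default_rng(11)
        med, counts = {}, {}
        # no arm sits near the genome arm-median: the lowest-SD arm is used
        levels = {"chr1": 3.0, "chr2": 1.0}
        for c in small_genome.chromosomes:
            n = -(-small_genome.lengths[c] // 10_000)
            med[c] = np.exp(rng.normal(0, 0.1, n))
            counts[c] = levels[c] * 50 * med[c] * np.exp(rng.normal(0, 0.02 if c == "chr2" else 0.3, n))
        coarse, info = single_cell_normalize(counts, med, small_genome, arm_tol=1e-6)
        assert info["constant_region"][0] == "chr2"

    def test_half_integer_rule_flags_wgd(self):
        rows = [
            {"chrom": "chr1", "arm": a, "cn_a": 0.5, "cn_b": 1.0, "sd_a": 0.05, "sd_b": 0.05}
            for a in ("p", "q")
        ] + [
            {"chrom": "chr2", "arm": a, "cn_a": 1.0, "cn_b": 1.0, "sd_a": 0.05, "sd_b": 0.05}
            for a in ("p", "q")
        ]
        call = single_cell_chrom_cn(pd.DataFrame(rows))
        assert call.wgd
        chr1 = call.states[call.states["chrom"] == "chr1"].iloc[0]
        assert (chr1["cnA"], chr1["cnB"]) == (1, 2)

    def test_diploid_integers_no_flag(self):
        rows = [
            {"chrom": c, "arm": a, "cn_a": 1.0, "cn_b": 1.0, "sd_a": 0.05, "sd_b": 0.05}
            for c in ("chr1", "chr2")
            for a in ("p", "q")
        ]
        call = single_cell_chrom_cn(pd.DataFrame(rows))
        assert not call.wgd and not call.tetraploid

    def test_uniform_tetraploid_degenerate_no_flag(self):
        # (2,2) everywhere is indistinguishable from (1,1) by ratios alone
        rows = [
            {"chrom": c, "arm": a, "cn_a": 2.0, "cn_b": 2.0, "sd_a": 0.05, "sd_b": 0.05}
            for c in ("chr1", "chr2")
            for a in ("p", "q")
        ]
        call = single_cell_chrom_cn(pd.DataFrame(rows))
        assert not call.wgd


def test_pipeline_config_rejects_nonpositive():
    with pytest.raises(ValueError):
        PipelineConfig(penalty_factor=0)
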