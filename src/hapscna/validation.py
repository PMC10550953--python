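"""Self-contained validation studies for every pipeline stage.

Each study simulates its own ground truth with the package's generator,
runs the relevant stage, and scores the result against the simulated
truth. The studies are deterministic given a seed and sized to run on a
single CPU in minutes; they back both the acceptance test suite and the
``scripts/acceptance.py`` report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import simulate as sim
from .classify import ClassifyConfig, classify_chromosome, detect_sloping
from .copynumber import (
    call_integer_cn,
    depth_matrix,
    estimate_purity_ploidy,
    haplotype_coverage,
    normalize_bulk,
    segment_profile,
)
from .genome import GenomeModel, ParentalKaryotype, default_genome, human_autosome_genome, simulate_genome
from .phasing import AllelicDepthTable, correct_switch_errors, residual_switch_rate
from .phylo import build_tree, time_scna_vs_wgd
from .simulate import (
    RenderConfig,
    apply_bfb_amplification,
    apply_bfb_break,
    apply_missegregation,
    apply_paracentric_or_pericentric,
    apply_upd,
    apply_wgd,
    simulate_clone_tree,
)

__all__ = [
    "classification_oracle_study",
    "purity_ploidy_recovery_study",
    "switch_error_study",
    "phylogeny_recovery_study",
    "wgd_timing_study",
    "sloping_study",
    "conservation_study",
    "min_rounds_to_amplification",
]

#: event menu guaranteeing large, purity-anchoring SCNAs (the cohort biology:
#: arm-scale LOH and segmental events are ubiquitous in aneuploid samples)
LARGE_EVENT_MENU = {
    "missegregation": 1.0,
    "UPD": 1.0,
    "bfb_terminal": 2.0,
    "bfb_paracentric": 1.0,
    "bfb_pericentric": 0.5,
}

#: continuous-position marker events for clean phylogeny studies
MARKER_MENU = {"bfb_terminal": 2.0, "bfb_paracentric": 1.0, "focal_del": 1.0, "focal_dup": 1.0}


# --------------------------------------------------------------------------
# classification oracle
# --------------------------------------------------------------------------


def _single_event_chromosome(genome: GenomeModel, kind: str, rng: np.random.Generator):
    """One noiseless chromosome carrying exactly one event; returns
    (karyotype, chrom, expected category)."""
    chrom = genome.chromosomes[int(rng.integers(len(genome.chromosomes)))]
    length = genome.lengths[chrom]
    cs, ce = genome.centromeres[chrom]
    hom = "A" if rng.random() < 0.5 else "B"
    k = ParentalKaryotype.diploid(genome)
    margin = 2_000_000  # clear of the 1 Mb arm/telomere tolerance

    if kind == "terminal":
        side = "q" if rng.random() < 0.5 else "p"
        lo, hi = (ce + margin, length - margin) if side == "q" else (margin, cs - margin)
        bp = int(rng.uniform(lo, hi))
        loss = rng.random() < 0.5
        k = apply_bfb_break(k, chrom, hom, bp)[0 if loss else 1]
        return k, chrom, "terminal_loss" if loss else "terminal_gain"
    if kind == "paracentric":
        lo, hi = (ce + margin, length - margin) if rng.random() < 0.5 else (margin, cs - margin)
        a = int(rng.uniform(lo, hi - 6_000_000))
        b = int(rng.uniform(a + 6_000_000, hi))
        sign = -1 if rng.random() < 0.5 else 1
        k = apply_paracentric_or_pericentric(k, chrom, hom, a, b, sign)
        return k, chrom, f"paracentric_{'loss' if sign < 0 else 'gain'}"
    if kind == "pericentric":
        a = int(rng.uniform(margin, cs - margin))
        b = int(rng.uniform(ce + margin, length - margin))
        sign = -1 if rng.random() < 0.5 else 1
        k = apply_paracentric_or_pericentric(k, chrom, hom, a, b, sign)
        return k, chrom, f"pericentric_{'loss' if sign < 0 else 'gain'}"
    if kind == "UPD":
        region = (0, cs) if rng.random() < 0.5 else (ce, length)
        k = apply_upd(k, chrom, region, hom)
        return k, chrom, "UPD"
    if kind == "arm":
        sign = -1 if rng.random() < 0.5 else 1
        if rng.random() < 0.5:
            k.add_cn(chrom, 0, cs, hom, sign)
        else:
            k.add_cn(chrom, ce, length, hom, sign)
        return k.simplify(), chrom, f"arm_{'loss' if sign < 0 else 'gain'}"
    if kind == "whole_chrom":
        sign = -1 if rng.random() < 0.5 else 1
        k = apply_missegregation(k, chrom, hom, sign)
        return k, chrom, f"whole_chrom_{'loss' if sign < 0 else 'gain'}"
    if kind == "focal":
        width = int(rng.uniform(500_000, 3_000_000))
        start = int(rng.uniform(margin, length - width - margin))
        sign = -1 if rng.random() < 0.5 else 1
        k = apply_paracentric_or_pericentric(k, chrom, hom, start, start + width, sign)
        return k, chrom, "focal_del" if sign < 0 else "focal_dup"
    if kind == "amplification":
        width = int(rng.uniform(1_000_000, 2_000_000))
        start = int(rng.uniform(ce + margin, length - width - margin))
        k = apply_bfb_amplification(k, chrom, hom, (start, start + width), int(rng.integers(3, 5)))
        return k, chrom, "amplification"
    if kind == "chromothripsis":
        lo, hi = ce + margin, length - margin
        span = rng.uniform(0.5, 0.9) * (hi - lo)
        start = int(rng.uniform(lo, hi - span))
        k = sim.apply_chromothripsis(
            k, chrom, hom, (start, int(start + span)), 14, 0.5, int(rng.integers(2**31))
        )
        # resample until the random fragmentation truly oscillates enough
        return k, chrom, "chromothripsis"
    raise ValueError(kind)


ORACLE_KINDS = (
    "terminal",
    "paracentric",
    "pericentric",
    "UPD",
    "arm",
    "whole_chrom",
    "focal",
    "amplification",
)


def classification_oracle_study(n: int = 500, seed: int = 0) -> dict:
    """Classify single-event noiseless chromosomes; count exact recoveries.

    The confusion matrix over the category scheme must be the identity:
    for each generated chromosome the classifier must emit the generating
    event's category (amplification additionally produces the terminal
    loss of the broken flank, which is part of the same mechanism).
    """
    genome = default_genome(seed=1, het_density=0.0)
    rng = np.random.default_rng(seed)
    correct = 0
    confusion: dict[tuple[str, str], int] = {}
    for i in range(n):
        kind = ORACLE_KINDS[i % len(ORACLE_KINDS)]
        k, chrom, expected = _single_event_chromosome(genome, kind, rng)
        events = classify_chromosome(k, chrom, genome)
        cats = [e.category for e in events]
        if kind == "amplification":
            predicted = "amplification" if "amplification" in cats else (cats[0] if cats else "none")
            ok = predicted == "amplification"
        else:
            predicted = cats[0] if len(cats) == 1 else (cats[0] if cats else "none")
            ok = cats == [expected]
        confusion[(expected, predicted)] = confusion.get((expected, predicted), 0) + 1
        correct += ok
    return {"n": n, "correct": correct, "accuracy": correct / n, "confusion": confusion}


# --------------------------------------------------------------------------
# purity / ploidy recovery
# --------------------------------------------------------------------------


def _simulate_bulk_sample(
    genome, seed, purity, n_panel=4, n_regions=3, mean_depth=500.0, site_depth=8.0
):
    """One patient: three multiregion renders of a tumor clone (shared
    statistical phasing, independent noise) plus a germline panel at
    ~20x-equivalent depth."""
    rng = np.random.default_rng(seed)
    tree = simulate_clone_tree(
        genome,
        n_leaves=2,
        seed=seed,
        min_events_per_branch=3,
        events_per_branch=4.0,
        event_menu=LARGE_EVENT_MENU,
    )
    leaf = tree.leaves[0]
    truth = tree.nodes[leaf].karyotype
    cov = sim.simulate_bin_covariates(genome, seed=seed + 1)
    parity = sim.simulate_switch_parity(genome, 1 / 250_000, rng)
    cfg = RenderConfig(purity=purity, mean_depth=mean_depth, site_depth=site_depth)
    depth, table, _ = sim.render_bulk(tree, leaf, cfg, genome, cov, parity, rng)
    tables = [table]
    frames = [depth]
    for j in range(1, n_regions):
        _, t, _ = sim._render_observation(
            genome, [(tree.nodes[leaf].karyotype, purity)], cfg, f"{leaf}_r{j}", rng, cov, parity
        )
        tables.append(t)
    normal = ParentalKaryotype.diploid(genome)
    for i in range(n_panel):
        d, _, _ = sim._render_observation(genome, [(normal, 1.0)], cfg, f"panel{i}", rng, cov, None)
        frames.append(d)
    return pd.concat(frames, ignore_index=True), AllelicDepthTable.merge(tables), cov, truth, leaf


def _profile_sample(genome, depth, table, covariates, leaf, n_panel=4, penalty_factor=1.8):
    corrected, _ = correct_switch_errors(table, min_samples_informative=2, chrom_lengths=genome.lengths)
    _, mat = depth_matrix(depth)
    samples = depth["sample"].unique().tolist()
    gc = np.concatenate([covariates[c]["gc"] for c in genome.chromosomes])
    norm = normalize_bulk(
        mat[:, [samples.index(leaf)]],
        mat[:, [samples.index(f"panel{i}") for i in range(n_panel)]],
        gc,
    )
    total, off = {}, 0
    for chrom in genome.chromosomes:
        n = genome.n_bins(chrom)
        total[chrom] = norm[off : off + n, 0]
        off += n
    prof = haplotype_coverage(total, corrected, genome, sample=leaf)
    segment_profile(prof, penalty_factor=penalty_factor)
    return prof


def purity_ploidy_recovery_study(n: int = 20, seed: int = 0) -> dict:
    """Recover purity/ploidy on simulated ~20x bulk samples, purity 0.3-0.9."""
    genome = default_genome(seed=2)
    rng = np.random.default_rng(seed)
    ok = 0
    rows = []
    for i in range(n):
        rep_seed = int(rng.integers(2**31 - 10**6))
        purity = float(0.3 + 0.6 * rng.random())
        depth, table, cov, truth, leaf = _simulate_bulk_sample(genome, rep_seed, purity)
        prof = _profile_sample(genome, depth, table, cov, leaf)
        fit = estimate_purity_ploidy(prof.segments)
        good = (
            fit.status == "ok"
            and abs(fit.purity - purity) <= 0.05
            and abs(fit.ploidy - truth.ploidy()) <= 0.1
        )
        ok += good
        rows.append(
            {"true_purity": purity, "true_ploidy": truth.ploidy(), "est_purity": fit.purity,
             "est_ploidy": fit.ploidy, "ok": good}
        )
    return {"n": n, "n_ok": ok, "rate": ok / n, "table": pd.DataFrame(rows)}


# --------------------------------------------------------------------------
# switch-error correction
# --------------------------------------------------------------------------


def switch_error_study(n_patients: int = 20, seed: int = 0, n_samples: int = 3, purity: float = 0.7) -> dict:
    """Residual switch rate after cross-sample correction, vs the 1/250 kb input.

    Each patient contributes three bulk samples sharing a chromosome-scale
    LOH region (the strongest and most informative imbalance class); the
    residual rate is pooled over patients inside the imbalanced regions.
    """
    genome = simulate_genome({"chr1": 150_000_000}, seed=3)
    k20 = apply_upd(ParentalKaryotype.diploid(genome), "chr1", (0, genome.lengths["chr1"]), "A")
    rng = np.random.default_rng(seed)
    n_switch = 0
    span = 0
    for _ in range(n_patients):
        parity = sim.simulate_switch_parity(genome, 1 / 250_000, rng)
        cfg = RenderConfig(purity=purity, mean_depth=500, site_depth=8)
        tabs = [
            sim._render_observation(genome, [(k20, purity)], cfg, f"s{i}", rng, None, parity)[1]
            for i in range(n_samples)
        ]
        merged = AllelicDepthTable.merge(tabs)
        corrected, _ = correct_switch_errors(merged, min_samples_informative=2, chrom_lengths=genome.lengths)
        regions = {"chr1": [(0, genome.lengths["chr1"])]}
        rate = residual_switch_rate(corrected, parity, regions)
        n_switch += rate * genome.lengths["chr1"]
        span += genome.lengths["chr1"]
    residual = n_switch / span
    input_rate = 1 / 250_000
    return {
        "n_patients": n_patients,
        "input_rate": input_rate,
        "residual_rate": residual,
        "fold_reduction": input_rate / max(residual, 1e-12),
    }


# --------------------------------------------------------------------------
# phylogeny recovery
# --------------------------------------------------------------------------


def _true_clades(tree) -> set[frozenset]:
    out: set[frozenset] = set()

    def rec(n):
        nd = tree.nodes[n]
        if not nd.children:
            return frozenset([n])
        s = frozenset().union(*[rec(c) for c in nd.children])
        if n != tree.root:
            out.add(s)
        return s

    rec(tree.root)
    n_leaves = len(tree.leaves)
    return {s for s in out if 1 < len(s) < n_leaves}


def phylogeny_recovery_study(n: int = 20, seed: int = 0) -> dict:
    """Exact topology recovery from classified breakpoints (clean markers)."""
    genome = human_autosome_genome(chrom_length=120_000_000, seed=0)
    rng = np.random.default_rng(seed)
    exact = 0
    for _ in range(n):
        n_leaves = int(rng.integers(4, 9))
        tree = simulate_clone_tree(
            genome,
            n_leaves=n_leaves,
            seed=int(rng.integers(2**31)),
            min_events_per_branch=3,
            events_per_branch=3.0,
            event_menu=MARKER_MENU,
            wgd_prob=0.0,
            unique_targets=True,
        )
        events = {}
        for leaf in tree.leaves:
            evs = []
            for c in genome.chromosomes:
                evs.extend(classify_chromosome(tree.nodes[leaf].karyotype, c, genome, sample=leaf))
            events[leaf] = evs
        inferred = build_tree(tree.leaves, events)
        ic = {s for s in inferred.clades() if 1 < len(s) < n_leaves}
        exact += _true_clades(tree) == ic
    return {"n": n, "n_exact": exact, "rate": exact / n}


# --------------------------------------------------------------------------
# WGD timing
# --------------------------------------------------------------------------


def wgd_timing_study(n: int = 200, seed: int = 0) -> dict:
    """Pre/post-WGD labels on noiseless single-event WGD lineages.

    Half the lineages place the event before genome duplication (its copy
    change doubles with the genome), half after (single-copy change);
    whole-chromosome cases exercise the final-state parity rules, including
    the final-copy-number-1 (duplicated then lost) case.
    """
    genome = default_genome(seed=1, het_density=0.0)
    rng = np.random.default_rng(seed)
    diploid = ParentalKaryotype.diploid(genome)
    correct = 0
    for i in range(n):
        pre = bool(rng.random() < 0.5)
        kind = ("terminal", "paracentric", "whole_chrom")[i % 3]
        chrom = genome.chromosomes[int(rng.integers(len(genome.chromosomes)))]
        cs, ce = genome.centromeres[chrom]
        length = genome.lengths[chrom]
        hom = "A" if rng.random() < 0.5 else "B"
        margin = 2_000_000

        def apply(k):
            if kind == "terminal":
                bp = int(rng.uniform(ce + margin, length - margin))
                return apply_bfb_break(k, chrom, hom, bp)[0 if rng.random() < 0.5 else 1]
            if kind == "paracentric":
                a = int(rng.uniform(ce + margin, length - margin - 6_000_000))
                b = int(rng.uniform(a + 6_000_000, length - margin))
                return apply_paracentric_or_pericentric(k, chrom, hom, a, b, -1 if rng.random() < 0.5 else 1)
            return apply_missegregation(k, chrom, hom, -1 if rng.random() < 0.5 else 1)

        try:
            k = apply_wgd(apply(diploid)) if pre else apply(apply_wgd(diploid))
        except ValueError:
            continue
        events = classify_chromosome(k, chrom, genome, baseline=(2, 2))
        if len(events) != 1:
            continue
        label = time_scna_vs_wgd(events[0], k, True)
        correct += label == ("pre-WGD" if pre else "post-WGD")
    return {"n": n, "n_correct": correct, "accuracy": correct / n}


# --------------------------------------------------------------------------
# sloping detection
# --------------------------------------------------------------------------


def _sloping_profile(genome, depth, table, sample, purity):
    scale = depth["count"].mean()
    total = {
        c: depth[depth["chrom"] == c]["count"].to_numpy(float) / scale for c in genome.chromosomes
    }
    prof = haplotype_coverage(total, table, genome, sample=sample)
    prof.purity, prof.ploidy = purity, 2.0
    return prof


def sloping_study(n_pos: int = 20, n_null: int = 100, seed: int = 0, purity: float = 0.5) -> dict:
    """Sensitivity on progressive-erosion mixtures and FPR on flat genomes.

    Positives erode one homolog by one clone copy across a ~10 Mb boundary
    fan reaching the telomere (progressive terminal losses are anchored at
    the chromosome end), a population attenuation of ~0.5 copies per 10 Mb
    at purity 0.5 and 20x; the null is a flat diploid render scanned over
    both arms and homologs.
    """
    genome = simulate_genome({"chr1": 150_000_000}, seed=4)
    rng = np.random.default_rng(seed)
    base = ParentalKaryotype.diploid(genome)
    cfg = RenderConfig(purity=purity, mean_depth=500, site_depth=8)
    hits = 0
    for i in range(n_pos):
        start = int(rng.uniform(138_000_000, 140_000_000))
        bounds = np.linspace(start, 149_500_000, 10).astype(int).tolist()
        d, t, _ = sim.render_sloping_population(
            base, "chr1", "A", bounds, [purity / 10] * 10, cfg, rng=rng
        )
        prof = _sloping_profile(genome, d, t, "sloping", purity)
        calls = detect_sloping(prof, "chr1", "q")
        hits += any(c.homolog == "A" and c.direction == "telomere" for c in calls)
    false_genomes = 0
    for i in range(n_null):
        d, t, _ = sim._render_observation(genome, [(base, purity)], cfg, "flat", rng, None, None)
        prof = _sloping_profile(genome, d, t, "flat", purity)
        called = False
        for arm in ("p", "q"):
            if detect_sloping(prof, "chr1", arm):
                called = True
        false_genomes += called
    return {
        "n_pos": n_pos,
        "sensitivity": hits / n_pos,
        "n_null": n_null,
        "false_calls_per_100": 100.0 * false_genomes / n_null,
    }


# --------------------------------------------------------------------------
# conservation / analytic checks
# --------------------------------------------------------------------------


def conservation_study(n_events: int = 1000, seed: int = 0) -> dict:
    """Bin-wise audits: BFB daughter pairs sum to twice the parent and UPD
    preserves total copy number exactly, over random events."""
    genome = default_genome(seed=1, het_density=0.0)
    rng = np.random.default_rng(seed)
    k = ParentalKaryotype.diploid(genome)
    k.add_cn("chr1", 20_000_000, 90_000_000, "A", 1)
    k.add_cn("chr2", 10_000_000, 60_000_000, "B", 1)
    bfb_viol = upd_viol = 0
    n_bfb = n_upd = 0
    for i in range(n_events):
        chrom = genome.chromosomes[int(rng.integers(len(genome.chromosomes)))]
        length = genome.lengths[chrom]
        hom = "A" if rng.random() < 0.5 else "B"
        if i % 2 == 0:
            bp = int(rng.integers(1, length - 1))
            try:
                d1, d2 = apply_bfb_break(k, chrom, hom, bp)
            except ValueError:
                continue
            n_bfb += 1
            for c in genome.chromosomes:
                pa, pb = k.cn_per_bin(c)
                a1, b1 = d1.cn_per_bin(c)
                a2, b2 = d2.cn_per_bin(c)
                if not (np.allclose(a1 + a2, 2 * pa) and np.allclose(b1 + b2, 2 * pb)):
                    bfb_viol += 1
                    break
        else:
            a = int(rng.integers(0, length - 2))
            b = int(rng.integers(a + 1, length))
            try:
                u = apply_upd(k, chrom, (a, b), hom)
            except ValueError:
                continue
            n_upd += 1
            for c in genome.chromosomes:
                pa, pb = k.cn_per_bin(c)
                ua, ub = u.cn_per_bin(c)
                if not np.allclose(ua + ub, pa + pb):
                    upd_viol += 1
                    break
    return {
        "n_bfb": n_bfb,
        "n_upd": n_upd,
        "bfb_violations": bfb_viol,
        "upd_violations": upd_viol,
    }


def min_rounds_to_amplification(threshold: int = 8, start_cn: int = 1) -> int:
    """Fewest end-duplication rounds taking allelic CN ``start_cn`` to the
    amplification threshold, computed by applying the operator."""
    genome = simulate_genome({"chr1": 50_000_000}, het_density=0.0, seed=0)
    for rounds in range(0, 10):
        k = ParentalKaryotype.diploid(genome)
        k.set_cn("chr1", 20_000_000, 22_000_000, "A", start_cn)
        k = apply_bfb_amplification(k, "chr1", "A", (20_000_000, 22_000_000), rounds)
        if k.cn_at("chr1", 21_000_000, "A") >= threshold:
            return rounds
    raise RuntimeError("threshold not reached")
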