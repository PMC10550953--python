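"""SCNA burden accounting, group comparisons, and the end-to-end pipeline.

Burden follows the altered-autosomal-homolog metric: each altered homolog
of each autosome counts once (44 maximum across 22 autosomes), classed by
its most complex alteration with precedence segmental > arm-level > UPD >
local. Group comparisons use the Mann-Whitney U test for burdens and
Fisher's exact test for gain/loss composition, with Benjamini-Hochberg
FDR across the reported comparisons (raw p retained).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import io as hio
from .classify import ClassifyConfig, ScnaEvent, classify_chromosome, infer_wgd_bulk
from .copynumber import (
    PipelineConfig,
    call_integer_cn,
    depth_matrix,
    estimate_purity_ploidy,
    haplotype_coverage,
    normalize_bulk,
    segment_profile,
)
from .genome import GenomeModel, ParentalKaryotype, default_genome
from .phasing import AllelicDepthTable, correct_switch_errors
from .phylo import assign_wgd_to_branches, build_tree, time_scna_vs_wgd

__all__ = [
    "BurdenSummary",
    "compute_burden",
    "allelic_distribution",
    "genome_fraction_states",
    "compare_groups",
    "run_pipeline",
]

#: burden category classes by decreasing complexity
_SEGMENTAL = {
    "terminal_gain",
    "terminal_loss",
    "paracentric_gain",
    "paracentric_loss",
    "pericentric_gain",
    "pericentric_loss",
    "chromothripsis",
    "amplification",
    "sloping",
}
_ARM = {"arm_gain", "arm_loss", "whole_chrom_gain", "whole_chrom_loss"}
_LOCAL = {"focal_del", "focal_dup"}
_PRECEDENCE = ("segmental", "arm", "UPD", "local")

SEX_CHROMS = ("chrX", "chrY", "X", "Y")


def _burden_class(category: str) -> str:
    if category in _SEGMENTAL:
        return "segmental"
    if category in _ARM:
        return "arm"
    if category == "UPD":
        return "UPD"
    return "local"


@dataclass
class BurdenSummary:
    """Altered-homolog burden of one sample or branch."""

    id: str
    total: int
    subcounts: dict[str, int]
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sum(self.subcounts.values()) != self.total:
            raise ValueError("subcounts must partition the total (one class per homolog)")


def compute_burden(
    events: Sequence[ScnaEvent], genome: GenomeModel, id: str = "", labels: Mapping[str, str] | None = None
) -> BurdenSummary:
    """Count altered autosomal homologs, one class per homolog.

    Each (autosome, homolog) pair with at least one event counts exactly
    once, classed by its highest-complexity category (segmental > arm-level
    > UPD > local). Sex chromosomes are excluded; with 22 autosomes the
    maximum is 44.
    """
    best: dict[tuple[str, str], str] = {}
    for e in events:
        if e.chrom in SEX_CHROMS:
            continue
        cls = _burden_class(e.category)
        key = (e.chrom, e.homolog)
        if key not in best or _PRECEDENCE.index(cls) < _PRECEDENCE.index(best[key]):
            best[key] = cls
    subcounts = {c: 0 for c in _PRECEDENCE}
    for cls in best.values():
        subcounts[cls] += 1
    return BurdenSummary(id, len(best), subcounts, dict(labels or {}))


def allelic_distribution(events_by_sample: Mapping[str, Sequence[ScnaEvent]]) -> pd.DataFrame:
    """Per-chromosome allelic pattern of segmental SCNAs across a patient.

    Chromosomes with a single segmental event are 'single'; with multiple
    events confined to one parental homolog 'mono_allelic'; with events on
    both homologs 'bi_allelic'. Multi-event chromosomes are sub-split by
    whether the breakpoints occur in one sample genome or several.
    """
    rows = []
    per_chrom: dict[str, list[tuple[str, ScnaEvent]]] = {}
    for sample, evs in events_by_sample.items():
        for e in evs:
            if e.category in _SEGMENTAL:
                per_chrom.setdefault(e.chrom, []).append((sample, e))
    for chrom, pairs in sorted(per_chrom.items()):
        homologs = {e.homolog for _, e in pairs}
        samples = {s for s, _ in pairs}
        if len(pairs) == 1:
            pattern = "single"
        elif len(homologs) == 1:
            pattern = "mono_allelic"
        else:
            pattern = "bi_allelic"
        rows.append(
            {
                "chrom": chrom,
                "n_events": len(pairs),
                "pattern": pattern,
                "genomes": "single_genome" if len(samples) == 1 else "multi_genome",
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "n_events", "pattern", "genomes"])


def genome_fraction_states(
    segments: pd.DataFrame,
    genome: GenomeModel,
    wgd: bool = False,
    grid: int = 100_000,
    subclonal_threshold: float = 0.3,
) -> dict[str, float]:
    """Fractions of the germline genome per allelic copy-number state.

    Computed on a 100 kb grid over both homologs (denominator = 2x genome
    length). Deletion: allelic CN 0. Duplication: allelic CN >= 2 in
    non-WGD samples, >= 3 after WGD. Subclonal loss/gain: flagged
    non-integer states below/above the germline-equivalent single copy
    (1, or 2 in WGD samples). Categories are disjoint; fractions sum <= 1.
    """
    base = 2 if wgd else 1
    dup_min = 3 if wgd else 2
    denom = 2 * genome.total_length()
    acc = {"deletion": 0.0, "subclonal_loss": 0.0, "subclonal_gain": 0.0, "duplication": 0.0}
    for r in segments.itertuples():
        length = int(r.end) - int(r.start)
        n_units = max(round(length / grid), 1) * grid if length >= grid else length
        for hom in ("a", "b"):
            cn = int(getattr(r, f"cn{hom.upper()}"))
            frac = float(getattr(r, f"frac_{hom}", cn))
            subclonal = abs(frac - cn) > subclonal_threshold
            if cn == 0 and not subclonal:
                acc["deletion"] += n_units
            elif cn >= dup_min and not subclonal:
                acc["duplication"] += n_units
            elif subclonal and frac < base:
                acc["subclonal_loss"] += n_units
            elif subclonal and frac > base:
                acc["subclonal_gain"] += n_units
    return {k: v / denom for k, v in acc.items()}


def _rank_biserial(u: float, n1: int, n2: int) -> float:
    return 1.0 - 2.0 * u / (n1 * n2)


def compare_groups(
    burdens: pd.DataFrame,
    value_col: str = "total",
    group_col: str = "group",
    fisher_tables: Mapping[str, np.ndarray] | None = None,
    n_boot: int = 2_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise burden comparisons with effect sizes, CIs and BH-FDR.

    Every pair of groups is compared by a two-sided Mann-Whitney U test;
    the rank-biserial correlation is the effect size and a bootstrap
    percentile interval of the median difference the CI. Optional 2x2
    count tables (e.g. gain/loss composition per group pair) are tested by
    Fisher's exact test with the odds ratio as effect size. Groups with
    fewer than 3 observations yield NA rows with a reason. A
    Benjamini-Hochberg FDR column is added across all reported p-values.
    """
    rng = np.random.default_rng(seed)
    groups = {g: sub[value_col].to_numpy(dtype=float) for g, sub in burdens.groupby(group_col)}
    names = sorted(groups)
    rows = []
    for i, g1 in enumerate(names):
        for g2 in names[i + 1 :]:
            x, y = groups[g1], groups[g2]
            if len(x) < 3 or len(y) < 3:
                rows.append(
                    {"comparison": f"{g1} vs {g2}", "test": "mann-whitney", "p": np.nan,
                     "effect_size": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                     "reason": "group with n < 3"}
                )
                continue
            res = stats.mannwhitneyu(x, y, alternative="two-sided")
            diffs = [
                np.median(rng.choice(x, len(x))) - np.median(rng.choice(y, len(y)))
                for _ in range(n_boot)
            ]
            lo, hi = np.percentile(diffs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
            rows.append(
                {
                    "comparison": f"{g1} vs {g2}",
                    "test": "mann-whitney",
                    "p": float(res.pvalue),
                    "effect_size": _rank_biserial(float(res.statistic), len(x), len(y)),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                    "reason": "",
                }
            )
    for name, table in (fisher_tables or {}).items():
        table = np.asarray(table)
        if table.shape != (2, 2) or table.sum() == 0:
            rows.append({"comparison": name, "test": "fisher", "p": np.nan, "effect_size": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan, "reason": "degenerate table"})
            continue
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        ci = stats.contingency.odds_ratio(table).confidence_interval(1 - alpha)
        rows.append(
            {"comparison": name, "test": "fisher", "p": float(p), "effect_size": float(odds),
             "ci_low": float(ci.low), "ci_high": float(ci.high), "reason": ""}
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        pvals = out["p"].to_numpy()
        ok = np.isfinite(pvals)
        fdr = np.full(len(pvals), np.nan)
        if ok.any():
            fdr[ok] = stats.false_discovery_control(pvals[ok], method="bh")
        out["fdr_bh"] = fdr
    return out


# --------------------------------------------------------------------------
# end-to-end pipeline
# --------------------------------------------------------------------------

from contextlib import contextmanager


@contextmanager
def _stage(name: str):
    """Tag any failure inside a pipeline stage with the stage name."""
    try:
        yield
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc


def run_pipeline(config: Mapping | None = None, outdir: str | Path | None = None) -> dict:
    """Simulate a patient and run every stage through to burdens.

    Stages: simulate (clone tree + bulk rendering with a germline panel)
    -> phase refinement -> normalization, haplotype coverage, segmentation,
    purity/ploidy, integer calls -> SCNA classification and WGD inference
    -> breakpoint phylogeny with WGD placement and timing -> burden report.
    Returns the artifact dictionary; when ``outdir`` is given, every table
    is written along with a manifest recording the seed. Idempotent for a
    fixed seed. A stage failure raises with the stage name attached.
    """
    from . import simulate as sim

    cfg = dict(config or {})
    seed = int(cfg.get("seed", 0))
    n_leaves = int(cfg.get("n_leaves", 4))
    n_panel = int(cfg.get("n_panel", 6))
    purity = float(cfg.get("purity", 0.7))
    mean_depth = float(cfg.get("mean_depth", 500.0))
    site_depth = float(cfg.get("site_depth", 8.0))
    pcfg = PipelineConfig()
    rng = np.random.default_rng(seed)
    artifacts: dict = {"seed": seed}

    # ---- simulate
    with _stage("simulate"):
        genome = cfg.get("genome") or default_genome(seed)
        tree = sim.simulate_clone_tree(
            genome,
            n_leaves=n_leaves,
            seed=seed,
            events_per_branch=float(cfg.get("events_per_branch", 2.0)),
            min_events_per_branch=int(cfg.get("min_events_per_branch", 1)),
        )
        covariates = sim.simulate_bin_covariates(genome, seed=seed + 1)
        parity = sim.simulate_switch_parity(genome, 1 / 250_000, rng)
        rcfg = sim.RenderConfig(mean_depth=mean_depth, site_depth=site_depth, purity=purity)
        depth_frames = []
        tables = []
        for leaf in tree.leaves:
            d, t, _ = sim.render_bulk(tree, leaf, rcfg, genome, covariates, parity, rng)
            depth_frames.append(d)
            tables.append(t)
        normal = ParentalKaryotype.diploid(genome)
        panel_names = [f"panel{i}" for i in range(n_panel)]
        for name in panel_names:
            d, _, _ = sim._render_observation(genome, [(normal, 1.0)], rcfg, name, rng, covariates, None)
            depth_frames.append(d)
        depth = pd.concat(depth_frames, ignore_index=True)
        table = AllelicDepthTable.merge(tables)
        artifacts["tree_true"] = tree
        artifacts["depth"] = depth

    # ---- refine phase
    with _stage("refine"):
        corrected, flips = correct_switch_errors(
            table, min_samples_informative=2, chrom_lengths=genome.lengths
        )
        artifacts["flips"] = flips

    # ---- copy number
    with _stage("copy_number"):
        idx, mat = depth_matrix(depth)
        samples = depth["sample"].unique().tolist()
        sample_cols = [samples.index(s) for s in tree.leaves]
        panel_cols = [samples.index(s) for s in panel_names]
        gc = np.concatenate([covariates[c]["gc"] for c in genome.chromosomes])
        norm = normalize_bulk(mat[:, sample_cols], mat[:, panel_cols], gc)
        karyotypes: dict[str, ParentalKaryotype] = {}
        fits = {}
        segtables = {}
        for j, leaf in enumerate(tree.leaves):
            total = {}
            off = 0
            for chrom in genome.chromosomes:
                n = genome.n_bins(chrom)
                total[chrom] = norm[off : off + n, j]
                off += n
            profile = haplotype_coverage(total, corrected, genome, sample=leaf)
            segment_profile(profile, penalty_factor=pcfg.penalty_factor)
            fit = estimate_purity_ploidy(profile.segments, subclonal_threshold=pcfg.subclonal_threshold)
            fits[leaf] = fit
            if fit.status != "ok":
                continue
            karyotype, segs = call_integer_cn(
                profile.segments, fit.purity, fit.ploidy, genome, pcfg.subclonal_threshold
            )
            karyotypes[leaf] = karyotype
            segtables[leaf] = segs
        artifacts["purity_ploidy"] = {s: (f.purity, f.ploidy, f.status) for s, f in fits.items()}
        artifacts["karyotypes"] = karyotypes
        artifacts["segments"] = segtables

    # ---- classify
    with _stage("classify"):
        events_by_sample: dict[str, list[ScnaEvent]] = {}
        wgd_flags: dict[str, bool] = {}
        for leaf, k in karyotypes.items():
            wgd = infer_wgd_bulk(k)
            wgd_flags[leaf] = wgd
            baseline = (2, 2) if wgd else (1, 1)
            evs: list[ScnaEvent] = []
            for chrom in genome.chromosomes:
                evs.extend(classify_chromosome(k, chrom, genome, sample=leaf, baseline=baseline))
            events_by_sample[leaf] = evs
        artifacts["events"] = events_by_sample
        artifacts["wgd_flags"] = wgd_flags

    # ---- phylogeny
    with _stage("phylogeny"):
        if len(events_by_sample) >= 2:
            ctree = build_tree(list(events_by_sample), events_by_sample, tol=pcfg.breakpoint_tol)
            assign_wgd_to_branches(ctree, wgd_flags)
            timing = {
                leaf: [
                    (e.category, e.chrom, time_scna_vs_wgd(e, karyotypes[leaf], wgd_flags.get(leaf, False)))
                    for e in evs
                ]
                for leaf, evs in events_by_sample.items()
            }
            artifacts["tree"] = ctree
            artifacts["timing"] = timing

    # ---- burdens
    with _stage("burden"):
        burdens = [
            compute_burden(evs, genome, id=leaf, labels={"wgd": str(wgd_flags.get(leaf, False))})
            for leaf, evs in events_by_sample.items()
        ]
        artifacts["burdens"] = burdens
        artifacts["allelic_distribution"] = allelic_distribution(events_by_sample)

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        hio.save_genome(genome, out / "genome.json")
        truth = {
            "newick": tree.newick(),
            "karyotypes": {n: nd.karyotype.to_dict() for n, nd in tree.nodes.items()},
            "events": {
                n: [
                    {"kind": e.kind, "chrom": e.chrom, "homolog": e.homolog,
                     "breakpoints": list(e.breakpoints)}
                    for e in nd.events
                ]
                for n, nd in tree.nodes.items()
            },
            "wgd_branches": [n for n, nd in tree.nodes.items() if nd.wgd_on_branch],
        }
        (out / "truth.json").write_text(json.dumps(truth))
        hio.save_depth(depth, out / "depth.tsv")
        hio.save_allelic(corrected, out / "allelic_corrected.tsv")
        hio.save_flips_bed(flips, out / "flips.bed")
        hio.save_karyotypes(karyotypes, out / "karyotypes.json")
        all_events = [e for evs in events_by_sample.values() for e in evs]
        hio.events_to_frame(all_events).to_csv(out / "events.tsv", sep="\t", index=False)
        if segtables:
            pd.concat(
                [t.assign(sample=s) for s, t in segtables.items()], ignore_index=True
            ).to_csv(out / "segments.tsv", sep="\t", index=False)
        if "tree" in artifacts:
            (out / "tree.newick").write_text(artifacts["tree"].newick())
            (out / "tree.json").write_text(json.dumps(artifacts["tree"].to_sidecar(), indent=1))
        pd.DataFrame(
            [{"id": b.id, "total": b.total, **b.subcounts, **b.labels} for b in burdens]
        ).to_csv(out / "burdens.tsv", sep="\t", index=False)
        manifest = {
            "seed": seed,
            "n_leaves": n_leaves,
            "purity": purity,
            "samples": list(events_by_sample),
            "purity_ploidy": artifacts["purity_ploidy"],
            "outputs": sorted(p.name for p in out.iterdir()),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return artifacts
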