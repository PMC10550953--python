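"""Het-site selection and switch-error correction of statistical phasing.

Statistical phasing stitches haplotype blocks with switch errors roughly
once per 250 kb. In regions of allelic imbalance (where one parental
homolog has a different copy number than the other) the per-site phased
depth difference changes sign at every switch error; aggregating that
difference across all samples of a patient (or across single cells)
localizes the switches so site orientations can be flipped back.

The flip algorithm segments the aggregated per-site sign signal with a
penalized changepoint criterion and majority-votes the orientation per
segment; ties keep the statistical-phasing orientation. Correction only
swaps the A/B orientation of sites — depths are never altered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .segmentation import changepoints

__all__ = [
    "GenotypeMatrix",
    "AllelicDepthTable",
    "WindowImbalance",
    "select_het_sites",
    "window_allelic_imbalance",
    "correct_switch_errors",
    "two_pass_correct_cells",
    "residual_switch_rate",
]


@dataclass
class GenotypeMatrix:
    """Candidate variant sites x samples with genotype calls and depths.

    ``genotypes`` uses codes 0 = hom-ref, 1 = het, 2 = hom-alt (shape
    (n_sites, n_samples)); ``ref_depth``/``alt_depth`` are the per-sample
    allelic read depths at each site.
    """

    chrom: np.ndarray
    pos: np.ndarray
    genotypes: np.ndarray
    ref_depth: np.ndarray
    alt_depth: np.ndarray
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(self.ref_depth < 0) or np.any(self.alt_depth < 0):
            raise ValueError("depths must be non-negative")


def select_het_sites(g: GenotypeMatrix, cohort_het_fraction_threshold: float = 0.5) -> np.ndarray:
    """Boolean mask of usable heterozygous sites.

    A site is kept when all four filters hold: (1) at least one sample is
    called heterozygous; (2) at least two samples show more than two
    alternate reads; (3) at least two samples show more than two reference
    reads; (4) the fraction of heterozygous samples does not exceed the
    threshold (under Hardy-Weinberg equilibrium the expected heterozygote
    frequency of a biallelic locus is at most 50%, so sites heterozygous in
    more than half the cohort are suspect artifacts).
    """
    if g.genotypes.size == 0:
        return np.zeros(0, dtype=bool)
    het = g.genotypes == 1
    n_samples = g.genotypes.shape[1]
    rule1 = het.any(axis=1)
    rule2 = (g.alt_depth > 2).sum(axis=1) >= 2
    rule3 = (g.ref_depth > 2).sum(axis=1) >= 2
    rule4 = het.sum(axis=1) / n_samples <= cohort_het_fraction_threshold
    return rule1 & rule2 & rule3 & rule4


def max_hardy_weinberg_het_fraction() -> float:
    """Maximum heterozygote frequency 2p(1-p) over allele frequencies p in [0,1]."""
    p = np.linspace(0.0, 1.0, 100_001)
    return float(np.max(2 * p * (1 - p)))


@dataclass
class AllelicDepthTable:
    """Het-site allelic depths, per sample, in the current phased orientation.

    ``depth_a[chrom][i, s]`` is the read depth of the allele currently
    assigned to haplotype A at site i in sample s. ``phase[chrom][i]`` is the
    orientation of site i relative to the chromosome-level haplotype (+1 as
    phased, -1 flipped by correction); it starts at +1 everywhere.
    """

    samples: list[str]
    positions: dict[str, np.ndarray]
    depth_a: dict[str, np.ndarray]
    depth_b: dict[str, np.ndarray]
    phase: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, pos in self.positions.items():
            if chrom not in self.phase:
                self.phase[chrom] = np.ones(len(pos), dtype=np.int8)
            for d in (self.depth_a[chrom], self.depth_b[chrom]):
                if d.shape != (len(pos), len(self.samples)):
                    raise ValueError(f"{chrom}: depth shape {d.shape} does not match sites x samples")
                if np.any(d < 0):
                    raise ValueError("depths must be non-negative")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.positions)

    def copy(self) -> "AllelicDepthTable":
        return AllelicDepthTable(
            list(self.samples),
            {c: v.copy() for c, v in self.positions.items()},
            {c: v.copy() for c, v in self.depth_a.items()},
            {c: v.copy() for c, v in self.depth_b.items()},
            {c: v.copy() for c, v in self.phase.items()},
        )

    def flip_sites(self, chrom: str, mask: np.ndarray) -> None:
        """Flip the phased orientation of the masked sites (swap A/B depths)."""
        a = self.depth_a[chrom][mask].copy()
        self.depth_a[chrom][mask] = self.depth_b[chrom][mask]
        self.depth_b[chrom][mask] = a
        self.phase[chrom][mask] *= -1

    def total_depth(self, chrom: str) -> np.ndarray:
        return self.depth_a[chrom] + self.depth_b[chrom]

    def subset_samples(self, names: Sequence[str]) -> "AllelicDepthTable":
        idx = [self.samples.index(n) for n in names]
        return AllelicDepthTable(
            [self.samples[i] for i in idx],
            {c: v.copy() for c, v in self.positions.items()},
            {c: v[:, idx].copy() for c, v in self.depth_a.items()},
            {c: v[:, idx].copy() for c, v in self.depth_b.items()},
            {c: v.copy() for c, v in self.phase.items()},
        )

    @staticmethod
    def merge(tables: Sequence["AllelicDepthTable"]) -> "AllelicDepthTable":
        """Column-concatenate tables over identical site grids."""
        first = tables[0]
        for t in tables[1:]:
            for chrom in first.positions:
                if not np.array_equal(t.positions[chrom], first.positions[chrom]):
                    raise ValueError("tables must share het-site positions")
        samples = [s for t in tables for s in t.samples]
        return AllelicDepthTable(
            samples,
            {c: v.copy() for c, v in first.positions.items()},
            {c: np.hstack([t.depth_a[c] for t in tables]) for c in first.positions},
            {c: np.hstack([t.depth_b[c] for t in tables]) for c in first.positions},
            {c: v.copy() for c, v in first.phase.items()},
        )


@dataclass
class WindowImbalance:
    """Windowed allelic-imbalance statistic per sample."""

    chrom: str
    edges: np.ndarray  # window boundaries, bp
    stat: np.ndarray  # (n_windows, n_samples): (A - B) / (A + B)
    total: np.ndarray  # (n_windows, n_samples): A + B
    informative: np.ndarray  # (n_windows, n_samples) bool


def window_allelic_imbalance(
    t: AllelicDepthTable,
    window_bp: int = 50_000,
    min_total: int = 50,
    chrom_lengths: Mapping[str, int] | None = None,
) -> dict[str, WindowImbalance]:
    """Depth-weighted allelic imbalance (A-B)/(A+B) in fixed windows.

    Windows whose total allele count falls below ``min_total`` (default 50,
    the minimum-total-allele-count filter) are flagged uninformative.
    """
    out: dict[str, WindowImbalance] = {}
    for chrom in t.chromosomes:
        pos = t.positions[chrom]
        hi = int(chrom_lengths[chrom]) if chrom_lengths else (int(pos[-1]) + 1 if len(pos) else window_bp)
        edges = np.arange(0, hi + window_bp, window_bp)
        idx = np.clip(np.searchsorted(edges, pos, side="right") - 1, 0, len(edges) - 2)
        n_win = len(edges) - 1
        n_s = len(t.samples)
        A = np.zeros((n_win, n_s))
        B = np.zeros((n_win, n_s))
        np.add.at(A, idx, t.depth_a[chrom])
        np.add.at(B, idx, t.depth_b[chrom])
        total = A + B
        with np.errstate(invalid="ignore", divide="ignore"):
            stat = np.where(total > 0, (A - B) / np.maximum(total, 1e-12), 0.0)
        out[chrom] = WindowImbalance(chrom, edges, stat, total, total >= min_total)
    return out


def _merge_windows(mask: np.ndarray, max_gap: int = 2, min_run: int = 2) -> list[tuple[int, int]]:
    """Runs of True windows, bridging gaps up to ``max_gap`` windows."""
    regions: list[tuple[int, int]] = []
    start = None
    gap = 0
    for i, m in enumerate(mask):
        if m:
            if start is None:
                start = i
            gap = 0
        elif start is not None:
            gap += 1
            if gap > max_gap:
                if i - gap - start + 1 >= min_run:
                    regions.append((start, i - gap + 1))
                start, gap = None, 0
    if start is not None and len(mask) - start >= min_run:
        regions.append((start, len(mask)))
    return regions


def correct_switch_errors(
    t: AllelicDepthTable,
    imbalance: Mapping[str, WindowImbalance] | None = None,
    min_samples_informative: int = 2,
    imbalance_threshold: float = 0.1,
    window_bp: int = 50_000,
    min_total: int = 50,
    penalty_factor: float = 0.4,
    chrom_lengths: Mapping[str, int] | None = None,
    min_flip_z: float = 3.0,
) -> tuple[AllelicDepthTable, list[tuple[str, int, int]]]:
    """Correct statistical-phasing switch errors using cross-sample imbalance.

    Within regions where at least ``min_samples_informative`` samples show
    informative allelic imbalance, the per-site phased depth difference
    (aggregated over those samples, orientation-aligned so samples with
    imbalance on opposite homologs reinforce rather than cancel) is
    segmented; segments whose sign disagrees with the region majority are
    flipped. Regions with no informative sample are left untouched.

    Returns the corrected table and the flipped site ranges as
    ``(chrom, start_bp, end_bp)`` (half-open, in bp).
    """
    out = t.copy()
    if imbalance is None:
        imbalance = window_allelic_imbalance(t, window_bp, min_total, chrom_lengths)
    flips: list[tuple[str, int, int]] = []
    for chrom in out.chromosomes:
        wi = imbalance[chrom]
        pos = out.positions[chrom]
        if len(pos) == 0:
            continue
        qualifying = wi.informative & (np.abs(wi.stat) >= imbalance_threshold)
        win_ok = qualifying.sum(axis=1) >= min_samples_informative
        # genuine allelic imbalance spans at least a focal event (hundreds
        # of kb); isolated noisy windows never form a long enough run
        for w_lo, w_hi in _merge_windows(win_ok, min_run=4):
            lo_bp, hi_bp = int(wi.edges[w_lo]), int(wi.edges[w_hi])
            site_mask = (pos >= lo_bp) & (pos < hi_bp)
            if site_mask.sum() < 4:
                continue
            # region-level confirmation: a truly imbalanced region keeps a
            # high mean |window stat| (windows are much shorter than the
            # switch spacing), while balanced noise averages out
            with np.errstate(invalid="ignore"):
                region_mean = np.nanmean(
                    np.where(wi.informative[w_lo:w_hi], np.abs(wi.stat[w_lo:w_hi]), np.nan),
                    axis=0,
                )
            confirmed = np.nan_to_num(region_mean) >= imbalance_threshold
            if confirmed.sum() < min_samples_informative:
                continue
            sample_idx = np.where(confirmed)[0]
            d = (out.depth_a[chrom][site_mask][:, sample_idx] -
                 out.depth_b[chrom][site_mask][:, sample_idx]).astype(float)
            # orientation-align samples against the strongest one: switch
            # errors are shared across samples, so relative signs are constant
            strength = np.abs(d.sum(axis=0))
            ref = int(np.argmax(strength))
            w_s = np.sign(d.T @ d[:, ref])
            w_s[w_s == 0] = 1.0
            x = d @ w_s
            # a liberal penalty: spurious changepoints are harmless (their
            # segments fail the significance guard or match the majority
            # sign) while a missed one leaves an uncorrected switch
            cps = changepoints(x, penalty_factor=penalty_factor, min_size=1)
            bounds = [0, *cps, len(x)]
            seg_sum = np.array([x[a:b].sum() for a, b in zip(bounds[:-1], bounds[1:])])
            seg_len = np.diff(bounds).astype(float)
            seg_sign = np.sign(seg_sum)
            majority = np.sign((seg_sign * seg_len).sum())
            if majority == 0:
                majority = 1.0  # tie: keep statistical-phasing orientation
            # noise scale of the per-site signal, from within-segment residuals
            resid = x.copy()
            for a, b in zip(bounds[:-1], bounds[1:]):
                resid[a:b] -= x[a:b].mean()
            sd = float(np.std(resid)) or 1.0
            z = np.abs(seg_sum) / (sd * np.sqrt(seg_len))
            site_idx = np.where(site_mask)[0]
            for j, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
                # flip only segments with a statistically clear minority
                # sign; ambiguous ones keep the statistical-phasing state
                if seg_sign[j] != 0 and seg_sign[j] != majority and z[j] >= min_flip_z:
                    flip_idx = site_idx[a:b]
                    m = np.zeros(len(pos), dtype=bool)
                    m[flip_idx] = True
                    out.flip_sites(chrom, m)
                    flips.append((chrom, int(pos[flip_idx[0]]), int(pos[flip_idx[-1]]) + 1))
    return out, flips


def two_pass_correct_cells(
    cells: AllelicDepthTable,
    chrom_lengths: Mapping[str, int] | None = None,
    coarse_window: int = 10_000_000,
    aneuploid_imbalance: float = 0.25,
    aneuploid_span: int = 10_000_000,
    min_total: int = 20,
    penalty_factor: float = 0.4,
) -> tuple[AllelicDepthTable, dict]:
    """Two-pass haplotype correction for single-cell collections.

    Pass 1 aggregates allelic-depth differences across all cells (each cell
    orientation-aligned by its coarse-window imbalance) to find recurrent
    imbalance and correct switch errors. Cells with at least one segment of
    ``aneuploid_span`` showing |imbalance| above ``aneuploid_imbalance`` are
    then identified, and only those aneuploid cells drive pass 2. If no
    aneuploid cell is found, the pass-1 result is returned with a warning.
    """
    if len(cells.samples) < 2:
        raise ValueError("need a collection of cells")

    def aggregate(table: AllelicDepthTable, subset: Sequence[int]) -> AllelicDepthTable:
        pos, da, db = {}, {}, {}
        for chrom in table.chromosomes:
            a = table.depth_a[chrom][:, subset].astype(float)
            b = table.depth_b[chrom][:, subset].astype(float)
            d = a - b
            # per-cell orientation against the strongest cell
            strength = np.abs(d.sum(axis=0))
            ref = int(np.argmax(strength)) if len(subset) else 0
            w = np.sign(d.T @ d[:, ref]) if len(subset) else np.array([])
            w[w == 0] = 1.0
            A = (np.where(w > 0, a, b)).sum(axis=1)
            B = (np.where(w > 0, b, a)).sum(axis=1)
            pos[chrom] = table.positions[chrom].copy()
            da[chrom] = A[:, None].astype(np.int64)
            db[chrom] = B[:, None].astype(np.int64)
        return AllelicDepthTable(["aggregate"], pos, da, db)

    all_idx = list(range(len(cells.samples)))

    def run_pass(
        table: AllelicDepthTable, subset: Sequence[int], min_flip_z: float = 3.0
    ) -> tuple[AllelicDepthTable, list]:
        agg = aggregate(table, subset)
        _, flips = correct_switch_errors(
            agg,
            min_samples_informative=1,
            window_bp=50_000,
            min_total=min_total,
            penalty_factor=penalty_factor,
            chrom_lengths=chrom_lengths,
            min_flip_z=min_flip_z,
        )
        corrected = table.copy()
        for chrom, lo, hi in flips:
            p = corrected.positions[chrom]
            corrected.flip_sites(chrom, (p >= lo) & (p < hi))
        return corrected, flips

    # pass 1 sees all cells, so its imbalance signal is diluted by the
    # diploid majority: only flip with high confidence, and leave the
    # precise work to pass 2 on the aneuploid subset
    pass1, flips1 = run_pass(cells, all_idx, min_flip_z=5.0)

    # identify aneuploid cells from coarse-window imbalance after pass 1
    wi = window_allelic_imbalance(pass1, coarse_window, min_total, chrom_lengths)
    n_needed = max(int(aneuploid_span // coarse_window), 1)
    aneuploid: list[int] = []
    for s in range(len(cells.samples)):
        for chrom, w in wi.items():
            big = w.informative[:, s] & (np.abs(w.stat[:, s]) > aneuploid_imbalance)
            run = 0
            for m in big:
                run = run + 1 if m else 0
                if run >= n_needed:
                    break
            if run >= n_needed:
                aneuploid.append(s)
                break
    info = {
        "aneuploid_cells": [cells.samples[i] for i in aneuploid],
        "pass1_flips": flips1,
        "pass2_flips": [],
    }
    if not aneuploid:
        warnings.warn("no aneuploid cell found; returning pass-1 haplotype", stacklevel=2)
        return pass1, info
    # the corrected pass-1 data only serves to identify the aneuploid cells;
    # the final haplotype is re-derived from the raw depths of those cells
    # alone, so pass-1 boundary errors (diluted signal) are not inherited
    pass2, flips2 = run_pass(cells, aneuploid)
    info["pass2_flips"] = flips2
    return pass2, info


def residual_switch_rate(
    t: AllelicDepthTable,
    true_parity: Mapping[str, np.ndarray],
    regions: Mapping[str, Sequence[tuple[int, int]]],
) -> float:
    """Residual switch errors per bp of the corrected phase inside regions.

    The corrected orientation matches truth up to one global sign per region
    (the region-level orientation is unidentifiable from imbalance alone);
    residual switches are sign *transitions* of phase x true parity.
    """
    n_switch = 0
    span = 0
    for chrom, regs in regions.items():
        pos = t.positions[chrom]
        agree = t.phase[chrom] * np.asarray(true_parity[chrom])
        for lo, hi in regs:
            m = (pos >= lo) & (pos < hi)
            if m.sum() < 2:
                continue
            a = agree[m]
            n_switch += int(np.sum(a[1:] != a[:-1]))
            span += hi - lo
    return n_switch / span if span else 0.0
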