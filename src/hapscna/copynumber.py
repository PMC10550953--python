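"""Coverage normalization, haplotype-specific copy number, purity/ploidy.

The bulk workflow: normalize binned read counts (GC correction plus a
reference panel of germline samples), optionally denoise against panel
eigensamples, split each bin's coverage into the two parental haplotypes
using corrected allelic depths, segment the joint haplotype signal, grid-
search purity and ploidy, and call integer allelic copy number per segment.

Purity/ploidy estimation is a transparent grid search: each candidate
(purity p, ploidy psi) implies allelic copy numbers for all segments,
candidates are refined to their assignment-basin optimum, and the pick
has the fewest subclonal (non-integer) states and then the lowest ploidy
among near-equally-good fits — a deterministic version of choosing the
solution with the fewest subclonal states from the candidate ladder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeModel, ParentalKaryotype, Segment
from .phasing import AllelicDepthTable
from .segmentation import pelt_changepoints

__all__ = [
    "PipelineConfig",
    "HaplotypeProfile",
    "PurityPloidyFit",
    "normalize_bulk",
    "denoise_with_eigensamples",
    "haplotype_coverage",
    "segment_profile",
    "estimate_purity_ploidy",
    "call_integer_cn",
    "single_cell_normalize",
    "single_cell_chrom_cn",
    "depth_matrix",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Numeric parameters of the copy-number workflow (all positive).

    Defaults follow the analysis this package implements: 25 kb allelic /
    5 kb raw-depth bulk bins, 10 kb / 50 kb / 1 Mb single-cell widths, a
    changepoint penalty factor of 1.8, minimum total allele count of 50,
    ten eigensamples, the tetraploid criterion (an arm with median allelic
    CN in [0.2, 0.8] and allelic-coverage SD < 0.25), amplification
    threshold of 8 allelic copies, and 100 kb breakpoint-match and
    rearrangement-filter tolerances.
    """

    bulk_allelic_bin: int = 25_000
    bulk_depth_bin: int = 5_000
    sc_depth_bin: int = 10_000
    sc_allelic_bin: int = 50_000
    sc_report_bin: int = 1_000_000
    penalty_factor: float = 1.8
    min_total_allele_count: int = 50
    n_eigensamples: int = 10
    tetraploid_band: tuple[float, float] = (0.2, 0.8)
    tetraploid_sd: float = 0.25
    amplification_threshold: int = 8
    breakpoint_tol: int = 100_000
    rearrangement_tol: int = 100_000
    subclonal_threshold: float = 0.3

    def __post_init__(self) -> None:
        for name in (
            "bulk_allelic_bin",
            "bulk_depth_bin",
            "sc_depth_bin",
            "sc_allelic_bin",
            "sc_report_bin",
            "penalty_factor",
            "min_total_allele_count",
            "n_eigensamples",
            "tetraploid_sd",
            "amplification_threshold",
            "breakpoint_tol",
            "rearrangement_tol",
            "subclonal_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def depth_matrix(depth: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Pivot a long binned-depth table into (bin index, bins x samples matrix)."""
    wide = depth.pivot_table(index=["chrom", "start", "end"], columns="sample", values="count", sort=False)
    idx = wide.index.to_frame(index=False)
    return idx, wide.to_numpy(dtype=float)


def _gc_correct(log_cov: np.ndarray, gc: np.ndarray, degree: int = 3) -> np.ndarray:
    """Remove a smooth polynomial trend of log-coverage vs GC, per sample."""
    out = np.empty_like(log_cov)
    for j in range(log_cov.shape[1]):
        y = log_cov[:, j]
        ok = np.isfinite(y)
        if ok.sum() < degree + 2 or np.ptp(gc[ok]) < 1e-9:
            out[:, j] = y
            continue
        coef = np.polyfit(gc[ok], y[ok], degree)
        out[:, j] = y - np.polyval(coef, gc)
        out[~ok, j] = np.nan
    return out


def normalize_bulk(
    counts: np.ndarray,
    panel: np.ndarray,
    gc: np.ndarray | None = None,
) -> np.ndarray:
    """Normalize raw bin counts to mean-1 coverage using a germline panel.

    GC-dependent bias is removed by a smooth polynomial fit of log-coverage
    against per-bin GC; the recurrent (FFPE library) bias is removed by
    dividing out the median profile of the panel samples after the same GC
    correction. Output columns are scaled to a length-weighted mean of 1, so
    copy-neutral regions of a diploid sample sit at 1. Bins with zero panel
    coverage are masked (NaN). Normalization is scale-invariant per sample.
    """
    squeeze = np.asarray(counts).ndim == 1
    counts = np.atleast_2d(np.asarray(counts, dtype=float).T).T
    panel = np.atleast_2d(np.asarray(panel, dtype=float).T).T
    if panel.shape[1] < 3:
        raise ValueError("need at least 3 panel samples")
    with np.errstate(divide="ignore"):
        log_c = np.log(counts / np.nanmean(counts, axis=0))
        log_p = np.log(panel / np.nanmean(panel, axis=0))
    log_c[~np.isfinite(log_c)] = np.nan
    log_p[~np.isfinite(log_p)] = np.nan
    if gc is not None:
        gc = np.asarray(gc, dtype=float)
        log_c = _gc_correct(log_c, gc)
        log_p = _gc_correct(log_p, gc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        panel_median = np.nanmedian(log_p, axis=1)
    mask = ~np.isfinite(panel_median)
    resid = log_c - panel_median[:, None]
    resid[mask] = np.nan
    cov = np.exp(resid)
    cov /= np.nanmean(cov, axis=0)
    return cov[:, 0] if squeeze else cov


def denoise_with_eigensamples(coverage: np.ndarray, panel: np.ndarray, k: int = 10) -> np.ndarray:
    """Remove the projection onto the top-k panel eigensamples.

    Eigensamples are the left singular vectors (bin space) of the panel's
    centered log-coverage matrix. Each sample's log-coverage is projected
    onto their span and the projection subtracted; ``k = 0`` is the
    identity. Raises when ``k`` exceeds the panel size.
    """
    squeeze = np.asarray(coverage).ndim == 1
    coverage = np.atleast_2d(np.asarray(coverage, dtype=float).T).T
    panel = np.atleast_2d(np.asarray(panel, dtype=float).T).T
    if k > panel.shape[1]:
        raise ValueError(f"k={k} exceeds panel size {panel.shape[1]}")
    if k == 0:
        return coverage[:, 0].copy() if squeeze else coverage.copy()
    with np.errstate(divide="ignore"):
        log_c = np.log(np.maximum(coverage, 1e-12))
        log_p = np.log(np.maximum(panel / np.nanmean(panel, axis=0), 1e-12))
    log_p = log_p - np.nanmean(log_p, axis=0, keepdims=True)
    log_p = np.nan_to_num(log_p)
    u, _, _ = np.linalg.svd(log_p, full_matrices=False)
    basis = u[:, :k]
    centered = log_c - np.nanmean(log_c, axis=0, keepdims=True)
    centered = np.nan_to_num(centered)
    denoised_log = log_c - basis @ (basis.T @ centered)
    out = np.exp(denoised_log)
    out /= np.nanmean(out, axis=0)
    return out[:, 0] if squeeze else out


@dataclass
class HaplotypeProfile:
    """Binned normalized coverage split by parental haplotype, plus calls.

    ``total``, ``hap_a``, ``hap_b`` map chromosome -> per-bin arrays with
    ``hap_a + hap_b == total`` exactly. ``informative`` flags bins whose
    haplotype fraction came from their own het sites rather than the nearest
    informative neighbor. ``segments`` (after segmentation / calling) is a
    table with columns chrom, start, end, cov_a, cov_b[, cnA, cnB, frac_a,
    frac_b, subclonal].
    """

    genome: GenomeModel
    total: dict[str, np.ndarray]
    hap_a: dict[str, np.ndarray]
    hap_b: dict[str, np.ndarray]
    informative: dict[str, np.ndarray] = field(default_factory=dict)
    segments: pd.DataFrame | None = None
    purity: float | None = None
    ploidy: float | None = None


def haplotype_coverage(
    total: Mapping[str, np.ndarray],
    table: AllelicDepthTable,
    genome: GenomeModel,
    sample: str | int = 0,
    min_sites: int = 2,
) -> HaplotypeProfile:
    """Split normalized total coverage into per-haplotype coverage per bin.

    The haplotype-A fraction per bin is the depth-weighted fraction of
    phase-corrected haplotype-A allele counts among het sites in the bin;
    ``hap_a = total * fraction`` so the two haplotypes sum to the total
    exactly. Bins without informative het sites inherit the nearest
    informative bin's fraction and are flagged.
    """
    s = table.samples.index(sample) if isinstance(sample, str) else sample
    hap_a: dict[str, np.ndarray] = {}
    hap_b: dict[str, np.ndarray] = {}
    informative: dict[str, np.ndarray] = {}
    for chrom in genome.chromosomes:
        edges = genome.bin_edges(chrom)
        n = len(edges) - 1
        pos = table.positions[chrom]
        a = table.depth_a[chrom][:, s].astype(float)
        b = table.depth_b[chrom][:, s].astype(float)
        idx = np.clip(np.searchsorted(edges, pos, side="right") - 1, 0, n - 1)
        A = np.bincount(idx, weights=a, minlength=n)
        B = np.bincount(idx, weights=b, minlength=n)
        n_sites = np.bincount(idx, minlength=n)
        ok = (n_sites >= min_sites) & (A + B > 0)
        frac = np.full(n, 0.5)
        frac[ok] = A[ok] / (A[ok] + B[ok])
        if ok.any() and not ok.all():
            # nearest informative bin
            good = np.where(ok)[0]
            nearest = good[np.argmin(np.abs(np.arange(n)[:, None] - good[None, :]), axis=1)]
            frac[~ok] = frac[nearest[~ok]]
        t = np.asarray(total[chrom], dtype=float)
        hap_a[chrom] = t * frac
        hap_b[chrom] = t * (1.0 - frac)
        informative[chrom] = ok
    return HaplotypeProfile(genome, {c: np.asarray(total[c], dtype=float) for c in genome.chromosomes}, hap_a, hap_b, informative)


def segment_profile(profile: HaplotypeProfile, penalty_factor: float = 1.8, min_size: int = 2) -> pd.DataFrame:
    """Joint changepoint segmentation of the (hapA, hapB) coverage signal.

    Changepoints minimize the penalized within-segment squared error on the
    two haplotype signals jointly; the configured factor multiplies the base
    penalty. Boundaries are reported in bp (aligned to bin edges) and stored
    on ``profile.segments`` with per-segment mean haplotype coverages.
    """
    rows = []
    for chrom in profile.genome.chromosomes:
        a = profile.hap_a[chrom]
        b = profile.hap_b[chrom]
        edges = profile.genome.bin_edges(chrom)
        x = np.column_stack([np.nan_to_num(a, nan=np.nanmedian(a)), np.nan_to_num(b, nan=np.nanmedian(b))])
        if len(x) < 2 * min_size:
            cps = []
        else:
            cps = pelt_changepoints(x, penalty_factor=penalty_factor, min_size=min_size)
        bounds = [0, *cps, len(a)]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(edges[lo]),
                    "end": int(edges[hi]),
                    "n_bins": hi - lo,
                    "cov_a": float(np.nanmean(a[lo:hi])),
                    "cov_b": float(np.nanmean(b[lo:hi])),
                }
            )
    profile.segments = pd.DataFrame(rows)
    return profile.segments


@dataclass
class PurityPloidyFit:
    status: str  # 'ok' or 'indeterminate'
    purity: float | None
    ploidy: float | None
    candidates: pd.DataFrame | None = None
    reason: str | None = None


def estimate_purity_ploidy(
    segments: pd.DataFrame,
    purity_grid: np.ndarray | None = None,
    ploidy_grid: np.ndarray | None = None,
    subclonal_threshold: float = 0.3,
    imbalance_min: float = 0.1,
    objective_tol: float = 2e-4,
    min_seg_len: int = 500_000,
    min_subclonal_len: int = 3_000_000,
    cn_cap: int = 6,
    max_nullisomy: float = 0.01,
) -> PurityPloidyFit:
    """Grid-search purity and ploidy from segment haplotype coverages.

    Each grid point (purity p, ploidy psi) maps segment coverage ``c`` to an
    implied allelic copy number ``q = (c * D - (1 - p)) / p`` with
    ``D = p * psi + 2 (1 - p)``; rounding gives an integer assignment whose
    linear model ``c = alpha * q + beta`` is then re-fit by weighted least
    squares, collapsing every assignment basin to its own optimum (and
    refining purity/ploidy beyond the grid resolution). Candidates implying
    nullisomy (both homologs at zero copies) over more than ``max_nullisomy``
    of the genome are discarded as biologically impossible. Among candidates
    fitting within ``objective_tol`` of the best length-weighted coverage
    residual, the automatic pick has the fewest subclonal (non-integer)
    states and then the lowest ploidy — integer rescalings and shifts of the
    copy-number lattice fit coverage equally well, and ploidy parsimony is
    the deterministic stand-in for a manual review of the candidate ladder.
    Samples without allelic imbalance are 'indeterminate' (no large SCNAs to
    anchor the fit).
    """
    segs = segments
    if purity_grid is None:
        purity_grid = np.round(np.arange(0.05, 1.0 + 1e-9, 0.01), 2)
    if ploidy_grid is None:
        ploidy_grid = np.round(np.arange(1.2, 6.0 + 1e-9, 0.05), 2)
    w = (segs["end"] - segs["start"]).to_numpy(dtype=float)
    cov = segs[["cov_a", "cov_b"]].to_numpy(dtype=float)  # (n_seg, 2)
    # short segments (segmentation shrapnel around complex regions) carry
    # amplified coverage noise and are excluded from the fit
    ok = np.isfinite(cov).all(axis=1) & (w >= min_seg_len)
    cov, w = cov[ok], w[ok]
    if len(cov) == 0:
        return PurityPloidyFit("indeterminate", None, None, reason="no usable segments")
    imb = np.abs(cov[:, 0] - cov[:, 1])
    if float(np.max(imb)) < imbalance_min:
        return PurityPloidyFit("indeterminate", None, None, reason="no allelic imbalance")

    P, S = np.meshgrid(purity_grid, ploidy_grid, indexing="ij")
    P = P.ravel()
    S = S.ravel()
    D = P * S + 2 * (1 - P)  # expected coverage scale
    q = (cov[None, :, :] * D[:, None, None] - (1 - P)[:, None, None]) / P[:, None, None]
    q_int = np.clip(np.round(q), 0, None)  # (n_grid, n_seg, 2)

    # refine (alpha, beta) of c = alpha q + beta per candidate by weighted
    # least squares over both homologs, collapsing each integer-assignment
    # basin to its optimum (the grid only has to land in the right basin)
    wn = w / w.sum()
    w2 = (np.repeat(wn, 2) / 2.0)[None, :]  # (1, n_seg * 2), sums to 1
    qf = q_int.reshape(len(P), -1)
    cf = np.broadcast_to(cov.reshape(1, -1), qf.shape)
    mq = np.sum(w2 * qf, axis=1)
    mc = np.sum(w2 * cf, axis=1)
    var_q = np.sum(w2 * (qf - mq[:, None]) ** 2, axis=1)
    cov_qc = np.sum(w2 * (qf - mq[:, None]) * (cf - mc[:, None]), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.where(var_q > 0, cov_qc / np.maximum(var_q, 1e-30), np.nan)
    beta = mc - alpha * mq
    # alpha = p/D, beta = (1-p)/D  ->  p = alpha / (alpha + beta)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_ref = alpha / (alpha + beta)
        D_ref = 1.0 / (alpha + beta)
        psi_ref = (D_ref - 2 * (1 - p_ref)) / np.maximum(p_ref, 1e-12)

    resid = cf - (alpha[:, None] * qf + beta[:, None])  # coverage units
    resid_cn = np.abs(resid) / np.maximum(alpha[:, None], 1e-12)  # copy units
    # two objectives: copy units for interpretability and subclonal flags,
    # coverage units for the acceptance band — exact rescalings/shifts of
    # the lattice tie exactly in coverage space after refinement, so the
    # band can be tight enough to reject genuinely worse fits
    objective = np.sum(w2 * np.minimum(resid_cn, 1.0), axis=1)
    objective_cov = np.sum(w2 * np.abs(resid), axis=1)
    # subclonal-state evidence comes from sizable segments only: residual
    # phase flips and segmentation shrapnel produce short off-lattice
    # segments that should not decide between candidate solutions
    countable = (qf <= cn_cap) & (np.repeat(w, 2)[None, :] >= min_subclonal_len)
    sub_mask = ((resid_cn > subclonal_threshold) & countable).reshape(len(P), -1, 2).any(axis=2)
    n_subclonal = sub_mask.sum(axis=1)
    sub_frac = np.sum(sub_mask * wn[None, :], axis=1)
    nullisomy = np.sum((q_int.sum(axis=2) == 0) * wn[None, :], axis=1)
    valid = (
        np.isfinite(p_ref)
        & np.isfinite(psi_ref)
        & (p_ref > 0.04)
        & (p_ref <= 1.0)
        & (psi_ref >= 1.0)
        & (psi_ref <= 6.5)
        & (alpha > 0)
        & (nullisomy <= max_nullisomy)
    )

    cand = pd.DataFrame(
        {
            "purity": np.round(p_ref, 4),
            "ploidy": np.round(psi_ref, 4),
            "objective": objective,
            "objective_cov": objective_cov,
            "n_subclonal": n_subclonal,
            "subclonal_fraction": sub_frac,
            "nullisomy_fraction": nullisomy,
            "valid": valid,
            "grid_purity": P,
            "grid_ploidy": S,
        }
    )
    usable = cand[cand["valid"]]
    if usable.empty:
        return PurityPloidyFit("indeterminate", None, None, cand, reason="no valid candidate")
    # adequacy first: fewest subclonal states with a one-segment tolerance
    # (a denser lattice can always absorb one stray segment, and one
    # artifact segment must not veto the true solution); then a generous
    # coverage-residual band rejects genuinely worse fits; the lowest
    # ploidy (bucketed, so trivially different refinements of one solution
    # do not compete) resolves the remaining exact-alias ladder
    min_sub = usable["n_subclonal"].min()
    adequate = usable[usable["n_subclonal"] <= min_sub + 1].copy()
    o_min = adequate["objective_cov"].min()
    near = adequate[adequate["objective_cov"] <= 2.0 * o_min + objective_tol].copy()
    near["ploidy_bucket"] = np.round(near["ploidy"] * 4) / 4
    best = near.sort_values(["ploidy_bucket", "objective_cov"], kind="mergesort").iloc[0]
    ranked = cand.sort_values(["objective", "ploidy"], kind="mergesort").reset_index(drop=True)
    return PurityPloidyFit(
        "ok", float(round(best["purity"], 2)), float(round(best["ploidy"], 2)), ranked
    )


def call_integer_cn(
    segments: pd.DataFrame,
    purity: float,
    ploidy: float,
    genome: GenomeModel,
    subclonal_threshold: float = 0.3,
) -> tuple[ParentalKaryotype, pd.DataFrame]:
    """Integer allelic copy number per segment given purity and ploidy.

    ``q = (cov * D - (1 - purity)) / purity`` per homolog, rounded to the
    nearest non-negative integer; residuals above ``subclonal_threshold``
    copies are flagged subclonal (the fractional value is retained in the
    returned table). Also returns the called karyotype.
    """
    if purity <= 0:
        raise ValueError("purity must be > 0")
    D = purity * ploidy + 2 * (1 - purity)
    out = segments.copy()
    for hom, col in (("a", "cov_a"), ("b", "cov_b")):
        q = (out[col].to_numpy(dtype=float) * D - (1 - purity)) / purity
        q_int = np.clip(np.round(q), 0, None).astype(int)
        out[f"frac_{hom}"] = q
        out[f"cn{hom.upper()}"] = q_int
    out["subclonal"] = (
        (np.abs(out["frac_a"] - out["cnA"]) > subclonal_threshold)
        | (np.abs(out["frac_b"] - out["cnB"]) > subclonal_threshold)
    )
    segs_by_chrom: dict[str, list[Segment]] = {}
    for chrom in genome.chromosomes:
        sub = out[out["chrom"] == chrom].sort_values("start")
        segs = [Segment(int(r.start), int(r.end), int(r.cnA), int(r.cnB)) for r in sub.itertuples()]
        if not segs:
            segs = [Segment(0, genome.lengths[chrom], 1, 1)]
        # pad any uncovered chromosome ends so the tiling invariant holds
        if segs[0].start != 0:
            segs.insert(0, Segment(0, segs[0].start, segs[0].cnA, segs[0].cnB))
        if segs[-1].end != genome.lengths[chrom]:
            segs.append(Segment(segs[-1].end, genome.lengths[chrom], segs[-1].cnA, segs[-1].cnB))
        segs_by_chrom[chrom] = segs
    karyotype = ParentalKaryotype(genome, segs_by_chrom).simplify()
    return karyotype, out


# --------------------------------------------------------------------------
# single cells
# --------------------------------------------------------------------------


def _arm_slices(genome: GenomeModel, chrom: str, edges: np.ndarray) -> dict[str, slice]:
    cs, ce = genome.centromeres[chrom]
    starts = edges[:-1]
    p = starts < cs
    q = starts >= ce
    return {"p": slice(0, int(p.sum())), "q": slice(len(starts) - int(q.sum()), len(starts))}


def single_cell_normalize(
    cell_counts: Mapping[str, np.ndarray],
    median_profile: Mapping[str, np.ndarray],
    genome: GenomeModel,
    gc: Mapping[str, np.ndarray] | None = None,
    bin_width: int = 10_000,
    report_bins: int = 100,
    arm_tol: float = 0.05,
) -> tuple[dict[str, np.ndarray], dict]:
    """Four-step total-copy-number normalization of one ~1x cell.

    (1) Center counts by the genome-wide mean. (2) Remove recurrent coverage
    bias: pick a constant-copy-number region — the largest chromosome arm
    whose median coverage is within ``arm_tol`` of the genome-wide median of
    arm medians, else the arm with the lowest coverage SD — and fit that
    region's log-coverage to a cubic polynomial of the log median coverage
    across cells; subtract the predicted bias genome-wide and exponentiate.
    (3) Remove GC-dependent variation (smooth fit vs %GC) when GC is given.
    (4) Average ``report_bins`` consecutive bins (1 Mb at 10 kb bins).

    Returns the 1 Mb normalized coverage per chromosome and an info dict
    naming the constant-CN region used.
    """
    # step 1: genome-wide mean centering
    allc = np.concatenate([np.asarray(cell_counts[c], dtype=float) for c in genome.chromosomes])
    mean = allc[allc > 0].mean() if np.any(allc > 0) else 1.0
    centered = {c: np.asarray(cell_counts[c], dtype=float) / mean for c in genome.chromosomes}

    # arm medians to find a constant-CN region
    arm_stats = []
    for chrom in genome.chromosomes:
        edges = np.arange(0, genome.lengths[chrom] + bin_width, bin_width)
        arms = _arm_slices(genome, chrom, edges[: len(centered[chrom]) + 1])
        for arm, sl in arms.items():
            vals = centered[chrom][sl]
            vals = vals[np.isfinite(vals)]
            if len(vals) < 10:
                continue
            arm_stats.append(
                {
                    "chrom": chrom,
                    "arm": arm,
                    "n": len(vals),
                    "median": float(np.median(vals)),
                    "sd": float(np.std(vals)),
                    "slice": (chrom, sl),
                }
            )
    stats = pd.DataFrame(arm_stats)
    genome_median = float(np.median(stats["median"]))
    near = stats[np.abs(stats["median"] - genome_median) < arm_tol]
    if not near.empty:
        pick = near.sort_values("n", ascending=False).iloc[0]
    else:
        pick = stats.sort_values("sd").iloc[0]
    chrom_pick, sl = pick["slice"]

    # step 2: cubic fit of log coverage vs log median coverage in that region
    y = centered[chrom_pick][sl]
    m = np.asarray(median_profile[chrom_pick], dtype=float)[sl]
    okm = (y > 0) & (m > 0) & np.isfinite(y) & np.isfinite(m)
    if okm.sum() > 10 and np.ptp(np.log(m[okm])) > 1e-9:
        coef = np.polyfit(np.log(m[okm]), np.log(y[okm]), 3)
    else:
        coef = np.zeros(4)  # constant median profile carries no recurrent bias
    normalized: dict[str, np.ndarray] = {}
    for chrom in genome.chromosomes:
        med = np.asarray(median_profile[chrom], dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            bias = np.polyval(coef, np.log(np.maximum(med, 1e-12)))
            logy = np.log(np.maximum(centered[chrom], 1e-12)) - bias
        normalized[chrom] = np.exp(logy)
        normalized[chrom][centered[chrom] <= 0] = 0.0

    # step 3: GC correction
    if gc is not None:
        for chrom in genome.chromosomes:
            g = np.asarray(gc[chrom], dtype=float)
            y = normalized[chrom]
            okg = (y > 0) & np.isfinite(g)
            if okg.sum() > 10 and np.ptp(g[okg]) > 1e-9:
                c2 = np.polyfit(g[okg], np.log(y[okg]), 2)
                normalized[chrom] = np.where(y > 0, np.exp(np.log(np.maximum(y, 1e-12)) - np.polyval(c2, g)), 0.0)

    # step 4: average into 1 Mb reporting bins; rescale to the constant-CN region
    scale = float(np.median(normalized[chrom_pick][sl][normalized[chrom_pick][sl] > 0]))
    coarse: dict[str, np.ndarray] = {}
    for chrom in genome.chromosomes:
        y = normalized[chrom] / max(scale, 1e-12)
        n_out = -(-len(y) // report_bins)
        pad = np.full(n_out * report_bins, np.nan)
        pad[: len(y)] = y
        coarse[chrom] = np.nanmean(pad.reshape(n_out, report_bins), axis=1)
    info = {"constant_region": (chrom_pick, pick["arm"]), "cubic_coef": coef}
    return coarse, info


@dataclass
class ChromCnCall:
    """Integer chromosomal copy-number states for one cell."""

    states: pd.DataFrame  # chrom, arm, cnA, cnB (integer, after WGD adjustment)
    wgd: bool
    tetraploid: bool


def single_cell_chrom_cn(
    arm_allelic: pd.DataFrame,
    tetraploid_band: tuple[float, float] = (0.2, 0.8),
    tetraploid_sd: float = 0.25,
    half_integer_tol: float = 0.15,
) -> ChromCnCall:
    """Chromosomal integer copy number with the half-integer WGD rule.

    ``arm_allelic`` columns: chrom, arm, cn_a, cn_b (median allelic copy
    number per arm, relative scale), sd_a, sd_b (allelic-coverage SDs).
    States are normalized by the genome median arm-level allelic copy
    number; since the minimum non-zero state is one, values clustering at
    half-integers reveal that the remaining chromosomes are duplicated, so
    all states are doubled and WGD is flagged. A genome is called near-
    tetraploid when at least one arm has median allelic CN inside
    ``tetraploid_band`` with allelic-coverage SD below ``tetraploid_sd``.
    A complete duplication with no subsequent loss is indistinguishable
    from diploid by coverage ratios alone and is not flagged.
    """
    df = arm_allelic.copy()
    vals = np.concatenate([df["cn_a"].to_numpy(float), df["cn_b"].to_numpy(float)])
    vals = vals[np.isfinite(vals)]
    med = np.median(vals[vals > 0.25]) if np.any(vals > 0.25) else 1.0
    for col in ("cn_a", "cn_b"):
        df[col] = df[col] / med

    states = np.concatenate([df["cn_a"].to_numpy(float), df["cn_b"].to_numpy(float)])
    dist_int = np.abs(states - np.round(states))
    dist_half = np.abs(states - (np.floor(states) + 0.5))
    is_half = (dist_half < half_integer_tol) & (dist_int > half_integer_tol)
    wgd = bool(np.any(is_half))

    sds = df[["sd_a", "sd_b"]].to_numpy(float) if {"sd_a", "sd_b"} <= set(df.columns) else np.zeros((len(df), 2))
    in_band = (
        ((df["cn_a"] >= tetraploid_band[0]) & (df["cn_a"] <= tetraploid_band[1]) & (sds[:, 0] < tetraploid_sd))
        | ((df["cn_b"] >= tetraploid_band[0]) & (df["cn_b"] <= tetraploid_band[1]) & (sds[:, 1] < tetraploid_sd))
    )
    tetraploid = bool(in_band.any())

    factor = 2.0 if (wgd or tetraploid) else 1.0
    out = df.copy()
    out["cnA"] = np.clip(np.round(out["cn_a"] * factor), 0, None).astype(int)
    out["cnB"] = np.clip(np.round(out["cn_b"] * factor), 0, None).astype(int)
    return ChromCnCall(out, wgd or tetraploid, tetraploid)
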