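"""Mechanistic classification of haplotype-specific copy-number alterations.

Given an integer haplotype-resolved karyotype, each altered region of a
chromosome is assigned one of the SCNA categories used throughout the
analysis: whole-chromosome or arm-level changes, uniparental disomy
(copy-neutral LOH), terminal events (one breakpoint reaching a telomere),
paracentric / pericentric internal events, chromothripsis (oscillating
copy number), focal amplification (allelic CN >= 8) and small focal
deletions/duplications. Sloping copy-number variation — a population-level
signature of ongoing terminal erosion — is detected separately on the
bin-level haplotype profile, using the intact homolog as internal control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .genome import GenomeModel, ParentalKaryotype
from .copynumber import HaplotypeProfile
from .segmentation import changepoints as _changepoints

__all__ = [
    "ScnaEvent",
    "ClassifyConfig",
    "RearrangementCandidate",
    "SlopingCall",
    "classify_chromosome",
    "classify_chromothripsis_footprint",
    "detect_sloping",
    "infer_wgd_bulk",
    "filter_rearrangements",
]

CATEGORIES = (
    "focal_del",
    "focal_dup",
    "UPD",
    "arm_gain",
    "arm_loss",
    "whole_chrom_gain",
    "whole_chrom_loss",
    "terminal_gain",
    "terminal_loss",
    "paracentric_gain",
    "paracentric_loss",
    "pericentric_gain",
    "pericentric_loss",
    "chromothripsis",
    "amplification",
    "sloping",
)

#: complexity color code: simple events, large segmental events, complex, amplified
COMPLEXITY_TIER = {
    "focal_del": "simple",
    "focal_dup": "simple",
    "UPD": "simple",
    "arm_gain": "simple",
    "arm_loss": "simple",
    "whole_chrom_gain": "simple",
    "whole_chrom_loss": "simple",
    "terminal_gain": "segmental",
    "terminal_loss": "segmental",
    "paracentric_gain": "segmental",
    "paracentric_loss": "segmental",
    "pericentric_gain": "segmental",
    "pericentric_loss": "segmental",
    "chromothripsis": "complex",
    "sloping": "complex",
    "amplification": "amplified",
}


@dataclass
class ScnaEvent:
    """One classified somatic copy-number alteration."""

    sample: str
    chrom: str
    homolog: str
    category: str
    breakpoints: tuple[int, ...] = ()
    copy_change: int = 0
    footprint: str = "NA"  # chromothripsis footprint
    complexity: str = ""
    span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        self.breakpoints = tuple(sorted(self.breakpoints))
        if not self.complexity:
            self.complexity = COMPLEXITY_TIER[self.category]


@dataclass(frozen=True)
class ClassifyConfig:
    """Thresholds of the category decision rules."""

    arm_tol: int = 1_000_000  # breakpoint within 1 Mb of centromere/telomere counts as arm-level
    focal_max: int = 5_000_000  # below this an interior event is 'focal'
    oscillation_min_switches: int = 8  # alternating two-state switches for chromothripsis
    amplification_threshold: int = 8
    breakpoint_tol: int = 100_000


def _modal_cn(segs, length: int) -> int:
    """Length-weighted modal copy number; ties go to the lower state."""
    weights: dict[int, int] = {}
    for s, e, cn in segs:
        weights[cn] = weights.get(cn, 0) + (e - s)
    best = sorted(weights.items(), key=lambda kv: (-kv[1], kv[0]))
    return best[0][0]


def _reference_cn(segs, length: int, baseline_h: int, min_fraction: float = 0.01) -> int:
    """Reference (unaltered) state for deviation calling on one homolog.

    The germline-equivalent baseline is the reference whenever any of it
    survives on the chromosome, even if a large alteration made the altered
    state modal (a 90 Mb terminal loss must read as a loss from the
    remaining baseline, not a gain of the other end); only when the
    baseline is essentially absent (whole-chromosome change) does the
    length-weighted modal state (ties to the lower copy number) stand in.
    """
    base_cov = sum(e - s for s, e, cn in segs if cn == baseline_h)
    if base_cov >= min_fraction * length:
        return baseline_h
    return _modal_cn(segs, length)


def _homolog_segments(k: ParentalKaryotype, chrom: str, homolog: str) -> list[tuple[int, int, int]]:
    out = []
    for s in k.segments[chrom]:
        cn = s.cn(homolog)
        if out and out[-1][2] == cn:
            out[-1] = (out[-1][0], s.end, cn)
        else:
            out.append((s.start, s.end, cn))
    return out


def _oscillation_runs(segs: Sequence[tuple[int, int, int]], min_switches: int) -> list[tuple[int, int]]:
    """Maximal runs of segments alternating between exactly two CN states."""
    runs: list[tuple[int, int]] = []
    i = 0
    n = len(segs)
    while i < n - 1:
        states = {segs[i][2], segs[i + 1][2]}
        if len(states) != 2:
            i += 1
            continue
        lo_state, hi_state = sorted(states)
        j = i + 1
        while j + 1 < n and segs[j + 1][2] in (lo_state, hi_state) and segs[j + 1][2] != segs[j][2]:
            j += 1
        n_switches = j - i
        if n_switches >= min_switches:
            runs.append((segs[i][0], segs[j][1]))
            i = j
        else:
            i += 1
    return runs


def classify_chromosome(
    k: ParentalKaryotype,
    chrom: str,
    genome: GenomeModel | None = None,
    sample: str = "",
    baseline: tuple[int, int] = (1, 1),
    cfg: ClassifyConfig = ClassifyConfig(),
) -> list[ScnaEvent]:
    """Classify the SCNAs on one chromosome of a called karyotype.

    ``baseline`` is the per-homolog germline-equivalent copy number (1, 1)
    for a non-WGD genome, (2, 2) after whole-genome duplication). The
    decision order: uniparental disomy (copy-neutral, one homolog lost and
    the other compensating) -> whole-chromosome / arm-level (deviation
    spanning a chromosome or arm within tolerance) -> chromothripsis
    (oscillating two-state copy number) -> terminal (one breakpoint
    reaching a telomere) -> paracentric / pericentric internal events or
    focal events below the size threshold. Focal amplification is called
    wherever allelic copy number reaches the amplification threshold,
    independent of the other rules.
    """
    genome = genome or k.genome
    length = genome.lengths[chrom]
    cs, ce = genome.centromeres[chrom]
    tol = cfg.arm_tol
    events: list[ScnaEvent] = []
    base = {"A": baseline[0], "B": baseline[1]}
    base_total = baseline[0] + baseline[1]

    # --- UPD: copy-neutral LOH, checked jointly on both homologs
    upd_mask: list[tuple[int, int]] = []
    runs: list[tuple[int, int, str]] = []  # start, end, recipient homolog
    for s in k.copy().simplify().segments[chrom]:
        recipient = None
        if s.total == base_total and s.cnA == 0 and s.cnB == s.total and s.total > 0 and base["A"] > 0:
            recipient = "A"
        elif s.total == base_total and s.cnB == 0 and s.cnA == s.total and s.total > 0 and base["B"] > 0:
            recipient = "B"
        if recipient is not None:
            if runs and runs[-1][1] == s.start and runs[-1][2] == recipient:
                runs[-1] = (runs[-1][0], s.end, recipient)
            else:
                runs.append((s.start, s.end, recipient))
    for start, end, recipient in runs:
        # uniparental disomy arises from a single repair event and spans a
        # terminal region or an arm; an interior copy-neutral stretch is a
        # coincidence of independent gain and loss, not UPD
        anchored = (
            start <= tol
            or end >= length - tol
            or abs(start - ce) <= tol
            or abs(end - cs) <= tol
        )
        if not anchored:
            continue
        bps = tuple(p for p in (start, end) if tol < p < length - tol)
        events.append(
            ScnaEvent(sample, chrom, recipient, "UPD", bps, 0, span=(start, end))
        )
        upd_mask.append((start, end))

    def masked(lo: int, hi: int) -> bool:
        return any(lo >= a - tol and hi <= b + tol for a, b in upd_mask)

    for homolog in ("A", "B"):
        segs = _homolog_segments(k, chrom, homolog)
        b = base[homolog]

        # --- amplification: exactly the segments at or above the threshold
        for s, e, cn in segs:
            if cn >= cfg.amplification_threshold:
                bps = tuple(p for p in (s, e) if 0 < p < length)
                events.append(
                    ScnaEvent(sample, chrom, homolog, "amplification", bps, cn - b, span=(s, e))
                )
        segs_na: list[tuple[int, int, int]] = []
        for s, e, cn in segs:
            cn2 = cn if cn < cfg.amplification_threshold else b
            if segs_na and segs_na[-1][2] == cn2:
                segs_na[-1] = (segs_na[-1][0], e, cn2)
            else:
                segs_na.append((s, e, cn2))
        modal = _reference_cn(segs_na, length, b)

        # --- chromothripsis: oscillating two-state runs
        osc_regions = _oscillation_runs(segs_na, cfg.oscillation_min_switches)
        for s, e in osc_regions:
            bps = tuple(x for s2, e2, _ in segs_na for x in (s2,) if s < x <= e and x > 0)
            events.append(
                ScnaEvent(sample, chrom, homolog, "chromothripsis", tuple(sorted(set(bps))), 0, span=(s, e))
            )

        def in_osc(lo: int, hi: int) -> bool:
            return any(lo >= a and hi <= b2 for a, b2 in osc_regions)

        # --- whole-chromosome deviation without internal breakpoints
        if len(segs_na) == 1:
            cn = segs_na[0][2]
            if cn != b and not masked(0, length):
                cat = "whole_chrom_gain" if cn > b else "whole_chrom_loss"
                events.append(ScnaEvent(sample, chrom, homolog, cat, (), cn - b, span=(0, length)))
            continue

        # --- deviation runs relative to the chromosome modal state
        i = 0
        n = len(segs_na)
        while i < n:
            s, e, cn = segs_na[i]
            if cn == modal or masked(s, e) or in_osc(s, e):
                i += 1
                continue
            # merge consecutive same-direction deviations into one run
            j = i
            while (
                j + 1 < n
                and segs_na[j + 1][2] != modal
                and not masked(*segs_na[j + 1][:2])
                and not in_osc(*segs_na[j + 1][:2])
                and np.sign(segs_na[j + 1][2] - modal) == np.sign(cn - modal)
            ):
                j += 1
            run_s, run_e = s, segs_na[j][1]
            run_cn = max((seg[2] for seg in segs_na[i : j + 1]), key=lambda c: abs(c - modal))
            delta = run_cn - modal
            direction = "gain" if delta > 0 else "loss"
            at_p = run_s <= tol
            at_q = run_e >= length - tol
            if at_p and at_q:
                cat = f"whole_chrom_{direction}"
                bps: tuple[int, ...] = ()
            elif (at_p and abs(run_e - cs) <= tol) or (at_q and abs(run_s - ce) <= tol):
                cat = f"arm_{direction}"
                bps = (run_e,) if at_p else (run_s,)
            elif at_p or at_q:
                cat = f"terminal_{direction}"
                bps = (run_e,) if at_p else (run_s,)
            elif run_e - run_s < cfg.focal_max:
                cat = "focal_dup" if delta > 0 else "focal_del"
                bps = (run_s, run_e)
            elif run_e <= cs or run_s >= ce:
                cat = f"paracentric_{direction}"
                bps = (run_s, run_e)
            else:
                cat = f"pericentric_{direction}"
                bps = (run_s, run_e)
            events.append(ScnaEvent(sample, chrom, homolog, cat, bps, delta, span=(run_s, run_e)))
            i = j + 1
    return events


def classify_chromothripsis_footprint(
    event: ScnaEvent,
    other_events: Iterable[ScnaEvent],
    genome: GenomeModel,
    tol: int = 1_000_000,
) -> str:
    """Footprint of a chromothripsis event relative to chromosome structure.

    'direct-bridge' when the oscillating region abuts the boundary of a
    large terminal or internal SCNA (the broken bridge terminus);
    'downstream-micronucleus' when the oscillation spans a centromeric or
    telomeric segment or an entire arm (fragmentation of a whole broken
    chromosome in a micronucleus); 'regional' otherwise. The two bridge
    footprints are not strictly distinguishable; the label is a best guess.
    """
    if event.category != "chromothripsis":
        raise ValueError("footprint classification requires a chromothripsis event")
    if event.span is None:
        return "NA"
    s, e = event.span
    length = genome.lengths[event.chrom]
    cs, ce = genome.centromeres[event.chrom]
    large = {"terminal_gain", "terminal_loss", "paracentric_gain", "paracentric_loss",
             "pericentric_gain", "pericentric_loss"}
    for ev in other_events:
        if ev.chrom != event.chrom or ev.category not in large:
            continue
        for bp in ev.breakpoints:
            if abs(bp - s) <= tol or abs(bp - e) <= tol:
                return "direct-bridge"
    touches_telomere = s <= tol or e >= length - tol
    spans_centromere = s < cs and e > ce
    whole_arm = (s <= tol and abs(e - cs) <= tol) or (abs(s - ce) <= tol and e >= length - tol)
    if touches_telomere or spans_centromere or whole_arm:
        return "downstream-micronucleus"
    return "regional"


@dataclass
class SlopingCall:
    chrom: str
    homolog: str
    arm: str
    start: int
    end: int
    direction: str  # 'telomere' or 'centromere'
    attenuation: float  # copies lost across the span
    rho: float  # rank correlation of coverage vs position


def detect_sloping(
    profile: HaplotypeProfile,
    chrom: str,
    arm: str,
    min_span: int = 5_000_000,
    min_attenuation: float = 0.3,
    rho_min: float = 0.5,
    flat_band: float = 0.15,
    grid_bp: int = 2_000_000,
    max_fit_points: int = 300,
    sample: str = "",
) -> list[SlopingCall]:
    """Detect sloping (gradually attenuating) copy number on one arm.

    Candidate regions anchored at the telomeric or centromeric end of the
    arm are scanned on a coarse grid; a call requires, on one homolog, a
    robust monotone trend — Spearman rank correlation at least ``rho_min``
    in magnitude plus a Theil-Sen robust linear fit — losing at least
    ``min_attenuation`` copies over at least ``min_span``, while the other
    homolog stays flat over the same region (fitted attenuation within
    ``flat_band``). A clonal step (single changepoint) is rejected by
    requiring the gradual model to explain the data at least as well as the
    best single-step fit. At most one call per homolog (the strongest) is
    returned.
    """
    genome = profile.genome
    lo, hi = genome.arms(chrom)[arm]
    if hi - lo < min_span:
        return []
    edges = genome.bin_edges(chrom)
    centers = (edges[:-1] + edges[1:]) / 2.0
    arm_mask = (centers >= lo) & (centers < hi)
    if arm_mask.sum() < 20:
        return []
    purity = profile.purity if profile.purity is not None else 1.0
    ploidy = profile.ploidy if profile.ploidy is not None else 2.0
    D = purity * ploidy + 2 * (1 - purity)
    x_arm = centers[arm_mask]
    cn = {
        h: (np.asarray(v, float)[arm_mask] * D - (1 - purity)) / purity
        for h, v in (("A", profile.hap_a[chrom]), ("B", profile.hap_b[chrom]))
    }

    # candidate regions anchor at one end of the arm; the attenuating end is
    # a telomere for regions reaching the telomeric side and vice versa
    telomeric_end = hi if arm == "q" else lo
    calls: list[SlopingCall] = []
    for h in ("A", "B"):
        other = "B" if h == "A" else "A"
        best: SlopingCall | None = None
        for anchor in ("left", "right"):
            n_grid = int((hi - lo - min_span) // grid_bp) + 1
            for i in range(max(n_grid, 1)):
                if anchor == "right":
                    r_lo, r_hi = lo + i * grid_bp, hi
                else:
                    r_lo, r_hi = lo, hi - i * grid_bp
                if r_hi - r_lo < min_span:
                    break
                m = (x_arm >= r_lo) & (x_arm < r_hi)
                if m.sum() < 20:
                    continue
                xs, ys = _thin(x_arm[m], cn[h][m], max_fit_points)
                ok = np.isfinite(ys)
                if ok.sum() < 20:
                    continue
                xs, ys = xs[ok], ys[ok]
                rho = stats.spearmanr(xs, ys).statistic
                if not np.isfinite(rho) or abs(rho) < rho_min:
                    continue
                slope, intercept, *_ = stats.theilslopes(ys, xs)
                span = xs[-1] - xs[0]
                attenuation = abs(slope) * span
                if attenuation < min_attenuation or span < min_span:
                    continue
                # the other homolog must be flat over the same region
                xo, yo = _thin(x_arm[m], cn[other][m], max_fit_points)
                oko = np.isfinite(yo)
                o_slope, *_ = stats.theilslopes(yo[oko], xo[oko])
                if abs(o_slope) * span >= flat_band:
                    continue
                # reject clonal steps: linear fit must beat a single-step fit
                resid_line = ys - (intercept + slope * xs)
                if _best_step_sse(ys) < float(np.sum(resid_line**2)):
                    continue
                # direction: which end of the region loses copies
                declining_right = slope < 0
                to_telomere = (declining_right and telomeric_end == hi) or (
                    not declining_right and telomeric_end == lo
                )
                call = SlopingCall(
                    chrom,
                    h,
                    arm,
                    int(r_lo),
                    int(r_hi),
                    "telomere" if to_telomere else "centromere",
                    float(attenuation),
                    float(rho),
                )
                if best is None or call.attenuation > best.attenuation:
                    best = call
        if best is not None:
            calls.append(best)
    return calls


def _thin(x: np.ndarray, y: np.ndarray, max_points: int) -> tuple[np.ndarray, np.ndarray]:
    """Evenly thin paired arrays (robust fits are quadratic in point count)."""
    if len(x) <= max_points:
        return x, y
    idx = np.linspace(0, len(x) - 1, max_points).astype(int)
    return x[idx], y[idx]


def _best_step_sse(y: np.ndarray) -> float:
    """SSE of the best piecewise-constant two-segment (single step) fit."""
    n = len(y)
    c = np.cumsum(y)
    c2 = np.cumsum(y**2)
    i = np.arange(1, n)
    sse_l = c2[i - 1] - c[i - 1] ** 2 / i
    sse_r = (c2[-1] - c2[i - 1]) - (c[-1] - c[i - 1]) ** 2 / (n - i)
    return float(np.min(sse_l + sse_r))


def infer_wgd_bulk(k: ParentalKaryotype, threshold: float = 0.5) -> bool:
    """Whole-genome duplication from the prevalence of duplicated homologs.

    WGD is called when the length-weighted fraction of the genome whose
    major homolog has at least two copies exceeds ``threshold``; the rule
    survives extensive post-WGD losses because losses rarely push the major
    homolog below two copies across most of the genome simultaneously.
    """
    dup = tot = 0.0
    for chrom, s in k.iter_segments():
        tot += s.length
        if max(s.cnA, s.cnB) >= 2:
            dup += s.length
    return bool(tot > 0 and dup / tot > threshold)


@dataclass(frozen=True)
class RearrangementCandidate:
    """A candidate rearrangement junction: two breakends and read support."""

    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    support: int = 0


def filter_rearrangements(
    cands: Sequence[RearrangementCandidate],
    cn_changepoints: Mapping[str, Sequence[int]],
    tol: int = 100_000,
) -> list[RearrangementCandidate]:
    """Copy-number-support filter for rearrangement candidates.

    Candidates with both breakpoints on one chromosome closer than ``tol``
    are removed first (FFPE chimera artifacts); the survivors are kept only
    when *both* breakends lie within ``tol`` of some copy-number
    changepoint.
    """
    kept = []
    for c in cands:
        if c.chrom1 == c.chrom2 and abs(c.pos1 - c.pos2) < tol:
            continue
        near1 = any(abs(c.pos1 - x) <= tol for x in cn_changepoints.get(c.chrom1, ()))
        near2 = any(abs(c.pos2 - x) <= tol for x in cn_changepoints.get(c.chrom2, ()))
        if near1 and near2:
            kept.append(c)
    return kept
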