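"""Mechanistic clone-evolution simulator and sequencing-like renderers.

Ground-truth karyotype evolution is generated by explicit event operators
(breakage-fusion-bridge outcomes, chromothripsis, whole-genome duplication,
missegregation, uniparental disomy, focal events) applied along the branches
of a clone tree. Renderers then turn leaf karyotypes into bulk FFPE-WGS-like
binned depth tables and allelic-depth tables at het sites (including
statistical-phasing switch errors), and into low-pass single-cell profiles.

Every operator preserves the segment-tiling invariant of
:class:`~hapscna.genome.ParentalKaryotype`; conservation laws (reciprocal
BFB daughters, copy-neutral UPD) hold exactly by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeModel, ParentalKaryotype, Segment
from .phasing import AllelicDepthTable

__all__ = [
    "EventSpec",
    "TreeNode",
    "TrueCloneTree",
    "RenderConfig",
    "apply_bfb_break",
    "apply_paracentric_or_pericentric",
    "apply_chromothripsis",
    "apply_bfb_amplification",
    "apply_wgd",
    "apply_missegregation",
    "apply_upd",
    "apply_event",
    "simulate_clone_tree",
    "simulate_bin_covariates",
    "simulate_switch_parity",
    "render_bulk",
    "render_sloping_population",
    "render_single_cell",
]

EVENT_KINDS = (
    "missegregation",
    "WGD",
    "multipolar_loss",
    "UPD",
    "bfb_terminal",
    "bfb_paracentric",
    "bfb_pericentric",
    "chromothripsis",
    "bfb_amplification",
    "progressive_erosion",
    "focal_del",
    "focal_dup",
)

#: event kinds that can fixate in clones with intact p53 (copy-neutral or focal)
PRE_TP53_KINDS = ("UPD", "focal_del", "focal_dup")


@dataclass
class EventSpec:
    """One mutational event with its target and parameters."""

    kind: str
    chrom: str | None = None
    homolog: str | None = None
    breakpoints: tuple[int, ...] = ()
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


# --------------------------------------------------------------------------
# event operators
# --------------------------------------------------------------------------


def apply_bfb_break(
    k: ParentalKaryotype, chrom: str, homolog: str, breakpoint: int
) -> tuple[ParentalKaryotype, ParentalKaryotype]:
    """Break a dicentric chromatid bridge: reciprocal terminal loss and gain.

    Returns two daughters: daughter 1 loses one copy of the segment distal of
    ``breakpoint`` (toward the q-terminus), daughter 2 gains one. For every
    bin, ``cn(d1) + cn(d2) == 2 * cn(parent)``.
    """
    length = k.genome.lengths[chrom]
    if not (0 < breakpoint < length):
        raise ValueError(f"breakpoint {breakpoint} not strictly inside {chrom}")
    if k.min_cn(chrom, breakpoint, length, homolog) < 1:
        raise ValueError(f"{chrom} homolog {homolog}: zero copy number in the broken region")
    d1, d2 = k.copy(), k.copy()
    d1.add_cn(chrom, breakpoint, length, homolog, -1)
    d2.add_cn(chrom, breakpoint, length, homolog, +1)
    return d1.simplify(), d2.simplify()


def apply_paracentric_or_pericentric(
    k: ParentalKaryotype, chrom: str, homolog: str, bp1: int, bp2: int, sign: int
) -> ParentalKaryotype:
    """Internal segmental gain/loss from chromosome-type bridge or ring breakage.

    The altered segment ``[bp1, bp2)`` must be interior (a segment touching a
    telomere is a terminal event, not an internal one). Whether the outcome is
    paracentric (within one arm) or pericentric (spanning the centromere) is
    determined by the centromere interval; use :func:`segment_arm_class`.
    """
    length = k.genome.lengths[chrom]
    if sign not in (+1, -1):
        raise ValueError("sign must be +1 or -1")
    if not (0 < bp1 < bp2 < length):
        raise ValueError("segment must be strictly interior (terminal events are separate)")
    if sign < 0 and k.min_cn(chrom, bp1, bp2, homolog) < 1:
        raise ValueError("loss requires copy number >= 1 on the segment")
    out = k.copy()
    out.add_cn(chrom, bp1, bp2, homolog, sign)
    return out.simplify()


def segment_arm_class(genome: GenomeModel, chrom: str, bp1: int, bp2: int) -> str:
    """'paracentric' if [bp1,bp2) lies within one arm, else 'pericentric'."""
    cs, ce = genome.centromeres[chrom]
    if bp2 <= cs or bp1 >= ce:
        return "paracentric"
    return "pericentric"


def apply_chromothripsis(
    k: ParentalKaryotype,
    chrom: str,
    homolog: str,
    region: tuple[int, int],
    n_fragments: int,
    retention_p: float,
    seed: int | np.random.Generator | None = None,
) -> ParentalKaryotype:
    """Shatter ``region`` into random fragments, each retained or lost.

    Fragment boundaries follow uniform stick-breaking. Each fragment is
    independently retained (copy number unchanged) with probability
    ``retention_p``, else loses one copy, producing the oscillating
    two-state pattern characteristic of chromothripsis on a uniform baseline.
    """
    start, end = region
    length = k.genome.lengths[chrom]
    if not (0 <= start < end <= length):
        raise ValueError("region outside chromosome")
    if n_fragments < 4:
        raise ValueError("chromothripsis requires >= 4 fragments")
    if k.min_cn(chrom, start, end, homolog) < 1:
        raise ValueError("copy number must be >= 1 on the shattered region")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cuts = np.sort(rng.uniform(start, end, size=n_fragments - 1)).astype(np.int64)
    edges = np.concatenate(([start], cuts, [end]))
    out = k.copy()
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi <= lo:
            continue
        if rng.random() >= retention_p:
            out.add_cn(chrom, int(lo), int(hi), homolog, -1)
    return out.simplify()


def apply_bfb_amplification(
    k: ParentalKaryotype, chrom: str, homolog: str, focus: tuple[int, int], rounds: int
) -> ParentalKaryotype:
    """Successive duplications at a broken chromosome end: focal amplification.

    The ``focus`` interval doubles its copy number each round (``rounds``
    rounds total) and the flank distal of the focus — toward the nearer
    telomere, the broken terminus — is lost. A focus at copy number 1
    requires three rounds to reach the amplification threshold of 8.
    """
    if rounds < 0:
        raise ValueError("rounds must be >= 0")
    start, end = focus
    length = k.genome.lengths[chrom]
    if not (0 <= start < end <= length):
        raise ValueError("focus outside chromosome")
    if k.min_cn(chrom, start, end, homolog) < 1:
        raise ValueError("focus copy number must be >= 1")
    out = k.copy()
    if rounds == 0:
        return out
    factor = 2**rounds
    out._split_at(chrom, start)
    out._split_at(chrom, end)
    segs = []
    for s in out.segments[chrom]:
        if s.start >= start and s.end <= end:
            cnA = s.cnA * factor if homolog == "A" else s.cnA
            cnB = s.cnB * factor if homolog == "B" else s.cnB
            segs.append(Segment(s.start, s.end, cnA, cnB))
        else:
            segs.append(s)
    out.segments[chrom] = segs
    # terminal loss distal of the focus (broken end)
    dist_p = start  # distance to p-telomere
    dist_q = length - end
    if dist_q <= dist_p and end < length:
        out.set_cn(chrom, end, length, homolog, 0)
    elif start > 0:
        out.set_cn(chrom, 0, start, homolog, 0)
    return out.simplify()


def apply_wgd(k: ParentalKaryotype) -> ParentalKaryotype:
    """Whole-genome duplication: every copy number doubles."""
    out = k.copy()
    for chrom, segs in out.segments.items():
        out.segments[chrom] = [Segment(s.start, s.end, 2 * s.cnA, 2 * s.cnB) for s in segs]
    return out


def apply_missegregation(k: ParentalKaryotype, chrom: str, homolog: str, sign: int) -> ParentalKaryotype:
    """Whole-chromosome gain or loss of one homolog."""
    if sign not in (+1, -1):
        raise ValueError("sign must be +1 or -1")
    length = k.genome.lengths[chrom]
    if sign < 0 and k.min_cn(chrom, 0, length, homolog) < 1:
        raise ValueError("cannot lose a homolog with copy number 0")
    out = k.copy()
    out.add_cn(chrom, 0, length, homolog, sign)
    return out.simplify()


def apply_upd(
    k: ParentalKaryotype, chrom: str, region: tuple[int, int], donor_homolog: str
) -> ParentalKaryotype:
    """Uniparental disomy: copy-neutral replacement of one homolog by the other.

    Over ``region`` the recipient homolog drops to 0 and the donor picks up
    the recipient's copies, so total copy number is exactly preserved.
    """
    start, end = region
    recipient = "B" if donor_homolog == "A" else "A"
    if k.min_cn(chrom, start, end, donor_homolog) < 1:
        raise ValueError("UPD donor homolog must have copy number >= 1 over the region")
    out = k.copy()
    out._split_at(chrom, start)
    out._split_at(chrom, end)
    segs = []
    for s in out.segments[chrom]:
        if s.start >= start and s.end <= end:
            if donor_homolog == "A":
                segs.append(Segment(s.start, s.end, s.cnA + s.cnB, 0))
            else:
                segs.append(Segment(s.start, s.end, 0, s.cnA + s.cnB))
        else:
            segs.append(s)
    out.segments[chrom] = segs
    return out.simplify()


# --------------------------------------------------------------------------
# clone trees
# --------------------------------------------------------------------------


@dataclass
class TreeNode:
    name: str
    parent: str | None
    children: list[str] = field(default_factory=list)
    karyotype: ParentalKaryotype | None = None
    tp53_lost: bool = False
    events: list[EventSpec] = field(default_factory=list)
    wgd_on_branch: bool = False


@dataclass
class TrueCloneTree:
    """Rooted ground-truth clone tree; children = parent karyotype + branch events."""

    root: str
    nodes: dict[str, TreeNode]

    @property
    def leaves(self) -> list[str]:
        return [n for n, nd in self.nodes.items() if not nd.children]

    def lineage(self, name: str) -> list[str]:
        """Path of node names from root to ``name`` inclusive."""
        path = [name]
        while self.nodes[path[-1]].parent is not None:
            path.append(self.nodes[path[-1]].parent)
        return path[::-1]

    def has_wgd_on_lineage(self, name: str) -> bool:
        return any(self.nodes[n].wgd_on_branch for n in self.lineage(name))

    def newick(self) -> str:
        def rec(n: str) -> str:
            nd = self.nodes[n]
            if not nd.children:
                return nd.name
            return "(" + ",".join(rec(c) for c in nd.children) + ")" + nd.name

        return rec(self.root) + ";"


def apply_event(
    k: ParentalKaryotype, spec: EventSpec, rng: np.random.Generator | None = None
) -> ParentalKaryotype:
    """Apply one :class:`EventSpec` to a karyotype (dispatch by kind)."""
    rng = rng or np.random.default_rng(0)
    kind = spec.kind
    if kind == "WGD":
        return apply_wgd(k)
    if kind == "missegregation":
        return apply_missegregation(k, spec.chrom, spec.homolog, spec.params["sign"])
    if kind == "multipolar_loss":
        out = k
        for chrom, hom in spec.params["losses"]:
            out = apply_missegregation(out, chrom, hom, -1)
        return out
    if kind == "UPD":
        return apply_upd(k, spec.chrom, (spec.breakpoints[0], spec.breakpoints[1]), spec.homolog)
    if kind in ("bfb_terminal", "progressive_erosion"):
        d1, d2 = apply_bfb_break(k, spec.chrom, spec.homolog, spec.breakpoints[0])
        return d1 if spec.params.get("daughter", "loss") == "loss" else d2
    if kind in ("bfb_paracentric", "bfb_pericentric"):
        return apply_paracentric_or_pericentric(
            k, spec.chrom, spec.homolog, spec.breakpoints[0], spec.breakpoints[1], spec.params["sign"]
        )
    if kind == "chromothripsis":
        return apply_chromothripsis(
            k,
            spec.chrom,
            spec.homolog,
            (spec.breakpoints[0], spec.breakpoints[1]),
            spec.params.get("n_fragments", 10),
            spec.params.get("retention_p", 0.5),
            spec.params.get("seed", rng),
        )
    if kind == "bfb_amplification":
        return apply_bfb_amplification(
            k, spec.chrom, spec.homolog, (spec.breakpoints[0], spec.breakpoints[1]), spec.params.get("rounds", 3)
        )
    if kind == "focal_del":
        return apply_paracentric_or_pericentric(k, spec.chrom, spec.homolog, *spec.breakpoints[:2], -1)
    if kind == "focal_dup":
        return apply_paracentric_or_pericentric(k, spec.chrom, spec.homolog, *spec.breakpoints[:2], +1)
    raise ValueError(f"cannot apply event kind {kind!r}")


DEFAULT_EVENT_MENU = {
    "missegregation": 1.0,
    "UPD": 1.0,
    "bfb_terminal": 2.0,
    "bfb_paracentric": 1.0,
    "bfb_pericentric": 0.5,
    "chromothripsis": 0.5,
    "bfb_amplification": 0.3,
    "focal_del": 1.0,
    "focal_dup": 1.0,
}


def _viable(k: ParentalKaryotype, max_nullisomy_span: int = 5_000_000) -> bool:
    """Cells tolerate focal homozygous deletions but not large nullisomy."""
    for _, s in k.iter_segments():
        if s.total == 0 and s.length > max_nullisomy_span:
            return False
    return True


def _draw_event(
    k: ParentalKaryotype,
    kind: str,
    rng: np.random.Generator,
    genome: GenomeModel,
    forbidden: set[tuple[str, str]] | None = None,
) -> EventSpec | None:
    """Draw random parameters for one event of ``kind``; None if no valid target.

    ``forbidden`` excludes (chromosome, homolog) slots already altered on
    the lineage, for studies requiring unique, non-overlapping markers.
    """
    chroms = genome.chromosomes
    for _ in range(40):  # rejection sampling over targets
        chrom = chroms[rng.integers(len(chroms))]
        homolog = "A" if rng.random() < 0.5 else "B"
        if forbidden:
            # UPD rearranges both homologs, so it needs the whole chromosome
            if kind == "UPD" and ((chrom, "A") in forbidden or (chrom, "B") in forbidden):
                continue
            if (chrom, homolog) in forbidden:
                continue
        length = genome.lengths[chrom]
        cs, ce = genome.centromeres[chrom]
        try:
            if kind == "missegregation":
                sign = -1 if rng.random() < 0.6 else +1
                if sign < 0 and k.min_cn(chrom, 0, length, homolog) < 1:
                    continue
                return EventSpec(kind, chrom, homolog, (), {"sign": sign})
            if kind == "UPD":
                # terminal or arm-scale copy-neutral LOH
                if rng.random() < 0.5:
                    region = (0, int(rng.uniform(0.2, 0.9) * cs)) if rng.random() < 0.5 else (
                        int(ce + rng.uniform(0.1, 0.8) * (length - ce)),
                        length,
                    )
                else:
                    region = (0, cs) if rng.random() < 0.5 else (ce, length)
                if region[1] - region[0] < 2 * genome.bin_width:
                    continue
                if k.min_cn(chrom, region[0], region[1], homolog) < 1:
                    continue
                return EventSpec(kind, chrom, homolog, region, {})
            if kind == "bfb_terminal":
                bp = int(rng.uniform(0.1, 0.9) * length)
                if k.min_cn(chrom, bp, length, homolog) < 1:
                    continue
                return EventSpec(kind, chrom, homolog, (bp,), {"daughter": "loss" if rng.random() < 0.5 else "gain"})
            if kind == "bfb_paracentric":
                lo, hi = (0, cs) if rng.random() < 0.5 else (ce, length)
                a, b = np.sort(rng.uniform(lo + 1, hi - 1, size=2)).astype(int)
                if b - a < 6_000_000:  # large internal segment, above focal scale
                    continue
                sign = -1 if rng.random() < 0.5 else +1
                if sign < 0 and k.min_cn(chrom, a, b, homolog) < 1:
                    continue
                return EventSpec(kind, chrom, homolog, (int(a), int(b)), {"sign": sign})
            if kind == "bfb_pericentric":
                a = int(rng.uniform(0.1, 0.9) * cs)
                b = int(ce + rng.uniform(0.1, 0.9) * (length - ce))
                sign = -1 if rng.random() < 0.5 else +1
                if sign < 0 and k.min_cn(chrom, a, b, homolog) < 1:
                    continue
                return EventSpec(kind, chrom, homolog, (a, b), {"sign": sign})
            if kind == "chromothripsis":
                arm_lo, arm_hi = (ce, length) if rng.random() < 0.5 else (0, cs)
                span = rng.uniform(0.4, 0.9) * (arm_hi - arm_lo)
                start = int(rng.uniform(arm_lo, arm_hi - span))
                region = (start, int(start + span))
                if k.min_cn(chrom, region[0], region[1], homolog) < 1:
                    continue
                return EventSpec(
                    kind,
                    chrom,
                    homolog,
                    region,
                    {"n_fragments": int(rng.integers(8, 20)), "retention_p": 0.5, "seed": int(rng.integers(2**31))},
                )
            if kind == "bfb_amplification":
                width = int(rng.uniform(1e6, 3e6))
                start = int(rng.uniform(ce, length - width))
                if k.min_cn(chrom, start, start + width, homolog) < 1:
                    continue
                return EventSpec(kind, chrom, homolog, (start, start + width), {"rounds": int(rng.integers(3, 5))})
            if kind in ("focal_del", "focal_dup"):
                width = int(rng.uniform(0.5e6, 3e6))
                start = int(rng.uniform(1e6, length - width - 1e6))
                if kind == "focal_del" and k.min_cn(chrom, start, start + width, homolog) < 1:
                    continue
                return EventSpec(kind, chrom, homolog, (start, start + width), {})
        except ValueError:
            continue
    return None


def simulate_clone_tree(
    genome: GenomeModel,
    n_leaves: int,
    seed: int | None = None,
    event_menu: Mapping[str, float] | None = None,
    tp53_rules: bool = True,
    events_per_branch: float = 2.0,
    wgd_prob: float = 0.5,
    min_events_per_branch: int = 0,
    unique_targets: bool = False,
) -> TrueCloneTree:
    """Generate a random clone tree with mechanistic events on each branch.

    Branches before biallelic TP53 loss fixate only copy-neutral or focal
    events (UPD, focal deletions/duplications); all event kinds, including
    WGD at probability ``wgd_prob`` per branch, are allowed after p53 loss.
    With ``unique_targets`` every event lands on a (chromosome, homolog)
    slot untouched on its lineage, so ancestral breakpoints are never
    overwritten — the clean-marker regime for phylogeny studies.
    Deterministic given ``seed``.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    menu = dict(event_menu or DEFAULT_EVENT_MENU)

    # random topology: grow by splitting a random leaf until n_leaves reached
    root = TreeNode("root", None, karyotype=ParentalKaryotype.diploid(genome))
    nodes = {"root": root}
    counter = 0

    def new_name() -> str:
        nonlocal counter
        counter += 1
        return f"n{counter}"

    leaves = ["root"]
    while len(leaves) < n_leaves:
        parent = leaves.pop(int(rng.integers(len(leaves))))
        for _ in range(2):
            child = new_name()
            nodes[child] = TreeNode(child, parent)
            nodes[parent].children.append(child)
            leaves.append(child)

    # TP53 loss: root's first branch point marks the dysplastic lineage
    tree = TrueCloneTree("root", nodes)
    order = [n for n in _preorder(tree) if n != "root"]
    tp53_branch = order[0] if tp53_rules and order else None
    used_slots: dict[str, set[tuple[str, str]]] = {"root": set()}

    for name in order:
        nd = nodes[name]
        parent = nodes[nd.parent]
        nd.tp53_lost = parent.tp53_lost or (name == tp53_branch) or not tp53_rules
        k = parent.karyotype.copy()
        slots = set(used_slots[nd.parent])
        if name == tp53_branch:
            # biallelic TP53 inactivation: a point mutation plus loss of the
            # other allele through arm-scale LOH (copy-neutral or deletion),
            # truncal to every aneuploid descendant
            chrom = genome.chromosomes[-1]
            cs, ce = genome.centromeres[chrom]
            homolog = "A" if rng.random() < 0.5 else "B"
            if rng.random() < 0.5:
                spec = EventSpec("UPD", chrom, homolog, (0, cs), {})
            else:
                spec = EventSpec(
                    "bfb_terminal", chrom, homolog, (cs,), {"daughter": "loss"}
                )
            try:
                k = apply_event(k, spec, rng)
                nd.events.append(spec)
                slots.add((spec.chrom, spec.homolog))
            except ValueError:
                pass
        allowed = [
            kind
            for kind in menu
            if (nd.tp53_lost or kind in PRE_TP53_KINDS) and menu[kind] > 0
        ]
        n_events = max(int(rng.poisson(events_per_branch)), min_events_per_branch)
        if nd.tp53_lost and rng.random() < wgd_prob:
            nd.wgd_on_branch = True
        weights = np.array([menu[kind] for kind in allowed], dtype=float)
        weights /= weights.sum()
        kinds = [allowed[int(rng.choice(len(allowed), p=weights))] for _ in range(n_events)]
        if nd.wgd_on_branch:
            # WGD falls early enough on the branch that at least two drawn
            # events follow it: most observed SCNAs postdate duplication,
            # and the resulting odd copy states are what make WGD genomes
            # identifiable from coverage
            kinds.insert(int(rng.integers(0, max(n_events - 1, 1))), "WGD")
        wgd_seen = False
        post_wgd_single_copy = False
        for kind in kinds:
            if kind == "WGD":
                k = apply_wgd(k)
                nd.events.append(EventSpec("WGD"))
                wgd_seen = True
                continue
            spec = _draw_event(k, kind, rng, genome, slots if unique_targets else None)
            if spec is None:
                continue
            try:
                k_new = apply_event(k, spec, rng)
            except ValueError:
                continue
            if not _viable(k_new):
                continue  # large nullisomy is lethal; the event never fixates
            k = k_new
            nd.events.append(spec)
            slots.add((spec.chrom, spec.homolog))
            if kind == "UPD":
                slots.add((spec.chrom, "A"))
                slots.add((spec.chrom, "B"))
            elif wgd_seen:
                post_wgd_single_copy = True
        if wgd_seen and not post_wgd_single_copy:
            # the post-duplication burst of arm-level changes: at least one
            # single-copy event follows every WGD
            for _ in range(10):
                kind = "missegregation" if rng.random() < 0.5 else "bfb_terminal"
                spec = _draw_event(k, kind, rng, genome, slots if unique_targets else None)
                if spec is None:
                    continue
                try:
                    k_new = apply_event(k, spec, rng)
                except ValueError:
                    continue
                if not _viable(k_new):
                    continue
                k = k_new
                nd.events.append(spec)
                slots.add((spec.chrom, spec.homolog))
                break
        nd.karyotype = k
        used_slots[name] = slots
    return tree


def _preorder(tree: TrueCloneTree) -> list[str]:
    out: list[str] = []
    stack = [tree.root]
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(reversed(tree.nodes[n].children))
    return out


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------


@dataclass
class RenderConfig:
    """Observation-model parameters for rendering karyotypes into read data.

    ``mean_depth`` is the expected read count per bin in a copy-neutral
    diploid region. ``site_depth`` is the expected total allele count per
    het site and haploid copy (20x bulk FFPE WGS with ~100 bp reads gives
    roughly 10 reads per copy at a SNP). Switch errors follow a Poisson
    process along the chromosome at ``switch_rate`` per bp (default one per
    250 kb, the rate of statistical-phasing switch errors).
    """

    mean_depth: float = 500.0
    site_depth: float = 10.0
    purity: float = 0.7
    subclone_fractions: Mapping[str, float] | None = None
    depth_dispersion: float = 0.02  # NB: var = mu + disp * mu^2
    allelic_dispersion: float = 0.01  # beta-binomial intra-class correlation
    ffpe_sigma: float = 0.03  # per-bin log-normal multiplicative jitter
    bias_sigma: float = 0.15  # amplitude of the shared recurrent-bias profile
    gc_coef: float = 1.0  # strength of GC-dependent bias
    switch_rate: float = 1 / 250_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.purity <= 1.0):
            raise ValueError("purity must lie in [0, 1]")
        fr = dict(self.subclone_fractions or {})
        if any(f < 0 or f > 1 for f in fr.values()) or sum(fr.values()) > 1 + 1e-9:
            raise ValueError("subclone fractions must lie in [0,1] and sum to <= 1")


def simulate_bin_covariates(
    genome: GenomeModel, seed: int | None = None, bias_sigma: float = 0.15
) -> dict[str, dict[str, np.ndarray]]:
    """Per-bin GC content and a smooth patient-level recurrent-bias profile.

    The recurrent bias (FFPE library bias shared by all samples of a patient)
    is a smooth random function of position; panel normalization is expected
    to remove it. GC content is a smooth covariate in [0.35, 0.55].
    """
    rng = np.random.default_rng(seed)
    out: dict[str, dict[str, np.ndarray]] = {}
    for chrom in genome.chromosomes:
        n = genome.n_bins(chrom)
        gc = 0.45 + 0.05 * _smooth_noise(n, rng, scale=40)
        bias = bias_sigma * _smooth_noise(n, rng, scale=25)
        out[chrom] = {"gc": gc, "log_bias": bias}
    return out


def _smooth_noise(n: int, rng: np.random.Generator, scale: int = 25) -> np.ndarray:
    """Standardized smooth random function of bin index (Gaussian blur of noise)."""
    x = rng.standard_normal(n + 2 * scale)
    kernel = np.exp(-0.5 * (np.arange(-3 * scale, 3 * scale + 1) / scale) ** 2)
    kernel /= kernel.sum()
    y = np.convolve(x, kernel, mode="same")[scale : scale + n]
    sd = y.std()
    return (y - y.mean()) / (sd if sd > 0 else 1.0)


def draw_switch_points(length: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Positions of phasing switch errors: a homogeneous Poisson process."""
    n_switch = rng.poisson(rate * length) if rate > 0 else 0
    return np.sort(rng.uniform(0, length, size=n_switch))


def simulate_switch_parity(genome: GenomeModel, rate: float, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Per-het-site orientation parity (+1/-1) from a Poisson switch process.

    Two switch points falling between the same pair of het sites cancel, so
    the site-observable switch count is slightly below the process rate.
    """
    parity: dict[str, np.ndarray] = {}
    for chrom in genome.chromosomes:
        sites = genome.het_sites[chrom]
        points = draw_switch_points(genome.lengths[chrom], rate, rng)
        flips = np.searchsorted(points, sites)  # switches left of each site
        parity[chrom] = np.where(flips % 2 == 0, 1, -1).astype(np.int8)
    return parity


def _gc_bias(gc: np.ndarray, coef: float) -> np.ndarray:
    """Unimodal GC bias: coverage drops away from 0.45 GC (log scale)."""
    return -coef * (gc - 0.45) ** 2 * 40.0


def _mixture_cn(
    genome: GenomeModel,
    components: Sequence[tuple[ParentalKaryotype, float]],
) -> tuple[dict[str, tuple[np.ndarray, np.ndarray]], dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Purity-weighted fractional (cnA, cnB) per bin and per het site.

    ``components`` are (karyotype, fraction) pairs; the remaining fraction is
    normal diploid (1,1).
    """
    total_f = sum(f for _, f in components)
    bins: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    sites: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in genome.chromosomes:
        n = genome.n_bins(chrom)
        a_bin = np.full(n, 1.0 - total_f)
        b_bin = np.full(n, 1.0 - total_f)
        het = genome.het_sites[chrom]
        a_site = np.full(len(het), 1.0 - total_f)
        b_site = np.full(len(het), 1.0 - total_f)
        for k, f in components:
            ka, kb = k.cn_per_bin(chrom)
            a_bin += f * ka
            b_bin += f * kb
            sa, sb = k.cn_at_sites(chrom, het)
            a_site += f * sa
            b_site += f * sb
        bins[chrom] = (a_bin, b_bin)
        sites[chrom] = (a_site, b_site)
    return bins, sites


def _render_observation(
    genome: GenomeModel,
    components: Sequence[tuple[ParentalKaryotype, float]],
    cfg: RenderConfig,
    sample: str,
    rng: np.random.Generator,
    covariates: Mapping[str, Mapping[str, np.ndarray]] | None = None,
    switch_parity: Mapping[str, np.ndarray] | None = None,
) -> tuple[pd.DataFrame, AllelicDepthTable, dict[str, np.ndarray]]:
    """Core renderer shared by bulk, sloping-population, and mixture cases."""
    bins_cn, sites_cn = _mixture_cn(genome, components)
    depth_rows = []
    pos: dict[str, np.ndarray] = {}
    da: dict[str, np.ndarray] = {}
    db: dict[str, np.ndarray] = {}
    true_parity: dict[str, np.ndarray] = {}
    for chrom in genome.chromosomes:
        edges = genome.bin_edges(chrom)
        a_bin, b_bin = bins_cn[chrom]
        t_bin = a_bin + b_bin
        log_bias = np.zeros(len(t_bin))
        if covariates is not None:
            cov = covariates[chrom]
            log_bias = cov["log_bias"] + _gc_bias(cov["gc"], cfg.gc_coef)
        jitter = rng.normal(0, cfg.ffpe_sigma, size=len(t_bin)) if cfg.ffpe_sigma > 0 else 0.0
        mu = cfg.mean_depth * (t_bin / 2.0) * np.exp(log_bias + jitter)
        counts = _nbinom(mu, cfg.depth_dispersion, rng)
        depth_rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": edges[:-1].astype(np.int64),
                    "end": edges[1:].astype(np.int64),
                    "sample": sample,
                    "count": counts,
                }
            )
        )
        # allelic depths at het sites
        het = genome.het_sites[chrom]
        a_s, b_s = sites_cn[chrom]
        t_s = a_s + b_s
        n_reads = rng.poisson(cfg.site_depth * t_s)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac_a = np.where(t_s > 0, a_s / np.maximum(t_s, 1e-12), 0.5)
        a_depth = _betabinom(n_reads, frac_a, cfg.allelic_dispersion, rng)
        b_depth = n_reads - a_depth
        parity = (
            np.asarray(switch_parity[chrom])
            if switch_parity is not None
            else np.ones(len(het), dtype=np.int8)
        )
        # observed orientation: swapped where the phasing parity is -1
        obs_a = np.where(parity > 0, a_depth, b_depth)
        obs_b = np.where(parity > 0, b_depth, a_depth)
        pos[chrom] = het.copy()
        da[chrom] = obs_a.astype(np.int64)
        db[chrom] = obs_b.astype(np.int64)
        true_parity[chrom] = parity.copy()
    depth = pd.concat(depth_rows, ignore_index=True)
    table = AllelicDepthTable(
        samples=[sample],
        positions=pos,
        depth_a={c: v[:, None] for c, v in da.items()},
        depth_b={c: v[:, None] for c, v in db.items()},
    )
    return depth, table, true_parity


def _nbinom(mu: np.ndarray, disp: float, rng: np.random.Generator) -> np.ndarray:
    """Overdispersed counts, var = mu + disp * mu^2 (gamma-Poisson mixture)."""
    mu = np.maximum(mu, 1e-9)
    if disp <= 0:
        return rng.poisson(mu)
    shape = 1.0 / disp
    lam = rng.gamma(shape, mu / shape)
    return rng.poisson(lam)


def _betabinom(n: np.ndarray, p: np.ndarray, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Beta-binomial draws with mean p and intra-class correlation rho."""
    n = np.asarray(n)
    p = np.clip(np.asarray(p, dtype=float), 0.0, 1.0)
    if rho <= 0:
        return rng.binomial(n, p)
    conc = (1.0 - rho) / rho
    a = np.maximum(p * conc, 1e-9)
    b = np.maximum((1.0 - p) * conc, 1e-9)
    q = rng.beta(a, b)
    q[p <= 0] = 0.0
    q[p >= 1] = 1.0
    return rng.binomial(n, q)


def render_bulk(
    tree: TrueCloneTree,
    leaf: str,
    cfg: RenderConfig,
    genome: GenomeModel,
    covariates: Mapping[str, Mapping[str, np.ndarray]] | None = None,
    switch_parity: Mapping[str, np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, AllelicDepthTable, dict[str, np.ndarray]]:
    """Render one bulk sample: binned depth plus allelic depths at het sites.

    The sample is a mixture of the leaf clone (fraction = purity), optional
    subclones, and normal diploid cells. ``switch_parity`` is the
    statistical-phasing orientation process; pass the same mapping for all
    samples of a patient (phasing is done once per patient). Returns the
    binned-depth table, the allelic-depth table in the *observed* (possibly
    switch-errored) orientation, and the true parity used.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    components = [(tree.nodes[leaf].karyotype, cfg.purity)]
    for name, f in (cfg.subclone_fractions or {}).items():
        components.append((tree.nodes[name].karyotype, f))
    if switch_parity is None:
        switch_parity = simulate_switch_parity(genome, cfg.switch_rate, rng)
    return _render_observation(genome, components, cfg, leaf, rng, covariates, switch_parity)


def render_sloping_population(
    base: ParentalKaryotype,
    chrom: str,
    homolog: str,
    boundaries: Sequence[int],
    fractions: Sequence[float],
    cfg: RenderConfig,
    rng: np.random.Generator | None = None,
    covariates: Mapping[str, Mapping[str, np.ndarray]] | None = None,
    toward: str = "telomere",
) -> tuple[pd.DataFrame, AllelicDepthTable, dict[str, np.ndarray]]:
    """Render a population with progressive terminal erosion (sloping CN).

    Each subclone i carries a terminal loss on ``homolog`` distal of
    ``boundaries[i]`` (toward the q-telomere when ``toward='telomere'``,
    toward position 0 otherwise ordered from the q-side so erosion runs
    toward the centromere). Expected coverage on the eroded homolog declines
    monotonically toward the eroded end; the other homolog stays flat.
    """
    if len(boundaries) != len(fractions):
        raise ValueError("boundaries and fractions must have equal length")
    rng = rng or np.random.default_rng(cfg.seed)
    genome = base.genome
    length = genome.lengths[chrom]
    components: list[tuple[ParentalKaryotype, float]] = []
    for bp, f in zip(boundaries, fractions):
        sub = base.copy()
        if toward == "telomere":
            sub.add_cn(chrom, int(bp), length, homolog, -1)
        else:
            sub.add_cn(chrom, 0, int(bp), homolog, -1)
        components.append((sub.simplify(), f))
    remaining = cfg.purity - sum(fractions)
    if remaining > 1e-9:
        components.append((base, remaining))
    return _render_observation(genome, components, cfg, "sloping", rng, covariates, None)


def render_single_cell(
    karyotype: ParentalKaryotype,
    seed: int | None = None,
    mean_bin_count: float = 50.0,
    bin_width: int = 10_000,
    amp_noise: float = 0.3,
    site_depth: float = 0.2,
) -> tuple[pd.DataFrame, AllelicDepthTable]:
    """Render one ~1x single cell: sparse 10 kb counts and 0/1 allelic depths.

    Whole-genome-amplification noise is modeled as a smooth long-range
    multiplicative field (log-scale amplitude ``amp_noise``); per-site allelic
    depths are Poisson with mean ``site_depth`` per haploid copy, so most
    sites carry 0 or 1 reads.
    """
    rng = np.random.default_rng(seed)
    genome = karyotype.genome
    # sequencing depth per cell is fixed, so counts reflect copy-number
    # *ratios* only: a uniformly duplicated genome reads exactly like a
    # diploid one (the motivation for the half-integer WGD rule)
    mean_cn = karyotype.ploidy()
    depth_rows = []
    pos: dict[str, np.ndarray] = {}
    da: dict[str, np.ndarray] = {}
    db: dict[str, np.ndarray] = {}
    for chrom in genome.chromosomes:
        length = genome.lengths[chrom]
        edges = np.arange(0, length + bin_width, bin_width)
        edges[-1] = min(edges[-1], length)
        edges = np.unique(edges)
        n = len(edges) - 1
        # per-bin CN on the 10 kb grid
        a = np.zeros(n)
        b = np.zeros(n)
        for s in karyotype.segments[chrom]:
            lo = np.clip(s.start, edges[:-1], edges[1:])
            hi = np.clip(s.end, edges[:-1], edges[1:])
            w = np.maximum(hi - lo, 0) / np.diff(edges)
            a += w * s.cnA
            b += w * s.cnB
        wga = np.exp(amp_noise * _smooth_noise(n, rng, scale=100))
        mu = mean_bin_count * (a + b) / mean_cn * wga
        counts = rng.poisson(np.maximum(mu, 0))
        depth_rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": edges[:-1].astype(np.int64),
                    "end": edges[1:].astype(np.int64),
                    "sample": "cell",
                    "count": counts,
                }
            )
        )
        het = genome.het_sites[chrom]
        sa, sb = karyotype.cn_at_sites(chrom, het)
        a_depth = rng.poisson(site_depth * 2.0 / mean_cn * sa)
        b_depth = rng.poisson(site_depth * 2.0 / mean_cn * sb)
        pos[chrom] = het.copy()
        da[chrom] = a_depth.astype(np.int64)
        db[chrom] = b_depth.astype(np.int64)
    depth = pd.concat(depth_rows, ignore_index=True)
    table = AllelicDepthTable(
        samples=["cell"],
        positions=pos,
        depth_a={c: v[:, None] for c, v in da.items()},
        depth_b={c: v[:, None] for c, v in db.items()},
    )
    return depth, table
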