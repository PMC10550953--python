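"""Sample phylogenies from haplotype-specific SCNA breakpoints.

Breakpoints are used as lineage markers because they are unaltered by
downstream whole-chromosome or whole-genome duplication. Events shared by
two or more samples (all breakpoints matching within tolerance, same
direction of change) become binary characters; a greedy perfect-phylogeny
construction over the character incidence matrix yields the tree, with
conflicting characters resolved deterministically (drop the character
supported by fewer breakpoints) and always reported. WGD events are placed
on the most ancestral branches compatible with per-sample WGD status, and
each SCNA is timed against duplication from integer copy-number states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import ScnaEvent
from .genome import ParentalKaryotype

__all__ = [
    "BreakpointMatch",
    "CloneTree",
    "match_breakpoints",
    "classify_event_relation",
    "build_tree",
    "assign_wgd_to_branches",
    "time_scna_vs_wgd",
    "snv_similarity",
]

#: categories matched by identity of (category, homolog) rather than breakpoints
_POSITIONLESS = {"whole_chrom_gain", "whole_chrom_loss"}


@dataclass(frozen=True)
class BreakpointMatch:
    relation: str  # 'identical' | 'complementary' | 'distinct'
    distance: float  # max breakpoint distance (bp); inf when distinct by definition


def match_breakpoints(eA: ScnaEvent, eB: ScnaEvent, tol: int = 100_000) -> BreakpointMatch:
    """Relate two events' breakpoints within segmentation tolerance.

    Identical: every breakpoint within ``tol`` of its counterpart and the
    same direction of copy-number change. Complementary: within ``tol`` but
    opposite directions (reciprocal products of a single breakage).
    Different homologs or chromosomes are distinct by definition.
    """
    if eA.chrom != eB.chrom or eA.homolog != eB.homolog:
        return BreakpointMatch("distinct", float("inf"))
    if eA.category in _POSITIONLESS or eB.category in _POSITIONLESS:
        if eA.category == eB.category:
            return BreakpointMatch("identical", 0.0)
        return BreakpointMatch("distinct", float("inf"))
    if not eA.breakpoints or not eB.breakpoints or len(eA.breakpoints) != len(eB.breakpoints):
        return BreakpointMatch("distinct", float("inf"))
    dists = [abs(a - b) for a, b in zip(eA.breakpoints, eB.breakpoints)]
    d = max(dists)
    if d > tol:
        return BreakpointMatch("distinct", float(d))
    same_dir = np.sign(eA.copy_change) == np.sign(eB.copy_change)
    return BreakpointMatch("identical" if same_dir else "complementary", float(d))


def classify_event_relation(eA: ScnaEvent, eB: ScnaEvent, tol: int = 100_000) -> str:
    """'shared', 'branching' or 'unrelated' for two events on one homolog.

    Shared: all breakpoints identical pairwise. Branching: a proper subset
    of breakpoints identical, or a complementary (reciprocal-daughter)
    relationship. Unrelated: nothing matches.
    """
    m = match_breakpoints(eA, eB, tol)
    if m.relation == "identical":
        return "shared"
    if m.relation == "complementary":
        return "branching"
    if eA.chrom != eB.chrom or eA.homolog != eB.homolog:
        return "unrelated"
    # subset matching between unequal breakpoint lists
    matched = 0
    used: set[int] = set()
    for a in eA.breakpoints:
        for j, b in enumerate(eB.breakpoints):
            if j not in used and abs(a - b) <= tol:
                matched += 1
                used.add(j)
                break
    n = max(len(eA.breakpoints), len(eB.breakpoints))
    if matched and matched < n:
        return "branching"
    if matched and matched == n:
        return "shared"
    return "unrelated"


@dataclass
class InferredNode:
    name: str
    samples: frozenset
    parent: str | None = None
    children: list[str] = field(default_factory=list)
    events: list[ScnaEvent] = field(default_factory=list)
    wgd: bool = False
    branch_length: int = 0
    timing: str = "NA"  # branch timing relative to WGD: pre/concurrent/post/NA


@dataclass
class CloneTree:
    """Inferred phylogeny: germline root, internal clades, sample leaves."""

    root: str
    nodes: dict[str, InferredNode]
    conflicts: list[dict] = field(default_factory=list)
    unplaced: list[str] = field(default_factory=list)

    @property
    def leaves(self) -> list[str]:
        return [n for n, nd in self.nodes.items() if not nd.children]

    def clades(self) -> set[frozenset]:
        """Leaf-sample sets of all internal nodes below the root (for topology comparison)."""
        out = set()
        for name, nd in self.nodes.items():
            if nd.children and name != self.root:
                out.add(nd.samples)
        return out

    def newick(self) -> str:
        def rec(n: str) -> str:
            nd = self.nodes[n]
            label = f"{n}:{max(nd.branch_length, 0)}"
            if not nd.children:
                return label
            return "(" + ",".join(rec(c) for c in nd.children) + ")" + label

        return rec(self.root) + ";"

    def to_sidecar(self) -> dict:
        return {
            "root": self.root,
            "nodes": {
                n: {
                    "samples": sorted(nd.samples),
                    "parent": nd.parent,
                    "children": nd.children,
                    "wgd": nd.wgd,
                    "branch_length": nd.branch_length,
                    "timing": nd.timing,
                    "n_events": len(nd.events),
                }
                for n, nd in self.nodes.items()
            },
            "conflicts": self.conflicts,
            "unplaced": self.unplaced,
        }


def _cluster_characters(
    events_by_sample: Mapping[str, Sequence[ScnaEvent]], tol: int
) -> list[dict]:
    """Cluster per-sample events into shared-marker characters (union-find)."""
    flat: list[tuple[str, ScnaEvent]] = [
        (s, e) for s, evs in events_by_sample.items() for e in evs
    ]
    parent = list(range(len(flat)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    by_key: dict[tuple, list[int]] = {}
    for idx, (s, e) in enumerate(flat):
        by_key.setdefault((e.chrom, e.homolog), []).append(idx)
    for idxs in by_key.values():
        for ii, i in enumerate(idxs):
            for j in idxs[ii + 1 :]:
                si, ei = flat[i]
                sj, ej = flat[j]
                if si == sj:
                    continue
                if classify_event_relation(ei, ej, tol) == "shared":
                    union(i, j)
    clusters: dict[int, list[int]] = {}
    for i in range(len(flat)):
        clusters.setdefault(find(i), []).append(i)
    out = []
    for members in clusters.values():
        samples = frozenset(flat[i][0] for i in members)
        events = [flat[i][1] for i in members]
        n_bp = sum(len(e.breakpoints) for e in events) or len(events)
        out.append({"samples": samples, "events": events, "support": n_bp})
    return out


def build_tree(
    samples: Sequence[str],
    events_by_sample: Mapping[str, Sequence[ScnaEvent]],
    tol: int = 100_000,
) -> CloneTree:
    """Greedy perfect phylogeny over shared-breakpoint characters.

    Characters present in two or more samples are accepted in decreasing
    order of breakpoint support when compatible (nested or disjoint) with
    the already-accepted family; a character conflicting with a
    better-supported one is dropped and logged, never silently. Branch
    length counts the distinct altered chromosomes assigned to the branch;
    private events go to terminal branches. The root is the germline
    (all-zero character) state.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    chars = _cluster_characters(events_by_sample, tol)
    shared = [c for c in chars if len(c["samples"]) >= 2]
    shared.sort(key=lambda c: (-c["support"], sorted(c["samples"])))

    accepted: list[dict] = []
    conflicts: list[dict] = []
    family: dict[frozenset, list[dict]] = {}
    all_set = frozenset(samples)
    for c in shared:
        s = c["samples"]
        ok = True
        for other in family:
            if not (s <= other or other <= s or not (s & other)):
                ok = False
                conflicts.append(
                    {
                        "samples": sorted(s),
                        "conflicts_with": sorted(other),
                        "support": c["support"],
                        "n_events": len(c["events"]),
                    }
                )
                break
        if ok:
            family.setdefault(s, []).append(c)
            accepted.append(c)

    # laminar family -> tree
    sets = sorted(set(family) | {all_set}, key=lambda s: (-len(s), sorted(s)))
    nodes: dict[str, InferredNode] = {"germline": InferredNode("germline", all_set)}
    name_of: dict[frozenset, str] = {}
    for i, s in enumerate(sets):
        name = f"anc{i}" if len(s) > 1 else next(iter(s))
        name_of[s] = name
        nodes[name] = InferredNode(name, s)
    for s in sorted(samples):
        single = frozenset([s])
        if single not in name_of:
            name_of[single] = s
            nodes[s] = InferredNode(s, single)

    for s in name_of:
        candidates = [o for o in name_of if s < o]
        parent_set = min(candidates, key=len) if candidates else None
        parent = name_of[parent_set] if parent_set else "germline"
        child = name_of[s]
        nodes[child].parent = parent
        nodes[parent].children.append(child)

    tree = CloneTree("germline", nodes, conflicts)

    # assign character events to the branch into their clade node
    for s, cs in family.items():
        node = nodes[name_of[s]]
        for c in cs:
            # one representative event per marker (they are 'shared' copies)
            node.events.append(c["events"][0])
    # private (single-sample) events on terminal branches
    for c in chars:
        if len(c["samples"]) == 1:
            (sample,) = c["samples"]
            nodes[sample].events.extend(c["events"])
    for nd in tree.nodes.values():
        nd.branch_length = len({e.chrom for e in nd.events})
    return tree


def assign_wgd_to_branches(tree: CloneTree, wgd_flags: Mapping[str, bool]) -> CloneTree:
    """Place WGD events on the most ancestral branches compatible with flags.

    Each maximal clade whose samples are all WGD-positive receives one WGD
    on its incoming branch; disjoint WGD clades get independent events. A
    WGD-flag pattern that is not a union of clades yields multiple
    placements, which is reported rather than hidden. Branch timing labels
    (pre / concurrent / post WGD) are set relative to the placements.
    """
    wgd_samples = {s for s, f in wgd_flags.items() if f}
    placements: list[str] = []
    for name, nd in tree.nodes.items():
        if name == tree.root:
            continue
        if nd.samples and nd.samples <= wgd_samples:
            parent = tree.nodes[nd.parent]
            parent_all_wgd = nd.parent != tree.root and parent.samples <= wgd_samples
            if not parent_all_wgd:
                placements.append(name)
    for name in placements:
        tree.nodes[name].wgd = True

    def downstream_of_wgd(name: str) -> bool:
        p = tree.nodes[name].parent
        while p is not None:
            if tree.nodes[p].wgd:
                return True
            p = tree.nodes[p].parent
        return False

    for name, nd in tree.nodes.items():
        if name == tree.root:
            continue
        if nd.wgd:
            nd.timing = "concurrent"
        elif downstream_of_wgd(name):
            nd.timing = "post"
        elif nd.samples & wgd_samples:
            # some descendant lineage later acquires WGD
            nd.timing = "pre"
        else:
            nd.timing = "NA"
    return tree


def time_scna_vs_wgd(
    event: ScnaEvent,
    karyotype: ParentalKaryotype,
    wgd_on_lineage: bool,
) -> str:
    """Time one SCNA relative to duplication from integer copy states.

    Segmental changes of two or more copies across a changepoint predate
    the duplication (the single-copy change was doubled with the genome);
    single-copy differences postdate it. Whole-chromosome or arm states in
    WGD samples follow the parity rules: a final copy number of 1 means the
    chromosome was duplicated and then lost (post-WGD loss); an odd state
    of 3 or more means duplication to the nearest even state followed by a
    single-copy gain or loss (post-WGD adjustment); even deviations from 2
    predate the duplication. Returns 'NA' without WGD on the lineage.
    """
    if not wgd_on_lineage:
        return "NA"
    chrom = event.chrom
    if event.category in ("whole_chrom_gain", "whole_chrom_loss", "arm_gain", "arm_loss"):
        if event.span is None:
            return "NA"
        lo, hi = event.span
        mid = (lo + hi) // 2
        cn = karyotype.cn_at(chrom, mid, event.homolog)
        if cn == 1:
            return "post-WGD"
        if cn % 2 == 1:
            return "post-WGD"
        return "pre-WGD" if cn != 2 else "NA"
    if not event.breakpoints:
        return "NA"
    bp = event.breakpoints[0]
    eps = 1
    left = karyotype.cn_at(chrom, max(bp - eps, 0), event.homolog)
    right = karyotype.cn_at(chrom, min(bp, karyotype.genome.lengths[chrom] - 1), event.homolog)
    delta = abs(right - left)
    if delta >= 2:
        return "pre-WGD"
    if delta == 1:
        return "post-WGD"
    return "NA"


def snv_similarity(support: pd.DataFrame, min_support: int = 3) -> pd.DataFrame:
    """Pairwise somatic-SNV similarity between samples.

    ``support`` holds variant-supporting read counts (variants x samples);
    a variant is present in a sample when supported by at least
    ``min_support`` reads. The similarity of A against B is
    ``|shared| / |A|`` — asymmetric, so both normalizations are reported in
    the matrix (row = denominator sample). Samples without any variant get
    similarity 0.
    """
    present = support.to_numpy() >= min_support
    samples = list(support.columns)
    n = len(samples)
    out = np.zeros((n, n))
    counts = present.sum(axis=0)
    for i in range(n):
        for j in range(n):
            if counts[i] == 0:
                out[i, j] = 0.0
            else:
                out[i, j] = np.sum(present[:, i] & present[:, j]) / counts[i]
    return pd.DataFrame(out, index=samples, columns=samples)
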