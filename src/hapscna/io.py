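"""Plain-text readers/writers for the pipeline's working formats.

Binned depth and allelic depths travel as TSV; ground truth, purity/ploidy
and tree sidecars as JSON; trees as Newick; flip regions and sloping calls
as BED; rearrangements as BEDPE. All coordinates are 0-based half-open.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import RearrangementCandidate, ScnaEvent, SlopingCall
from .genome import GenomeModel, ParentalKaryotype
from .phasing import AllelicDepthTable

__all__ = [
    "save_genome",
    "load_genome",
    "save_depth",
    "load_depth",
    "save_allelic",
    "load_allelic",
    "save_karyotypes",
    "load_karyotypes",
    "events_to_frame",
    "frame_to_events",
    "save_flips_bed",
    "save_sloping_bed",
    "save_bedpe",
    "load_bedpe",
]


def save_genome(genome: GenomeModel, path: str | Path) -> None:
    d = {
        "lengths": dict(genome.lengths),
        "centromeres": {c: list(v) for c, v in genome.centromeres.items()},
        "het_sites": {c: np.asarray(v).tolist() for c, v in genome.het_sites.items()},
        "bin_width": genome.bin_width,
    }
    Path(path).write_text(json.dumps(d))


def load_genome(path: str | Path) -> GenomeModel:
    d = json.loads(Path(path).read_text())
    return GenomeModel(
        d["lengths"],
        {c: tuple(v) for c, v in d["centromeres"].items()},
        {c: np.asarray(v, dtype=np.int64) for c, v in d["het_sites"].items()},
        d["bin_width"],
    )


def save_depth(depth: pd.DataFrame, path: str | Path) -> None:
    depth.to_csv(path, sep="\t", index=False)


def load_depth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_allelic(table: AllelicDepthTable, path: str | Path) -> None:
    """Long-format TSV: chrom, pos, phase, then a_<sample> / b_<sample> columns."""
    frames = []
    for chrom in table.chromosomes:
        df = pd.DataFrame({"chrom": chrom, "pos": table.positions[chrom], "phase": table.phase[chrom]})
        for j, s in enumerate(table.samples):
            df[f"a_{s}"] = table.depth_a[chrom][:, j]
            df[f"b_{s}"] = table.depth_b[chrom][:, j]
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def load_allelic(path: str | Path) -> AllelicDepthTable:
    df = pd.read_csv(path, sep="\t")
    samples = [c[2:] for c in df.columns if c.startswith("a_")]
    positions, da, db, phase = {}, {}, {}, {}
    for chrom, sub in df.groupby("chrom", sort=False):
        positions[chrom] = sub["pos"].to_numpy(np.int64)
        phase[chrom] = sub["phase"].to_numpy(np.int8)
        da[chrom] = sub[[f"a_{s}" for s in samples]].to_numpy(np.int64)
        db[chrom] = sub[[f"b_{s}" for s in samples]].to_numpy(np.int64)
    return AllelicDepthTable(samples, positions, da, db, phase)


def save_karyotypes(karyotypes: Mapping[str, ParentalKaryotype], path: str | Path) -> None:
    Path(path).write_text(json.dumps({name: k.to_dict() for name, k in karyotypes.items()}))


def load_karyotypes(genome: GenomeModel, path: str | Path) -> dict[str, ParentalKaryotype]:
    d = json.loads(Path(path).read_text())
    return {name: ParentalKaryotype.from_dict(genome, v) for name, v in d.items()}


def events_to_frame(events: Sequence[ScnaEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": e.sample,
                "chrom": e.chrom,
                "homolog": e.homolog,
                "category": e.category,
                "breakpoints": ",".join(map(str, e.breakpoints)),
                "copy_change": e.copy_change,
                "footprint": e.footprint,
                "complexity": e.complexity,
                "span_start": e.span[0] if e.span else -1,
                "span_end": e.span[1] if e.span else -1,
            }
            for e in events
        ]
    )


def frame_to_events(df: pd.DataFrame) -> list[ScnaEvent]:
    out = []
    for r in df.itertuples():
        bps = tuple(int(x) for x in str(r.breakpoints).split(",") if x not in ("", "nan"))
        span = (int(r.span_start), int(r.span_end)) if r.span_start >= 0 else None
        out.append(
            ScnaEvent(r.sample, r.chrom, r.homolog, r.category, bps, int(r.copy_change), r.footprint, r.complexity, span)
        )
    return out


def save_flips_bed(flips: Sequence[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, lo, hi in flips:
            fh.write(f"{chrom}\t{lo}\t{hi}\tflip\n")


def save_sloping_bed(calls: Sequence[SlopingCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\tsloping_{c.homolog}_{c.direction}\t{c.attenuation:.3f}\n"
            )


def save_bedpe(cands: Sequence[RearrangementCandidate], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in cands:
            fh.write(
                f"{c.chrom1}\t{c.pos1}\t{c.pos1 + 1}\t{c.chrom2}\t{c.pos2}\t{c.pos2 + 1}"
                f"\t.\t{c.support}\t{c.strand1}\t{c.strand2}\n"
            )


def load_bedpe(path: str | Path) -> list[RearrangementCandidate]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        out.append(RearrangementCandidate(f[0], int(f[1]), f[8], f[3], int(f[4]), f[9], int(f[7])))
    return out
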