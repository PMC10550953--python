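"""Shared fixtures: small genomes and pre-rendered observations.

Session-scoped fixtures cache expensive renders so independent tests can
reuse them; everything is seeded and deterministic.
"""

import numpy as np
import pandas as pd
import pytest

from hapscna import (
    ParentalKaryotype,
    RenderConfig,
    apply_missegregation,
    apply_upd,
    default_genome,
    simulate_genome,
)
import hapscna.simulate as sim
from hapscna.phasing import AllelicDepthTable


@pytest.fixture(scope="session")
def genome():
    """The default 4-chromosome test genome (150/120/90/60 Mb)."""
    return default_genome(seed=1)


@pytest.fixture(scope="session")
def small_genome():
    """Two short chromosomes for cheap rendering tests."""
    return simulate_genome({"chr1": 80_000_000, "chr2": 60_000_000}, seed=5)


@pytest.fixture(scope="session")
def diploid(genome):
    return ParentalKaryotype.diploid(genome)


@pytest.fixture(scope="session")
def loh_patient(genome):
    """Three bulk samples of one patient sharing a (2,0) chromosome 1,
    rendered with one shared switch-error process; returns
    (merged allelic table, true parity, karyotype)."""
    k20 = apply_upd(ParentalKaryotype.diploid(genome), "chr1", (0, genome.lengths["chr1"]), "A")
    rng = np.random.default_rng(77)
    parity = sim.simulate_switch_parity(genome, 1 / 250_000, rng)
    cfg = RenderConfig(purity=0.7, mean_depth=500, site_depth=8)
    tables = []
    for i in range(3):
        _, t, _ = sim._render_observation(genome, [(k20, 0.7)], cfg, f"s{i}", rng, None, parity)
        tables.append(t)
    return AllelicDepthTable.merge(tables), parity, k20


@pytest.fixture(scope="session")
def cell_collection(small_genome):
    """12 aneuploid (chr1 homolog-A loss) and 20 diploid ~1x cells with a
    shared switch-error process injected; returns (table, parity)."""
    diploid = ParentalKaryotype.diploid(small_genome)
    aneu = apply_missegregation(diploid, "chr1", "A", -1)
    cells = []
    for i in range(12):
        _, t = sim.render_single_cell(aneu, seed=100 + i, site_depth=0.3)
        t.samples = [f"aneu{i}"]
        cells.append(t)
    for i in range(20):
        _, t = sim.render_single_cell(diploid, seed=200 + i, site_depth=0.3)
        t.samples = [f"dip{i}"]
        cells.append(t)
    merged = AllelicDepthTable.merge(cells)
    rng = np.random.default_rng(9)
    parity = sim.simulate_switch_parity(small_genome, 1 / 250_000, rng)
    for c in small_genome.chromosomes:
        swap = parity[c] < 0
        a = merged.depth_a[c][swap].copy()
        merged.depth_a[c][swap] = merged.depth_b[c][swap]
        merged.depth_b[c][swap] = a
    return merged, parity
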