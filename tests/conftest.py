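"""Shared fixtures: toy panels and the session-scoped simulation grids.

The two grid fixtures are expensive (minutes); they are computed once per
session and shared by the acceptance-style tests.
"""

import numpy as np
import pytest

from finemapsim.panel import (HaplotypePanel, PanelModelParams, VariantRecord,
                              synthesize_panel)
from finemapsim.pipeline import GridConfig, run_grid


def make_panel(hap, positions=None, population="toy", coding=None,
               region_length=None, ids=None):
    """Build a HaplotypePanel straight from a 0/1 matrix (tests only)."""
    hap = np.asarray(hap, dtype=np.uint8)
    h, m = hap.shape
    if positions is None:
        positions = list(range(100, 100 * (m + 1), 100))
    if region_length is None:
        region_length = int(max(positions)) + 100
    freqs = hap.mean(axis=0)
    variants = [
        VariantRecord(
            id=(ids[j] if ids else f"t{j:03d}"), position=int(positions[j]),
            ref="A", alt="G", ancestral_freq=float(freqs[j]),
            alt_freq=float(freqs[j]),
            is_coding=bool(coding[j]) if coding is not None else False)
        for j in range(m)
    ]
    return HaplotypePanel(population=population, variants=variants,
                          haplotypes=hap, region_length=region_length)


@pytest.fixture(scope="session")
def panel600():
    """A 1 Mb panel at ~600 common variants per Mb, 200 haplotypes."""
    return synthesize_panel(PanelModelParams(seed=11, target_density=600.0),
                            1_000_000)


@pytest.fixture(scope="session")
def panel3000():
    """A 1 Mb panel at the default common-variant density."""
    return synthesize_panel(PanelModelParams(seed=12), 1_000_000)


# ----------------------------------------------------------------------
# shared simulation grids (used by the acceptance-style tests)
# ----------------------------------------------------------------------

GOLD_GRID_REPLICATES = 60
GWAS_GRID_REPLICATES = 16


@pytest.fixture(scope="session")
def gold_grid():
    """Gold-standard scenario grid: RAF x OR, full-sequence cohorts."""
    cfg = GridConfig(
        replicates=GOLD_GRID_REPLICATES,
        raf_levels=(0.05, 0.10, 0.20, 0.50), or_levels=(1.1, 1.2, 1.5),
        scenarios=("gold",), panel_density=600.0, seed=2101)
    summary, outcomes = run_grid(cfg)
    return cfg, summary, outcomes


@pytest.fixture(scope="session")
def gwas_grid():
    """Array-downsampled scenario grid with imputation and QC."""
    cfg = GridConfig(
        replicates=GWAS_GRID_REPLICATES,
        raf_levels=(0.05, 0.10, 0.20, 0.50), or_levels=(1.1, 1.2, 1.5),
        scenarios=("gwas",), panel_density=600.0, seed=2102)
    summary, outcomes = run_grid(cfg)
    return cfg, summary, outcomes
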