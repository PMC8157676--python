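"""Shared fixtures: synthetic panels reused across the suite.

Session scope keeps the expensive objects (panels, kinship spectra) built
once; every stochastic fixture is seeded so the suite is reproducible.
"""

import numpy as np
import pytest

from windowgwas import data_io, emmax, simulate, windows

HET_PANEL_SEED = 1  # default heterogeneous desk-scale panel


def mc_se(x, n_batches=20):
    """Batch-means Monte-Carlo standard error (robust to autocorrelation)."""
    x = np.asarray(x, dtype=float)
    n = (x.shape[0] // n_batches) * n_batches
    b = x[:n].reshape(n_batches, -1, *x.shape[1:]).mean(axis=1)
    return b.std(axis=0, ddof=1) / np.sqrt(n_batches)


@pytest.fixture(scope="session")
def het_panel():
    """Default heterogeneous-density panel: n=300, ~4k SNPs, 2 hotspot stretches."""
    cfg = simulate.GenoSimConfig(seed=HET_PANEL_SEED)
    G, mm = simulate.simulate_genotypes(cfg)
    return G


@pytest.fixture(scope="session")
def het_windows(het_panel):
    ws = windows.build_windows_bp(het_panel.map, 1_000_000)
    dense = windows.detect_dense_windows(ws)
    return ws, dense


@pytest.fixture(scope="session")
def small_panel():
    """Smaller homogeneous-leaning panel for calibration studies (n=250)."""
    cfg = simulate.GenoSimConfig(
        n_individuals=250, n_chromosomes=2, chrom_length_bp=10_000_000,
        snps_per_mb=75.0, hotspots=[], seed=11,
    )
    G, _ = simulate.simulate_genotypes(cfg)
    return G


@pytest.fixture(scope="session")
def small_windows(small_panel):
    return windows.build_windows_bp(small_panel.map, 1_000_000)


def toy_genotypes(rng, n, p, sample_prefix="s", chrom="chr1"):
    """Small random dosage panel with a valid map (no LD structure)."""
    f = rng.uniform(0.1, 0.5, size=p)
    dosages = rng.binomial(2, f, size=(n, p)).astype(float)
    mm = data_io.MarkerMap(
        np.array([f"m{j}" for j in range(p)], dtype=object),
        np.array([chrom] * p, dtype=object),
        np.arange(1, p + 1) * 1000,
    )
    ids = np.array([f"{sample_prefix}{i}" for i in range(n)], dtype=object)
    return data_io.GenotypeMatrix(dosages, ids, mm)
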