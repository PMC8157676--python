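"""Synthetic genotype panels with heterogeneous SNP density, and phenotypes.

The generator emulates the structure of a diversity-panel SNP chip: a few
hundred individuals, markers spread over a handful of chromosomes at a
baseline density, plus localized "hotspot" stretches genotyped several-fold
more densely, so that per-window SNP counts have a long right tail and
dense windows exist by construction.

Marker positions follow a piecewise-constant intensity (baseline, with
fold-multiplied hotspot segments).  Each individual carries two independent
haplotypes; the allele at marker j on a haplotype is the indicator
``Z_j > Phi^{-1}(1 - f_j)`` where Z is a Gaussian process with
``corr(Z_j, Z_{j+1}) = ld_rho * exp(-dist / ld_decay_bp)`` and the allele
frequency ``f_j`` is uniform on ``maf_range``.  Thresholding a correlated
Gaussian gives adjacent-marker linkage disequilibrium with one
interpretable decay parameter.  Dosage is the haplotype sum; columns whose
realized MAF falls below the configured minimum are dropped.

Phenotypes follow the additive QTL model: a configurable number of QTL are
drawn uniformly from the genotyped SNPs (optionally restricted to
non-dense windows), effects are i.i.d. standard normal, and the residual
variance is set from the *realized* genetic variance so the target
heritability holds on the simulated sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import GenotypeMatrix, MarkerMap, PhenotypeVector
from .windows import WindowSet

__all__ = [
    "GenoSimConfig",
    "PhenoSimConfig",
    "SimTruth",
    "simulate_genotypes",
    "simulate_phenotypes",
    "permute_phenotypes",
]


@dataclass
class GenoSimConfig:
    """Panel layout and LD parameters.

    ``hotspots`` is a list of ``(count, fold, width_bp)`` groups: ``count``
    segments of ``width_bp`` whose marker intensity is ``fold`` times the
    baseline, placed uniformly at random without overlap.
    """

    n_individuals: int = 300
    n_chromosomes: int = 4
    chrom_length_bp: int = 10_000_000
    snps_per_mb: float = 75.0
    hotspots: list = field(default_factory=lambda: [(2, 8.0, 1_000_000)])
    ld_rho: float = 0.9
    ld_decay_bp: float = 100_000.0
    maf_range: tuple = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be within (0, 0.5]")
        for count, fold, width in self.hotspots:
            if fold <= 1.0:
                raise ValueError("hotspot fold must exceed 1")
            if width > self.chrom_length_bp:
                raise ValueError("hotspot width exceeds chromosome length")


@dataclass
class PhenoSimConfig:
    n_qtl: int = 10
    h2: float = 0.5
    exclude_dense: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_qtl < 1:
            raise ValueError("n_qtl must be at least 1")
        if not 0.0 < self.h2 <= 1.0:
            raise ValueError("h2 must lie in (0, 1]")


@dataclass
class SimTruth:
    """Ground truth for ROC evaluation against a window set."""

    qtl_marker_indices: np.ndarray
    qtl_effects: np.ndarray
    window_labels: np.ndarray  # per-window bool: contains >= 1 QTL
    realized_h2: float

    def labels_for(self, ws: WindowSet) -> np.ndarray:
        """Recompute positive labels on a different window partition."""
        m2w = ws.marker_to_window()
        labels = np.zeros(ws.n_windows, dtype=bool)
        labels[m2w[self.qtl_marker_indices]] = True
        return labels


def _place_hotspots(cfg: GenoSimConfig, rng: np.random.Generator):
    """Non-overlapping hotspot segments: list of (chrom_idx, start, end, fold)."""
    placed: list = []
    for count, fold, width in cfg.hotspots:
        for _ in range(count):
            for _attempt in range(1000):
                c = int(rng.integers(cfg.n_chromosomes))
                start = int(rng.integers(0, cfg.chrom_length_bp - width + 1))
                end = start + width
                if all(
                    not (c == pc and start < pe and ps < end)
                    for pc, ps, pe, _f in placed
                ):
                    placed.append((c, start, end, fold))
                    break
            else:
                raise ValueError("could not place hotspots without overlap")
    return placed


def _segment_positions(rng, lo, hi, rate):
    """Poisson-count uniform positions on the 1-based interval (lo, hi]."""
    count = rng.poisson(rate * (hi - lo))
    if count == 0:
        return np.empty(0, dtype=np.int64)
    pos = np.unique(rng.integers(lo + 1, hi + 1, size=count))
    return pos.astype(np.int64)


def simulate_genotypes(cfg: GenoSimConfig) -> tuple[GenotypeMatrix, MarkerMap]:
    """Generate a dosage panel; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    base_rate = cfg.snps_per_mb / 1e6
    hotspots = _place_hotspots(cfg, rng)
    n = cfg.n_individuals

    all_dos, ids, chroms, positions = [], [], [], []
    for c in range(cfg.n_chromosomes):
        # piecewise-constant intensity: split the chromosome at hotspot edges
        edges = sorted({0, cfg.chrom_length_bp}
                       | {s for hc, s, e, f in hotspots if hc == c}
                       | {e for hc, s, e, f in hotspots if hc == c})
        pos_parts = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            fold = next(
                (f for hc, s, e, f in hotspots if hc == c and s <= lo and hi <= e),
                1.0,
            )
            pos_parts.append(_segment_positions(rng, lo, hi, base_rate * fold))
        pos = np.sort(np.concatenate(pos_parts))
        pos = np.unique(pos)
        p_c = len(pos)
        if p_c == 0:
            continue
        f = rng.uniform(*cfg.maf_range, size=p_c)
        tau = stats.norm.ppf(1.0 - f)
        # AR-style Gaussian copula along the chromosome, 2n haplotypes at once
        Z = np.empty((2 * n, p_c))
        Z[:, 0] = rng.standard_normal(2 * n)
        if p_c > 1:
            d = np.diff(pos).astype(float)
            rho = cfg.ld_rho * np.exp(-d / cfg.ld_decay_bp)
            innov = rng.standard_normal((2 * n, p_c - 1))
            for j in range(1, p_c):
                r = rho[j - 1]
                Z[:, j] = r * Z[:, j - 1] + np.sqrt(1.0 - r * r) * innov[:, j - 1]
        alleles = (Z > tau).astype(np.int8)
        dos = alleles[:n] + alleles[n:]
        all_dos.append(dos)
        chroms.extend([f"chr{c + 1}"] * p_c)
        positions.append(pos)
        ids.extend(f"chr{c + 1}_{p}" for p in pos)

    dosages = np.concatenate(all_dos, axis=1).astype(np.float64)
    mm = MarkerMap(np.array(ids, dtype=object), np.array(chroms, dtype=object),
                   np.concatenate(positions))
    sample_ids = np.array([f"ind{i + 1:04d}" for i in range(n)], dtype=object)
    G = GenotypeMatrix(dosages, sample_ids, mm)
    # drop columns whose realized MAF fell below the configured minimum
    freq = G.allele_freqs()
    maf = np.minimum(freq, 1.0 - freq)
    keep = np.flatnonzero(maf >= cfg.maf_range[0])
    G = GenotypeMatrix(G.dosages[:, keep], sample_ids, mm.subset(keep))
    return G, G.map


def simulate_phenotypes(
    G: GenotypeMatrix,
    ws: WindowSet,
    dense_ids: set,
    cfg: PhenoSimConfig,
) -> tuple[PhenotypeVector, SimTruth]:
    """Additive QTL phenotypes on a fixed panel; deterministic given seed.

    Residual variance is ``Var_pop(g) * (1 - h2) / h2`` with ``Var_pop`` the
    population variance of the realized genetic values, so ``realized_h2``
    concentrates near the target without being exactly equal.
    """
    rng = np.random.default_rng(cfg.seed)
    m2w = ws.marker_to_window()
    if cfg.exclude_dense and dense_ids:
        dense_ord = {k for k, w in enumerate(ws.windows) if w.window_id in dense_ids}
        eligible = np.flatnonzero(~np.isin(m2w, list(dense_ord)))
    else:
        eligible = np.arange(G.n_markers)
    if len(eligible) < cfg.n_qtl:
        raise ValueError(
            f"only {len(eligible)} eligible SNPs for {cfg.n_qtl} QTL"
        )
    qtl = np.sort(rng.choice(eligible, size=cfg.n_qtl, replace=False))
    effects = rng.standard_normal(cfg.n_qtl)
    g = G.dosages[:, qtl] @ effects
    var_g = float(np.var(g))
    if cfg.h2 >= 1.0:
        e = np.zeros_like(g)
    else:
        var_e = var_g * (1.0 - cfg.h2) / cfg.h2
        e = rng.standard_normal(len(g)) * np.sqrt(var_e)
    y = g + e
    var_y = float(np.var(y))
    labels = np.zeros(ws.n_windows, dtype=bool)
    labels[m2w[qtl]] = True
    truth = SimTruth(
        qtl_marker_indices=qtl,
        qtl_effects=effects,
        window_labels=labels,
        realized_h2=var_g / var_y if var_y > 0 else 1.0,
    )
    return PhenotypeVector(G.sample_ids, y), truth


def permute_phenotypes(y: PhenotypeVector, seed: int) -> PhenotypeVector:
    """Shuffle trait values against the fixed sample order (null diagnostic)."""
    if len(y) < 2:
        raise ValueError("need at least two phenotypes to permute")
    rng = np.random.default_rng(seed)
    return PhenotypeVector(y.sample_ids, rng.permutation(y.values))


def write_truth(truth: SimTruth, G: GenotypeMatrix, ws: WindowSet,
                qtl_path, window_path) -> None:
    """Serialize ground truth: (marker_id, effect) and per-window labels."""
    pd.DataFrame(
        {
            "marker_id": G.map.marker_id[truth.qtl_marker_indices],
            "effect": truth.qtl_effects,
        }
    ).to_csv(qtl_path, sep="\t", index=False)
    pd.DataFrame(
        {"window_id": ws.ids, "label": truth.window_labels.astype(int)}
    ).to_csv(window_path, sep="\t", index=False)
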