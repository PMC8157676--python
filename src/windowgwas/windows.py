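"""Genomic windows, per-window variance proportions, and WPPA.

A window set partitions the markers into non-overlapping groups, either by
physical span (every marker with position ``pos`` on a chromosome falls in
the 1-based half-open bin ``floor((pos-1)/size_bp)``; empty bins are not
counted) or by fixed SNP count (consecutive runs of ``k`` markers that never
span a chromosome; a short trailing window is kept and flagged).

For each stored MCMC draw the genotypic value of window w is
``g_w = M_w alpha_w``; its variance ``sigma2_gw`` is the population variance
(divide by n) and ``q_w = sigma2_gw / sigma2_g`` is the share of the total
genetic variance the window explains.  WPPA is the fraction of draws in
which ``q_w`` strictly exceeds a threshold T.  Three threshold schemes are
supported: a constant (e.g. 0.1%), ``1/N`` with N the number of windows,
and the window-specific ``T_w = p_w / p`` that neutralises SNP-density
differences between windows.

Windows whose SNP count exceeds Q3 + 1.5 IQR of the per-window count
distribution (linear-interpolation quantiles) are flagged as dense.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayescpi import PosteriorDraws
from .data_io import GenotypeMatrix, MarkerMap

__all__ = [
    "Window",
    "WindowSet",
    "ThresholdScheme",
    "WindowPosterior",
    "build_windows_bp",
    "build_windows_count",
    "genetic_variance",
    "window_q_samples",
    "resolve_thresholds",
    "compute_wppa",
    "dense_cutoff",
    "detect_dense_windows",
    "results_table",
]


@dataclass
class Window:
    window_id: str
    chromosome: str
    start: int  # bp, inclusive
    end: int    # bp, inclusive
    indices: np.ndarray  # marker column indices, ascending
    partial: bool = False  # count-scheme trailing window shorter than k

    @property
    def size(self) -> int:
        """Number of SNPs in the window (p_w)."""
        return len(self.indices)


@dataclass
class WindowSet:
    windows: list
    scheme_tag: str  # "bp" | "count"
    p: int  # total marker count

    def __post_init__(self) -> None:
        seen = np.concatenate([w.indices for w in self.windows]) if self.windows else np.empty(0, int)
        if len(seen) != self.p or len(np.unique(seen)) != self.p:
            raise ValueError("windows must cover every marker exactly once")
        if any(w.size < 1 for w in self.windows):
            raise ValueError("every window must contain at least one marker")

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def counts(self) -> np.ndarray:
        """Per-window SNP counts p_w."""
        return np.array([w.size for w in self.windows], dtype=np.int64)

    @property
    def ids(self) -> list:
        return [w.window_id for w in self.windows]

    def marker_to_window(self) -> np.ndarray:
        """Array mapping marker column index -> window ordinal."""
        out = np.empty(self.p, dtype=np.int64)
        for k, w in enumerate(self.windows):
            out[w.indices] = k
        return out


@dataclass
class ThresholdScheme:
    """Resolved per-window exceedance thresholds for WPPA."""

    kind: str  # "constant" | "one_over_N" | "per_window"
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any((self.values <= 0) | (self.values >= 1)):
            raise ValueError("thresholds must lie strictly inside (0, 1)")


@dataclass
class WindowPosterior:
    """Per-window q_w sample paths and summaries from one chain."""

    q_samples: np.ndarray  # (n_windows, n_stored)
    q_mean: np.ndarray     # (n_windows,)
    sigma2_g: np.ndarray   # (n_stored,) total genetic variance per draw

    @property
    def n_stored(self) -> int:
        return self.q_samples.shape[1]


def build_windows_bp(mm: MarkerMap, size_bp: int) -> WindowSet:
    """Partition markers into non-overlapping physical windows of ``size_bp``.

    Window k on a chromosome spans 1-based positions
    ``[k*size_bp + 1, (k+1)*size_bp]``; a marker exactly at a boundary
    belongs to the lower window.  Bins containing no marker are omitted, so
    ``N`` counts only testable windows.
    """
    if size_bp <= 0:
        raise ValueError("size_bp must be positive")
    windows = []
    bins = (mm.position - 1) // size_bp
    for chrom in mm.chromosomes:
        on_chrom = np.flatnonzero(mm.chromosome == chrom)
        for b in np.unique(bins[on_chrom]):
            idx = on_chrom[bins[on_chrom] == b]
            start = int(b) * size_bp + 1
            end = (int(b) + 1) * size_bp
            windows.append(
                Window(f"{chrom}:{start}-{end}", chrom, start, end, idx)
            )
    return WindowSet(windows, "bp", len(mm))


def build_windows_count(mm: MarkerMap, k: int) -> WindowSet:
    """Partition markers into consecutive runs of ``k`` SNPs per chromosome.

    Windows never span chromosomes; a trailing run shorter than ``k`` is
    kept and marked ``partial``.
    """
    if k <= 0:
        raise ValueError("window SNP count k must be positive")
    windows = []
    for chrom in mm.chromosomes:
        on_chrom = np.flatnonzero(mm.chromosome == chrom)
        for s in range(0, len(on_chrom), k):
            idx = on_chrom[s : s + k]
            start = int(mm.position[idx[0]])
            end = int(mm.position[idx[-1]])
            windows.append(
                Window(
                    f"{chrom}:{start}-{end}", chrom, start, end, idx,
                    partial=len(idx) < k,
                )
            )
    return WindowSet(windows, "count", len(mm))


def genetic_variance(g: np.ndarray) -> float:
    """Population variance of a genotypic-value vector: mean(g^2) - mean(g)^2."""
    g = np.asarray(g, dtype=np.float64)
    if g.size == 0:
        raise ValueError("empty genotypic-value vector")
    return float(np.mean(g * g) - np.mean(g) ** 2)


def window_q_samples(G: GenotypeMatrix, draws: PosteriorDraws, ws: WindowSet) -> WindowPosterior:
    """Per-draw window variance shares q_w = sigma2_gw / sigma2_g.

    For a draw with zero total genetic variance every q_w is set to 0 (the
    window explains nothing when nothing is explained), keeping sample
    counts equal across windows.
    """
    if draws.n_stored == 0:
        raise ValueError("no stored draws")
    if draws.n_markers != ws.p or G.n_markers != ws.p:
        raise ValueError("draws, genotypes and window set disagree on marker count")
    Mc = G.dosages - G.dosages.mean(axis=0)  # variance is shift-invariant
    A = draws.alpha.T  # (p, S)
    g_all = Mc @ A  # (n, S)
    s2g = g_all.var(axis=0)  # population variance
    q = np.empty((ws.n_windows, draws.n_stored))
    for k, w in enumerate(ws.windows):
        gw = Mc[:, w.indices] @ A[w.indices]
        q[k] = gw.var(axis=0)
    nz = s2g > 0
    q[:, nz] /= s2g[nz]
    q[:, ~nz] = 0.0
    return WindowPosterior(q_samples=q, q_mean=q.mean(axis=1), sigma2_g=s2g)


def resolve_thresholds(kind: str, ws: WindowSet, constant_value: float | None = None) -> ThresholdScheme:
    """Resolve a threshold scheme to per-window T values.

    ``constant`` uses ``constant_value`` everywhere; ``one_over_N`` uses 1/N
    with N the (non-empty) window count; ``per_window`` uses T_w = p_w / p,
    which sums to 1 over windows.
    """
    N = ws.n_windows
    if kind == "constant":
        if constant_value is None or not 0.0 < constant_value < 1.0:
            raise ValueError("constant threshold must lie in (0, 1)")
        vals = np.full(N, float(constant_value))
    elif kind == "one_over_N":
        vals = np.full(N, 1.0 / N)
    elif kind == "per_window":
        vals = ws.counts / ws.p
    else:
        raise ValueError(f"unknown threshold scheme {kind!r}")
    return ThresholdScheme(kind, vals)


def compute_wppa(q_samples: np.ndarray, T: float) -> float:
    """Fraction of q_w samples strictly exceeding T (ties do not count)."""
    q_samples = np.asarray(q_samples, dtype=np.float64)
    if q_samples.size == 0:
        raise ValueError("empty q_w sample vector")
    return float(np.mean(q_samples > T))


def wppa_per_window(wp: WindowPosterior, scheme: ThresholdScheme) -> np.ndarray:
    """Vector of WPPA values, one per window, under a resolved scheme."""
    if len(scheme.values) != wp.q_samples.shape[0]:
        raise ValueError("threshold scheme and window posterior sizes differ")
    return np.array(
        [compute_wppa(wp.q_samples[k], t) for k, t in enumerate(scheme.values)]
    )


def dense_cutoff(counts: np.ndarray) -> float:
    """Tukey upper fence Q3 + 1.5 (Q3 - Q1) on per-window SNP counts.

    Quantiles use the linear-interpolation convention (numpy default).
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.size < 4:
        raise ValueError("need at least 4 windows to estimate quartiles")
    q1, q3 = np.quantile(counts, [0.25, 0.75])
    return float(q3 + 1.5 * (q3 - q1))


def detect_dense_windows(ws: WindowSet) -> set:
    """Window ids whose SNP count strictly exceeds the Tukey upper fence."""
    cutoff = dense_cutoff(ws.counts)
    return {w.window_id for w in ws.windows if w.size > cutoff}


def results_table(
    ws: WindowSet,
    wp: WindowPosterior,
    scheme: ThresholdScheme,
    dense_ids: set | None = None,
) -> pd.DataFrame:
    """Per-window GWAS results: the Manhattan-plot input table."""
    dense_ids = detect_dense_windows(ws) if dense_ids is None else dense_ids
    wppa = wppa_per_window(wp, scheme)
    return pd.DataFrame(
        {
            "window_id": ws.ids,
            "chromosome": [w.chromosome for w in ws.windows],
            "start": [w.start for w in ws.windows],
            "end": [w.end for w in ws.windows],
            "p_w": ws.counts,
            "q_mean": wp.q_mean,
            "T": scheme.values,
            "WPPA": wppa,
            "dense_flag": [w.window_id in dense_ids for w in ws.windows],
        }
    )
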