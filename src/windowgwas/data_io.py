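"""Genotype/phenotype input-output, sample alignment, and the MAF filter.

Genotypes are additive allele dosages coded 0/1/2 on ``n`` individuals by
``p`` biallelic markers.  Two dialects are accepted:

* delimited text — a dosage matrix (CSV/TSV; header row of marker ids,
  first column ``sample_id``), a 3-column marker map
  (``marker_id  chromosome  position``) and a 2-column phenotype table
  (``sample_id  value``);
* PLINK bed/bim/fam — dosages counted on the A1 allele of the .bim file.

Map positions are 1-based base pairs.  Allele frequency for a column is
``f = sum(dosages) / (2n)`` and MAF is ``min(f, 1 - f)``; markers with MAF
exactly equal to the threshold are retained.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "AlignmentError",
    "MarkerMap",
    "GenotypeMatrix",
    "PhenotypeVector",
    "LoadReport",
    "load_dataset",
    "filter_maf",
    "write_delimited",
    "write_plink",
    "read_plink",
]


class FormatError(ValueError):
    """A file does not parse under the declared dialect."""


class AlignmentError(ValueError):
    """Genotype and phenotype tables share no samples."""


@dataclass
class MarkerMap:
    """Marker identifiers with genomic coordinates, ordered along the genome.

    Invariants (checked on construction): each chromosome occupies one
    contiguous block, positions are strictly increasing within a chromosome,
    and marker ids are unique.
    """

    marker_id: np.ndarray
    chromosome: np.ndarray
    position: np.ndarray

    def __post_init__(self) -> None:
        self.marker_id = np.asarray(self.marker_id, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.position = np.asarray(self.position, dtype=np.int64)
        if not (len(self.marker_id) == len(self.chromosome) == len(self.position)):
            raise ValueError("map columns have unequal lengths")
        if len(np.unique(self.marker_id)) != len(self.marker_id):
            raise ValueError("marker ids are not unique")
        if np.any(self.position < 1):
            raise ValueError("positions must be positive 1-based coordinates")
        # contiguous chromosome blocks, strictly increasing positions within
        seen: set = set()
        prev_chrom = None
        prev_pos = -1
        for c, pos in zip(self.chromosome, self.position):
            if c != prev_chrom:
                if c in seen:
                    raise ValueError(f"chromosome {c!r} is not contiguous in the map")
                seen.add(c)
                prev_chrom = c
                prev_pos = pos
            else:
                if pos <= prev_pos:
                    raise ValueError(
                        f"positions not strictly increasing on chromosome {c!r}"
                    )
                prev_pos = pos

    def __len__(self) -> int:
        return len(self.marker_id)

    def subset(self, idx: np.ndarray) -> "MarkerMap":
        """Return the map restricted to (ordered) marker indices ``idx``."""
        return MarkerMap(self.marker_id[idx], self.chromosome[idx], self.position[idx])

    @property
    def chromosomes(self) -> list:
        """Chromosome labels in order of first appearance."""
        out, seen = [], set()
        for c in self.chromosome:
            if c not in seen:
                seen.add(c)
                out.append(c)
        return out


@dataclass
class GenotypeMatrix:
    """An ``n x p`` dosage matrix tied to a :class:`MarkerMap`."""

    dosages: np.ndarray
    sample_ids: np.ndarray
    map: MarkerMap

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D matrix")
        if self.dosages.shape[0] != len(self.sample_ids):
            raise ValueError("row count does not match sample ids")
        if self.dosages.shape[1] != len(self.map):
            raise ValueError("column count does not match marker map length")
        if len(np.unique(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids are not unique")
        finite = self.dosages[np.isfinite(self.dosages)]
        if not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing dosages must be coded 0/1/2")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def allele_freqs(self) -> np.ndarray:
        """Per-column allele frequency f = column sum / (2n); requires no missing."""
        if np.isnan(self.dosages).any():
            raise ValueError("allele frequencies require complete dosages")
        return self.dosages.sum(axis=0) / (2.0 * self.n_samples)


@dataclass
class PhenotypeVector:
    """A single quantitative trait aligned to genotyped samples."""

    sample_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.sample_ids) != len(self.values):
            raise ValueError("sample ids and values differ in length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("phenotype values must be finite")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class LoadReport:
    """Bookkeeping from :func:`load_dataset`."""

    n_samples: int
    n_markers: int
    n_dropped_missing_phenotype: int = 0
    n_dropped_no_genotype: int = 0
    n_imputed_dosages: int = 0


def _sep_for(path: str | os.PathLike) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def _read_genotype_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path), dtype={0: str})
    if df.shape[1] < 2 or df.columns[0] not in ("sample_id", "id", "IID"):
        raise FormatError(
            f"{path}: expected first column 'sample_id' then marker columns"
        )
    df = df.set_index(df.columns[0])
    mat = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=np.float64)
    raw_na = df.isna().to_numpy()
    bad = ~np.isnan(mat) & ~np.isin(mat, (0.0, 1.0, 2.0))
    bad |= np.isnan(mat) & ~raw_na  # non-numeric garbage
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise FormatError(
            f"{path}: line {r + 2}: invalid dosage {df.iat[r, c]!r} "
            f"for marker {df.columns[c]!r} (expect 0/1/2 or missing)"
        )
    return pd.DataFrame(mat, index=df.index, columns=df.columns)


def _read_map(path) -> MarkerMap:
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chromosome": str})
    need = {"marker_id", "chromosome", "position"}
    if not need.issubset(df.columns):
        raise FormatError(f"{path}: map needs columns {sorted(need)}")
    try:
        return MarkerMap(df["marker_id"], df["chromosome"], df["position"])
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def _read_phenotype(path) -> pd.Series:
    df = pd.read_csv(path, sep=_sep_for(path), dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError(f"{path}: phenotype table needs (sample_id, value) columns")
    vals = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    return pd.Series(vals.to_numpy(), index=df.iloc[:, 0].to_numpy())


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam (SNP-major .bed; dosage counts the A1 allele of the .bim)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit codes, SNP-major: 00 hom A1 (dosage 2), 01 missing, 10 het, 11 hom A2
_BED_DECODE = np.array([2.0, np.nan, 1.0, 0.0])


def read_plink(prefix: str | os.PathLike) -> tuple[pd.DataFrame, MarkerMap]:
    """Read a PLINK bed/bim/fam triple given its shared path prefix.

    Returns the dosage table (samples x markers, NaN for missing) and the map.
    """
    prefix = str(prefix)
    if prefix.endswith(".bed"):
        prefix = prefix[:-4]
    bim = pd.read_csv(
        prefix + ".bim",
        sep=r"\s+",
        header=None,
        names=["chrom", "marker_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "marker_id": str},
    )
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None, dtype=str)
    sample_ids = fam.iloc[:, 1].to_numpy()
    n, p = len(sample_ids), len(bim)
    raw = np.fromfile(prefix + ".bed", dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise FormatError(f"{prefix}.bed: bad magic bytes (not SNP-major PLINK bed)")
    bpm = (n + 3) // 4  # bytes per marker
    body = raw[3:]
    if len(body) != bpm * p:
        raise FormatError(f"{prefix}.bed: size inconsistent with {n} samples x {p} markers")
    blocks = body.reshape(p, bpm)
    codes = np.empty((p, bpm * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (blocks >> (2 * k)) & 0b11
    mat = _BED_DECODE[codes[:, :n]].T  # (n, p)
    mm = MarkerMap(bim["marker_id"], bim["chrom"], bim["pos"])
    return pd.DataFrame(mat, index=sample_ids, columns=mm.marker_id), mm


def write_plink(G: GenotypeMatrix, prefix: str | os.PathLike) -> None:
    """Write a bed/bim/fam triple (test fixtures; A1 is the counted allele)."""
    prefix = str(prefix)
    n, p = G.dosages.shape
    with open(prefix + ".bim", "w") as fh:
        for mid, chrom, pos in zip(G.map.marker_id, G.map.chromosome, G.map.position):
            fh.write(f"{chrom}\t{mid}\t0\t{pos}\tA\tB\n")
    with open(prefix + ".fam", "w") as fh:
        for sid in G.sample_ids:
            fh.write(f"{sid} {sid} 0 0 0 -9\n")
    encode = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}
    bpm = (n + 3) // 4
    out = np.zeros((p, bpm), dtype=np.uint8)
    for j in range(p):
        for i in range(n):
            d = G.dosages[i, j]
            code = 0b01 if np.isnan(d) else encode[d]
            out[j, i // 4] |= code << (2 * (i % 4))
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(out.tobytes())


# ---------------------------------------------------------------------------


def write_delimited(
    G: GenotypeMatrix,
    y: PhenotypeVector | None,
    genotype_path,
    map_path,
    phenotype_path=None,
) -> None:
    """Write the delimited fixture dialect consumed by :func:`load_dataset`."""
    geno = pd.DataFrame(G.dosages, columns=G.map.marker_id)
    # integral dosages render without a decimal point so round trips are exact
    if not np.isnan(G.dosages).any():
        geno = geno.astype(np.int64)
    geno.insert(0, "sample_id", G.sample_ids)
    geno.to_csv(genotype_path, sep=_sep_for(genotype_path), index=False)
    pd.DataFrame(
        {
            "marker_id": G.map.marker_id,
            "chromosome": G.map.chromosome,
            "position": G.map.position,
        }
    ).to_csv(map_path, sep="\t", index=False)
    if y is not None and phenotype_path is not None:
        pd.DataFrame({"sample_id": y.sample_ids, "value": y.values}).to_csv(
            phenotype_path, sep="\t", index=False
        )


def load_dataset(
    genotype_path,
    map_path,
    phenotype_path,
    format: str = "delimited",
) -> tuple[GenotypeMatrix, PhenotypeVector, LoadReport]:
    """Load, align and complete a genotype/phenotype dataset.

    Samples present in both tables are kept in genotype order; samples with a
    missing phenotype are dropped; remaining missing dosages are imputed with
    the column mean rounded to the nearest integer dosage (ties to even,
    numpy rounding).  The report records how many of each happened.

    ``format`` is ``"delimited"`` or ``"plink"`` (then ``genotype_path`` is
    the bed prefix, ``map_path`` is ignored, and the phenotype is still the
    2-column table).
    """
    if format == "delimited":
        geno = _read_genotype_table(genotype_path)
        mm = _read_map(map_path)
        if list(geno.columns) != list(mm.marker_id):
            raise FormatError(
                f"{genotype_path}: marker columns do not match the map"
            )
    elif format == "plink":
        geno, mm = read_plink(genotype_path)
    else:
        raise ValueError(f"unknown format {format!r}")

    pheno = _read_phenotype(phenotype_path)
    geno_ids = list(geno.index)
    pheno_ids = set(pheno.index)
    shared = [s for s in geno_ids if s in pheno_ids]
    if not shared:
        raise AlignmentError("no overlapping samples between genotypes and phenotypes")

    n_no_geno = len(pheno_ids - set(geno_ids))
    pheno = pheno.loc[shared]
    keep = [s for s in shared if np.isfinite(pheno[s])]
    n_dropped = len(shared) - len(keep)
    if not keep:
        raise AlignmentError("all overlapping samples have missing phenotypes")

    mat = geno.loc[keep].to_numpy(dtype=np.float64)
    missing = np.isnan(mat)
    n_imputed = int(missing.sum())
    if n_imputed:
        with np.errstate(invalid="ignore"):
            col_means = np.nanmean(mat, axis=0)
        if np.isnan(col_means).any():
            j = int(np.argwhere(np.isnan(col_means))[0])
            raise FormatError(f"marker {mm.marker_id[j]!r} is missing in every sample")
        fill = np.rint(col_means)
        mat[missing] = np.broadcast_to(fill, mat.shape)[missing]

    G = GenotypeMatrix(mat, np.asarray(keep, dtype=object), mm)
    y = PhenotypeVector(np.asarray(keep, dtype=object), pheno.loc[keep].to_numpy())
    report = LoadReport(
        n_samples=G.n_samples,
        n_markers=G.n_markers,
        n_dropped_missing_phenotype=n_dropped,
        n_dropped_no_genotype=n_no_geno,
        n_imputed_dosages=n_imputed,
    )
    return G, y, report


def filter_maf(G: GenotypeMatrix, min_maf: float) -> GenotypeMatrix:
    """Drop markers with minor allele frequency below ``min_maf``.

    MAF = min(f, 1-f) with f the dosage-sum allele frequency.  Ties at
    exactly ``min_maf`` are retained.  Column order is preserved.
    """
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError(f"min_maf must lie in [0, 0.5], got {min_maf}")
    if np.isnan(G.dosages).any():
        raise ValueError("filter_maf requires complete dosages (impute first)")
    f = G.allele_freqs()
    maf = np.minimum(f, 1.0 - f)
    keep = np.flatnonzero(maf >= min_maf)
    return GenotypeMatrix(G.dosages[:, keep], G.sample_ids, G.map.subset(keep))
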