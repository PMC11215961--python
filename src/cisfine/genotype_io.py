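"""Genotype and expression I/O.

Reads genotype panels from PLINK 1.9 bed/bim/fam filesets or VCF, expression
matrices from TSV or GTEx-style expression BED, and gene->TSS maps from TSV.
Dosages count ALT alleles (0, 1, 2); missing calls are mean-imputed per
variant so downstream penalized regressions see a dense matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt"]

#: PLINK bed magic bytes (v1.00, SNP-major).
_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit bed codes -> ALT-allele dosage, with A1 = ALT:
# 00 hom A1 -> 2, 01 missing -> nan, 10 het -> 1, 11 hom A2 -> 0
_BED_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def _ext(prefix, ext):
    """PLINK member path; avoids Path.with_suffix mangling dotted prefixes."""
    return Path(str(prefix) + "." + ext)


class GenotypeFormatError(ValueError):
    """A genotype fileset is malformed or internally inconsistent."""


class EmptyPanelError(ValueError):
    """A filtering step removed every variant."""


@dataclass
class GenotypePanel:
    """Samples x variants ALT-allele dosage matrix with variant metadata.

    ``dosages`` is float64 with entries in [0, 2] after imputation.
    ``variants`` is a DataFrame with columns variant_id, chrom, pos (1-based),
    ref, alt; variant_ids must be unique.
    """

    dosages: np.ndarray
    sample_ids: list[str]
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.ndim != 2:
            raise GenotypeFormatError("dosages must be 2-D (samples x variants)")
        n, p = self.dosages.shape
        if len(self.sample_ids) != n:
            raise GenotypeFormatError(
                f"{len(self.sample_ids)} sample ids for {n} dosage rows"
            )
        if len(self.variants) != p:
            raise GenotypeFormatError(
                f"{len(self.variants)} variant records for {p} dosage columns"
            )
        ids = self.variants["variant_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise GenotypeFormatError(f"duplicate variant_id {dup!r}")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def maf(self) -> np.ndarray:
        """Minor-allele frequency per variant, independent of REF/ALT orientation."""
        f = self.dosages.sum(axis=0) / (2.0 * self.n_samples)
        return np.minimum(f, 1.0 - f)

    def subset_variants(self, indices: np.ndarray) -> "GenotypePanel":
        indices = np.asarray(indices, dtype=int)
        return GenotypePanel(
            dosages=self.dosages[:, indices].copy(),
            sample_ids=list(self.sample_ids),
            variants=self.variants.iloc[indices].reset_index(drop=True),
        )


@dataclass
class CisRegion:
    """Indices of a gene's cis-window variants within a :class:`GenotypePanel`."""

    gene_id: str
    chrom: str
    tss: int
    window_bp: int
    variant_indices: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    @property
    def n_variants(self) -> int:
        return len(self.variant_indices)


def _impute_mean(dosages: np.ndarray) -> np.ndarray:
    """Replace missing calls (NaN) by the per-variant mean of observed dosages."""
    missing = np.isnan(dosages)
    if not missing.any():
        return dosages
    with np.errstate(invalid="ignore"):
        col_mean = np.nanmean(dosages, axis=0)
    col_mean = np.nan_to_num(col_mean, nan=0.0)  # all-missing column -> 0
    idx = np.nonzero(missing)
    dosages[idx] = col_mean[idx[1]]
    return dosages


def read_plink(prefix: str | Path) -> GenotypePanel:
    """Read a PLINK 1.9 bed/bim/fam fileset into a :class:`GenotypePanel`.

    Dosages count A1 alleles, which this package writes (and expects) as ALT.
    Missing genotypes are imputed to the per-variant mean dosage. Sample order
    follows the .fam file, variant order the .bim file.
    """
    prefix = Path(prefix)
    fam = pd.read_csv(_ext(prefix, "fam"), sep=r"\s+", header=None, dtype=str)
    sample_ids = fam[1].tolist()
    bim = pd.read_csv(_ext(prefix, "bim"), sep=r"\s+", header=None, dtype=str)
    variants = pd.DataFrame(
        {
            "variant_id": bim[1],
            "chrom": bim[0],
            "pos": bim[3].astype(int),
            "ref": bim[5],  # A2
            "alt": bim[4],  # A1
        }
    )
    n, p = len(sample_ids), len(variants)
    raw = _ext(prefix, "bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise GenotypeFormatError(f"{prefix}.bed lacks the PLINK v1 SNP-major magic")
    bytes_per_variant = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != p * bytes_per_variant:
        raise GenotypeFormatError(
            f"{prefix}.bed has {body.size} data bytes, expected "
            f"{p * bytes_per_variant} for {n} samples x {p} variants"
        )
    packed = body.reshape(p, bytes_per_variant)
    codes = np.empty((p, bytes_per_variant * 4), dtype=np.uint8)
    for k, shift in enumerate((0, 2, 4, 6)):
        codes[:, k::4] = (packed >> shift) & 0b11
    dosages = _BED_CODE_TO_DOSAGE[codes[:, :n]].T.copy()
    n_missing = int(np.isnan(dosages).sum())
    if n_missing:
        logger.info("imputed %d missing genotype calls to column means", n_missing)
    return GenotypePanel(_impute_mean(dosages), sample_ids, variants)


def write_plink(panel: GenotypePanel, prefix: str | Path) -> None:
    """Write a panel as a PLINK 1.9 fileset with A1 = ALT (complete calls only)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    rounded = np.rint(panel.dosages)
    if np.isnan(panel.dosages).any() or not np.isin(rounded, (0, 1, 2)).all():
        raise GenotypeFormatError("write_plink requires complete hard calls in {0,1,2}")
    n, p = panel.dosages.shape
    with _ext(prefix, "fam").open("w") as fh:
        for sid in panel.sample_ids:
            fh.write(f"{sid} {sid} 0 0 0 -9\n")
    with _ext(prefix, "bim").open("w") as fh:
        for rec in panel.variants.itertuples(index=False):
            fh.write(f"{rec.chrom} {rec.variant_id} 0 {rec.pos} {rec.alt} {rec.ref}\n")
    # dosage -> 2-bit code (inverse of _BED_CODE_TO_DOSAGE)
    code_of = np.array([0b11, 0b10, 0b00], dtype=np.uint8)
    codes = code_of[rounded.astype(int).T]  # (p, n)
    bytes_per_variant = (n + 3) // 4
    padded = np.full((p, bytes_per_variant * 4), 0b11, dtype=np.uint8)  # pad hom A2
    padded[:, :n] = codes
    packed = np.zeros((p, bytes_per_variant), dtype=np.uint8)
    for k, shift in enumerate((0, 2, 4, 6)):
        packed |= padded[:, k::4] << shift
    with _ext(prefix, "bed").open("wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_vcf(path: str | Path) -> GenotypePanel:
    """Read a VCF/BCF into a :class:`GenotypePanel`.

    Per-sample DS (dosage) is preferred over GT when present, clipped to
    [0, 2]. Multiallelic records are skipped with a logged count; missing
    calls are mean-imputed.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    columns: list[np.ndarray] = []
    records: list[tuple] = []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        ds = None
        try:
            ds = v.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=np.float64).reshape(-1)[: len(sample_ids)]
            col = np.where(np.isfinite(col), np.clip(col, 0.0, 2.0), np.nan)
        else:
            # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
            gt_map = np.array([0.0, 1.0, np.nan, 2.0])
            col = gt_map[np.asarray(v.gt_types, dtype=int)]
        columns.append(col)
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}:{v.REF}:{v.ALT[0]}"
        records.append((vid, str(v.CHROM), int(v.POS), v.REF, v.ALT[0]))
    vcf.close()
    if n_multi:
        logger.info("skipped %d multiallelic records in %s", n_multi, path)
    if not records:
        raise EmptyPanelError(f"no biallelic records in {path}")
    dosages = np.column_stack(columns)
    variants = pd.DataFrame(records, columns=VARIANT_COLUMNS)
    return GenotypePanel(_impute_mean(dosages), sample_ids, variants)


def filter_variants(panel: GenotypePanel, min_maf: float = 0.01) -> GenotypePanel:
    """Drop variants with MAF below ``min_maf``; monomorphic variants always go.

    ``min_maf=0`` mimics pipelines that apply no frequency filter (monomorphic
    variants are still removed — they carry no information for regression).
    """
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError(f"min_maf must be in [0, 0.5], got {min_maf}")
    maf = panel.maf
    keep = (maf > 0.0) & (maf >= min_maf)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info(
            "filter_variants removed %d of %d variants (min_maf=%g)",
            n_removed,
            panel.n_variants,
            min_maf,
        )
    if not keep.any():
        raise EmptyPanelError(f"no variants with MAF >= {min_maf}")
    return panel.subset_variants(np.flatnonzero(keep))


def cis_variants(
    panel: GenotypePanel,
    gene_id: str,
    chrom: str,
    tss: int,
    window_bp: int = 1_000_000,
) -> CisRegion:
    """Variants within the closed interval [tss - window_bp, tss + window_bp]
    on the gene's chromosome. An empty window yields an empty region; the
    caller decides whether to skip the gene."""
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    pos = panel.variants["pos"].to_numpy()
    same_chrom = panel.variants["chrom"].astype(str).to_numpy() == str(chrom)
    in_window = np.abs(pos - int(tss)) <= window_bp
    idx = np.flatnonzero(same_chrom & in_window)
    return CisRegion(gene_id=gene_id, chrom=str(chrom), tss=int(tss), window_bp=int(window_bp), variant_indices=idx)


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Expression TSV: first column sample_id, one column per gene.

    Returns a samples x genes DataFrame indexed by sample_id.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    return df.set_index(df.columns[0])


def write_expression_tsv(expression: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        if header:
            fh.write(header if header.endswith("\n") else header + "\n")
        expression.rename_axis("sample_id").reset_index().to_csv(fh, sep="\t", index=False)


def read_expression_bed(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """GTEx-style expression BED: chrom, start, end, gene_id, then one column
    per sample. Returns (samples x genes expression, gene map with columns
    gene_id, chrom, tss) where tss = start + 1 (BED is 0-based)."""
    df = pd.read_csv(path, sep="\t")
    chrom_col, start_col, _end_col, gene_col = df.columns[:4]
    gene_map = pd.DataFrame(
        {
            "gene_id": df[gene_col].astype(str),
            "chrom": df[chrom_col].astype(str).str.replace("^#", "", regex=True),
            "tss": df[start_col].astype(int) + 1,
        }
    )
    expr = df.iloc[:, 4:].T
    expr.columns = gene_map["gene_id"]
    expr.index.name = "sample_id"
    return expr.astype(float), gene_map


def read_gene_map(path: str | Path) -> pd.DataFrame:
    """Gene map TSV with columns gene_id, chrom, tss (1-based)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "tss"}
    if not required.issubset(df.columns):
        raise GenotypeFormatError(f"gene map must have columns {sorted(required)}")
    df["tss"] = df["tss"].astype(int)
    return df
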