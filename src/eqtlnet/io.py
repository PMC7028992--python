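"""Readers and writers for the pipeline's external file formats.

Genotypes arrive either as a VCF (GT field only) or as a dosage TSV
(samples x SNPs, additive 0/1/2 coding, ``NA`` for missing).  Everything
else is plain TSV: expression matrices, gene annotation (TSV or BED),
covariates, GWAS-catalog-like labels, LD-block assignments and GMT gene
sets.  All internal coordinates are 1-based; BED input is converted from
0-based half-open on read.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class GenotypeMatrix:
    """Additive-coded genotypes plus per-SNP metadata.

    ``dosages`` is samples x SNPs with values in {0, 1, 2, NaN}; ``snps``
    is indexed by SNP id with columns ``chrom``, ``pos``, ``maf``,
    ``call_rate``.  MAF is computed on non-missing calls and folded to
    <= 0.5.
    """

    dosages: pd.DataFrame
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.dosages.columns.equals(self.snps.index):
            self.snps = self.snps.loc[self.dosages.columns]

    @property
    def samples(self) -> pd.Index:
        return self.dosages.index

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosages.columns

    def subset_snps(self, ids) -> "GenotypeMatrix":
        ids = pd.Index(ids)
        return GenotypeMatrix(self.dosages[ids], self.snps.loc[ids])

    def subset_samples(self, samples) -> "GenotypeMatrix":
        g = GenotypeMatrix(self.dosages.loc[samples], self.snps.copy())
        recompute_snp_stats(g)
        return g

    def equals(self, other: "GenotypeMatrix") -> bool:
        a = self.dosages
        b = other.dosages
        return (
            a.index.equals(b.index)
            and a.columns.equals(b.columns)
            and np.allclose(a.to_numpy(float), b.to_numpy(float), equal_nan=True)
            and self.snps[["chrom", "pos"]].equals(other.snps[["chrom", "pos"]])
        )


def recompute_snp_stats(g: GenotypeMatrix) -> None:
    """Fill/refresh the ``maf`` and ``call_rate`` metadata columns in place."""
    x = g.dosages.to_numpy(float)
    called = ~np.isnan(x)
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore"):
        alt_freq = np.nansum(x, axis=0) / (2 * np.maximum(n_called, 1))
    maf = np.minimum(alt_freq, 1 - alt_freq)
    maf[n_called == 0] = np.nan
    g.snps["maf"] = maf
    g.snps["call_rate"] = n_called / x.shape[0]


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read genotypes from VCF or dosage TSV into additive coding.

    Non-biallelic VCF records are skipped with a warning; a duplicated SNP
    id raises ``ValueError``.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix in {".vcf", ".gz"} or path.name.endswith(".vcf.gz") else "tsv"
    if format == "vcf":
        return _read_genotypes_vcf(path)
    if format == "tsv":
        return _read_genotypes_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_genotypes_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, rows = [], [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            warnings.warn(f"skipping non-biallelic-SNP record at {rec.CHROM}:{rec.POS}")
            continue
        snp_id = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = rec.gt_types.astype(float)
        dose = np.where(gt == 3, 2.0, gt)
        dose[gt == 2] = np.nan
        ids.append(snp_id)
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        rows.append(dose)
    if len(set(ids)) != len(ids):
        dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
        raise ValueError(f"duplicated SNP id(s) in {path}: {dupes}")
    dosages = pd.DataFrame(np.array(rows).T, index=pd.Index(samples, name="sample"),
                           columns=pd.Index(ids, name="snp_id"))
    snps = pd.DataFrame({"chrom": chroms, "pos": poss}, index=dosages.columns)
    g = GenotypeMatrix(dosages, snps)
    recompute_snp_stats(g)
    return g


def _read_genotypes_tsv(path: Path) -> GenotypeMatrix:
    """Dosage TSV: first column sample id, remaining columns SNP ids.

    A sidecar ``<stem>.snps.tsv`` with columns snp_id/chrom/pos supplies
    positions; without it the metadata has missing coordinates.
    """
    dosages = pd.read_csv(path, sep="\t", index_col=0)
    dosages.index.name = "sample"
    dosages.columns.name = "snp_id"
    if dosages.columns.duplicated().any():
        raise ValueError(f"duplicated SNP id(s) in {path}")
    dosages = dosages.astype(float)
    bad = ~(dosages.isin([0.0, 1.0, 2.0]) | dosages.isna())
    if bad.to_numpy().any():
        raise ValueError(f"{path}: dosages must be 0/1/2 or NA")
    meta_path = Path(str(path).removesuffix(".tsv") + ".snps.tsv")
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t").set_index("snp_id")
        snps = meta.reindex(dosages.columns)[["chrom", "pos"]]
    else:
        snps = pd.DataFrame({"chrom": pd.NA, "pos": np.nan}, index=dosages.columns)
    g = GenotypeMatrix(dosages, snps)
    recompute_snp_stats(g)
    return g


def write_genotypes_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    path = Path(path)
    out = g.dosages.copy()
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", float_format="%.10g", na_rep="NA")
    meta = g.snps.reset_index().rename(columns={"index": "snp_id"})
    meta.to_csv(Path(str(path).removesuffix(".tsv") + ".snps.tsv"),
                sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# expression / annotation / covariates
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> pd.DataFrame:
    """Samples x genes matrix of (already normalized) expression values."""
    df = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    df.index.name = "sample"
    df.columns.name = "gene_id"
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format="%.10g", na_rep="NA")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Gene annotation: gene_id, chrom, tss (1-based), strand.

    Accepts the package's TSV (header with those columns) or BED
    (chrom/start/end/name/score/strand, 0-based half-open; TSS taken
    strand-aware from the interval ends).
    """
    path = Path(path)
    if path.suffix == ".bed":
        bed = pd.read_csv(path, sep="\t", header=None)
        cols = ["chrom", "start", "end", "gene_id", "score", "strand"][: bed.shape[1]]
        bed.columns = cols
        strand = bed["strand"] if "strand" in bed else "+"
        tss = np.where(strand == "-", bed["end"], bed["start"] + 1)
        ann = pd.DataFrame({"gene_id": bed["gene_id"], "chrom": bed["chrom"],
                            "tss": tss.astype(int), "strand": strand})
    else:
        ann = pd.read_csv(path, sep="\t")
        missing = {"gene_id", "chrom", "tss"} - set(ann.columns)
        if missing:
            raise ValueError(f"{path}: annotation missing columns {sorted(missing)}")
        if "strand" not in ann:
            ann["strand"] = "+"
    return ann.set_index("gene_id")


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann.reset_index().to_csv(path, sep="\t", index=False)


def read_covariates(path: str | Path) -> pd.DataFrame:
    cov = pd.read_csv(path, sep="\t", index_col=0)
    cov.index.name = "sample"
    return cov


# ---------------------------------------------------------------------------
# labels, gene sets, blocks
# ---------------------------------------------------------------------------

def read_gwas_labels(path: str | Path) -> pd.DataFrame:
    """GWAS-catalog-like TSV with columns snp_id, trait, p_value."""
    df = pd.read_csv(path, sep="\t")
    missing = {"snp_id", "trait", "p_value"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: GWAS label file missing columns {sorted(missing)}")
    return df


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines and # comments ignored."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    return genes


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene sets: name<TAB>description<TAB>gene1<TAB>gene2..."""
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description and >=1 gene")
        sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path) -> None:
    lines = [
        "\t".join([name, "na", *sorted(genes)]) for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_ld_blocks(path: str | Path) -> pd.Series:
    """LD-block TSV (snp_id, block_id) -> Series snp_id -> block_id."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "block_id": str})
    missing = {"snp_id", "block_id"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: LD-block file missing columns {sorted(missing)}")
    if df["snp_id"].duplicated().any():
        raise ValueError(f"{path}: a SNP may belong to only one LD block")
    return df.set_index("snp_id")["block_id"]


def write_ld_blocks(blocks: pd.Series, path: str | Path) -> None:
    blocks.rename("block_id").rename_axis("snp_id").reset_index().to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# sample alignment
# ---------------------------------------------------------------------------

def align_samples(
    genotypes: GenotypeMatrix,
    expression: pd.DataFrame,
    covariates: pd.DataFrame,
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Restrict all three tables to their common samples, in genotype order.

    Raises ``ValueError`` when the intersection is empty; logs what was
    dropped from each table.
    """
    common = genotypes.samples.intersection(expression.index).intersection(covariates.index)
    if len(common) == 0:
        raise ValueError("no samples shared between genotypes, expression and covariates")
    common = genotypes.samples[genotypes.samples.isin(common)]  # keep genotype order
    for name, idx in (("genotypes", genotypes.samples),
                      ("expression", expression.index),
                      ("covariates", covariates.index)):
        dropped = idx.difference(common)
        if len(dropped):
            logger.info("align_samples: dropping %d %s-only samples", len(dropped), name)
    logger.info("align_samples: %d samples in common", len(common))
    return genotypes.subset_samples(common), expression.loc[common], covariates.loc[common]
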