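"""Gene-level allele-specific expression (ASE) calling from RNA-seq counts.

Input is a table of phase-consistent per-SNP allele counts (hap1/hap2 reads
at heterozygous SNPs, with the haplotype labels consistent within each
gene).  Counts are summed per gene and summarized by the allelic expression
ratio

    ratio = 100 * minor_total / ((hap1_total + hap2_total) / 2)
          = 200 * minor_fraction,

so the ratio lives on [0, 100]: 100 means perfectly balanced biallelic
expression, 0 means strict monoallelic expression.  A gene is monoallelic
when its ratio is strictly below the cutoff (default 40, i.e. the minor
allele carries <20% of reads), biallelic otherwise, and uninformative when
its total coverage falls below ``min_gene_reads`` (default 20) or it has no
heterozygous SNP.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .thresholds import Thresholds

__all__ = [
    "load_ase_table",
    "aggregate_gene_counts",
    "classify_gene_ase",
    "filter_informative_genes",
]

REQUIRED_COLUMNS = ("gene_id", "snp_id", "hap1_count", "hap2_count")


def load_ase_table(path) -> pd.DataFrame:
    """Read a per-SNP allele count TSV (gene_id, snp_id, chrom, pos,
    hap1_count, hap2_count)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    for col in ("hap1_count", "hap2_count"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or (vals < 0).any():
            raise ValueError(f"{path}: {col} must be nonnegative integers")
        df[col] = vals.astype(int)
    return df


def classify_gene_ase(allelic_ratio, thresholds: Thresholds | None = None):
    """Monoallelic iff the allelic ratio is strictly below the cutoff
    (default 40); a ratio of exactly 40 is biallelic.  Vectorized."""
    th = thresholds or Thresholds()
    ratio = np.asarray(allelic_ratio, dtype=float)
    cls = np.where(ratio < th.rnaseq_ratio_cutoff, "monoallelic", "biallelic")
    return cls if ratio.ndim else str(cls)


def aggregate_gene_counts(snp_counts: pd.DataFrame,
                          thresholds: Thresholds | None = None,
                          ) -> pd.DataFrame:
    """Sum allele counts over each gene's SNPs and classify.

    Returns one row per gene present in the input: gene_id, n_snps,
    hap1_total, hap2_total, minor_fraction, allelic_ratio, allelic_class.
    Genes with total coverage below ``min_gene_reads`` are uninformative
    (ratio still reported when total > 0).
    """
    th = thresholds or Thresholds()
    g = (snp_counts.groupby("gene_id", sort=True)
         .agg(n_snps=("snp_id", "size"),
              hap1_total=("hap1_count", "sum"),
              hap2_total=("hap2_count", "sum"))
         .reset_index())
    total = (g.hap1_total + g.hap2_total).astype(float)
    minor = np.minimum(g.hap1_total, g.hap2_total).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        minor_fraction = np.where(total > 0, minor / total, np.nan)
    allelic_ratio = 200.0 * minor_fraction
    informative = total >= th.min_gene_reads
    cls = np.where(informative,
                   classify_gene_ase(np.nan_to_num(allelic_ratio), th),
                   "uninformative")
    g["minor_fraction"] = minor_fraction
    g["allelic_ratio"] = allelic_ratio
    g["allelic_class"] = cls
    return g


def filter_informative_genes(results: pd.DataFrame,
                             gene_model: pd.DataFrame | None = None,
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep informative genes and summarize them per chromosome.

    Returns ``(informative, summary)`` where ``summary`` counts informative,
    biallelic and monoallelic genes per chromosome (chromosome 'NA' when no
    gene model is supplied).
    """
    informative = results[results.allelic_class != "uninformative"].copy()
    if gene_model is not None:
        chrom_map = gene_model.set_index("gene_id")["chrom"]
        informative["chrom"] = informative.gene_id.map(chrom_map).fillna("NA")
    else:
        informative["chrom"] = "NA"
    if informative.empty:
        summary = pd.DataFrame(columns=["chrom", "n_informative",
                                        "n_biallelic", "n_monoallelic"])
    else:
        summary = (informative.groupby("chrom")
                   .agg(n_informative=("gene_id", "size"),
                        n_biallelic=("allelic_class",
                                     lambda s: int((s == "biallelic").sum())),
                        n_monoallelic=("allelic_class",
                                       lambda s: int((s == "monoallelic").sum())))
                   .reset_index())
    return informative, summary
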