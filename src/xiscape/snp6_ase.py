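"""Nascent-RNA SNP-array allelic expression pipeline.

Raw per-SNP two-channel intensities (nascent nuclear RNA hybridized to a
genotyping array) are scored in three steps, each producing one flag per SNP:

1. **expression** — the SNP's total intensity (A + B) clears a per-array
   adaptive threshold (a quantile of all totals, median by default);
2. **informativeness** — the SNP is heterozygous, retains both genomic
   alleles (minor copy number >= 1 when provided), and lies outside any
   loss-of-heterozygosity (LOH) segment;
3. **allelic class** — among expressed informative SNPs, biallelic when the
   minor channel carries at least ``snp_minor_fraction`` (default 20%) of
   the total signal, monoallelic otherwise.

SNP statuses are then cumulated along the chromosome in sliding windows of
``window_size`` consecutive informative SNPs (default 50), and at gene level:
a gene is monoallelic when strictly fewer than ``gene_biallelic_snp_fraction``
(default 2/3) of its expressed informative SNPs are biallelic.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .thresholds import Thresholds

logger = logging.getLogger(__name__)

__all__ = [
    "load_snp_table",
    "score_expression",
    "mask_noninformative",
    "classify_snp_allelic",
    "window_profile",
    "gene_call",
    "clonality_check",
    "call_sample",
]

REQUIRED_COLUMNS = ("snp_id", "chrom", "pos", "genotype",
                    "channel_a", "channel_b")
GENOTYPES = {"AA", "AB", "BB", "NoCall"}


def load_snp_table(path) -> pd.DataFrame:
    """Read a per-SNP intensity TSV and return records sorted by (chrom, pos).

    Required columns: snp_id, chrom, pos, genotype, channel_a, channel_b;
    optional: seg_major_cn, seg_minor_cn.  Malformed rows raise with their
    1-based data row number.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    for col in ("channel_a", "channel_b", "pos"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric {col!r} in data row(s) "
                f"{[int(i) + 1 for i in bad[:5]]}")
        df[col] = vals
    bad_geno = ~df.genotype.isin(GENOTYPES)
    if bad_geno.any():
        rows = [int(i) + 1 for i in df.index[bad_geno][:5]]
        raise ValueError(f"{path}: invalid genotype in data row(s) {rows}")
    if (df.channel_a < 0).any() or (df.channel_b < 0).any():
        raise ValueError(f"{path}: negative channel intensity")
    if (df.pos < 1).any():
        raise ValueError(f"{path}: positions must be 1-based (>= 1)")
    for col in ("seg_major_cn", "seg_minor_cn"):
        if col not in df.columns:
            df[col] = np.nan
    return (df.sort_values(["chrom", "pos"], kind="mergesort")
              .reset_index(drop=True))


def score_expression(records: pd.DataFrame,
                     thresholds: Thresholds | None = None) -> pd.Series:
    """Flag expressed SNPs: total intensity >= the per-array quantile
    threshold (ties pass).  An absolute threshold, when configured,
    overrides the adaptive one."""
    if len(records) == 0:
        raise ValueError("no records to score")
    th = thresholds or Thresholds()
    total = records.channel_a + records.channel_b
    if th.expr_absolute is not None:
        cutoff = th.expr_absolute
    else:
        cutoff = float(np.quantile(total, th.expr_quantile))
    if (total == 0).all():
        warnings.warn("all SNP intensities are zero; nothing is expressed")
        return pd.Series(False, index=records.index, name="expressed")
    return pd.Series(total.values >= cutoff, index=records.index,
                     name="expressed")


def mask_noninformative(records: pd.DataFrame,
                        loh_segments: Sequence[tuple[str, int, int]] = (),
                        ) -> pd.Series:
    """Flag informative SNPs: heterozygous, minor allele genomically
    retained, and outside every LOH segment (1-based inclusive; overlapping
    segments are unioned)."""
    het = records.genotype == "AB"
    minor_cn = records.get("seg_minor_cn")
    if minor_cn is not None:
        retained = minor_cn.isna() | (minor_cn >= 1)
    else:
        retained = pd.Series(True, index=records.index)
    in_loh = np.zeros(len(records), dtype=bool)
    for c, s, e in loh_segments:
        in_loh |= ((records.chrom.values == c)
                   & (records.pos.values >= s) & (records.pos.values <= e))
    return pd.Series(het.values & retained.values & ~in_loh,
                     index=records.index, name="informative")


def classify_snp_allelic(records: pd.DataFrame,
                         thresholds: Thresholds | None = None,
                         expressed: pd.Series | None = None,
                         informative: pd.Series | None = None,
                         loh_segments: Sequence[tuple[str, int, int]] = (),
                         ) -> pd.DataFrame:
    """Per-SNP allelic calls.

    Returns a frame with snp_id, chrom, pos, expressed, informative,
    minor_channel_fraction, major_channel ('A'/'B', ties 'A'), and
    allelic_class in {biallelic, monoallelic, NA}.  Only expressed
    informative SNPs receive a class; the fraction is defined whenever
    A + B > 0.
    """
    th = thresholds or Thresholds()
    if expressed is None:
        expressed = score_expression(records, th)
    if informative is None:
        informative = mask_noninformative(records, loh_segments)
    a = records.channel_a.values.astype(float)
    b = records.channel_b.values.astype(float)
    total = a + b
    if np.any((total == 0) & expressed.values):
        raise ValueError("SNP flagged expressed with zero total intensity")
    with np.errstate(invalid="ignore", divide="ignore"):
        minor_frac = np.where(total > 0, np.minimum(a, b) / total, np.nan)
    callable_ = expressed.values & informative.values
    cls = np.where(callable_,
                   np.where(minor_frac >= th.snp_minor_fraction,
                            "biallelic", "monoallelic"),
                   "NA")
    return pd.DataFrame({
        "snp_id": records.snp_id,
        "chrom": records.chrom,
        "pos": records.pos,
        "expressed": expressed.values,
        "informative": informative.values,
        "minor_channel_fraction": minor_frac,
        "major_channel": np.where(a >= b, "A", "B"),
        "allelic_class": cls,
    }, index=records.index)


def window_profile(calls: pd.DataFrame,
                   thresholds: Thresholds | None = None) -> pd.DataFrame:
    """Sliding-window profile of allelic status along each chromosome.

    Windows span ``window_size`` consecutive member SNPs (members are
    informative SNPs by default, or all SNPs with ``window_members='all'``),
    advance by ``window_step`` members, and never cross chromosomes.  Each
    row counts the expressed informative SNPs in the window by allelic
    class.  A chromosome with fewer members than the window size yields one
    truncated window, flagged ``truncated=True``.
    """
    th = thresholds or Thresholds()
    rows = []
    if len(calls) == 0:
        return pd.DataFrame(columns=[
            "chrom", "window_index", "center_pos", "n_snps",
            "n_expressed_informative", "n_biallelic", "n_monoallelic",
            "truncated"])
    for chrom, sub in calls.groupby("chrom", sort=False):
        sub = sub.sort_values("pos", kind="mergesort")
        if th.window_members == "informative":
            sub = sub[sub.informative]
        n = len(sub)
        if n == 0:
            continue
        pos = sub.pos.values
        bi = ((sub.allelic_class == "biallelic").values).astype(int)
        mono = ((sub.allelic_class == "monoallelic").values).astype(int)
        size = th.window_size
        if n < size:
            starts = [0]
            eff = n
            truncated = True
        else:
            starts = range(0, n - size + 1, th.window_step)
            eff = size
            truncated = False
        for w, s in enumerate(starts):
            sl = slice(s, s + eff)
            n_bi = int(bi[sl].sum())
            n_mono = int(mono[sl].sum())
            rows.append({
                "chrom": chrom,
                "window_index": w,
                "center_pos": int(pos[s + (eff - 1) // 2]),
                "n_snps": eff,
                "n_expressed_informative": n_bi + n_mono,
                "n_biallelic": n_bi,
                "n_monoallelic": n_mono,
                "truncated": truncated,
            })
    return pd.DataFrame(rows)


def _assign_genes(calls: pd.DataFrame, gene_model: pd.DataFrame) -> pd.DataFrame:
    """Join SNPs to genes by coordinate overlap (1-based inclusive gene
    spans).  A SNP inside two overlapping genes is assigned to both, with a
    warning."""
    pieces = []
    for chrom, genes in gene_model.groupby("chrom", sort=False):
        sub = calls[calls.chrom == chrom]
        if sub.empty:
            continue
        sub = sub.sort_values("pos", kind="mergesort")
        pos = sub.pos.values
        for g in genes.itertuples():
            lo = np.searchsorted(pos, g.start, side="left")
            hi = np.searchsorted(pos, g.end, side="right")
            if hi > lo:
                block = sub.iloc[lo:hi].copy()
                block["gene_id"] = g.gene_id
                pieces.append(block)
    if not pieces:
        return calls.iloc[0:0].assign(gene_id=pd.Series(dtype=str))
    out = pd.concat(pieces, ignore_index=True)
    dup = out.duplicated("snp_id", keep=False)
    if dup.any():
        n = out.loc[dup, "snp_id"].nunique()
        logger.warning("%d SNP(s) overlap more than one gene; "
                       "assigned to all of them", n)
    return out


def gene_call(calls: pd.DataFrame, gene_model: pd.DataFrame,
              thresholds: Thresholds | None = None) -> pd.DataFrame:
    """Gene-level monoallelic/biallelic calls.

    A gene is informative when it has at least
    ``min_informative_snps_per_gene`` expressed informative SNPs;
    monoallelic when its biallelic-SNP fraction is strictly below
    ``gene_biallelic_snp_fraction`` (default 2/3), biallelic otherwise.
    Returns one row per gene in the model: gene_id, chrom, n_snps,
    n_expressed_informative, n_biallelic, biallelic_fraction, allelic_class.
    """
    th = thresholds or Thresholds()
    assigned = _assign_genes(calls, gene_model)
    rows = []
    grouped = dict(tuple(assigned.groupby("gene_id"))) if len(assigned) else {}
    for g in gene_model.itertuples():
        sub = grouped.get(g.gene_id)
        if sub is None:
            n_snps = n_ei = n_bi = 0
        else:
            n_snps = len(sub)
            called = sub.allelic_class != "NA"
            n_ei = int(called.sum())
            n_bi = int((sub.allelic_class == "biallelic").sum())
        if n_ei >= th.min_informative_snps_per_gene and n_ei > 0:
            frac = n_bi / n_ei
            cls = ("monoallelic"
                   if frac < th.gene_biallelic_snp_fraction else "biallelic")
        else:
            frac = np.nan
            cls = "uninformative"
        rows.append({"gene_id": g.gene_id, "chrom": g.chrom,
                     "n_snps": n_snps, "n_expressed_informative": n_ei,
                     "n_biallelic": n_bi, "biallelic_fraction": frac,
                     "allelic_class": cls})
    return pd.DataFrame(rows)


def clonality_check(calls: pd.DataFrame, phase: pd.DataFrame,
                    thresholds: Thresholds | None = None,
                    chrom: str = "chrX") -> dict:
    """Check that monoallelic X expression comes from a single haplotype.

    ``phase`` maps snp_id to hap1_allele ('A'/'B').  Returns the fraction of
    monoallelic X SNPs whose expressed (major) channel allele lies on the
    majority haplotype; the sample is clonal when that fraction reaches
    ``clonal_fraction`` (default 0.95).  With no phased monoallelic X SNPs
    the status is 'indeterminate'.
    """
    th = thresholds or Thresholds()
    sub = calls[(calls.chrom == chrom)
                & (calls.allelic_class == "monoallelic")]
    sub = sub.merge(phase[["snp_id", "hap1_allele"]], on="snp_id")
    if len(sub) == 0:
        return {"status": "indeterminate", "n_snps": 0,
                "majority_fraction": np.nan, "majority_haplotype": None,
                "clonal": False}
    on_hap1 = (sub.major_channel.values == sub.hap1_allele.values)
    frac_hap1 = float(on_hap1.mean())
    if frac_hap1 >= 0.5:
        majority, frac = "hap1", frac_hap1
    else:
        majority, frac = "hap2", 1.0 - frac_hap1
    return {"status": "ok", "n_snps": int(len(sub)),
            "majority_fraction": frac, "majority_haplotype": majority,
            "clonal": bool(frac >= th.clonal_fraction)}


def call_sample(records: pd.DataFrame, gene_model: pd.DataFrame,
                loh_segments: Sequence[tuple[str, int, int]] = (),
                thresholds: Thresholds | None = None,
                ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run the full per-sample array pipeline.

    Returns ``(snp_calls, window_profile, gene_calls)``.
    """
    th = thresholds or Thresholds()
    expressed = score_expression(records, th)
    informative = mask_noninformative(records, loh_segments)
    calls = classify_snp_allelic(records, th, expressed, informative)
    windows = window_profile(calls, th)
    genes = gene_call(calls, gene_model, th)
    return calls, windows, genes
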