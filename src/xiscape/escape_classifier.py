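"""Integration of gene-level allelic calls into escape-from-XCI categories.

Given a gene x sample matrix of allelic classes (monoallelic / biallelic /
uninformative) from the array and/or RNA-seq pipelines, plus a reference
annotation of known XCI statuses, each informative (gene, cancer sample)
pair is assigned one of four mutually exclusive categories:

* ``cancer_specific_escapee`` — biallelic in the cancer sample, AND either
  monoallelic in every informative normal sample or annotated as subject to
  XCI, AND not annotated as a known escapee;
* ``constitutive_escapee`` — biallelic in the cancer sample and biallelic
  in at least one normal sample or annotated as a known escapee;
* ``subject`` — monoallelic in the cancer sample;
* ``uninformative`` — no allelic call in the cancer sample, or biallelic
  with no normal-sample or annotation evidence either way.

The module also computes the cross-platform overlap of cancer-specific
escapee sets, the heterozygous-X sample filter used before scoring tumor
cohorts, and recurrently biallelic genes across tumors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .thresholds import Thresholds

__all__ = [
    "load_reference_lists",
    "build_status_matrix",
    "classify_escape",
    "EscapeeReport",
    "combine_platforms",
    "filter_heterozygous_x_samples",
    "recurrent_biallelic_genes",
    "summarize",
]

REFERENCE_STATUSES = {"subject", "escapee", "variable", "unknown"}


def load_reference_lists(path) -> dict[str, str]:
    """Load an XCI reference-status TSV (gene_id, status).

    Statuses come from published surveys of XCI escape; valid tokens are
    subject / escapee / variable / unknown.  A gene listed twice with
    conflicting statuses becomes 'variable'.
    """
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "status"} <= set(df.columns):
        raise ValueError(f"{path}: needs columns gene_id, status")
    bad = ~df.status.isin(REFERENCE_STATUSES)
    if bad.any():
        raise ValueError(
            f"{path}: unknown status token(s) "
            f"{sorted(df.status[bad].unique())}")
    out: dict[str, str] = {}
    for gene, status in zip(df.gene_id, df.status):
        if gene in out and out[gene] != status:
            out[gene] = "variable"
        else:
            out[gene] = status
    return out


def build_status_matrix(calls_by_sample: Mapping[str, pd.DataFrame],
                        class_col: str = "allelic_class") -> pd.DataFrame:
    """Pivot per-sample gene-call frames (gene_id + allelic_class) into a
    gene x sample matrix, filling absent genes as uninformative."""
    cols = {}
    for sample, df in calls_by_sample.items():
        cols[sample] = df.set_index("gene_id")[class_col]
    mat = pd.DataFrame(cols)
    return mat.fillna("uninformative")


@dataclass
class EscapeeReport:
    """Per-(gene, cancer sample) categories plus per-sample summary counts."""

    calls: pd.DataFrame    # gene_id, sample, cancer_class, category
    summary: pd.DataFrame  # sample, n_informative, n_escapees, n_cancer_specific, percent_cancer_specific

    def cancer_specific_sets(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for sample, sub in self.calls.groupby("sample"):
            out[sample] = set(
                sub.loc[sub.category == "cancer_specific_escapee", "gene_id"])
        return out


def classify_escape(status_matrix: pd.DataFrame,
                    normal_samples: Sequence[str],
                    cancer_samples: Sequence[str],
                    annotation: Mapping[str, str] | None = None,
                    ) -> EscapeeReport:
    """Assign escape categories per gene and cancer sample.

    ``status_matrix`` is a gene x sample frame with values monoallelic /
    biallelic / uninformative.  ``annotation`` maps gene_id to a reference
    XCI status; missing genes default to 'unknown'.
    """
    annotation = annotation or {}
    missing = [s for s in list(normal_samples) + list(cancer_samples)
               if s not in status_matrix.columns]
    if missing:
        raise ValueError(f"samples absent from status matrix: {missing}")

    rows = []
    for gene in status_matrix.index:
        ann = annotation.get(gene, "unknown")
        normal_calls = [status_matrix.at[gene, s] for s in normal_samples]
        informative_normals = [c for c in normal_calls
                               if c != "uninformative"]
        mono_in_all_normals = (len(informative_normals) > 0 and
                               all(c == "monoallelic"
                                   for c in informative_normals))
        biallelic_in_a_normal = any(c == "biallelic"
                                    for c in informative_normals)
        for sample in cancer_samples:
            cancer_class = status_matrix.at[gene, sample]
            if cancer_class == "uninformative":
                category = "uninformative"
            elif cancer_class == "monoallelic":
                category = "subject"
            else:  # biallelic in the cancer sample
                if biallelic_in_a_normal or ann == "escapee":
                    category = "constitutive_escapee"
                elif mono_in_all_normals or ann == "subject":
                    category = "cancer_specific_escapee"
                else:
                    # biallelic, but no normal-sample evidence and no
                    # reference status: cannot attribute the escape to cancer
                    category = "uninformative"
            rows.append({"gene_id": gene, "sample": sample,
                         "cancer_class": cancer_class,
                         "annotation": ann, "category": category})
    calls = pd.DataFrame(rows)

    sum_rows = []
    for sample, sub in calls.groupby("sample"):
        informative = sub[sub.category != "uninformative"]
        n_inf = len(informative)
        n_cs = int((informative.category == "cancer_specific_escapee").sum())
        n_const = int((informative.category == "constitutive_escapee").sum())
        sum_rows.append({
            "sample": sample,
            "n_informative": n_inf,
            "n_escapees": n_cs + n_const,
            "n_constitutive": n_const,
            "n_cancer_specific": n_cs,
            "percent_cancer_specific":
                100.0 * n_cs / n_inf if n_inf else np.nan,
        })
    return EscapeeReport(calls=calls, summary=pd.DataFrame(sum_rows))


def combine_platforms(report_a: EscapeeReport, report_b: EscapeeReport,
                      ) -> pd.DataFrame:
    """Union the cancer-specific escapee sets of two platforms per sample
    and report their overlap.

    The headline overlap is the Jaccard index x 100 (|A & B| / |A | B|);
    per-platform percentages (|A & B| / |A|, / |B|) are reported alongside
    because the symmetric and one-sided denominators can differ
    substantially for sets of unequal size.
    """
    sets_a = report_a.cancer_specific_sets()
    sets_b = report_b.cancer_specific_sets()
    shared = sorted(set(sets_a) & set(sets_b))
    if not shared:
        raise ValueError("the two reports share no sample names")
    rows = []
    for sample in shared:
        a, b = sets_a[sample], sets_b[sample]
        inter, union = a & b, a | b
        rows.append({
            "sample": sample,
            "n_platform_a": len(a),
            "n_platform_b": len(b),
            "n_union": len(union),
            "n_intersection": len(inter),
            "union_genes": ",".join(sorted(union)),
            "overlap_jaccard_pct":
                100.0 * len(inter) / len(union) if union else np.nan,
            "overlap_pct_of_a": 100.0 * len(inter) / len(a) if a else np.nan,
            "overlap_pct_of_b": 100.0 * len(inter) / len(b) if b else np.nan,
        })
    return pd.DataFrame(rows)


def filter_heterozygous_x_samples(sample_genotypes: pd.DataFrame,
                                  min_het_fraction: float = 0.10,
                                  chrom: str = "chrX") -> pd.DataFrame:
    """Retain samples that kept a heterozygous X chromosome.

    ``sample_genotypes`` holds per-SNP genotype calls (sample_id, chrom,
    genotype).  A sample is retained when its fraction of heterozygous (AB)
    X SNPs reaches ``min_het_fraction``: such samples likely retained an
    inactive X (or part of one) and are interpretable for allelic analysis.
    Samples with zero X SNPs are excluded with a warning.
    """
    rows = []
    for sample, sub in sample_genotypes.groupby("sample_id"):
        x = sub[sub.chrom == chrom]
        if len(x) == 0:
            warnings.warn(f"sample {sample!r} has no X SNPs; excluded")
            rows.append({"sample_id": sample, "n_x_snps": 0,
                         "het_fraction": np.nan, "retained": False})
            continue
        frac = float((x.genotype == "AB").mean())
        rows.append({"sample_id": sample, "n_x_snps": len(x),
                     "het_fraction": frac,
                     "retained": frac >= min_het_fraction})
    return pd.DataFrame(rows)


def recurrent_biallelic_genes(per_sample_calls: pd.DataFrame,
                              min_samples: int = 2) -> pd.DataFrame:
    """Genes biallelically expressed in at least ``min_samples`` samples.

    ``per_sample_calls`` is a gene x sample matrix of allelic classes.
    Returns gene_id and n_biallelic_samples, sorted by recurrence (desc)
    then gene name.
    """
    counts = (per_sample_calls == "biallelic").sum(axis=1)
    keep = counts[counts >= min_samples]
    out = (keep.rename("n_biallelic_samples").rename_axis("gene_id")
           .reset_index())
    return (out.sort_values(["n_biallelic_samples", "gene_id"],
                            ascending=[False, True])
            .reset_index(drop=True))


def summarize(report: EscapeeReport) -> pd.DataFrame:
    """Per-sample breakdown of informative genes by reference annotation and
    allelic outcome (a platform-summary table).

    Counts in each row sum to that sample's n_informative.
    """
    rows = []
    for sample, sub in report.calls.groupby("sample"):
        informative = sub[sub.category != "uninformative"]
        n_inf = len(informative)
        row = {"sample": sample, "n_informative": n_inf}
        for ann in ("subject", "escapee", "variable", "unknown"):
            for outcome in ("monoallelic", "biallelic"):
                key = f"{ann}_{outcome}"
                row[key] = int(((informative.annotation == ann)
                                & (informative.cancer_class == outcome)).sum())
        row["n_cancer_specific"] = int(
            (informative.category == "cancer_specific_escapee").sum())
        row["n_constitutive_escapee"] = int(
            (informative.category == "constitutive_escapee").sum())
        row["percent_cancer_specific"] = (
            100.0 * row["n_cancer_specific"] / n_inf if n_inf else np.nan)
        rows.append(row)
    if not rows:
        cols = (["sample", "n_informative"]
                + [f"{a}_{o}" for a in ("subject", "escapee", "variable",
                                        "unknown")
                   for o in ("monoallelic", "biallelic")]
                + ["n_cancer_specific", "n_constitutive_escapee",
                   "percent_cancer_specific"])
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)
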