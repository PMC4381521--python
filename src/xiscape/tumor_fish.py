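"""Tumor-level scoring of per-nucleus XIST / nascent-RNA FISH observations.

Each scored nucleus contributes a count of XIST RNA domains and, per probed
gene, whether a nascent-RNA signal lies at or within a XIST domain
(candidate Xi expression) or elsewhere (presumed Xa expression).  A tumor
is XIST-positive when at least 10% of its nuclei show a domain (the
inclusive rule; a strict > rule is selectable), and a gene is called
reactivated from the Xi in a XIST-positive tumor when at least 5% of scored
nuclei show an in-domain signal.  Cohort tables cross-tabulate calls by
molecular subtype (Luminal / HER2 / BLC).
"""

from __future__ import annotations

import pandas as pd

from .thresholds import Thresholds

__all__ = ["load_fish_table", "score_tumor", "score_cohort", "cohort_table"]

SUBTYPES = ("Luminal", "HER2", "BLC")


def load_fish_table(path) -> pd.DataFrame:
    """Read a per-nucleus FISH TSV (tumor_id, nucleus_id, n_xist_domains,
    gene, signal_in_domain, signal_outside_domain)."""
    df = pd.read_csv(path, sep="\t")
    need = {"tumor_id", "nucleus_id", "n_xist_domains", "gene",
            "signal_in_domain"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    for col in ("signal_in_domain", "signal_outside_domain"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    if (df.n_xist_domains < 0).any():
        raise ValueError(f"{path}: n_xist_domains must be >= 0")
    bad = df.signal_in_domain & (df.n_xist_domains < 1)
    if bad.any():
        raise ValueError(
            f"{path}: {int(bad.sum())} row(s) report an in-domain signal "
            "in a nucleus without a XIST domain")
    return df


def score_tumor(records: pd.DataFrame,
                thresholds: Thresholds | None = None) -> dict:
    """Score one tumor from its per-nucleus records.

    Returns a dict with frac_xist_nuclei, xist_positive, and per gene
    frac_reactivated_nuclei plus the reactivated call.  Gene reactivation is
    only evaluated in XIST-positive tumors; the reactivation denominator is
    all scored nuclei by default (configurable to domain-bearing nuclei).
    """
    th = thresholds or Thresholds()
    if records.empty:
        raise ValueError("tumor has zero scored nuclei")
    nuclei = records.drop_duplicates("nucleus_id")
    n_nuclei = len(nuclei)
    frac_xist = float((nuclei.n_xist_domains >= 1).mean())
    if th.xist_rule_inclusive:
        xist_positive = frac_xist >= th.xist_pos_frac
    else:
        xist_positive = frac_xist > th.xist_pos_frac
    out = {
        "tumor_id": records.tumor_id.iloc[0],
        "n_nuclei": n_nuclei,
        "frac_xist_nuclei": frac_xist,
        "xist_positive": bool(xist_positive),
        "genes": {},
    }
    if th.react_denominator == "xist_positive":
        denom_ids = set(nuclei.loc[nuclei.n_xist_domains >= 1, "nucleus_id"])
    else:
        denom_ids = set(nuclei.nucleus_id)
    for gene, sub in records.groupby("gene"):
        sub = sub[sub.nucleus_id.isin(denom_ids)]
        denom = len(denom_ids)
        frac = float(sub.signal_in_domain.sum()) / denom if denom else 0.0
        out["genes"][gene] = {
            "frac_reactivated_nuclei": frac,
            "reactivated": bool(xist_positive and frac >= th.react_frac),
        }
    return out


def score_cohort(records: pd.DataFrame,
                 subtype_map: pd.DataFrame | None = None,
                 thresholds: Thresholds | None = None) -> pd.DataFrame:
    """Score every tumor in a cohort; one row per (tumor, gene).

    Unknown or missing subtype labels fall into the 'NA' bucket.
    """
    th = thresholds or Thresholds()
    subtypes = {}
    if subtype_map is not None:
        subtypes = dict(zip(subtype_map.tumor_id, subtype_map.subtype))
    columns = ["tumor_id", "subtype", "n_nuclei", "frac_xist_nuclei",
               "xist_positive", "gene", "frac_reactivated_nuclei",
               "reactivated"]
    if records.empty:
        return pd.DataFrame(columns=columns)
    rows = []
    for tumor_id, sub in records.groupby("tumor_id"):
        s = score_tumor(sub, th)
        subtype = subtypes.get(tumor_id, "NA")
        if subtype not in SUBTYPES:
            subtype = "NA"
        for gene, g in s["genes"].items():
            rows.append({
                "tumor_id": tumor_id,
                "subtype": subtype,
                "n_nuclei": s["n_nuclei"],
                "frac_xist_nuclei": s["frac_xist_nuclei"],
                "xist_positive": s["xist_positive"],
                "gene": gene,
                "frac_reactivated_nuclei": g["frac_reactivated_nuclei"],
                "reactivated": g["reactivated"],
            })
    return pd.DataFrame(rows, columns=columns)


def cohort_table(summaries: pd.DataFrame) -> pd.DataFrame:
    """Cross-tabulate tumor calls by molecular subtype.

    ``summaries`` is the output of :func:`score_cohort`.  Returns one row
    per subtype (plus a Total row): number of tumors, number XIST-positive,
    and per probed gene the number of XIST-positive tumors with Xi-linked
    reactivation of that gene.
    """
    genes = sorted(summaries.gene.unique()) if len(summaries) else []
    rows = []
    order = [s for s in (*SUBTYPES, "NA")
             if s in set(summaries.subtype)] if len(summaries) else []
    for subtype in order + ["Total"]:
        sub = (summaries if subtype == "Total"
               else summaries[summaries.subtype == subtype])
        tumors = sub.drop_duplicates("tumor_id")
        row = {"subtype": subtype,
               "n_tumors": len(tumors),
               "n_xist_positive": int(tumors.xist_positive.sum())}
        for gene in genes:
            gsub = sub[(sub.gene == gene) & sub.xist_positive]
            row[f"n_reactivated_{gene}"] = int(gsub.reactivated.sum())
        rows.append(row)
    cols = (["subtype", "n_tumors", "n_xist_positive"]
            + [f"n_reactivated_{g}" for g in genes])
    return pd.DataFrame(rows, columns=cols)
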