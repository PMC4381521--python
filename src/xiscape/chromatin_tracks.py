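"""Chromosome-scale ChIP coverage comparison.

Coverage arrives as bedGraph-style intervals (0-based half-open) and is
reduced to fixed-width bins by length-weighted averaging.  Binned tracks
from different samples are made comparable by classic quantile
normalization (each track's values are replaced by the across-track mean of
order statistics at the same rank), after which per-bin log2 ratios against
a reference sample expose regional gains and losses of a mark (e.g.
H3K27me3 erosion along the inactive X).  TSS-centered metaprofiles and
repressive-domain enrichment summaries complete the comparison toolkit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .thresholds import Thresholds

__all__ = [
    "read_bedgraph",
    "bin_coverage",
    "quantile_normalize",
    "bin_log_ratio",
    "bin_difference",
    "tss_profile",
    "tss_group_profiles",
    "domain_enrichment",
]


def read_bedgraph(path) -> pd.DataFrame:
    """Read a 4-column bedGraph (chrom, start, end, value)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str})
    if (df.end <= df.start).any():
        raise ValueError(f"{path}: intervals must satisfy start < end")
    if (df.value < 0).any():
        raise ValueError(f"{path}: coverage values must be >= 0")
    return df


def bin_coverage(coverage: pd.DataFrame, bin_size: int,
                 chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Average bedGraph coverage into fixed-width bins.

    Per bin, the value is the length-weighted mean of overlapping interval
    values, with uncovered bases counting as zero; the last, possibly
    partial, bin is normalized by its true width.  Intervals extending
    beyond the chromosome length raise.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    pieces = []
    for chrom, sub in coverage.groupby("chrom", sort=False):
        length = (chrom_lengths or {}).get(chrom, int(sub.end.max()))
        if (sub.end > length).any():
            raise ValueError(
                f"{chrom}: interval beyond chromosome length {length}")
        if bin_size > length:
            raise ValueError(
                f"{chrom}: bin size {bin_size} exceeds chromosome length")
        n_bins = int(np.ceil(length / bin_size))
        sums = np.zeros(n_bins)
        for s, e, v in zip(sub.start.values, sub.end.values,
                           sub.value.values):
            b0, b1 = s // bin_size, (e - 1) // bin_size
            if b0 == b1:
                sums[b0] += (e - s) * v
            else:
                sums[b0] += ((b0 + 1) * bin_size - s) * v
                sums[b1] += (e - b1 * bin_size) * v
                sums[b0 + 1:b1] += bin_size * v
        starts = np.arange(n_bins, dtype=np.int64) * bin_size
        ends = np.minimum(starts + bin_size, length)
        widths = (ends - starts).astype(float)
        pieces.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends,
            "value": sums / widths}))
    if not pieces:
        return pd.DataFrame(columns=["chrom", "start", "end", "value"])
    return pd.concat(pieces, ignore_index=True)


def _check_same_grid(tracks: dict[str, pd.DataFrame]) -> None:
    names = list(tracks)
    ref = tracks[names[0]]
    for name in names[1:]:
        t = tracks[name]
        if (len(t) != len(ref)
                or not (t.chrom.values == ref.chrom.values).all()
                or not (t.start.values == ref.start.values).all()
                or not (t.end.values == ref.end.values).all()):
            raise ValueError(
                f"tracks {names[0]!r} and {name!r} have different bin grids")


def quantile_normalize(tracks: dict[str, pd.DataFrame],
                       ) -> dict[str, pd.DataFrame]:
    """Classic quantile normalization across binned tracks.

    Each track's values are ranked and replaced by the across-track mean of
    order statistics; ties receive the mean of their tied ranks' reference
    values.  After normalization every track carries an identical value
    multiset, so chromosome-scale profiles can be compared directly.
    """
    if len(tracks) < 2:
        raise ValueError("quantile normalization needs at least 2 tracks")
    _check_same_grid(tracks)
    mat = np.column_stack([t.value.values.astype(float)
                           for t in tracks.values()])
    reference = np.sort(mat, axis=0).mean(axis=1)
    n = mat.shape[0]
    out = {}
    grid = np.arange(1, n + 1, dtype=float)
    for j, (name, t) in enumerate(tracks.items()):
        ranks = rankdata(mat[:, j], method="average")
        values = np.interp(ranks, grid, reference)
        nt = t.copy()
        nt["value"] = values
        out[name] = nt
    return out


def bin_log_ratio(track: pd.DataFrame, reference: pd.DataFrame,
                  pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-bin log2((v + eps) / (r + eps)).  NA-free by construction."""
    _check_same_grid({"track": track, "reference": reference})
    eps = float(pseudocount)
    if eps < 0:
        raise ValueError("pseudocount must be >= 0")
    out = track.copy()
    out["value"] = np.log2((track.value.values + eps)
                           / (reference.value.values + eps))
    return out


def bin_difference(track: pd.DataFrame, reference: pd.DataFrame,
                   ) -> pd.DataFrame:
    """Per-bin raw difference v - r (alternative to the log ratio)."""
    _check_same_grid({"track": track, "reference": reference})
    out = track.copy()
    out["value"] = track.value.values - reference.value.values
    return out


def _step_lookup(sub: pd.DataFrame):
    """Point lookup into non-overlapping bedGraph intervals of one
    chromosome (uncovered positions read 0)."""
    sub = sub.sort_values("start", kind="mergesort")
    starts = sub.start.values
    ends = sub.end.values
    values = sub.value.values.astype(float)

    def lookup(pos: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(starts, pos, side="right") - 1
        idx_c = np.clip(idx, 0, len(starts) - 1)
        inside = (idx >= 0) & (pos < ends[idx_c])
        return np.where(inside, values[idx_c], 0.0)

    return lookup


def tss_profile(coverage: pd.DataFrame, tss: pd.DataFrame,
                flank: int = 1500, step: int = 50,
                chrom_lengths: dict[str, int] | None = None,
                ) -> tuple[pd.DataFrame, pd.Series]:
    """Strand-oriented coverage matrix around transcription start sites.

    ``tss`` needs columns gene_id, chrom, tss (0-based position) and strand;
    minus-strand genes are flipped so that +x is always downstream.  Genes
    whose window would cross a chromosome edge are kept as all-NA rows and
    excluded from the mean profile.  Returns ``(matrix, mean_profile)``
    indexed/keyed by the signed offset from the TSS.
    """
    offsets = np.arange(-flank, flank + 1, step)
    lookups = {chrom: _step_lookup(sub)
               for chrom, sub in coverage.groupby("chrom", sort=False)}
    max_end = {chrom: int(sub.end.max())
               for chrom, sub in coverage.groupby("chrom", sort=False)}
    rows = []
    for g in tss.itertuples():
        length = (chrom_lengths or {}).get(g.chrom, max_end.get(g.chrom))
        sign = -1 if g.strand == "-" else 1
        pos = g.tss + sign * offsets
        if pos.min() < 0 or (length is not None and pos.max() >= length):
            rows.append(np.full(len(offsets), np.nan))
            continue
        lookup = lookups.get(g.chrom)
        rows.append(lookup(pos) if lookup is not None
                    else np.zeros(len(offsets)))
    matrix = pd.DataFrame(rows, index=list(tss.gene_id), columns=offsets)
    complete = matrix.dropna()
    if len(complete):
        mean_profile = complete.mean(axis=0)
    else:
        mean_profile = pd.Series(np.nan, index=offsets)
    mean_profile.name = "mean"
    return matrix, mean_profile


def tss_group_profiles(coverage: pd.DataFrame, tss: pd.DataFrame,
                       gene_sets: dict[str, list[str]],
                       flank: int = 1500, step: int = 50,
                       chrom_lengths: dict[str, int] | None = None,
                       ) -> pd.DataFrame:
    """One mean TSS profile per named gene set (columns), e.g. the
    cancer-specific escapees of each cell line."""
    matrix, _ = tss_profile(coverage, tss, flank, step, chrom_lengths)
    cols = {}
    for name, genes in gene_sets.items():
        sub = matrix.loc[matrix.index.intersection(genes)].dropna()
        cols[name] = (sub.mean(axis=0) if len(sub)
                      else pd.Series(np.nan, index=matrix.columns))
    return pd.DataFrame(cols)


def domain_enrichment(track: pd.DataFrame, domains: pd.DataFrame,
                      min_overlap: float = 0.5) -> pd.DataFrame:
    """Mean binned signal inside vs outside labeled domains.

    A bin counts as inside a label when at least ``min_overlap`` of its
    width overlaps that label's intervals; outside bins overlap no interval
    of any label.  When no bin lies outside, the ratio is undefined and
    flagged.  Returns one row per label: mean_in, mean_out, ratio, n_in,
    n_out, defined.
    """
    starts = track.start.values
    ends = track.end.values
    widths = (ends - starts).astype(float)
    values = track.value.values.astype(float)
    chroms = track.chrom.values

    def overlap_frac(sub: pd.DataFrame) -> np.ndarray:
        ov = np.zeros(len(track))
        for d in sub.itertuples():
            same = chroms == d.chrom
            lo = np.maximum(starts, d.start)
            hi = np.minimum(ends, d.end)
            ov += np.where(same, np.clip(hi - lo, 0, None), 0.0)
        return ov / widths

    any_overlap = np.zeros(len(track), dtype=bool)
    in_masks = {}
    for label, sub in domains.groupby("label", sort=True):
        frac = overlap_frac(sub)
        in_masks[label] = frac >= min_overlap
        any_overlap |= frac > 0
    outside = ~any_overlap

    rows = []
    mean_out = float(values[outside].mean()) if outside.any() else np.nan
    for label, mask in in_masks.items():
        mean_in = float(values[mask].mean()) if mask.any() else np.nan
        defined = outside.any() and mask.any() and mean_out != 0
        rows.append({
            "label": label,
            "mean_in": mean_in,
            "mean_out": mean_out,
            "ratio": mean_in / mean_out if defined else np.nan,
            "n_in": int(mask.sum()),
            "n_out": int(outside.sum()),
            "defined": bool(defined),
        })
    return pd.DataFrame(rows)
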