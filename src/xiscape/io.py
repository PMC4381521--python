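"""Readers and writers for the plain-text formats the pipeline exchanges.

Conventions: TSV coordinates are 1-based inclusive; BED and bedGraph are
0-based half-open.  Images are written as multipage TIFF stacks and masks
as 8-bit PNGs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd


def write_tsv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def write_gene_bed(genes: pd.DataFrame, path) -> Path:
    """6-column BED from a 1-based inclusive gene table."""
    bed = pd.DataFrame({
        "chrom": genes.chrom,
        "start": genes.start - 1,
        "end": genes.end,
        "name": genes.gene_id,
        "score": 0,
        "strand": genes.get("strand", "+"),
    })
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    bed.to_csv(path, sep="\t", index=False, header=False)
    return path


def read_gene_bed(path) -> pd.DataFrame:
    """Read a 4+-column BED into a 1-based inclusive gene table."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                      dtype={0: str})
    ncol = bed.shape[1]
    out = pd.DataFrame({
        "gene_id": bed[3] if ncol > 3 else [f"g{i}" for i in range(len(bed))],
        "chrom": bed[0],
        "start": bed[1] + 1,
        "end": bed[2],
    })
    out["strand"] = bed[5] if ncol > 5 else "+"
    return out


def gene_tss(genes: pd.DataFrame) -> pd.DataFrame:
    """0-based TSS per gene from a 1-based inclusive gene table."""
    plus = genes.get("strand", pd.Series("+", index=genes.index)) != "-"
    return pd.DataFrame({
        "gene_id": genes.gene_id,
        "chrom": genes.chrom,
        "tss": np.where(plus, genes.start - 1, genes.end - 1),
        "strand": np.where(plus, "+", "-"),
    })


def write_bed(intervals: pd.DataFrame, path, cols=("chrom", "start", "end", "label")) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    intervals.loc[:, list(c for c in cols if c in intervals.columns)].to_csv(
        path, sep="\t", index=False, header=False)
    return path


def read_domain_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "label"],
                     dtype={"chrom": str})
    return df


def write_bedgraph(track: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    track[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", index=False, header=False)
    return path


def read_loh_segments(path) -> list[tuple[str, int, int]]:
    """LOH segments from a 3-column TSV/BED-like file (chrom, start, end),
    interpreted as 1-based inclusive."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={"chrom": str})
    return [(r.chrom, int(r.start), int(r.end)) for r in df.itertuples()]


def write_truth_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=1, default=default))
    return path


def write_image_stack(stack: np.ndarray, path) -> Path:
    import tifffile

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.astype(np.float32))
    return path


def read_image_stack(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path)


def write_mask_stack(masks: np.ndarray, path) -> Path:
    import tifffile

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, (masks.astype(np.uint8) * 255))
    return path


def read_mask_stack(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path) > 0
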