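"""Ground-truth simulators for every stage of the Xi-reactivation pipeline.

The generators emulate the statistical structure that the downstream analyses
assume in clonal female cells:

* an X chromosome expressed monoallelically from the active X (Xa), apart
  from pseudoautosomal (PAR) genes and constitutive escapees that retain
  partial expression from the inactive X (Xi);
* an all-biallelic autosome as an internal control;
* cancer samples carrying a planted set of "cancer-specific" reactivated
  genes (normally silenced on the Xi, biallelic only in the cancer sample);
* loss-of-heterozygosity (LOH) segments that erase allelic information;
* two-channel array intensities with multiplicative lognormal noise on the
  hybridization signal plus an additive background floor;
* allele-specific read counts with negative-binomial depth and binomial
  allele sampling;
* chromosome-scale chromatin tracks with blocky repressive domains, and a
  perturbed counterpart with flattened or regionally lost domains;
* single nuclei with an elliptical nucleus, a disk-shaped XIST domain with a
  planted intensity contrast, and Gaussian detection noise;
* per-nucleus tumor FISH tables with Bernoulli XIST-domain presence and
  in-domain gene signals.

Every generator is a pure function of ``(config, seed)``: the same
configuration yields byte-identical tables on rerun.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, fields, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SampleSpec",
    "GroundTruth",
    "simulate_annotation",
    "simulate_clone",
    "simulate_snp6_intensities",
    "simulate_ase_counts",
    "simulate_chip_tracks",
    "simulate_nuclei",
    "simulate_tumor_table",
]

X_CHROM = "chrX"
AUTOSOME = "chr2"  # all-biallelic control chromosome

GENE_LENGTH = 20_000
GENE_GAP = 5_000


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with defaults set to the study
    conditions the pipeline is meant to recover (300 X-linked genes, 15%
    constitutive escapees, 10 planted reactivations per cancer sample,
    mean sequencing depth 50 reads per SNP, twofold imaging contrast)."""

    seed: int = 0
    # gene / SNP annotation
    n_genes_x: int = 300
    n_genes_autosome: int = 100
    snps_per_gene: tuple[int, int] = (3, 8)
    frac_par: float = 0.05
    frac_constitutive_escapee: float = 0.15
    frac_silent_genes: float = 0.4
    # allelic structure
    n_cancer_reactivated_per_sample: int = 10
    xi_leak_fraction: float = 0.01
    escapee_xi_fraction_range: tuple[float, float] = (0.15, 0.5)
    loh_segments: list[tuple[str, int, int]] = field(default_factory=list)
    # RNA-seq allele counting
    mean_depth: float = 50.0
    depth_dispersion: float = 0.2
    # nascent-RNA array channels
    base_expression: float = 1000.0
    expression_sigma: float = 0.5
    array_noise_sigma: float = 0.25
    array_background: float = 50.0
    # chromatin tracks
    track_chrom: str = X_CHROM
    track_chrom_length: int = 20_000_000
    track_bin_size: int = 100_000
    n_domains: int = 4
    domain_contrast: float = 3.0
    track_noise_sigma: float = 0.1
    # nucleus images
    image_shape: tuple[int, int] = (128, 128)
    nucleus_radii: tuple[float, float] = (48.0, 40.0)
    domain_radius: float = 12.0
    domain_contrast_ratio: float = 2.0
    image_background: float = 100.0
    image_noise_sd: float = 10.0
    # tumor FISH cohort
    n_tumors: int = 40
    n_nuclei: int = 100
    frac_xist_nuclei: float = 0.3
    frac_reactivated_nuclei: float = 0.1
    frac_outside_signal: float = 0.2
    fish_genes: tuple[str, ...] = ("HDAC8", "ATRX", "TBL1X")

    def __post_init__(self) -> None:
        for name in ("frac_par", "frac_constitutive_escapee",
                     "frac_silent_genes", "xi_leak_fraction",
                     "frac_xist_nuclei", "frac_reactivated_nuclei",
                     "frac_outside_signal"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]; got {v}")
        lo, hi = self.escapee_xi_fraction_range
        if not (0.0 < lo < hi <= 0.5):
            # escapees are expressed from the Xi at a lower level than from
            # the Xa, so their Xi fraction stays strictly below one half
            raise ValueError(
                "escapee_xi_fraction_range must satisfy 0 < lo < hi <= 0.5")
        for name in ("n_genes_x", "n_genes_autosome",
                     "n_cancer_reactivated_per_sample", "n_tumors",
                     "n_nuclei"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        a, b = self.snps_per_gene
        if not 1 <= a <= b:
            raise ValueError("snps_per_gene must be a range with 1 <= lo <= hi")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.depth_dispersion < 0:
            raise ValueError("depth_dispersion must be >= 0")
        if self.array_background < 0:
            raise ValueError("array channel background must be >= 0")
        if self.array_noise_sigma < 0 or self.track_noise_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")
        if self.track_bin_size > self.track_chrom_length:
            raise ValueError("track bin size exceeds chromosome length")
        if self.domain_contrast_ratio <= 0:
            raise ValueError("domain contrast ratio must be > 0")
        h, w = self.image_shape
        ry, rx = self.nucleus_radii
        if 2 * self.domain_radius >= 2 * min(ry, rx):
            raise ValueError("XIST domain does not fit inside the nucleus")
        if 2 * ry >= h or 2 * rx >= w:
            raise ValueError("nucleus does not fit inside the image")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("snps_per_gene", "escapee_xi_fraction_range",
                    "image_shape", "nucleus_radii", "fish_genes"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if "loh_segments" in d:
            d["loh_segments"] = [tuple(s) for s in d["loh_segments"]]
        return cls(**d)


@dataclass
class SampleSpec:
    """One simulated sample: a normal clone or a cancer line, with a named
    Xi haplotype (maternal or paternal)."""

    sample_id: str
    xi_haplotype: str = "maternal"
    sample_class: str = "normal"  # or "cancer"
    loh_segments: list[tuple[str, int, int]] | None = None

    def __post_init__(self) -> None:
        if self.xi_haplotype not in ("maternal", "paternal"):
            raise ValueError("xi_haplotype must be 'maternal' or 'paternal'")
        if self.sample_class not in ("normal", "cancer"):
            raise ValueError("sample_class must be 'normal' or 'cancer'")


@dataclass
class GroundTruth:
    """Per-sample truth: gene-level Xi-allele fractions and statuses, the
    SNP phase map (which array allele sits on which haplotype), and the
    LOH segments active in this sample."""

    sample_id: str
    sample_class: str
    xi_haplotype: str
    genes: pd.DataFrame  # gene_id, chrom, start, end, xci_status, expressed, xi_fraction
    snps: pd.DataFrame   # snp_id, gene_id, chrom, pos, hap1_allele
    loh_segments: list[tuple[str, int, int]]

    @property
    def reactivated_genes(self) -> list[str]:
        g = self.genes
        return sorted(g.loc[g.xci_status == "cancer_reactivated", "gene_id"])


def _rng(config: SimulationConfig, *labels: str) -> np.random.Generator:
    """Deterministic child generator keyed on the config seed and a label."""
    keys = [zlib.crc32(lab.encode()) for lab in labels]
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, *keys])


# ---------------------------------------------------------------------------
# annotation

def simulate_annotation(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tile non-overlapping genes on chrX and one control autosome and drop
    SNPs at distinct positions inside each gene.

    Returns ``(genes, snps)``.  Gene coordinates are 1-based inclusive.
    PAR genes sit at the two extremities of chrX; constitutive escapees are
    drawn among the remaining X genes; every other X gene is subject to XCI.
    The autosome is entirely biallelic ("autosomal" status).  Each gene also
    carries an ``expressed`` flag (nascent transcription detectable) and, for
    escapees, a stable per-gene Xi expression fraction.
    """
    if config.n_genes_x <= 0:
        raise ValueError("n_genes_x must be positive")
    rng = _rng(config, "annotation")

    rows = []
    pitch = GENE_LENGTH + GENE_GAP
    for chrom, n in ((X_CHROM, config.n_genes_x),
                     (AUTOSOME, config.n_genes_autosome)):
        for i in range(n):
            start = 1 + i * pitch
            rows.append({
                "gene_id": f"{chrom.replace('chr', 'g')}_{i:04d}",
                "chrom": chrom,
                "start": start,
                "end": start + GENE_LENGTH - 1,
                "strand": "+" if rng.random() < 0.5 else "-",
            })
    genes = pd.DataFrame(rows)

    # statuses on chrX: PAR at both extremities, escapees among the rest
    x_mask = genes.chrom == X_CHROM
    x_idx = genes.index[x_mask]
    n_par = int(round(config.frac_par * config.n_genes_x))
    par_idx = list(x_idx[: (n_par + 1) // 2]) + list(x_idx[len(x_idx) - n_par // 2:])
    status = pd.Series("autosomal", index=genes.index)
    status[x_idx] = "subject"
    status[par_idx] = "PAR"
    non_par = [i for i in x_idx if i not in set(par_idx)]
    n_esc = min(int(round(config.frac_constitutive_escapee * config.n_genes_x)),
                len(non_par))
    esc_idx = rng.choice(non_par, size=n_esc, replace=False) if n_esc else []
    status[esc_idx] = "constitutive_escapee"
    genes["xci_status"] = status

    genes["expressed"] = rng.random(len(genes)) >= config.frac_silent_genes
    xi_frac = np.full(len(genes), np.nan)
    lo, hi = config.escapee_xi_fraction_range
    xi_frac[genes.index.isin(esc_idx)] = rng.uniform(lo, hi, size=len(esc_idx))
    genes["escapee_xi_fraction"] = xi_frac

    # SNPs: distinct 1-based positions inside each gene, one haplotype-phase
    # label per SNP (the array allele carried by haplotype 1 = maternal)
    lo_s, hi_s = config.snps_per_gene
    snp_rows = []
    for g in genes.itertuples():
        n_snps = int(rng.integers(lo_s, hi_s + 1))
        pos = np.sort(rng.choice(
            np.arange(g.start, g.end + 1), size=n_snps, replace=False))
        for j, p in enumerate(pos):
            snp_rows.append({
                "snp_id": f"{g.gene_id}_s{j}",
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "pos": int(p),
                "hap1_allele": "A" if rng.random() < 0.5 else "B",
            })
    snps = pd.DataFrame(snp_rows)
    return genes, snps


# ---------------------------------------------------------------------------
# per-sample allelic truth

def simulate_clone(config: SimulationConfig, sample_spec: SampleSpec,
                   annotation: tuple[pd.DataFrame, pd.DataFrame] | None = None,
                   ) -> GroundTruth:
    """Derive one sample's allelic ground truth from the shared annotation.

    Normal clones express every subject gene from the Xa haplotype only (Xi
    fraction = ``xi_leak_fraction``); two clones with opposite Xi haplotypes
    therefore show mirrored monoallelic phase.  Cancer samples additionally
    carry exactly ``n_cancer_reactivated_per_sample`` planted reactivated
    genes drawn from the expressed subject genes, with Xi fractions drawn
    from the escapee range.
    """
    if annotation is None:
        annotation = simulate_annotation(config)
    genes, snps = annotation
    genes = genes.copy()

    xi_fraction = np.where(
        genes.xci_status.isin(["PAR", "autosomal"]), 0.5,
        np.where(genes.xci_status == "constitutive_escapee",
                 genes.escapee_xi_fraction, config.xi_leak_fraction))
    genes["xi_fraction"] = xi_fraction
    status = genes.xci_status.copy()

    if sample_spec.sample_class == "cancer":
        pool = genes.index[(genes.xci_status == "subject") & genes.expressed]
        n_react = config.n_cancer_reactivated_per_sample
        if n_react > len(pool):
            raise ValueError(
                f"requested {n_react} reactivated genes but only "
                f"{len(pool)} expressed subject genes are available")
        rng = _rng(config, "clone", sample_spec.sample_id)
        picked = rng.choice(pool, size=n_react, replace=False)
        lo, hi = config.escapee_xi_fraction_range
        genes.loc[picked, "xi_fraction"] = rng.uniform(lo, hi, size=n_react)
        status[picked] = "cancer_reactivated"
    genes["xci_status"] = status

    loh = sample_spec.loh_segments
    if loh is None:
        loh = list(config.loh_segments) if sample_spec.sample_class == "cancer" else []
    return GroundTruth(
        sample_id=sample_spec.sample_id,
        sample_class=sample_spec.sample_class,
        xi_haplotype=sample_spec.xi_haplotype,
        genes=genes,
        snps=snps.copy(),
        loh_segments=[tuple(s) for s in loh],
    )


def _in_segments(chrom: pd.Series, pos: pd.Series,
                 segments: Sequence[tuple[str, int, int]]) -> np.ndarray:
    """1-based inclusive membership of positions in a segment union."""
    hit = np.zeros(len(pos), dtype=bool)
    for c, s, e in segments:
        hit |= (chrom.values == c) & (pos.values >= s) & (pos.values <= e)
    return hit


def _xi_allele(truth: GroundTruth) -> np.ndarray:
    """Per SNP, the array allele ('A'/'B') residing on the Xi haplotype.

    For autosomes there is no Xi; the 'Xi allele' is simply the haplotype-1
    allele so that the biallelic 0.5 fraction is split phase-consistently.
    """
    hap1 = truth.snps.hap1_allele.values
    other = np.where(hap1 == "A", "B", "A")
    on_x = (truth.snps.chrom == X_CHROM).values
    if truth.xi_haplotype == "maternal":
        xi = hap1.copy()
    else:
        xi = other.copy()
    xi[~on_x] = hap1[~on_x]
    return xi


# ---------------------------------------------------------------------------
# nascent-RNA SNP array intensities

def simulate_snp6_intensities(truth: GroundTruth, config: SimulationConfig,
                              ) -> pd.DataFrame:
    """Two-channel intensities emulating nascent-RNA hybridization to a SNP
    array after upstream genotyping.

    Per SNP, each channel carries (gene expression x allele fraction x
    lognormal noise) + additive background.  Genotypes are heterozygous
    except inside LOH segments, where the Xi allele is lost: the genotype is
    forced homozygous for the retained (Xa) allele and the lost channel falls
    to background.
    """
    if config.array_background < 0:
        raise ValueError("background must be >= 0")
    rng = _rng(config, "snp6", truth.sample_id)
    snps = truth.snps.merge(
        truth.genes[["gene_id", "xi_fraction", "expressed"]], on="gene_id")

    # per-gene expression level for this sample (0 for silent genes)
    gene_ids = truth.genes.gene_id.values
    expr = np.exp(rng.normal(np.log(config.base_expression),
                             config.expression_sigma, size=len(gene_ids)))
    expr_map = dict(zip(gene_ids, expr * truth.genes.expressed.values))
    e = snps.gene_id.map(expr_map).values

    xi_allele = _xi_allele(truth)
    f_xi = snps.xi_fraction.values
    loh = _in_segments(snps.chrom, snps.pos, truth.loh_segments)
    f_xi = np.where(loh, 0.0, f_xi)  # Xi allele genomically lost

    def noise(n: int) -> np.ndarray:
        if config.array_noise_sigma == 0:
            return np.ones(n)
        return np.exp(rng.normal(0.0, config.array_noise_sigma, size=n))

    sig_xi = e * f_xi * noise(len(snps))
    sig_xa = e * (1.0 - f_xi) * noise(len(snps))
    # background floor with continuous upward jitter (vanishes at sigma=0),
    # so channel >= background always holds and totals are tie-free
    bg = config.array_background

    def floor(n: int) -> np.ndarray:
        return bg * (1.0 + rng.uniform(0, config.array_noise_sigma, size=n))

    channel_a = np.where(xi_allele == "A", sig_xi, sig_xa) + floor(len(snps))
    channel_b = np.where(xi_allele == "B", sig_xi, sig_xa) + floor(len(snps))

    xa_allele = np.where(xi_allele == "A", "B", "A")
    genotype = np.where(loh, np.char.add(xa_allele, xa_allele), "AB")
    out = pd.DataFrame({
        "snp_id": snps.snp_id,
        "chrom": snps.chrom,
        "pos": snps.pos,
        "genotype": genotype,
        "channel_a": channel_a,
        "channel_b": channel_b,
        "seg_major_cn": np.where(loh, 2, 1),
        "seg_minor_cn": np.where(loh, 0, 1),
    })
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# RNA-seq allele counts

def simulate_ase_counts(truth: GroundTruth, config: SimulationConfig,
                        ) -> pd.DataFrame:
    """Per-SNP haplotype-resolved read counts.

    Depth per heterozygous SNP is negative-binomial with mean ``mean_depth``
    and dispersion ``depth_dispersion`` (variance m + d m^2; Poisson when
    d = 0); the Xi-haplotype count is Binomial(depth, gene Xi fraction).
    Silent genes receive zero reads; SNPs inside LOH segments are not
    heterozygous and are omitted.
    """
    if config.mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = _rng(config, "ase", truth.sample_id)
    snps = truth.snps.merge(
        truth.genes[["gene_id", "xi_fraction", "expressed"]], on="gene_id")
    loh = _in_segments(snps.chrom, snps.pos, truth.loh_segments)
    snps = snps.loc[~loh].reset_index(drop=True)

    m = config.mean_depth
    d = config.depth_dispersion
    n = len(snps)
    if d > 0:
        size = 1.0 / d
        depth = rng.negative_binomial(size, size / (size + m), size=n)
    else:
        depth = rng.poisson(m, size=n)
    depth = np.where(snps.expressed.values, depth, 0)

    xi_count = rng.binomial(depth, snps.xi_fraction.values)
    xa_count = depth - xi_count
    xi_is_hap1 = (truth.xi_haplotype == "maternal") | \
        (snps.chrom != X_CHROM).values  # autosomes: hap1 takes the 'xi' share
    hap1 = np.where(xi_is_hap1, xi_count, xa_count)
    hap2 = depth - hap1
    out = pd.DataFrame({
        "gene_id": snps.gene_id,
        "snp_id": snps.snp_id,
        "chrom": snps.chrom,
        "pos": snps.pos,
        "hap1_count": hap1,
        "hap2_count": hap2,
    })
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# chromatin tracks

def simulate_chip_tracks(config: SimulationConfig,
                         ) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, dict]:
    """Blocky repressive-domain coverage along one chromosome.

    Returns ``(tracks, domains, truth)`` where ``tracks`` maps
    ``"normal"``/``"perturbed"`` to binned bedGraph-style frames
    (chrom, start, end, value; 0-based half-open), ``domains`` is a BED-style
    frame with alternating H3K27me3/H3K9me3 labels, and ``truth`` records the
    planted contrast and the perturbed regions.

    The perturbed track models epigenetic erosion: domains in the second half
    of the chromosome are flattened to baseline, and the first 10% of the
    chromosome is zeroed (regional genetic loss of the Xi).
    """
    L, bs = config.track_chrom_length, config.track_bin_size
    if bs > L:
        raise ValueError("bin size exceeds chromosome length")
    n_bins = int(np.ceil(L / bs))
    starts = np.arange(n_bins, dtype=np.int64) * bs
    ends = np.minimum(starts + bs, L)

    # alternating segments: odd segments are domains
    n_seg = 2 * config.n_domains + 1
    seg_edges = np.linspace(0, L, n_seg + 1).astype(np.int64)
    dom_rows = []
    labels = ["H3K27me3", "H3K9me3"]
    for k in range(config.n_domains):
        s, e = seg_edges[2 * k + 1], seg_edges[2 * k + 2]
        dom_rows.append({"chrom": config.track_chrom, "start": int(s),
                         "end": int(e), "label": labels[k % 2]})
    domains = pd.DataFrame(dom_rows)

    centers = (starts + ends) / 2.0
    in_domain = np.zeros(n_bins, dtype=bool)
    for r in dom_rows:
        in_domain |= (centers >= r["start"]) & (centers < r["end"])
    base = np.where(in_domain, config.domain_contrast, 1.0)

    zero_region = (0, int(0.1 * L))
    flatten_from = int(0.5 * L)
    perturbed = base.copy()
    perturbed[(centers >= flatten_from) & in_domain] = 1.0
    perturbed[(centers >= zero_region[0]) & (centers < zero_region[1])] = 0.0

    rng = _rng(config, "chip")

    def make(values: np.ndarray, tag: str) -> pd.DataFrame:
        noise_rng = _rng(config, "chip-noise", tag)
        if config.track_noise_sigma > 0:
            values = values * np.exp(noise_rng.normal(
                0.0, config.track_noise_sigma, size=n_bins))
        return pd.DataFrame({"chrom": config.track_chrom, "start": starts,
                             "end": ends, "value": values})

    tracks = {"normal": make(base, "normal"),
              "perturbed": make(perturbed, "perturbed")}
    truth = {"contrast": config.domain_contrast,
             "zero_region": zero_region,
             "flattened_from": flatten_from,
             "in_domain": in_domain}
    del rng
    return tracks, domains, truth


# ---------------------------------------------------------------------------
# nucleus images

def simulate_nuclei(config: SimulationConfig, n: int,
                    ) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray,
                               pd.DataFrame]:
    """Synthetic single-nucleus images with a planted XIST-domain contrast.

    Returns ``(channels, nucleus_masks, domain_masks, truth)`` where
    ``channels`` maps ``"mark"`` and ``"coloc"`` to float stacks of shape
    (n, H, W), the masks are boolean stacks, and ``truth`` records the
    planted contrast per nucleus.  The mark channel has mean
    ``contrast x background`` inside the domain and ``background`` in the
    rest of the nucleus, plus Gaussian noise; the second channel shares the
    same spatial structure (scaled) with independent noise, for
    colocalization tests.
    """
    if config.domain_contrast_ratio <= 0:
        raise ValueError("contrast must be > 0")
    rng = _rng(config, "nuclei")
    h, w = config.image_shape
    ry, rx = config.nucleus_radii
    yy, xx = np.mgrid[0:h, 0:w]

    mark = np.zeros((n, h, w))
    coloc = np.zeros((n, h, w))
    nuc_masks = np.zeros((n, h, w), dtype=bool)
    dom_masks = np.zeros((n, h, w), dtype=bool)
    rows = []
    for i in range(n):
        cy = h / 2 + rng.uniform(-3, 3)
        cx = w / 2 + rng.uniform(-3, 3)
        nuc = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        # place the domain fully inside the nucleus
        max_off = min(ry, rx) - config.domain_radius - 2
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0, max(max_off, 0))
        dy, dx = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
        dom = ((yy - dy) ** 2 + (xx - dx) ** 2 <= config.domain_radius ** 2) & nuc

        bg = config.image_background
        img = np.where(dom, config.domain_contrast_ratio * bg, bg) * nuc
        img2 = 0.8 * img
        if config.image_noise_sd > 0:
            img = img + rng.normal(0, config.image_noise_sd, size=(h, w))
            img2 = img2 + rng.normal(0, config.image_noise_sd, size=(h, w))
        mark[i] = np.clip(img, 0, None)
        coloc[i] = np.clip(img2, 0, None)
        nuc_masks[i] = nuc
        dom_masks[i] = dom
        rows.append({"nucleus_id": f"nuc_{i:03d}",
                     "contrast": config.domain_contrast_ratio,
                     "n_domains": 1,
                     "domain_area_px": int(dom.sum())})
    return {"mark": mark, "coloc": coloc}, nuc_masks, dom_masks, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# tumor FISH tables

def simulate_tumor_table(config: SimulationConfig,
                         ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-nucleus FISH scoring tables for a simulated tumor cohort.

    Returns ``(records, subtypes, truth)``.  Per nucleus, XIST-domain
    presence is Bernoulli(``frac_xist_nuclei``); in domain-bearing nuclei
    each scored gene shows an in-domain nascent signal with probability
    ``frac_reactivated_nuclei``, independently across nuclei.  Signals
    outside the domain (presumed Xa expression) occur with probability
    ``frac_outside_signal`` in any nucleus.
    """
    rng = _rng(config, "tumor")
    subtypes_cycle = ["Luminal", "HER2", "BLC"]
    rec_rows = []
    sub_rows = []
    truth_rows = []
    for t in range(config.n_tumors):
        tumor_id = f"T{t + 1:03d}"
        subtype = subtypes_cycle[int(rng.integers(0, 3))]
        sub_rows.append({"tumor_id": tumor_id, "subtype": subtype})
        has_domain = rng.random(config.n_nuclei) < config.frac_xist_nuclei
        for gene in config.fish_genes:
            in_dom = has_domain & (
                rng.random(config.n_nuclei) < config.frac_reactivated_nuclei)
            out_dom = rng.random(config.n_nuclei) < config.frac_outside_signal
            for i in range(config.n_nuclei):
                rec_rows.append({
                    "tumor_id": tumor_id,
                    "nucleus_id": f"{tumor_id}_n{i:04d}",
                    "n_xist_domains": int(has_domain[i]),
                    "gene": gene,
                    "signal_in_domain": bool(in_dom[i]),
                    "signal_outside_domain": bool(out_dom[i]),
                })
        truth_rows.append({
            "tumor_id": tumor_id, "subtype": subtype,
            "true_frac_xist": config.frac_xist_nuclei,
            "true_frac_reactivated": config.frac_reactivated_nuclei,
            "obs_frac_xist": float(has_domain.mean()),
        })
    return (pd.DataFrame(rec_rows), pd.DataFrame(sub_rows),
            pd.DataFrame(truth_rows))
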