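"""Numeric thresholds used across the allelic-expression and scoring pipelines.

All cutoffs that enter a biological call live here, in one configurable
container, so that every rule is explicit and overridable:

* ``snp_minor_fraction`` — a SNP is biallelically expressed when its minor
  channel/allele carries at least this fraction of the total signal.
* ``gene_biallelic_snp_fraction`` — a gene is monoallelic when *strictly less*
  than this fraction of its expressed informative SNPs are biallelic.
* ``rnaseq_ratio_cutoff`` — a gene is monoallelic by RNA-seq when its allelic
  expression ratio (100 x minor reads / per-allele mean reads, i.e.
  200 x minor fraction) is strictly below this value.
* ``xist_pos_frac`` / ``react_frac`` — tumor-level FISH calling fractions.

Defaults reproduce the published calling rules (<2/3 biallelic SNPs, ratio
<40, XIST-positive at >=10% of nuclei, reactivated at >=5% of nuclei,
50-SNP windows, 1-Mb bins, +/-1.5 kb TSS flanks).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields


@dataclass
class Thresholds:
    # nascent-RNA SNP array
    expr_quantile: float = 0.5
    expr_absolute: float | None = None  # overrides the quantile when set
    snp_minor_fraction: float = 0.20
    gene_biallelic_snp_fraction: float = 2.0 / 3.0
    window_size: int = 50
    window_step: int = 1
    window_members: str = "informative"  # or "all"
    min_informative_snps_per_gene: int = 1
    clonal_fraction: float = 0.95
    # RNA-seq ASE
    rnaseq_ratio_cutoff: float = 40.0
    min_gene_reads: int = 20
    # cohort / escape calling
    min_het_fraction: float = 0.10
    min_recurrent_samples: int = 2
    # tumor FISH
    xist_pos_frac: float = 0.10
    react_frac: float = 0.05
    xist_rule_inclusive: bool = True  # >= vs strict > for XIST positivity
    react_denominator: str = "all"  # or "xist_positive"
    # chromatin tracks
    bin_size: int = 1_000_000
    tss_flank: int = 1500
    tss_step: int = 50
    log_ratio_pseudocount: float = 1.0
    domain_bin_overlap: float = 0.5

    def __post_init__(self) -> None:
        for name in ("expr_quantile", "snp_minor_fraction",
                     "gene_biallelic_snp_fraction", "clonal_fraction",
                     "min_het_fraction", "xist_pos_frac", "react_frac",
                     "domain_bin_overlap"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1); got {v}")
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if self.window_step < 1:
            raise ValueError("window_step must be >= 1")
        if self.window_members not in ("informative", "all"):
            raise ValueError("window_members must be 'informative' or 'all'")
        if self.react_denominator not in ("all", "xist_positive"):
            raise ValueError(
                "react_denominator must be 'all' or 'xist_positive'")
        if self.rnaseq_ratio_cutoff <= 0 or self.rnaseq_ratio_cutoff > 100:
            raise ValueError("rnaseq_ratio_cutoff must lie in (0, 100]")
        if self.bin_size < 1 or self.tss_flank < 1 or self.tss_step < 1:
            raise ValueError("bin_size, tss_flank and tss_step must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "Thresholds":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        return cls(**d)
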