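import numpy as np
import pandas as pd
import pytest

import xiscape as x


@pytest.fixture(scope="session")
def small_config():
    return x.SimulationConfig(seed=11, n_genes_x=60, n_genes_autosome=20,
                              n_cancer_reactivated_per_sample=4)


@pytest.fixture(scope="session")
def small_annotation(small_config):
    return x.simulate_annotation(small_config)


@pytest.fixture(scope="session")
def exact_config():
    """Noise-free, fully expressed conditions: allelic structure is exactly
    recoverable from the array channels."""
    return x.SimulationConfig(
        seed=7, n_genes_x=60, n_genes_autosome=20,
        n_cancer_reactivated_per_sample=4,
        frac_silent_genes=0.0, expression_sigma=0.0,
        array_noise_sigma=0.0, array_background=0.0)


@pytest.fixture(scope="session")
def study_config():
    """The default study conditions: 300 X genes, 15% constitutive
    escapees, 10 planted reactivations per cancer sample, depth 50."""
    return x.SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def study_samples(study_config):
    annotation = x.simulate_annotation(study_config)
    specs = [
        x.SampleSpec("clone_1", "maternal", "normal"),
        x.SampleSpec("clone_28", "paternal", "normal"),
        x.SampleSpec("cancer_1", "maternal", "cancer"),
        x.SampleSpec("cancer_2", "maternal", "cancer"),
        x.SampleSpec("cancer_3", "maternal", "cancer"),
    ]
    truths = {s.sample_id: x.simulate_clone(study_config, s, annotation)
              for s in specs}
    return annotation, truths


@pytest.fixture(scope="session")
def reference_annotation(study_samples):
    """XCI reference-status map derived from the simulated ground truth
    (stands in for the published escape surveys)."""
    (genes, _), _ = study_samples
    out = {}
    for g in genes.itertuples():
        if g.xci_status == "subject":
            out[g.gene_id] = "subject"
        elif g.xci_status == "constitutive_escapee":
            out[g.gene_id] = "escapee"
    return out


def make_calls(snp_rows):
    """Small helper: build a per-SNP call frame from
    (snp_id, chrom, pos, expressed, informative, allelic_class) tuples."""
    df = pd.DataFrame(snp_rows, columns=[
        "snp_id", "chrom", "pos", "expressed", "informative",
        "allelic_class"])
    df["minor_channel_fraction"] = np.nan
    df["major_channel"] = "A"
    return df
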