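from pathlib import Path

import pandas as pd
import pytest

from meiowave.simulate import default_params

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def params():
    """Default study conditions (panel, wave timing, noise)."""
    return default_params()


@pytest.fixture(scope="session")
def fixture_paths():
    return {
        "counts": DATA / "fixture_counts.tsv",
        "samples": DATA / "fixture_samples.tsv",
        "lengths": DATA / "fixture_gene_lengths.tsv",
    }


@pytest.fixture(scope="session")
def fixture_de():
    """DE tables and FPKM for the 8-gene cascade fixture, via the library."""
    from meiowave import rnaseq
    from meiowave.io import read_count_matrix

    cm = read_count_matrix(DATA / "fixture_counts.tsv",
                           DATA / "fixture_samples.tsv",
                           DATA / "fixture_gene_lengths.tsv")
    meta = cm.sample_meta
    fpkm = rnaseq.compute_fpkm(cm)

    def ids(**criteria):
        sel = pd.Series(True, index=meta.index)
        for key, val in criteria.items():
            sel &= meta[key] == val
        return list(meta.index[sel])

    de = {}
    for age in (12.5, 14.5, 16.5):
        de[f"s2_E{age}"] = rnaseq.de_contrast(
            cm, ids(tissue="ovary", genotype="wildtype", age=age),
            ids(tissue="ovary", genotype="kit_null", age=age))
    de["s3"] = rnaseq.de_contrast(
        cm, ids(tissue="ovary", genotype="wildtype", age=14.5),
        ids(tissue="testis", genotype="wildtype", age=14.5))
    for age in (14.5, 16.5):
        de[f"s4_E{age}"] = rnaseq.de_contrast(
            cm, ids(tissue="ovary", genotype="wildtype", age=age),
            ids(tissue="ovary", genotype="wildtype", age=12.5))
    config = rnaseq.FilterConfig(
        stage2_contrasts=("s2_E12.5", "s2_E14.5", "s2_E16.5"),
        stage3_contrast="s3",
        stage4_contrasts=("s4_E14.5", "s4_E16.5"),
    )
    return fpkm, meta, de, config
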