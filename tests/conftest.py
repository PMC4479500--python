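import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from gctmethyl.synthetic import GroupSpec, PlantedDmr, SyntheticSpec, generate_cohort

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


def small_spec(**overrides) -> SyntheticSpec:
    """Desk-scale two-group cohort with two planted blocks, for fast tests."""
    defaults = dict(
        groups=(
            GroupSpec("A", 8, "M", "bimodal"),
            GroupSpec("B", 8, "M", "intermediate"),
        ),
        n_probes_per_chrom=(("1", 1200), ("2", 1000)),
        planted_dmrs=(
            PlantedDmr("A", "B", "hyperA", "1"),
            PlantedDmr("A", "B", "hyperA", "2"),
        ),
    )
    defaults.update(overrides)
    return SyntheticSpec(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_spec(), seed=7)


@pytest.fixture()
def toy_manifest_frame():
    """Five probes on two chromosomes, deliberately unsorted."""
    return pd.DataFrame(
        {
            "probe_id": [f"cg{i}" for i in range(5)],
            "chrom": ["2", "1", "1", "X", "2"],
            "pos": [500, 900, 100, 50, 100],
            "strand": ["+", "-", "+", "+", "-"],
            "gene_symbols": ["G1", "G2", "G2", "G3", "G1"],
            "tss_distance_class": ["TSS200", "none", "TSS1500", "none", "none"],
            "region_classes": ["EXON1", "GENE.BODY", "5'UTR;GENE.BODY", "3'UTR", "GENE.BODY"],
            "island": [True, False, True, False, False],
            "repeat_class": ["none", "LINE", "none", "SINE", "none"],
            "mir": [False, False, True, False, False],
            "snrna": [False, False, False, True, False],
        }
    )


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
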