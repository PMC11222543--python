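import pytest

from sangerase.synthetic_data import (
    GenePlacement,
    LocusFixtureSpec,
    RepeatPlacement,
    TrioSimulationConfig,
    simulate_locus_fixture,
    simulate_trio_dataset,
)


@pytest.fixture
def balanced_trio_dataset():
    """10 animals x 3 SNPs at true maternal fraction 0.5, cv 0.1."""
    return simulate_trio_dataset(
        TrioSimulationConfig(theta_true=0.5, n_animals=10, n_snps=3, seed=11)
    )


@pytest.fixture
def locus_fixture(tmp_path):
    """Two genes 2.4 kb apart with LTR/LINE repeats in the intergenic span."""
    spec = LocusFixtureSpec(
        seq_length=120_000,
        genes=[
            GenePlacement("TH", 1_000, 11_000, "+"),
            GenePlacement("INS", 13_400, 14_000, "+"),
        ],
        repeats=[
            RepeatPlacement("MYSERV-int", "LTR/ERVK", 11_500, 12_100),
            RepeatPlacement("L1Md_T", "LINE/L1", 11_900, 12_500),
            RepeatPlacement("L1Md_T", "LINE/L1", 11_900, 12_500),  # duplicate hit
            RepeatPlacement("B1_Mus", "SINE/Alu", 50, 400),  # outside intergenic
        ],
        cpg_islands=[(20_000, 21_000, 30.0)],
        seed=3,
    )
    return simulate_locus_fixture(spec, tmp_path)
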