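import warnings

import pytest

import paraclone as pc
from paraclone.locus_forge import PsvSpec

warnings.filterwarnings("ignore", message=".*edit threshold.*")
warnings.filterwarnings("ignore", message=".*zero control depth.*")


@pytest.fixture(scope="session")
def locus():
    return pc.build_locus(1)


@pytest.fixture(scope="session")
def indices(locus):
    return pc.build_indices(locus)


@pytest.fixture(scope="session")
def mini_params():
    """A ~2 kb paralog pair, small enough for all-offset brute forcing."""
    return pc.LocusParams(
        gene_len=800,
        core_start=150,
        core_len=450,
        separation_bp=300,
        flank=150,
        psvs=(
            PsvSpec(60, "A", "G", True, 0.2),
            PsvSpec(70, "C", "T", True, 0.01),
            PsvSpec(300, "C", "G", True, 0.002),
            PsvSpec(320, "C", "G", True, 0.01),
            PsvSpec(350, "A", "G", False, 0.0),
        ),
        delins_interval=(250, 270),
        conversion_start_pseudo=330,
        embedded_del_gene=(620, 623),
    )


@pytest.fixture(scope="session")
def mini_locus(mini_params):
    return pc.build_locus(5, mini_params)


@pytest.fixture(scope="session")
def scenario_runs(locus, indices):
    """One full two-build run per case archetype, shared across tests."""
    return {
        scen: pc.run_scenario(locus, scen, seed=11, references=indices)
        for scen in (
            "plain_control",
            "case1_pseudolike_het_snv",
            "case2_control",
            "case3_gene_delins",
        )
    }


@pytest.fixture(scope="session")
def case4_run(locus, indices):
    res = pc.run_scenario(locus, "case4_gene_conversion_sv", seed=7, references=indices)
    ratio, segments = pc.cn_scan(
        locus, "case4_gene_conversion_sv", seed=7, index=indices["buildB"]
    )
    return res, ratio, segments
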