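import numpy as np
import pytest

from ffsig.oracle import (
    Scenario,
    ScenarioKind,
    contributors_for_scenario,
    expected_allele_freqs,
)
from ffsig.panel import Panel, SnpLocus, build_panel
from ffsig.signature import ALLELES, ALLELE_INDEX, AlleleCountTable
from ffsig.simulate import SimConfig, simulate_case, simulate_panel


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig()


@pytest.fixture(scope="session")
def default_panel(default_config) -> Panel:
    return simulate_panel(default_config, seed=42)


@pytest.fixture(scope="session")
def normal_bundle(default_config, default_panel):
    scenario = Scenario(ScenarioKind.NORMAL, 0.10)
    return simulate_case(
        scenario, default_config, seed=1, panel=default_panel
    )


def exact_counts(panel: Panel, scenario: Scenario, depth: float = 1e6):
    """Noise-free count table: exact mixture frequencies x a large depth."""
    contributors = contributors_for_scenario(scenario)
    counts = {}
    for locus in panel:
        row = np.zeros(4)
        if locus.is_y_locus:
            from ffsig.oracle import expected_locus_mass

            row[0] = depth * expected_locus_mass(contributors, locus)
        else:
            for allele, freq in expected_allele_freqs(
                contributors, locus
            ).items():
                row[ALLELE_INDEX[allele]] += freq * depth
        counts[locus.snp_id] = row
    return AlleleCountTable(counts)


@pytest.fixture(scope="session")
def mini_panel() -> Panel:
    """One locus per class/subtype, with a Y locus."""
    return build_panel(
        [
            SnpLocus("t1a", "X", 100, ("A", "A"), ("G", "G")),
            SnpLocus("t2a", "X", 200, ("C", "C"), ("C", "C")),
            SnpLocus("t3p1a", "X", 300, ("T", "T"), ("C", "T")),
            SnpLocus("t3p2a", "X", 400, ("G", "G"), ("G", "A")),
            SnpLocus("t4aa", "X", 500, ("A", "G"), ("A", "A")),
            SnpLocus("t4ba", "X", 600, ("A", "G"), ("G", "G")),
            SnpLocus("t5a", "X", 700, ("A", "C"), ("A", "C")),
            SnpLocus("y1", "Y", 800, is_y_locus=True),
        ]
    )
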