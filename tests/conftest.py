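import pytest

from msiscore import (CohortTable, LocusDefinition, PanelDefinition,
                      SimulationConfig, demo_panel, simulate_cohort)


@pytest.fixture
def small_panel() -> PanelDefinition:
    """Two handcrafted homopolymer loci with known flanks."""
    return PanelDefinition(
        loci=[
            LocusDefinition(
                locus_id="BAT_X", chrom="chr2", repeat_start=1000,
                repeat_end=1010, repeat_unit="A", ref_repeat_length=10,
                left_flank="GATTACACATGGCTC", right_flank="GTTCGAGGACTGACT",
            ),
            LocusDefinition(
                locus_id="NR_Y", chrom="chr7", repeat_start=5000,
                repeat_end=5012, repeat_unit="T", ref_repeat_length=12,
                left_flank="TTGACCGGATCCAGC", right_flank="ACCGGTAACGTCAGG",
            ),
        ],
        panel_name="fixture2",
        version="1",
    )


@pytest.fixture(scope="session")
def demo81() -> PanelDefinition:
    return demo_panel()


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition cohort (294 samples, Table-1 class mix)."""
    return simulate_cohort(SimulationConfig(seed=0))
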