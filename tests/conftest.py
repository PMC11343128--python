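import pytest

from snase import simdata
from snase.types import GeneModel, IsoformModel, PhasedVariant


@pytest.fixture(scope="session")
def read_fixture():
    """Medium read-level fixture with multimappers and WASP failures."""
    return simdata.simulate_read_fixture(simdata.ReadSimConfig(n_molecules=400, seed=3))


@pytest.fixture(scope="session")
def clean_read_fixture():
    """Error-free fixture where every read is usable."""
    return simdata.simulate_read_fixture(
        simdata.ReadSimConfig(
            n_molecules=300, seed=5, error_rate=0.0, frac_multimapped=0.0, frac_wasp_fail=0.0
        )
    )


@pytest.fixture()
def toy_gene():
    """One plus-strand gene: two exons, UTRs at either end."""
    exons = ((1000, 1400), (2200, 2600))
    isoforms = (
        IsoformModel("T1_G", "G", exons, spliced=True),
        IsoformModel("unspliced_G", "G", ((1000, 2600),), spliced=False),
    )
    return GeneModel(
        "G", "chr1", "+", (1000, 2600), isoforms,
        utr5_blocks=((1000, 1100),), utr3_blocks=((2400, 2600),),
    )


def make_variant(pos, gt="0|1", individual="ind", chrom="chr1"):
    return PhasedVariant(chrom, pos, "A", "G", {individual: gt})
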