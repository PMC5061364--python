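import pytest

from ventpop.io_align import PopulationSample, complete_sites
from ventpop.synthetic_data import make_fixture


def as_population(aln, **kw) -> PopulationSample:
    return PopulationSample(aln, complete_sites(aln, aln.ids()), **kw)


@pytest.fixture
def tajima_toy():
    aln, expected = make_fixture("tajima_toy")
    return as_population(aln), expected


@pytest.fixture
def mono():
    aln, expected = make_fixture("mono")
    return as_population(aln), expected


@pytest.fixture
def fst_fixed():
    aln, expected = make_fixture("fst_fixed")
    g1 = [r.seq for r in aln.records[:5]]
    g2 = [r.seq for r in aln.records[5:]]
    return (g1, g2), expected
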