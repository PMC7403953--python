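import pytest

from tkms import reference as R
from tkms.species import default_catalog
from tkms.spectra import Condition, Peak, PeakList


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()

@pytest.fixture(scope="session")
def species(catalog):
    return {c.name: c for c in catalog}


@pytest.fixture(scope="session")
def precursors(species):
    """The four fragmented precursors keyed by their nominal-mass label."""
    return {
        "425": species["ThDP"],
        "485": species["ThDP+GliA"],
        "487": species["ThDP+GliA+H2"],
        "467": species["ThDP+GliA-H2O"],
    }


@pytest.fixture(scope="session")
def fragment_peaklists(precursors):
    """Per-precursor MS/MS peak lists built from the reference fragment
    table's experimental m/z columns (unit intensities)."""
    out = {}
    for label, prec in precursors.items():
        peaks = tuple(
            Peak(row.observed[label], 100.0)
            for row in R.FRAGMENT_TABLE
            if label in row.observed
        )
        out[label] = PeakList(
            f"frag_{label}", peaks, Condition(msms_precursor=prec.theoretical_mass)
        )
    return out
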