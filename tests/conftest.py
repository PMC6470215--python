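import pytest

from primerfusion import TaxonProfile


@pytest.fixture
def three_primer_profiles() -> list[TaxonProfile]:
    """Small same-sample trio: one unique taxon, one max-of-two, one tie."""
    return [
        TaxonProfile("s1", "V1V3", "phylum",
                     {"k__Bacteria;p__Chloroflexi": 80,
                      "k__Bacteria;p__Proteobacteria": 100}),
        TaxonProfile("s1", "V4", "phylum",
                     {"k__Bacteria;p__Proteobacteria": 250,
                      "k__Bacteria;p__Acidobacteria": 50}),
        TaxonProfile("s1", "V5V8", "phylum",
                     {"k__Bacteria;p__Acidobacteria": 50}),
    ]
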