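import pytest

from glycoreg.ingest import GeneSet, PathwayClassification, TFGeneRecord


@pytest.fixture
def tiny_records():
    """Six edges, two TFs, one cancer; targets g1..g4."""
    return [
        TFGeneRecord("STAT1", "B4GALT3", "BRCA_1", 0.9, 0.5),
        TFGeneRecord("STAT1", "FUT7", "BRCA_1", 0.8, 0.6),
        TFGeneRecord("STAT1", "GALNT3", "BRCA_1", 0.7, 0.45),
        TFGeneRecord("IRF1", "FUT7", "BRCA_1", 0.6, 0.5),
        TFGeneRecord("IRF1", "HAS1", "BRCA_1", 0.9, 0.9),
        TFGeneRecord("IRF1", "GALNT3", "BRCA_1", 0.55, 0.41),
    ]


@pytest.fixture
def tiny_classification():
    return PathwayClassification(
        pathways=("Fucosylation", "GalNAc-type O-glycans", "Hyaluronan synthesis"),
        assignment={
            "FUT7": frozenset({"Fucosylation"}),
            "GALNT3": frozenset({"GalNAc-type O-glycans"}),
            "HAS1": frozenset({"Hyaluronan synthesis"}),
        },
    )


@pytest.fixture
def glyco_universe():
    return GeneSet(
        name="universe",
        members=frozenset({"B4GALT3", "FUT7", "GALNT3", "HAS1", "NDST1"}),
    )
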