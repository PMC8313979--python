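"""Shared study conditions for the numbered analysis drivers.

A scaled-down cohort standing in for the database extract the pipeline was
designed around: 4 tumor cohorts, 120 TFs, 341 candidate glycogenes of which
200 are classified into 20 pathways of 10 genes.  Three (TF, pathway) pairs
are planted at enrichment factor 5 and three TF co-regulation blocks are
planted in the unclassified gene range, so the drivers can report recovery
against known ground truth.
"""

from pathlib import Path

from glycoreg.synthetic import PlantedBlock, PlantedPair, SyntheticConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
SIM_DIR = RESULTS / "synthetic"

STUDY_CONFIG = SyntheticConfig(
    n_cancers=4,
    n_tfs=120,
    n_genes=341,
    n_pathways=20,
    pathway_size=10,
    planted_pairs=(
        PlantedPair(0, 0, 5.0),
        PlantedPair(1, 5, 5.0),
        PlantedPair(2, 12, 5.0),
    ),
    planted_blocks=(
        PlantedBlock(tuple(range(10, 18)), tuple(range(210, 230)), 0.9),
        PlantedBlock(tuple(range(18, 26)), tuple(range(230, 250)), 0.9),
        PlantedBlock(tuple(range(26, 34)), tuple(range(250, 270)), 0.9),
    ),
    seed=29,
)
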