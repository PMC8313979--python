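"""Generate the synthetic study cohort and write its input tables.

Writes the TF–gene relationship table, the gene→pathway classification, the
signaling GMT and the planted ground truth under results/synthetic/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

from study_config import SIM_DIR, STUDY_CONFIG

from glycoreg import synthetic


def main() -> None:
    truth = synthetic.generate(STUDY_CONFIG)
    paths = synthetic.write_truth(truth, SIM_DIR)
    print(f"cohort: {STUDY_CONFIG.n_cancers} cancer types, "
          f"{STUDY_CONFIG.n_tfs} TFs, {STUDY_CONFIG.n_genes} candidate glycogenes")
    print(f"raw TF–gene relationships: {len(truth.table)}")
    print(f"classified genes: {len(truth.classification.genes)} "
          f"in {len(truth.classification.pathways)} pathways")
    print(f"planted (TF, pathway) pairs: {len(truth.true_pairs)}; "
          f"planted TF blocks: {len(truth.true_blocks)}")
    for name, path in sorted(paths.items()):
        print(f"  wrote {name}: {path}")


if __name__ == "__main__":
    main()
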