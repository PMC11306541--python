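"""Consensus-cluster the tumors on the most variable phosphosites and pick
the number of phospho-subtypes from the consensus CDF areas.

Run ``01`` and ``02`` first (uses the MAD-selected matrix from step 02).
"""

import json
from pathlib import Path

import pandas as pd

from phoskin.subtype import consensus_cluster

RESULTS = Path("results")
SEED = 2


def main() -> None:
    m = pd.read_csv(RESULTS / "02_matrix_mad_top10pct.tsv", sep="\t", index_col=0)
    res = consensus_cluster(m, k_range=range(2, 7), n_resamples=250, seed=SEED)

    res.labels.to_frame("cluster").to_csv(RESULTS / "03_subtype_labels.csv")
    with open(RESULTS / "03_consensus_summary.json", "w") as fh:
        json.dump(
            {
                "chosen_k": res.chosen_k,
                "cdf_areas": {str(k): round(v, 4) for k, v in res.cdf_areas.items()},
                "delta_areas": {str(k): round(v, 4) for k, v in res.delta_areas.items()},
                "cluster_sizes": res.labels.value_counts().sort_index().to_dict(),
            },
            fh, indent=1, sort_keys=True,
        )

    print(f"consensus clustering over k=2..6 ({250} resamples)")
    print("relative CDF-area increase per k:",
          {k: round(v, 3) for k, v in res.delta_areas.items()})
    print(f"chosen k = {res.chosen_k}; cluster sizes "
          f"{res.labels.value_counts().sort_index().to_dict()}")


if __name__ == "__main__":
    main()
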