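"""Differential phosphosites between the phospho-subtypes (moderated F,
BH <= 0.05, |log2 FC| >= 1), mutation-stratified contrasts, the signed
-log10 P rank metric, and PTM-SEA-style kinase-substrate signature scores
averaged per subtype.

Run ``01``–``03`` first.
"""

import json
from pathlib import Path

import pandas as pd

from phoskin import diffstat, enrich, preprocess
from phoskin.maxquant_io import (
    GLOBAL_PST,
    exclude_records,
    filter_class1,
    read_clinical,
    read_network,
    read_sites,
)
from phoskin.pipeline import _kinase_site_signatures

COHORT = Path("scratch/cohort")
RESULTS = Path("results")


def main() -> None:
    sites = filter_class1(exclude_records(read_sites(
        COHORT / "Phospho (STY)Sites_global.txt", GLOBAL_PST)))
    clinical = read_clinical(COHORT / "clinical.csv")
    net = read_network(COHORT / "kinase_substrate_network.tsv")
    labels = pd.read_csv(RESULTS / "03_subtype_labels.csv", index_col=0)["cluster"]

    norm = preprocess.normalize_median_site(sites)
    logm = preprocess.log2_prepare(preprocess.filter_data_presence(norm, 0.10))

    res = diffstat.moderated_test(logm.data, labels)
    sig = diffstat.significant_features(res, q_max=0.05, fc_min=2.0)
    res.table.to_csv(RESULTS / "04_differential_sites.tsv", sep="\t")
    metric = diffstat.rank_metric(res)
    metric.to_frame("signed_log10p").to_csv(RESULTS / "04_rank_metric.tsv", sep="\t")

    contrasts = {}
    for gene, col in (("TP53", "tp53_status"), ("KRAS", "kras_status")):
        glab = clinical[col].reindex(logm.data.columns)
        if glab.nunique() == 2 and glab.value_counts().min() >= 2:
            d2 = diffstat.moderated_test(logm.data, glab)
            s2 = diffstat.significant_features(d2, q_max=0.05, fc_min=2.0, use_q=False)
            contrasts[gene] = {"groups": glab.value_counts().to_dict(),
                               "n_significant": len(s2)}

    sigs = _kinase_site_signatures(net, norm.meta)
    es = enrich.ptm_sea_score(norm, sigs)
    means = enrich.average_by_cluster(es, labels)
    means.round(4).to_csv(RESULTS / "04_ptm_sea_cluster_means.tsv", sep="\t")

    with open(RESULTS / "04_differential_summary.json", "w") as fh:
        json.dump(
            {
                "n_tested": int(res.table["tested"].sum()),
                "n_significant_subtype": len(sig),
                "prior_d0": round(res.d0, 3) if res.d0 != float("inf") else "inf",
                "mutation_contrasts": contrasts,
                "n_site_signatures": len(sigs),
            },
            fh, indent=1, sort_keys=True,
        )

    print(f"moderated F over {int(res.table['tested'].sum())} tested sites: "
          f"{len(sig)} differential at q<=0.05, |log2FC|>=1")
    for gene, c in contrasts.items():
        print(f"{gene} contrast {c['groups']}: {c['n_significant']} sites "
              f"(p<=0.05, |log2FC|>=1)")
    print(f"{len(sigs)} kinase-substrate site signatures scored; "
          f"cluster means in 04_ptm_sea_cluster_means.tsv")


if __name__ == "__main__":
    main()
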