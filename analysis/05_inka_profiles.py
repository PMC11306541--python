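"""INKA kinase-activity profiles per sample and per phospho-subtype for both
enrichment channels, with top-20 rankings and between-subtype comparisons.

Run ``01``–``03`` first.
"""

import json
from pathlib import Path

import pandas as pd

from phoskin import inka, preprocess
from phoskin.maxquant_io import (
    GLOBAL_PST,
    PY,
    exclude_records,
    filter_class1,
    read_clinical,
    read_network,
    read_sites,
    spectral_counts_from_evidence,
)

COHORT = Path("scratch/cohort")
RESULTS = Path("results")


def main() -> None:
    clinical = read_clinical(COHORT / "clinical.csv")
    net = read_network(COHORT / "kinase_substrate_network.tsv")
    evidence = spectral_counts_from_evidence(COHORT / "evidence.txt")
    labels = pd.read_csv(RESULTS / "03_subtype_labels.csv", index_col=0)["cluster"]

    summary = {}
    for channel, fname, chan_id in (
        (GLOBAL_PST, "Phospho (STY)Sites_global.txt", "pST"),
        (PY, "Phospho (STY)Sites_pY.txt", "pY"),
    ):
        sites = filter_class1(exclude_records(read_sites(COHORT / fname, channel)))
        if channel == GLOBAL_PST:
            sites = preprocess.normalize_median_site(sites)
        else:
            sites = preprocess.normalize_total_count(
                sites, clinical["lysate_spectral_count"])
        profs = inka.sample_profiles(sites, evidence, net, channel=chan_id)
        smat = inka.score_matrix(profs)
        smat.round(3).to_csv(RESULTS / f"05_inka_scores_{chan_id}.tsv", sep="\t")

        chan_labels = labels.reindex(sites.samples).dropna()
        gprofs = inka.group_profile(sites, evidence, net, chan_labels, channel=chan_id)
        tops = {}
        for g, prof in gprofs.items():
            t = inka.top_n(prof, 20)
            tops[str(g)] = [
                {"kinase": k, "score": round(float(r["score"]), 1),
                 "dp_pct": float(r["dp_pct"])}
                for k, r in t.iterrows()
            ]
        summary[chan_id] = {
            "n_samples": len(sites.samples),
            "n_scored_kinases": int((smat > 0).any(axis=1).sum()),
            "top20_by_group": tops,
        }
        top1 = {g: v[0]["kinase"] for g, v in tops.items()}
        print(f"{chan_id}: {len(sites.samples)} samples, "
              f"{summary[chan_id]['n_scored_kinases']} kinases scored; "
              f"top kinase per subtype: {top1}")

    with open(RESULTS / "05_inka_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)


if __name__ == "__main__":
    main()
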