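"""Associate kinase activity with overall survival: per-kinase Spearman
correlation of INKA scores vs OS, bimodal OS cutoff, Kaplan–Meier medians per
subtype, and the extreme short-vs-long differential contrast.

Run ``01``–``05`` first.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from phoskin import preprocess, survival
from phoskin.maxquant_io import (
    GLOBAL_PST,
    exclude_records,
    filter_class1,
    read_clinical,
    read_sites,
)

COHORT = Path("scratch/cohort")
RESULTS = Path("results")


def main() -> None:
    clinical = read_clinical(COHORT / "clinical.csv")
    labels = pd.read_csv(RESULTS / "03_subtype_labels.csv", index_col=0)["cluster"]
    smat = pd.read_csv(RESULTS / "05_inka_scores_pST.tsv", sep="\t", index_col=0)

    assoc = survival.spearman_survival(smat, clinical, naive_only=True)
    assoc.table.round(4).to_csv(RESULTS / "06_survival_association.tsv", sep="\t")
    sig = assoc.table[(assoc.table["p"] < 0.05) & (assoc.table["rho"] < 0)]

    cutoff = survival.bimodal_cutoff(clinical["os_months"])
    cutoff_source = "bimodal KDE"
    if cutoff is None:
        # exponential-like OS has no second mode; split at the median instead
        cutoff = float(np.median(clinical["os_months"]))
        cutoff_source = "median (no bimodal structure)"
    km_medians = {}
    for g in sorted(labels.unique()):
        ids = labels.index[labels == g]
        km = survival.km_estimate(clinical.loc[ids, "os_months"],
                                  clinical.loc[ids, "event_flag"])
        km_medians[str(g)] = round(km["median"], 1) if np.isfinite(km["median"]) else None

    extreme = None
    if cutoff is not None:
        try:
            groups = survival.define_outcome_groups(clinical, cutoff, naive_only=True)
            os_ = clinical["os_months"]
            short3 = sorted(groups.short_ids, key=lambda s: os_[s])[:3]
            long3 = sorted(groups.long_ids, key=lambda s: -os_[s])[:3]
            sites = filter_class1(exclude_records(read_sites(
                COHORT / "Phospho (STY)Sites_global.txt", GLOBAL_PST)))
            logm = preprocess.log2_prepare(preprocess.filter_data_presence(
                preprocess.normalize_median_site(sites), 0.10))
            if len(short3) >= 2 and len(long3) >= 2:
                eg = survival.OutcomeGroups(cutoff, short3, long3, True)
                _, ext_sig = survival.extreme_group_diff(logm.data, eg)
                extreme = {"n_short": len(short3), "n_long": len(long3),
                           "n_significant": len(ext_sig),
                           "group_sizes_at_cutoff": {"short": len(groups.short_ids),
                                                     "long": len(groups.long_ids)}}
        except ValueError as exc:
            extreme = {"note": str(exc)}

    with open(RESULTS / "06_survival_summary.json", "w") as fh:
        json.dump(
            {
                "n_kinases_assessed": int(len(assoc.table)),
                "poor_survival_kinases": {
                    k: {"rho": round(r["rho"], 3), "p": round(r["p"], 4)}
                    for k, r in sig.iterrows()
                },
                "os_cutoff_months": round(cutoff, 2) if cutoff is not None else None,
                "os_cutoff_source": cutoff_source,
                "km_median_by_subtype": km_medians,
                "extreme_contrast": extreme,
            },
            fh, indent=1, sort_keys=True,
        )

    print(f"{len(assoc.table)} kinases assessed (treatment-naive samples)")
    for k, r in sig.iterrows():
        print(f"  {k}: rho={r['rho']:.2f}, P={r['p']:.3g} (poor survival)")
    print(f"OS cutoff: {round(cutoff, 1)} months ({cutoff_source}); "
          f"KM median OS by subtype: {km_medians}")
    if extreme:
        print(f"extreme short-vs-long contrast: {extreme}")


if __name__ == "__main__":
    main()
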