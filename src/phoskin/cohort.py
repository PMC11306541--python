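"""Cohort-level mutation tallies and frequency arithmetic.

The defaults of the synthetic generator emulate a 42-tumor resected PDAC
cohort with targeted sequencing of commonly mutated genes. The tallies below
encode that cohort's published mutation counts and are used both to seed the
generator's frequencies and to recompute the headline percentages.
"""

from __future__ import annotations

import pandas as pd

#: 42 resected tumors; KRAS wild-type in 2; TP53 mutant in 31. Among the 40
#: KRAS-mutant tumors the allele variant is known for 37 (3 not available).
REFERENCE_COHORT = {
    "n_samples": 42,
    "kras_wildtype": 2,
    "tp53_mutant": 31,
    "kras_alleles": {
        "G12V": 16,
        "G12D": 14,
        "G12R": 4,
        "G12R/G12V": 1,
        "G13D": 1,
        "Q61H": 1,
        "NA": 3,
    },
}


def reference_mutation_table() -> pd.DataFrame:
    """The reference cohort tallies as a per-sample table (sample_id,
    kras_status, kras_allele, tp53_status)."""
    c = REFERENCE_COHORT
    rows = []
    for allele, n in c["kras_alleles"].items():
        rows.extend({"kras_status": "mut", "kras_allele": allele} for _ in range(n))
    rows.extend(
        {"kras_status": "WT", "kras_allele": "WT"} for _ in range(c["kras_wildtype"])
    )
    df = pd.DataFrame(rows)
    assert len(df) == c["n_samples"]
    df["sample_id"] = [f"T{i + 1:02d}" for i in range(len(df))]
    df["tp53_status"] = ["mut"] * c["tp53_mutant"] + ["WT"] * (len(df) - c["tp53_mutant"])
    return df.set_index("sample_id", drop=False)


def mutation_frequencies(clinical: pd.DataFrame) -> dict:
    """Mutation frequencies (percent) from a per-sample table.

    Gene frequencies are over all samples; KRAS allele-variant frequencies
    are over the KRAS-mutant tumors with a known allele call."""
    n = len(clinical)
    out = {
        "kras_mut_pct": round(100.0 * (clinical["kras_status"] == "mut").sum() / n, 1),
        "tp53_mut_pct": round(100.0 * (clinical["tp53_status"] == "mut").sum() / n, 1),
    }
    mut = clinical[clinical["kras_status"] == "mut"]
    n_mut = len(mut)
    if n_mut and "kras_allele" in clinical:
        freqs = {}
        for allele, cnt in mut["kras_allele"].value_counts().items():
            freqs[str(allele)] = round(100.0 * cnt / n_mut, 1)
        out["kras_allele_pct"] = freqs
    return out
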