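"""Generate the synthetic PDAC-like study cohort used by all later steps.

Writes the MaxQuant-dialect fixture (site tables for both enrichment
channels, evidence, network, clinical table, planted truth) under
``scratch/cohort/`` and a small cohort summary under ``results/``.
"""

import json
from pathlib import Path

from phoskin.cohort import mutation_frequencies
from phoskin.synthetic_data import SimulationConfig, simulate_cohort, write_fixture

OUT = Path("scratch/cohort")
RESULTS = Path("results")
SEED = 1


def main() -> None:
    cfg = SimulationConfig(seed=SEED)
    truth, sites_g, sites_y, evidence, clinical = simulate_cohort(cfg)
    paths = write_fixture(truth, sites_g, sites_y, evidence, clinical, OUT)

    freqs = mutation_frequencies(clinical)
    summary = {
        "n_samples": cfg.n_samples,
        "n_sites_global": int(len(sites_g.data)),
        "n_sites_py": int(len(sites_y.data)),
        "n_py_samples": len(sites_y.samples),
        "subtype_sizes": truth.subtype_labels.value_counts().sort_index().to_dict(),
        "mutation_frequencies": freqs,
        "hyperactive_kinase": cfg.hyper_kinase,
        "prognostic_kinase": cfg.prognostic_kinase,
        "files": paths,
    }
    RESULTS.mkdir(exist_ok=True)
    with open(RESULTS / "01_cohort_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=str)

    print(f"simulated {cfg.n_samples} tumors: "
          f"{len(sites_g.data)} global pS/T sites, {len(sites_y.data)} pY sites "
          f"({len(sites_y.samples)} samples with pY data)")
    print(f"planted subtypes: {summary['subtype_sizes']}")
    print(f"KRAS mutant {freqs['kras_mut_pct']}%, TP53 mutant {freqs['tp53_mut_pct']}%")
    print(f"fixture written to {OUT}/")


if __name__ == "__main__":
    main()
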