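# phoskin

Phosphoproteomic subtyping, integrative inferred kinase activity (INKA) and
survival association for label-free tumor cohorts.

Mass-spectrometry phosphoproteomics of resected tumors (the motivating
setting is pancreatic ductal adenocarcinoma, profiled in a global pS/T IMAC
channel and a pY immunoprecipitation channel) yields phosphosite × sample
intensity matrices with structured missingness, plus phosphopeptide
spectral counts. `phoskin` takes such data from MaxQuant-dialect tables to
biology: it normalizes per channel, filters to confidently localized
(class-I) sites, discovers tumor subtypes by resampling consensus
clustering, tests sites between subtypes or mutation strata with a
moderated t/F statistic, scores single-sample signature enrichment
(ssGSEA / PTM-SEA style), ranks kinase activities per sample and per group,
and associates them with overall survival.

The central statistic is the INKA score. For kinase *k* in one analysis
unit, spectral-count evidence is split into a kinase-centric arm
K = C_kin + C_act (the kinase's own phosphosites plus its activation-loop
sites) and a substrate-centric arm S = C_psp + C_nwk (curated plus
score-filtered predicted substrate sites), integrated as

    INKA_k = sqrt(K × S)

so that only kinases supported by *both* lines of evidence rank; kinases
with kinase-centric evidence only are listed separately. The moderated test
shrinks per-site variances toward an empirical-Bayes prior
s²_post = (d0·s0² + d_g·s²_g)/(d0 + d_g), with (d0, s0²) fitted by moment
matching on the log variances. Subtypes come from Monti-style consensus
clustering with the number of clusters chosen from the relative increase in
the consensus-CDF area. Details and all defaults are in
[docs/methods.md](docs/methods.md).

Because real cohort data of this kind are access-controlled, the package
ships a first-class synthetic-cohort generator (`phoskin.synthetic_data`)
that emulates the study design — subtype-structured kinase activities
driving site intensities through a kinase–substrate network,
intensity-dependent missingness, spectral-count saturation, pY channel
dropout, clinical covariates and survival tied to a prognostic kinase —
with full planted truth, so every stage is tested by recovery rather than
by fiat.

## Worked example

The `analysis/` scripts run the full study on a simulated 42-tumor cohort;
each writes its tables under `results/` (the cohort fixture itself goes to
`scratch/`). Running them in order prints, abbreviated:

```text
$ python analysis/01_simulate_cohort.py
simulated 42 tumors: 600 global pS/T sites, 150 pY sites (33 samples with pY data)
planted subtypes: {1: 14, 2: 14, 3: 14}
KRAS mutant 95.2%, TP53 mutant 64.3%

$ python analysis/02_preprocess_qc.py
class-I sites: 552 global, 138 pY
10% DP keeps 551 global sites; MAD top 10% keeps 56 for clustering
site identifications vs cellularity: rho=0.938 (P=4.8e-20)

$ python analysis/03_subtype_consensus.py
relative CDF-area increase per k: {2: 0.455, 3: 0.502, 4: 0.031, 5: 0.037, 6: 0.036}
chosen k = 3; cluster sizes {1: 14, 2: 14, 3: 14}

$ python analysis/04_differential_enrichment.py
moderated F over 548 tested sites: 112 differential at q<=0.05, |log2FC|>=1
TP53 contrast {'mut': 27, 'WT': 15}: 6 sites (p<=0.05, |log2FC|>=1)

$ python analysis/05_inka_profiles.py
pST: 42 samples, 12 kinases scored; top kinase per subtype: {'1': 'KIN06', '2': 'KIN08', '3': 'KIN01'}
pY: 33 samples, 6 kinases scored; top kinase per subtype: {'1': 'KIN18', '2': 'KIN14', '3': 'KIN13'}

$ python analysis/06_survival_association.py
12 kinases assessed (treatment-naive samples)
  KIN11: rho=-0.72, P=5.42e-05 (poor survival)
OS cutoff: 15.3 months (median (no bimodal structure)); KM median OS by subtype: {'1': 44.8, '2': 7.3, '3': 54.9}
```

Reading the output against the planted truth: the consensus step recovers
exactly the three simulated subtypes (the CDF-area gain collapses from
~0.5 at the true k to ~0.03 beyond it); the designated hyperactive kinase
KIN01 tops the INKA ranking of its subtype; and the subtype whose kinases
include the prognostic one (here subtype 2, median OS 7.3 months vs ~45–55)
shows the poor-survival kinase module — the significant Spearman hits are
kinases co-activated with the prognostic kinase in that subtype. The same
pipeline runs from a single config via `phoskin.pipeline.run_all`.

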