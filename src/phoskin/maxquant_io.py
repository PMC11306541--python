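"""Readers, writers and containers for MaxQuant-dialect tables.

The pipeline consumes three MaxQuant output tables — ``Phospho (STY) Sites``,
``modificationSpecificPeptides`` and ``evidence`` — together with a
kinase–substrate relation table, GMT signature files and a clinical table.
Intensities of zero are treated as *not observed* (MaxQuant writes 0 for
absent values) and are stored as NaN; no imputation is ever performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

GLOBAL_PST = "global_pST"
PY = "pY"

#: required headers of a "Phospho (STY) Sites"-dialect table
SITE_HEADERS = (
    "Protein",
    "Position",
    "Amino acid",
    "Localization prob",
    "Sequence window",
    "Reverse",
    "Potential contaminant",
)

INTENSITY_PREFIX = "Intensity "


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


def site_key(protein: str, position: int, multiplicity: int = 1) -> str:
    """Stable feature key: (protein accession, position, multiplicity)."""
    return f"{protein}|{int(position)}|M{int(multiplicity)}"


def parse_site_key(key: str) -> tuple[str, int, int]:
    prot, pos, mult = key.rsplit("|", 2)
    return prot, int(pos), int(mult.lstrip("M"))


@dataclass
class SiteMatrix:
    """Phosphosite x sample quantification for one enrichment channel.

    ``data`` holds intensities (features x samples, NaN = not observed);
    ``meta`` carries per-feature annotation aligned on the same index:
    protein, gene, position, residue, window (15-mer, X-padded),
    localization_probability, multiplicity, reverse, contaminant.
    """

    data: pd.DataFrame
    meta: pd.DataFrame
    channel: str = GLOBAL_PST

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.meta.index):
            raise ValueError("data and meta must share the feature index")
        if self.channel not in (GLOBAL_PST, PY):
            raise ValueError(f"unknown channel {self.channel!r}")

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def subset(self, keys) -> "SiteMatrix":
        keys = pd.Index(keys)
        return SiteMatrix(self.data.loc[keys], self.meta.loc[keys], self.channel)

    def copy(self) -> "SiteMatrix":
        return SiteMatrix(self.data.copy(), self.meta.copy(), self.channel)


@dataclass
class PeptideEvidence:
    """Per-peptide spectral counts (and optional intensities) across samples.

    ``counts``: modified-sequence x sample integer matrix (0 = unobserved);
    ``peptide_meta``: per-peptide ``protein`` accession and ``position``
    (first phosphosite position) used to attribute counts to sites.
    """

    counts: pd.DataFrame
    peptide_meta: pd.DataFrame
    intensities: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise FormatError("spectral counts must be non-negative")


@dataclass
class KinaseSubstrateNetwork:
    """Directed kinase->site relations plus kinase-centric site annotation.

    ``edges`` columns: kinase, substrate, position, residue, source
    (curated|predicted), score (NaN for curated edges).
    ``self_sites`` / ``activation_loop_sites`` map a kinase to the
    (protein, position) pairs on its own protein; activation-loop sites are
    kept out of ``self_sites`` so kinase-centric evidence is never counted
    twice.
    """

    edges: pd.DataFrame
    self_sites: dict[str, set[tuple[str, int]]] = field(default_factory=dict)
    activation_loop_sites: dict[str, set[tuple[str, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pred = self.edges[self.edges["source"] == "predicted"]
        if pred["score"].isna().any():
            raise FormatError("predicted edges must carry a prediction score")
        dup = self.edges.duplicated(subset=["kinase", "substrate", "position", "source"])
        if dup.any():
            raise FormatError("duplicate (kinase, substrate, position) within a source")

    @property
    def kinases(self) -> list[str]:
        ks = set(self.edges["kinase"]) | set(self.self_sites) | set(self.activation_loop_sites)
        return sorted(ks)


REQUIRED_CLINICAL = ("sample_id", "os_months", "event_flag", "treatment_naive")


# ---------------------------------------------------------------------------
# readers


def _parse_intensity_block(df: pd.DataFrame, path: str) -> pd.DataFrame:
    cols = [c for c in df.columns if c.startswith(INTENSITY_PREFIX)]
    if not cols:
        raise FormatError(f"{path}: no '{INTENSITY_PREFIX}<sample>' columns found")
    block = {}
    for c in cols:
        sample = c[len(INTENSITY_PREFIX):]
        vals = pd.to_numeric(df[c].replace("", np.nan), errors="coerce")
        bad = df[c].notna() & (df[c].astype(str).str.strip() != "") & vals.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.values)[0])
            raise FormatError(f"{path}: non-numeric intensity in column {c!r}, row {row}")
        vals = vals.mask(vals == 0)  # MaxQuant writes 0 for absent
        block[sample] = vals
    return pd.DataFrame(block, index=df.index)


def read_sites(path, channel: str = GLOBAL_PST) -> SiteMatrix:
    """Read a "Phospho (STY) Sites"-dialect TSV into a :class:`SiteMatrix`.

    Sample names are taken verbatim from the ``Intensity <sample>`` column
    suffixes. Intensities of 0 or empty are stored as NaN.
    """
    df = pd.read_csv(path, sep="\t", dtype={"Reverse": str, "Potential contaminant": str})
    for h in SITE_HEADERS:
        if h not in df.columns:
            raise FormatError(f"{path}: missing required header {h!r}")
    data = _parse_intensity_block(df, str(path))
    mult = df["Multiplicity"] if "Multiplicity" in df.columns else pd.Series(1, index=df.index)
    keys = [site_key(p, q, m) for p, q, m in zip(df["Protein"], df["Position"], mult)]
    meta = pd.DataFrame(
        {
            "protein": df["Protein"].astype(str).values,
            "gene": df.get("Gene names", pd.Series("", index=df.index)).fillna("").astype(str).values,
            "position": df["Position"].astype(int).values,
            "residue": df["Amino acid"].astype(str).values,
            "window": df["Sequence window"].astype(str).values,
            "localization_probability": df["Localization prob"].astype(float).values,
            "multiplicity": pd.Series(mult).astype(int).values,
            "reverse": (df["Reverse"].fillna("").astype(str).str.strip() == "+").values,
            "contaminant": (df["Potential contaminant"].fillna("").astype(str).str.strip() == "+").values,
        },
        index=keys,
    )
    bad_p = ~meta["localization_probability"].between(0, 1)
    if bad_p.any():
        raise FormatError(f"{path}: localization probability outside [0,1]")
    data.index = pd.Index(keys)
    if meta.index.duplicated().any():
        raise FormatError(f"{path}: duplicate (protein, position, multiplicity) keys")
    return SiteMatrix(data, meta, channel)


def exclude_records(m: SiteMatrix, return_report: bool = False):
    """Drop reverse hits, contaminants and rows with no observed intensity.

    Returns the filtered matrix; with ``return_report=True`` also a dict of
    removal counts per reason (a row is attributed to the first matching
    reason: reverse, contaminant, all-missing).
    """
    rev = m.meta["reverse"].values
    con = m.meta["contaminant"].values & ~rev
    empty = m.data.isna().all(axis=1).values & ~rev & ~con
    keep = ~(rev | con | empty)
    report = {
        "reverse": int(rev.sum()),
        "contaminant": int(con.sum()),
        "all_missing": int(empty.sum()),
    }
    out = m.subset(m.data.index[keep])
    if report["reverse"] or report["contaminant"] or report["all_missing"]:
        log.info("exclude_records: removed %s", report)
    return (out, report) if return_report else out


def filter_class1(m: SiteMatrix, threshold: float = 0.75) -> SiteMatrix:
    """Keep class-I sites: localization probability >= ``threshold`` (inclusive)."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    keep = m.meta["localization_probability"] >= threshold
    return m.subset(m.data.index[keep.values])


def spectral_counts_from_evidence(path) -> PeptideEvidence:
    """Aggregate MS/MS spectral counts per (modified peptide, sample) from an
    evidence-dialect TSV (columns: Modified sequence, Proteins, Positions,
    Experiment, MS/MS count; multiple rows per peptide/sample are summed)."""
    df = pd.read_csv(path, sep="\t")
    for h in ("Modified sequence", "Proteins", "Positions", "Experiment", "MS/MS count"):
        if h not in df.columns:
            raise FormatError(f"{path}: missing required header {h!r}")
    if (df["MS/MS count"] < 0).any():
        raise FormatError(f"{path}: negative MS/MS count")
    counts = (
        df.pivot_table(
            index="Modified sequence",
            columns="Experiment",
            values="MS/MS count",
            aggfunc="sum",
            fill_value=0,
        )
        .astype(int)
    )
    counts.columns.name = None
    counts.index.name = None
    meta = (
        df.drop_duplicates("Modified sequence")
        .set_index("Modified sequence")[["Proteins", "Positions"]]
        .rename(columns={"Proteins": "protein", "Positions": "position"})
    )
    meta["position"] = meta["position"].astype(int)
    meta.index.name = None
    return PeptideEvidence(counts=counts, peptide_meta=meta.loc[counts.index])


def read_network(path) -> KinaseSubstrateNetwork:
    """Read a kinase–substrate TSV (kinase, substrate, position, residue,
    source, score). Rows with source ``self`` / ``activation_loop`` annotate
    the kinase's own sites; ``curated`` / ``predicted`` rows are substrate
    edges, and predicted rows must carry a numeric score."""
    df = pd.read_csv(path, sep="\t", dtype={"score": float})
    for h in ("kinase", "substrate", "position", "residue", "source"):
        if h not in df.columns:
            raise FormatError(f"{path}: missing required header {h!r}")
    if "score" not in df.columns:
        df["score"] = np.nan
    self_sites: dict[str, set] = {}
    act_sites: dict[str, set] = {}
    for i, row in df.iterrows():
        if row["source"] == "predicted" and pd.isna(row["score"]):
            raise FormatError(f"{path}: line {i + 2}: predicted edge without score")
        tgt = (str(row["substrate"]), int(row["position"]))
        if row["source"] == "self":
            self_sites.setdefault(row["kinase"], set()).add(tgt)
        elif row["source"] == "activation_loop":
            act_sites.setdefault(row["kinase"], set()).add(tgt)
        elif row["source"] not in ("curated", "predicted"):
            raise FormatError(f"{path}: line {i + 2}: unknown source {row['source']!r}")
    edges = df[df["source"].isin(["curated", "predicted"])].reset_index(drop=True)
    edges["position"] = edges["position"].astype(int)
    return KinaseSubstrateNetwork(edges=edges, self_sites=self_sites, activation_loop_sites=act_sites)


def read_gmt(path):
    """Read a GMT file into a list of :class:`phoskin.enrich.SignatureSet`.

    Undersized sets are kept (scoring applies the size bounds later) but a
    warning is logged."""
    from .enrich import SignatureSet

    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: expected name, description, members")
            name, _desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if not members:
                raise FormatError(f"{path}: line {lineno}: empty member list")
            sig = SignatureSet(name=name, members=frozenset(members))
            if len(sig.members) < sig.min_size:
                log.warning("GMT set %s has %d members (< min %d)", name, len(sig.members), sig.min_size)
            sets.append(sig)
    return sets


def read_clinical(path) -> pd.DataFrame:
    """Read and validate the clinical CSV (one row per sample)."""
    df = pd.read_csv(path)
    for h in REQUIRED_CLINICAL:
        if h not in df.columns:
            raise FormatError(f"{path}: missing required column {h!r}")
    if (df["os_months"] <= 0).any():
        bad = df.index[df["os_months"] <= 0][0]
        raise FormatError(f"{path}: os_months <= 0 at row {bad}")
    for flag in ("event_flag", "treatment_naive"):
        if not df[flag].isin([0, 1]).all():
            raise FormatError(f"{path}: {flag} must be binary")
    if "cellularity_pct" in df.columns and not df["cellularity_pct"].between(0, 100).all():
        raise FormatError(f"{path}: cellularity_pct outside [0, 100]")
    return df.set_index("sample_id", drop=False)


# ---------------------------------------------------------------------------
# writers (the MaxQuant dialect emitted by the simulator; round-trips through
# the readers above)


def write_sites(m: SiteMatrix, path) -> None:
    df = pd.DataFrame(
        {
            "Protein": m.meta["protein"].values,
            "Gene names": m.meta["gene"].values,
            "Position": m.meta["position"].values,
            "Amino acid": m.meta["residue"].values,
            "Sequence window": m.meta["window"].values,
            "Localization prob": m.meta["localization_probability"].values,
            "Multiplicity": m.meta["multiplicity"].values,
            "Reverse": np.where(m.meta["reverse"].values, "+", ""),
            "Potential contaminant": np.where(m.meta["contaminant"].values, "+", ""),
        }
    )
    for s in m.samples:
        df[INTENSITY_PREFIX + s] = m.data[s].fillna(0).values
    df.to_csv(path, sep="\t", index=False)


def write_network(net: KinaseSubstrateNetwork, path) -> None:
    rows = [net.edges[["kinase", "substrate", "position", "residue", "source", "score"]]]
    for mapping, source in ((net.self_sites, "self"), (net.activation_loop_sites, "activation_loop")):
        recs = [
            {"kinase": k, "substrate": p, "position": pos, "residue": "", "source": source, "score": np.nan}
            for k in sorted(mapping)
            for p, pos in sorted(mapping[k])
        ]
        if recs:
            rows.append(pd.DataFrame(recs))
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)


def write_gmt(sets, path) -> None:
    with open(path, "w") as fh:
        for sig in sets:
            fh.write("\t".join([sig.name, sig.description or "na", *sorted(sig.members)]) + "\n")
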