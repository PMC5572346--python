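"""Gene-catalog ingestion and differential enzyme selection.

The gene catalog is the study's raw material: per-sample read counts for
genes annotated with a KEGG ortholog (KO) and an order-level taxon.  This
module validates the catalog against a study design (sample -> environment,
replicate), aggregates reads through a KO->EC mapping into long-form enzyme
profiles with taxon breakdowns, and selects the differentially abundant
enzyme sets used to build environment-specific networks.

Differential abundance is normally computed externally (the study used
edgeR) and supplied as a table of per-enzyme log2 fold changes and FDR
values.  A labelled stand-in based on an exact binomial test is provided so
the pipeline runs end-to-end without R; it makes no claim of edgeR
equivalence and is marked ``provenance="standin"``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from rhizoscope._errors import FormatError, ValidationError
from rhizoscope.netbuild import EC_RE, read_tsv

logger = logging.getLogger(__name__)

#: sentinel taxon for reads without an order-level assignment
UNASSIGNED = "unassigned"

CATALOG_COLUMNS = ("gene_id", "sample_id", "read_count", "ko_id", "taxon")
DESIGN_COLUMNS = ("sample_id", "environment", "replicate")
KO2EC_COLUMNS = ("ko_id", "ec")
DA_COLUMNS = ("enzyme", "log2fc", "fdr")


@dataclass
class GeneCatalog:
    """Validated gene records plus the study design.

    ``records``: columns gene_id, sample_id, read_count, ko_id, taxon.
    ``design``: columns sample_id, environment, replicate.
    """

    records: pd.DataFrame
    design: pd.DataFrame

    @property
    def samples(self) -> list[str]:
        return sorted(self.design["sample_id"])

    def environments(self) -> list[str]:
        return sorted(self.design["environment"].unique())

    def samples_for(self, environment: str) -> list[str]:
        d = self.design
        return sorted(d.loc[d["environment"] == environment, "sample_id"])


@dataclass
class DifferentialSet:
    """Enzymes enriched in one environment of a pairwise comparison."""

    environment: str
    enzymes: frozenset[str]
    provenance: str  # "external" | "standin"


def read_design(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path, DESIGN_COLUMNS)
    if df["sample_id"].duplicated().any():
        dupes = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
        raise ValidationError(f"design: duplicate sample_id(s) {dupes}")
    df = df.copy()
    df["replicate"] = df["replicate"].astype(int)
    if (df["replicate"] < 1).any():
        raise ValidationError("design: replicate numbers must be >= 1")
    return df


def read_gene_catalog(catalog_path: str | Path, design_path: str | Path) -> GeneCatalog:
    """Read and validate the gene catalog against the study design.

    Rows with a sample id absent from the design are rejected; duplicate
    (gene_id, sample_id) rows are summed with a warning; empty taxon fields
    become the ``unassigned`` sentinel.
    """
    design = read_design(design_path)
    df = read_tsv(catalog_path, CATALOG_COLUMNS).copy()
    try:
        df["read_count"] = df["read_count"].astype(int)
    except ValueError as exc:
        raise ValidationError(f"catalog: non-integer read_count ({exc})") from None
    neg = df.index[df["read_count"] < 0]
    if len(neg):
        raise ValidationError(f"catalog: negative read_count at row {neg[0]}")
    known = set(design["sample_id"])
    bad = sorted(set(df["sample_id"]) - known)
    if bad:
        raise ValidationError(f"catalog: sample id(s) not in design: {bad}")
    df["taxon"] = df["taxon"].replace("", UNASSIGNED)

    n_before = len(df)
    df = (
        df.groupby(["gene_id", "sample_id", "ko_id", "taxon"], as_index=False)[
            "read_count"
        ].sum()
    )
    if len(df) < n_before:
        logger.warning(
            "catalog: summed %d duplicate (gene_id, sample_id) rows",
            n_before - len(df),
        )
    return GeneCatalog(df, design)


def read_ko2ec(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path, KO2EC_COLUMNS)
    bad = [e for e in df["ec"] if not EC_RE.match(e)]
    if bad:
        raise ValidationError(f"ko2ec: malformed EC string {bad[0]!r}")
    return df.drop_duplicates()


def build_enzyme_profile(catalog: GeneCatalog, ko2ec: pd.DataFrame) -> pd.DataFrame:
    """Aggregate gene records into per-(enzyme, sample, taxon) read counts.

    A KO mapping to k ECs contributes its full count to each EC (duplication,
    not splitting): dominance is computed per EC over that EC's own reads, so
    duplication does not bias taxon fractions.  KOs with no EC are dropped and
    counted in a log summary.
    """
    bad = [e for e in ko2ec["ec"] if not EC_RE.match(e)]
    if bad:
        raise ValidationError(f"ko2ec: malformed EC string {bad[0]!r}")
    records = catalog.records
    merged = records.merge(ko2ec, on="ko_id", how="left")
    dropped = merged["ec"].isna()
    if dropped.any():
        n_kos = merged.loc[dropped, "ko_id"].nunique()
        logger.info(
            "build_enzyme_profile: dropped %d KO(s) with no EC mapping (%d reads)",
            n_kos,
            merged.loc[dropped, "read_count"].sum(),
        )
    merged = merged.loc[~dropped]
    profile = (
        merged.groupby(["ec", "sample_id", "taxon"], as_index=False)["read_count"]
        .sum()
        .rename(columns={"ec": "enzyme"})
        .sort_values(["enzyme", "sample_id", "taxon"], ignore_index=True)
    )
    return profile


def _pooled_counts(profile: pd.DataFrame, samples: list[str]) -> pd.Series:
    sub = profile[profile["sample_id"].isin(samples)]
    return sub.groupby("enzyme")["read_count"].sum()


def _per_sample_counts(profile: pd.DataFrame, samples: list[str]) -> pd.DataFrame:
    sub = profile[profile["sample_id"].isin(samples)]
    return (
        sub.groupby(["enzyme", "sample_id"])["read_count"]
        .sum()
        .unstack(fill_value=0)
        .reindex(columns=samples, fill_value=0)
    )


def select_differential(
    profile: pd.DataFrame,
    design: pd.DataFrame,
    env_a: str,
    env_b: str,
    fold_threshold: float = 2.0,
    fdr_threshold: float = 0.01,
    external_table: str | Path | pd.DataFrame | None = None,
) -> tuple[DifferentialSet, DifferentialSet]:
    """Select the enzymes differentially abundant between two environments.

    External mode (``external_table`` given, columns enzyme/log2fc/fdr with
    log2fc > 0 meaning enriched in ``env_a``): apply the fold and FDR
    thresholds to the supplied table; enzymes present in the profile but
    missing from the table are treated as non-differential with a warning.

    Stand-in mode: per enzyme, pooled counts are tested with an exact
    binomial test against the two environments' library-size proportions,
    Benjamini-Hochberg corrected across enzymes; an enzyme is retained only
    if additionally the pooled fold change (pseudocount 1) exceeds
    ``fold_threshold`` and the fold-change direction is identical in every
    replicate-vs-replicate comparison between the environments.  The two
    returned sets are disjoint by construction (sign of the change).
    """
    for env in (env_a, env_b):
        if env not in set(design["environment"]):
            raise ValidationError(f"environment {env!r} not in design")
    enzymes_present = frozenset(profile["enzyme"].unique())

    if external_table is not None:
        if not isinstance(external_table, pd.DataFrame):
            external_table = read_tsv(external_table, DA_COLUMNS)
        tab = external_table.copy()
        tab["log2fc"] = tab["log2fc"].astype(float)
        tab["fdr"] = tab["fdr"].astype(float)
        missing = enzymes_present - set(tab["enzyme"])
        if missing:
            logger.warning(
                "select_differential: %d catalog enzyme(s) missing from the "
                "external table; treated as non-differential",
                len(missing),
            )
        lfc_cut = math.log2(fold_threshold)
        sig = tab[(tab["fdr"] < fdr_threshold) & (tab["log2fc"].abs() > lfc_cut)]
        sig = sig[sig["enzyme"].isin(enzymes_present)]
        set_a = frozenset(sig.loc[sig["log2fc"] > 0, "enzyme"])
        set_b = frozenset(sig.loc[sig["log2fc"] < 0, "enzyme"])
        return (
            DifferentialSet(env_a, set_a, "external"),
            DifferentialSet(env_b, set_b, "external"),
        )

    samples_a = sorted(design.loc[design["environment"] == env_a, "sample_id"])
    samples_b = sorted(design.loc[design["environment"] == env_b, "sample_id"])
    pooled_a = _pooled_counts(profile, samples_a)
    pooled_b = _pooled_counts(profile, samples_b)
    lib_a = float(pooled_a.sum())
    lib_b = float(pooled_b.sum())
    if lib_a == 0 or lib_b == 0:
        raise ValidationError("select_differential: an environment has zero total reads")

    enzymes = sorted(enzymes_present)
    counts_a = pooled_a.reindex(enzymes, fill_value=0).to_numpy()
    counts_b = pooled_b.reindex(enzymes, fill_value=0).to_numpy()
    p_null = lib_a / (lib_a + lib_b)
    pvals = np.array(
        [
            stats.binomtest(int(a), int(a + b), p_null).pvalue if a + b > 0 else 1.0
            for a, b in zip(counts_a, counts_b)
        ]
    )
    fdr = multipletests(pvals, method="fdr_bh")[1]
    # pooled fold change on library-normalised proportions, pseudocount 1
    prop_a = (counts_a + 1.0) / lib_a
    prop_b = (counts_b + 1.0) / lib_b
    fold = prop_a / prop_b

    # replicate consistency: same direction in every cross-environment pair
    per_a = _per_sample_counts(profile, samples_a).reindex(enzymes, fill_value=0)
    per_b = _per_sample_counts(profile, samples_b).reindex(enzymes, fill_value=0)
    libs_a = per_a.sum(axis=0).to_numpy(dtype=float)
    libs_b = per_b.sum(axis=0).to_numpy(dtype=float)
    libs_a[libs_a == 0] = 1.0
    libs_b[libs_b == 0] = 1.0
    pa = (per_a.to_numpy(dtype=float) + 1.0) / libs_a  # enzymes x samples_a
    pb = (per_b.to_numpy(dtype=float) + 1.0) / libs_b
    diffs = pa[:, :, None] - pb[:, None, :]  # enzymes x |a| x |b|
    all_up = (diffs > 0).all(axis=(1, 2))
    all_down = (diffs < 0).all(axis=(1, 2))

    sig = fdr < fdr_threshold
    up = sig & (fold > fold_threshold) & all_up
    down = sig & (1.0 / fold > fold_threshold) & all_down
    set_a = frozenset(np.asarray(enzymes)[up])
    set_b = frozenset(np.asarray(enzymes)[down])
    return (
        DifferentialSet(env_a, set_a, "standin"),
        DifferentialSet(env_b, set_b, "standin"),
    )
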