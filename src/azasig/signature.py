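"""Signature scoring, responder-like classification and survival validation.

A gene-set-level score is the per-sample mean log2 expression of a set's
leading-edge genes found in the cohort. Samples of an independent cohort
are clustered on the z-scored scores (1 - Pearson, average linkage, cut
at k = 2); the cluster whose orientation statistic — mean responder-up
z-score minus mean non-responder-up z-score — is higher is named
responder-like. The two groups are then compared by prediction accuracy
against known response labels and by a two-group log-rank test on
right-censored survival.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .containers import (
    NON_RESPONDER,
    RESPONDER,
    ExpressionMatrix,
    GeneSetCollection,
    PhenotypeTable,
)
from .gsea import NONRESPONDER_UP, RESPONDER_UP
from .simulate import NON_RESPONDER_LIKE, RESPONDER_LIKE

logger = logging.getLogger(__name__)

__all__ = [
    "SignatureScoreMatrix",
    "CohortPartition",
    "SurvivalComparison",
    "score_samples",
    "classify_cohort",
    "prediction_accuracy",
    "logrank_compare",
]


@dataclass
class SignatureScoreMatrix:
    """Samples x signature-set score matrix.

    ``raw`` holds mean leading-edge log2 expression; ``zscores`` the same
    standardized per set across samples; ``coverage`` the fraction of each
    set's genes found in the cohort; ``directions`` labels each set
    ``responder_up`` or ``nonresponder_up``.
    """

    raw: pd.DataFrame
    zscores: pd.DataFrame
    coverage: pd.Series
    directions: dict[str, str]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.raw.index)

    @property
    def set_names(self) -> list[str]:
        return list(self.raw.columns)

    def orientation(self) -> pd.Series:
        """Per-sample responder-orientation statistic.

        Mean z-score over responder-up sets minus mean z-score over
        non-responder-up sets; higher values look more responder-like.
        """
        r_up = [s for s, d in self.directions.items() if d == RESPONDER_UP]
        nr_up = [s for s, d in self.directions.items() if d == NONRESPONDER_UP]
        stat = pd.Series(0.0, index=self.raw.index)
        if r_up:
            stat = stat + self.zscores[r_up].mean(axis=1)
        if nr_up:
            stat = stat - self.zscores[nr_up].mean(axis=1)
        return stat


def score_samples(
    matrix: ExpressionMatrix,
    leading_edges: GeneSetCollection,
    directions: Mapping[str, str],
    low_coverage: float = 0.3,
) -> SignatureScoreMatrix:
    """Mean leading-edge log2 expression per sample per signature set.

    Genes are matched across cohorts by exact ID; sets with coverage below
    ``low_coverage`` are kept but logged. A set with no genes found at all
    is an error (it would have no defined score).
    """
    log2 = matrix.log2
    present = set(matrix.gene_ids)
    scores: dict[str, np.ndarray] = {}
    coverage: dict[str, float] = {}
    dirs: dict[str, str] = {}
    for gs in leading_edges:
        if gs.name not in directions:
            raise ValueError(f"no direction given for set {gs.name!r}")
        if directions[gs.name] not in (RESPONDER_UP, NONRESPONDER_UP):
            raise ValueError(
                f"direction for {gs.name!r} must be "
                f"{RESPONDER_UP!r} or {NONRESPONDER_UP!r}"
            )
        found = [g for g in gs.genes if g in present]
        if not found:
            raise ValueError(
                f"signature set {gs.name!r} has no genes in the cohort"
            )
        cov = len(found) / len(gs.genes)
        if cov < low_coverage:
            logger.warning(
                "set %r coverage %.2f below %.2f (%d/%d genes found)",
                gs.name, cov, low_coverage, len(found), len(gs.genes),
            )
        scores[gs.name] = log2.loc[found].mean(axis=0).to_numpy()
        coverage[gs.name] = cov
        dirs[gs.name] = directions[gs.name]
    raw = pd.DataFrame(scores, index=matrix.sample_ids)
    sd = raw.std(axis=0, ddof=0)
    z = (raw - raw.mean(axis=0)) / sd.replace(0.0, np.nan)
    z = z.fillna(0.0)
    return SignatureScoreMatrix(
        raw=raw, zscores=z, coverage=pd.Series(coverage), directions=dirs
    )


@dataclass
class CohortPartition:
    """A two-way sample partition named by signature orientation."""

    labels: pd.Series  # sample -> responder_like / non_responder_like
    orientation: pd.Series  # per-sample orientation statistic

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)

    def samples_with_label(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])


def classify_cohort(scores: SignatureScoreMatrix) -> CohortPartition:
    """Cluster samples on z-scored signature scores and name the clusters.

    Average-linkage hierarchical clustering on 1 - Pearson distance
    between sample score profiles, cut at k = 2; the cluster with the
    higher mean orientation statistic is ``responder_like``.
    """
    z = scores.zscores.to_numpy()
    if z.shape[0] < 4:
        raise ValueError("classification needs at least 4 samples")
    if z.shape[1] < 2:
        raise ValueError("classification needs at least 2 signature sets")
    d = np.clip(pdist(z, metric="correlation"), 0.0, 2.0)
    d = np.nan_to_num(d, nan=1.0)  # constant profiles: undefined corr -> d=1
    linkage = hierarchy.average(d)
    flat = hierarchy.fcluster(linkage, t=2, criterion="maxclust")
    part = pd.Series(flat, index=scores.raw.index)
    sizes = part.value_counts()
    if sizes.min() < 2:
        warnings.warn("degenerate clustering: a cluster is a singleton")
    orient = scores.orientation()
    mean_1 = orient[part == 1].mean()
    mean_2 = orient[part == 2].mean()
    responder_cluster = 1 if mean_1 >= mean_2 else 2
    labels = part.map(
        lambda c: RESPONDER_LIKE if c == responder_cluster else NON_RESPONDER_LIKE
    )
    labels.name = "label"
    return CohortPartition(labels=labels, orientation=orient)


_TRUTH_ALIASES = {
    RESPONDER: RESPONDER_LIKE,
    NON_RESPONDER: NON_RESPONDER_LIKE,
    RESPONDER_LIKE: RESPONDER_LIKE,
    NON_RESPONDER_LIKE: NON_RESPONDER_LIKE,
}


def prediction_accuracy(
    partition: CohortPartition, truth: Mapping[str, str] | pd.Series
) -> float:
    """Fraction of samples whose partition label matches the known group.

    ``responder`` and ``responder_like`` truth labels are equivalent (and
    likewise for non-responders). Truth must cover every sample.
    """
    truth = pd.Series(dict(truth)) if not isinstance(truth, pd.Series) else truth
    missing = [s for s in partition.sample_ids if s not in truth.index]
    if missing:
        raise ValueError(f"truth labels missing for samples: {missing[:5]}")
    mapped = truth.reindex(partition.sample_ids).map(_TRUTH_ALIASES)
    if mapped.isna().any():
        bad = truth.reindex(partition.sample_ids)[mapped.isna()].iloc[0]
        raise ValueError(f"unrecognized truth label {bad!r}")
    return float((mapped == partition.labels.reindex(partition.sample_ids)).mean())


@dataclass
class SurvivalComparison:
    """Two-group log-rank comparison with Kaplan-Meier summaries."""

    statistic: float  # chi-square, 1 df
    p_value: float
    km_tables: dict[str, pd.DataFrame]  # group -> KM survival table
    median_survival: dict[str, float]
    group_sizes: dict[str, int]


def logrank_compare(
    phenotypes: PhenotypeTable, partition: CohortPartition
) -> SurvivalComparison:
    """Standard two-group log-rank test between the partition's groups.

    Kaplan-Meier curves and median survival are computed per group with
    right censoring. Raises when the cohort has no observed events or a
    partition group has no samples with survival data.
    """
    if not phenotypes.has_survival:
        raise ValueError("phenotype table has no survival columns")
    df = phenotypes.data
    groups: dict[str, pd.DataFrame] = {}
    for label in (RESPONDER_LIKE, NON_RESPONDER_LIKE):
        samples = [
            s for s in partition.samples_with_label(label) if s in df.index
        ]
        sub = df.loc[samples].dropna(subset=["time", "event"])
        if sub.empty:
            raise ValueError(f"group {label!r} has no samples with survival")
        groups[label] = sub
    total_events = sum(int(g["event"].sum()) for g in groups.values())
    if total_events == 0:
        raise ValueError("no observed events in the cohort")

    g1 = groups[RESPONDER_LIKE]
    g2 = groups[NON_RESPONDER_LIKE]
    res = logrank_test(
        g1["time"], g2["time"],
        event_observed_A=g1["event"], event_observed_B=g2["event"],
    )
    km_tables: dict[str, pd.DataFrame] = {}
    medians: dict[str, float] = {}
    for label, sub in groups.items():
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"], label=label)
        km_tables[label] = kmf.survival_function_
        medians[label] = float(kmf.median_survival_time_)
    return SurvivalComparison(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        km_tables=km_tables,
        median_survival=medians,
        group_sizes={k: len(v) for k, v in groups.items()},
    )
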