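"""Network mechanism-of-action (MoA) scoring between response groups.

For every edge of a regulatory network the joint expression distribution
of the two endpoint genes is compared between responders and
non-responders: within each group the genes are rank-transformed,
binned on an ``n_bins x n_bins`` grid with add-half pseudocounts, and
scored with the symmetrized Kullback-Leibler divergence. Significance
comes from phenotype-label permutations (one stream shared by every
edge). Per gene, the incident-edge p-values are integrated with Fisher's
combination and adjusted across genes with Benjamini-Hochberg; the genes
whose network neighborhoods are most perturbed between groups are the
MoA candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import (
    NON_RESPONDER,
    RESPONDER,
    ExpressionMatrix,
    PhenotypeTable,
    RegulatoryNetwork,
)
from .simulate import substream

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeDivergence",
    "MoaResult",
    "edge_divergence",
    "integrate_gene",
    "rank_moa",
]


@dataclass(frozen=True)
class EdgeDivergence:
    """Symmetrized KL divergence of one edge's binned joint densities."""

    edge: tuple[str, str]
    divergence: float
    p_value: float
    n_permutations: int


def _rank_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Rank-transform rows to (0, 1] and bin into ``n_bins`` levels."""
    ranks = stats.rankdata(values, axis=-1) / values.shape[-1]
    return np.clip(np.ceil(ranks * n_bins).astype(int) - 1, 0, n_bins - 1)


def _joint_counts(bx: np.ndarray, by: np.ndarray, n_bins: int) -> np.ndarray:
    """Joint histograms per row: (..., n) bins -> (..., n_bins**2) counts."""
    codes = bx * n_bins + by
    b2 = n_bins * n_bins
    if codes.ndim == 1:
        return np.bincount(codes, minlength=b2).astype(float)
    n_rows = codes.shape[0]
    flat = codes + (np.arange(n_rows) * b2)[:, None]
    return (
        np.bincount(flat.ravel(), minlength=n_rows * b2)
        .reshape(n_rows, b2)
        .astype(float)
    )


def _sym_kl(counts_a: np.ndarray, counts_b: np.ndarray) -> np.ndarray:
    """Symmetrized KL between add-half-smoothed histograms, row-wise."""
    pa = counts_a + 0.5
    pb = counts_b + 0.5
    pa = pa / pa.sum(axis=-1, keepdims=True)
    pb = pb / pb.sum(axis=-1, keepdims=True)
    log_ratio = np.log(pa) - np.log(pb)
    return 0.5 * ((pa * log_ratio).sum(axis=-1) + (pb * -log_ratio).sum(axis=-1))


def _divergence_for_edge(
    x: np.ndarray,
    y: np.ndarray,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    n_bins: int,
) -> float:
    """Observed divergence for one edge and one group assignment."""
    bxa = _rank_bins(x[idx_a], n_bins)
    bya = _rank_bins(y[idx_a], n_bins)
    bxb = _rank_bins(x[idx_b], n_bins)
    byb = _rank_bins(y[idx_b], n_bins)
    return float(
        _sym_kl(_joint_counts(bxa, bya, n_bins), _joint_counts(bxb, byb, n_bins))
    )


def _permuted_divergences(
    x: np.ndarray,
    y: np.ndarray,
    perm_a: np.ndarray,
    perm_b: np.ndarray,
    n_bins: int,
) -> np.ndarray:
    """Divergences for all permutations at once.

    ``perm_a``/``perm_b`` are (n_perm x group size) integer index arrays
    into the samples.
    """
    bxa = _rank_bins(x[perm_a], n_bins)
    bya = _rank_bins(y[perm_a], n_bins)
    bxb = _rank_bins(x[perm_b], n_bins)
    byb = _rank_bins(y[perm_b], n_bins)
    return _sym_kl(
        _joint_counts(bxa, bya, n_bins), _joint_counts(bxb, byb, n_bins)
    )


def _permutation_indices(
    n_samples: int, n_a: int, n_perm: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    perms = np.array([rng.permutation(n_samples) for _ in range(n_perm)])
    return perms[:, :n_a], perms[:, n_a:]


def edge_divergence(
    matrix: ExpressionMatrix,
    phenotypes: PhenotypeTable,
    edge: tuple[str, str],
    n_bins: int = 4,
    n_perm: int = 1000,
    seed: int = 0,
) -> EdgeDivergence:
    """Group-difference divergence of one edge with its permutation p.

    Rank binning makes the score invariant to strictly monotone
    transforms of either gene. The p-value is the fraction of label
    permutations with divergence at least as large as observed.
    """
    resp = [s for s in phenotypes.samples_in_group(RESPONDER)
            if s in set(matrix.sample_ids)]
    nonresp = [s for s in phenotypes.samples_in_group(NON_RESPONDER)
               if s in set(matrix.sample_ids)]
    if len(resp) < 4 or len(nonresp) < 4:
        raise ValueError("each group needs at least 4 samples")
    a, b = edge
    for g in (a, b):
        if g not in set(matrix.gene_ids):
            raise KeyError(f"edge gene {g!r} absent from matrix")
    samples = resp + nonresp
    log2 = matrix.log2[samples]
    x = log2.loc[a].to_numpy()
    y = log2.loc[b].to_numpy()
    idx_a = np.arange(len(resp))
    idx_b = np.arange(len(resp), len(samples))
    obs = _divergence_for_edge(x, y, idx_a, idx_b, n_bins)
    rng = substream(seed, "moa-permutations")
    perm_a, perm_b = _permutation_indices(len(samples), len(resp), n_perm, rng)
    null = _permuted_divergences(x, y, perm_a, perm_b, n_bins)
    p = float((null >= obs - 1e-12).mean())
    return EdgeDivergence(edge=(a, b), divergence=obs, p_value=p,
                          n_permutations=n_perm)


def integrate_gene(p_values: list[float], n_perm: int = 1000) -> float:
    """Fisher's combination of a gene's incident-edge p-values.

    ``X = -2 * sum(ln p)`` referred to chi-square with 2k degrees of
    freedom; exact zeros are floored at ``1 / (n_perm + 1)``.
    """
    if not p_values:
        raise ValueError("need at least one edge p-value")
    floor = 1.0 / (n_perm + 1)
    ps = np.clip(np.asarray(p_values, dtype=float), floor, 1.0)
    x = -2.0 * np.log(ps).sum()
    return float(stats.chi2.sf(x, df=2 * len(ps)))


@dataclass
class MoaResult:
    """Per-gene MoA ranking.

    ``table`` columns: n_edges, p_value (Fisher-combined), p_adjusted
    (Benjamini-Hochberg across genes), log2_fold_change (non-responder
    mean minus responder mean, positive = up in non-responders), rank.
    ``edge_table`` holds the per-edge divergences and p-values.
    """

    table: pd.DataFrame
    edge_table: pd.DataFrame
    n_permutations: int

    def top(self, n: int = 20) -> pd.DataFrame:
        return self.table.head(n)


def rank_moa(
    matrix: ExpressionMatrix,
    phenotypes: PhenotypeTable,
    network: RegulatoryNetwork,
    n_bins: int = 4,
    n_perm: int = 1000,
    seed: int = 0,
) -> MoaResult:
    """Score every network edge and rank genes by integrated perturbation.

    All edges share one permutation stream. Genes without a scored edge
    are excluded; output is sorted by adjusted p (ties by raw p, then
    gene ID).
    """
    if network.n_edges() == 0:
        raise ValueError("empty network")
    resp = [s for s in phenotypes.samples_in_group(RESPONDER)
            if s in set(matrix.sample_ids)]
    nonresp = [s for s in phenotypes.samples_in_group(NON_RESPONDER)
               if s in set(matrix.sample_ids)]
    if len(resp) < 4 or len(nonresp) < 4:
        raise ValueError("each group needs at least 4 samples")
    if min(len(resp), len(nonresp)) < 8:
        logger.warning(
            "groups of %d/%d samples give limited permutation resolution",
            len(resp), len(nonresp),
        )
    samples = resp + nonresp
    log2 = matrix.log2[samples]
    present = set(matrix.gene_ids)
    idx_a = np.arange(len(resp))
    idx_b = np.arange(len(resp), len(samples))
    rng = substream(seed, "moa-permutations")
    perm_a, perm_b = _permutation_indices(len(samples), len(resp), n_perm, rng)

    edge_rows = []
    per_gene: dict[str, list[float]] = {}
    for a, b in network.edges:
        if a not in present or b not in present:
            logger.warning("edge %r-%r skipped: gene absent from matrix", a, b)
            continue
        x = log2.loc[a].to_numpy()
        y = log2.loc[b].to_numpy()
        obs = _divergence_for_edge(x, y, idx_a, idx_b, n_bins)
        null = _permuted_divergences(x, y, perm_a, perm_b, n_bins)
        p = float((null >= obs - 1e-12).mean())
        edge_rows.append((a, b, obs, p))
        per_gene.setdefault(a, []).append(p)
        per_gene.setdefault(b, []).append(p)
    if not edge_rows:
        raise ValueError("no network edge could be scored against the matrix")
    edge_table = pd.DataFrame(
        edge_rows, columns=["gene_a", "gene_b", "divergence", "p_value"]
    )

    genes = sorted(per_gene)
    combined = np.array([
        integrate_gene(per_gene[g], n_perm=n_perm) for g in genes
    ])
    _, adjusted, _, _ = multipletests(combined, method="fdr_bh")
    mean_r = log2.loc[genes, resp].mean(axis=1)
    mean_nr = log2.loc[genes, nonresp].mean(axis=1)
    table = pd.DataFrame(
        {
            "n_edges": [len(per_gene[g]) for g in genes],
            "p_value": combined,
            "p_adjusted": adjusted,
            "log2_fold_change": (mean_nr - mean_r).to_numpy(),
        },
        index=pd.Index(genes, name="gene"),
    )
    table = table.reset_index().sort_values(
        ["p_adjusted", "p_value", "gene"]
    ).set_index("gene")
    table["rank"] = np.arange(1, len(table) + 1)
    return MoaResult(table=table, edge_table=edge_table, n_permutations=n_perm)
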