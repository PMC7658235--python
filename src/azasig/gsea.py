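"""From-scratch gene set enrichment analysis (GSEA).

Genes are ranked by a signal-to-noise statistic between responders and
non-responders on the log2 view; each gene set's enrichment score (ES) is
the signed maximum deviation of a weighted Kolmogorov-Smirnov running sum
down the ranked list (hit increment |r|^p normalized over set hits, miss
decrement 1/(N - N_hits)). Significance comes from phenotype-label
permutations: the normalized enrichment score (NES) divides the observed
ES by the mean magnitude of sign-matched permuted ES, nominal p is the
sign-matched permutation tail, FDR uses the pooled normalized permutation
null and FWER the per-permutation extreme-NES null. Leading-edge genes
are the set members at or before the running-sum peak (positive ES) or at
or after it (negative ES).
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    NON_RESPONDER,
    RESPONDER,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    PhenotypeTable,
)
from .simulate import substream

logger = logging.getLogger(__name__)

__all__ = [
    "RankedList",
    "GseaResult",
    "rank_genes",
    "signal_to_noise",
    "enrichment_score",
    "leading_edge",
    "permute_and_normalize",
]

RESPONDER_UP = "responder_up"
NONRESPONDER_UP = "nonresponder_up"

# variance floor of the signal-to-noise metric: each group's standard
# deviation is raised to at least max(0.2 * |mean|, 0.2)
_SD_FLOOR_FRACTION = 0.2
_SD_FLOOR_ABS = 0.2


@dataclass
class RankedList:
    """Genes ordered by descending ranking score (ties by gene ID)."""

    genes: list[str]
    scores: np.ndarray  # aligned with genes, descending

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores must align")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("ranking scores must be finite")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be in descending order")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def positions(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}


def _floored_sd(sd: np.ndarray, mean: np.ndarray) -> np.ndarray:
    return np.maximum(
        sd, np.maximum(_SD_FLOOR_FRACTION * np.abs(mean), _SD_FLOOR_ABS)
    )


def signal_to_noise(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Signal-to-noise ratio (mu_a - mu_b) / (sd_a + sd_b), row-wise.

    Group standard deviations (ddof=1) are floored as in the classic GSEA
    implementation so low-variance genes cannot dominate the ranking.
    """
    mean_a, mean_b = a.mean(axis=-1), b.mean(axis=-1)
    sd_a = _floored_sd(a.std(axis=-1, ddof=1), mean_a)
    sd_b = _floored_sd(b.std(axis=-1, ddof=1), mean_b)
    return (mean_a - mean_b) / (sd_a + sd_b)


def rank_genes(
    matrix: ExpressionMatrix, phenotypes: PhenotypeTable
) -> RankedList:
    """Rank genes by responder-vs-non-responder signal-to-noise."""
    resp = [s for s in phenotypes.samples_in_group(RESPONDER)
            if s in set(matrix.sample_ids)]
    nonresp = [s for s in phenotypes.samples_in_group(NON_RESPONDER)
               if s in set(matrix.sample_ids)]
    if len(resp) < 2 or len(nonresp) < 2:
        raise ValueError("each group needs at least 2 samples for ranking")
    log2 = matrix.log2
    scores = signal_to_noise(log2[resp].to_numpy(), log2[nonresp].to_numpy())
    order = sorted(
        range(len(scores)), key=lambda i: (-scores[i], matrix.gene_ids[i])
    )
    return RankedList(
        genes=[matrix.gene_ids[i] for i in order], scores=scores[order]
    )


def enrichment_score(
    ranked: RankedList, genes: list[str] | tuple[str, ...] | set[str],
    weight_p: float = 1.0,
) -> tuple[float, np.ndarray, int]:
    """Weighted KS enrichment score of a gene set against a ranked list.

    Returns ``(ES, running profile, peak_index)`` where the profile holds
    the running-sum value after each rank and ``peak_index`` is the
    1-based rank at which |running sum| is maximal (first occurrence on
    ties). Raises if the set does not intersect the ranked genes.
    """
    members = set(genes)
    hit = np.fromiter((g in members for g in ranked.genes), dtype=bool,
                      count=len(ranked))
    n_hits = int(hit.sum())
    n = len(ranked)
    if n_hits == 0:
        raise ValueError("gene set has no genes in the ranked list")
    weights = np.where(hit, np.abs(ranked.scores) ** weight_p, 0.0)
    total = weights.sum()
    if total == 0:  # all hit scores exactly zero: fall back to uniform hits
        weights = hit.astype(float)
        total = float(n_hits)
    if n_hits == n:
        profile = np.cumsum(weights / total)
        return 1.0, profile, int(np.argmax(profile)) + 1
    miss_dec = 1.0 / (n - n_hits)
    step = weights / total - np.where(hit, 0.0, miss_dec)
    profile = np.cumsum(step)
    # signed maximum deviation; exact ties resolve to the positive extreme
    # (matching the vectorized permutation path)
    hi, lo = profile.max(), profile.min()
    if hi >= -lo:
        peak = int(np.argmax(profile))
    else:
        peak = int(np.argmin(profile))
    return float(profile[peak]), profile, peak + 1


def leading_edge(
    ranked: RankedList,
    genes: list[str] | tuple[str, ...] | set[str],
    es: float,
    peak_index: int,
) -> list[str]:
    """Set members driving the enrichment peak, in ranked order.

    Positive ES: members at ranks <= peak; negative ES: members at ranks
    >= peak; zero ES: empty.
    """
    if es == 0:
        return []
    members = set(genes)
    if es > 0:
        return [g for g in ranked.genes[:peak_index] if g in members]
    return [g for g in ranked.genes[peak_index - 1:] if g in members]


@dataclass
class GseaResult:
    """Permutation-normalized GSEA results for a gene-set collection.

    ``table`` columns: size, es, nes, p_value, fdr, fwer, peak_index,
    n_leading_edge; ``leading_edges`` maps set name to the leading-edge
    gene list; ``directions`` names each set's enriched phenotype from
    the ES sign (positive = higher in responders).
    """

    table: pd.DataFrame
    leading_edges: dict[str, list[str]]
    ranked: RankedList
    n_permutations: int
    skipped_sets: dict[str, str] = field(default_factory=dict)

    @property
    def directions(self) -> dict[str, str]:
        return {
            name: (RESPONDER_UP if es > 0 else NONRESPONDER_UP)
            for name, es in self.table["es"].items()
            if es != 0
        }

    def top_sets(self, n_up: int = 10, n_down: int = 10) -> pd.DataFrame:
        """The strongest positive and negative NES rows (Table-2-style)."""
        ordered = self.table.sort_values("nes", ascending=False)
        up = ordered[ordered["nes"] > 0].head(n_up)
        down = ordered[ordered["nes"] < 0].tail(n_down).iloc[::-1]
        return pd.concat([up, down])

    def leading_edge_collection(self, names: list[str] | None = None
                                ) -> GeneSetCollection:
        chosen = self.leading_edges if names is None else {
            n: self.leading_edges[n] for n in names
        }
        return GeneSetCollection.from_sets(
            GeneSet(name, "leading edge", tuple(genes))
            for name, genes in chosen.items()
        )


def _permutation_masks(
    n_samples: int, n_group_a: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Boolean (n_perm x n_samples) masks of permuted group-A membership.

    Enumerates every distinct assignment when fewer than ``n_perm`` exist.
    """
    total = math.comb(n_samples, n_group_a)
    if total <= n_perm:
        logger.info(
            "only %d distinct label assignments; enumerating all", total
        )
        masks = np.zeros((total, n_samples), dtype=bool)
        for i, combo in enumerate(
            itertools.combinations(range(n_samples), n_group_a)
        ):
            masks[i, list(combo)] = True
        return masks
    masks = np.zeros((n_perm, n_samples), dtype=bool)
    for i in range(n_perm):
        masks[i, rng.permutation(n_samples)[:n_group_a]] = True
    return masks


def _batch_signal_to_noise(x: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Signal-to-noise for every permutation at once.

    ``x`` is genes x samples, ``masks`` is perms x samples (True = group
    A). Returns genes x perms.
    """
    n_a = masks[0].sum()
    n_b = masks.shape[1] - n_a
    ma = masks.T.astype(float)  # samples x perms
    mb = 1.0 - ma
    sum_a = x @ ma
    sum_b = x @ mb
    sumsq_a = (x**2) @ ma
    sumsq_b = (x**2) @ mb
    mean_a, mean_b = sum_a / n_a, sum_b / n_b
    var_a = np.maximum(sumsq_a - n_a * mean_a**2, 0.0) / (n_a - 1)
    var_b = np.maximum(sumsq_b - n_b * mean_b**2, 0.0) / (n_b - 1)
    sd_a = _floored_sd(np.sqrt(var_a), mean_a)
    sd_b = _floored_sd(np.sqrt(var_b), mean_b)
    return (mean_a - mean_b) / (sd_a + sd_b)


def _batch_es(
    positions: np.ndarray, weights: np.ndarray, n_genes: int
) -> np.ndarray:
    """ES per permutation from hit positions and hit weights.

    ``positions``: k x P 0-based rank positions of the set members per
    permutation; ``weights``: k x P corresponding |score|^p. Exploits the
    fact that the running sum is extremal only adjacent to hits.
    """
    k, n_perm = positions.shape
    if k == n_genes:
        return np.ones(n_perm)
    order = np.argsort(positions, axis=0)
    pos = np.take_along_axis(positions, order, axis=0)
    w = np.take_along_axis(weights, order, axis=0)
    total = w.sum(axis=0)
    zero = total == 0
    if zero.any():
        w[:, zero] = 1.0
        total = w.sum(axis=0)
    cum = np.cumsum(w, axis=0) / total
    miss = (pos - np.arange(k)[:, None]) / (n_genes - k)
    after = cum - miss
    before = np.vstack([np.zeros(n_perm), cum[:-1]]) - miss
    max_after = after.max(axis=0)
    min_before = np.minimum(before.min(axis=0), 0.0)
    return np.where(max_after >= -min_before, max_after, min_before)


def permute_and_normalize(
    matrix: ExpressionMatrix,
    phenotypes: PhenotypeTable,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
    min_size: int = 15,
    max_size: int = 500,
) -> GseaResult:
    """Phenotype-permutation GSEA over a gene-set collection.

    Sets are intersected with the matrix genes and filtered to
    ``min_size <= size <= max_size``. NES, nominal p, FDR and FWER are all
    computed from one shared permutation stream; when fewer distinct
    label assignments than ``n_perm`` exist they are enumerated instead.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    resp = phenotypes.samples_in_group(RESPONDER)
    nonresp = phenotypes.samples_in_group(NON_RESPONDER)
    if len(resp) < 2 or len(nonresp) < 2:
        raise ValueError("each group needs at least 2 samples")
    samples = resp + nonresp
    x = matrix.log2[samples].to_numpy()
    gene_ids = matrix.gene_ids
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    n_genes = len(gene_ids)

    kept: list[tuple[str, list[str]]] = []
    skipped: dict[str, str] = {}
    for gs in sorted(sets, key=lambda s: s.name):
        inside = [g for g in gs.genes if g in gene_pos]
        if not inside:
            skipped[gs.name] = "no genes in expression matrix"
        elif len(inside) < min_size:
            skipped[gs.name] = f"size {len(inside)} below min_size {min_size}"
        elif len(inside) > max_size:
            skipped[gs.name] = f"size {len(inside)} above max_size {max_size}"
        else:
            kept.append((gs.name, inside))
    for name, reason in skipped.items():
        logger.info("skipping set %r: %s", name, reason)
    if not kept:
        raise ValueError("no gene set passed the size filters")

    # observed statistics via the scalar path (gives profiles/leading edges)
    ranked = rank_genes(matrix, phenotypes)
    observed_es = np.empty(len(kept))
    peaks: list[int] = []
    edges: dict[str, list[str]] = {}
    for i, (name, inside) in enumerate(kept):
        es, _, peak = enrichment_score(ranked, inside, weight_p)
        observed_es[i] = es
        peaks.append(peak)
        edges[name] = leading_edge(ranked, inside, es, peak)

    rng = substream(seed, "gsea-permutations")
    masks = _permutation_masks(len(samples), len(resp), n_perm, rng)
    n_used = masks.shape[0]
    scores = _batch_signal_to_noise(x, masks)  # genes x perms
    order = np.argsort(-scores, axis=0, kind="stable")
    inv = np.empty_like(order)
    inv[order, np.arange(n_used)[None, :]] = np.arange(n_genes)[:, None]
    abs_w = np.abs(scores) ** weight_p

    perm_es = np.empty((len(kept), n_used))
    for i, (name, inside) in enumerate(kept):
        rows = [gene_pos[g] for g in inside]
        perm_es[i] = _batch_es(inv[rows, :], abs_w[rows, :], n_genes)

    # sign-matched normalization constants per set
    pos_mean = np.array([
        row[row > 0].mean() if (row > 0).any() else np.nan for row in perm_es
    ])
    neg_mean = np.array([
        (-row[row < 0]).mean() if (row < 0).any() else np.nan for row in perm_es
    ])

    nes = np.full(len(kept), np.nan)
    nominal_p = np.ones(len(kept))
    for i, es in enumerate(observed_es):
        row = perm_es[i]
        if es > 0:
            n_pos = (row > 0).sum()
            nominal_p[i] = ((row >= es).sum() / n_pos) if n_pos else 1.0
            nes[i] = es / pos_mean[i] if np.isfinite(pos_mean[i]) else np.nan
        elif es < 0:
            n_neg = (row < 0).sum()
            nominal_p[i] = ((row <= es).sum() / n_neg) if n_neg else 1.0
            nes[i] = es / neg_mean[i] if np.isfinite(neg_mean[i]) else np.nan
        else:
            nes[i] = 0.0
            nominal_p[i] = 1.0
    missing = [kept[i][0] for i in range(len(kept)) if np.isnan(nes[i])]
    for name in missing:
        logger.warning(
            "set %r has an empty sign-matched permutation null; NES missing",
            name,
        )

    # normalized permutation null (sets x perms), sign-matched scaling
    with np.errstate(invalid="ignore"):
        norm_null = np.where(
            perm_es > 0,
            perm_es / pos_mean[:, None],
            perm_es / neg_mean[:, None],
        )
    valid = ~np.isnan(nes)
    fdr = np.full(len(kept), np.nan)
    fwer = np.full(len(kept), np.nan)
    null_valid = norm_null[valid]
    pos_null = null_valid[null_valid > 0]
    neg_null = null_valid[null_valid < 0]
    obs_valid = nes[valid]
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # permutations with no sign-matched null leave an all-NaN column
        warnings.simplefilter("ignore", RuntimeWarning)
        max_per_perm = np.nanmax(np.where(null_valid > 0, null_valid, np.nan),
                                 axis=0)
        min_per_perm = np.nanmin(np.where(null_valid < 0, null_valid, np.nan),
                                 axis=0)
    for i in range(len(kept)):
        if np.isnan(nes[i]):
            continue
        v = nes[i]
        if v > 0:
            null_tail = (pos_null >= v).sum() / len(pos_null) if len(pos_null) else 0
            obs_tail = (obs_valid >= v).sum() / max((obs_valid > 0).sum(), 1)
            fwer[i] = np.mean(np.nan_to_num(max_per_perm, nan=-np.inf) >= v)
        elif v < 0:
            null_tail = (neg_null <= v).sum() / len(neg_null) if len(neg_null) else 0
            obs_tail = (obs_valid <= v).sum() / max((obs_valid < 0).sum(), 1)
            fwer[i] = np.mean(np.nan_to_num(min_per_perm, nan=np.inf) <= v)
        else:
            fdr[i] = 1.0
            fwer[i] = 1.0
            continue
        fdr[i] = min(1.0, null_tail / obs_tail) if obs_tail > 0 else 1.0

    table = pd.DataFrame(
        {
            "size": [len(inside) for _, inside in kept],
            "es": observed_es,
            "nes": nes,
            "p_value": nominal_p,
            "fdr": fdr,
            "fwer": fwer,
            "peak_index": peaks,
            "n_leading_edge": [len(edges[name]) for name, _ in kept],
        },
        index=pd.Index([name for name, _ in kept], name="set"),
    )
    return GseaResult(
        table=table,
        leading_edges=edges,
        ranked=ranked,
        n_permutations=n_used,
        skipped_sets=skipped,
    )
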