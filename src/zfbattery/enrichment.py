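"""Gene-set enrichment of bulk differential-expression results.

The transcriptomic stage consumes a DE table (gene, log2 fold change,
p-value, BH-adjusted p) and asks which gene sets — typically the top-k
marker genes of single-cell clusters, or curated ontology sets — are
enriched among the most regulated genes.  Three statistics are provided:

* DEG filtering and 3-way Venn partition of gene lists (p < 0.05 and
  |log2FC| > 0.2 by default, both strict);
* the GSEA running-sum enrichment score: walking down a signed gene
  ranking, set members ("hits") increment the sum by their normalized
  |score|^p weight and non-members decrement it by 1/(N − N_hit); the ES
  is the signed extremum, the leading edge the hits at or before it (at
  or after it for negative ES).  Significance uses a gene-set permutation
  null (random same-size sets), a sign-matched normalized ES, and BH FDR
  across sets;
* hypergeometric over-representation (ORA) of a query list against each
  set within a finite universe.

Marker sets are built from a cluster-labeled expression matrix by
one-vs-rest rank-sum tests on log-normalized counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError, logger

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "filter_degs",
    "venn_overlap",
    "rank_genes",
    "build_marker_sets",
    "gsea_es",
    "gsea_significance",
    "ora",
]


@dataclass
class GeneSet:
    """Named gene set with unique members (order preserved)."""

    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        self.members = tuple(self.members)
        if len(set(self.members)) != len(self.members):
            raise ValidationError(f"gene set {self.name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p_value: float
    q_value: float
    n_hits: int
    leading_edge: list[str] = field(default_factory=list)


def filter_degs(table: pd.DataFrame, p_max: float = 0.05,
                lfc_min: float = 0.2) -> list[str]:
    """Genes with p_value < p_max (strict) and |log2FC| > lfc_min
    (strict); up- and down-regulated genes are combined."""
    if not len(table):
        return []
    keep = (table["pvalue"] < p_max) & (table["log2FoldChange"].abs() > lfc_min)
    return table.loc[keep, "gene"].tolist()


def venn_overlap(lists: Sequence[Iterable[str]]) -> dict[str, int]:
    """Counts for the 7 disjoint regions of a 3-set Venn diagram.

    Keys are membership patterns over the three input lists in order:
    '100' = first list only, '110' = first and second only, ... '111' =
    all three.  Counts sum to the size of the union.
    """
    if len(lists) != 3:
        raise ValidationError("venn_overlap takes exactly 3 gene lists")
    sets = [set(l) for l in lists]
    counts = {f"{a}{b}{c}": 0
              for a in (0, 1) for b in (0, 1) for c in (0, 1)
              if a or b or c}
    for g in set.union(*sets):
        key = "".join("1" if g in s else "0" for s in sets)
        counts[key] += 1
    return counts


def rank_genes(table: pd.DataFrame, metric: str = "signed_logp") -> pd.DataFrame:
    """Signed gene ranking for GSEA, descending by score.

    ``signed_logp`` = sign(log2FC) * (−log10 p); ``log2FC`` ranks by the
    fold change itself.  Ties break by gene id (lexicographic); rows with
    missing scores are excluded with a warning.
    """
    if table["gene"].duplicated().any():
        raise ValidationError("duplicate gene ids in ranking input")
    if metric == "signed_logp":
        p = np.clip(table["pvalue"].to_numpy(dtype=float), 1e-300, None)
        score = np.sign(table["log2FoldChange"].to_numpy(dtype=float)) * (-np.log10(p))
    elif metric == "log2FC":
        score = table["log2FoldChange"].to_numpy(dtype=float)
    else:
        raise ValidationError(f"unknown ranking metric {metric!r}")
    out = pd.DataFrame({"gene": table["gene"].to_numpy(), "score": score})
    bad = out["score"].isna()
    if bad.any():
        logger.warning("excluding %d gene(s) with missing scores", int(bad.sum()))
        out = out[~bad]
    out = out.sort_values(["score", "gene"], ascending=[False, True],
                          kind="mergesort", ignore_index=True)
    return out


def build_marker_sets(matrix: pd.DataFrame, labels: pd.Series, k: int = 500,
                      alpha: float = 0.05) -> list[GeneSet]:
    """Top-k marker gene sets per cluster by one-vs-rest rank-sum tests.

    Counts are log-normalized (counts per 10k, log1p) per cell; for each
    cluster, genes are tested in-cluster vs rest (two-sided Mann-Whitney),
    BH-adjusted, filtered to positive log fold-change and padj < alpha,
    ordered by (padj ascending, logFC descending, gene id) and truncated
    at k.  Clusters with fewer than 2 cells are skipped with a warning.
    """
    if matrix.shape[0] != len(labels):
        raise ValidationError("labels must match matrix rows (cells)")
    values = matrix.to_numpy(dtype=float)
    totals = values.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    logn = np.log1p(values / totals * 1e4)
    genes = np.asarray(matrix.columns)
    lab = np.asarray(labels)
    sets: list[GeneSet] = []
    for cluster in sorted(set(lab)):
        mask = lab == cluster
        if mask.sum() < 2 or (~mask).sum() < 2:
            logger.warning("cluster %r too small; skipped", cluster)
            continue
        inside = logn[mask]
        outside = logn[~mask]
        with np.errstate(divide="ignore", invalid="ignore"):
            res = sps.mannwhitneyu(inside, outside, axis=0, alternative="two-sided")
        pvals = np.nan_to_num(res.pvalue, nan=1.0)
        padj = sps.false_discovery_control(pvals)
        lfc = inside.mean(axis=0) - outside.mean(axis=0)
        order = pd.DataFrame({"gene": genes, "padj": padj, "lfc": lfc})
        order = order[(order["lfc"] > 0) & (order["padj"] < alpha)]
        order = order.sort_values(["padj", "lfc", "gene"],
                                  ascending=[True, False, True], kind="mergesort")
        sets.append(GeneSet(str(cluster), f"markers of cluster {cluster}",
                            tuple(order["gene"].head(k))))
    return sets


# ---------------------------------------------------------------------------
# GSEA running sum

def _hit_weights(scores: np.ndarray, hit_mask: np.ndarray, p: float) -> np.ndarray:
    w = np.abs(scores[hit_mask]) ** p
    total = w.sum()
    if total <= 0:  # all-zero scores degenerate to unweighted hits
        return np.full(hit_mask.sum(), 1.0 / hit_mask.sum())
    return w / total


def gsea_es(ranking: pd.DataFrame, gene_set: GeneSet, weight: float = 1.0
            ) -> tuple[float, np.ndarray, list[str]]:
    """Enrichment score of one set against a ranking.

    Returns ``(ES, running_sum, leading_edge)`` where ``running_sum`` has
    one value per ranked gene.  The set must intersect the ranking and
    must not cover it entirely.
    """
    genes = ranking["gene"].to_numpy()
    scores = ranking["score"].to_numpy(dtype=float)
    n = len(genes)
    hit_mask = np.isin(genes, list(gene_set.members))
    n_hit = int(hit_mask.sum())
    if n_hit == 0:
        raise ValidationError(f"set {gene_set.name!r} does not intersect the ranking")
    if n_hit == n:
        raise ValidationError(f"set {gene_set.name!r} covers the whole ranking")
    increments = np.where(hit_mask, 0.0, -1.0 / (n - n_hit))
    increments[hit_mask] = _hit_weights(scores, hit_mask, weight)
    running = np.cumsum(increments)
    i_ext = int(np.argmax(np.abs(running)))
    es = float(running[i_ext])
    if es >= 0:
        leading = genes[: i_ext + 1][hit_mask[: i_ext + 1]]
    else:
        leading = genes[i_ext:][hit_mask[i_ext:]]
    return es, running, list(leading)


def _es_from_positions(positions: np.ndarray, weights: np.ndarray, n: int) -> float:
    """ES from sorted 0-based hit positions — O(m) per evaluation.

    Between hits the running sum falls linearly, so its extrema occur just
    after a hit (candidate maxima) or just before one (candidate minima).
    """
    m = len(positions)
    miss = 1.0 / (n - m)
    cum = np.cumsum(weights)
    k = np.arange(m)
    after = cum - (positions - k) * miss          # value at each hit
    before = np.concatenate(([0.0], cum[:-1])) - (positions - k) * miss
    i_hi = int(np.argmax(after))
    i_lo = int(np.argmin(before))
    hi = float(after[i_hi])
    # normalized weights make the running sum end at exactly 0, so the
    # minimum is always attained just before some hit
    lo = float(before[i_lo])
    if hi > -lo:
        return hi
    if hi < -lo:
        return lo
    # exact tie on |ES|: earliest extremum wins, matching the full walk
    return lo if positions[i_lo] - 1 < positions[i_hi] else hi


def gsea_significance(ranking: pd.DataFrame, sets: Sequence[GeneSet],
                      weight: float = 1.0, n_perm: int = 1000,
                      seed: int = 0) -> list[EnrichmentResult]:
    """GSEA with a gene-set permutation null.

    For each set, null enrichment scores come from random gene sets of
    the same size drawn from the ranking; NES divides the observed ES by
    the mean |null ES| of matching sign, and p conditions on the sign:
    (1 + #{same-sign null at least as extreme}) / (1 + #{same-sign
    null}), so null p-values are uniform overall.  q-values are BH
    across sets.
    """
    if n_perm < 50:
        warnings.warn("n_perm < 50 gives unstable q-values", stacklevel=2)
    scores = ranking["score"].to_numpy(dtype=float)
    n = len(scores)
    rng = np.random.default_rng(seed)
    results: list[EnrichmentResult] = []
    for gene_set in sets:
        es, _, leading = gsea_es(ranking, gene_set, weight)
        m = int(np.isin(ranking["gene"].to_numpy(), list(gene_set.members)).sum())
        null = np.empty(n_perm)
        for r in range(n_perm):
            pos = np.sort(rng.choice(n, m, replace=False))
            w = np.abs(scores[pos]) ** weight
            total = w.sum()
            w = w / total if total > 0 else np.full(m, 1.0 / m)
            null[r] = _es_from_positions(pos, w, n)
        if es >= 0:
            same = null[null > 0]
            extreme = int(np.sum(same >= es - 1e-12))
        else:
            same = null[null < 0]
            extreme = int(np.sum(same <= es + 1e-12))
        p = (1 + extreme) / (1 + len(same))
        nes = float(es / np.abs(same).mean()) if len(same) else float("nan")
        results.append(EnrichmentResult(gene_set.name, es, nes, p, float("nan"),
                                        m, leading))
    qs = sps.false_discovery_control([r.p_value for r in results]) \
        if results else []
    for r, q in zip(results, qs):
        r.q_value = float(q)
    return results


def ora(query: Iterable[str], sets: Sequence[GeneSet],
        universe: Iterable[str]) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each set.

    p = P(X >= observed overlap) for X ~ Hypergeometric(|universe|,
    |set ∩ universe|, |query|); q is BH across sets.
    """
    uni = set(universe)
    if not uni:
        raise ValidationError("empty universe")
    q = set(query)
    if not q <= uni:
        raise ValidationError("query genes outside the universe")
    rows = []
    for s in sets:
        members = set(s.members) & uni
        overlap = len(members & q)
        p = float(sps.hypergeom.sf(overlap - 1, len(uni), len(members), len(q)))
        rows.append({"set": s.name, "overlap": overlap, "set_size": len(members),
                     "query_size": len(q), "p_value": min(p, 1.0)})
    out = pd.DataFrame(rows, columns=["set", "overlap", "set_size",
                                      "query_size", "p_value"])
    if len(out):
        out["q_value"] = sps.false_discovery_control(out["p_value"].to_numpy())
    else:
        out["q_value"] = []
    return out
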