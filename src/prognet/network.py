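"""Global regulatory-network inference from expression profiles.

The procedure mirrors the classical MI reverse-engineering recipe: score
every TF-involved pair by mutual information, keep pairs above a
permutation-calibrated Bonferroni threshold, prune indirect links with the
data processing inequality (DPI), and stabilize the result by bootstrap
consensus voting over resampled cohorts.

Pairs are scored once per unordered pair (a TF-TF pair is never computed
twice).  Stored edges are directed TF -> target; for a significant TF-TF
pair each TF appears in the other's regulon, since MI alone cannot orient
the link.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from .mi import _mi_from_bins, estimate_mi, mi_threshold, n_bins, rank_bins
from .types import (
    ConsensusNetwork,
    ExpressionMatrix,
    MIThreshold,
    NetworkEdge,
    ProbeGeneMap,
    PrognetError,
)

logger = logging.getLogger(__name__)

Pair = frozenset


def apply_dpi(edges: list[NetworkEdge], epsilon: float = 0.0) -> list[NetworkEdge]:
    """Data-processing-inequality pruning of fully connected triangles.

    For every triangle (i, j, k) whose three pairs are all present, the edge
    (i, j) is marked for removal when ``mi_ij < min(mi_ik, mi_jk) * (1 -
    epsilon)`` — strictly, so exact ties survive.  All removals are applied
    simultaneously after scanning every triangle, which makes the result
    independent of edge order.
    """
    if not (0.0 <= epsilon < 1.0):
        raise PrognetError("epsilon must be in [0, 1)")
    pair_mi: dict[frozenset, float] = {}
    for e in edges:
        pair_mi[Pair((e.regulator, e.target))] = e.mi
    neighbors: dict[str, set[str]] = {}
    for p in pair_mi:
        a, b = tuple(p)
        neighbors.setdefault(a, set()).add(b)
        neighbors.setdefault(b, set()).add(a)
    doomed: set[frozenset] = set()
    for p, mi_ij in pair_mi.items():
        i, j = tuple(p)
        for k in neighbors[i] & neighbors[j]:
            mi_ik = pair_mi[Pair((i, k))]
            mi_jk = pair_mi[Pair((j, k))]
            if mi_ij < min(mi_ik, mi_jk) * (1.0 - epsilon):
                doomed.add(p)
                break
    return [e for e in edges if Pair((e.regulator, e.target)) not in doomed]


def _pair_list(tf_ids: list[str], features: list[str]) -> list[tuple[str, str]]:
    """All unordered TF-involved pairs, TF listed first; TF-TF pairs once."""
    tf_set = set(tf_ids)
    pairs: list[tuple[str, str]] = []
    for i, tf in enumerate(tf_ids):
        for g in features:
            if g == tf:
                continue
            if g in tf_set and tf_ids.index(g) < i:
                continue  # TF-TF pair already emitted from the other side
            pairs.append((tf, g))
    return pairs


def _directed_edges(
    pairs: dict[tuple[str, str], tuple[float, int]], tf_set: set[str]
) -> list[NetworkEdge]:
    """Expand unordered TF-involved pairs into directed TF -> target edges."""
    edges: list[NetworkEdge] = []
    for (a, b), (mi, support) in pairs.items():
        edges.append(NetworkEdge(a, b, mi, support))
        if b in tf_set:
            edges.append(NetworkEdge(b, a, mi, support))
    return edges


def present_tfs(expr: ExpressionMatrix, tf_ids: list[str]) -> list[str]:
    """TFs measured in the matrix; absent ones are dropped with a warning."""
    feats = set(expr.feature_ids)
    present = [t for t in tf_ids if t in feats]
    absent = [t for t in tf_ids if t not in feats]
    if absent:
        logger.warning("dropping %d TF(s) absent from matrix: %s", len(absent), absent[:10])
    if not present:
        raise PrognetError("no TF from the list is present in the expression matrix")
    return present


def infer_single_network(
    expr: ExpressionMatrix,
    tf_ids: list[str],
    threshold: MIThreshold,
    epsilon: float = 0.0,
) -> list[NetworkEdge]:
    """One-shot network: MI-thresholded TF-involved pairs, DPI-pruned."""
    tfs = present_tfs(expr, tf_ids)
    values = expr.data.to_numpy(dtype=float)
    n = values.shape[1]
    bins = n_bins(n)
    binned = {f: rank_bins(values[i], bins) for i, f in enumerate(expr.feature_ids)}
    constant = {f for i, f in enumerate(expr.feature_ids) if np.ptp(values[i]) == 0}
    tf_set = set(tfs)
    kept: dict[tuple[str, str], tuple[float, int]] = {}
    for tf, g in _pair_list(tfs, expr.feature_ids):
        if tf in constant or g in constant:
            continue
        mi = _mi_from_bins(binned[tf], binned[g], bins, n)
        if mi >= threshold.threshold_mi:
            kept[(tf, g)] = (mi, 1)
    edges = _directed_edges(kept, tf_set)
    return apply_dpi(edges, epsilon)


def bootstrap_consensus(
    expr: ExpressionMatrix,
    tf_ids: list[str],
    B: int = 100,
    alpha: float = 0.05,
    epsilon: float = 0.0,
    seed: int = 0,
    n_perm: int = 1000,
    level: str = "gene",
) -> ConsensusNetwork:
    """Bootstrap-consensus network over ``B`` resampled cohorts.

    Each replicate resamples samples with replacement, recalibrates the MI
    threshold on the replicate, infers a network and votes for its edges.
    An edge enters the consensus when its support count is significant under
    Binomial(B, p_hat), where p_hat is the pooled per-pair occurrence rate,
    at Bonferroni-corrected ``alpha`` over candidate pairs.  Consensus MI is
    the mean over the supporting replicates.
    """
    if B < 2:
        raise PrognetError("need at least 2 bootstrap replicates")
    n = expr.n_samples
    if n < 8:
        raise PrognetError(f"too few samples for bootstrap resampling ({n} < 8)")
    tfs = present_tfs(expr, tf_ids)
    candidate_pairs = _pair_list(tfs, expr.feature_ids)
    n_pairs = len(candidate_pairs)
    rng = np.random.default_rng(seed)
    support: dict[frozenset, int] = {}
    mi_sum: dict[frozenset, float] = {}
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        boot = ExpressionMatrix(expr.data.iloc[:, idx].set_axis(
            [f"b{i}" for i in range(n)], axis=1), expr.cohort_label)
        thr = mi_threshold(
            n_samples=n,
            n_tests=n_pairs,
            alpha=alpha,
            n_perm=n_perm,
            seed=int(rng.integers(0, 2**31 - 1)),
            resample_idx=idx,
        )
        edges = infer_single_network(boot, tfs, thr, epsilon)
        seen: set[frozenset] = set()
        for e in edges:
            p = Pair((e.regulator, e.target))
            if p in seen:
                continue
            seen.add(p)
            support[p] = support.get(p, 0) + 1
            mi_sum[p] = mi_sum.get(p, 0.0) + e.mi
    total = sum(support.values())
    if total == 0:
        return ConsensusNetwork([], B=B, level=level)
    p_hat = total / (B * n_pairs)
    cut = alpha / n_pairs
    tf_set = set(tfs)
    consensus: dict[tuple[str, str], tuple[float, int]] = {}
    for tf, g in candidate_pairs:
        p = Pair((tf, g))
        s = support.get(p, 0)
        if s == 0:
            continue
        # P(Binomial(B, p_hat) >= s)
        pval = stats.binom.sf(s - 1, B, p_hat)
        if pval < cut:
            consensus[(tf, g)] = (mi_sum[p] / s, s)
    return ConsensusNetwork(_directed_edges(consensus, tf_set), B=B, level=level)


def collapse_probes(net: ConsensusNetwork, pmap: ProbeGeneMap) -> ConsensusNetwork:
    """Merge a probe-level network to gene level.

    Duplicate gene pairs keep the maximal MI and maximal support (the most
    optimistic evidence across probes); edges between two probes of the same
    gene become self-loops and are dropped.
    """
    if net.level != "probe":
        raise PrognetError("collapse_probes expects a probe-level network")
    gene_of = pmap.gene_of
    missing = sorted({p for e in net.edges for p in (e.regulator, e.target)
                      if p not in gene_of})
    if missing:
        raise PrognetError(f"probe(s) absent from probe-gene map: {missing}")
    merged: dict[tuple[str, str], tuple[float, int]] = {}
    for e in net.edges:
        reg, tgt = gene_of[e.regulator], gene_of[e.target]
        if reg == tgt:
            continue
        prev = merged.get((reg, tgt))
        if prev is None:
            merged[(reg, tgt)] = (e.mi, e.support)
        else:
            merged[(reg, tgt)] = (max(prev[0], e.mi), max(prev[1], e.support))
    edges = [NetworkEdge(r, t, mi, s) for (r, t), (mi, s) in merged.items()]
    return ConsensusNetwork(edges, B=net.B, level="gene")


def edge_recovery(
    inferred: ConsensusNetwork | list[NetworkEdge],
    true_pairs: set[tuple[str, str]],
) -> tuple[float, float]:
    """(precision, recall) of inferred vs planted links, compared as
    unordered pairs because MI cannot orient an edge."""
    edges = inferred.edges if isinstance(inferred, ConsensusNetwork) else inferred
    inf_pairs = {Pair((e.regulator, e.target)) for e in edges}
    tru = {Pair(p) for p in true_pairs}
    if not inf_pairs:
        return (float("nan"), 0.0)
    tp = len(inf_pairs & tru)
    return tp / len(inf_pairs), tp / len(tru)
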