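"""Synthetic two-cohort generator with a planted regulatory ground truth.

Emulates, at desk scale, the statistical structure the pipeline expects
from a pair of microarray colorectal-cancer cohorts:

* a set of TFs and a bipartite TF -> target network with signed linear
  coefficients, plus occasional TF -> TF edges so that the network has the
  higher-order structure the downstream analysis must tolerate;
* prognostic groups (good / poor) that shift the expression of each TF in
  a planted direction, which propagates to the targets;
* a risk-classed signature drawn from the regulated targets — low-risk
  genes are up in the good-prognosis group, high-risk genes down — ordered
  by planted differential-expression magnitude;
* disease-free survival times that are exponential within group with a
  higher hazard in the poor group, administratively censored.

Baseline expression is fixed at 7.0 log2 units (a typical microarray
midrange); the absolute scale is irrelevant to every rank or correlation
statistic downstream.  Same seed means identical cohorts; each cohort
label draws from its own deterministic sub-stream.
"""

from __future__ import annotations

import logging
import zlib

import numpy as np
import pandas as pd

from .effect import assign_effect
from .types import (
    ACTIVATION,
    GOOD,
    HIGH,
    LOW,
    POOR,
    REPRESSION,
    CohortConfig,
    ExpressionMatrix,
    GroundTruth,
    GroupLabels,
    PrognetError,
    Signature,
    SurvivalTable,
)

logger = logging.getLogger(__name__)

BASELINE = 7.0


def _tf_name(i: int) -> str:
    return f"TF{i + 1:03d}"


def _gene_name(i: int) -> str:
    return f"G{i + 1:04d}"


def generate_truth(config: CohortConfig) -> GroundTruth:
    """Plant a random TF -> target structure with prognostic directions.

    Every TF gets a regulon of uniformly drawn size within
    ``regulon_size_range`` (targets sampled without replacement, so a
    target may answer to several TFs), a nonzero coefficient per edge with
    |beta| in [0.5, 1.5] and random sign; a planted fraction of TFs is
    prognostic, with a direction (up or down in the good group) that
    propagates to their targets.  TF -> TF edges are added from earlier to
    later TFs with probability ``tf_tf_prob`` (keeping the structure
    acyclic).  The signature is the ``n_signature`` regulated targets with
    the largest planted group difference; risk class follows its sign.
    The planted prognostic effect of each TF is computed from its edge
    signs and its signature targets' risk classes by the same majority rule
    the pipeline applies.
    """
    rng = np.random.default_rng(config.seed)
    tfs = [_tf_name(i) for i in range(config.n_tfs)]
    genes = [_gene_name(i) for i in range(config.n_targets)]
    lo, hi = config.regulon_size_range

    def draw_beta() -> float:
        return float(rng.uniform(0.5, 1.5) * rng.choice([-1.0, 1.0]))

    edges: list[tuple[str, str, float]] = []
    for tf in tfs:
        size = int(rng.integers(lo, hi + 1))
        for g in rng.choice(config.n_targets, size=size, replace=False):
            edges.append((tf, genes[g], draw_beta()))
    for j in range(1, config.n_tfs):
        if rng.random() < config.tf_tf_prob:
            i = int(rng.integers(0, j))
            edges.append((tfs[i], tfs[j], draw_beta()))

    # A subset of TFs is prognostic (direction +1 = up in the good group,
    # -1 = down, 0 = no group dependence).  Only their targets acquire a
    # planted group difference, so the signature concentrates in the
    # prognostic TFs' regulons — the master-regulator structure the
    # downstream enrichment is meant to find.
    n_prog = max(1, round(config.prognostic_tf_fraction * config.n_tfs))
    prog_set = set(rng.choice(config.n_tfs, size=n_prog, replace=False).tolist())
    direction = {
        tf: (float(rng.choice([-1.0, 1.0])) if i in prog_set else 0.0)
        for i, tf in enumerate(tfs)
    }

    # good-minus-poor group mean difference, propagated through TF-TF edges
    diff: dict[str, float] = {tf: direction[tf] * config.group_shift for tf in tfs}
    for tf, target, beta in edges:  # edges go from earlier to later TFs: one pass
        if target in diff:
            diff[target] += beta * diff[tf]
    gene_diff: dict[str, float] = {}
    for tf, target, beta in edges:
        if target not in diff:
            gene_diff[target] = gene_diff.get(target, 0.0) + beta * diff[tf]

    informative = {g: d for g, d in gene_diff.items() if abs(d) > 1e-9}
    if not informative:
        raise PrognetError("no regulated target carries a planted group difference")
    n_sig = min(config.n_signature, len(informative))
    chosen = sorted(informative, key=lambda g: -abs(informative[g]))[:n_sig]
    entries = [(g, LOW if informative[g] > 0 else HIGH) for g in chosen]
    signature = Signature(entries, {g: abs(informative[g]) for g in chosen})

    risk = signature.risk_of
    prognostic: dict[str, str] = {}
    for tf in tfs:
        pairs = [
            (risk[t], ACTIVATION if b > 0 else REPRESSION)
            for tf2, t, b in edges
            if tf2 == tf and t in risk
        ]
        if pairs:
            prognostic[tf] = assign_effect(pairs)
    return GroundTruth(
        tf_ids=tfs,
        edges=edges,
        signature=signature,
        prognostic_tfs=prognostic,
        tf_direction=direction,
        group_diff={**{t: d for t, d in diff.items()}, **gene_diff},
    )


def _cohort_rng(config: CohortConfig, cohort_label: str) -> np.random.Generator:
    sub = zlib.crc32(cohort_label.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence((config.seed, sub)))


def simulate_expression(
    truth: GroundTruth, config: CohortConfig, cohort_label: str
) -> tuple[ExpressionMatrix, GroupLabels]:
    """Draw one cohort's expression matrix and its prognostic groups.

    TFs are Normal(baseline, 1) plus +-group_shift/2 in their planted
    direction per group; a regulated feature adds ``sum_edges beta * (TF -
    TF mean)`` plus Normal(0, noise_sd) — or Normal(0, 1) when the feature
    is itself a TF, which keeps unit-scale TF variability.  Two cohorts
    generated from the same truth share structure but use independent
    noise sub-streams keyed by the cohort label.
    """
    rng = _cohort_rng(config, cohort_label)
    n = config.n_samples
    samples = [f"{cohort_label}_S{i + 1:04d}" for i in range(n)]
    group = np.where(rng.random(n) < 0.5, GOOD, POOR)
    sign = np.where(group == GOOD, 1.0, -1.0)

    parents: dict[str, list[tuple[str, float]]] = {}
    for tf, target, beta in truth.edges:
        parents.setdefault(target, []).append((tf, beta))

    expr: dict[str, np.ndarray] = {}
    # TFs first (edges only go from earlier to later TFs, so order works)
    for tf in truth.tf_ids:
        shift = truth.tf_direction[tf] * config.group_shift / 2.0 * sign
        centered = np.zeros(n)
        for p, beta in parents.get(tf, []):
            centered += beta * (expr[p] - BASELINE)
        expr[tf] = BASELINE + shift + centered + rng.normal(0.0, 1.0, size=n)
    all_genes = [_gene_name(i) for i in range(config.n_targets)]
    for g in all_genes:
        if g in parents:
            centered = np.zeros(n)
            for p, beta in parents[g]:
                centered += beta * (expr[p] - BASELINE)
            expr[g] = BASELINE + centered + rng.normal(0.0, config.noise_sd, size=n)
        else:
            expr[g] = BASELINE + rng.normal(0.0, 1.0, size=n)

    features = truth.tf_ids + all_genes
    data = pd.DataFrame(
        np.vstack([expr[f] for f in features]), index=features, columns=samples
    )
    labels = GroupLabels(dict(zip(samples, group.tolist())))
    return ExpressionMatrix(data, cohort_label=cohort_label), labels


def simulate_survival(labels: GroupLabels, config: CohortConfig,
                      stream: str = "survival") -> SurvivalTable:
    """Exponential disease-free survival, censored at ``censor_time``.

    Time ~ Exponential(hazard of the sample's group); event = 0 iff the
    administrative censoring at ``censor_time`` truncates the draw.
    """
    if not labels.assignments:
        raise PrognetError("no labeled samples")
    rng = _cohort_rng(config, stream)
    records: list[tuple[str, float, int]] = []
    for sample, group in labels.assignments.items():
        hazard = config.hazard_good if group == GOOD else config.hazard_poor
        t = float(rng.exponential(1.0 / hazard))
        if t >= config.censor_time:
            records.append((sample, config.censor_time, 0))
        else:
            records.append((sample, t, 1))
    return SurvivalTable(records)


def simulate_cohorts(
    config: CohortConfig, cohort_labels: tuple[str, str] = ("discovery", "validation")
) -> dict:
    """Full study bundle: truth, two cohorts, labels and survival tables."""
    truth = generate_truth(config)
    out = {"truth": truth, "cohorts": {}}
    for label in cohort_labels:
        expr, labels = simulate_expression(truth, config, label)
        surv = simulate_survival(labels, config, stream=f"survival:{label}")
        out["cohorts"][label] = {"expression": expr, "labels": labels, "survival": surv}
    return out
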