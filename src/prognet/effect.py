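"""Regulatory-mode annotation and prognostic-effect assignment.

The regulatory mode of an edge is the sign of the Spearman rank correlation
between TF and target expression across a cohort (positive = activation,
negative = repression).  A TF's prognostic effect is "+" when strictly more
than half of its signature targets are regulated in favor of the low-risk
expression pattern — i.e. activated low-risk genes plus repressed high-risk
genes form a strict majority — and "-" otherwise.  An exact half is "-":
"more than half" is read strictly.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from .types import (
    ACTIVATION,
    HIGH,
    LOW,
    REPRESSION,
    UNDETERMINED,
    EffectRow,
    ExpressionMatrix,
    NetworkEdge,
    PrognetError,
    Signature,
)

logger = logging.getLogger(__name__)


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise PrognetError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise PrognetError("Spearman correlation undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


def annotate_modes(edges: list[NetworkEdge], expr: ExpressionMatrix) -> list[NetworkEdge]:
    """Attach mode and rho to every edge from one cohort's expression."""
    feats = set(expr.feature_ids)
    missing = sorted({g for e in edges for g in (e.regulator, e.target)} - feats)
    if missing:
        raise PrognetError(f"edge endpoint(s) missing from expression: {missing}")
    out: list[NetworkEdge] = []
    for e in edges:
        rho = spearman_rho(expr.row(e.regulator), expr.row(e.target))
        if rho > 0:
            mode = ACTIVATION
        elif rho < 0:
            mode = REPRESSION
        else:
            mode = UNDETERMINED
        out.append(NetworkEdge(e.regulator, e.target, e.mi, e.support, mode, rho))
    return out


def assign_effect(tf_targets: list[tuple[str, str]]) -> str:
    """Prognostic effect from a TF's (risk_class, mode) target pairs.

    favorable = #(activation & low-risk) + #(repression & high-risk);
    "+" iff favorable > n/2 strictly, where n counts targets with a
    determined mode.  Undetermined modes are excluded from both counts.
    """
    determined = [(r, m) for r, m in tf_targets if m in (ACTIVATION, REPRESSION)]
    if not determined:
        raise PrognetError("no target with a determined regulatory mode")
    favorable = sum(
        1
        for risk, mode in determined
        if (mode == ACTIVATION and risk == LOW) or (mode == REPRESSION and risk == HIGH)
    )
    return "+" if favorable > len(determined) / 2 else "-"


def effect_table(
    edges: list[NetworkEdge],
    expr: ExpressionMatrix,
    sig: Signature,
    tfs: list[str] | None = None,
) -> list[EffectRow]:
    """Per-TF effect summary for one cohort.

    Modes and correlations are recomputed on this cohort's expression, over
    all its samples (groups pooled).  Mean rho is taken over the TF's own
    network targets within each risk class.  TFs with no signature targets
    are skipped with a note.
    """
    risk = sig.risk_of
    annotated = annotate_modes(
        [e for e in edges if e.target in risk], expr
    )
    by_tf: dict[str, list[NetworkEdge]] = {}
    for e in annotated:
        by_tf.setdefault(e.regulator, []).append(e)
    rows: list[EffectRow] = []
    for tf in tfs if tfs is not None else sorted(by_tf):
        tf_edges = by_tf.get(tf, [])
        if not tf_edges:
            logger.info("TF %s has no signature targets in this cohort; skipped", tf)
            continue
        pairs = [(risk[e.target], e.mode) for e in tf_edges]
        low_rhos = [e.rho for e in tf_edges if risk[e.target] == LOW]
        high_rhos = [e.rho for e in tf_edges if risk[e.target] == HIGH]
        n_act_low = sum(1 for r, m in pairs if m == ACTIVATION and r == LOW)
        n_rep_high = sum(1 for r, m in pairs if m == REPRESSION and r == HIGH)
        rows.append(
            EffectRow(
                tf=tf,
                n_targets=len(tf_edges),
                n_activated_low=n_act_low,
                n_repressed_high=n_rep_high,
                effect=assign_effect(pairs),
                mean_rho_low=float(np.mean(low_rhos)) if low_rhos else float("nan"),
                mean_rho_high=float(np.mean(high_rhos)) if high_rhos else float("nan"),
                cohort_label=expr.cohort_label,
            )
        )
    return rows


def cohort_consistency(
    edges: list[NetworkEdge],
    cohorts: list[ExpressionMatrix],
    sig: Signature,
    tfs: list[str] | None = None,
) -> tuple[dict[str, list[EffectRow]], float]:
    """Effect tables per cohort plus the cross-cohort concordance.

    Concordance is the fraction of TFs (present in every cohort's table)
    whose assigned effect sign agrees across all cohorts.
    """
    if len(cohorts) < 2:
        raise PrognetError("need at least two cohorts for a concordance verdict")
    tables = {c.cohort_label: effect_table(edges, c, sig, tfs) for c in cohorts}
    per_tf: dict[str, set[str]] = {}
    counts: dict[str, int] = {}
    for rows in tables.values():
        for row in rows:
            per_tf.setdefault(row.tf, set()).add(row.effect)
            counts[row.tf] = counts.get(row.tf, 0) + 1
    common = [tf for tf, c in counts.items() if c == len(cohorts)]
    if not common:
        raise PrognetError("no TF present in every cohort")
    agree = sum(1 for tf in common if len(per_tf[tf]) == 1)
    return tables, agree / len(common)
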