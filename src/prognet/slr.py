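"""Stepwise linear regression filtering of TF -> signature-gene links.

Each signature gene's log2 expression is modeled as a linear combination of
the log2 expression of its candidate upstream TFs (the MRA-significant TFs
linked to it in the network).  A bidirectional stepwise search under AIC
picks the minimal explanatory set, coefficients with non-significant
t-tests are pruned by iterative refit, and the surviving (TF, gene) pairs
form the filtered network.  TF coverage is then recomputed and re-ranked.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
from scipy import stats

from .mra import MRARow, Regulon, competition_ranks, rank_and_select
from .types import ExpressionMatrix, LinearFit, PrognetError, Signature

logger = logging.getLogger(__name__)


def aic_score(rss: float, n: int, n_params: int) -> float:
    """AIC with additive constants dropped: ``n ln(rss/n) + 2 n_params``.

    Only AIC differences matter for selection, so the Gaussian-likelihood
    constants are omitted.  ``n_params`` counts all estimated mean
    parameters (intercept included).
    """
    if n <= n_params:
        raise PrognetError(f"saturated model: n={n} <= n_params={n_params}")
    if rss < 0:
        raise PrognetError("negative RSS")
    if rss == 0:
        warnings.warn("zero RSS: perfect fit, AIC -> -inf", stacklevel=2)
        return -math.inf
    return n * math.log(rss / n) + 2 * n_params


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Least squares with intercept column already in X; returns (beta, rss)."""
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def _fit(y: np.ndarray, cols: list[str], data: dict[str, np.ndarray]) -> tuple[np.ndarray, float, float]:
    n = len(y)
    X = np.column_stack([np.ones(n)] + [data[c] for c in cols])
    beta, rss = _ols(y, X)
    # floor RSS at numerical-noise scale so an exact fit cannot keep
    # "improving" by ulp-level residual shuffling when junk is added
    tss = float(np.sum((y - y.mean()) ** 2))
    floor = max(tss, 1.0) * 1e-12
    return beta, rss, aic_score(max(rss, floor), n, X.shape[1])


def _coef_p_values(y: np.ndarray, cols: list[str], data: dict[str, np.ndarray]) -> np.ndarray:
    """Two-sided t-test p per TF coefficient from OLS standard errors."""
    n = len(y)
    X = np.column_stack([np.ones(n)] + [data[c] for c in cols])
    beta, rss = _ols(y, X)
    df = n - X.shape[1]
    if df <= 0:
        return np.ones(len(cols))
    sigma2 = rss / df
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.maximum(np.diag(XtX_inv) * sigma2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf)
    p = 2 * stats.t.sf(np.abs(tvals), df)
    return p[1:]  # drop intercept


def _dedupe_collinear(candidates: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    kept: dict[str, np.ndarray] = {}
    for name, v in candidates.items():
        dup = next(
            (k for k, w in kept.items() if np.allclose(v, w, atol=1e-12)), None
        )
        if dup is not None:
            warnings.warn(f"dropping candidate {name!r}: duplicate of {dup!r}", stacklevel=3)
            continue
        kept[name] = v
    return kept


def stepwise_select(
    y: np.ndarray, candidates: dict[str, np.ndarray], target_gene: str = ""
) -> LinearFit:
    """Bidirectional stepwise AIC search from the intercept-only model.

    At each step the single add-or-drop move with the largest AIC decrease
    is applied; the search stops when no move decreases AIC.  With more
    candidates than the fit can support, candidates are pre-screened by
    marginal |correlation| down to n - 3.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if not candidates:
        raise PrognetError("need at least one candidate")
    data = _dedupe_collinear({k: np.asarray(v, dtype=float) for k, v in candidates.items()})
    if n <= len(data) + 2:
        keep = min(n - 3, len(data))
        if keep < 1:
            raise PrognetError(f"too few observations (n={n}) for any candidate")
        scored = sorted(
            data, key=lambda c: -abs(_safe_corr(y, data[c]))
        )[:keep]
        logger.info("pre-screened %d candidates down to %d by |corr|", len(data), keep)
        data = {c: data[c] for c in scored}
    current: list[str] = []
    _, rss, aic = _fit(y, current, data)
    while True:
        best_move: tuple[float, str, str] | None = None  # (aic, action, name)
        for c in data:
            if c in current:
                continue
            try:
                _, _, a = _fit(y, current + [c], data)
            except PrognetError:
                continue
            if best_move is None or a < best_move[0]:
                best_move = (a, "add", c)
        for c in current:
            _, _, a = _fit(y, [x for x in current if x != c], data)
            if best_move is None or a < best_move[0]:
                best_move = (a, "drop", c)
        if best_move is None or best_move[0] >= aic - 1e-12:
            break
        aic = best_move[0]
        if best_move[1] == "add":
            current.append(best_move[2])
        else:
            current.remove(best_move[2])
    beta, rss, aic = _fit(y, current, data)
    return LinearFit(
        target_gene=target_gene,
        selected_tfs=list(current),
        coefficients=beta,
        coef_p_values=_coef_p_values(y, current, data) if current else np.array([]),
        rss=rss,
        aic=aic,
        n=n,
    )


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def prune_nonsignificant(
    fit: LinearFit, candidates: dict[str, np.ndarray], y: np.ndarray, alpha: float = 0.05
) -> LinearFit:
    """Iteratively drop the TF with the worst p >= alpha and refit.

    Backward refit rather than single pass: removing one regressor changes
    the remaining coefficients' p-values.
    """
    data = {k: np.asarray(v, dtype=float) for k, v in candidates.items()}
    y = np.asarray(y, dtype=float)
    current = list(fit.selected_tfs)
    while current:
        p = _coef_p_values(y, current, data)
        worst = int(np.argmax(p))
        if p[worst] < alpha:
            break
        current.pop(worst)
    beta, rss, aic_val = _fit(y, current, data)
    return LinearFit(
        target_gene=fit.target_gene,
        selected_tfs=current,
        coefficients=beta,
        coef_p_values=_coef_p_values(y, current, data) if current else np.array([]),
        rss=rss,
        aic=aic_val,
        n=fit.n,
    )


def slr_network(
    expr: ExpressionMatrix,
    mra_rows: list[MRARow],
    regulons: list[Regulon],
    sig: Signature,
    alpha: float = 0.05,
    fdr_cut: float = 0.05,
    k: int = 10,
) -> tuple[list[tuple[str, str]], list[MRARow]]:
    """Stepwise-filter TF -> signature-gene links and re-rank by coverage.

    For each signature gene, candidates are the MRA-significant TFs whose
    regulon contains it.  Surviving pairs after stepwise selection and
    coefficient pruning form the filtered network; each TF's coverage is the
    number of signature genes that retained it, re-ranked by
    ``rank_and_select``.  Signature genes with no upstream TF are skipped.
    """
    sig_tfs = {r.tf for r in mra_rows if r.fdr < fdr_cut}
    regulon_of = {r.tf: r.targets for r in regulons}
    feats = set(expr.feature_ids)
    kept_pairs: list[tuple[str, str]] = []
    for gene in sig.genes:
        if gene not in feats:
            logger.info("signature gene %s not measured; skipped", gene)
            continue
        upstream = sorted(
            tf for tf in sig_tfs if gene in regulon_of.get(tf, ()) and tf in feats
        )
        if not upstream:
            logger.info("signature gene %s has no upstream TF; skipped", gene)
            continue
        y = expr.row(gene)
        cands = {tf: expr.row(tf) for tf in upstream}
        fit = stepwise_select(y, cands, target_gene=gene)
        fit = prune_nonsignificant(fit, cands, y, alpha=alpha)
        kept_pairs.extend((tf, gene) for tf in fit.selected_tfs)
    coverage: dict[str, int] = {}
    for tf, _ in kept_pairs:
        coverage[tf] = coverage.get(tf, 0) + 1
    refined = [
        MRARow(
            tf=r.tf,
            regulon_size=r.regulon_size,
            overlap=coverage.get(r.tf, 0),
            p_value=r.p_value,
            fdr=r.fdr,
        )
        for r in mra_rows
        if r.fdr < fdr_cut
    ]
    refined = rank_and_select(refined, fdr_cut=1.0 + 1e-9, k=k)
    return kept_pairs, refined
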