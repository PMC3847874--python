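"""Survival-marker evaluation: class prediction, Kaplan-Meier, log-rank.

A linear support-vector classifier is trained on the marker rows of a
labeled cohort (per-marker standardized with training statistics) and used
to call good/poor prognostic groups in an independent cohort; the predicted
groups are then compared by the Kaplan-Meier estimator and the unstratified
log-rank test.  The log-rank statistic is accumulated explicitly over
distinct event times so per-group observed/expected counts can be reported;
ties between an event and a censoring at the same time follow the standard
convention that events precede censorings.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from sklearn.svm import SVC

from .types import (
    GOOD,
    POOR,
    ExpressionMatrix,
    GroupLabels,
    LogRankResult,
    PrognetError,
    SurvivalTable,
)

logger = logging.getLogger(__name__)


def classify_cohort(
    train: ExpressionMatrix,
    train_labels: GroupLabels,
    test: ExpressionMatrix,
    markers: list[str],
    C: float = 1.0,
) -> GroupLabels:
    """Predict good/poor groups in ``test`` from a linear-kernel SVM.

    Features are the marker rows, standardized per marker using training
    mean and standard deviation.  Markers missing from either matrix are
    dropped with a warning.
    """
    usable = [m for m in markers if m in set(train.feature_ids) and m in set(test.feature_ids)]
    dropped = [m for m in markers if m not in usable]
    if dropped:
        logger.warning("dropping %d marker(s) missing from a matrix: %s", len(dropped), dropped)
    if not usable:
        raise PrognetError("no marker present in both matrices")
    train_samples = [s for s in train.sample_ids if s in train_labels.assignments]
    y = np.array([train_labels.assignments[s] for s in train_samples])
    if len(set(y)) < 2:
        raise PrognetError("training labels contain a single class")
    Xtr = train.data.loc[usable, train_samples].to_numpy(dtype=float).T
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    clf = SVC(kernel="linear", C=C)
    clf.fit((Xtr - mu) / sd, y)
    Xte = test.data.loc[usable, :].to_numpy(dtype=float).T
    pred = clf.predict((Xte - mu) / sd)
    return GroupLabels(dict(zip(test.sample_ids, pred)))


def km_estimate(
    surv: SurvivalTable, groups: GroupLabels
) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier product-limit curve per group.

    Returns, per group, a frame with columns ``time`` and ``survival``
    (the step function evaluated at the observed times, starting at 1).
    """
    frame = surv.to_frame()
    unknown = sorted(set(groups.assignments) - set(frame["sample"]))
    if unknown:
        raise PrognetError(f"labeled sample(s) missing from survival table: {unknown}")
    out: dict[str, pd.DataFrame] = {}
    for group in sorted(set(groups.assignments.values())):
        members = groups.samples_in(group)
        sub = frame[frame["sample"].isin(members)]
        if sub.empty:
            raise PrognetError(f"group {group!r} has no survival records")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        out[group] = sf
    return out


def logrank_test(surv: SurvivalTable, groups: GroupLabels) -> LogRankResult:
    """Unstratified two-group log-rank test (1 df).

    Accumulates observed minus expected events and the hypergeometric
    variance over distinct event times; p is the chi-square upper tail.
    """
    frame = surv.to_frame()
    labeled = frame[frame["sample"].isin(groups.assignments)]
    group_of = groups.assignments
    names = sorted({group_of[s] for s in labeled["sample"]})
    if len(names) != 2:
        raise PrognetError(f"log-rank test needs exactly two non-empty groups, got {names}")
    g = labeled["sample"].map(group_of).to_numpy()
    t = labeled["time"].to_numpy(dtype=float)
    d = labeled["event"].to_numpy(dtype=int)
    if d.sum() == 0:
        raise PrognetError("no events")
    a = names[0]
    obs_a = 0.0
    exp_a = 0.0
    var = 0.0
    for time in np.unique(t[d == 1]):
        at_risk = t >= time
        n_risk = int(at_risk.sum())
        n_risk_a = int((at_risk & (g == a)).sum())
        events = (t == time) & (d == 1)
        d_total = int(events.sum())
        d_a = int((events & (g == a)).sum())
        obs_a += d_a
        exp_a += d_total * n_risk_a / n_risk
        if n_risk > 1:
            var += (
                d_total
                * (n_risk_a / n_risk)
                * (1 - n_risk_a / n_risk)
                * (n_risk - d_total)
                / (n_risk - 1)
            )
    if var <= 0:
        chi2 = 0.0
    else:
        chi2 = (obs_a - exp_a) ** 2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    obs_total = float(d.sum())
    n_events = {name: int(d[(g == name)].sum()) for name in names}
    oe = {
        names[0]: (obs_a, exp_a),
        names[1]: (obs_total - obs_a, obs_total - exp_a),
    }
    return LogRankResult(chi_square=float(chi2), p_value=p, n_events=n_events,
                         observed_expected=oe)


def size_sweep(
    orderings: dict[str, list[str]],
    sizes: list[int],
    train: ExpressionMatrix,
    train_labels: GroupLabels,
    test: ExpressionMatrix,
    surv_test: SurvivalTable,
) -> pd.DataFrame:
    """Log-rank p for growing marker-list prefixes.

    For each named ordering and each prefix size, trains the classifier on
    the prefix, predicts the test cohort, and records the log-rank p of the
    predicted groups.  Sizes beyond a list's length are truncated with a
    warning.  Returns a frame indexed by size with one column per ordering.
    """
    result: dict[str, list[float]] = {}
    for name, markers in orderings.items():
        ps: list[float] = []
        for size in sizes:
            if size > len(markers):
                logger.warning("size %d exceeds %s list length %d; truncating",
                               size, name, len(markers))
                size = len(markers)
            prefix = markers[:size]
            try:
                pred = classify_cohort(train, train_labels, test, prefix)
                p = logrank_test(surv_test, pred).p_value
            except PrognetError as exc:
                logger.info("sweep %s size %d: %s", name, size, exc)
                p = float("nan")
            ps.append(p)
        result[name] = ps
    return pd.DataFrame(result, index=pd.Index(sizes, name="size"))
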