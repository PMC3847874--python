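"""Shared domain types for the upstream-regulator pipeline.

All identifiers are case-sensitive and matched exactly; there is no symbol
aliasing anywhere in the package, because silent mis-joins between probe,
gene and sample namespaces are the dominant bug class in this kind of
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GOOD = "good"
POOR = "poor"
LOW = "low"
HIGH = "high"
ACTIVATION = "activation"
REPRESSION = "repression"
UNDETERMINED = "undetermined"

RISK_CLASSES = (LOW, HIGH)
GROUPS = (GOOD, POOR)
MODES = (ACTIVATION, REPRESSION)


class PrognetError(ValueError):
    """Raised on any contract violation (bad input file, invariant breach)."""


@dataclass
class ExpressionMatrix:
    """Log2 expression values, features (probes or genes) x samples.

    ``data`` is a float DataFrame whose index holds feature identifiers and
    whose columns hold sample identifiers.  Values must be finite; missing
    values are rejected rather than imputed.
    """

    data: pd.DataFrame
    cohort_label: str = ""

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise PrognetError(f"duplicate feature identifier(s): {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise PrognetError(f"duplicate sample identifier(s): {dups}")
        values = self.data.to_numpy()
        if values.dtype.kind not in "fi":
            raise PrognetError("expression values must be numeric")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise PrognetError(
                "non-finite expression value at feature "
                f"{self.data.index[bad[0]]!r}, sample {self.data.columns[bad[1]]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def row(self, feature: str) -> np.ndarray:
        if feature not in self.data.index:
            raise PrognetError(f"feature {feature!r} not in expression matrix")
        return self.data.loc[feature].to_numpy(dtype=float)

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise PrognetError(f"sample(s) not in matrix: {missing}")
        return ExpressionMatrix(self.data.loc[:, sample_ids], self.cohort_label)


@dataclass
class Signature:
    """Ordered prognostic gene list split into low- and high-risk classes.

    ``entries`` maps gene -> risk class in reading order; ``ordering_value``
    optionally holds a differential-expression magnitude per gene, used to
    order prefixes in the marker-size sweep.
    """

    entries: list[tuple[str, str]]
    ordering_value: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.entries:
            raise PrognetError("no signature entries")
        seen: set[str] = set()
        for gene, risk in self.entries:
            if gene in seen:
                raise PrognetError(f"duplicate signature gene: {gene!r}")
            seen.add(gene)
            if risk not in RISK_CLASSES:
                raise PrognetError(
                    f"risk class {risk!r} for {gene!r} not in {RISK_CLASSES}"
                )

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.entries]

    @property
    def risk_of(self) -> dict[str, str]:
        return dict(self.entries)

    @property
    def low_risk(self) -> list[str]:
        return [g for g, r in self.entries if r == LOW]

    @property
    def high_risk(self) -> list[str]:
        return [g for g, r in self.entries if r == HIGH]

    def class_counts(self) -> tuple[int, int]:
        return len(self.low_risk), len(self.high_risk)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class ProbeGeneMap:
    """Many-to-one probe -> gene mapping."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        probes = [p for p, _ in self.pairs]
        if len(probes) != len(set(probes)):
            dups = sorted({p for p in probes if probes.count(p) > 1})
            raise PrognetError(f"probe(s) mapped more than once: {dups}")

    @property
    def gene_of(self) -> dict[str, str]:
        return dict(self.pairs)


@dataclass
class SurvivalTable:
    """Disease-free survival records: (sample, time in months, event flag)."""

    records: list[tuple[str, float, int]]

    def __post_init__(self) -> None:
        ids = [s for s, _, _ in self.records]
        if len(ids) != len(set(ids)):
            raise PrognetError("duplicate sample identifiers in survival table")
        for sample, time, event in self.records:
            if time < 0:
                raise PrognetError(f"negative survival time for {sample!r}: {time}")
            if event not in (0, 1):
                raise PrognetError(f"event flag for {sample!r} must be 0 or 1, got {event}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["sample", "time", "event"])

    @property
    def sample_ids(self) -> list[str]:
        return [s for s, _, _ in self.records]

    def subset(self, sample_ids: list[str]) -> "SurvivalTable":
        by_id = {s: (s, t, e) for s, t, e in self.records}
        missing = [s for s in sample_ids if s not in by_id]
        if missing:
            raise PrognetError(f"sample(s) not in survival table: {missing}")
        return SurvivalTable([by_id[s] for s in sample_ids])


@dataclass
class GroupLabels:
    """Prognostic group assignment per sample (good / poor)."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        for sample, group in self.assignments.items():
            if group not in GROUPS:
                raise PrognetError(f"group for {sample!r} must be in {GROUPS}, got {group!r}")

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.assignments.items() if g == group]

    def __len__(self) -> int:
        return len(self.assignments)


@dataclass
class NetworkEdge:
    """A directed TF -> target link with MI weight and bootstrap support."""

    regulator: str
    target: str
    mi: float
    support: int = 1
    mode: str | None = None
    rho: float | None = None

    def __post_init__(self) -> None:
        if self.mi < 0:
            raise PrognetError(f"negative MI on edge {self.regulator}->{self.target}")
        if self.mode is not None and self.mode not in (*MODES, UNDETERMINED):
            raise PrognetError(f"unknown regulatory mode token: {self.mode!r}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.regulator, self.target)


@dataclass
class ConsensusNetwork:
    """Bootstrap-consensus regulatory network at probe or gene level."""

    edges: list[NetworkEdge]
    B: int = 1
    level: str = "gene"

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for e in self.edges:
            if e.regulator == e.target:
                raise PrognetError(f"self-edge on {e.regulator!r}")
            if e.pair in seen:
                raise PrognetError(f"duplicate edge {e.pair}")
            seen.add(e.pair)
            if not (0 <= e.support <= self.B):
                raise PrognetError(
                    f"support {e.support} outside [0, B={self.B}] on edge {e.pair}"
                )

    @property
    def regulators(self) -> list[str]:
        out: list[str] = []
        for e in self.edges:
            if e.regulator not in out:
                out.append(e.regulator)
        return out

    @property
    def genes(self) -> set[str]:
        nodes: set[str] = set()
        for e in self.edges:
            nodes.add(e.regulator)
            nodes.add(e.target)
        return nodes


@dataclass
class MIThreshold:
    """Permutation-calibrated MI significance threshold.

    ``threshold_mi`` solves the fitted exponential null tail
    ln P(MI > t) = a - b t at the Bonferroni level alpha / n_tests.
    """

    alpha: float
    n_tests: int
    threshold_mi: float
    null_tail_params: tuple[float, float]  # (a, b) of ln P(MI > t) ~ a - b t
    n_samples: int = 0
    n_perm: int = 0


@dataclass
class Regulon:
    """A TF and the set of its network targets."""

    tf: str
    targets: set[str]

    def __post_init__(self) -> None:
        if self.tf in self.targets:
            raise PrognetError(f"regulon of {self.tf!r} contains itself")
        if not self.targets:
            raise PrognetError(f"empty regulon for {self.tf!r}")


@dataclass
class MRARow:
    """One master-regulator-analysis result row."""

    tf: str
    regulon_size: int
    overlap: int
    p_value: float
    fdr: float = float("nan")
    rank: int = 0
    selected: bool = False


@dataclass
class LinearFit:
    """Result of stepwise TF selection for one signature gene."""

    target_gene: str
    selected_tfs: list[str]
    coefficients: np.ndarray  # intercept first, then one per selected TF
    coef_p_values: np.ndarray  # per selected TF (intercept excluded)
    rss: float
    aic: float
    n: int


@dataclass
class EffectRow:
    """Per-TF prognostic-effect summary within one cohort."""

    tf: str
    n_targets: int
    n_activated_low: int
    n_repressed_high: int
    effect: str  # "+" or "-"
    mean_rho_low: float
    mean_rho_high: float
    cohort_label: str = ""


@dataclass
class LogRankResult:
    """Two-group log-rank comparison."""

    chi_square: float
    p_value: float
    n_events: dict[str, int]
    observed_expected: dict[str, tuple[float, float]]


@dataclass
class GroundTruth:
    """Planted regulatory structure behind a synthetic cohort pair."""

    tf_ids: list[str]
    edges: list[tuple[str, str, float]]  # (tf, target, beta), beta != 0
    signature: Signature
    prognostic_tfs: dict[str, str]  # tf -> "+" / "-"
    tf_direction: dict[str, float] = field(default_factory=dict)
    group_diff: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tf, target, beta in self.edges:
            if beta == 0:
                raise PrognetError(f"zero planted coefficient on {tf}->{target}")
        regulated = {t for _, t, _ in self.edges}
        orphans = [g for g in self.signature.genes if g not in regulated]
        if orphans:
            raise PrognetError(f"signature gene(s) without planted regulator: {orphans}")

    @property
    def edge_pairs(self) -> set[tuple[str, str]]:
        return {(tf, t) for tf, t, _ in self.edges}


@dataclass
class CohortConfig:
    """Knobs of the synthetic two-cohort generator.

    Defaults emulate, at desk scale, a pair of microarray colorectal-cancer
    cohorts with a planted TF->target structure, a risk-classed signature and
    group-dependent disease-free survival.  ``group_shift`` is in log2 units
    (1.0 = two-fold between prognostic groups); hazards are events/month.
    """

    n_samples: int = 150
    n_tfs: int = 10
    n_targets: int = 100
    regulon_size_range: tuple[int, int] = (5, 25)
    noise_sd: float = 0.2
    group_shift: float = 1.0
    hazard_good: float = 0.01
    hazard_poor: float = 0.03
    censor_time: float = 60.0
    n_signature: int = 40
    tf_tf_prob: float = 0.1
    prognostic_tf_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_tfs, self.n_targets, self.n_signature) < 1:
            raise PrognetError("all counts must be >= 1")
        lo, hi = self.regulon_size_range
        if not (1 <= lo <= hi):
            raise PrognetError("invalid regulon_size_range")
        if hi > self.n_targets:
            raise PrognetError(
                f"regulon sizes up to {hi} infeasible with {self.n_targets} targets"
            )
        if self.hazard_good <= 0 or self.hazard_poor <= 0:
            raise PrognetError("hazards must be positive")
        # equality is allowed so null (no-prognostic-difference) studies can
        # be simulated; a planted difference needs hazard_poor > hazard_good
        if self.hazard_poor < self.hazard_good:
            raise PrognetError("hazard_poor must be >= hazard_good")
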