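"""End-to-end pipeline driver.

Runs the full chain — (synthetic or on-disk) inputs, bootstrap-consensus
network inference, master regulator analysis, stepwise-regression edge
filtering, prognostic-effect assignment, and survival evaluation — and
writes every stage's artifact plus a manifest recording seeds, thresholds
and completion state.  With a fixed seed the run is fully reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .effect import cohort_consistency, effect_table
from .mra import (
    extract_regulons,
    mra_enrichment,
    rank_and_select,
    selected_tfs,
    selection_overlap,
    union_coverage,
)
from .network import bootstrap_consensus, edge_recovery
from .simulate import simulate_cohorts
from .slr import slr_network
from .survival import classify_cohort, logrank_test, size_sweep
from .types import CohortConfig, ConsensusNetwork, NetworkEdge, PrognetError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, resolvable from a YAML mapping."""

    out_dir: str = "prognet_run"
    seed: int = 0
    # inputs: either synthetic=True, or paths for every artifact
    synthetic: bool = True
    cohort: CohortConfig = field(default_factory=CohortConfig)
    expression_paths: list[str] = field(default_factory=list)  # >= 1 cohort
    signature_path: str | None = None
    tf_list_path: str | None = None
    labels_path: str | None = None
    survival_paths: list[str] = field(default_factory=list)
    # stage parameters
    bootstrap: int = 25
    alpha: float = 0.05
    epsilon: float = 0.0
    n_perm: int = 1000
    fdr_cut: float = 0.05
    top_k: int = 10
    slr_alpha: float = 0.05
    evaluate: bool = True
    sweep_sizes: list[int] = field(default_factory=list)

    @classmethod
    def from_mapping(cls, raw: dict) -> "PipelineConfig":
        cohort = CohortConfig(**raw.pop("cohort", {}))
        return cls(cohort=cohort, **raw)


def _preflight(cfg: PipelineConfig) -> None:
    if cfg.synthetic:
        return
    needed = {
        "expression_paths": cfg.expression_paths,
        "signature_path": cfg.signature_path,
        "tf_list_path": cfg.tf_list_path,
        "labels_path": cfg.labels_path,
    }
    if cfg.evaluate:
        needed["survival_paths"] = cfg.survival_paths
    missing = [k for k, v in needed.items() if not v]
    if missing:
        raise PrognetError(f"pipeline config missing required input(s): {missing}")
    for p in [*cfg.expression_paths, cfg.signature_path, cfg.tf_list_path,
              cfg.labels_path, *cfg.survival_paths]:
        if p and not Path(p).exists():
            raise PrognetError(f"input path does not exist: {p}")


def read_tf_list(path: str | Path) -> list[str]:
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#") and line.lower() != "tf":
            out.append(line)
    if not out:
        raise PrognetError(f"{path}: empty TF list")
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute stages end to end; returns a manifest dict (also written).

    On stage failure, artifacts of completed stages are retained and the
    manifest marks how far the run got.
    """
    _preflight(cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "parameters": {
            "bootstrap": cfg.bootstrap, "alpha": cfg.alpha, "epsilon": cfg.epsilon,
            "n_perm": cfg.n_perm, "fdr_cut": cfg.fdr_cut, "top_k": cfg.top_k,
            "slr_alpha": cfg.slr_alpha,
        },
        "stages": {},
    }

    def _done(stage: str, **info) -> None:
        manifest["stages"][stage] = {"status": "done", **info}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    try:
        # ---------------------------------------------------------- inputs
        if cfg.synthetic:
            cohort_cfg = CohortConfig(**{**asdict(cfg.cohort), "seed": cfg.seed})
            bundle = simulate_cohorts(cohort_cfg)
            truth = bundle["truth"]
            labels_by_cohort = {}
            surv_by_cohort = {}
            exprs = []
            for label, parts in bundle["cohorts"].items():
                exprs.append(parts["expression"])
                labels_by_cohort[label] = parts["labels"]
                surv_by_cohort[label] = parts["survival"]
                io.write_expression_matrix(parts["expression"], out / f"expression_{label}.tsv")
                io.write_labels(parts["labels"], out / f"labels_{label}.tsv")
                io.write_survival(parts["survival"], out / f"survival_{label}.tsv")
            sig = truth.signature
            tf_ids = truth.tf_ids
            io.write_signature(sig, out / "signature.tsv")
            truth_net = ConsensusNetwork(
                [NetworkEdge(tf, t, abs(b)) for tf, t, b in truth.edges], B=1)
            io.write_network(truth_net, out / "truth_edges.tsv")
        else:
            exprs = [io.read_expression_matrix(p) for p in cfg.expression_paths]
            sig = io.read_signature(cfg.signature_path)
            tf_ids = read_tf_list(cfg.tf_list_path)
            train_labels = io.read_labels(cfg.labels_path)
            labels_by_cohort = {exprs[0].cohort_label: train_labels}
            surv_by_cohort = {}
            for expr, p in zip(exprs, cfg.survival_paths):
                surv_by_cohort[expr.cohort_label] = io.read_survival(p)
            truth = None
        train = exprs[0]
        test = exprs[1] if len(exprs) > 1 else exprs[0]
        _done("inputs", cohorts=[e.cohort_label for e in exprs],
              n_signature=len(sig), n_tfs=len(tf_ids))

        # --------------------------------------------------------- network
        net = bootstrap_consensus(
            train, tf_ids, B=cfg.bootstrap, alpha=cfg.alpha, epsilon=cfg.epsilon,
            seed=cfg.seed, n_perm=cfg.n_perm,
        )
        io.write_network(net, out / "network.tsv")
        info = {"edges": len(net.edges)}
        if truth is not None:
            prec, rec = edge_recovery(net, truth.edge_pairs)
            info.update(precision=prec, recall=rec)
        _done("infer", **info)

        # ------------------------------------------------------------- MRA
        regulons = extract_regulons(net)
        rows = mra_enrichment(regulons, sig, universe=net.genes)
        rows = rank_and_select(rows, fdr_cut=cfg.fdr_cut, k=cfg.top_k)
        mra_frame = pd.DataFrame(
            [{**asdict(r)} for r in rows]
        )
        io.write_table(mra_frame, out / "mra_table.tsv")
        _done("mra", significant=int((mra_frame["fdr"] < cfg.fdr_cut).sum()),
              selected=selected_tfs(rows),
              union_coverage=union_coverage(rows, regulons, sig))

        # ------------------------------------------------------------- SLR
        pairs, refined = slr_network(
            train, rows, regulons, sig, alpha=cfg.slr_alpha,
            fdr_cut=cfg.fdr_cut, k=cfg.top_k,
        )
        slr_edges = [
            NetworkEdge(tf, g, next(e.mi for e in net.edges if e.pair == (tf, g)),
                        next(e.support for e in net.edges if e.pair == (tf, g)))
            for tf, g in pairs
        ]
        io.write_network(ConsensusNetwork(slr_edges, B=net.B), out / "network_slr.tsv")
        io.write_table(pd.DataFrame([asdict(r) for r in refined]), out / "mra_slr_table.tsv")
        inter, union = selection_overlap(rows, refined)
        _done("slr", kept_pairs=len(pairs), selected=selected_tfs(refined),
              intersection=sorted(inter), union=sorted(union))

        # ---------------------------------------------------------- effect
        union_tfs = sorted(union) or None  # fall back to every TF with targets
        sig_edges = [e for e in net.edges if e.target in set(sig.genes)]
        if len(exprs) >= 2:
            tables, concordance = cohort_consistency(sig_edges, exprs, sig, union_tfs)
        else:
            tables = {train.cohort_label: effect_table(sig_edges, train, sig, union_tfs)}
            concordance = float("nan")
        effect_frames = []
        for label, tab in tables.items():
            effect_frames.append(pd.DataFrame([asdict(r) for r in tab]))
        io.write_table(pd.concat(effect_frames, ignore_index=True), out / "effects.tsv")
        _done("effect", concordance=concordance)

        # -------------------------------------------------------- evaluate
        if cfg.evaluate:
            train_labels = labels_by_cohort[train.cohort_label]
            surv_test = surv_by_cohort[test.cohort_label]
            results = {}
            marker_sets = {
                "signature": sig.genes,
                "tf_mra": selected_tfs(rows),
                "tf_mra_slr": selected_tfs(refined),
            }
            for name, markers in marker_sets.items():
                if not markers:
                    continue
                pred = classify_cohort(train, train_labels, test, markers)
                io.write_labels(pred, out / f"predicted_{name}.tsv")
                lr = logrank_test(surv_test, pred)
                results[name] = {"chi_square": lr.chi_square, "p_value": lr.p_value,
                                 "n_markers": len(markers)}
            io.write_table(
                pd.DataFrame(
                    [{"markers": k, **v} for k, v in results.items()]
                ),
                out / "logrank.tsv",
            )
            if cfg.sweep_sizes:
                sweep = size_sweep(
                    {"signature": sig.genes, "tf_mra": selected_tfs(rows)},
                    cfg.sweep_sizes, train, train_labels, test, surv_test,
                )
                sweep.reset_index().to_csv(out / "size_sweep.tsv", sep="\t", index=False)
            _done("evaluate", **results)
    except Exception as exc:  # keep partial outputs + mark failure
        manifest["stages"]["failed"] = {"status": "error", "message": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    return manifest
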