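# prognet

Upstream-regulator discovery for prognostic gene-expression signatures.

Prognostic signatures — lists of genes whose expression separates patients
into good and poor outcome groups — are typically dominated by *passenger*
genes that track disease state without driving it. The transcription
factors (TFs) upstream of a signature are better candidates for drivers,
and often make smaller, equally powerful marker panels. `prognet`
implements the full discovery chain for such upstream regulators from
expression data alone:

1. **Network inference.** Pairwise mutual information I(TF, gene) between
   every TF and every gene, estimated on copula (rank) transforms with
   equal-frequency binning and Miller–Madow bias correction. Pairs must
   exceed a permutation-calibrated threshold at a Bonferroni-corrected
   familywise level (α = 0.05 over all candidate pairs). Indirect links are
   pruned by the data processing inequality: in any fully connected triangle
   the edge with I < min of the other two (tolerance 0) is removed. The
   network is stabilized by bootstrap consensus: B = 100 resampled cohorts
   are re-inferred (threshold recalibrated per replicate) and an edge is
   kept when its vote count is significant under Binomial(B, p̂) at
   Bonferroni α, with p̂ the pooled per-pair occurrence rate.
2. **Master regulator analysis (MRA).** Each TF's regulon (its network
   targets) is tested for overlap with the signature by a one-sided Fisher
   exact test, with Benjamini–Hochberg FDR control. TFs at FDR < 0.05 are
   ranked by *signature coverage* (number of signature genes in the
   regulon) using competition ranking, and the top k = 10 are selected
   (whole tie groups included at the boundary).
3. **Stepwise regression filtering (SLR).** Each signature gene's log2
   expression is regressed on its candidate upstream TFs; bidirectional
   stepwise search under AIC (n·ln(RSS/n) + 2p) picks a minimal model and
   coefficients with t-test p ≥ 0.05 are pruned by iterative refit. The
   surviving links define refined coverages and a second top-10 ranking.
4. **Prognostic effect.** Each retained edge is labelled activation or
   repression by the sign of the TF–target Spearman correlation; a TF is
   assigned effect “+” when activated low-risk plus repressed high-risk
   targets form a strict majority of its signature targets, and “−”
   otherwise. Effects are checked for consistency across cohorts.
5. **Survival evaluation.** A linear-kernel SVM trained on one labelled
   cohort predicts good/poor groups in an independent cohort; groups are
   compared by Kaplan–Meier curves and the log-rank test, optionally over a
   sweep of marker-panel sizes.

A synthetic two-cohort generator (`prognet.simulate`) plants a known
TF→target network, a risk-classed signature, and group-dependent
exponential survival, so every stage can be tested against ground truth.

## Worked example

Run the full pipeline on a synthetic study:

```python
from prognet import CohortConfig, PipelineConfig, run_pipeline

cfg = PipelineConfig(
    out_dir="demo_run", seed=1,
    cohort=CohortConfig(n_tfs=5, n_targets=50, n_samples=200,
                        regulon_size_range=(5, 15), n_signature=20),
    bootstrap=25,
)
manifest = run_pipeline(cfg)
print(manifest["stages"]["infer"])
print(manifest["stages"]["evaluate"]["tf_mra_slr"])
```

prints (seed 1):

```
{'status': 'done', 'edges': 50, 'precision': 1.0, 'recall': 0.8928571428571429}
{'chi_square': 8.459512592702247, 'p_value': 0.003631391554651619, 'n_markers': 2}
```

meaning: the consensus network recovered the planted regulatory links with
precision 1.0 and recall 0.89, and the selected master-regulator TFs —
a panel ten times smaller than the signature — split the held-out cohort
into groups whose disease-free survival differs at log-rank p ≈ 0.0036.
All stage artifacts (network, MRA table, filtered network, effect table,
predicted labels, log-rank report, manifest with every seed and threshold)
are written under `demo_run/`.

The same stages are exposed on the command line:

```
prognet simulate --seed 1 --out-dir sim
prognet infer --expression sim/expression_discovery.tsv --tf-list sim/tf_list.txt \
        --bootstrap 25 --seed 1 --out network.tsv
prognet mra --network network.tsv --signature sim/signature.tsv
prognet pipeline --config config.yaml
```

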