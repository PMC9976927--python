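# pausescape

Quantify promoter-proximal RNA polymerase II pausing from nascent-
transcription coverage and model it from genome-wide protein binding maps.

After transcription initiation, Pol II pauses 30-60 bp downstream of the
transcription start site; release into productive elongation is a key
rate-limiting step of gene expression, regulated by trans-acting factors
(DSIF, NELF, P-TEFb, the 7SK snRNP) and by sequence context. `pausescape`
implements the full analysis that turns raw coverage and peak files into a
ranked list of candidate pause regulators:

1. **Pausing index.** For every expressed, CAGE-validated protein-coding
   transcript, `PI = log2((c_tss + 1)/w_tss) - log2((c_body + 1)/w_body)`:
   the log2 ratio of length-normalized strand-specific coverage in a short
   window centered on the TSS versus the rest of the transcript span. The
   window half-width is chosen by scanning a grid and maximizing the
   negative Pearson correlation between PI and log10 FPKM expression.
2. **Feature matrix.** Binary ChIP/CLIP binding flags per factor and
   derived region (5', coding exon, intron, 3'), the same flags on the two
   most TSS-proximal non-coding RNAs, and 18 annotation/sequence features
   (CpG islands, exon structure, GC content, CAGE cluster shape,
   housekeeping status), min-max scaled.
3. **Models.** Gradient-boosted tree regression of the PI (XGBoost by
   default; LightGBM, random forest and ridge as references) with internal
   cross-validated hyperparameter selection, a 50% pre-training holdout,
   cross-cell-line validation on synchronized feature columns, and
   differential-pausing evaluation.
4. **Interpretation.** Per-transcript additive (SHAP-style) feature
   attributions, aggregated into per-factor contribution scores, factor-set
   and binding-mode aggregates, Fisher enrichment tests, and the minimal
   factor set covering 50% of all contributions.

A first-class synthetic-data generator plants known effect sizes, causal
factors and 7SK binders in a complete file bundle (FASTA, GTF, BED, wiggle,
TSV), so every stage is validated end-to-end against ground truth. See
`docs/methods.md` for the model, the generator's design and its limits.

## Worked example

```python
from pausescape import GeneratorConfig, generate_bundle, inputs_from_bundle, run_pipeline
from pausescape.pipeline import PipelineSettings
from pausescape.modeling import ModelSpec

cfg = GeneratorConfig(n_genes=600, n_ncrnas=50, n_factors=20, n_causal=5, seed=0)
bundle = generate_bundle(cfg)
settings = PipelineSettings(
    model=ModelSpec(learning_rates=(0.1,), max_depths=(4, 6),
                    n_rounds=300, early_stopping_rounds=25, seed=0)
)
report = run_pipeline(inputs_from_bundle(bundle), settings)

print(f"transcripts analyzed : {len(report.prepared.y)}")
print(f"TSS half-width chosen: {report.prepared.best_halfwidth} "
      f"(rho = {report.prepared.rho_profile[report.prepared.best_halfwidth]:.2f})")
print(f"holdout R^2          : {report.fit.holdout_r2:.2f}")
print(f"minimal factor set   : {report.minimal_set}")
print(f"planted causal       : {bundle.truth.causal_factors}")
```

prints

```
transcripts analyzed : 533
TSS half-width chosen: 1 (rho = -0.92)
holdout R^2          : 0.55
minimal factor set   : ['FCL001', 'FCL010']
planted causal       : ['FCH001', 'FCL001', 'FCL005', 'FCL008', 'FCL010']
```

Of the 600 generated transcripts, 533 survive the expression, CAGE,
sequence, overlap and signal filters. The window optimizer recovers the
3 bp TSS window in which the generator concentrated the pause signal
(correlation with expression -0.92: paused transcripts are weakly
expressed). The boosted model explains 55% of the holdout PI variance —
the generator calibrates noise so the true design explains ~70% — and the
two factors whose contribution shares already cover 50% of the total are
both planted causal factors.

The same pipeline runs from files on disk:

```sh
pausescape simulate --out bundle/ --seed 0 --n-genes 600
pausescape pi  --data-dir bundle/ --out pi.tsv
pausescape run --data-dir bundle/ --out results/ --seed 0
pausescape crosscell --data-dir-a a/ --data-dir-b b/
```

`run` persists the PI table, the feature matrix with column metadata,
per-factor contribution scores, the minimal factor set and a JSON report.

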