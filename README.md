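# fragdecipher

Cell-free DNA (cfDNA) fragmentomics for cancer detection from low-pass
plasma whole-genome sequencing, built around three feature families and an
ensemble risk score:

* **CNV** — bin-level copy-number log2 ratios
  `l_t = log2(r_t / h_t)`, where `r_t` is the sample's normalized fragment
  abundance in bin *t* and `h_t` a healthy-panel baseline, optionally
  smoothed by a three-state (loss / neutral / gain) Viterbi segmentation;
* **FSD** — fragment-size distributions: the proportion of fragments in 24
  five-bp length bins (100–104 … 215–219 bp) on each of 39 chromosome arms
  (936 features), z-scored within each sample;
* **PFE** — promoter fragmentation entropy: for each gene, the mean
  probability over 2,000 Dirichlet-posterior draws
  (`alpha = 20 * prior + promoter length counts`) that the draw's Shannon
  entropy exceeds all five background-control entropies by a random margin
  `1 + k`, `k ~ Gamma(0.5, 1)` — a [0, 1] score that rises with promoter
  fragmentation disorder, a proxy of transcriptional activity.

Per family, a randomized model search ranked by out-of-fold (OOF) AUC keeps
the top 10 candidates; their averaged probabilities give a per-family score
and the cancer **risk score** is the equal-weight mean of the three. The
decision cutoff is fixed on training OOF scores at 95% sensitivity.
Evaluation covers ROC/AUC with DeLong inference, exact Clopper–Pearson CIs
for Se/Sp/PPV/NPV/accuracy, prevalence-adjusted predictive values,
calibration (Brier, intercept, slope), rank-based group comparisons and the
Jonckheere–Terpstra stage-trend test, plus a depth-stability analysis that
downsamples high-depth composite samples and measures the Pearson
concordance of the recomputed PFE vectors.

A synthetic cohort generator (scaled genome: 100 kb arms, 10 kb bins)
produces labeled fragment sets with the phenomena the analysis targets —
short-fragment (100–150 bp) enrichment, arm-level gains/losses, elevated
promoter entropy at tumor-marker genes — so the whole pipeline is testable
without patient data.

## Worked example

```bash
fragdecipher run-all --out demo_run --seed 7
```

runs simulate → features → train → evaluate on a 20 + 20 training and
16 + 16 validation cohort and prints, for this seed:

```
training_oof: AUC 1.000 cutoff 0.745 Brier 0.039
validation: AUC 1.000 cutoff 0.745 Brier 0.036
```

`training_oof` is computed from out-of-fold predictions (each training
sample scored by models that never saw it); `validation` applies the frozen
ensemble and cutoff to an untouched cohort. The synthetic default effect
size (tumor fraction ≈ 0.2) is deliberately strong, so both AUCs saturate;
`demo_run/reports.json` holds the confusion counts, exact CIs, the
prevalence table and calibration summaries, and `demo_run/model/` the
selected-model manifest.

The same stages are available programmatically:

```python
from fragdecipher.synthetic import SimulationConfig, build_genome_model
from fragdecipher.pfe import PFEConfig, pfe_scores

model = build_genome_model(SimulationConfig())
# ... simulate or load a FragmentSet, then:
# result = pfe_scores(fragments, model, PFEConfig())
```

## Layout

```
src/fragdecipher/
  fragments.py   BED/BAM fragment I/O, filtering, downsampling, assignment
  synthetic.py   scaled genome model + cohort generator
  cnv.py         bin counts, baseline, log2 ratios, Viterbi segmentation
  fsd.py         936-dimensional size-distribution features
  pfe.py         promoter fragmentation entropy, normalization, selection
  ensemble.py    OOF-ranked candidate search, top-K averaging, risk score
  metrics.py     AUC/DeLong, exact CIs, calibration, trend tests
  stability.py   composite construction and depth-stability analysis
  pipeline.py    end-to-end orchestration
  cli.py         `fragdecipher` command-line interface
```

See `docs/methods.md` for the model details, parameter defaults and known
limitations.
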