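# mmdiscover

Multimodal biomarker discovery for clinically significant prostate cancer.

Prostate cancer spans indolent disease (Gleason 3+3), safely watched, and
clinically significant disease (Gleason ≥ 3+4), which needs treatment.
Neither PSA nor any single modality separates the two reliably.
`mmdiscover` implements, as a reusable and fully tested pipeline, a
discovery procedure that combines two non-invasive views of the tumor:

* **MR radiomics** — quantitative texture/shape/intensity features
  computed from lesion regions of interest on bi-parametric MRI
  (T2-weighted and ADC), and
* **liquid biopsy** — plasma exosomal miRNA expression panels,

plus clinical covariates (age, PSA, PIRADS) as a baseline.  It is aimed at
researchers prototyping small-cohort multimodal classifier studies and at
anyone who needs the individual stages (IBSI-style radiomics with
brute-force-verified features, R²-based redundancy reduction, exhaustive
low-dimensional logistic search) as library components.

## The method

Given per-sample feature tables `X` (samples × features, one per modality)
and binary labels `y` (1 = Gleason ≥ 3+4):

1. **Redundancy reduction.** For every feature pair, compute the
   coefficient of determination `R² = corr(x_i, x_j)²` across samples.
   Pairs with `R² ≥ 0.99` are linked; connected components of this graph
   form dependent groups, and only the member with the highest variance
   survives.
2. **Univariate screening.** Each surviving feature is tested with the
   two-sided Wilcoxon rank-sum test (exact enumeration for combined
   n ≤ 20), significant at `p ≤ 0.05`.
3. **Exhaustive model search.** Every subset of 1–3 features is fit with
   a ridge-stabilized logistic regression.  Performance is estimated by
   stratified 80/20 hold-out splits repeated ≥ 200 times; the decision
   threshold is chosen on each training fold to maximize Youden's
   `J = sensitivity + specificity − 1`.  Ensemble test-set Se, Sp, PPV,
   NPV and the Mann–Whitney AUC (mean, SD, 2.5–97.5 percentile interval
   over repeats) are reported, and models are ranked by `J`, ties broken
   by mean AUC.
4. **Multimodal fusion.** The top candidates of each modality are
   concatenated on the matched cohort (samples with all modalities),
   refit, and re-ensembled, giving joint miRNA+imaging models.

With 300 retained miRNA features the 3-feature search spans
C(300, 3) = 4,455,100 subsets (708,561 for a 163-feature T2W panel;
971,970 for a 181-feature ADC panel); a two-stage mode (single-split
prescreen, full ensemble for the top M) keeps large searches tractable.

Because the patient data behind such studies is not publicly deposited,
the package ships a first-class synthetic cohort generator
(`mmdiscover.synthetic`) that emulates the study structure — matched
multimodal samples, log2-scale miRNA features with planted differential
markers, near-duplicate feature blocks, and 3D lesion volumes whose
texture differs by class — with known ground truth for every stage.

## Worked example

`examples/04_model_search_and_fusion.py` builds a 13-sample matched
cohort (7 indolent / 6 significant) where the miRNA table and the T2W
table each carry one independent planted marker (standardized shift 3),
runs the univariate search per modality, and fuses the top candidates:

```
top miRNA model:    ('miR-000',) AUC 1.000  J 0.855
top T2W model:      ('tex000',) AUC 1.000  J 0.740
top fused model:    ('T2W:tex000', 'miRNA:miR-000')
  Se/Sp 1.000/1.000  PPV/NPV 1.000/1.000
  AUC 1.000 [1.000-1.000], SD 0.000  J 1.000
```

The single-modality ensembles rank the planted features first (AUC 1.0
across held-out repeats, but imperfect J because 2–3-sample test folds
make thresholded Se/Sp noisy); the fused two-feature model combines both
signals and reaches perfect held-out classification on this synthetic
cohort.  The other examples show cohort generation, the radiomic feature
panel, redundancy/screening accounting (322 → 300 features, 6.8%
removed), and the end-to-end pipeline with its report artifacts.

## Layout

* `src/mmdiscover/` — library: `containers`, `synthetic`, `radiomics`,
  `expression`, `selection`, `model_search`, `pipeline`, `cli`
* `examples/` — one narrative script per capability
* `docs/methods.md` — models, conventions, parameter defaults, limitations
* `mmdiscover` CLI — `simulate`, `radiomics`, `run`, `rank`,
  `default-config` (thin wrappers over the library)
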