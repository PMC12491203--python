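# gaitfusion

Multidimensional gait assessment for knee osteoarthritis (KOA) and
post-arthroplasty (TKA) populations, built for movement scientists and
rehabilitation researchers working with lower-limb joint-angle recordings.

Clinical gait in KOA is hard to characterize with spatiotemporal
parameters alone: the disease disrupts both *inter-joint coordination*
and *movement complexity*, and the two must be quantified together.
`gaitfusion` fuses two feature families extracted from hip/knee/ankle
sagittal angle traces:

- **Hip–knee cyclogram morphology.** The angle–angle loop (hip θ_h on X,
  knee θ_k on Y, traversed clockwise over one gait cycle) is summarized
  by the per-joint range of motion `RoM = max θ − min θ`, the centroid
  `(mean θ_h, mean θ_k)`, the closed-loop perimeter
  `P = Σᵢ √((θ_h,i+1 − θ_h,i)² + (θ_k,i+1 − θ_k,i)²)` (closing segment
  included), and the shoelace area
  `A = ½ |Σᵢ (θ_h,i θ_k,i+1 − θ_k,i θ_h,i+1)|`, each decomposed into
  stance-phase and swing-phase parts with `stance + swing = total` exact.
- **Sample entropy of joint angles.**
  `SampEn(m, r, N) = −ln(φ^{m+1}(r) / φ^m(r))` with embedding dimension
  m = 2, Chebyshev template distance and tolerance r = 0.1 × SD of the
  series — higher values mean less regular, more complex motion.

Around the features sit the full study workflow: gait-cycle segmentation
from ankle-angle extrema (toe-off at maximal plantarflexion, heel strike
at the onset of ankle-angle change), cubic-spline time normalization to
101 points per cycle, the group-statistics protocol (Shapiro–Wilk,
Kruskal–Wallis, Mann–Whitney with the Bonferroni threshold p < 0.017,
ANCOVA with partial η² and Tukey HSD), and a nested stratified
cross-validation harness comparing four feature sets × four classifiers
(RF, SVM, DT, KNN) with an LDA baseline. A seeded synthetic cohort
generator emulates Healthy/KOA/TKA gait — including the KOA signature of
*decreased cyclogram features with increased sample entropy* — so every
stage is testable without clinical recordings.

## Worked example

```python
from gaitfusion import (
    RunConfig, default_spec, generate_cohort, run_extract, run_stats,
)

cohort, manifest = generate_cohort(default_spec(seed=1))   # 70 subjects
matrix, rejects = run_extract(cohort, RunConfig(seed=1))
report = run_stats(matrix, RunConfig(seed=1))

g = matrix.data.groupby("group")[["knee_rom", "perimeter_total", "se_hip"]].mean()
print(g.round(3))
print("knee RoM change, KOA vs Healthy:",
      report["percent_change"]["knee_rom"]["KOA_vs_Healthy"], "%")
```

Output:

```
         knee_rom  perimeter_total  se_hip
group
Healthy    62.346          180.504   0.231
KOA        52.679          159.271   0.269
TKA        47.247          141.233   0.213
knee RoM change, KOA vs Healthy: -15.5 %
```

Reading it: the osteoarthritis group walks with a compressed knee range
of motion and a smaller hip–knee loop (coordination loss) but a *higher*
hip-angle sample entropy (more irregular motion); the arthroplasty group
is smaller still in morphology while its entropy drops below healthy
levels — the post-operative regularization the package is designed to
detect. `run_classify(matrix, RunConfig(seed=1))` then evaluates how well
fused versus single-category features recover the group labels.

The same stages are scriptable from a shell:

```bash
gaitfusion simulate --out cohort/ --seed 1
gaitfusion extract cohort/ --out features.csv
gaitfusion stats features.csv --out stats.json
gaitfusion classify features.csv --out cv_report.json
gaitfusion all --out bundle/ --seed 1      # end-to-end with a manifest
```

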