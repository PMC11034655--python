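# wsitriage

Patch-based triage of cervical biopsy whole-slide images (WSIs).

Cervical biopsy slides are reported in four diagnostic categories with a
total severity order — normal/inflammation < low grade (HPV change, CIN 1)
< high grade (CIN 2–3) < malignant (squamous carcinoma, adenocarcinoma,
CGIN and other malignancies) — and a screening service cares most about
never letting a malignant slide through. `wsitriage` implements the full
pipeline that turns a gigapixel H&E slide plus polygon annotations into a
slide-level diagnosis tuned for malignant sensitivity:

1. **Tiling** — non-overlapping `P × P` patches are found on a thumbnail at
   magnification level `m` (a patch occupies `P/2^m × P/2^m` thumbnail
   pixels; level-0 origins are the thumbnail coordinates times `2^m`).
2. **Tissue detection** — a patch counts as tissue if even one of its
   thumbnail pixels is tissue (luminance below 0.88 of white, or
   saturation above 0.07).
3. **Max-severity labelling** — a tissue patch is labelled with the most
   severe category whose annotation polygon touches any of its pixels.
4. **Sampling** — *imbalanced* mode keeps every malignant patch, an equal
   number of random normal patches and all low/high-grade patches
   (training then uses focal loss); *balanced* mode equalizes counts
   (cross-entropy).
5. **Patch classifier** — a pluggable 4-class image classifier trained
   with SGD (momentum 0.9, weight decay 5·10⁻⁴, learning rate halved
   every 2 epochs, at most 20 epochs, early stopping on validation
   accuracy). The desk-scale default is a committee of nine small MLPs
   over block colour and nucleus-density features, temperature-calibrated
   on the validation split.
6. **Heatmaps** — per-category probability grids, one cell per patch.
7. **Slide features** — the 90-dimensional *forest* scheme
   (`area_ratio`/`prob_area` at thresholds 0.5–0.9 for the malignant,
   high-grade and low-grade heatmaps plus 10 regional shape/intensity
   features of the 2 largest connected components each) and the 182-
   dimensional *boosted* scheme (6 global area ratios plus masked regional
   features of the 7/5/3/2 largest regions per heatmap).
8. **Slide classifier** — weighted gradient-boosted trees (XGBoost, 60
   estimators of depth 3, class weights 1.0 for malignant and 0.1
   elsewhere, 20 seeded restarts selected by malignant sensitivity then
   accuracy) or a random forest tuned by randomized search.
9. **Evaluation** — confusion matrices, per-class sensitivity, and
   inter-observer agreement via nominal Cohen's kappa
   `κ = (p_o − p_e)/(1 − p_e)`, with mean pairwise kappa for three or
   more observers.

A deterministic synthetic cohort generator (`wsitriage.synthetic`) renders
multi-resolution slides — near-white background, H&E-like tissue blobs
with simulated nuclei, category-specific lesion textures, per-lab stain
shifts — together with exact polygon annotations and a manifest, so the
whole pipeline runs and is tested without any clinical data.

## Worked example

Generate a 120-slide, 4-lab synthetic cohort and run everything —
lab-held-out stratified split (all slides of two random labs plus 10% of
the rest go to test; the remainder splits 2:1 into training and
validation), patching at 64 px on level-3 thumbnails, imbalanced sampling,
focal-loss training, inference, forest-90 features, boosted slide
classifier:

```sh
wsitriage demo --n 120 --labs 4 --seed 1 --out scratch/demo
```

prints the test-split confusion matrix (rows = truth) and summary metrics:

```
            normal  low_grade  high_grade  malignant
normal          10          2           0          0
low_grade        6         16           0          0
high_grade       1          0          11          1
malignant        0          0           0         19
test slides:              66
test accuracy:            0.848
malignant sensitivity:    1.000
```

Every truly malignant test slide is called malignant (sensitivity 1.0);
accuracy is lower because the 0.1 class weights deliberately trade
high-grade/low-grade precision for malignant recall — the triage profile.

The agreement statistics run standalone; the packaged three-pathologist
re-annotation tables of a 200-sample subset give, for observer A's
categories against the original labels, `p_o = 0.955`, `p_e = 0.25`,
`κ = 0.94`:

```python
from wsitriage.evaluation import cohens_kappa, load_interobserver_category_table
stats = cohens_kappa(load_interobserver_category_table("A"))
print(round(stats.p_o, 3), round(stats.p_e, 3), round(stats.kappa, 3))
# 0.955 0.25 0.94
```

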