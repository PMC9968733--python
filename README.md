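# chondroprint

Single-cell morphometric fingerprinting of chondrocyte phenotype under
control and inflammatory (IL-1β-like) conditions.

## The problem

Chondrocytes — the resident cells of articular cartilage — change shape when
they dedifferentiate or respond to inflammatory cytokines such as IL-1β:
healthy cells are round, inflamed or fibroblastic cells become elongated and
grow cytoplasmic processes. Quantifying that change over thousands of cells,
and relating it to the expression of matrix genes (COL2A1, ACAN, SOX9) and
inflammatory genes (IL-6, IL-8) measured by droplet digital PCR, yields a
*morphological fingerprint* that discriminates control from inflamed
phenotypes. `chondroprint` implements that entire analysis as a tested,
reusable Python pipeline, plus a synthetic-data module that emulates the
microscopy and ddPCR inputs so every stage is verifiable without any
download.

## What it computes

1. **Synthetic experiments** (`chondroprint.synthetic`) — ground-truth cell
   populations with published effect presets (human osteoarthritic and
   healthy bovine chondrocytes under IL-1β), rendered as noisy two-channel
   tiles (cell-body + nucleus stains), and paired ddPCR tables in copies/µL.
2. **Trainable segmentation** (`chondroprint.segmentation`) — 3-class pixel
   classification (nucleus / cytosol / background) from scribbles on
   multi-scale image features, followed by marker-based watershed instance
   separation using nucleus components as markers.
3. **Morphometry** (`chondroprint.morphometry`) — the seven-descriptor shape
   panel per cell, in physical units:
   area *A*, length *L* (major axis), width *W* (minor axis),
   circularity = 4π·A/P², aspect ratio AR = L/W,
   roundness = 4A/(π·L²), solidity = A/A_hull.
4. **Population statistics** (`chondroprint.stats`) — normality-gated
   two-group tests (Student's t / Mann–Whitney), Kruskal–Wallis ANOVA on
   ranks with Dunn's post-hoc, donor-paired fold changes (each control set
   to 1), percent-change comparison matrices, and class-coded correlograms
   with Pearson/Spearman dispatch.
5. **Fingerprinting** (`chondroprint.fingerprint`) — clustered image maps of
   z-scored features (Euclidean-distance hierarchical clustering) and a
   from-scratch NIPALS PLS-DA whose component-1 loadings rank each feature's
   importance for discriminating control (class 0) from treated (class 1)
   samples.

## Worked example

```python
import chondroprint as cp
from chondroprint.fingerprint import scale_center

# A full synthetic experiment: 8 control + 8 IL-1β-treated samples from
# 8 donors, each with a rendered two-channel tile and a ddPCR row.
images, table = cp.build_experiment(cp.get_preset("human-oa"), seed=11,
                                    field_size=(500., 500.), pixel_size=1.5)

for gene in ("COL2A1", "IL-6", "IL-8"):
    fc = cp.fold_change(table, gene)
    print(f"{gene}: mean fold {fc.mean:.1f} +/- {fc.sem:.1f} SEM")

res = cp.compare_two_groups(table[table.condition == 0]["roundness"],
                            table[table.condition == 1]["roundness"])
print(f"roundness: {res.test}, p = {res.p_value:.4f}")

feats = [*cp.DESCRIPTOR_NAMES, *cp.GENES]
z, _ = scale_center(table.set_index("sample_id")[feats])
model = cp.plsda_fit(z, table["condition"].to_numpy(), ncomp=2)
print(cp.rank_discriminative_features(model).head(6).to_string(index=False))
```

Output:

```
COL2A1: mean fold 0.1 +/- 0.0 SEM
IL-6: mean fold 81.8 +/- 7.9 SEM
IL-8: mean fold 159.3 +/- 14.7 SEM
roundness: t-test, p = 0.0001
     feature   loading  importance  marks_class  rank
   roundness -0.379811    0.379811            0     1
      COL2A1 -0.368521    0.368521            0     2
        ACAN  -0.367567    0.367567            0     3
        IL-6   0.366656    0.366656            1     4
aspect_ratio  0.364784    0.364784            1     5
        IL-8   0.328697    0.328697            1     6
```

Read it as: IL-1β suppressed COL2A1 to 0.1× of its donor-matched control and
raised IL-6/IL-8 by roughly two orders of magnitude; treated cells are
significantly less round; and the PLS-DA loading signs assign roundness and
the matrix genes to the control phenotype (class 0) while IL-6, IL-8 and
elongation mark the inflammatory phenotype (class 1) — the morphological
fingerprint.

A command-line interface wraps the same stages:

```bash
chondroprint simulate --preset human-oa --seed 1 --out sim/
chondroprint run-all --preset human-oa --seed 1 --out bundle/
```

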