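# hist2rna

Patient-level gene-expression prediction from H&E-stained breast-cancer
histopathology, built around a deliberately *efficient* training strategy:
instead of optimising a deep network over every image patch, patch features
from a pretrained backbone are averaged into one slide-level vector per
patient before a small regression head is trained.

## Who this is for

Computational-pathology researchers who want an image-to-transcriptome
pipeline that runs end to end — annotation ingest, tissue masking, 224×224
patch tiling at 0.25 µm/px, Macenko stain normalization, feature extraction,
slide-level aggregation, a 1D-convolutional regression head, per-gene /
per-patient evaluation with FDR control, PAM50-style subtype calling and
survival analysis — and that is fully testable on synthetic fixtures with
known ground truth, without downloading any cohort.

## The model

Each patient contributes N patch-feature vectors x₁…x_N (length F) from a
pretrained backbone. The slide-level representation is their mean,

    z = (1/N) · Σᵢ xᵢ ,

so training touches **one record per patient per epoch** instead of one per
patch — the source of the method's order-of-magnitude training-cost
advantage. The head treats z as a 1-channel sequence and applies three 1D
convolutions (C1: 256 kernels of size 5; C2, C3: 512 kernels of size 1, all
ReLU), global average pooling, and a linear output layer with one neuron per
target gene (default 138). Targets are RSEM-style expression values on the
log2(1+x) scale. Training uses Adam (learning rate 0.001), MSE loss,
minibatches of 12, early stopping with patience 4, at most 150 epochs, and
restores the best monitored weights. The head, its gradients and the
optimiser are implemented directly in NumPy — the model is a few matrix
products, so every arithmetic step is visible and testable.

Downstream, predicted PAM50 genes feed a four-member soft-voting classifier
(random forest, multilayer perceptron, linear discriminant analysis,
logistic regression) for intrinsic-subtype calls, and the survival module
provides Kaplan–Meier curves, log-rank tests, the concordance index and
Cox proportional-hazards fits at the standard clinical cut-offs (grade
1 & 2 vs 3, size >20 vs ≤20 mm, age >55 vs ≤55, nodal status, LumB vs LumA).

## Worked example

```python
import numpy as np
from hist2rna import (make_cohort, aggregate, FeatureTensor, TrainConfig,
                      HeadConfig, train_head, predict, evaluate)
from hist2rna.expression import ExpressionMatrix
from hist2rna.head import predict_matrix

# A synthetic cohort whose expression is a known linear map of mean features
cohort = make_cohort(n_patients=120, patches_per_patient=20, n_features=32,
                     n_genes=20, noise_sd=0.1, seed=1)
aggs = [aggregate(FeatureTensor(p, cohort.features[p], "synthetic"))
        for p in cohort.patient_ids]

train, test = aggs[:80], aggs[80:]
truth = cohort.expression
expr_train = ExpressionMatrix(truth.patient_ids[:80], truth.gene_symbols,
                              truth.values[:80], scale="log2p1")
cfg = TrainConfig(seed=1, monitor="train", validation_fraction=0.0,
                  early_stop_patience=16)
model = train_head(train, expr_train, cfg, HeadConfig(output_dim=20))

pred = ExpressionMatrix(truth.patient_ids[80:], truth.gene_symbols,
                        predict_matrix(model, np.stack([a.values for a in test])),
                        scale="log2p1")
truth_test = ExpressionMatrix(truth.patient_ids[80:], truth.gene_symbols,
                              truth.values[80:], scale="log2p1")
report = evaluate(pred, truth_test)
print(report.summary())
```

prints

```
{'median_rho_per_patient': 0.9067669172932331, 'median_rho_per_gene': 0.8886491557223264, 'n_significant_genes': 20, 'fdr_threshold': 0.05}
```

meaning: for the median held-out patient, the predicted 20-gene profile
rank-correlates with the true one at ρ ≈ 0.91; the median gene is recovered
across patients at ρ ≈ 0.89; and all 20 genes stay significant after
Benjamini–Hochberg correction at the 5% FDR level.

A command-line interface mirrors the stages:

```bash
hist2rna fixtures --seed 7 --n-patients 60 --outdir fx
hist2rna tile slide.png annotation.geojson --outdir patches
hist2rna normalise patches/*.png --outdir normed
hist2rna extract patches/sample_manifest.tsv --backbone toy --out features.h5
hist2rna train features.h5 expression.tsv
hist2rna energy --n-devices 4 --hours 8.48     # -> 10,176 Wh (10.176 kWh)
hist2rna run-all --seed 7 --outdir run
```

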