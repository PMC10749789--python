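# histoexpr

Spot-resolved gene expression prediction from H&E histology images.

Spatial transcriptomics (ST) measures expression at barcoded spots on a
tissue section but is expensive; the H&E slide that accompanies every
section is nearly free. `histoexpr` learns the map from local histology to
expression: given a section's slide image, spot table and spot×gene count
matrix, it trains a hybrid network and predicts normalised expression at
every spot of an unseen section. It is aimed at computational biologists
who want a desk-scale, CPU-only, fully reproducible implementation of this
architecture family — including a synthetic-data generator so the entire
pipeline can be exercised and validated without downloading any dataset.

## The model

One section is one training unit. For each spot, a 112×112 RGB patch is
cut at the spot centre, and the network maps patches to expression
through four stages:

1. **Omni-dimensional dynamic convolution** — each layer holds *n*
   candidate kernels W₁…Wₙ and computes, per patch, four sigmoid
   attention vectors α_w ∈ ℝⁿ, α_k ∈ ℝ^{k×k}, α_c ∈ ℝ^{c_in},
   α_o ∈ ℝ^{c_out} from a squeeze branch; the patch is convolved with
   W_eff = Σᵢ α_wi · (α_ki ⊙ α_ci ⊙ α_oi ⊙ Wᵢ).
2. **Capsule routing** — the feature map becomes primary capsules,
   activated by squash(s) = (1 − e^{−‖s‖}) s/‖s‖ and routed by
   self-attention: predictions U = uW, coupling coefficients
   C = softmax(Σ U Uᵀ/√d) over output capsules, next layer
   s′ = (C + B)ᵀU with learned log-priors B.
3. **Position fusion + transformer** — learned embeddings E_x, E_y of
   the integer array coordinates are concatenated with the capsule
   feature; a multi-head self-attention encoder,
   softmax(QKᵀ/√d_k)V per head, runs over all spots of the section.
4. **Graph attention** — on the directed 4-nearest-neighbour graph of
   spot pixel coordinates (Euclidean distances), edge scores
   e_ij = f(W_h h_i, W_h h_j) are LeakyReLU-softmax-normalised into α_ij,
   neighbourhoods aggregated as h_Ω(v_i) = Σ α_it h_t, and spots updated
   as ELU(concat(h_i, h_Ω(v_i)) ω + β) before a linear head predicts the
   gene panel.

Evaluation follows the field's conventions: leave-one-out cross-validation
over sections, per-gene Pearson correlation (PCC) between predicted and
observed expression with t-distribution p-values, gene ranking by mean
−log₁₀ p, and spatial-domain recovery scored by the adjusted Rand index
(ARI) of K-means clusters against reference domain labels.
See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Simulate four synthetic sections (H&E-like nuclei images whose texture
statistics drive a low-rank expression program with negative-binomial
noise), run leave-one-out cross-validation, and print the report:

```python
import histoexpr as hx
from histoexpr.model import ModelConfig, loocv

sections, truths = hx.make_dataset(hx.SynthConfig(seed=0))
report = loocv(sections, ModelConfig(n_genes=20, seed=0))
print(report.summary())
```

```
Leave-one-out evaluation
==============================================
config hash   c808c1e78b77
seed          0
sections      4
genes         20
mean PCC      0.6797

per-section mean PCC:
  synth0           +0.7807
  synth1           +0.7854
  synth2           +0.7114
  synth3           +0.4411

top genes by mean -log10 p: g15, g14, g0, g12, g1
```

Each held-out section's spots were predicted by a model trained on the
other three. A mean per-gene PCC of ≈ 0.68 means the network recovered
most of the image-driven expression signal (a ridge read-out of the
*true* latent programs — the generator's ceiling — reaches ≈ 0.92 on the
same data). The top-ranked genes are those whose spatial pattern is
predicted most confidently across sections.

The same pipeline runs from the shell:

```bash
histoexpr simulate --out data/ --sections 4 --grid 8 --genes 20 --seed 0
histoexpr train --data-dir data/ --seed 0 --out report.json
histoexpr preprocess --counts c.tsv --spots s.tsv --out proc/   # real data
```

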