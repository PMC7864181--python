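# ifcmms — noise-robust intuitionistic fuzzy C-means segmentation

`ifcmms` segments 2-D grayscale images — the motivating case is bright-tumor
detection in FLAIR-like brain MR slices — with a fuzzy C-means variant built
for impulse (salt-and-pepper) noise: **IFCM-MS**, intuitionistic fuzzy
C-means with membership information transfer and an adaptive gray/distance
similarity. It is a library first (everything is importable, with short
narrative scripts under `examples/`) plus a thin `ifcmms` command-line tool,
and ships a classical FCM baseline, tumor-evaluation metrics and a seeded
brain-phantom generator so the whole method can be exercised without any
external dataset.

## The model

Classical FCM assigns each pixel $x_k$ a membership $u_{ik}\in[0,1]$ to each
cluster $i$ (with $\sum_i u_{ik}=1$) by alternating

$$v_i=\frac{\sum_k u_{ik}^m x_k}{\sum_k u_{ik}^m},\qquad
u_{ik}=\frac{\lVert x_k-v_i\rVert^{-2/(m-1)}}{\sum_j \lVert x_k-v_j\rVert^{-2/(m-1)}},$$

which uses no spatial information, so every noise pixel is classified by its
corrupted intensity alone. IFCM-MS changes three things:

1. **Adaptive similarity.** The raw intensity distance is replaced by
   $\mathrm{Sim}(x_k,c_i)=w_d\,w_g$ with
   $w_d=\exp(-\mathrm{dis}^2(x_k,c_i)/D)$ and
   $w_g=\exp\!\big(-[(g(x_k)-g(c_i))/G]^2\big)$, where $\mathrm{dis}$ is the
   Euclidean distance to the cluster's membership-weighted spatial centroid
   and $D,G$ are per-pixel mean absolute deviations of the cluster distances
   and squared gray gaps. A salt pixel matches the tumor cluster in gray but
   sits far from its centroid, so its similarity is damped. Memberships
   follow $u'_{ik}\propto S_{ik}^{2/(m-1)}$ and centers are plain
   $u'$-weighted means.
2. **Intuitionistic hesitation.** Each membership is augmented with a
   hesitation degree $\pi_{ik}$ from a Sugeno complement generator
   ($\nu=(1-\mu)/(1+\lambda\mu)$, $\pi=1-\mu-\nu$); the stack
   $u'=u+\pi$ is renormalized, and the entropy
   $\sum_i \pi'_i e^{1-\pi'_i}$ is tracked in the objective.
3. **Membership information transfer.** Between iterations, each cluster's
   membership map from the previous iteration is median-filtered and used as
   the guidance image of a (fast) guided filter applied to the current map.
   Impulse outliers are removed from the guidance, the guided filter smooths
   the current memberships while preserving the edges the guidance contains,
   and the stack is renormalized. Iteration stops when the max-abs change of
   the stack falls below $\eta$.

Evaluation is binary tumor-vs-rest: accuracy, precision, recall and
specificity from pixel confusion counts, with the tumor cluster defaulting
to the brightest gray center.

## Worked example

`python examples/segment_noisy_phantom.py` builds the default 128×128
phantom (background 10, brain 90, tissue 140, tumor 220, within-class sd 4),
corrupts 2% of pixels to the intensity extremes, and runs both algorithms:

```
FCM: 48 iterations, gray centers [6.9, 13.6, 90.5, 160.8]
   accuracy=0.9302  precision=0.1592  recall=0.9863  specificity=0.9294
IFCM-MS: 100 iterations, gray centers [9.8, 9.9, 92.2, 235.8]
   accuracy=0.9999  precision=1.0000  recall=0.9909  specificity=1.0000
```

On this seed FCM spends two centers on the dark end and merges the tumor
with tissue, so the "tumor" prediction covers the whole tissue blob
(precision 0.16). IFCM-MS keeps a center on the bright end, the transfer
step strips the salt pixels out of the membership maps, and the tumor is
recovered almost exactly. `examples/ablation_ladder.py` attributes the gain
to the individual ingredients and `examples/noise_sweep.py` shows the
accuracy staying flat across the 0–2% noise grid.

## Command line

```sh
ifcmms phantom --shape 128x128 --seed 0 --noise 0.02 --out img.png --mask mask.png
ifcmms segment --input img.png --clusters 4 --seed 0 --output labels.png --report report.json
ifcmms evaluate --pred labels.png --truth mask.png --out metrics.json
ifcmms sweep --seeds 5 --out sweep.csv          # noise-grid batch, one CSV row per run
```

All flags mirror a flat key/value config file (`--config`, dotted keys such
as `transfer.radius`); every run is reproducible from its `--seed`.

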