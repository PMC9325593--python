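# dermseg

Automatic segmentation of skin lesions in dermoscopic images.

Dermoscopy images of pigmented lesions are hard to segment
automatically: hairs, specular glare, shadow gradients and low contrast
defeat naive thresholds, while active-contour (snake) methods need a
good initial contour that is usually drawn by hand.  `dermseg`
implements a fully automatic pipeline in which a seed mask is derived
from the image itself — Gaussian smoothing, maximum-entropy (Kapur)
thresholding and binary morphology — and a greedy snake then refines
that mask's boundary to the lesion edge.  A phantom generator with
exact ground truth makes every stage testable without clinical data.

## Method

**Seed mask.**  The RGB image is converted to gray (BT.601 luma),
median-filtered to suppress hair strokes and specular highlights, and
smoothed with a normalized Gaussian kernel
`h(n1,n2) = exp(-(n1²+n2²)/2σ²) / Σ exp(·)`.  The threshold *T*
maximizes the summed Shannon entropies of the two intensity classes,

```
H_B(t) = -Σ_{i≤t} p_i ln p_i,   H_W(t) = -Σ_{i>t} q_i ln q_i,
T = argmax_t [H_B(t) + H_W(t)],
```

with `p`, `q` the class-renormalized histogram values.  Lesions are
darker than skin, so pixels ≤ *T* form the foreground.  The binary
mask is cleaned by area opening (8-connectivity), a disk opening
(radius 9) and closing (radius 25), and largest-component selection.

**Snake refinement.**  The seed boundary is traced, resampled to *N*
equally spaced points, and evolved greedily under the classic energy

```
E = Σ_i ½(α|v_i − v_{i−1}|² + β|v_{i−1} − 2v_i + v_{i+1}|²) + E_img(v_i),
E_img = −|∇(G_σ ∗ I)|²  (normalized to [−1, 0]),
```

where each point moves within its pixel neighborhood only when the
move strictly lowers the total energy.  The converged contour is
rasterized, lightly opened/closed, hole-filled, and reduced to its
largest component.

**Evaluation.**  Prediction *R* vs ground truth *A* is scored with the
Jaccard region-coincidence index `P = |A∩R| / |A∪R|` and the Dice
coefficient `DSC = 2|A∩R| / (|A|+|R|)`.

## Worked example

```python
from dermseg import PhantomSpec, generate_phantom, segment_lesion, score_pair

phantom = generate_phantom(PhantomSpec(seed=3, n_hairs=12, contrast=70.0))
result = segment_lesion(phantom.image)
seed_score = score_pair(result.seed_mask, phantom.truth_mask)
final_score = score_pair(result.final_mask, phantom.truth_mask)
print(f"threshold T = {result.threshold.threshold}")
print(f"seed mask   P = {seed_score.jaccard_p:.3f}  DSC = {seed_score.dice:.3f}")
print(f"final mask  P = {final_score.jaccard_p:.3f}  DSC = {final_score.dice:.3f}")
```

prints

```
threshold T = 164
seed mask   P = 0.907  DSC = 0.951
final mask  P = 0.977  DSC = 0.989
```

The entropy threshold lands at gray level 164, between the lesion and
skin intensity modes; the morphological seed already overlaps the true
lesion well (DSC 0.951), and the snake tightens the boundary to the
image gradient (DSC 0.989).

The same pipeline is available from the shell:

```sh
dermseg synth --n 20 --seed 42 --out phantoms/       # images + ground truth
dermseg segment phantoms/image_000.png --out mask.png --overlay overlay.png
dermseg evaluate --pred preds/ --truth truths/ --out scores.csv
```

`segment` exits with code 2 when no usable seed mask can be found
(e.g. a featureless image).

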