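# dmcodex — visual codewords of protein distance matrices

A protein domain's pairwise Cα distance matrix, rendered as a grayscale
image, is a rotation- and translation-invariant picture of its fold:
secondary structure, long-range contacts and — crucially — tandem
structural repeats all appear as characteristic texture.  `dmcodex`
analyzes that texture with a Bag-of-Visual-Words model and turns it into
quantitative statistics about protein structure.

The pipeline, for a corpus of domains:

1. **Distance matrix → image.** `D_ij = ‖r_i − r_j‖` over all Cα atoms,
   mapped to intensity `I_ij = 1 − D_ij / max(D)` so that short-range
   contacts are white and the longest contact is black.
2. **Feature extraction.** A KAZE-style multiscale detector (implemented
   in this package) builds a nonlinear-diffusion scale space, finds
   determinant-of-Hessian extrema, and describes each keypoint with an
   upright 64-dimensional M-SURF gradient descriptor.
3. **Codebook.** All descriptors of the corpus are pooled into a visual
   dictionary `F = {f_1 … f_M}` and clustered with seeded k-means; the K
   centroids are the *codewords*.
4. **Histograms.** Each image becomes a length-K count vector by hard
   assignment of every feature to its nearest codeword.

On top of the histograms the package computes:

- **cosine nearest-neighbor retrieval** scored against the four-level
  structural hierarchy (class / fold / superfamily / family, sids like
  `a.1.1.1`);
- **codeword statistics**: presence-based relative frequency, and the
  normalized distance of each codeword's keypoints from the matrix main
  diagonal, `d = |x̂ − ŷ| / √2 ∈ [0, √2/2]` — frequent codewords sit near
  the diagonal (local structure), rare ones in the corners (long-range
  contacts);
- the **unique-word ratio** `uwr = (# distinct codewords) / (# features)`,
  a scalar measure of structural repetitiveness: solenoid and tandem-repeat
  domains reuse the same few codewords and score low, globular domains
  score high;
- a **linear SVM** on L1-normalized histograms that discriminates solenoid
  from globular domains under 2-fold cross-validation with fold-specific
  codebooks, reported as a TP/FP/TN/FN table with per-class accuracies;
- PCA embedding of the histogram matrix and Pearson correlations
  (feature count vs domain length, uwr vs size).

A synthetic-backbone module generates labeled test corpora — ideal
helices, twisted solenoids built from a repeating unit (periodic
off-diagonal bands), and compact self-avoiding globular chains — so the
whole pipeline is testable without downloading structure databases.

## Worked example

Twenty synthetic domains (~150 residues; 10 noisy solenoids, 10 globular
chains), a 200-word codebook, unique-word ratios and the cross-validated
SVM:

```python
import numpy as np
from dmcodex import synthetic, distance_matrix, to_gray_image, extract_features
from dmcodex.bovw import build_dictionary, build_codebook, encode
from dmcodex.analysis import unique_word_ratio
from dmcodex.classify import twofold_cv, metrics

specs = synthetic.benchmark_specs(n_solenoid=10, n_globular=10,
                                  n_residues=150, seed=1)
traces = [synthetic.generate(s, f"{s.kind}{i:03d}") for i, s in enumerate(specs)]
images = [to_gray_image(distance_matrix(t)) for t in traces]
feature_sets = [extract_features(im) for im in images]

codebook = build_codebook(build_dictionary(feature_sets), k=200, seed=1)
hists = [encode(f, codebook) for f in feature_sets]
ratios = np.array([unique_word_ratio(h).ratio for h in hists])
is_sol = np.array([s.kind == "solenoid" for s in specs])
print(f"mean unique-word ratio  solenoid: {ratios[is_sol].mean():.3f}")
print(f"mean unique-word ratio  globular: {ratios[~is_sol].mean():.3f}")

counts = twofold_cv(feature_sets, [s.kind for s in specs], vocab_size=200, seed=1)
m = metrics(counts)
print(f"2-fold CV confusion: TP={counts.tp} FP={counts.fp} TN={counts.tn} FN={counts.fn}")
print(f"accuracy: solenoid {m.solenoid_acc}  globular {m.globular_acc}  overall {m.overall_acc}")
```

prints (about half a minute on one CPU):

```
mean unique-word ratio  solenoid: 0.245
mean unique-word ratio  globular: 0.330
2-fold CV confusion: TP=10 FP=0 TN=10 FN=0
accuracy: solenoid 100.0  globular 100.0  overall 100.0
```

The repeat texture of the solenoids lowers their unique-word ratio below
the globular mean, and the histogram SVM separates the two classes
perfectly on this corpus: every solenoid (TP) and every globular chain
(TN) is classified correctly by a model that never saw it, with the
vocabulary itself rebuilt from each training fold.

The same pipeline is available from the shell:

```sh
dmcodex synth --out corpus --n-solenoid 10 --n-globular 10 --seed 1
dmcodex distmat --manifest corpus/manifest.tsv --out images
dmcodex extract --images images --out feats
dmcodex codebook --features feats/features.tsv --k 200 --seed 1 --out cb
dmcodex encode --features feats/features.tsv --codebook cb/codebook.tsv --out hists
dmcodex stats --features feats/features.tsv --codebook cb/codebook.tsv \
              --sizes feats/image_sizes.tsv --out stats
dmcodex svm --manifest corpus/manifest.tsv --vocab 200 --seed 1 --out svm_out
```

Every command writes a JSON run-record (configuration, seed, SHA-256 of
its inputs) next to its outputs.

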