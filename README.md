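# fgde — frequency-aware contrastive few-shot class-incremental learning

`fgde` implements a frequency-aware contrastive learning pipeline for
**fine-grained plant-image identification under few-shot class-incremental
learning (FSCIL)**: a base session with ample labelled data is followed by
N-way K-shot sessions that each introduce novel species, and the model must
classify *all* species seen so far without retraining on old data.

Fine-grained plant data is hard precisely because inter-class differences
are subtle, high-frequency texture details, while within-class variation
(pose, layout, illumination) is large and mostly low-frequency.  The
package exploits that structure directly.

## Method

**Frequency decomposition.**  Each channel of an image `X` is mapped to its
spectrum with the orthonormal type-II 2-D DCT and split by a binary
Manhattan-distance mask `M[h,w] = 1 iff h + w ≤ τ`:

    P = DCT2(X),   P_low = P ⊙ M,   P_high = P ⊙ (1 − M)

The inverse transforms `I_l = IDCT2(P_low)` and `I_h = IDCT2(P_high)` are
fused back onto the image (`I ⊙ X + X`) to give detail-enhanced encoder
inputs.

**Domain extension.**  Every training image is expanded into N ordered
variants — original, high-frequency fused, low-frequency fused, colour
jitter, rotation (N = 5 by default) — and the label space extends in
lock-step: variant `n` of class `y` gets the extended label `y·N + n`.

**Contrastive base training.**  A query encoder `f_q` (feature extractor +
linear head) is trained by SGD; a key encoder tracks it by momentum EMA and
feeds a FIFO feature queue with a parallel label queue.  Anchors pull
label-matched candidates together and push the rest apart via a
temperature-scaled InfoNCE objective, optimised jointly (unweighted sum)
with extended-label cross-entropy and a prototype-softened feature
augmentation loss:

    L = L_ce + L_cl + L_al

**Incremental inference.**  After base training the backbone is frozen.
Each class owns one prototype per variant (the mean support embedding);
incremental sessions only *append* prototypes for novel classes.  A test
image is classified by summing cosine similarities of its variant
embeddings against each class's variant prototypes:

    ŷ = argmax_y Σ_n sim(f(x_n), w_yn)

Evaluation reports per-session accuracy and the harmonic mean
`HM = 2·A_base·A_inc / (A_base + A_inc)` balancing base-class retention
against novel-class learning.

Because no public fine-grained herb FSCIL dataset ships with the package,
`fgde.synthetic` generates a benchmark with the same statistical signature:
classes share smooth low-frequency layouts within structure groups while
identity is carried by class-specific high-frequency texture (spatial
frequency + colour mix), with free pose variation inside each class.

## Worked example

```python
import numpy as np
from fgde import FGDEClassifier, SyntheticConfig, generate_dataset
from fgde.synthetic import make_protocol, split_train_test

images, labels, _ = generate_dataset(SyntheticConfig(seed=1))     # 12 classes, 40 images each
protocol = make_protocol(12, n_base=8, n_sessions=2, n_way=2, k_shot=5, seed=1)
train, test = split_train_test(labels, seed=1)

base = np.isin(labels, protocol.base_classes)
est = FGDEClassifier(epochs=25, lr=0.05, random_state=1)
est.fit(images[np.intersect1d(train, np.flatnonzero(base))],
        labels[np.intersect1d(train, np.flatnonzero(base))])

te = np.intersect1d(test, np.flatnonzero(base))
print(f"base accuracy: {100 * est.score(images[te], labels[te]):.1f}%")
```

prints

```
base accuracy: 87.5%
```

i.e. after the base session the frozen-prototype classifier identifies
87.5 % of held-out base-class images (seed 1 of the desk-scale profile).
Running the full protocol — `fgde.run_fscil_experiment(1)` — continues with
the two 2-way 5-shot sessions and reports the session accuracies and the
harmonic mean (65.6 % for this seed), plus the same run with the
frequency variants ablated (N = 1), whose harmonic mean collapses to
42.7 %: the frequency-aware extension is what carries novel-class
generalisation.

The same pipeline is scriptable from a shell:

```bash
fgde synth --out data/ --seed 1          # synthetic benchmark as PNG tree
fgde freq --input leaf.png --tau 8       # low/high decomposition of one image
fgde run --seed 1 --out report.json      # full FSCIL experiment + report
fgde evaluate --data data/ --out m.json  # per-class metrics + confusion matrix
```

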