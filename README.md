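# emdir — EMD-channel image retrieval

`emdir` is a content-based image retrieval toolkit for 2D grayscale
medical images (radiographs and similar). It addresses a concrete problem
in picture-archive search: given a query image, return database images of
the same modality, body orientation, anatomical region and organ system —
without relying on textual metadata.

The pipeline:

1. **Bidimensional empirical mode decomposition (BEMD).** Each image
   `x` is adaptively decomposed into intrinsic mode functions and a
   residual trend, `x = Σ_j c_j + r_n`, by iterative envelope-mean
   sifting. Earlier IMFs carry higher spatial frequencies. The network
   input stacks the original image with its mid-frequency components
   IMF2–IMF4 (IMF1 is mostly noise, the residual a bare intensity trend).
2. **Attention-CNN embedding.** A residual-attention network (bottleneck
   residual units, one bottom-up/top-down attention mask block per stage,
   `(1 + mask) · trunk` gating) maps the 4-channel stack to a compact
   32-dimensional feature vector, trained as a classifier under the joint
   supervision signal

   `L = L_softmax + λ·L_center`,  with
   `L_center = ½·mean_i ‖x_i − c_{y_i}‖²`, λ = 0.002,

   where `c_y` are per-class centers updated by a moving-average rule.
   The center term makes embeddings intra-class compact and inter-class
   dispersed — exactly what nearest-neighbour retrieval needs.
3. **Retrieval and evaluation.** Exhaustive nearest-neighbour search over
   the embeddings (cosine similarity, Euclidean or Manhattan distance),
   classified by the 1-NN rule, scored with the hierarchical **IRMA
   error** (a position-weighted penalty over the four code axes
   `TTTT-DDD-AAA-BBB`, where an early wrong decision poisons all deeper
   ones and a `*` wildcard costs half) and with **mean average precision**
   over full-depth rankings.

Because the network is fit/predict-shaped, the package exposes
scikit-learn estimators (`EMDChannelStacker`, `AttentionEmbeddingClassifier`)
that compose with sklearn pipelines, plus an `emdir` command-line
interface. A built-in phantom generator produces radiograph-like
multi-scale test images with hierarchical codes, so everything runs
without external data. The CNN engine itself (autodiff, convolutions,
batch norm, Adam) is implemented in the package on top of numpy and runs
on a single CPU core; the `reduced` architecture preset (widths ÷ 4,
64×64 inputs) trains in about a minute, the `full` preset is the
full-scale 256×256 configuration.

## Worked example

```python
import numpy as np
from emdir import (
    EMDChannelStacker, AttentionEmbeddingClassifier,
    EmbeddingRecord, build_index, evaluate, CodeScheme,
)
from emdir.phantoms import PhantomSpec, generate_phantom_arrays

# 8 phantom classes, 25 train + 10 test images each, 64x64
images, labels, codes, splits = generate_phantom_arrays(PhantomSpec(seed=7))
stacks = EMDChannelStacker().transform(images)      # (280, 64, 64, 4)
tr, te = splits == "train", splits == "test"

clf = AttentionEmbeddingClassifier(
    epochs=30, learning_rate=3e-3, early_stopping_patience=8,
    dropout_rate=0.25, augment_rotate=True, augment_flip=False, seed=0,
)
clf.fit(stacks[tr], labels[tr])

emb_tr, emb_te = clf.transform(stacks[tr]), clf.transform(stacks[te])
index = build_index(
    [EmbeddingRecord(f"db{i}", e, codes[np.flatnonzero(tr)[i]], int(l))
     for i, (e, l) in enumerate(zip(emb_tr, labels[tr]))],
    measure="cosine",
)
report = evaluate(
    index,
    [(f"q{i}", e, codes[np.flatnonzero(te)[i]], int(l))
     for i, (e, l) in enumerate(zip(emb_te, labels[te]))],
    CodeScheme(),
)
print(f"mAP {report.map_score:.3f}  total IRMA error {report.total_irma_error:.2f}")
```

```
mAP 0.890  total IRMA error 3.57
```

The mAP of 0.89 says that, averaged over the 80 test queries, relevant
database images (same class) dominate the top of each cosine ranking.
The total IRMA error of 3.57 — summed over all 80 queries, each scored
in [0, 1] — says 1-NN misclassifications are uncommon and, when they
happen, tend to be near misses on deeper code positions rather than
wrong top-level branches (a fully wrong prediction would cost 1.0 per
image). Other training seeds land in the same range (mAP 0.87–0.96).

The same workflow is available from the shell:

```bash
emdir fixtures generate --classes 8 --per-class 35 --size 64 --seed 7 --out data/
emdir train    --manifest data/manifest.csv --preset reduced --out model/ \
               --epochs 30 --lr 3e-3 --patience 8 --cache-dir cache/
emdir index    --model model/ --manifest data/manifest.csv --out index.h5 --cache-dir cache/
emdir evaluate --index index.h5 --model model/ --manifest data/manifest.csv \
               --out report/ --cache-dir cache/
emdir decompose --input data/class_00/phantom_00_000.png --out stack.h5 --preview montage.png
```

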