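# sais — surgical activity recognition from frozen frame features

`sais` is a Python package for decoding what happens during robot-assisted
surgery — suturing subphases (needle handling, driving, withdrawal), discrete
dissection gestures (hook, clip, cold cut, …) and binary skill assessments —
from videos that have already been reduced, offline, to per-frame embedding
streams by a frozen feature extractor.  It is aimed at surgical data-science
groups who have per-frame features and clip-level annotations and want a
tested, end-to-end recognition stack: clip classifier, whole-video decoder,
metrics and outcome association.

## The model

Each clip is represented by two streams of D-dimensional frame embeddings:
appearance ("RGB") and motion (optical flow, computed from image pairs 0.5 s
apart).  Frames are subsampled per task (ten equally spaced frames for
gestures; every tenth frame for subphases and skill).  A transformer encoder
(four layers by default, parameters shared across modalities) with a learnable
classification token e_cls and learned temporal positional embeddings
summarises each stream into h_RGB and h_Flow; variable-length batches are
zero-padded and masked so padding is never attended to.  The summaries are
fused additively,

    h_agg = h_RGB + h_Flow,

projected through two linear layers with a ReLU to an E-dimensional video
embedding h_video, and classified against C learned category prototypes p_j
by a softmax over cosine similarities.  Training minimises the prototype
InfoNCE objective (raw cosines as logits, no temperature),

    L = − Σ_i log [ exp(s(h_video, p_c)) / Σ_j exp(s(h_video, p_j)) ],

with SGD (batch 8, learning rate 0.1), so each embedding is attracted to its
own category's prototype and repelled from the rest.  Evaluation uses
video-level Monte Carlo cross-validation: each fold holds out 10% of whole
case videos for testing and 10% of the rest for epoch selection.

Entire untrimmed videos are decoded without annotations: curated windows
(10-s sliding + 5-s tiled for subphases; 1-s tiled for gestures) are
classified under three test-time augmentations (start-frame offsets 0/3/6),
all outputs landing on a timespan — across window approaches, folds and
augmentations (3 × 10 × 3 = 90 for an interior subphase timespan) — are
averaged (bagging), averages with Shannon entropy above a threshold S_thresh
are abstained from, and surviving same-category predictions less than a gap
(3 s subphases, 2 s gestures) apart are chained into discrete events.
Attention out of the classification token provides per-frame importance for
explaining skill assessments, and an adjusted logistic model
Y = σ(b0 + b1·Z1 + b2·Z2 + b3·Z3) relates skill probabilities Z1 to binary
patient outcomes (odds ratio e^{b1}), controlling for surgeon caseload Z2 and
patient age Z3.

Everything is exercisable end-to-end on synthetic data: the generator
produces class-conditional, temporally smooth (AR(1)), modality-correlated
feature streams, whole timelines with a planted gesture grammar, and
simulated skill/outcome cohorts.

## Worked example

```python
import numpy as np
from sais import SyntheticConfig, TrainConfig, InferenceConfig, VideoEventDecoder
from sais.synthetic import gen_dataset, gen_timeline
from sais.training import cross_validate
from sais.evaluation import segmental_f1, fold_report

# 1. simulate a gesture-recognition study: 160 labelled clips (3 dissection
#    gestures + idle background), 32-dim frame features, snr 5
cfg = SyntheticConfig(categories=("hook", "clip", "cold_cut"), dim=32, snr=5.0, seed=11)
clips = gen_dataset(160, cfg, task="gesture", include_background=True)

# 2. ten-fold Monte Carlo cross-validation at the video level
models, reports = cross_validate(
    clips, n_folds=10, config=TrainConfig(n_epochs=15, seed=5),
    n_layers=2, n_heads=4, embed_dim=32,
)
print(fold_report("test macro AUC", [r["test_auc"] for r in reports]))

# 3. decode a 10-minute unlabelled video with the full ensemble stack
appearance, motion, truth = gen_timeline(600.0, cfg)
decoder = VideoEventDecoder(
    models, InferenceConfig(regime="gesture", background_category="background"))
result = decoder.decode(appearance, motion, fps=30.0)
print(f"decoded {len(result.events)} events (ground truth: {len(truth)})")
print("first three:", *result.events[:3], sep="\n  ")
print(f"segmental F1@10: {segmental_f1(result.events, truth, 0.10):.1f}")
```

Output:

```
test macro AUC: 1.000 ± 0.000 (n=10 folds)
decoded 87 events (ground truth: 85)
first three:
  EventInterval(category='hook', start_s=3.0, end_s=6.0)
  EventInterval(category='clip', start_s=11.0, end_s=13.0)
  EventInterval(category='cold_cut', start_s=15.0, end_s=20.0)
segmental F1@10: 98.8
```

The AUC line is the mean ± standard deviation of the one-vs-rest macro AUC
over the ten held-out video sets (at snr 5 the four categories are cleanly
separable).  The decoder recovers the planted hook → clip → cold-cut pattern:
87 decoded events against 85 planted ones, and a segmental F1 of 98.8 at a
10% intersection-over-union matching threshold.

The same pipeline is scriptable from the shell:

```sh
sais simulate --out run/sim --n-videos 4 --duration-s 120 --seed 3
sais train    --features run/sim/features.h5 --annotations run/sim/annotations.tsv \
              --out run/models --regime gesture --n-folds 10
sais infer    --features run/sim/features.h5 --checkpoints run/models --out run/decoded
sais evaluate --pred run/decoded/events.tsv --truth run/sim/annotations.tsv \
              --out run/metrics.json
```

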