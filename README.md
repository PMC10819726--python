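# pigcall

Multi-feature classification of pig vocalizations — grunts, squeals and
coughs — for precision livestock monitoring.  Pigs in large-scale
breeding houses signal their condition acoustically: grunts are
low-energy contact calls, long high-energy squeals indicate distress,
and short cough bursts track respiratory health.  `pigcall` implements a
complete classification pipeline over single-call WAV clips:

1. **Feature extraction** — each clip is summarized by a fused
   33-dimensional descriptor: short-time energy (STE), mean frequency
   centroid (FC), four formant frequencies FF-1..FF-4 with their three
   first-order differences ΔFF, and 12 MFCC plus 12 ΔMFCC coefficients.
2. **PCA composite scoring** — the feature table is z-scored, the
   correlation matrix R is eigendecomposed, and components are retained
   until the cumulative contribution rate δ_k = Σ_{i≤k} λ_i/Σλ reaches
   85%.  Each sample additionally receives a *comprehensive evaluation
   score* F_comp = Σ_{i≤k} w_i F_i with weights w_i = C_i/δ_k, a single
   scalar that separates the call classes.
3. **GA-BP classification** — a three-layer sigmoid network
   (input–10–3) whose initial weights and thresholds are found by a
   real-coded genetic algorithm (population 50, 100 generations,
   crossover 0.5, mutation 0.01, genes in [−1, 1]) and refined by
   incremental backpropagation (1000 epochs, learning rate 0.01, target
   error 1e−5).  Three input variants are supported: the raw 33-D
   features, the retained principal components, and the components plus
   the comprehensive score.
4. **Evaluation** — 3×3 confusion matrices with accuracy (trace/total),
   per-class precision TP/(TP+FP) and recall TP/(TP+FN), and macro
   averages, printed to one decimal.

Because corpora of labeled barn recordings are rarely redistributable,
the package ships a source-filter **synthesizer** that generates
grunt/squeal/cough-like clips whose duration, energy, centroid ordering
and formant statistics emulate published per-class summaries — the
synthesis resonators give ground-truth formants, making every stage of
the pipeline testable end to end.

## Worked example

```sh
pigcall simulate --out data/ --n 100 --seed 1
pigcall extract  --audio data/ --out features.csv
pigcall train    --features features.csv --variant pca15_plus_score \
                 --out models/ --seed 1
```

`simulate` writes 300 WAV clips plus a `labels.csv`; `extract` reads
them back and writes one 33-feature row per clip (294 of the 300 here —
clips whose formant tracks are too unstable to trust are skipped with a
logged warning, and the command's exit code 2 signals the partial
result).  `train` then prints the validation confusion matrix for the
held-out 30% split (29–30 clips per class):

```
Type of Vocalization	Grunt	Squeal	Cough	Total	Recall/%
Grunt	29	0	0	29	100.0
Squeal	0	30	0	30	100.0
Cough	0	0	30	30	100.0
Total	29	30	30
Precision/%	100.0	100.0	100.0
Accuracy/%	100.0
```

Rows are true classes, columns predictions.  At this scale the three
synthetic classes separate perfectly; at the full study scale of
291/357/291 clips (see below) accuracies land in the low 90s, with the
residual confusions between grunts and coughs — both short,
low-pitched calls.  The same surface is available programmatically:

```python
from pigcall import (SyntheticDatasetSpec, ValidationError, generate_dataset,
                     extract_features, train_variant)
from pigcall.features import features_to_frame

clips = generate_dataset(SyntheticDatasetSpec(class_counts=(100, 100, 100), seed=1))
vectors = []
for clip in clips:
    try:
        vectors.append(extract_features(clip))
    except ValidationError:
        pass  # skip clips with unstable formant tracks
bundle = train_variant(features_to_frame(vectors), "pca15_plus_score", seed=1)
print(bundle.validation_report["accuracy"])
```

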