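# aesmbe — EEG biometrics with automatic electrode selection

`aesmbe` implements a complete EEG-based person-identification pipeline
for researchers in biometrics and brain–computer interfacing: it learns,
for every enrolled person, which few electrodes carry their most
distinctive brain activity, identifies people from those electrodes
alone, and scores the result under a standard biometric verification
protocol.  The package ships a synthetic EEG generator with *planted*
subject signatures so every stage is testable end to end without access
to a recording lab.

## The method

**Stage 1 — pre-training / electrode selection.**  For each subject, a
4-class intent classifier (rest vs motor execution vs motor imagery vs
*other subject*) is trained on 1 s windows, normalized per window and
per channel:

    I[i, j] = (Input[i, j] − mean_i) / σ_i

The network starts with a channel-attention gate: a pooled per-channel
descriptor `z ∈ R^C` passes through a square weight matrix `W ∈ R^{C×C}`
(initialized U(−1/√C, 1/√C)) and a sigmoid, giving gates
`α = σ(W z) ∈ [0,1]^C` that rescale each channel.  A multi-scale
bidirectional encoder follows: per temporal direction, a local (k=3) and
a global (k=7) convolution with a channel-mixing residual projection,
the backward branch running on the time-reversed signal.  After
training, electrode importance is read off the attention weights alone:

    s_c = Σ_j |W[j, c]|

and the top-*n* channels become the subject's frozen montage.

**Stage 2 — registration / identification.**  Windows restricted to each
subject's selected electrodes (stacked in ascending electrode order, so
the input is always `n × 160` regardless of which physical electrodes
were chosen) train a single K-class CNN–Transformer classifier (strided
1-D convolutions, then multi-head self-attention
`softmax(QKᵀ/√d)V`, global average pooling, softmax).

**Stage 3 — verification.**  Every held-out window is paired with all K
possible identity claims: one genuine trial (score = softmax posterior
of the true identity) and K−1 impostor trials.  A claim is accepted when
its score ≥ τ; sweeping τ yields FAR(τ) and FRR(τ) and their crossing is
the equal error rate (EER).

All splits are run-wise: whole recording runs are assigned to train or
test before any windowing, so temporally adjacent windows can never
straddle a fold.

## Worked example

```python
import numpy as np
from aesmbe import (
    SyntheticConfig, generate_dataset, segment_run,
    IntentBackbone, PersonIdentifier, assemble_input,
    enumerate_trials, error_curve_and_eer,
)
from aesmbe.data import relabel_for_pretraining, make_folds, REGISTRATION_TEMPLATE
from aesmbe.synthetic import make_signature

cfg = SyntheticConfig(n_subjects=4, n_channels=16, run_duration_s=30, snr=8, seed=1)
runs = generate_dataset(cfg)
windows = [w for r in runs for w in segment_run(r)]

# stage 1: electrode selection (shown for subject 0)
rankings = {}
for s in range(4):
    ws, labels = relabel_for_pretraining(windows, target_subject=s, seed=0)
    intent = IntentBackbone(n_blocks=1, lr=0.02, batch_size=128,
                            max_epochs=40, patience=40, seed=0)
    intent.fit(np.stack([w.data for w in ws]), labels)
    rankings[s] = intent.channel_ranking(s)
print("selected:", rankings[0].top(4))
print("planted: ", sorted(make_signature(0, cfg).planted_channels))
```

```
selected: [7, 11, 14, 15]
planted:  [6, 7, 11, 15]
```

The learned ranking recovered three of the four channels the generator
secretly made subject-discriminative.  Continuing to identification and
verification:

```python
train_w, test_w = make_folds(runs, REGISTRATION_TEMPLATE)[0]
Xtr = np.stack([assemble_input(w.data, rankings[w.subject_id], 4) for w in train_w])
ytr = np.array([w.subject_id for w in train_w])
Xte = np.stack([assemble_input(w.data, rankings[w.subject_id], 4) for w in test_w])
yte = np.array([w.subject_id for w in test_w])

ident = PersonIdentifier(conv_channels=(32, 32, 32), n_layers=1, lr=0.02,
                         batch_size=128, max_epochs=10, patience=10, seed=0)
ident.fit(Xtr, ytr)
post = ident.predict_proba(Xte)
acc = (ident.classes_[post.argmax(1)] == yte).mean()
labels_idx = np.array([list(ident.classes_).index(v) for v in yte])
eer = error_curve_and_eer(enumerate_trials(post, labels_idx)).eer
print(f"identification accuracy {acc:.3f}, EER {eer:.4f}")
```

```
identification accuracy 1.000, EER 0.0000
```

With four planted channels per subject at this signal-to-noise ratio,
four well-chosen electrodes identify every held-out window, and genuine
and impostor scores separate completely (EER 0).  The command-line
interface wraps the same stages (`aesmbe simulate / pretrain / register /
verify / report`), driven by a YAML config.

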