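# fpnet — feedback-free neural network training by forward projection

`fpnet` trains feed-forward classifiers **without backpropagation, in a
single epoch, in closed form**. It is aimed at people studying
biologically plausible learning rules and at settings where the
training data can only be streamed once, where activations are not
differentiable, or where hidden layers must be auditable — e.g.
biomedical signal, sequence and image classification, where a clinician
may want to inspect what an intermediate layer has learned before any
downstream layer exists.

## The method

For a network `a_l = f_l(a_{l-1} W_l)`, each hidden layer receives an
explicit target for its membrane potentials, built in the forward pass
from fixed random Gaussian projections of its inputs and the one-hot
label:

    z̃_l = g(a_{l-1} Q_l) + g(y U_l)

with `g = sign` by default. The weights are then the streaming ridge
solution

    W_l = (A_{l-1}ᵀ A_{l-1} + λI)⁻¹ (A_{l-1}ᵀ Z̃_l),

accumulated batch-by-batch (memory independent of the number of
samples) and solved once per layer. Layers are fitted in order and
frozen — no error signal, gradient, or any other information ever flows
backwards. Because the label is planted additively in every layer's
potentials, hidden layers decode into local label predictions:

    ŷ_l = g⁻¹(z_l − g(a_{l-1} Q_l)) U_l⁺,

which yields per-position saliency maps for convolutional layers at any
depth, before the rest of the network is even built. Training one dense
m×m layer costs `N(2m² + m·m_L)` multiply-accumulates forward and
`2Nm² + 2m³` for the update — independent of epochs, because there is
exactly one.

See `docs/methods.md` for the full model description, numerical
choices, and what the synthetic benchmark tasks do and do not emulate.

## Worked example

Train a 1D convolutional network on a synthetic 12-lead waveform task
(positives carry a planted transient in a known window), then decode a
hidden layer and score how well its saliency map localizes the planted
feature:

```python
import numpy as np
from fpnet import (make_waveforms, ForwardProjectionConvClassifier, evaluate,
                   explain_layer, saliency_map, localization_score)
from fpnet.targets import derive_seed

train = make_waveforms(200, seed=derive_seed(0, 1))
test = make_waveforms(120, seed=derive_seed(0, 2))

clf = ForwardProjectionConvClassifier(n_blocks=2, base_filters=8, random_state=0)
clf.fit(train.X, train.labels)
print("per-layer train residuals:", [round(r, 3) for r in clf.train_residuals_])

metrics = evaluate(clf, test.X, test.labels)
print(f"test AUC {metrics['auc']:.1f}, accuracy {metrics['accuracy']:.3f}")

pos = test.labels == 1
expl = explain_layer(clf, 1, test.X[pos])
print(f"layer 1 reliability (train residual): {expl.reliability:.3f}")
maps = saliency_map(expl, class_index=1, spatial_shape=test.X.shape[2:])
loc = np.mean([localization_score(maps[i], test.masks[pos][i])["auc"]
               for i in range(maps.shape[0])])
print(f"mean localization AUC over {pos.sum()} positives: {loc:.3f}")
```

Output:

```
per-layer train residuals: [0.815, 0.718, 0.683, 0.632]
test AUC 97.0, accuracy 0.850
layer 1 reliability (train residual): 0.718
mean localization AUC over 60 positives: 0.695
```

The residuals are each layer's relative target-fit error
`‖Z − Z̃‖/‖Z̃‖` — the reliability gauge for interpretation (a residual
near 1 would flag the decoded predictions as untrustworthy). Test AUC
is on the 0–100 scale. The localization AUC of 0.695 says the decoded
layer-1 label map ranks time points inside the planted transient window
above points outside it well beyond chance (0.5) — the hidden layer has
learned *where* the class evidence is, two layers before the readout.

Estimators follow the scikit-learn protocol (`fit` / `predict` /
`decision_function`, `get_params`/`set_params`, `clone`), so they
compose with sklearn model selection. `ForwardProjectionClassifier` is
the dense (MLP) variant; both accept `fit_mode` in
`{"fp", "rf", "label_projection", "noisy_label_projection"}` for the
feedback-free baselines.

## Command line

```sh
fpnet simulate --config run.yaml --seed 1 --out runs/data
fpnet fit      --config run.yaml --data runs/data --seed 1 --out runs/fit
fpnet predict  --model runs/fit --data runs/data --out runs/pred
fpnet explain  --model runs/fit --data runs/data --layer 1 --out runs/expl
fpnet fewshot  --config run.yaml --data runs/data --seed 1 --n-per-class 5,10,20 --out runs/fs
fpnet complexity 60000 100 1000 10
```

Each command writes a JSON run manifest (config hash, seeds, metrics);
re-running an archived config reproduces its artifacts bit for bit.

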