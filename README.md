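# gaitprint

What makes a running gait individually recognizable — and which movement
variables carry that individuality?

`gaitprint` is a research package for gait-individuality analysis in human
running.  It identifies individuals from single-stance *stride patterns* —
the concatenation of 12 time-normalized trajectories (9 lower-limb joint
angles from marker-cluster kinematics and 3 ground-reaction-force
components) into a 1×1200 feature vector — using a shallow neural network,
explains the network's decisions with layer-wise relevance propagation
(LRP), and quantifies where identity information lives by re-evaluating
the fixed network on relevance-ranked variable subsets.  It is aimed at
biomechanists and movement scientists studying gait as a biometric and at
anyone who needs a tested, self-contained reference implementation of the
LRP-plus-ablation recipe for time-series classification.

Because gait datasets are rarely shareable, the package ships a synthetic
multi-subject gait generator whose discriminative structure is *planted*
and therefore exactly known: identity lives in a chosen subset of channels
(by default the frontal/transverse-plane angles and the medio-lateral
force) and a chosen stance window (by default the first 30%).  Every
downstream stage — stance segmentation at the 15 N force threshold,
zero-phase filtering, time normalization, per-participant standardization,
training, LRP, ablation — is tested against that ground truth.

## The model

A stride pattern `x ∈ [−1, 1]^1200` is classified by a one-hidden-layer
network

    score(x) = W₂ᵀ tanh(W₁ᵀ x + b₁) + b₂

(1200–2400–50 at study scale; sizes scale with the data), trained with
seeded mini-batch gradient descent under softmax cross-entropy on all
day-1 patterns and evaluated on day-2 patterns.  Performance is the
participant-wise accuracy

    Accuracy(p) = n_p / N_p · 100,

with `n_p` the correctly assigned and `N_p` all stride patterns of
participant `p`, summarized as the unweighted mean over participants.
For every correctly classified day-2 pattern the predicted class's
pre-softmax score is decomposed into input relevances with the
ε-stabilized LRP rule

    R_j = Σ_k (a_j w_jk) / (Σ_j' a_j' w_j'k + ε·sign(·)) · R_k,

and the per-stride maps are aggregated (normalize to own maximum →
average → rectify → triple (¼, ½, ¼) smoothing per channel → rescale to
[0, 1]) into one group-level relevance pattern.  Sorting variables by that
pattern and zeroing all but the top k yields the accuracy-vs-k ablation
curve.

See `docs/methods.md` for the full account: the synthetic world and its
assumptions, the normalization's consequences for identity information,
the spectral initialization the second-order learning problem requires,
and all numerical choices.

## Worked example

```python
from gaitprint import (TrainConfig, desk_scale_spec, run_experiment,
                       summarize)

# 10 subjects, 30 trials/day on two days, identity planted in five
# channels during early stance; network scaled to 1200-600-10
res = run_experiment(desk_scale_spec(seed=0),
                     train_config=TrainConfig(hidden_size=600,
                                              max_epochs=1000))

print(f"day-2 accuracy: {res.report.mean_accuracy:.1f}%")
print({k: round(a, 1) for k, a in zip(res.curve.k_values,
                                      res.curve.accuracies)})
print({k: round(v, 1)
       for k, v in summarize(res.aggregated)["phase_totals"].items()})
```

prints (exact numbers from this configuration and seed):

```
day-2 accuracy: 98.3%
{16: 10.0, 25: 14.7, 50: 35.3, 100: 79.3, 200: 95.7, 300: 97.0,
 500: 98.0, 800: 98.7, 1200: 98.3}
{'early': 54.3, 'mid': 25.2, 'late': 15.9}
```

Read: the network re-identifies unseen day-2 strides at 97%; accuracy
rises steeply over the first few hundred top-relevance variables and
saturates near the full-data value; and aggregated relevance concentrates
in early stance, where the generator planted the identity signal.
`res.planted_channel_accuracy` vs `res.nonplanted_channel_accuracy`
(channel-subset reclassification) shows the same dissociation at the
channel level.  Figures analogous to a per-participant accuracy bar chart,
the 12×100 relevance heat map with marginal sums, and the ablation curve
come from `gaitprint.plots`.

## Layout

| module | contents |
|---|---|
| `gaitprint.channels` | channel registry, feature index map |
| `gaitprint.synthetic` | synthetic gait generator (processed + raw modes), dataset I/O |
| `gaitprint.kinematics` | rigid cluster fits, Z-X-Y cardan angles |
| `gaitprint.preprocessing` | stance detection, filtering, normalization, stride patterns |
| `gaitprint.classifier` | tanh network, training, participant-wise accuracy |
| `gaitprint.relevance` | LRP, aggregation recipe, summaries |
| `gaitprint.reduction` | relevance ranking, masking, ablation curves |
| `gaitprint.plots` | report figures |
| `gaitprint.experiment` | one-call end-to-end driver |
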