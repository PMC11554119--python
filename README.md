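# pescale

**Does the brain's surprise response track low-level or high-level visual
features?** In statistical-learning fMRI experiments, a cue probabilistically
predicts the next image; unexpected images evoke larger responses
(prediction errors). A central question in hierarchical predictive
processing is what *kind* of surprise drives this up-regulation: a local
mismatch in each area's own feature space (edges and orientations in early
visual cortex, object identity in higher areas), or a high-level surprise
signal computed late in the hierarchy and broadcast down to earlier areas.

`pescale` is a tested re-implementation of the analysis pipeline that
arbitrates between these hypotheses, exercised end-to-end on a synthetic-data
generator with planted ground truth. It is written for methods researchers
who want to study, stress-test or extend the analysis chain — trial-wise
feature-model dissimilarity scoring, parametric-modulation GLMs,
least-squares-separate (LSS) single-trial estimation, searchlight
representational similarity analysis (RSA), surprise-scaling regression,
linear decoding, and the accompanying behavioral statistics — without access
to human data.

## The model

The experiment pairs 8 consonant letter cues one-to-one with 8 object images
(4 animate, 4 inanimate). Per run, the cue's paired image follows it 7 times
and each of the 7 other images once, so

P(expected image | cue) = 7/14 = 0.5,

and every image appears equally often (no frequency confound). Trial-wise
**surprise** under a feature model *m* with representational dissimilarity
matrix RDM_m is, on each unexpected trial,

s_m(trial) = RDM_m[expected(cue), seen image],

z-scored within subject. Feature models are layer-wise RDMs of a visual
network hierarchy (correlation distance, 1 − r, averaged over model
instances), plus animacy (binary), word-embedding (semantic) and
untrained-network control RDMs. The BOLD response on unexpected trials is
modeled as scaling linearly with surprise: in the GLM, each z-scored s_m
enters as a parametric modulator of the unexpected-trial regressor
(500 ms events, double-gamma HRF); complementarily, LSS single-trial
estimates β_t are regressed per subject on s_m and the slopes tested across
subjects with one-sample t tests. The signature result this pipeline can
reproduce on synthetic data is the dissociation: feedforward (localizer)
responses follow a low-to-high layer gradient across regions, while
prediction-error scaling prefers the top layers everywhere — including the
"early" region.

## Worked example

Eight synthetic subjects with a planted high-level (layer-8) scaling slope of
1.0 in the `high_scaling` voxel population; full chain: design → features →
surprise → BOLD synthesis → LSS → ROI scaling regression.

```python
import numpy as np
from pescale.stimuli import default_stimulus_set
from pescale.design import build_tpm, generate_run
from pescale.features import correlation_rdm, trial_surprise
from pescale.synth import default_ground_truth, synth_bold, synth_feature_hierarchy
from pescale.lss import lss
from pescale.scaling import scaling_regression

stimuli = default_stimulus_set()
tpm = build_tpm(stimuli)

subject_stacks, subject_z = [], []
for subject in range(8):
    events = generate_run(tpm, rng_seed=subject)
    layers = synth_feature_hierarchy(stimulus_ids=stimuli.stimulus_ids,
                                     rng_seed=100 + subject)
    sv8 = trial_surprise(correlation_rdm(layers[7]), events, stimuli,
                         model_id="layer8")
    truth = default_ground_truth(grid=(10, 8, 6), high_slope=1.0,
                                 rng_seed=subject)
    bold = synth_bold(events, {"layer8": sv8}, truth, noise_sd=1.0,
                      rng_seed=subject)
    subject_stacks.append(lss(bold, events).restrict("unexpected"))
    subject_z.append(sv8.z)

roi = truth.voxels_in("high_scaling")
res = scaling_regression(subject_stacks, subject_z, roi_voxels=roi, scope="roi")
print(f"mean slope = {res['mean_slope']:.3f} BOLD units per z-unit of surprise")
print(f"t({res['dof']}) = {res['t']:.2f}, p = {res['p']:.2g}, dz = {res['dz']:.2f}")
```

Output:

```
mean slope = 0.992 BOLD units per z-unit of surprise
t(7) = 84.58, p = 8.5e-12, dz = 29.90
```

The recovered group-mean slope (0.992) matches the planted value (1.0): each
z-unit of high-level surprise adds about one arbitrary BOLD unit to the
unexpected-trial response in the scaled population, and the one-sample t
across the 8 subjects rejects the no-modulation null. (At this noise level
recovery is nearly exact; group statistics on realistically weak effects are
exercised by the test suite.)

A command-line interface mirrors the main stages:

```bash
pescale design run --seed 1 --out events.tsv      # 128-trial events TSV
pescale features --layer 8 --out rdm.tsv          # synthetic layer RDM
pescale run-all --subjects 2 --out pescale_out    # end-to-end with manifest
```

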