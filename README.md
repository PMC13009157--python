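# hairplate

Analysis toolkit for studying **proprioceptive limit detectors** on the
insect leg — hair plates, the fields of stiff mechanosensory hairs at
joint folds that fire when a limb nears the extreme of its movement
range. The package implements, as a tested and reusable pipeline, the
three computational analyses by which such a study links a sensor to its
reflex function:

1. **Connectome circuit analysis** (`hairplate.circuits`) — from directed
   synapse tables and neuron annotations: cell-class output fractions,
   motor-module input fractions, two-layer sensorimotor circuit diagrams,
   and the signed **motor impact score** of a hair plate onto each leg
   motor module.
2. **3-D leg kinematics** (`hairplate.kinematics`) — behavior
   classification from ball/body velocities, swing/stance segmentation of
   tarsus trajectories, step filtering, AEP/PEP extraction, normalized
   swing trajectories, inter-leg phase coupling, and resting-posture
   metrics (body height, pitch, tarsal stance-polygon area).
3. **Ratiometric calcium tuning** (`hairplate.calcium`) — GCaMP/tdTomato
   ROI traces to baseline-z-scored activity, upsampled and low-pass
   filtered to the leg-tracking rate, then summarized as 1-D and 2-D
   joint-angle tuning curves and behavior probabilities at peak activity.

A statistics module (`hairplate.stats`) provides the study's three group
comparisons — a linear mixed-effects model with fly identity as random
intercept, Welch t-tests on per-fly means, and the two-sample Kuiper test
for circular step phases, each with explicit Bonferroni correction — and
a synthetic-data module (`hairplate.synthetic`) generates connectomes,
tripod-gait pose sessions, and calcium sessions with known ground truth
so every stage is testable without any experimental data.

## The motor impact score

For a hair plate *H* (a set of sensory axons) and a motor module *M* (a
group of motor neurons sharing presynaptic input and controlling the same
joint), with `syn(a→b)` the synapse count and `in(x)` the total input
synapses of *x* (from all annotated neurons):

```
w1 = syn(H→M) / in(M)                                (monosynaptic)

w2 = Σ_p  sign(p) · syn(H→p)/in(p) · syn(p→M)/in(M)  (di-synaptic)

impact = w1 + w2
```

where the sum runs over premotor interneurons *p* and `sign(p)` is +1 for
cholinergic and −1 for GABAergic or glutamatergic neurons (glutamate is
inhibitory in the fly nerve cord). A positive impact predicts that
stimulating the hair plate recruits the module; a negative impact
predicts suppression. Circuit *diagrams* additionally apply the
convention that a downstream cell is analyzed only if it receives an
average of ≥ 4 synapses per upstream neuron of a class; the impact score
itself is computed without that threshold.

## Worked example

A hand-checkable circuit: one hair plate makes 20 of a module's 200 input
synapses directly (w1 = 0.1) and drives an excitatory premotor neuron
(25 of its 50 inputs) that contributes 40 synapses to the module:

```python
import pandas as pd
from hairplate.io import NeuronRecord
from hairplate.circuits import SynapseGraph, motor_impact

ann = [NeuronRecord("hp1", "sensory", hair_plate="HP"),
       NeuronRecord("p", "premotor", hemilineage="20A",
                    neurotransmitter="acetylcholine"),
       NeuronRecord("m1", "motor", motor_module=1),
       NeuronRecord("bgp", "other"), NeuronRecord("bgm", "other")]
edges = pd.DataFrame([("hp1", "m1", 20), ("hp1", "p", 25), ("bgp", "p", 25),
                      ("p", "m1", 40), ("bgm", "m1", 140)],
                     columns=["pre_id", "post_id", "n_synapses"])
s = motor_impact(SynapseGraph(edges, ann), "HP", 1)
print(s.w1, s.w2, s.total)
```

prints `0.1 0.1 0.2`: the hair plate supplies 10% of the module's input
directly, and another signed 10% through the premotor layer (0.5 of the
premotor neuron's input × 0.2 of the module's input). Re-annotating the
premotor neuron as GABAergic flips `w2` to −0.1 and the total impact to
0.0 — direct excitation exactly cancelled by di-synaptic inhibition.

The CLI chains the same library functions on CSV tables:

```
$ hpc simulate --kind gait --seed 3 --out scratch/gait
INFO hairplate: simulate gait: 3 flies, 690 frames each
$ hpc steps --pose scratch/gait/pose.csv --out scratch/steps
INFO hairplate: steps: 387 retained step cycles from 3 sessions
```

`steps.csv` then holds one step cycle per row (leg, swing/stance frames,
AEP and PEP in mm, durations, step frequency, swing distance), e.g. a
front-leg step with swing duration 0.0333 s, stance 0.0667 s, and step
frequency 10.0 steps/s. Other subcommands: `hpc simulate --kind
connectome|calcium`, `hpc impact`, `hpc tuning`, and `hpc compare`
(mixed-model / t-test / Kuiper comparisons of any table column).

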