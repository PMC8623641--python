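# eegconn

A toolkit for comparing functional-connectivity measures in resting-state
EEG brain-network analysis, built for studies that discriminate clinical
groups (e.g. subjective cognitive impairment, mild cognitive impairment and
Alzheimer's disease) from multichannel scalp recordings.

## What it computes

Given band-filtered EEG epochs (delta 1–4, theta 4–8, alpha 8–12, beta
12–30 Hz; third-order Butterworth), the toolkit quantifies the coupling
between every electrode pair with four measures:

* **Epoch-based entropy (EpEn).** A continuous left-to-right hidden Markov
  model with Gaussian-mixture emissions is fitted to the stacked
  two-dimensional observations of a channel pair; the Viterbi path segments
  the pair into quasi-stationary epochs $S_1,\dots,S_N$, and

  $$H^*(Z_i) = -\sum_{z \in S_i} P_i(z)\,\log_2 P_i(z), \qquad
    \mathrm{EpEn}(Z) = \frac{1}{N}\sum_{i=1}^{N} H^*(Z_i),$$

  where $P_i$ is the state-$i$ emission density. High joint EpEn indicates
  high information content conveyed by the coupling.
* **Phase lag index.** $\mathrm{PLI} = |\langle \mathrm{sign}\,
  \sin \Delta\phi(t_k)\rangle| \in [0,1]$, with instantaneous phases from
  the Hilbert analytic signal.
* **Magnitude squared coherence.** Welch segment-averaged
  $|\langle X Y^*\rangle|^2 / (\langle|X|^2\rangle\langle|Y|^2\rangle)$,
  averaged over in-band frequency bins.
* **Spectrogram mutual information.**
  $I_w = \sum_{k,f} C_{xy}\log_2\!\big(C_{xy}/(C_x C_y)\big)$ over
  normalized time–frequency energy distributions.

Connectivity matrices are binarized by **proportional thresholding** (the
strongest fraction PT of connections is kept, equalizing density across
subjects) and described by five local graph parameters per node: degree,
clustering coefficient, characteristic path length, local efficiency and
betweenness. Node-level features are ranked by **orthogonal forward
regression** with a Gram–Schmidt update and selected by the **random
probe** criterion (accept while the probability that a pure-noise probe
ranks at or before the current step stays below a 10% risk), first within
each band and then across pooled band survivors. A linear SVM is
cross-validated over the 9 PT values × 3–10 feature counts of the protocol
grid, and three-class decisions are obtained by coupling pairwise
posteriors:

$$\Pr(C_i \mid x) = \Big(\sum_{j \ne i} 1/\Pr_{ij} - (K-2)\Big)^{-1}.$$

A synthetic-cohort generator plants phase-lag, linear-mixing or shared
variance-regime coupling with known strength, so every stage is testable
end to end without clinical data.

## Worked example

```python
import numpy as np
from eegconn import (two_group_spec, generate_cohort, bandpass, CANONICAL_BANDS,
                     build_connectivity_matrix, proportional_threshold, node_metric,
                     epen_coupling, HMMConfig)

spec = two_group_spec(n_per_group=(6, 6), n_channels=8, fs=128.0,
                      duration_s=20.0, seed=42, pair=(6, 3))
recs, manifest = generate_cohort(spec)
print("planted coupling:", manifest["coupling"]["A"][0])

rec = bandpass(recs[0], CANONICAL_BANDS["alpha"])
cm = build_connectivity_matrix(rec, "PLI", CANONICAL_BANDS["alpha"])
print(f"PLI[F8, F3] = {cm.values[6, 3]:.3f}")
print(f"median off-diagonal PLI = {np.median(cm.values[np.triu_indices(8, 1)]):.3f}")

g = proportional_threshold(cm, pt=0.3)
print("degree of F3 at PT=0.3:", int(node_metric(g, 'K').values[3]))

e = epen_coupling(rec.data[6], rec.data[3],
                  HMMConfig(n_states=5, n_mix=2, dim=2), mode="rate")
print(f"joint EpEn (rate mode) of the coupled pair = {e:.2f} bits")
```

prints

```
planted coupling: {'pair': ['F8', 'F3'], 'mechanism': 'phase_lag', 'strength': 0.8}
PLI[F8, F3] = 1.000
median off-diagonal PLI = 0.076
degree of F3 at PT=0.3: 5
joint EpEn (rate mode) of the coupled pair = 11.63 bits
```

The planted F8–F3 phase lag saturates the PLI while uncoupled pairs sit
near the noise floor; after proportional thresholding the coupled
electrodes carry the highest degrees, which is exactly the node-level
signal the feature selection recovers downstream.

The same pipeline is scriptable from the shell:

```sh
eegconn simulate --config cohort.json --out cohort/      # EDF + manifest
eegconn connectivity cohort/A-000.edf --measure PLI --band alpha --out cm.tsv
eegconn graph cm.tsv --pt 0.3 --param K --out degrees.tsv
eegconn all --config run.json --out results/ --seed 1    # full grid
```

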