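# msnpipe

Morphometric similarity network (MSN) analysis of disinhibition in
dementia, packaged as a tested, reproducible pipeline with a synthetic
cohort simulator.

## The problem

Disinhibition — socially inappropriate behaviour measured by the NPI-Q
(presence plus severity 1–3) — occurs in both behavioural-variant
frontotemporal dementia (bvFTD) and dementia of the Alzheimer's type
(DAT). A transdiagnostic question is whether the symptom tracks the
integrity of specific large-scale brain networks rather than the clinical
diagnosis. MSNs address this with structural MRI alone: for each subject,
every cortical region of a 360-parcel atlas is described by 7 FreeSurfer
grey-matter features (GM volume, surface area, cortical thickness,
intrinsic curvature, mean curvature, curved index, folding index), and the
edge weight between regions *i* and *j* is the Pearson correlation of
their feature vectors (self- and negative correlations removed). Within
the salience network (SN; 56 cingulo-opercular + 6 orbito-affective
parcels) and the cognitive control network (CCN; 23 dorsal-attention + 50
frontoparietal parcels), the weighted graphs are proportionally
thresholded at densities 0.25–0.45, normalized, and summarized by

- **transitivity** `T = Σᵢ[(W^{1/3})³]ᵢᵢ / Σᵢ kᵢ(kᵢ−1)` (segregation),
- **global efficiency** `E = (1/(n(n−1))) Σ_{i≠j} 1/d_ij` with
  `d_ij` the shortest path length on edge lengths `1/w` (integration),
- the **small-world coefficient** `σ = (C/C_rand)/(L/L_rand)` against
  degree-preserving rewired nulls (descriptive characterization).

Group effects are tested per network and metric with a 2 (disinhibition
presence) × 2 (diagnosis) × 5 (density) repeated-measures ANCOVA
(between-subject effects, Type III, effects coding) adjusted for age, sex,
total intracranial volume, MRI-to-NPI-Q interval, CDR-SB, scanner (dummy
coded against Siemens) and education, with partial η² effect sizes.

Because the motivating MRI cohorts are access-restricted, the package
ships a documented synthetic-cohort generator whose inter-regional
correlation structure carries configurable, network-localized group
effects, so every downstream stage is testable end to end.

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 0   # 30 DAT + 20 bvFTD demo cohort
python analysis/02_network_metrics.py            # MSNs -> metric table
python analysis/03_ancova.py                     # ANCOVA + demographics
```

The second step prints the metric table summary, e.g.

```
metric           transitivity  global_efficiency
network density
CCN     0.25           0.7491             0.4068
        0.45           0.7138             0.5036
SN      0.25           0.7271             0.4223
        0.45           0.6403             0.4977
fraction of connected subject-graphs: CCN 90.40%, SN 96.00%
```

i.e. per subject, network and density the weighted segregation and
integration of the thresholded subnetwork, with disconnected low-density
graphs flagged rather than fatal. The third step prints one F test per
between-subject effect, e.g.

```
CCN_global_efficiency  disinhibition  F(1,38) = 1.57, p = 0.2174, partial eta^2 = 0.040
```

(at this demonstration size the injected CCN attenuation is not
significant; at the reference size of 111 + 75 subjects the same effect
yields F ≈ 16, p < 0.001 — see the reproduction script below). The same
pipeline is available as one command (`msnpipe run-all --seed 5 --output
results/run`) and as stage-wise subcommands (`simulate`, `build-msn`,
`metrics`, `analyze`, `demographics`) that read and write only delimited
text, so real FreeSurfer regional exports can replace the simulator at any
stage boundary.

`analysis/04_recovery_and_calibration.py` and
`analysis/05_small_world_profile.py` run the validation studies: recovery
of an injected 0.5 CCN similarity attenuation, type-I calibration of the
ANCOVA, and the σ-versus-density profile.

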