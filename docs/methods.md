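# Methods

## Pipeline overview

Per subject, a morphometric similarity network (MSN) is built from a table
of 360 cortical regions × 7 grey-matter features. Feature columns are
z-scored across regions (mean 0, sample SD 1) before correlation: the raw
features have incommensurate units (mm³, mm², mm, dimensionless indices),
and without standardization large-scale features would dominate the
region–region correlations. Edge weights are Pearson correlations of the
two regions' 7-feature vectors; the diagonal is zeroed and negative
correlations are clamped to 0, so all weights lie in [0, 1]. A region
whose feature vector is constant (undefined correlations) gets similarity
0 everywhere with a logged warning rather than failing the subject — this
keeps large simulated runs alive and is visible in the logs.

Subnetworks (SN: 62 nodes, CCN: 73 nodes) are extracted *before*
thresholding, so the density contract is exact within each analyzed
network; the alternative (whole-brain thresholding first) is available by
thresholding the full matrix and then extracting. Proportional
thresholding keeps exactly `round(d·n(n−1)/2)` strongest edges
(round-half-up; ties broken by ascending (i, j) node-index order for
bit-reproducibility), then divides by the largest retained weight so the
strongest edge is exactly 1. If fewer positive edges exist than requested,
all are kept with a warning; a density retaining zero edges is an error.

## Graph metrics

All metrics operate on weighted undirected matrices with weights in
[0, 1]:

- transitivity `T = tr((W^{1/3})³) / Σᵢ kᵢ(kᵢ−1)` with `kᵢ` the binary
  degree; 0 when no node has degree ≥ 2.
- per-node Onnela clustering `cᵢ = [(W^{1/3})³]ᵢᵢ / (kᵢ(kᵢ−1))`.
- shortest paths use edge length `1/w` — the standard convention for
  similarity weights, where stronger edges are shorter. Global efficiency
  averages `1/d_ij` over ordered pairs, with unreachable pairs
  contributing 0 (so disconnection lowers, never breaks, the metric);
  characteristic path length averages `d_ij` over reachable pairs with a
  warning when the graph is disconnected.
- small-world coefficient `σ = (C/C_rand)/(L/L_rand)`, with C the mean
  Onnela clustering and L the characteristic path length. Null networks
  are degree-preserving double-edge-swap rewirings (about 10 swaps per
  edge) of the binary topology, with the empirical weight multiset
  reassigned to the rewired edges in random order; 10 nulls by default,
  seeds derived per graph. σ requires a connected input. The published
  small-world values this mirrors specify neither the clustering variant
  nor the null model, so exact numerical agreement is not expected; the
  qualitative profile (σ ≈ 1.6–1.9 at density 0.25 falling to ≈ 1.1 at
  0.45) is reproduced by the defaults.

Vectorized implementations are tested to 1e-10 against literal loop-based
oracles (triple-loop triangle sums, Floyd–Warshall, BFS) on hundreds of
random small graphs, and against networkx where it offers an equivalent.

## Statistical model

The design is 2 (disinhibition presence) × 2 (diagnosis) × 5 (density)
with density as a within-subject factor included only to show results are
not threshold-specific. Because every subject has all five densities and
all covariates are subject-constant, the between-subject F tests of a
repeated-measures ANCOVA are exactly the F tests of an OLS model on the
per-subject mean across densities; that reduction is what `rm_ancova`
fits. Factors are effects-coded (Sum), sums of squares are Type III,
covariates are age, sex, TIV, MRI-to-NPI-Q days, CDR-SB, scanner
(treatment-coded against Siemens) and education. Partial
η² = SS_effect/(SS_effect + SS_error). Within-subject (density) effects
are reported descriptively in the metric table only; no sphericity
machinery is needed for the between-subject tests under this reduction.
The reported adjusted direction (`estimate`) is the difference of model
predictions with the factor toggled for the whole sample.

Covariate factor levels unobserved in a given cohort (e.g. a scanner make
nobody used) are dropped from the model rather than producing a singular
design. An empty design cell raises an estimability error naming the
cell.

Demographic tables use the pooled two-sample t by default, switching to
Welch (Satterthwaite df) when a two-sided variance-ratio screen rejects
equal variances at α = 0.05, and uncorrected Pearson χ² for categorical
variables. All are computable from summary statistics (means/SDs/ns or
counts), so published cohort tables can be checked without raw data.
Recomputing a reference table from 2-decimal printed summaries reproduces
the published statistics to 2 decimals except where the publication's own
input rounding moves the third digit (education t: −1.68 recomputed vs
−1.67 printed); p-values are reported at full precision and no
multiple-testing correction is applied.

## Synthetic cohort generator

The generator emulates the structure, not the values, of a two-diagnosis
dementia cohort. Covariates are drawn per diagnosis group from normal
distributions with the reference cohort's printed means/SDs (age,
education, CDR-SB, MRI-to-NPI-Q days), clipped to plausible ranges; TIV
has no published summary and uses a typical adult 1.45 ± 0.15 L; sex,
scanner mix, disinhibition prevalence (24% DAT, 83% bvFTD) and the
severity distribution among disinhibited subjects (proportional to
15/27/20) follow the printed counts. A single master seed determines
everything; per-subject streams are keyed by a hash of the subject id so
generation is independent of cohort order.

Morphometrics follow an additive latent model per region (see the module
docstring for the formula): a fixed iid archetype (SD 0.25); a fixed
archetype *gradient* — loadings on two latent feature axes whose phase
wraps 6 full cycles along each hemisphere, with left/right twins sharing
the phase — at scale 2.0; a subject-level smooth gradient (one sweep per
hemisphere, scale 0.25); subject-level latents shared by all regions of a
functional network (scale 0.5) and of a composite analysis network (SN,
CCN; scale 0.7); and iid noise (SD 0.2). Raw features are emitted on
realistic per-feature scales; the affine per-feature transform is removed
again by standardization during MSN construction.

Why this shape: any component constant across all 360 regions is removed
by cross-region feature standardization, so similarity must be carried by
region-varying structure. A plain block-latent model (network latent +
noise) makes proportional thresholding retain only within-block edges —
splitting each two-block subnetwork into components and stranding
weak-archetype nodes, which contradicts the connectivity at density 0.25
that motivates the 0.25 floor. The wrapped archetype gradient provides a
heterogeneous, subject-stable banded backbone (mirroring the spatial
autocorrelation, homotopic similarity and cross-subject reproducibility
of real MSN edges) that keeps thresholded subnetworks connected, while
the network/composite latents add the long-range within-network
similarity that group effects modulate.

Effects are declared as (network, subgroup, attenuation) rules; an
attenuation a ∈ [0, 1] multiplies the network and composite latents by
(1 − a) for matching subjects (subgroups: disinhibition presence or a
diagnosis), lowering expected within-network similarity, thresholded-graph
efficiency and clustering monotonically in a. The defaults were fixed once
so that the simulated study reproduces the qualitative regime of the real
one — ≈96% of subject-network graphs connected at density 0.25 (all by
0.45), σ falling from ≈1.6–1.9 to ≈1.1–1.2 across the density range, and
a 0.5 CCN attenuation detectable at n = 100 — and are not otherwise
calibrated to any data.

What the generator does *not* emulate: atrophy gradients tied to
diagnosis, site/scanner effects on features, missing data,
age-by-network interactions, spatially contiguous parcel geometry, or any
image-level process. Passing tests therefore demonstrate that the
pipeline recovers network-localized similarity changes of known size and
placement under clean conditions — not that real effects of that size
would be detected in real, messier data.

## Validation study sizes

The packaged studies run at sizes chosen as the smallest that give stable
rates: parameter recovery uses 20 seeds × (50 + 50) subjects with
disinhibition prevalence 0.5 in both groups (balanced cells); type-I
calibration uses 500 replicates of 100-subject cohorts from the null
generator with metric responses drawn independently of all predictors
(equivalent in law, for the between-subject tests, to running the full
imaging pipeline at zero attenuation, and orders of magnitude cheaper);
the small-world profile uses 5 subjects × 5 nulls per graph. The
acceptance script finishes in about 2 minutes on one CPU.

## Known limitations

- The generator's 7-dimensional feature space makes single-pair
  correlations extremely noisy (n = 7 points per correlation); stable
  structure exists only in aggregate, as in real MSNs.
- The between-subject reduction deliberately forgoes density-by-group
  interaction tests; densities enter descriptively.
- The small-world null model is one of several in use; σ values are
  comparable only within a fixed recipe.
- The synthetic atlas assigns functional networks in contiguous blocks;
  real assignment tables (same three-column schema) can be supplied but
  their scattered memberships may lower subnetwork connectivity at the
  sparsest density.
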