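# Methods

`aifdetect` implements automatic detection of the arterial input function
(AIF) in dynamic susceptibility contrast MRI (DSC-MRI) by reproducible
clustering of voxel time–concentration curves, together with a digital
phantom that provides ground truth for validating the detection chain.
This note records the models, the conventions, the parameter choices, and
the limitations — in particular which properties of real perfusion data the
phantom does and does not emulate.

## Pipeline overview

1. **Input**: a 4D DSC-MRI volume (one operator-chosen slice is analyzed)
   or a matrix of per-voxel signal curves.
2. **Conversion** of signal to contrast-agent concentration through the
   T2\* susceptibility model.
3. **Exclusion cascade**: three filters (area, roughness, partial-volume
   ratio) thin the pool to plausible arterial candidates.
4. **Clustering** of the surviving concentration curves into k = 5 groups
   with one of three deterministic backends (normalized cut, agglomerative
   hierarchy, affinity propagation), all on Euclidean distance.
5. **Selection**: the cluster whose mean curve maximizes
   M = PV / (TTP × FWHM) is declared arterial; the AIF is that mean curve.
6. **Evaluation** (simulation only): RMSE against the known true AIF and
   the PVE level (percent non-arterial members of the selected cluster).

Every stage is deterministic: repeated runs on identical input produce
bit-identical output, and reordering the input curves changes cluster
labels only up to renaming. This is the property that motivates the choice
of these three backends over k-means or fuzzy c-means, whose random
initialization makes AIF detection irreproducible between runs.

## The digital phantom

### Sampling grid

Frame *i* (1-based, *i* = 1…60) is sampled at *t* = *i*·TR with
TR = 1.5 s and TE = 0.03 s, so the grid spans 1.5–90 s — the only
convention under which 60 frames cover a 90-s scan. The bolus arrives at
t₀ = 26 s, leaving 17 pre-contrast baseline frames.

### Arterial input

The first bolus passage is a gamma-variate

    AIF(t) = scale · (t − t₀)^α · exp(−(t − t₀)/β),   t > t₀  (else 0)

with α = 3.0 (vascular architecture), β = 1.5 s (flow), scale = 1.
Recirculation is the same curve delayed by τ_d = 8 s and convolved with an
exponential kernel of time constant τ_r = 30 s. The kernel is normalized
to unit discrete area, so the recirculation carries `amplitude` (default 1)
times the first-passage area; both the amplitude and the normalization are
configurable because no single convention is standard and the effective
recirculation gain in the literature varies. The delayed curve is obtained
by linear interpolation of the samples; when the bolus-arrival time is
known (as in the phantom) interpolation leakage below arrival is zeroed so
the recirculation contributes exactly nothing for t ≤ t₀ + τ_d.

Sixteen "false arterial" voxels — delayed, dispersed near-copies of the
AIF such as venous or distal arterial signals — enumerate the Cartesian
grid t₀ ∈ {27, 28, 29, 30} s × τ_d ∈ {9, 10, 11, 12} s.

### Tissue curves

Indicator-dilution theory gives the tissue concentration as

    C_t(t) = c · CBF · (AIF ⊗ R)(t),   R(t) = exp(−t / MTT)

discretized with the grid spacing as integration step. Tissue states:
normal grey matter CBV = 4 ml/100 g, MTT = 4 ± 0.33 s; pathological grey
matter CBV = 3.3, MTT = 10 ± 0.7 s; white matter CBV = 2, MTT = 5.45 ±
0.33 s. The "±" values are treated as per-voxel i.i.d. Gaussian standard
deviations; CBF = CBV/MTT by the central volume principle.

The constant *c* (`tissue_scale`, default 0.1) converts the product of
CBF in ml/100 g/s and blood concentration into measured tissue
concentration units. It is deliberately not the literal per-100-g reading
(c = 1), which would make grey-matter peaks three times *higher* than the
arterial peak — contradicting both perfusion physiology and the premise
that arterial curves are the tallest — nor the strict per-gram physical
value (c ≈ 0.01), under which the arterial signal would saturate to zero
at the echo time and 40 %-GM calibration used here, destroying the
arterial curve shape on conversion. c = 0.1 places the phantom in the
regime clinical DSC data occupy: grey-matter concentration peaks near one
third of the arterial peak and the arterial signal dips by ~80 % without
saturating.

### Partial-volume voxels

400 voxels are linear mixtures w·arterial + (1−w)·tissue **in signal
units** (magnitude mixing is the physical PVE mechanism), with w uniform
on (0, 1) and the tissue class drawn uniformly per voxel.

### Signal model and noise

Signals follow S(t) = S₀·exp(−κ_vox·TE·C_t(t)) with S₀ = 100. κ_vox is
calibrated so the *nominal* grey-matter curve (MTT at its mean) dips
exactly 40 % below baseline — the typical clinical contrast. Zero-mean
Gaussian noise with σ = S₀/SNR = 5 (SNR 20) is added in signal units to a
random subset of 400 curves, mirroring a protocol in which 400 randomly
extracted curves of the slice carry measurement noise; `noise_subset=None`
corrupts every curve instead. Noise can push signals non-positive; values
are clipped at a small configurable floor (default 0.01) before the
logarithmic conversion.

What the phantom does **not** emulate: spatial structure (voxels are
labeled but not arranged), Rician noise statistics, B0/EPI distortion,
motion, T1 leakage, and contrast extravasation. Passing tests therefore
demonstrate correctness of the detection machinery under idealized
conditions, not clinical robustness.

## Signal ↔ concentration conversion

Concentration is recovered as C_t = −ln(S/S_b)/(TE·κ_vox), with S_b the
mean signal over the pre-contrast window (all frames with t < 26 s for the
phantom; for clinical data the window ends at an automatically detected
bolus arrival — the first frame where the cohort-mean signal falls 2 SD
below its running baseline — unless overridden). On clinical data κ_vox is
unknown; because the conversion is linear in 1/(TE·κ_vox) and clustering,
M-selection and the filter ratios are invariant to a global concentration
scale, the default κ_vox·TE = 1 simply reports concentrations in arbitrary
units.

## Exclusion cascade

1. **Area filter**: the fraction P_AUC = 0.90 of curves with the smallest
   trapezoidal areas is excluded (tissue curves have small areas).
2. **Roughness filter**: of the survivors, the fraction P_rough = 0.25
   with the largest Λ(C) = ∫ C″(t)² dt is excluded (central second
   differences scaled by 1/TR², squared, trapezoid rule over interior
   samples). This targets curves corrupted by pulsation, voxel shift and
   other fluctuation artifacts.
3. **Partial-volume ratio filter**: each survivor's first passage is fit
   to a gamma-variate by bounded nonlinear least squares; the steady-state
   integral SS (10 time points starting at the first post-peak sample
   below 30 % of the maximum; an off-by-one alternative window is a config
   switch) is compared with the analytic first-passage area
   AUC¹ˢᵗ = scale·Γ(α+1)·β^(α+1). Curves whose SS/AUC¹ˢᵗ ratio falls
   outside the pool mean ± 20 % are discarded.

Exclusion counts use ⌊fraction × pool size⌋; ties break by ascending curve
index. Fit initialization: t₀ from the 10 %-of-peak crossing, α and β from
a log-linearization of the rising limb, amplitude from the peak; bounds
t₀ ∈ [0, t_peak), α ∈ [0.05, 50], β ∈ [10⁻³, 10³]. A fit that converges
but leaves a relative residual above 0.5 over its window is rejected as a
failure — without this, a single degenerate fit can drag the ratio-pool
mean far enough that the ±20 % band excludes nearly every curve. Curves
with failed fits or steady-state windows that overrun the grid are dropped
with a logged reason and do not enter the ratio pool.

## Clustering backends

All three operate on the raw concentration curves with Euclidean distance
and return exactly k clusters (default 5), canonically labeled by
ascending smallest member index.

* **hier** — scipy's agglomerative clustering, average linkage (the common
  deterministic choice for curve clustering; the linkage is configurable),
  tree cut at k.
* **ncut** — Gaussian similarity w_ij = exp(−d_ij²/σ²) with σ the 20th
  percentile of pairwise distances (configurable); recursive two-way
  normalized cuts. Each bipartition takes the second-smallest eigenvector
  of the symmetric normalized Laplacian (eigenvector sign fixed so its
  first nonzero component is positive), sweeps every threshold between
  distinct eigenvector values with incremental O(n²) cut/association
  updates, and keeps the minimum-Ncut split; at each step the cluster
  whose best split is cheapest is divided. No k-means post-processing, so
  the partition is fully deterministic.
* **fastap** — affinity propagation with similarity −‖x_i − x_j‖², written
  as deterministic vectorized message passing (no tie-breaking noise; a
  library implementation that injects random jitter would violate the
  reproducibility contract). The shared preference is bisected until
  exactly k exemplars emerge; if the cluster count jumps past k at the
  configured damping (default 0.9), a fixed damping ladder (0.95, 0.85,
  0.8, 0.92, 0.88, 0.75) is tried before reporting the achievable range.
  Exact duplicate curves make the messages oscillate on ties, so the
  search runs on unique rows and duplicates inherit their representative's
  assignment.

## Shape metrics and selection

PV and TTP are the sampled maximum and its grid time (ties: earliest
sample; no interpolation). FWHM is the distance between the two
half-maximum crossings found by linear interpolation between bracketing
samples; a missing crossing on either side marks the curve as censored and
disqualifies it from selection. AUC is the trapezoidal integral;
M = PV/(TTP·FWHM) exactly. Exact M ties select the lowest cluster id.
On the 1.5-s grid the sampled PV underestimates the continuous peak by up
to ~2 % depending on how the sampling phase falls relative to the peak;
FWHM values quoted for the analytic reference AIF are computed on a finely
resolved evaluation of the same curve, where linear interpolation
converges to the continuous half-width.

RMSE between an estimated and a reference AIF is the root mean squared
per-sample difference over all 60 samples of the 90-s window. The PVE
level is 100 × (non-arterial members)/(cluster size) of the selected
cluster, computable only where ground truth exists.

## The canonical simulation benchmark

`aifdetect.benchmark.detect_on_phantom` runs conversion (with the
phantom's calibrated κ_vox and the known t₀ = 26 s baseline), the full
exclusion cascade, clustering with each backend at k = 5, M-selection, and
scoring. `ordering_study` repeats this across noise seeds and reports
per-method median RMSE and PVE level. The cascade is applied to simulated
data as well as clinical data: without it, noise-spike curves — whose
narrow interpolated FWHM gives them the largest M — are isolated as
singleton clusters by every backend and detection degenerates.

`scripts/acceptance.py` runs this benchmark over 10 seeds at the full
1902-curve composition (about half a minute on one CPU).

## Known limitations

* The false-arterial voxels are, by construction, near-copies of the true
  AIF shifted by only 1–4 s. The M measure penalizes a TTP delay linearly
  (~5 % per 1.5 s), so a clean cluster of false-arterial curves scores
  within ~1 % of a pure true-arterial cluster, while any true-arterial
  cluster is diluted by high-w partial-volume members whose admixture
  lowers its mean's M below that margin. Consequently the selected cluster
  in this phantom is typically a group of false-arterial voxels: its curve
  is close to the true AIF in shape (the benchmark's median RMSE ≈ 0.3 for
  ncut/hier, roughly 7 % of the arterial peak), but it contains no true
  arterial members, so the PVE level saturates at 100 % for all backends
  and does not discriminate between them. The RMSE ranking (ncut ≤ hier <
  fastap) is the discriminating output of the benchmark.
* The roughness filter ranks curves by integrated squared second
  derivative. In this phantom the noiseless arterial curves are also the
  *sharpest* curves, so once fewer than P_rough of the pool are
  noise-corrupted, the filter begins excluding arterial voxels — a
  phantom-specific artifact; on clinical data roughness is dominated by
  artifact fluctuation, which is the filter's target.
* The affinity-propagation preference search guarantees exactly k
  exemplars when some preference achieves it; for adversarial geometries
  the count can skip k at every damping tried, which raises an error
  naming the achievable range rather than silently returning a different k.
* Clinical (in vivo) validation, motion correction, and perfusion-map
  deconvolution are out of scope; inputs are assumed motion-corrected.
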