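# aifdetect

Automatic detection of the **arterial input function (AIF)** in dynamic
susceptibility contrast MRI (DSC-MRI), by reproducible clustering of voxel
time–concentration curves.

Quantifying cerebral perfusion (CBF, CBV, MTT) from a DSC-MRI bolus scan
requires the AIF — the contrast-agent concentration over time in an artery
feeding the tissue. Drawing it manually on the middle cerebral artery is
slow and operator-dependent, and popular automatic methods built on
k-means or fuzzy c-means give different answers on every run. This package
implements the fully deterministic alternative: filter the voxel curves,
cluster them with a reproducible algorithm — **normalized cut (ncut)**,
**agglomerative hierarchy (hier)**, or **affinity propagation (fastap)** —
and select the arterial cluster by the shape score

```
M = PV / (TTP × FWHM)
```

where PV is the peak concentration, TTP the time to peak, and FWHM the
full width at half maximum: arterial curves are tall, early and narrow.
It is intended for perfusion-MRI researchers comparing AIF-detection
strategies and as a tested reference implementation of the
phantom-validated detection chain.

The package contains:

* `aifdetect.phantom` — a digital DSC-MRI phantom with known ground truth:
  a gamma-variate bolus `AIF(t) ∝ (t−t₀)^α e^{−(t−t₀)/β}` plus delayed,
  dispersed recirculation; false-arterial (delayed-bolus) voxels; three
  tissue classes via the indicator-dilution convolution
  `C_t = CBF · AIF ⊗ e^{−t/MTT}`; random partial-volume mixtures; Gaussian
  signal noise at SNR 20.
* `aifdetect.signal_model` — T2\* conversion `S = S₀ e^{−κ·TE·C_t}` and its
  inverse with an averaged pre-contrast baseline, plus calibration of κ to
  a 40 % grey-matter peak drop.
* `aifdetect.preprocess` — the three-stage exclusion cascade (area
  percentile, curve roughness `∫C″(t)²dt`, steady-state/first-passage
  partial-volume ratio with a gamma-variate fit).
* `aifdetect.clustering` — the three deterministic backends, each yielding
  exactly k clusters (default 5) on Euclidean distance.
* `aifdetect.selection_eval` — shape metrics, M-measure selection, RMSE
  and PVE-level evaluation.
* `aifdetect.cli_io` — the `aifdetect` command-line tool and NIfTI/CSV/
  JSON/YAML I/O with full run manifests.

See `docs/methods.md` for the models, conventions and limitations.

## Worked example

Simulate the default phantom (1902 voxel curves: 6 true arterial, 16
false arterial, 440 + 440 + 600 tissue, 400 partial-volume), then score
all three clustering methods against the known true AIF:

```bash
$ aifdetect simulate --out sim --seed 3
wrote 1902 curves ({'arterial': 6, 'false_arterial': 16, 'gm': 440,
'gm_path': 440, 'wm': 600, 'pve': 400}) to sim_curves.csv

$ aifdetect evaluate --curves sim_curves.csv --reference sim_true_aif.csv \
      --out sim --methods ncut,hier,fastap
method  pve_level       pv  ttp     fwhm       auc     rmse        m  cluster_size   time_s
  ncut      100.0 4.536847 31.5 6.193194 55.855863 0.297261 0.023256             3 0.006855
  hier      100.0 4.536847 31.5 6.193194 55.855863 0.297261 0.023256             3 0.004590
fastap      100.0 4.459249 33.0 6.295056 55.469601 0.565995 0.021466             3 0.230817
```

Reading the table: each row is one clustering backend. `pv/ttp/fwhm/auc/m`
describe the detected AIF's shape — compare with the true AIF's sampled
peak 4.459 at 30.0 s with half-width ≈ 6.2 s. `rmse` is the per-sample
error against the true AIF (here ≈ 0.30 for ncut/hier, about 7 % of the
arterial peak, versus 0.57 for fastap — the ncut ≤ hier < fastap error
ranking is the expected outcome). `pve_level` is the percentage of
selected-cluster members that are not true arterial voxels; in this
phantom the winning cluster consists of delayed-bolus (false-arterial)
voxels whose curves are near-copies of the AIF, so the contamination level
reads 100 % for every method (see the limitations section of
`docs/methods.md`). `cluster_size` and `time_s` report the selected
cluster's membership and the wall-clock per method.

Detection on your own data (one slice of a 4D NIfTI volume, first two
non-steady-state frames discarded, exclusion cascade on):

```bash
aifdetect detect --input perfusion.nii.gz --slice 9 --method ncut --out case01
```

which writes the AIF curve, cluster labels, a filter report and a manifest
recording the exact configuration and seed.

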