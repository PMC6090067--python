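# swa-brainage

Brain-age analysis of mouse sleep EEG slow-wave activity (SWA).

NREM-sleep SWA — EEG power in the delta band (0.75–4.0 Hz), here averaged
per hour over the 12-h baseline light period into a 12-dimensional profile
per mouse — rises with age and falls with long-term voluntary exercise.
This package implements the full analysis that turns that observation into
a quantitative "brain age" readout for six groups (ages 6/18/24 months ×
running-wheel vs sedentary control):

* **Supervised stage** — per-group multivariate-normal *templates*
  N(μ_c, Σ_c) fitted after PCA reduction, scored by the **perceived
  information** PI(S;C) = H(C) − H(C|S) (the class-entropy reduction under
  the model posterior, evaluated by leave-one-out with a percentile
  bootstrap CI) and by the **success rate** of maximum-likelihood
  classification under a stratified 50-50 profile/test split.
* **Unsupervised stage** — k-means clustering of PCA-reduced profiles with
  **Gap-statistic** selection of the cluster count, pairwise Euclidean
  distances between group centroids, and a 1-D **brain age**: each group's
  centroid distance from the young-exercising reference, with the percent
  attenuation achieved by exercise at each age.
* **Synthetic cohorts** — a generator with the published group structure
  (sizes 11/8/9 controls, 9/9/8 running-wheel; control-minus-RW offsets
  47 / 24.8 / 60.44 μV²/0.5 Hz) so every stage is testable without any
  data download, plus an epoch-level simulator (4-s epochs, 0.5–25 Hz
  spectra, hypnogram, artifacts) feeding the spectral-reduction stage.

See `docs/methods.md` for the model, defaults and numerical choices.

## Worked example

```python
import swa_brainage as sb

# six-group cohort at the published sizes, strongly separated regime
profiles = sb.simulate_profiles(sb.well_separated_spec(seed=1))

pi = sb.perceived_information(profiles, d=3, priors="uniform", seed=1)
print(f"PI = {pi.pi:.3f} bits of H(C) = {pi.class_entropy:.3f}")
# PI = 2.585 bits of H(C) = 2.585

report = sb.success_rate(profiles, d=3, seed=1)
print(f"success rate = {100 * report.success_rate:.0f}%")
# success rate = 100%

matrix = sb.centroid_distances(sb.REFERENCE_CENTROIDS)  # published coordinates
ba = sb.brain_age(matrix, "6RW")
print({k: round(v, 2) for k, v in ba.distances.items()})
# {'6C': 221.59, '6RW': 0.0, '18C': 384.61, '18RW': 267.2, '24C': 430.14, '24RW': 344.37}
print(ba.attenuation_pct)
# {18: 31, 24: 20}
```

PI = 2.585 bits equals log₂6 — the profiles carry the full 6-way class
information — and every held-out mouse is classified correctly. On the
published centroid coordinates, the young controls sit closest to the
young-exercising reference and the 24-month controls farthest; a running
wheel shrinks the 24-month group's brain-age distance by 20%.

The same analysis is available from the shell:

```
swa-brainage simulate --scale 0.0015 --seed 1 --out swa.csv
swa-brainage profile  --in swa.csv --dims 3 --priors uniform --seed 1 --out pi.json
swa-brainage classify --in swa.csv --seed 1 --out report.json
swa-brainage cluster  --in swa.csv --dims 3 --kmax 6 --restarts 1000 -B 100 \
                      --seed 1 --out clusters.json --centroids-out centroids.csv
swa-brainage brainage --centroids centroids.csv --reference 6RW --out brainage.json
swa-brainage run-all  --outdir run --seed 1        # all of the above in one go
```

`run-all` on the default separated cohort reports `k_star = 6` (the Gap
statistic recovers exactly the six experimental groups),
`success_rate_pct = 100.0` and `pi_bits = 2.585`, and writes every stage's
output plus a manifest with per-file digests; a rerun with the same config
and seed regenerates all outputs byte-identically.

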