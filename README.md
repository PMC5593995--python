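# mipscsf

Analysis pipeline linking **cerebrospinal-fluid (CSF) volume loss** to
**magnetic-induction phase-shift (MIPS)** signal change during
intracerebral hematoma expansion.

MIPS is a non-contact monitoring technique: a phase difference between an
excitation coil and a sensor coil across the head, sensitive to the
conductivity distribution of the tissue between them. Because CSF is by
far the most conductive intracranial compartment, the phase signal tracks
CSF displacement while the Monro–Kellie compensation mechanism buffers an
expanding hematoma — which is why the phase falls *before* intracranial
pressure rises, and reverses when compensation fails. This package
provides the computational side of that investigation, for researchers
working on bioimpedance brain monitoring or MR-based CSF volumetry:

* conditioning of raw phase recordings (block averaging, baseline
  normalization) and **reversal-point detection** on the injected-blood
  axis;
* **CSF segmentation** from T2-like MR volumes by fuzzy c-means with
  Markov-random-field spatial regularization, template masking, and
  voxel-counting volumetry;
* synchronization of the two modalities by injected blood volume and the
  **correlation battery**: multiple regression with ANOVA, first-order
  partial correlations, derivative-curve correlation;
* **synthetic generators** — compensation trajectories, dense phase
  recordings, MR phantoms with exact ground truth — so the whole chain is
  testable without any acquisition.

The measured 8-animal cohort tables (normalized phase and CSF volume at
nine blood volumes) are packaged as fixtures.

## The model in brief

CSF volume is piecewise linear in injected blood `b` with one breakpoint
`b*` (compensation failure): `csf(b) = V0 + s_pre·min(b, b*) +
s_post·max(0, b − b*)`, slopes ≤ 0. The phase responds linearly to
compartment volumes, `phase = φ0 + a_csf·Δcsf + a_blood·(b − b_on)_+ +`
periodic terms + noise. The segmenter minimizes

```
J(U,V) = Σ_i Σ_k u_ik^m (x_i − v_k)² + β σ̄² Σ_i Σ_k u_ik^m · mean_{j∈N(i)}(1 − u_jk)
```

and the statistics are OLS with the classical ANOVA summary, the
first-order partial-correlation recursion r_xy·z = (r_xy − r_xz r_yz) /
√((1−r_xz²)(1−r_yz²)) with t tests on n−3 df, and Pearson correlation of
fitted derivative curves. See `docs/methods.md` for assumptions,
defaults and limitations.

## Worked example

Run the correlation battery on the packaged cohort tables:

```bash
$ mipscsf reproduce-tables
statistic                     computed   published
multiple_R                     0.82429       0.824
R_squared                      0.67946        0.68
adj_R_squared                  0.57261       0.573
se_estimate                    0.33900     0.33882
F                              6.35906       6.369
regression_p                   0.03294       0.033
partial_r_mips_csf             0.79151       0.792
partial_r_mips_blood           0.74774       0.748
derivative_correlation_R       0.45837       0.751
```

Reading the output: the mean phase trajectory is strongly explained by
mean CSF volume and injected blood together (multiple R ≈ 0.824,
significant at p ≈ 0.033), and the partial correlation of phase with CSF
controlling blood (0.792) exceeds that with blood controlling CSF
(0.748) — the phase signal is more tightly coupled to CSF than to the
injected blood itself. The derivative-curve correlation at the default
degree-4 fit computes to 0.458; the published 0.751 is not recoverable
from the four-decimal printed tables under any stated convention (the
"high-class" fit degree behind it is unspecified), so the computed value
is reported without forcing agreement.

The same battery runs on your own cohort TSVs
(`mipscsf analyze --mips t1.tsv --csf t2.tsv --out report.json`), and the
other subcommands cover the rest of the chain:

```bash
mipscsf simulate --seed 7 --out cohort/          # synthetic cohort
mipscsf smooth --in raw.csv --out series.tsv     # 2700 samples -> 9 blocks
mipscsf reversal --in series.tsv --out rev.json  # reversal point + section
mipscsf segment --in vol.nii.gz --template tpl.nii.gz --out seg/
mipscsf quantify --mask seg/csf_mask.nii.gz --out q.json
```

On the packaged tables the detected reversal sits at 1.66 ml injected
blood — the phase falls while CSF compensates, then turns as
compensation approaches failure.

## Layout

| module | contents |
| --- | --- |
| `mipscsf.schedule` | constant-rate injection protocol, blood-volume clock |
| `mipscsf.synthetic` | compensation/phase simulators, MR phantoms, cohorts |
| `mipscsf.processing` | block smoothing, normalization, fits, reversal detection |
| `mipscsf.segmentation` | preprocessing, FCM+MRF, template masking, volumetry |
| `mipscsf.stats` | synchronization, regression/partial/derivative correlations |
| `mipscsf.fixtures`, `mipscsf.io`, `mipscsf.config`, `mipscsf.cli` | packaged tables, file formats, configuration, command line |
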