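# nirsmap

Online brain-activation mapping for functional near-infrared spectroscopy
(fNIRS). `nirsmap` estimates, **while a recording is still in progress**,
which measurement channels show a task-evoked hemodynamic response: a Kalman
filter updates the coefficients of a general linear model (GLM) at every
sample, a running one-tailed *t*-test with a Bonferroni-type correction turns
the task coefficient into a per-channel activation call, and an AR(1)
prewhitening step keeps physiological serial correlation from inflating the
statistics. It is aimed at researchers prototyping real-time NIRS analyses,
neurofeedback/BCI pipelines, or anyone who wants an auditable reference
implementation of recursive GLM estimation for optical neuroimaging.

## The model

Raw dual-wavelength light intensities are converted to oxy-/deoxy-hemoglobin
concentration changes with the modified Beer–Lambert law: with
ΔOD<sub>λ</sub>(k) = −log₁₀ I<sub>λ</sub>(k)/I<sub>λ</sub>(ref),

ΔOD<sub>λ</sub> = (α<sub>HbO</sub>(λ)·ΔC<sub>HbO</sub> +
α<sub>HbR</sub>(λ)·ΔC<sub>HbR</sub>) · L · DPF<sub>λ</sub>,

a 2×2 linear system per channel and time step. The ΔHbO series of channel
*i* is then modelled as

y<sup>i</sup>(k) = H(k) β<sup>i</sup>(k) + ε<sup>i</sup>(k),

where the rows of H hold L = 5 regressors: a stimulus boxcar convolved with a
double-gamma hemodynamic response, a constant baseline, and three
discrete-cosine (DCT) high-pass columns absorbing very-low-frequency drift.
Serial correlation is removed by AR(1) differencing, y*(k) = y(k) − ρ y(k−1)
(and likewise for H), with ρ estimated online from the running lag-1
autocorrelation of the residuals. The coefficient vector follows a random
walk, X(k) = X(k−1) + w(k), w ~ N(0, qI), observed through y*(k) = H*(k)X(k)
+ v(k), v ~ N(0, r) — a standard Kalman predict/update pair per sample and
channel, run for all channels in parallel. At each step the task coefficient
is tested with

t<sup>i</sup>(k) = cᵀβ̂<sup>i</sup>(k) / √( σ̂²ᵢ(k) ·
cᵀ[Σ₁ᵏ HᵀH]⁻¹c ),  σ̂²ᵢ(k) = RSS(k)/(k−L),

against a *t* distribution with k−L degrees of freedom, and the per-test
threshold is corrected for the growing number of tests with
p_b = (1 − (1 − p_in)^j)/j.

## Worked example

```python
import nirsmap as nm

# a realistic synthetic 552 s finger-tapping session: 24 channels at 1.81 Hz,
# a 1 uM response on channel 6, cardiac/respiratory/Mayer oscillations,
# slow drift, and measurement noise
out = nm.simulate(nm.SimSpec.realistic(seed=7))

model = nm.OnlineGLM.from_hemo(out.hemo, nm.FINGER_TAPPING_PROTOCOL)
res = model.fit(snapshot_times_s=nm.DEMO_SNAPSHOT_SCHEDULE)
print(res.summary())
```

The summary table lists, per channel, the final task-coefficient estimate,
its running *t*-value, the uncorrected one-tailed *p*, the corrected
activation call, and the detection time. A representative run prints (head
of the table):

```
 channel  beta_task        t     p_unc  active  t_detect_s
     ch1      0.180     2.05  2.04e-02   False           -
     ...
     ch6      0.906    13.71  1.29e-39    True        79.0
```

Channel 6 — the truly active channel — is the only one that crosses the
corrected threshold; its estimated response (0.906 μM) is within 10% of the
simulated 1.0 μM amplitude, and it is flagged 79 s into the run, long before
the experiment ends. `res.detection_table()`, `res.snapshots` and
`res.to_csv(outdir)` expose the same information programmatically.

A command-line interface wraps the same pipeline:

```sh
nirsmap example-config -o cfg.yaml
nirsmap simulate -c cfg.yaml -o sim/ --seed 3
nirsmap run -c cfg.yaml -i sim/hbo.csv -o out/
nirsmap verify -c cfg.yaml -i sim/hbo.csv   # online-vs-batch-OLS report
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
regenerates the full demonstration from scratch: it simulates a realistic
24-channel session through the forward optical model, inverts it back to
hemoglobin space, replays it through the online estimator with prewhitening
and the corrected running *t*-test, prints the resulting summary and
detection calls, and cross-checks the recursive estimator against a per-step
batch least-squares oracle before writing its JSON output.
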