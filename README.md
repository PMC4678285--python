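# pbmtox

Pelvic bone-marrow dosimetry and early haematologic-toxicity analysis for
pelvic radiotherapy cohorts, comparing conformal (CRT) and
intensity-modulated (IMRT) delivery.

Radical chemoradiation for anal cancer irradiates a large share of the
body's proliferating bone marrow. IMRT trades high-dose conformity for a
"low-dose bath" that can raise pelvic bone-marrow (PBM) exposure and with it
the risk of severe acute cytopenias (haematologic toxicity of CTCAE grade
3+, "HT3+"). `pbmtox` packages the full analysis chain used to study that
trade-off:

- **DVH metrics** (`pbmtox.dvh`) — differential/cumulative dose-volume
  histograms on a 0.1 Gy grid, V5–V25 (% volume receiving ≥ 5–25 Gy) for
  whole-pelvis, iliac, lumbosacral and lower-pelvis marrow, CSV I/O.
- **LKB NTCP engine** (`pbmtox.lkb`) — the Lyman–Kutcher–Burman model:
  per-bin fractionation correction
  `LQED2_i = D_i (1 + (D_i/e)/(α/β)) / (1 + 2/(α/β))` with α/β = 10 Gy,
  effective dose `Deff = (Σ v_i LQED2_i^{1/n})^n` (summed over phases for
  two-phase conformal plans), and `NTCP = Φ((Deff − TD50)/(m·TD50))` with
  n = 1 (parallel organ), m = 0.09, TD50 = 30 Gy for HT3+. Maximum-likelihood
  refitting of (m, TD50) from binary outcomes is a scikit-learn-style
  estimator, `LKBProbitModel`, with profile-likelihood 95% CIs.
- **Haematology** (`pbmtox.hematology`) — weekly HgB/WCC/ANC/platelet
  series, count ratios vs baseline, nadirs, CTCAE v4.0 cytopenia grading
  and the HT3+ endpoint.
- **Statistics** (`pbmtox.stats`) — two-sided Mann–Whitney U (exact for
  small tie-free samples), Welch t, OLS and logistic regression, Holm and
  Benjamini–Hochberg correction applied within test families.
- **Synthetic cohorts** (`pbmtox.simulate`) — a calibrated generator
  (default 25 CRT + 21 IMRT patients) reproducing the published group
  dose-metric distributions, blood-count dynamics with a week-2/3 nadir, and
  HT3+ outcomes drawn from the LKB model, so every stage is testable with no
  clinical data.
- **Pipeline & CLI** (`pbmtox.pipeline`, `pbmtox` command) — end-to-end
  orchestration emitting the standard report tables.

## Worked example

```python
import numpy as np
from pbmtox import LKBParams, PlanPhase, deff_plan, dose_metrics, ntcp, ntcp_interval
from pbmtox.simulate import CohortGenerator

gen = CohortGenerator()                       # default published calibration
rng = np.random.default_rng(11)
dvh = gen.generate_dvh("IMRT", "whole_pelvis", rng)

m = dose_metrics(dvh)
print(f"V5={m.v5:.1f}% V10={m.v10:.1f}% V15={m.v15:.1f}% "
      f"V20={m.v20:.1f}% V25={m.v25:.1f}% volume={m.volume_ccm:.0f} cm^3")

params = LKBParams(n=1.0, m=0.09, td50=30.0, alpha_beta=10.0,
                   m_ci=(0.3, 0.4), td50_ci=(28.0, 32.0))
plan = [PlanPhase({"whole_pelvis": dvh}, 28)]  # single-phase IMRT, 28 fractions
d = deff_plan(plan, "whole_pelvis", params)
lo, hi = ntcp_interval(d, params)
print(f"Deff={d:.2f} Gy  NTCP={ntcp(d, params).ntcp:.3f}  "
      f"(CI-endpoint range {lo:.3f}-{hi:.3f})")
```

prints

```
V5=93.1% V10=85.9% V15=77.5% V20=73.1% V25=62.5% volume=974 cm^3
Deff=28.56 Gy  NTCP=0.297  (CI-endpoint range 0.297-0.527)
```

i.e. this synthetic IMRT patient has 85.9% of pelvic marrow receiving at
least 10 Gy; collapsing the fractionation-corrected DVH at n = 1 gives an
effective uniform dose of 28.6 Gy, just below TD50, for a modelled 29.7%
probability of grade-3+ haematologic toxicity (the range spans the model
evaluated at the published parameter CI endpoints; see `docs/methods.md` on
the slope CI as printed).

The same analysis end to end from the shell:

```bash
pbmtox run --seed 7 -o out/          # simulate a cohort, analyse, emit tables
pbmtox simulate --seed 7 -o cohort/  # just the cohort CSVs
pbmtox metrics --dvh cohort/dvh.csv -o metrics.tsv
pbmtox analyze --dvh cohort/dvh.csv --bloods cohort/bloods.csv \
               --covariates cohort/covariates.csv -o results/
```

`run` writes `dose_metrics.tsv` (group means/SDs and Mann–Whitney p per
structure × level), `blood_nadirs.tsv`, `weekly_ratios.tsv`,
`regressions.tsv` (univariate/multivariate linear and logistic panels with
Holm and BH decisions), `ntcp_panel.tsv` / `ntcp_summary.tsv`, plus a
`manifest.json` that makes the run byte-for-byte reproducible from its seed.

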