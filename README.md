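# taucog

Tau-PET signal in cognitive-domain-specific brain regions as a predictor of
domain-specific cognitive decline in the Alzheimer's disease spectrum — and
as the basis of *personalized* cognitive composite endpoints for clinical
trials.

## What this package does

Flortaucipir tau-PET patterns mirror the heterogeneity of cognitive symptoms
in AD. `taucog` implements an analysis pipeline that exploits this:

1. **Domain-specific tau-PET ROIs.** Binary meta-analytic task-fMRI
   activation maps for episodic memory (MEM), language (LAN), executive
   functioning (EF) and visuospatial abilities (VS) are masked with cortical
   gray matter, excluding tracer off-target regions (hippocampus, subcortex,
   cerebellum). Conventional comparators: a global neocortical ROI and a
   temporal-lobe ROI (Braak-stage 1/3/4 regions).
2. **Tau-positivity probabilities (TPP).** Per voxel, the across-subject
   SUVR sample is fitted with a two-component Gaussian mixture
   (tau-negative vs tau-positive subpopulations); a subject's TPP at a voxel
   is the posterior probability of the higher-mean component,
   `TPP(x) = w2 φ(x; μ2, σ2) / (w1 φ(x; μ1, σ1) + w2 φ(x; μ2, σ2))`.
   ROI signal is the mean TPP (or mean SUVR) over the ROI's voxels.
3. **Annual cognitive change rates.** Per domain, a linear mixed model
   `score ~ time` with correlated random intercept and slope (REML);
   a subject's change rate is the fixed slope plus the BLUP slope deviation.
4. **Bootstrapped ROI comparison.** Per domain, B = 1000 bootstrap
   iterations regress the change rate on one tau ROI plus covariates (age,
   sex, education, clinical status, APOE4, baseline score); the tau term's
   partial R² = (RSS_reduced − RSS_full) / RSS_reduced is extracted per
   iteration, and the paired per-iteration distributions of the domain ROI
   vs global/temporal ROIs are compared with paired t-tests, Cohen's d, and
   percentile 95% CIs.
5. **Personalized composites.** A 1000-model bootstrap ensemble (change ~
   domain tau + age + sex + clinical status + APOE4) predicts each subject's
   per-domain decline; squared ranks of the predictions (1 = slowest … 16 =
   fastest predicted decline) weight the subject's actual z-scored change
   rates into a personalized composite, compared against the unweighted
   z-score mean by paired t-test (d_paired = t/√n).
6. **Trial power simulation.** Interventions attenuating change rates by
   20/30/40% are evaluated per endpoint (MEM change, unweighted composite,
   personalized composite): two-sample Cohen's d between actual and
   attenuated changes, and the smallest per-arm n reaching 80% power for a
   two-tailed two-sample t-test at α = 0.05 (noncentral-t power curve).

Because the study cohorts (ADNI and the AVID-1451-A05 trial) are
access-restricted, the package ships a first-class **synthetic cohort
generator** that reproduces the published cohort structure: group sizes
(121 Aβ− controls + 62/53/25 Aβ+ CN/MCI/dementia), covariate
distributions, per-group change-rate means/SDs, global tau-PET SUVR levels
rising from 1.06 (controls) to 1.46 (dementia), and a latent per-domain tau
burden that couples each domain's decline to tau in that domain's regions.

## Worked example

```python
from taucog.config import SimulationConfig
from taucog.pipeline import PipelineConfig, run_pipeline
import pandas as pd, json

cfg = PipelineConfig(simulate=SimulationConfig.adni_like(), seed=1, bootstrap=1000)
out = run_pipeline(cfg, "out")

r2 = pd.read_csv(out / "bootstrap_r2.csv")
print(r2.groupby(["domain", "roi"])["partial_r2"].mean().round(3).unstack())
print(json.loads((out / "composite_comparison.json").read_text()))
```

prints (seed 1):

```
roi        EF  GLOBAL    LAN    MEM  TEMPORAL     VS
domain
EF      0.176   0.106    NaN    NaN     0.102    NaN
LAN       NaN   0.186  0.268    NaN     0.187    NaN
MEM       NaN   0.153    NaN  0.234     0.150    NaN
VS        NaN   0.283    NaN    NaN     0.288  0.462
{'t': -5.149, 'p': 8.6e-07, 'd_paired': -0.435, 'n': 140}
```

Reading this: for every cognitive domain the matched domain-specific tau-PET
ROI explains more variance in that domain's annual cognitive change (mean
bootstrapped partial R², covariate-adjusted, Aβ+ sample n = 140) than the
global or temporal-lobe ROI — e.g. 0.234 vs 0.153/0.150 for episodic
memory. The negative paired t statistic says the personalized composite
declines faster than the unweighted composite of the same subjects'
z-scored change rates. `power_table.csv` in the same directory shows the
personalized composite needs the fewest subjects per arm at every simulated
intervention strength.

The same pipeline is scriptable from the shell:

```bash
taucog run-all --config config.json --outdir out --seed 1 --bootstrap 1000
```

with subcommands `simulate`, `signals`, `slopes`, `compare`, `personalize`,
`power` for stage-wise runs on the same output directory.

## Limitations

The synthetic generator works on small schematic voxel grids without
spatial autocorrelation, PET physics, or real neuroanatomy; see
`docs/methods.md` for the generative model, parameter choices, and what
passing tests do and do not establish about real cohort data.
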