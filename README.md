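# palzsim

Simulation pipeline for quantifying how atlas-based MR attenuation
correction (MRAC) error affects automated FDG-PET diagnosis of
Alzheimer's disease (AD).

On combined PET/MR scanners the attenuation map must be derived from MR
images rather than a CT scan. Vendor atlas-based MRAC leaves a smooth,
spatially structured bias in the reconstructed uptake — typically a
1–2 % underestimation across the brain, weaker in AD-related association
cortex than elsewhere. Because automated AD scoring normalizes each scan
to an "AD-preserved" reference region, such regionally uneven error can
shift the diagnostic score even when the global bias cancels. `palzsim`
reproduces, at desk scale and from a single seed, the simulation design
used to measure that effect: voxel-wise multiplicative error maps are
imposed on every subject of a template-space PET cohort, every perturbed
image is rescored, and the change in diagnostic accuracy at fixed score
cutoffs is summarized.

## The scoring model

Each spatially normalized, 12 mm-smoothed image is scored in four steps:

1. **Intensity normalization** — divide by the mean uptake in the
   AD-preserved mask.
2. **Expected values** — per-voxel linear regression of normalized uptake
   on age, fit on a healthy-control reference database: intercept `a_v`,
   slope `b_v`, residual SD `s_v`, `n` subjects, mean age `ā`,
   `Sxx = Σ(age_i − ā)²`.
3. **Voxel t-values** —

   ```
   t_v = (a_v + b_v·age − u_v) / (s_v · sqrt(1 + 1/n + (age − ā)²/Sxx))
   ```

   positive `t_v` marks hypometabolism.
4. **AD t-sum and PET score** — `T = Σ_{v ∈ AD mask} t_v` and
   `PET score = log2(T / 11089 + 1)`, where 11089 is the 95 % prediction
   limit of the AD t-sum in healthy controls. Score ≥ 1.0 classifies AD
   versus normal; score ≥ 0.79 predicts conversion from mild cognitive
   impairment (MCI) to AD within 24 months.

The cross simulation multiplies each of 203 synthetic cohort images
(48 NC, 59 AD, 96 MCI with 33 converters) with each of 47 synthetic error
maps (20 + 27 from two emulated institutions), rescoring all
203 × 47 = 9541 pairs from the intensity-normalization step onward.
Error fields are calibrated so that across maps the brain-average error is
−1.37 % ± 1.98 % with the AD mask less underestimated (−0.86 %) than the
rest of the brain (−1.59 %).

## Worked example

```python
from palzsim import SimStudyConfig, StudyConfig, make_cohorts, score_subject
from palzsim.study import prepare_scoring_inputs
from palzsim.errorsim import run_cross_simulation
from palzsim.evaluation import score_differences

config = StudyConfig(sim=SimStudyConfig(seed=1))
cohorts = make_cohorts(config.sim)                      # 203 subjects, 47 maps
subjects, model = prepare_scoring_inputs(cohorts, config)

for s in (subjects[0], subjects[48]):                   # one NC, one AD
    r = score_subject(s.volume, s.record.age, model, cohorts.template,
                      subject_id=s.record.subject_id, already_normalized=True)
    print(s.record.subject_id, s.record.group, round(r.ad_t_sum), round(r.pet_score, 3))

scores = run_cross_simulation(subjects, cohorts.error_maps, model, cohorts.template)
diffs = score_differences(scores)
print(diffs.attrs["overall"])
```

prints

```
nc-000 NC -1965 -0.281
ad-000 AD 17125 1.347
{'mean': -0.069, 'sd': 0.059, 'n': 9541}
```

The healthy control scores near 0 and the AD subject far above the 1.0
cutoff; across all 9541 subject-by-map pairs the PET score drops by 0.069
on average — error maps underestimate non-AD (including the normalization
region) more than AD cortex, which makes AD-mask uptake look relatively
hotter and pulls every t-value down.

The same study runs from the shell:

```bash
palzsim run-study --seed 1 --out study/
```

writing the cohort table, reference model, 9744-row score table, regional
error summaries, per-map diagnostic accuracy at both cutoffs,
Bland–Altman agreement for the best/worst three maps, the
between-institution comparison and a manifest under `study/`.

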