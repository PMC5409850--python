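# surfatlas

Probabilistic surface-atlas construction and evaluation on triangulated
cortical meshes — for researchers who build group ROI atlases from
multi-subject surface labels and need to quantify (a) how well the atlas
predicts an unseen subject and (b) how it corresponds to another
parcellation.

Given per-subject ROIs as vertex sets on a shared template surface, the
package

- builds per-vertex **probabilistic maps** (fraction of subjects covering
  each vertex) and **maximum probability maps** (hard argmax assignment with
  deterministic tie-breaking);
- scores atlas **predictability** by exhaustive leave-one-out
  cross-validation: the group map from all-but-one subjects, thresholded
  over the grid {0, 1/n, …, 1}, is compared with the held-out ROI by the
  dice coefficient `dc = 2|I∩G| / (|I|+|G|)`;
- compares two alignment conditions with a **paired sign-flip permutation
  test** on per-fold dice differences (10,000 permutations, add-one
  smoothed two-sided p, exact enumeration for small n);
- quantifies **parcellation correspondence** by the directional overlap
  proportion `|m∩c| / |m|` averaged over brains, against a chance level
  resampled 1000× with replacement from the (brain, ROI) pool, with
  Bonferroni correction per hemisphere — plus a tie-corrected Friedman test
  (which, unlike scipy's, accepts two treatments) for hemisphere effects;
- ships a **synthetic cohort generator** — geodesic patches on an icosphere
  with per-subject tangent-plane center jitter emulating residual
  misalignment under two alignment templates — so everything above runs and
  is tested without any imaging data.

ROI files are FreeSurfer ASCII `.label` (0-based vertex indices); meshes are
OFF or FreeSurfer ASCII surfaces.  Hemispheres are never mixed.

## Worked example

```python
from surfatlas import (default_config, generate_cohort, make_icosphere,
                       loocv_dice, paired_permutation_test)

cfg = default_config(subdiv=4, n_subjects=9, n_rois=8, seed=0)
mesh = make_icosphere(cfg.subdiv)
cohorts = generate_cohort(cfg, mesh)   # {"cba_pm": low jitter, "cba_fs": high}

cv_lo = loocv_dice(cohorts["cba_pm"], "hOc1", "left")
cv_hi = loocv_dice(cohorts["cba_fs"], "hOc1", "left")
print(round(cv_lo.dice_at(0.375).mean(), 3))   # 0.838
print(round(cv_hi.dice_at(0.375).mean(), 3))   # 0.721

res = paired_permutation_test(cv_lo.dice_at(0.375), cv_hi.dice_at(0.375),
                              n_perm=10_000, seed=0)
print(round(res.p_value, 4))                   # 0.0183
```

The two numbers are the mean cross-validated dice for this ROI at the 0.375
group-map threshold (vertices shared by ≥ 3 of the 8 group subjects): the
atlas predicts a held-out subject's ROI with dice 0.84 under 0.05 rad of
simulated misalignment, dropping to 0.72 at 0.10 rad; the permutation p
says that per-fold difference would arise by sign symmetry alone about 2% of
the time.

The numbered drivers under `analysis/` run the full study and write their
tables to `results/`:

```sh
python analysis/01_simulate_cohort.py        # cohort .label files + mesh
python analysis/02_crossvalidate_templates.py  # results/loocv_dice.tsv + permutation_tests.json
python analysis/03_compare_parcellations.py    # results/comparison.tsv
python analysis/04_full_pipeline.py            # everything, with manifest
```

`02` prints, per ROI, the mean dice under both conditions and the
Bonferroni-corrected permutation p (e.g. `FG3  low-jitter 0.713
high-jitter 0.373  corrected p 0.0384 *`); `03` prints each derived region's
best-matching ROI with its resampled chance level.  See `docs/methods.md`
for the model, parameter defaults and their rationale, and known
limitations.

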