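"""Score atlas predictability under the two alignment conditions.

Runs exhaustive leave-one-out cross-validation of every ROI's group
probabilistic map over the full threshold sweep, for both simulated alignment
conditions, then tests the per-ROI condition difference at threshold .375
with a paired sign-flip permutation test (10,000 permutations, Bonferroni
over ROIs).  Writes results/loocv_dice.tsv and results/permutation_tests.json
and prints the summary.
"""

import json
from pathlib import Path

import pandas as pd

from surfatlas import (
    bonferroni,
    default_config,
    generate_cohort,
    loocv_dice,
    make_icosphere,
    paired_permutation_test,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
EVAL_T = 0.375


def main() -> None:
    cfg = default_config(subdiv=4, n_subjects=9, n_rois=8, seed=0)
    mesh = make_icosphere(cfg.subdiv)
    cohorts = generate_cohort(cfg, mesh)
    frames, perm = [], {}
    for roi in cohorts["cba_pm"].rois:
        cv = {c: loocv_dice(cohorts[c], roi, "left") for c in cohorts}
        frames += [r.to_frame() for r in cv.values()]
        res = paired_permutation_test(
            cv["cba_pm"].dice_at(EVAL_T), cv["cba_fs"].dice_at(EVAL_T),
            n_perm=10_000, seed=cfg.seed,
        )
        perm[roi] = {
            "mean_dice_cba_pm": float(cv["cba_pm"].dice_at(EVAL_T).mean()),
            "mean_dice_cba_fs": float(cv["cba_fs"].dice_at(EVAL_T).mean()),
            "observed_difference": res.observed,
            "p": res.p_value,
            "p_corrected": bonferroni(res.p_value, len(cohorts["cba_pm"].rois)),
        }
    RESULTS.mkdir(exist_ok=True)
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(RESULTS / "loocv_dice.tsv", sep="\t", index=False, float_format="%.10g")
    (RESULTS / "permutation_tests.json").write_text(
        json.dumps(perm, indent=2, sort_keys=True) + "\n"
    )

    print(f"threshold {EVAL_T}: cross-validated dice by ROI and condition")
    for roi, row in perm.items():
        star = " *" if row["p_corrected"] < 0.05 else ""
        print(f"  {roi:6s} low-jitter {row['mean_dice_cba_pm']:.3f}  "
              f"high-jitter {row['mean_dice_cba_fs']:.3f}  "
              f"corrected p {row['p_corrected']:.4f}{star}")
    means = table[table.threshold.sub(EVAL_T).abs() < 1e-9].groupby("condition").dice.mean()
    print(f"overall: low-jitter {means['cba_pm']:.3f} vs high-jitter {means['cba_fs']:.3f} "
          "- precision drops as simulated misalignment grows")


if __name__ == "__main__":
    main()
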