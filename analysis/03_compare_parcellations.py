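"""Compare the probabilistic atlas with a derived second parcellation.

Derives group-level regions by displacing each ROI template 0.10 rad (with
one quarter of them split in two), scores the directional overlap proportion
of every (region, ROI) pair averaged over brains, estimates region-specific
chance levels by resampling the (brain, ROI) pool 1000 times with
replacement, and applies Bonferroni over the 8 ROIs.  Writes
results/comparison.tsv and prints the per-region best matches.
"""

from pathlib import Path

from surfatlas import (
    compare_atlases,
    default_config,
    derive_second_parcellation,
    generate_cohort,
    make_icosphere,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cfg = default_config(subdiv=4, n_subjects=9, n_rois=8, seed=0)
    mesh = make_icosphere(cfg.subdiv)
    cohort = generate_cohort(cfg, mesh)["cba_pm"]
    mrois, provenance = derive_second_parcellation(
        cfg, mesh, displacement=0.10, split_fraction=0.25
    )
    report = compare_atlases(mrois, cohort, alpha=0.05, n_iter=1000, seed=cfg.seed)
    RESULTS.mkdir(exist_ok=True)
    report.table.to_csv(RESULTS / "comparison.tsv", sep="\t", index=False,
                        float_format="%.10g")

    print("best-matching ROI per derived region (mean overlap, chance mean):")
    for mroi_id, src in provenance.items():
        rows = report.table[report.table.mroi == mroi_id]
        best = rows.loc[rows.mean_overlap.idxmax()]
        mark = " <- source" if best.croi == src else ""
        print(f"  {mroi_id:12s} -> {best.croi:6s} "
              f"{best.mean_overlap:.3f} (chance {best.chance_mean:.3f}){mark}")
    n_sig = int(report.table.significant.sum())
    print(f"{n_sig}/{len(report.table)} cells exceed chance after Bonferroni; "
          "the single-draw chance pool contains each region's own source ROI, "
          "which bounds how small the exceedance p can get in this one-to-one design")


if __name__ == "__main__":
    main()
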