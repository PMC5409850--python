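"""Simulate the reference synthetic cohort and write it to disk.

Generates the package's default study design — 9 subjects x 8 ventral-stream-
like ROIs on a subdivision-4 icosphere, under two alignment conditions that
differ only in center jitter (0.05 vs 0.10 rad) — and writes a cohort
directory of FreeSurfer ASCII .label files, the mesh, the config and a
manifest under results/cohort/.
"""

import json
from pathlib import Path

from surfatlas import default_config, generate_cohort, make_icosphere, write_label, write_mesh

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main() -> None:
    cfg = default_config(subdiv=4, n_subjects=9, n_rois=8, seed=0)
    mesh = make_icosphere(cfg.subdiv)
    cohorts = generate_cohort(cfg, mesh)
    OUT.mkdir(parents=True, exist_ok=True)
    write_mesh(mesh, OUT / "mesh.off")
    cfg.to_yaml(OUT / "config.yaml")
    manifest: dict = {"conditions": {}, "n_subjects": cfg.n_subjects}
    for cond, cohort in cohorts.items():
        cdir = OUT / cond
        cdir.mkdir(exist_ok=True)
        files = []
        for (s, r, h), lab in sorted(cohort.labels.items(), key=lambda kv: kv[0][:2]):
            if lab is None:
                continue
            name = f"{s}.{h.value}.{r}.label"
            write_label(lab, mesh, cdir / name)
            files.append(name)
        manifest["conditions"][cond] = files
        print(f"{cond}: wrote {len(files)} labels "
              f"(jitter sd {cfg.center_jitter_sd[cond]} rad)")
    (OUT / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    print(f"cohort written to {OUT}")


if __name__ == "__main__":
    main()
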