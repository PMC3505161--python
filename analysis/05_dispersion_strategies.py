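#!/usr/bin/env python
"""Dispersion-estimation strategies and the dispersion-vs-mean picture.

Compares quasi-Poisson k, per-gene NB dispersion, the common dispersion and
moderated dispersions (prior_n in {3, 10, 20}) on the simulated study data,
and writes the dispersion-versus-mean scatter with the zero-count-block
genes flagged — the analogue of the density spike caused by one subject's
all-zero gene block.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import countvar as cv
import countvar.glm_engine as ge


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/dispersion"))
    args = ap.parse_args()

    truth = pd.read_csv(args.data / "sim_truth.tsv", sep="\t", index_col=0)
    matrix = cv.filter_expressed(cv.read_counts(args.data / "lane_counts.tsv"))
    design = cv.read_design(args.data / "lane_design.tsv")
    subj = cv.sum_lane_pairs(matrix, design)
    st = cv.subject_table(design).loc[list(subj.sample_ids)]
    dinfo = ge.build_design(st, cv.ModelSpec())
    off = cv.make_offsets(cv.normalize(subj, "upper_quartile"), subj.sample_ids)

    pois = ge.fit_all(subj, dinfo, off, family="poisson")
    pergene = cv.estimate_phi_pergene(subj, dinfo, off)
    common = cv.estimate_phi_common(subj, dinfo, off)
    table = pd.DataFrame({"gene_id": subj.gene_ids, "k": cv.estimate_k(pois),
                          "phi_pergene": pergene}).set_index("gene_id")
    for prior in (3.0, 10.0, 20.0):
        table[f"phi_mod{prior:g}"] = cv.estimate_phi_moderated(
            subj, dinfo, off, prior_n=prior)
    args.out.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out / "dispersions.tsv", sep="\t")

    gene_pos = {g: i for i, g in enumerate(
        "g" + (truth.index + 1).astype(str).str.zfill(5))}
    zero_all = truth["zero_block"].to_numpy()
    zmask = np.array([zero_all[gene_pos[g]] for g in subj.gene_ids])
    pv = cv.phi_vs_mean(table["phi_mod3"].to_numpy(), subj.counts.mean(axis=1),
                        zero_block=zmask)
    pv.to_csv(args.out / "phi_vs_mean.tsv", sep="\t", index=False)

    mod3 = table["phi_mod3"]
    print(f"common phi = {common:.3f}; moderated (prior 3): "
          f"{(mod3 < 0.15).mean():.0%} of estimates < 0.15, "
          f"{(mod3 > 0.25).mean():.0%} > 0.25")
    print(f"dispersion-vs-mean trend slope {pv.attrs['trend_slope']:+.4f} "
          "(no mean dependence apart from the flagged block)")
    print(f"zero-block genes: moderated phi median "
          f"{np.nanmedian(mod3[zmask]):.3f} vs {np.nanmedian(mod3[~zmask]):.3f} "
          "elsewhere — the artefactual spike at mid/high means")


if __name__ == "__main__":
    main()
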