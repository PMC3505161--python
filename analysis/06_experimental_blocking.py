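#!/usr/bin/env python
"""Experimental (blocking) variation: lane-pair, batch and flow cell.

Adds each blocking factor to the NB group model (moderated dispersions,
upper-quartile offset) and summarises the GOF distributions; then extracts
the flow-cell contrast coefficients by run order with and without the
offset, exposing the depth-regime shift of the mid-study software upgrade.
With one subject per group per flow cell, blocking absorbs biological
noise, so the blocked GOF distributions fall below their chi-square
references — the over-fitting trade-off.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

import countvar as cv
import countvar.glm_engine as ge


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/blocking"))
    args = ap.parse_args()

    matrix = cv.filter_expressed(cv.read_counts(args.data / "lane_counts.tsv"))
    design = cv.read_design(args.data / "lane_design.tsv")
    subj = cv.sum_lane_pairs(matrix, design)
    st = cv.subject_table(design).loc[list(subj.sample_ids)]
    base = ge.build_design(st, cv.ModelSpec())
    off = cv.make_offsets(cv.normalize(subj, "upper_quartile"), subj.sample_ids)
    moderated = cv.estimate_phi_moderated(subj, base, off, prior_n=3.0)
    phi = np.nan_to_num(moderated, nan=np.nanmedian(moderated))

    args.out.mkdir(parents=True, exist_ok=True)
    rows = []
    for blocking in ("none", "lane_pair", "batch", "flow_cell"):
        dinfo = ge.build_design(st, cv.ModelSpec(blocking=blocking))
        fits = ge.fit_all(subj, dinfo, off, family="nb", phi=phi)
        rows.append({"blocking": blocking, "p": dinfo.p, "df": fits.df,
                     "max_X2": fits.pearson_X2.max(),
                     "median_X2": np.median(fits.pearson_X2),
                     "chisq_median": stats.chi2(fits.df).median()})
    summary = pd.DataFrame(rows)
    summary.to_csv(args.out / "blocking_gof.tsv", sep="\t", index=False)
    print(summary.to_string(index=False, float_format=lambda v: f"{v:.1f}"))

    dinfo_fc = ge.build_design(st, cv.ModelSpec(blocking="flow_cell"))
    for tag, offs in (("no_offset", None), ("uq_offset", off)):
        eff = ge.collect_blocking_effects(ge.fit_all(subj, dinfo_fc, offs,
                                                     family="nb", phi=phi),
                                          "flow_cell")
        eff.median().rename("median_coef").to_csv(
            args.out / f"flowcell_effects_{tag}.tsv", sep="\t")
        med = eff.median()
        pre = med[[c for c in med.index if int(c[2:]) <= 5]].mean()
        post = med[[c for c in med.index if int(c[2:]) > 5]].mean()
        print(f"{tag}: mean flow-cell contrast pre-upgrade {pre:+.3f}, "
              f"post-upgrade {post:+.3f}")
    print("the upgrade step is visible without an offset and vanishes with it; "
          "residual blocked GOF medians sit below their chi-square references "
          "(over-fitting), so blocking factors are left out of the headline models")


if __name__ == "__main__":
    main()
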