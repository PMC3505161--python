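import numpy as np
import pandas as pd
import pytest

import countvar as cv
import countvar.glm_engine as ge


def prep_subject_level(matrix, design, norm="upper_quartile", spec=None):
    """Filter, collapse lane pairs, and build the subject-level model inputs."""
    expressed = cv.filter_expressed(matrix)
    keep = np.isin(matrix.gene_ids, expressed.gene_ids)
    subj = cv.sum_lane_pairs(expressed, design)
    st = cv.subject_table(design).loc[list(subj.sample_ids)]
    dinfo = ge.build_design(st, spec or cv.ModelSpec())
    nr = cv.normalize(subj, norm)
    off = cv.make_offsets(nr, subj.sample_ids)
    return {"keep": keep, "subj": subj, "subjects": st, "design_info": dinfo,
            "norm": nr, "offsets": off}


@pytest.fixture(scope="session")
def study_design():
    return cv.replicate_study_design()


@pytest.fixture(scope="session")
def nb_bundle(study_design):
    """Study-scale NB simulation at a single dispersion (phi = 0.131)."""
    cfg = cv.SimConfig(n_genes=1000, dispersion=cv.DispersionSpec.point(0.131),
                       seed=31)
    matrix, design, truth = cv.simulate_experiment(cfg, design=study_design)
    out = prep_subject_level(matrix, design)
    out.update(matrix=matrix, design=design, truth=truth, phi_true=0.131)
    return out


@pytest.fixture(scope="session")
def zero_block_bundle(study_design):
    """Simulation with one subject's mid/high-expression gene block zeroed."""
    cfg = cv.SimConfig(n_genes=600, dispersion=cv.DispersionSpec.point(0.1),
                       zero_subject=True, zero_gene_fraction=0.05, seed=9)
    matrix, design, truth = cv.simulate_experiment(cfg, design=study_design)
    out = prep_subject_level(matrix, design)
    out.update(matrix=matrix, design=design, truth=truth)
    zmask = np.zeros(len(truth.phi), bool)
    zmask[truth.zero_genes] = True
    out["zero_mask"] = zmask[out["keep"]]
    out["moderated"] = cv.estimate_phi_moderated(out["subj"], out["design_info"],
                                                 out["offsets"], prior_n=3.0)
    return out


@pytest.fixture()
def toy_design():
    """Two subjects x two lanes plus one failed-lane subject."""
    rows = []
    for subj, group, fc, status2 in [("s1", "high", "FC01", "ok"),
                                     ("s2", "low", "FC01", "ok"),
                                     ("s3", "high", "FC02", "failed")]:
        for rep in (1, 2):
            rows.append({
                "lane_id": f"{subj}_r{rep}", "subject_id": subj, "group": group,
                "flowcell_id": fc, "lane_number": rep, "lane_pair_id": "LP1",
                "batch_id": "B1", "software_version": "SCS2.01",
                "tech_rep_index": rep,
                "status": "ok" if rep == 1 else status2,
            })
    return cv.LaneDesign(pd.DataFrame(rows))
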