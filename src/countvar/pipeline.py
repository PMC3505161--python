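"""End-to-end orchestration: simulate -> normalize -> fit -> dispersion ->
diagnostics, with every intermediate serialized as TSV for auditability.

Also hosts the chi-square asymptotics validation (null NB simulation checked
against its chi-square reference) and small reporting helpers.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import countio, diagnostics, dispersion, simdata
from .normalize import make_offsets, normalize as normalize_counts
from .glm_engine import ModelSpec, build_design, fit_all

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    sim: simdata.SimConfig = field(default_factory=simdata.SimConfig)
    use_study_design: bool = True
    specs: list[ModelSpec] = field(default_factory=lambda: [
        ModelSpec("poisson", 0.0, "none", "upper_quartile"),
        ModelSpec("nb", "common", "none", "upper_quartile"),
        ModelSpec("nb", "moderated", "none", "upper_quartile"),
    ])
    prior_n: float = 3.0
    out_dir: str = "results/pipeline"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.specs:
            raise ValueError("at least one ModelSpec is required")

    def digest(self) -> str:
        payload = {
            "sim": {k: (v.label if isinstance(v, simdata.DispersionSpec) else str(v))
                    for k, v in vars(self.sim).items()},
            "specs": [s.label for s in self.specs],
            "prior_n": self.prior_n, "seed": self.seed,
            "use_study_design": self.use_study_design,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        disp = sim_raw.pop("dispersion", None)
        if disp is not None:
            sim_raw["dispersion"] = (simdata.DispersionSpec.point(float(disp))
                                     if not isinstance(disp, str)
                                     else getattr(simdata.DispersionSpec, disp)())
        specs = [ModelSpec(**s) for s in raw.pop("specs", [])]
        cfg = cls(sim=simdata.SimConfig(**sim_raw), **raw)
        if specs:
            cfg.specs = specs
        return cfg


@dataclass
class ReportBundle:
    gof_summaries: pd.DataFrame
    meanvar_fit: diagnostics.MeanVarFit
    dispersions: dispersion.DispersionSet
    tech_qc: pd.DataFrame
    provenance: dict
    paths: dict


def _write(frame: pd.DataFrame, path: Path, provenance: dict, index=True) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# seed={provenance['seed']} config={provenance['config_digest']}\n")
        frame.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute all stages in order, writing intermediates under out_dir."""
    out = Path(config.out_dir)
    prov = {"seed": config.seed, "config_digest": config.digest()}
    paths: dict = {}

    sim_cfg = config.sim
    if sim_cfg.seed != config.seed:
        sim_cfg = simdata.SimConfig(**{**vars(sim_cfg), "seed": config.seed})
    design = simdata.replicate_study_design() if config.use_study_design else None
    lanes, design, truth = simdata.simulate_experiment(sim_cfg, design=design)
    logger.info("simulated %d genes x %d lanes", lanes.n_genes, lanes.n_samples)

    out.mkdir(parents=True, exist_ok=True)
    header = f"seed={prov['seed']} config={prov['config_digest']}"
    countio.write_counts(lanes, out / "lane_counts.tsv", header)
    countio.write_design(design, out / "lane_design.tsv", header)
    _write(truth.to_frame(), out / "sim_truth.tsv", prov)
    paths.update(counts=out / "lane_counts.tsv", design=out / "lane_design.tsv",
                 truth=out / "sim_truth.tsv")

    expressed = countio.filter_expressed(lanes)
    logger.info("expressed genes: %d of %d", expressed.n_genes, lanes.n_genes)

    # technical QC on the first subject's lane pair
    lane_tbl = design.ok()
    first_subj = lane_tbl["subject_id"].iloc[0]
    pair = lane_tbl[lane_tbl["subject_id"] == first_subj]["lane_id"].tolist()
    i1, i2 = [list(expressed.sample_ids).index(l) for l in pair]
    totals = expressed.counts.sum(axis=0)
    y1, y2 = expressed.counts[:, i1], expressed.counts[:, i2]
    pair_gof = diagnostics.technical_pair_gof(y1, y2, totals[i1], totals[i2])
    tech = pd.DataFrame({
        "subject": [first_subj],
        "spearman": [diagnostics.spearman_pair(y1, y2)],
        "median_pair_X2": [float(pair_gof["X2"].median())],
    })
    _write(tech, out / "technical_qc.tsv", prov, index=False)

    subjects_mx = countio.sum_lane_pairs(expressed, design)
    subj_tbl = countio.subject_table(design).loc[list(subjects_mx.sample_ids)]

    norms = {m: normalize_counts(subjects_mx, m)
             for m in ["none", "total", "upper_quartile"]}
    _write(pd.DataFrame({m: r.constants for m, r in norms.items()}),
           out / "norm_constants.tsv", prov)

    # mean-variance characterisation on upper-quartile-scaled counts
    uq_const = norms["upper_quartile"].constants.reindex(
        list(subjects_mx.sample_ids)).to_numpy()
    mv_points = diagnostics.group_mean_variance(
        subjects_mx, subj_tbl["group"].to_numpy(), uq_const)
    mv_fit = diagnostics.fit_variance_laws(mv_points)
    _write(mv_points, out / "meanvar_points.tsv", prov, index=False)

    # dispersion set under the group-only design with UQ offsets
    base_design = build_design(subj_tbl, ModelSpec("nb", "common", "none", "upper_quartile"))
    uq_off = make_offsets(norms["upper_quartile"], subjects_mx.sample_ids)
    pois_base = fit_all(subjects_mx, base_design, uq_off, family="poisson")
    disp = dispersion.estimate_all(subjects_mx, base_design, uq_off,
                                   prior_n=config.prior_n, poisson_fits=pois_base)
    _write(pd.DataFrame({
        "gene_id": subjects_mx.gene_ids, "phi_pergene": disp.per_gene_phi,
        "phi_moderated": disp.moderated_phi, "k": disp.pergene_k,
    }).set_index("gene_id"), out / "dispersions.tsv", prov)

    summaries = []
    for spec in config.specs:
        dinfo = build_design(subj_tbl, spec)
        offs = make_offsets(norms[spec.normalization], subjects_mx.sample_ids)
        phi = disp.resolve(spec.dispersion_source) if spec.variance_family == "nb" else 0.0
        if isinstance(phi, np.ndarray):
            phi = np.nan_to_num(phi, nan=disp.common_phi)
        fits = fit_all(subjects_mx, dinfo, offs, family=spec.variance_family, phi=phi)
        gof = diagnostics.gof_table(fits, subjects_mx.counts)
        slug = spec.label.replace("/", "_").replace(":", "")
        _write(gof, out / f"gof_{slug}.tsv", prov)
        qq = diagnostics.qq_against_chisq(gof["X2"], fits.df)
        _write(qq.to_frame(), out / f"qq_{slug}.tsv", prov, index=False)
        summaries.append({
            "model": spec.label, "df": fits.df,
            "max_X2": float(gof["X2"].max()),
            "median_X2": float(gof["X2"].median()),
            "p99_X2": float(gof["X2"].quantile(0.99)),
            "n_nonconverged": int((~fits.converged).sum()),
        })
        logger.info("fit %s: max X2 %.1f, %d non-converged",
                    spec.label, summaries[-1]["max_X2"], summaries[-1]["n_nonconverged"])
    summary = pd.DataFrame(summaries)
    _write(summary, out / "gof_summary.tsv", prov, index=False)
    paths["summary"] = out / "gof_summary.tsv"

    return ReportBundle(gof_summaries=summary, meanvar_fit=mv_fit,
                        dispersions=disp, tech_qc=tech,
                        provenance=prov, paths=paths)


def validate_chisq_asymptotics(n_samples: int, mean_vector_spec=(0.0, 4.0),
                               dispersion_spec=None, seed: int = 0,
                               n_genes: int = 5000) -> diagnostics.QQData:
    """Null-NB calibration of the chi-square reference for the GOF statistic.

    Simulates ``n_genes`` null NB genes (no group effect) at ``n_samples``
    samples each, computes the Pearson statistic using the sample mean and
    the TRUE dispersion, and returns QQ data against chi-square(n - 1).
    ``mean_vector_spec`` is a (lo, hi) log10-uniform interval or an explicit
    mean vector; ``dispersion_spec`` is a DispersionSpec, scalar, vector, or
    None for the study-like mixture.
    """
    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    rng = np.random.default_rng(seed)
    if isinstance(mean_vector_spec, tuple):
        mu = 10.0 ** rng.uniform(*mean_vector_spec, n_genes)
    else:
        mu = np.asarray(mean_vector_spec, float)
        n_genes = mu.size
    if dispersion_spec is None:
        dispersion_spec = simdata.DispersionSpec.study_mixture()
    if isinstance(dispersion_spec, simdata.DispersionSpec):
        phi = dispersion_spec.draw(rng, n_genes)
    else:
        phi = np.broadcast_to(np.asarray(dispersion_spec, float), (n_genes,)).copy()

    lam = np.where(phi[:, None] > 0,
                   mu[:, None] * rng.gamma(1.0 / np.maximum(phi, 1e-12)[:, None],
                                           np.maximum(phi, 1e-12)[:, None],
                                           (n_genes, n_samples)),
                   mu[:, None])
    y = rng.poisson(lam).astype(float)
    ybar = y.mean(axis=1)
    keep = ybar > 0
    y, ybar, phi = y[keep], ybar[keep], phi[keep]
    var = ybar[:, None] + phi[:, None] * ybar[:, None] ** 2
    x2 = ((y - ybar[:, None]) ** 2 / var).sum(axis=1)
    return diagnostics.qq_against_chisq(x2, df=n_samples - 1)


def implied_cv(phi: float) -> int:
    """Between-subject coefficient of variation implied by an NB dispersion.

    sqrt(phi) is the CV of the Gamma-distributed subject means; reported as
    a whole percent.
    """
    if phi < 0:
        raise ValueError("phi must be >= 0")
    return int(round(100.0 * np.sqrt(phi)))
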