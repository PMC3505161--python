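"""Synthetic lane-level mRNA-Seq count generator.

The generator emulates a two-group human sequencing study: subjects from a
high and a low response group, one subject of each group per flow cell, two
technical-replicate lanes per (unstimulated) specimen.  Technical noise is
Poisson; biological noise enters through a per-subject Gamma multiplier on
each gene's rate, so subject-level counts follow a negative binomial with
Var(y) = mu + phi * mu^2.  Per-lane sequencing depth varies within a stated
range, with a mid-study regime shift mimicking a software upgrade that
raised read yields.

Every random quantity used to build a matrix (baseline means, dispersions,
subject multipliers, depth factors, effects) is returned in a
:class:`SimTruth` record so that estimators can be tested for parameter
recovery against the exact generating values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .countio import DESIGN_COLUMNS, CountMatrix, LaneDesign

__all__ = [
    "DispersionSpec",
    "SimConfig",
    "SimTruth",
    "simulate_experiment",
    "inject_zero_subject",
    "replicate_study_design",
]


@dataclass(frozen=True)
class DispersionSpec:
    """Distribution of per-gene NB dispersions phi_g.

    ``point(v)`` gives a point mass (v = 0 degenerates to Poisson).
    ``study_mixture()`` matches the study's summary of moderated estimates:
    82% below 0.15, ~5% above 0.25 with a heavy right tail.
    """

    draw_fn: Callable[[np.random.Generator, int], np.ndarray]
    label: str = "custom"

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        phi = np.asarray(self.draw_fn(rng, n), dtype=float)
        if phi.shape != (n,):
            raise ValueError("dispersion spec returned wrong shape")
        if (phi < 0).any():
            raise ValueError("negative dispersion drawn")
        return phi

    @classmethod
    def point(cls, value: float) -> "DispersionSpec":
        if value < 0:
            raise ValueError("phi must be >= 0")
        return cls(lambda rng, n: np.full(n, float(value)), f"point({value})")

    @classmethod
    def study_mixture(cls) -> "DispersionSpec":
        # 82% small, 13% intermediate, 5% heavy right tail above 0.25
        def _draw(rng: np.random.Generator, n: int) -> np.ndarray:
            comp = rng.choice(3, size=n, p=[0.82, 0.13, 0.05])
            phi = np.empty(n)
            phi[comp == 0] = rng.uniform(0.005, 0.15, (comp == 0).sum())
            phi[comp == 1] = rng.uniform(0.15, 0.25, (comp == 1).sum())
            phi[comp == 2] = 0.25 + rng.exponential(0.15, (comp == 2).sum())
            return phi

        return cls(_draw, "study_mixture")

    @classmethod
    def two_point(cls, lo: float, hi: float, w_hi: float = 0.5) -> "DispersionSpec":
        def _draw(rng: np.random.Generator, n: int) -> np.ndarray:
            return np.where(rng.random(n) < w_hi, hi, lo)

        return cls(_draw, f"two_point({lo},{hi})")


@dataclass
class SimConfig:
    """Settings for one simulated experiment.

    n_subjects_per_group may be an int (both groups equal) or a
    (n_high, n_low) pair; the default (12, 11) matches the 23 retained
    subjects of the emulated study.  depth_range is in millions of reads per
    lane; lanes on flow cells before ``upgrade_at_flowcell`` draw totals from
    the lower half of the range, later ones from the upper half.
    """

    n_genes: int = 2000
    n_subjects_per_group: int | tuple[int, int] = (12, 11)
    groups: tuple[str, str] = ("high", "low")
    lanes_per_specimen: int = 2
    mean_log10_range: tuple[float, float] = (0.0, 5.0)
    dispersion: DispersionSpec = field(default_factory=DispersionSpec.study_mixture)
    depth_range: tuple[float, float] = (3.7, 10.7)
    upgrade_at_flowcell: int | None = 5
    flowcell_effect_sd: float = 0.0
    batch_effect_sd: float = 0.0
    de_fraction: float = 0.0
    de_log2fc: float = 0.0
    zero_subject: bool = False
    zero_gene_fraction: float = 0.02
    transcriptome_size: int | None = 17337
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        nh, nl = self.group_sizes
        if nh <= 0 or nl <= 0:
            raise ValueError("n_subjects_per_group must be positive")
        if self.lanes_per_specimen != 2:
            raise ValueError("only 2 technical-replicate lanes per specimen supported")
        if self.depth_range[0] > self.depth_range[1] or self.depth_range[0] <= 0:
            raise ValueError("depth_range must be a positive, ordered interval")
        if self.mean_log10_range[0] > self.mean_log10_range[1]:
            raise ValueError("mean_log10_range inverted")

    @property
    def group_sizes(self) -> tuple[int, int]:
        n = self.n_subjects_per_group
        return (n, n) if isinstance(n, int) else (int(n[0]), int(n[1]))


@dataclass
class SimTruth:
    """Generating values behind one simulated matrix."""

    mu: np.ndarray                      # per-gene baseline mean rate
    phi: np.ndarray                     # per-gene NB dispersion
    multipliers: np.ndarray             # genes x subjects Gamma multipliers
    depth_factors: pd.Series            # per-lane depth factor d_lane
    lane_targets: pd.Series             # per-lane target totals (reads)
    group_log2fc: np.ndarray            # per-gene log2 fold change (high vs low)
    flowcell_effects: dict
    batch_effects: dict
    zero_subject: str | None = None
    zero_genes: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        zg = np.zeros(len(self.mu), dtype=bool)
        if self.zero_genes is not None:
            zg[self.zero_genes] = True
        return pd.DataFrame({
            "mu": self.mu, "phi": self.phi,
            "group_log2fc": self.group_log2fc, "zero_block": zg,
        })


def replicate_study_design() -> LaneDesign:
    """Deterministic replica of the study's retained lane layout.

    23 subjects (12 high, 11 low responders) spread over 13 flow cells —
    ten cells carry one subject of each group, three carry a single subject
    (the residue of failed/re-run samples) — two unstimulated lanes per
    subject, four lane-pair position levels, and six observed library-prep
    batches (a seventh batch contained only dropped subjects).  Flow cells
    1-5 ran the older base-calling software.
    """
    subjects = []  # (subject, group, flowcell_index)
    for i in range(10):
        subjects.append((f"H{i + 1:02d}", "high", i + 1))
        subjects.append((f"L{i + 1:02d}", "low", i + 1))
    subjects.append(("H11", "high", 11))
    subjects.append(("H12", "high", 12))
    subjects.append(("L11", "low", 13))

    rows = []
    for k, (subj, group, fc) in enumerate(subjects):
        # alternate the flow-cell half and the pair position within the half
        half = 0 if (fc + (group == "low")) % 2 == 0 else 1
        pos_in_half = k % 2
        lane_pair = 2 * half + pos_in_half + 1           # 1..4
        first_lane = 4 * half + 2 * pos_in_half + 1
        batch = f"B{k // 4 + 1}"                          # 6 batches over 23
        software = "SCS2.01" if fc <= 5 else "SCS2.4"
        for rep in (1, 2):
            rows.append({
                "lane_id": f"{subj}_r{rep}",
                "subject_id": subj,
                "group": group,
                "flowcell_id": f"FC{fc:02d}",
                "lane_number": first_lane + rep - 1,
                "lane_pair_id": f"LP{lane_pair}",
                "batch_id": batch,
                "software_version": software,
                "tech_rep_index": rep,
                "status": "ok",
            })
    return LaneDesign(pd.DataFrame(rows, columns=DESIGN_COLUMNS))


def _build_layout(config: SimConfig, rng: np.random.Generator) -> LaneDesign:
    """Paired allocation: flow cell i carries the i-th high and low subject."""
    nh, nl = config.group_sizes
    gh, gl = config.groups
    names = [(f"{gh[0].upper()}{i + 1:02d}", gh) for i in range(nh)] + \
            [(f"{gl[0].upper()}{i + 1:02d}", gl) for i in range(nl)]
    n_fc = max(nh, nl)
    rows = []
    for fc in range(1, n_fc + 1):
        members = []
        if fc <= nh:
            members.append(names[fc - 1])
        if fc <= nl:
            members.append(names[nh + fc - 1])
        halves = [0, 1] if len(members) == 2 else [0]
        rng.shuffle(halves)
        for (subj, group), half in zip(members, halves):
            pos_in_half = int(rng.integers(2))
            lane_pair = 2 * half + pos_in_half + 1
            first_lane = 4 * half + 2 * pos_in_half + 1
            batch = f"B{(fc - 1) % 7 + 1}"
            sw = "SCS2.01" if (config.upgrade_at_flowcell is None
                              or fc <= config.upgrade_at_flowcell) else "SCS2.4"
            for rep in (1, 2):
                rows.append({
                    "lane_id": f"{subj}_r{rep}",
                    "subject_id": subj,
                    "group": group,
                    "flowcell_id": f"FC{fc:02d}",
                    "lane_number": first_lane + rep - 1,
                    "lane_pair_id": f"LP{lane_pair}",
                    "batch_id": batch,
                    "software_version": sw,
                    "tech_rep_index": rep,
                    "status": "ok",
                })
    return LaneDesign(pd.DataFrame(rows, columns=DESIGN_COLUMNS))


def _flowcell_order(design: LaneDesign) -> list:
    return sorted(design.table["flowcell_id"].unique())


def simulate_experiment(
    config: SimConfig,
    design: LaneDesign | None = None,
) -> tuple[CountMatrix, LaneDesign, SimTruth]:
    """Generate a lane-level count matrix under the configured design.

    Per gene g and subject s the subject-level rate is
    ``lambda_gs = mu_g * m_gs * effects`` with ``m_gs ~ Gamma(1/phi_g, phi_g)``
    (mean 1, variance phi_g; m = 1 when phi_g = 0), and each of the subject's
    lanes draws ``y ~ Poisson(lambda_gs * d_lane)``.  One RNG stream seeded
    from ``config.seed``; draws are ordered gene-major, so the same seed is
    byte-identical across runs.
    """
    rng = np.random.default_rng(config.seed)
    G = config.n_genes

    lo, hi = config.mean_log10_range
    mu = 10.0 ** rng.uniform(lo, hi, G)
    phi = config.dispersion.draw(rng, G)

    if design is None:
        design = _build_layout(config, rng)
    lanes = design.ok().reset_index(drop=True)
    subjects = list(dict.fromkeys(lanes["subject_id"]))
    S, L = len(subjects), len(lanes)
    subj_index = {s: i for i, s in enumerate(subjects)}
    lane_subj = np.array([subj_index[s] for s in lanes["subject_id"]])

    multipliers = np.ones((G, S))
    pos = phi > 0
    if pos.any():
        shape = 1.0 / phi[pos]
        multipliers[pos] = rng.gamma(shape[:, None], 1.0 / shape[:, None], (pos.sum(), S))

    # group effect (high vs low), optional differential expression
    group_log2fc = np.zeros(G)
    if config.de_fraction > 0 and config.de_log2fc != 0:
        n_de = int(round(config.de_fraction * G))
        de_genes = rng.choice(G, n_de, replace=False)
        group_log2fc[de_genes] = config.de_log2fc
    subj_group = np.array([lanes.loc[lanes["subject_id"] == s, "group"].iloc[0]
                           for s in subjects])
    is_high = (subj_group == config.groups[0]).astype(float)

    fcs = _flowcell_order(design)
    fc_eff = {f: (rng.normal(0, config.flowcell_effect_sd)
                  if config.flowcell_effect_sd > 0 else 0.0) for f in fcs}
    batches = sorted(lanes["batch_id"].unique())
    batch_eff = {b: (rng.normal(0, config.batch_effect_sd)
                     if config.batch_effect_sd > 0 else 0.0) for b in batches}
    subj_fc = lanes.groupby("subject_id", sort=False)["flowcell_id"].first()
    subj_batch = lanes.groupby("subject_id", sort=False)["batch_id"].first()
    subj_log_eff = np.array([fc_eff[subj_fc[s]] + batch_eff[subj_batch[s]]
                             for s in subjects])

    lam = (mu[:, None] * multipliers
           * np.exp2(group_log2fc[:, None] * is_high[None, :])
           * np.exp(subj_log_eff)[None, :])

    # per-lane depth: target totals uniform within the pre/post-upgrade regime
    d_lo, d_hi = np.array(config.depth_range) * 1e6
    mid = 0.5 * (d_lo + d_hi)
    if config.upgrade_at_flowcell is None:
        pre = np.ones(L, dtype=bool)
        targets = rng.uniform(d_lo, d_hi, L)
    else:
        fc_rank = {f: i + 1 for i, f in enumerate(fcs)}
        pre = np.array([fc_rank[f] <= config.upgrade_at_flowcell
                        for f in lanes["flowcell_id"]])
        targets = np.where(pre, rng.uniform(d_lo, mid, L), rng.uniform(mid, d_hi, L))
    # Lane totals describe the full expressed transcriptome; when simulating a
    # gene subsample, keep per-gene depth at transcriptome scale by dividing by
    # the expected total over `transcriptome_size` genes, not the subsample sum.
    if config.transcriptome_size is None:
        expected_total = mu.sum()
    else:
        lo10, hi10 = config.mean_log10_range
        mean_mu = ((10.0 ** hi10 - 10.0 ** lo10) / ((hi10 - lo10) * np.log(10.0))
                   if hi10 > lo10 else 10.0 ** lo10)
        expected_total = config.transcriptome_size * mean_mu
    depth = targets / expected_total

    counts = rng.poisson(lam[:, lane_subj] * depth[None, :])

    matrix = CountMatrix(
        np.array([f"g{i + 1:05d}" for i in range(G)], dtype=object),
        lanes["lane_id"].to_numpy(), counts,
    )
    truth = SimTruth(
        mu=mu, phi=phi, multipliers=multipliers,
        depth_factors=pd.Series(depth, index=lanes["lane_id"]),
        lane_targets=pd.Series(targets, index=lanes["lane_id"]),
        group_log2fc=group_log2fc,
        flowcell_effects=fc_eff, batch_effects=batch_eff,
    )

    if config.zero_subject:
        # mid/high-expression block zeroed in one subject, as observed in the
        # study's dispersion-vs-mean "spike"
        eligible = np.flatnonzero(mu >= np.quantile(mu, 0.6))
        n_zero = max(1, int(round(config.zero_gene_fraction * G)))
        zero_genes = np.sort(rng.choice(eligible, min(n_zero, eligible.size),
                                        replace=False))
        subject = subjects[int(rng.integers(S))]
        matrix = inject_zero_subject(matrix, design, config.zero_gene_fraction,
                                     seed=0, subject=subject, genes=zero_genes)
        truth.zero_subject = subject
        truth.zero_genes = zero_genes

    return matrix, design, truth


def inject_zero_subject(
    counts: CountMatrix,
    design: LaneDesign,
    gene_fraction: float,
    seed: int = 0,
    subject: str | None = None,
    genes: Sequence[int] | np.ndarray | None = None,
) -> CountMatrix:
    """Zero out a block of genes in both lanes of one subject.

    Emulates the study's anomaly where one subject had zero counts in both
    replicates for a sizeable gene block.  ``genes`` (row indices) and
    ``subject`` override the seeded random choice.
    """
    if not 0 <= gene_fraction < 1:
        raise ValueError("gene_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    subjects = design.subjects
    if subject is None:
        subject = subjects[int(rng.integers(len(subjects)))]
    elif subject not in subjects:
        raise ValueError(f"subject {subject!r} not present in design")
    if genes is None:
        n_zero = int(round(gene_fraction * counts.n_genes))
        genes = np.sort(rng.choice(counts.n_genes, n_zero, replace=False))
    genes = np.asarray(genes, dtype=int)
    if genes.size == 0:
        return CountMatrix(counts.gene_ids, counts.sample_ids, counts.counts.copy())

    lanes = design.ok()
    lane_ids = set(lanes.loc[lanes["subject_id"] == subject, "lane_id"])
    cols = [i for i, s in enumerate(counts.sample_ids) if s in lane_ids]
    new = counts.counts.copy()
    new[np.ix_(genes, cols)] = 0
    return CountMatrix(counts.gene_ids, counts.sample_ids, new)
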