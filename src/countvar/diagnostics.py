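"""Goodness-of-fit and variance-structure diagnostics.

Three diagnostic surfaces drive the analysis:

* per-gene Pearson chi-square statistics from the GLM fits, displayed as QQ
  plots against the chi-square(n - p) reference with the top 1% / next 4% of
  statistics flagged;
* technical-replicate pair QC — per-gene Pearson statistics for the
  two-lane split of a specimen (Poisson reference, 1 df), minus-versus-
  average (MVA) coordinates with a moving-average bias smoother, and the
  Spearman rank correlation of the two lanes;
* the mean-variance characterisation — per gene and response group, the
  sample mean and variance of scaled counts, with the three candidate
  variance laws Var = mu (Poisson), Var = k*mu (over-dispersed Poisson) and
  Var = mu + phi*mu^2 (negative binomial) fitted by through-origin least
  squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .glm_engine import FitBatch, GeneFit, pearson_statistic

LOW_COUNT_MEAN = 5.0     # "average count per subject < 5" flag


@dataclass
class GOFRecord:
    gene_id: str
    X2: float
    df: int
    family: str
    low_count_flag: bool


@dataclass
class QQData:
    """Sorted observed statistics vs chi-square quantiles at (i - 0.5) / G."""

    observed: np.ndarray
    theoretical: np.ndarray
    df: float
    decile_ticks: np.ndarray
    top1pct: np.ndarray      # boolean, aligned to sorted observed
    next4pct: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "observed": self.observed, "theoretical": self.theoretical,
            "top1pct": self.top1pct, "next4pct": self.next4pct,
        })


def pearson_gof(fit: GeneFit) -> GOFRecord:
    """Pearson statistic of one fit with the family-appropriate variance."""
    y_mean = float(np.mean(fit.fitted)) if fit.fitted.size else 0.0
    return GOFRecord(
        gene_id=fit.gene_id, X2=fit.pearson_X2, df=fit.df, family=fit.family,
        low_count_flag=y_mean < LOW_COUNT_MEAN,
    )


def gof_table(fits: FitBatch, counts: np.ndarray | None = None) -> pd.DataFrame:
    """Per-gene GOF statistics for a batch of fits."""
    if counts is None:
        counts = fits.fitted
    mean_count = np.asarray(counts).mean(axis=1)
    return pd.DataFrame({
        "gene_id": fits.gene_ids, "X2": fits.pearson_X2, "df": fits.df,
        "family": fits.family, "low_count_flag": mean_count < LOW_COUNT_MEAN,
        "converged": fits.converged,
    }).set_index("gene_id")


def qq_against_chisq(statistics, df: float) -> QQData:
    """QQ data for observed statistics against a common chi-square reference.

    The top 1% of observed statistics (by rank) are flagged red and the next
    4% blue in the study's plots; flag counts are ceil(0.01 G) and
    ceil(0.05 G) - ceil(0.01 G).
    """
    obs = np.sort(np.asarray(statistics, float))
    G = obs.size
    if G < 10:
        raise ValueError("need at least 10 statistics for a QQ summary")
    pp = (np.arange(1, G + 1) - 0.5) / G
    theo = stats.chi2.ppf(pp, df)
    n_top = int(np.ceil(0.01 * G))
    n_top5 = int(np.ceil(0.05 * G))
    top1 = np.zeros(G, bool)
    top1[G - n_top:] = True
    next4 = np.zeros(G, bool)
    next4[G - n_top5:G - n_top] = True
    deciles = stats.chi2.ppf(np.arange(0.1, 1.0, 0.1), df)
    return QQData(observed=obs, theoretical=theo, df=df,
                  decile_ticks=deciles, top1pct=top1, next4pct=next4)


def technical_pair_gof(y1, y2, N1: float, N2: float) -> pd.DataFrame:
    """Per-gene Poisson Pearson statistics for a technical-replicate pair.

    Expected lane counts split the pair total proportionally to the lane
    totals: yhat_l = N_l * (y1 + y2) / (N1 + N2); the statistic is
    chi-square with 1 df under Poisson technical noise.  Genes with zero
    pair total are excluded (0/0) and counted in the ``excluded`` attribute.
    """
    y1 = np.asarray(y1, float)
    y2 = np.asarray(y2, float)
    if N1 <= 0 or N2 <= 0:
        raise ValueError("lane totals must be positive")
    total = y1 + y2
    keep = total > 0
    e1 = N1 * total[keep] / (N1 + N2)
    e2 = N2 * total[keep] / (N1 + N2)
    x2 = (y1[keep] - e1) ** 2 / e1 + (y2[keep] - e2) ** 2 / e2
    out = pd.DataFrame({"X2": x2, "total": total[keep]},
                       index=np.flatnonzero(keep))
    out.attrs["excluded"] = int((~keep).sum())
    out.attrs["df"] = 1
    return out


def mva(y1, y2, N1: float, N2: float, window_frac: float = 0.05) -> pd.DataFrame:
    """Minus-versus-average coordinates for a technical pair, with smoother.

    Counts are scaled by lane totals; only genes positive in both lanes are
    plotted (log scale).  M = log2 ratio, A = mean log2 scaled count; the
    bias smoother is a centred moving average of M over A-sorted genes with
    a window of ``window_frac`` of the points.
    """
    y1 = np.asarray(y1, float)
    y2 = np.asarray(y2, float)
    if N1 <= 0 or N2 <= 0:
        raise ValueError("lane totals must be positive")
    keep = (y1 > 0) & (y2 > 0)
    if keep.sum() < 10:
        raise ValueError("fewer than 10 mutually positive genes")
    l1 = np.log2(y1[keep] / N1)
    l2 = np.log2(y2[keep] / N2)
    A = 0.5 * (l1 + l2)
    M = l1 - l2
    order = np.argsort(A, kind="stable")
    win = max(1, int(round(window_frac * keep.sum())))
    kernel = np.ones(win) / win
    sm_sorted = np.convolve(np.pad(M[order], (win // 2, win - 1 - win // 2),
                                   mode="edge"), kernel, mode="valid")
    smooth = np.empty_like(M)
    smooth[order] = sm_sorted
    return pd.DataFrame({"A": A, "M": M, "smooth": smooth},
                        index=np.flatnonzero(keep))


def spearman_pair(y1, y2) -> float:
    """Spearman rank correlation (midrank ties) of a technical pair."""
    y1 = np.asarray(y1, float)
    y2 = np.asarray(y2, float)
    if y1.size < 3 or y1.size != y2.size:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(y1) == 0 or np.ptp(y2) == 0:
        raise ValueError("constant vector has no rank correlation")
    return float(stats.spearmanr(y1, y2).statistic)


def group_mean_variance(subject_matrix, groups, scale_constants=None) -> pd.DataFrame:
    """Per gene x response group, mean and variance of scaled counts.

    Counts are divided by their sample's normalization constant and
    multiplied by the mean constant, keeping points on the count scale.
    One row per (gene, group); columns ``xbar`` and ``s2`` (unbiased).
    """
    Y = np.asarray(getattr(subject_matrix, "counts", subject_matrix), float)
    gene_ids = getattr(subject_matrix, "gene_ids", np.arange(Y.shape[0]))
    groups = np.asarray(groups)
    if scale_constants is not None:
        c = np.asarray(scale_constants, float)
        Y = Y / c[None, :] * c.mean()
    frames = []
    for lev in np.unique(groups):
        cols = groups == lev
        if cols.sum() < 2:
            raise ValueError(f"group {lev!r} has fewer than 2 subjects")
        sub = Y[:, cols]
        frames.append(pd.DataFrame({
            "gene_id": gene_ids, "group": lev,
            "xbar": sub.mean(axis=1), "s2": sub.var(axis=1, ddof=1),
        }))
    return pd.concat(frames, ignore_index=True)


@dataclass
class MeanVarFit:
    """Through-origin fits of the candidate variance laws to (xbar, s2)."""

    k_linear: float          # slope of s2 = k * xbar
    phi_quadratic: float     # slope of (s2 - xbar) = phi * xbar^2

    def sd_curves(self, xbar: np.ndarray) -> pd.DataFrame:
        """The three laws on the SD scale for plotting."""
        return pd.DataFrame({
            "xbar": xbar,
            "sd_poisson": np.sqrt(xbar),
            "sd_od_poisson": np.sqrt(self.k_linear * xbar),
            "sd_nb": np.sqrt(xbar + self.phi_quadratic * xbar**2),
        })


def fit_variance_laws(points: pd.DataFrame) -> MeanVarFit:
    """Least-squares slopes of the OD-Poisson and NB variance laws."""
    pts = points[points["xbar"] > 0]
    if len(pts) < 1:
        raise ValueError("no points with positive mean")
    x = pts["xbar"].to_numpy()
    s2 = pts["s2"].to_numpy()
    k = float((x * s2).sum() / (x**2).sum())
    x2 = x**2
    phi = float((x2 * (s2 - x)).sum() / (x2**2).sum())
    return MeanVarFit(k_linear=k, phi_quadratic=phi)


def phi_vs_mean(phi: np.ndarray, mean_counts: np.ndarray,
                zero_block: np.ndarray | None = None,
                n_bins: int = 40) -> pd.DataFrame:
    """Dispersion-versus-mean scatter summary.

    Returns one row per gene with log10 mean, the dispersion estimate, a 2-D
    density bin id, and the zero-subject-block flag (empty when no block was
    injected).  The attrs carry the slope of phi on log10 mean — near 0 when
    dispersion is not a function of the mean.
    """
    phi = np.asarray(phi, float)
    mean_counts = np.asarray(mean_counts, float)
    keep = np.isfinite(phi) & (mean_counts > 0)
    logm = np.log10(mean_counts[keep])
    out = pd.DataFrame({
        "log10_mean": logm, "phi": phi[keep],
        "flagged": (np.zeros(keep.sum(), bool) if zero_block is None
                    else np.asarray(zero_block, bool)[keep]),
    }, index=np.flatnonzero(keep))
    xb = np.digitize(logm, np.linspace(logm.min(), logm.max() + 1e-9, n_bins))
    yb = np.digitize(out["phi"], np.linspace(phi[keep].min(),
                                             phi[keep].max() + 1e-9, n_bins))
    out["density_bin"] = xb * n_bins + yb
    slope = np.polyfit(logm, phi[keep], 1)[0] if keep.sum() > 1 else np.nan
    out.attrs["trend_slope"] = float(slope)
    return out


def refit_with_dispersion(fits: FitBatch, counts, phi) -> np.ndarray:
    """Pearson statistics of existing fitted means under NB variance."""
    Y = np.asarray(getattr(counts, "counts", counts), float)
    return pearson_statistic(Y, fits.fitted, "nb", phi)
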