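"""Per-gene log-link count GLMs fitted by iteratively reweighted least squares.

Three variance families are supported for a common log-link mean model
``log mu_i = x_i' beta + offset_i``:

* ``poisson``      Var(y) = mu
* ``od_poisson``   Var(y) = k * mu, k estimated from the Pearson statistic of
                   the Poisson fit (quasi-likelihood; the beta estimate is the
                   Poisson one)
* ``nb``           Var(y) = mu + phi * mu^2 with a fixed, per-gene dispersion

Fisher scoring for all three families uses working weights w_i = mu_i
(Poisson / OD Poisson) or mu_i / (1 + phi * mu_i) (NB).  Fits are vectorised
across genes sharing a design matrix, which is what makes the profile
dispersion searches in :mod:`countvar.dispersion` affordable.

Degrees-of-freedom bookkeeping follows the study convention: the model
degree of freedom ``p`` counts non-intercept columns only (a group-only
model has p = 1), and the chi-square reference for the Pearson statistic has
``df = n - p``.  The true residual df ``n - p - 1`` is kept alongside for
moment estimators that need it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

ETA_CLAMP = 30.0          # |linear predictor| bound; exp(-30) ~ 1e-13 handles all-zero groups
_W_FLOOR = 1e-10

BLOCKING_COLUMN = {
    "none": None,
    "flow_cell": "flowcell_id",
    "lane_pair": "lane_pair_id",
    "batch": "batch_id",
}


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: variance family, dispersion source, blocking, normalization."""

    variance_family: str = "poisson"        # poisson | od_poisson | nb
    dispersion_source: str | float = "common"  # fixed value | per_gene | common | moderated
    blocking: str = "none"                  # none | flow_cell | lane_pair | batch
    normalization: str = "upper_quartile"   # none | total | upper_quartile

    def __post_init__(self) -> None:
        if self.variance_family not in ("poisson", "od_poisson", "nb"):
            raise ValueError(f"unknown variance family {self.variance_family!r}")
        if self.blocking not in BLOCKING_COLUMN:
            raise ValueError(f"unknown blocking factor {self.blocking!r}")

    @property
    def label(self) -> str:
        disp = (f"fixed:{self.dispersion_source}"
                if isinstance(self.dispersion_source, float) else self.dispersion_source)
        return f"{self.variance_family}/{disp}/block={self.blocking}/norm={self.normalization}"


@dataclass
class DesignInfo:
    """Design matrix with the study's model-df accounting (p = non-intercept columns)."""

    matrix: np.ndarray
    columns: list[str]
    p: int
    level_order: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def build_design(subjects: pd.DataFrame, spec: ModelSpec) -> DesignInfo:
    """Intercept + treatment-coded group + treatment-coded blocking levels.

    Levels are ordered by sorted label with the first as reference; levels
    with no subjects are pruned.  A blocking factor confounded with group
    (rank-deficient design) raises, naming the aliased columns.
    """
    n = len(subjects)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    level_order: dict = {}

    def add_factor(values: pd.Series, tag: str) -> None:
        levels = sorted(values.unique())
        level_order[tag] = levels
        for lev in levels[1:]:
            cols.append((values == lev).to_numpy(float))
            names.append(f"{tag}[{lev}]")

    add_factor(subjects["group"], "group")
    blocking_col = BLOCKING_COLUMN[spec.blocking]
    if blocking_col is not None:
        if blocking_col not in subjects.columns:
            raise ValueError(f"subject table lacks column {blocking_col!r}")
        add_factor(subjects[blocking_col], spec.blocking)

    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns via pivoted QR diagonal
        _, r = np.linalg.qr(X)
        bad = [names[j] for j in range(X.shape[1]) if abs(r[j, j]) < 1e-8]
        raise ValueError(
            f"design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"aliased columns: {bad or 'indeterminate'}"
        )
    return DesignInfo(matrix=X, columns=names, p=X.shape[1] - 1, level_order=level_order)


@dataclass
class GeneFit:
    """One gene's GLM result."""

    gene_id: str
    coefficients: np.ndarray
    fitted: np.ndarray
    family: str
    dispersion_used: float
    converged: bool
    iterations: int
    pearson_X2: float
    df: int            # n - p, the study's chi-square reference df
    df_resid: int      # n - p - 1, true residual df
    degenerate: bool = False


class FitBatch:
    """Vectorised collection of per-gene fits sharing one design matrix."""

    def __init__(self, gene_ids, beta, fitted, family, dispersion,
                 converged, iterations, pearson_X2, design: DesignInfo,
                 degenerate=None):
        self.gene_ids = np.asarray(gene_ids, dtype=object)
        self.beta = beta
        self.fitted = fitted
        self.family = family
        self.dispersion = np.broadcast_to(np.asarray(dispersion, float),
                                          (len(self.gene_ids),)).copy()
        self.converged = converged
        self.iterations = iterations
        self.pearson_X2 = pearson_X2
        self.design = design
        self.degenerate = (np.zeros(len(self.gene_ids), bool)
                           if degenerate is None else degenerate)

    @property
    def df(self) -> int:
        return self.design.n - self.design.p

    @property
    def df_resid(self) -> int:
        return self.design.n - self.design.p - 1

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __getitem__(self, g: int) -> GeneFit:
        return GeneFit(
            gene_id=str(self.gene_ids[g]), coefficients=self.beta[g],
            fitted=self.fitted[g], family=self.family,
            dispersion_used=float(self.dispersion[g]),
            converged=bool(self.converged[g]), iterations=int(self.iterations[g]),
            pearson_X2=float(self.pearson_X2[g]), df=self.df,
            df_resid=self.df_resid, degenerate=bool(self.degenerate[g]),
        )

    def __iter__(self) -> Iterator[GeneFit]:
        return (self[g] for g in range(len(self)))

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(self.beta, columns=self.design.columns,
                           index=pd.Index(self.gene_ids, name="gene_id"))
        out["dispersion"] = self.dispersion
        out["pearson_X2"] = self.pearson_X2
        out["df"] = self.df
        out["converged"] = self.converged
        return out


def _irls(Y: np.ndarray, X: np.ndarray, offset: np.ndarray, phi: np.ndarray,
          max_iter: int = 50, tol: float = 1e-8):
    """Batched Fisher scoring; returns (beta, mu, converged, iterations)."""
    G, n = Y.shape
    q = X.shape[1]
    phi = phi[:, None]

    mu = np.maximum(Y, 0) + 0.5
    eta = np.log(mu)
    beta = np.zeros((G, q))
    dev = _deviance(Y, mu, phi)
    converged = np.zeros(G, bool)
    iterations = np.zeros(G, int)
    eye = np.eye(q)

    for it in range(1, max_iter + 1):
        w = np.maximum(mu / (1.0 + phi * mu), _W_FLOOR)
        z = (eta - offset) + (Y - mu) / mu
        xtwx = np.einsum("gn,ni,nj->gij", w, X, X, optimize=True)
        xtwz = np.einsum("gn,ni->gi", w * z, X, optimize=True)
        # tiny ridge keeps degenerate (all-zero) genes solvable
        scale = np.trace(xtwx, axis1=1, axis2=2)[:, None, None] / q
        beta = np.linalg.solve(xtwx + 1e-12 * scale * eye, xtwz[..., None])[..., 0]
        eta = np.clip(beta @ X.T + offset, -ETA_CLAMP, ETA_CLAMP)
        mu = np.exp(eta)
        new_dev = _deviance(Y, mu, phi)
        just = ~converged & (np.abs(new_dev - dev) <= tol * (np.abs(new_dev) + 0.1))
        iterations[~converged] = it
        converged |= just
        dev = new_dev
        if converged.all():
            break
    return beta, mu, converged, iterations


def _deviance(Y, mu, phi) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        ylogy = np.where(Y > 0, Y * np.log(np.maximum(Y, 1) / mu), 0.0)
        r = 1.0 / np.maximum(phi, 1e-300)
        nb_tail = np.where(phi > 0,
                           -(Y + r) * np.log((Y + r) / (mu + r)), -(Y - mu))
    return 2.0 * (ylogy + nb_tail).sum(axis=1)


def pearson_statistic(Y, mu, family: str, dispersion) -> np.ndarray:
    """Sum over samples of (y - yhat)^2 / Var(yhat) with the family variance."""
    disp = np.asarray(dispersion, float).reshape(-1, 1)
    if family == "poisson":
        var = mu
    elif family == "od_poisson":
        var = disp * mu
    elif family == "nb":
        var = mu + disp * mu**2
    else:
        raise ValueError(f"unknown family {family!r}")
    num = (Y - mu) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(num == 0, 0.0, num / var)
    # a clamped-to-zero fitted mean with an observed zero contributes nothing
    contrib = np.where((Y == 0) & (mu <= 1e-8), 0.0, contrib)
    contrib = np.where((var == 0) & (num > 0), np.inf, contrib)
    return contrib.sum(axis=1)


def fit_all(matrix, design: DesignInfo, offsets: np.ndarray | None = None,
            family: str = "poisson", phi=0.0,
            max_iter: int = 50, tol: float = 1e-8) -> FitBatch:
    """Fit every gene of a CountMatrix (or a plain genes x n array) at once.

    ``phi`` is a scalar or per-gene vector of fixed NB dispersions (ignored
    for poisson; for od_poisson the scale k is estimated from the Poisson
    Pearson statistic after the fit).  Per-gene failures are flagged, never
    raised.
    """
    Y = np.asarray(getattr(matrix, "counts", matrix), float)
    gene_ids = getattr(matrix, "gene_ids", np.arange(Y.shape[0]))
    G, n = Y.shape
    if design.matrix.shape[0] != n:
        raise ValueError("design rows do not match sample count")
    offset = np.zeros(n) if offsets is None else np.asarray(offsets, float)
    if offset.shape != (n,):
        raise ValueError("offsets must be one value per sample")

    phi_vec = np.broadcast_to(np.asarray(phi, float), (G,)).copy()
    if family != "nb":
        phi_fit = np.zeros(G)
    else:
        if (phi_vec < 0).any():
            raise ValueError("phi must be >= 0 for the NB family")
        phi_fit = phi_vec
    beta, mu, converged, iterations = _irls(Y, design.matrix, offset, phi_fit,
                                            max_iter=max_iter, tol=tol)
    degenerate = Y.sum(axis=1) == 0

    if family == "od_poisson":
        x2_pois = pearson_statistic(Y, mu, "poisson", 0.0)
        df_resid = max(n - design.matrix.shape[1], 1)
        k = np.maximum(x2_pois / df_resid, _W_FLOOR)
        x2 = pearson_statistic(Y, mu, "od_poisson", k)
        dispersion = k
    elif family == "nb":
        x2 = pearson_statistic(Y, mu, "nb", phi_fit)
        dispersion = phi_fit
    else:
        x2 = pearson_statistic(Y, mu, "poisson", 0.0)
        dispersion = np.zeros(G)

    return FitBatch(gene_ids, beta, mu, family, dispersion, converged,
                    iterations, x2, design, degenerate=degenerate)


def fit_gene(y, design: DesignInfo, offsets=None, family: str = "poisson",
             phi_fixed: float = 0.0, **kw) -> GeneFit:
    """Single-gene convenience wrapper around :func:`fit_all`."""
    y = np.asarray(y, float)[None, :]
    return fit_all(y, design, offsets, family=family, phi=phi_fixed, **kw)[0]


def collect_blocking_effects(fits: FitBatch, factor: str,
                             run_order: list | None = None) -> pd.DataFrame:
    """Per-gene contrast coefficients for each non-reference blocking level.

    Columns are ordered by ``run_order`` (default: sorted level labels), so a
    depth-regime shift shows up as a step in the column medians.
    """
    prefix = f"{factor}["
    cols = [c for c in fits.design.columns if c.startswith(prefix)]
    if not cols:
        raise ValueError(f"fits do not include blocking factor {factor!r}")
    idx = [fits.design.columns.index(c) for c in cols]
    out = pd.DataFrame(fits.beta[:, idx], columns=[c[len(prefix):-1] for c in cols],
                       index=pd.Index(fits.gene_ids, name="gene_id"))
    if run_order is not None:
        keep = [lev for lev in run_order if lev in out.columns]
        out = out[keep]
    return out
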