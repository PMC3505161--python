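"""Per-sample normalization constants and GLM offsets.

Sequencing depth differs across lanes/lane-pairs, so modelled counts are
treated as rates via an offset: a linear-predictor term with coefficient
fixed at 1, equal to the log of a per-sample normalization constant.  Two
constants are provided — the total count, and the 75th-percentile
(upper-quartile) count, which is robust to a handful of very high-count
genes dominating the total.  Offsets are centred by the mean log-constant so
the intercept stays on the count scale; centring provably does not change
fitted-mean ratios or Pearson statistics (the intercept absorbs it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .countio import CountMatrix


@dataclass
class NormResult:
    method: str                 # none | total | upper_quartile
    constants: pd.Series        # per-sample, strictly positive
    offsets: pd.Series          # log constants, centred

    def __post_init__(self) -> None:
        if (self.constants <= 0).any():
            bad = self.constants.index[self.constants <= 0].tolist()
            raise ValueError(f"non-positive normalization constant for {bad}")
        if not np.isfinite(self.offsets).all():
            raise ValueError("non-finite offsets")


def _offsets_from(constants: pd.Series) -> pd.Series:
    logc = np.log(constants)
    return logc - logc.mean()


def none_norm(matrix: CountMatrix) -> NormResult:
    """No normalization: unit constants, zero offsets."""
    ones = pd.Series(1.0, index=list(matrix.sample_ids))
    return NormResult("none", ones, ones * 0.0)


def total_count(matrix: CountMatrix) -> NormResult:
    """Per-sample total count as the normalization constant."""
    totals = matrix.counts.sum(axis=0).astype(float)
    if (totals <= 0).any():
        bad = [s for s, t in zip(matrix.sample_ids, totals) if t <= 0]
        raise ValueError(f"all-zero sample(s): {bad}")
    constants = pd.Series(totals, index=list(matrix.sample_ids))
    return NormResult("total", constants, _offsets_from(constants))


def upper_quartile(matrix: CountMatrix) -> NormResult:
    """Nearest-rank 75th-percentile count over dataset-expressed genes.

    Restriction to genes observed somewhere in the dataset keeps the
    constant from collapsing to 0 when many genes are silent everywhere;
    should a sample's 75th-percentile still be 0, its smallest positive
    count is used with a warning.
    """
    expressed = matrix.counts.sum(axis=1) >= 1
    if not expressed.any():
        raise ValueError("no expressed genes in matrix")
    sub = matrix.counts[expressed]
    m = sub.shape[0]
    rank = int(np.ceil(0.75 * m))        # 1-based nearest-rank
    constants = {}
    for j, sample in enumerate(matrix.sample_ids):
        col = np.sort(sub[:, j])
        c = float(col[rank - 1])
        if c <= 0:
            positive = col[col > 0]
            if positive.size == 0:
                raise ValueError(f"sample {sample!r} has no positive counts")
            warnings.warn(f"sample {sample!r}: zero upper quartile; "
                          "falling back to smallest positive count")
            c = float(positive[0])
        constants[sample] = c
    constants = pd.Series(constants, index=list(matrix.sample_ids))
    return NormResult("upper_quartile", constants, _offsets_from(constants))


METHODS = {"none": none_norm, "total": total_count, "upper_quartile": upper_quartile}


def normalize(matrix: CountMatrix, method: str) -> NormResult:
    try:
        return METHODS[method](matrix)
    except KeyError:
        raise ValueError(f"unknown normalization method {method!r}") from None


def make_offsets(result: NormResult, sample_ids=None) -> np.ndarray:
    """Offset vector (aligned to ``sample_ids`` if given) for the GLM engine."""
    if sample_ids is None:
        return result.offsets.to_numpy(float)
    return result.offsets.reindex(list(sample_ids)).to_numpy(float)
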