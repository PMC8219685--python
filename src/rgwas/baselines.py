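"""Conventional phenotype robustifications used as comparators.

Two standard pre-processing rules, each feeding the same LMM scan as
the beta-divergence modification: the 7-sigma rule, which *removes*
observations outside mean +- 7 SD, and the rank-based inverse-normal
transformation (INT), which maps the trait onto standard-normal
quantiles while preserving order and sample size.  Both treat the
trait as unimodal, which is exactly where they fall short on
genotype-group-structured phenotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import PhenotypeVector

__all__ = ["TransformRecord", "sigma7_filter", "inverse_normal_transform"]


@dataclass
class TransformRecord:
    """What a baseline robustification did to the phenotype."""

    method: str
    n_before: int
    n_after: int
    removed_indices: np.ndarray | None = None
    offset: float | None = None  # INT rank offset


def sigma7_filter(y, n_sigma: float = 7.0
                  ) -> tuple[np.ndarray | PhenotypeVector, TransformRecord]:
    """Remove observations outside mean +- ``n_sigma`` sample SDs.

    Mean and SD come from the full (possibly contaminated) vector, as
    the rule is conventionally applied.  Retained values are returned
    bit-identical; the caller must drop genotype rows in lockstep using
    ``record.removed_indices``.  Zero variance returns the input
    unchanged with a warning.
    """
    pheno = y if isinstance(y, PhenotypeVector) else None
    yv = y.values if pheno is not None else np.asarray(y, float)
    n = yv.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    sd = float(np.std(yv))
    if sd == 0:
        warnings.warn("zero variance; 7-sigma filter is the identity",
                      stacklevel=2)
        removed = np.array([], dtype=int)
    else:
        center = float(np.mean(yv))
        removed = np.flatnonzero(np.abs(yv - center) > n_sigma * sd)
    keep = np.setdiff1d(np.arange(n), removed)
    record = TransformRecord("sigma7", n, keep.size, removed_indices=removed)
    if pheno is not None:
        return PhenotypeVector(pheno.individual_ids[keep], yv[keep]), record
    return yv[keep].copy(), record


def inverse_normal_transform(y, offset: float = 3.0 / 8.0
                             ) -> tuple[np.ndarray | PhenotypeVector,
                                        TransformRecord]:
    """Rank-based inverse-normal transformation (Blom offset by default).

    y_i -> Phi^-1((r_i - c) / (n - 2c + 1)) with average ranks for ties;
    order-preserving, n-preserving, and invariant to strictly monotone
    transformations of the input.
    """
    pheno = y if isinstance(y, PhenotypeVector) else None
    yv = y.values if pheno is not None else np.asarray(y, float)
    n = yv.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    ranks = stats.rankdata(yv, method="average")
    z = stats.norm.ppf((ranks - offset) / (n - 2.0 * offset + 1.0))
    record = TransformRecord("int", n, n, offset=offset)
    if pheno is not None:
        return pheno.with_values(z), record
    return z, record
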