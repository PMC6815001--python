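"""Mahalanobis whitening of multi-trait Z-scores.

Traits measured on the same cohort are correlated — partly through sample
overlap, partly through genuine trait-level (vertical) causal structure.
Under the null of no horizontal pleiotropy a variant's row of Z-scores is
multivariate normal N(0, Σ) with Σ the trait–trait correlation. Whitening
by the symmetric inverse square root,

    Z = Σ̃^(−1/2) · Z_raw,

removes that correlation so that downstream scores can treat traits as
independent standard-normal coordinates. Σ̃ is estimated empirically from
the Z columns, optionally on an LD-pruned variant subset so that linked
variants do not dominate the estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SummaryMatrix
from .ld import PairwiseLD

__all__ = [
    "TraitCorrelationModel",
    "WhitenedMatrix",
    "estimate_correlation",
    "inverse_sqrt",
    "whiten",
    "prune_by_r2",
]

#: Default relative eigenvalue floor (fraction of the largest eigenvalue).
DEFAULT_EIGEN_FLOOR = 1e-6


@dataclass
class TraitCorrelationModel:
    """Estimated trait–trait correlation Σ̃ of Z-scores.

    ``sigma`` is symmetric with unit diagonal; ``near_singular`` flags an
    off-diagonal entry at ±1 (duplicated traits), which the eigenvalue floor
    in :func:`inverse_sqrt` keeps invertible.
    """

    sigma: np.ndarray
    trait_ids: pd.Index
    estimation_strategy: str = "all_variants"
    n_variants_used: int = 0
    eigen_floor: float = DEFAULT_EIGEN_FLOOR
    near_singular: bool = False

    def __post_init__(self) -> None:
        s = np.asarray(self.sigma, dtype=float)
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError("sigma must be square")
        if not np.allclose(s, s.T, atol=1e-12):
            raise ValueError("sigma must be symmetric")
        if not np.allclose(np.diag(s), 1.0, atol=1e-9):
            raise ValueError("sigma diagonal must be 1")
        self.sigma = s
        off = s - np.eye(len(s))
        if np.any(np.abs(off) > 1.0 - 1e-10):
            self.near_singular = True

    @property
    def n_traits(self) -> int:
        return self.sigma.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.sigma, index=self.trait_ids, columns=self.trait_ids)

    def save(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def load(cls, path: str, **kw) -> "TraitCorrelationModel":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(float), pd.Index(df.columns), **kw)


@dataclass
class WhitenedMatrix:
    """Whitened Z-scores with the correlation model that produced them."""

    z: np.ndarray
    variants: pd.DataFrame
    traits: pd.DataFrame
    model: TraitCorrelationModel

    @property
    def n_variants(self) -> int:
        return self.z.shape[0]

    @property
    def n_traits(self) -> int:
        return self.z.shape[1]

    @property
    def variant_ids(self) -> pd.Index:
        return self.variants.index

    @property
    def trait_ids(self) -> pd.Index:
        return self.traits.index


def estimate_correlation(
    m: SummaryMatrix,
    strategy: str = "all_variants",
    prune_index=None,
) -> TraitCorrelationModel:
    """Estimate Σ̃ as the Pearson correlation of Z columns.

    With ``strategy="pruned_variants"`` the correlation is computed over the
    variant subset ``prune_index`` (ids or boolean/positional mask) so LD
    does not inflate the effective weight of clustered variants. The result
    is symmetrized and its diagonal set to exactly 1.
    """
    if strategy not in ("all_variants", "pruned_variants"):
        raise ValueError(f"unknown strategy {strategy!r}")
    z = m.z
    if strategy == "pruned_variants":
        if prune_index is None or len(prune_index) == 0:
            raise ValueError("pruned_variants strategy requires a nonempty prune_index")
        arr = np.asarray(prune_index)
        if arr.dtype == bool or np.issubdtype(arr.dtype, np.integer):
            z = z[arr]
        else:
            rows = m.variant_ids.get_indexer(prune_index)
            if (rows < 0).any():
                raise KeyError("prune_index contains unknown variant ids")
            z = z[rows]
    if z.shape[0] < 2:
        raise ValueError("need at least 2 variants to estimate a correlation")
    sd = z.std(axis=0)
    zero = np.flatnonzero(sd == 0.0)
    if zero.size:
        raise ValueError(
            f"zero-variance Z column for trait(s) {list(m.trait_ids[zero])}"
        )
    sigma = np.corrcoef(z, rowvar=False)
    sigma = (sigma + sigma.T) / 2.0
    np.fill_diagonal(sigma, 1.0)
    return TraitCorrelationModel(
        sigma,
        trait_ids=m.trait_ids,
        estimation_strategy=strategy,
        n_variants_used=z.shape[0],
    )


def inverse_sqrt(sigma: np.ndarray, eigen_floor: float = DEFAULT_EIGEN_FLOOR):
    """Symmetric inverse square root Σ^(−1/2) via eigendecomposition.

    Eigenvalues below ``eigen_floor`` × (largest eigenvalue) are raised to
    that floor before inversion, so near-singular correlation matrices
    (e.g. duplicated traits that escaped QC) stay invertible.

    Returns
    -------
    (matrix, floored):
        The symmetric inverse square root and a flag telling whether any
        eigenvalue was floored (in which case M·Σ·M ≠ I).
    """
    sigma = np.asarray(sigma, dtype=float)
    if not np.allclose(sigma, sigma.T, atol=1e-8):
        raise ValueError("matrix is not symmetric")
    if eigen_floor <= 0:
        raise ValueError("eigen_floor must be > 0")
    vals, vecs = np.linalg.eigh((sigma + sigma.T) / 2.0)
    floor = eigen_floor * float(vals.max())
    floored = bool((vals < floor).any())
    vals = np.maximum(vals, floor)
    m = (vecs / np.sqrt(vals)) @ vecs.T
    return (m + m.T) / 2.0, floored


def whiten(m: SummaryMatrix, model: TraitCorrelationModel) -> WhitenedMatrix:
    """Apply Z = Σ̃^(−1/2)·Z_raw to every variant's trait vector."""
    if model.n_traits != m.n_traits:
        raise ValueError(
            f"model has {model.n_traits} traits but matrix has {m.n_traits}"
        )
    if not model.trait_ids.equals(m.trait_ids):
        raise ValueError("model trait ids do not match matrix trait ids")
    if np.array_equal(model.sigma, np.eye(model.n_traits)):
        # identity model: the transform is the identity map, bit for bit
        return WhitenedMatrix(m.z.copy(), m.variants, m.traits, model)
    w, _ = inverse_sqrt(model.sigma, model.eigen_floor)
    # rows are variant vectors; W is symmetric so z_i ← W z_i is z @ W
    return WhitenedMatrix(m.z @ w, m.variants, m.traits, model)


def prune_by_r2(
    pairwise: PairwiseLD, variant_ids, threshold: float = 0.1
) -> list:
    """Greedy LD pruning: scan in position order, keep a variant iff its r²
    with every previously kept variant is below ``threshold``.

    ``variant_ids`` must be in position order; only pairs represented in the
    pairwise structure (same block / recorded pair) can exclude a variant.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    kept: set = set()
    out = []
    for v in variant_ids:
        ok = True
        for u, r2 in pairwise.neighbors(v):
            if u in kept and r2 >= threshold:
                ok = False
                break
        if ok:
            kept.add(v)
            out.append(v)
    return out
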