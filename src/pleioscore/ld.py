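"""Linkage-disequilibrium containers: per-variant LD scores and pairwise r².

Two kinds of LD information are used downstream:

* the *LD score* of a variant, ``ℓ_i = Σ_j r²_ij`` over its neighbourhood,
  which the score correction regresses on; and
* pairwise ``r²`` between variants, needed for pruning (correlation-matrix
  estimation) and for clumping score hits into loci.

Pairwise structure is represented sparsely: either as an analytic AR(1)
block model (:class:`BlockLD`, produced by the simulator) or as an explicit
table of pairs (:class:`SparseLD`). Pairs absent from either structure are
treated as unlinked (r² = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = ["PairwiseLD", "BlockLD", "SparseLD", "LDProfile"]


class PairwiseLD:
    """Interface for sparse pairwise r² lookup."""

    def r2(self, a: str, b: str) -> float:
        raise NotImplementedError

    def neighbors(self, a: str) -> Iterator[tuple[str, float]]:
        """Yield ``(variant_id, r²)`` for variants potentially linked to *a*.

        Variants not yielded have r² = 0 with *a* by construction.
        """
        raise NotImplementedError


class BlockLD(PairwiseLD):
    """Block-diagonal AR(1) LD: r_ij = rho^|i−j| within a block, 0 across.

    Parameters
    ----------
    variant_ids:
        Variant identifiers in position order.
    block_size:
        Either a fixed number of consecutive variants per block (the last
        block may be short), or a sequence of block lengths that is cycled
        until all variants are covered — heterogeneous block lengths give a
        realistic spread of LD scores.
    rho:
        AR(1) correlation between adjacent variants, in [0, 1).
    """

    def __init__(self, variant_ids, block_size, rho: float):
        if not 0.0 <= rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        self.variant_ids = pd.Index(variant_ids)
        if self.variant_ids.has_duplicates:
            raise ValueError("duplicate variant ids in LD structure")
        self.rho = float(rho)
        n = len(self.variant_ids)
        if np.isscalar(block_size):
            if block_size < 1:
                raise ValueError("block_size must be >= 1")
            self.block_size = int(block_size)
            sizes = [self.block_size] * (n // self.block_size)
            if n % self.block_size:
                sizes.append(n % self.block_size)
        else:
            pattern = [int(s) for s in block_size]
            if not pattern or min(pattern) < 1:
                raise ValueError("block sizes must be positive")
            self.block_size = pattern
            sizes, total = [], 0
            i = 0
            while total < n:
                s = min(pattern[i % len(pattern)], n - total)
                sizes.append(s)
                total += s
                i += 1
        self._starts = np.concatenate([[0], np.cumsum(sizes)])  # len n_blocks+1
        self._block_id = np.repeat(np.arange(len(sizes)), sizes)
        self._pos = {v: i for i, v in enumerate(self.variant_ids)}

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def block_sizes(self) -> np.ndarray:
        return np.diff(self._starts).astype(int)

    def _block_of(self, i: int) -> int:
        return int(self._block_id[i])

    def _block_range(self, i: int) -> tuple[int, int]:
        b = self._block_id[i]
        return int(self._starts[b]), int(self._starts[b + 1])

    def r2(self, a: str, b: str) -> float:
        ia, ib = self._pos.get(a), self._pos.get(b)
        if ia is None or ib is None:
            return 0.0
        if self._block_id[ia] != self._block_id[ib]:
            return 0.0
        return self.rho ** (2 * abs(ia - ib))

    def neighbors(self, a: str) -> Iterator[tuple[str, float]]:
        ia = self._pos.get(a)
        if ia is None:
            return
        lo, hi = self._block_range(ia)
        for j in range(lo, hi):
            if j != ia:
                yield self.variant_ids[j], self.rho ** (2 * abs(ia - j))

    def ld_scores(self) -> pd.Series:
        """Exact LD scores ℓ_i = Σ_j r²_ij (including the variant itself)."""
        n = self.n_variants
        ell = np.empty(n)
        r2 = self.rho**2
        for i in range(n):
            lo, hi = self._block_range(i)
            offs = np.abs(np.arange(lo, hi) - i)
            ell[i] = np.sum(r2**offs)
        return pd.Series(ell, index=self.variant_ids, name="L2")

    def correlation_block(self, size: int) -> np.ndarray:
        """Dense AR(1) correlation matrix for a block of the given size."""
        idx = np.arange(size)
        return self.rho ** np.abs(idx[:, None] - idx[None, :])


class SparseLD(PairwiseLD):
    """Pairwise r² stored as an explicit symmetric table of pairs."""

    def __init__(self, pairs: dict[tuple[str, str], float] | None = None):
        self._adj: dict[str, dict[str, float]] = {}
        for (a, b), v in (pairs or {}).items():
            self.add(a, b, v)

    def add(self, a: str, b: str, r2: float) -> None:
        if a == b:
            return
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"r² must be in [0, 1], got {r2}")
        self._adj.setdefault(a, {})[b] = r2
        self._adj.setdefault(b, {})[a] = r2

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._adj.get(a, {}).get(b, 0.0)

    def neighbors(self, a: str) -> Iterator[tuple[str, float]]:
        yield from self._adj.get(a, {}).items()


@dataclass
class LDProfile:
    """Per-variant LD scores, optionally with the pairwise structure behind them.

    Attributes
    ----------
    scores:
        LD score ℓ per variant, indexed by variant id.
    zero_variance:
        True when ℓ is constant across variants — the LD regression is then
        undefined and correction must be skipped.
    pairwise:
        Optional pairwise r² structure (for pruning / clumping).
    """

    scores: pd.Series
    zero_variance: bool = False
    pairwise: PairwiseLD | None = None

    def __post_init__(self) -> None:
        self.scores = pd.Series(self.scores, dtype=float)
        if self.scores.index.has_duplicates:
            raise ValueError("duplicate variant ids in LD profile")
        if len(self.scores) and float(self.scores.dropna().var()) == 0.0:
            self.zero_variance = True

    def reindex(self, variant_ids) -> "LDProfile":
        """Align to a variant universe; missing variants get NaN ℓ."""
        return LDProfile(
            self.scores.reindex(variant_ids), pairwise=self.pairwise
        )
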