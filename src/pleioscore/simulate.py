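"""Synthetic multi-trait GWAS summary statistics with known pleiotropy.

The generator draws a variants × traits Z-score matrix under a null-plus-
signal model with three layers:

1. Causal architecture. A fraction ``prop_pleio`` of variants is pleiotropic:
   each is causal for a uniformly random subset of ``nu`` traits. Separately
   and independently per trait, a fraction ``prop_nonpleio`` of the remaining
   variants is causal for that trait alone. Causal (variant, trait) pairs
   receive a latent standardized effect μ ~ N(0, effective_n·h²): ``h2`` is
   the per-variant heritability contributed to each affected trait and
   ``effective_n`` the GWAS sample-size scale that turns it into a Z-score
   non-centrality, so a causal Z has marginal variance 1 + effective_n·h².
   (A ``literal`` mode instead draws causal Z directly from N(0, h²),
   reproducing a common shorthand in which the causal variance *replaces*
   the null variance; with h² ≤ 0.2 such "causal" variants are statistically
   quieter than null ones, so the default is the non-centrality convention.)
2. Linkage disequilibrium. Variants sit in consecutive AR(1) blocks of size
   ``ld_block_size`` with neighbour correlation ``ld_rho``: observed
   Z = R·μ + R^{1/2}·ε per block, the standard summary-statistics model in
   which a variant tags its neighbours' effects while null marginal variance
   stays 1. LD scores ℓ are computed exactly from R.
3. Trait correlation. Optionally, trait columns are mixed by the Cholesky
   factor of a random factor-model correlation matrix, emulating the
   correlated traits (vertical pleiotropy) that whitening must remove.

Default parameter values are the headline simulation conditions: 100 traits,
h² = 0.002, 0.1% pleiotropic variants each affecting ν = 10 traits, no
non-pleiotropic causal variants, effective_n = 10,000.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import SummaryMatrix, _empty_trait_meta, _empty_variant_meta
from .ld import BlockLD, LDProfile

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "make_ld_structure",
    "assign_causal",
    "simulate_zscores",
    "simulate_dataset",
    "factor_model_correlation",
    "evaluate_detection",
]


@dataclass
class SimulationConfig:
    """Parameters of one simulation scenario.

    The grid studied with this generator crosses h² ∈ {0.0002, 0.002, 0.02,
    0.2}, pleiotropic fraction {0.1%, 1%}, non-pleiotropic fraction
    {0, 0.1%, 1%}, ν ∈ {10, 20}, and trait correlation absent/present.
    """

    n_variants: int = 100_000
    n_traits: int = 100
    h2: float = 0.002
    prop_pleio: float = 0.001
    prop_nonpleio: float = 0.0
    nu: int = 10
    effective_n: float = 10_000.0
    ld_block_size: int = 1
    ld_rho: float = 0.0
    trait_corr: str = "identity"  # or "factor_model"
    n_factors: int = 5
    literal: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1 or self.n_traits < 1:
            raise ValueError("n_variants and n_traits must be positive")
        if not 0.0 <= self.prop_pleio <= 1.0 or not 0.0 <= self.prop_nonpleio <= 1.0:
            raise ValueError("causal proportions must be in [0, 1]")
        if not 1 <= self.nu <= self.n_traits:
            raise ValueError("nu must be in [1, n_traits]")
        if self.h2 < 0 or self.effective_n <= 0:
            raise ValueError("h2 must be >= 0 and effective_n > 0")
        if self.trait_corr not in ("identity", "factor_model"):
            raise ValueError("trait_corr must be 'identity' or 'factor_model'")


@dataclass
class SimulationTruth:
    """Ground-truth causal labels for one simulated dataset."""

    pleiotropic: np.ndarray  # bool (n_variants,)
    causal_mask: np.ndarray  # bool (n_variants, n_traits)
    noncentrality_sd: float  # sd of latent causal effects (0 in literal mode)

    @property
    def causal_traits(self) -> list[set[int]]:
        return [set(np.flatnonzero(row)) for row in self.causal_mask]

    def to_frame(self, variant_ids) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": np.asarray(variant_ids),
                "pleiotropic": self.pleiotropic,
                "causal_traits": [
                    ",".join(map(str, sorted(np.flatnonzero(r))))
                    for r in self.causal_mask
                ],
            }
        )


def _variant_ids(n: int) -> pd.Index:
    return pd.Index([f"v{i}" for i in range(n)], name="variant_id")


def make_ld_structure(
    n_variants: int, block_size: int = 1, rho: float = 0.0
) -> LDProfile:
    """Block-diagonal AR(1) LD with exact LD scores ℓ_i = Σ_j rho^(2|i−j|)."""
    block = BlockLD(_variant_ids(n_variants), block_size, rho)
    return LDProfile(block.ld_scores(), pairwise=block)


def assign_causal(config: SimulationConfig) -> SimulationTruth:
    """Draw the causal architecture for one scenario.

    Exactly ``round(prop_pleio·n_variants)`` pleiotropic variants are chosen
    globally, each causal for a uniform random ν-subset of traits;
    independently per trait, ``round(prop_nonpleio·n_variants)`` additional
    causal variants are drawn from the non-pleiotropic variants (from all
    variants in literal mode, where overlap is permitted).
    """
    rng = np.random.default_rng(config.seed)
    n, l = config.n_variants, config.n_traits
    n_pleio = int(round(config.prop_pleio * n))
    n_non = int(round(config.prop_nonpleio * n))
    if n_pleio > n:
        raise ValueError("more pleiotropic variants than variants")

    pleio = np.zeros(n, dtype=bool)
    mask = np.zeros((n, l), dtype=bool)
    pleio_idx = rng.choice(n, size=n_pleio, replace=False)
    pleio[pleio_idx] = True
    for i in pleio_idx:
        mask[i, rng.choice(l, size=config.nu, replace=False)] = True

    pool = np.arange(n) if config.literal else np.flatnonzero(~pleio)
    if n_non > len(pool):
        raise ValueError("not enough non-pleiotropic variants for prop_nonpleio")
    for t in range(l):
        mask[rng.choice(pool, size=n_non, replace=False), t] = True

    ncp_sd = (
        0.0 if config.literal else float(np.sqrt(config.effective_n * config.h2))
    )
    return SimulationTruth(pleiotropic=pleio, causal_mask=mask, noncentrality_sd=ncp_sd)


def _propagate_ld(
    noise: np.ndarray, mu: np.ndarray | None, block: BlockLD
) -> np.ndarray:
    """Observed Z = R·μ + R^{1/2}·ε per LD block, vectorized by block size."""
    sizes = block.block_sizes
    starts = block._starts
    out = np.empty_like(noise)
    for s in np.unique(sizes):
        r = block.correlation_block(int(s))
        vals, vecs = np.linalg.eigh(r)
        r_half = (vecs * np.sqrt(np.maximum(vals, 0.0))) @ vecs.T
        which = np.flatnonzero(sizes == s)
        rows = (starts[which][:, None] + np.arange(s)[None, :]).ravel()
        chunk = (r_half @ noise[rows].reshape(len(which), s, -1))
        if mu is not None:
            chunk = chunk + r @ mu[rows].reshape(len(which), s, -1)
        out[rows] = chunk.reshape(len(rows), -1)
    return out


def factor_model_correlation(
    l: int, n_factors: int, rng: np.random.Generator
) -> np.ndarray:
    """Random correlation matrix Σ = D^{-1/2}(ΛΛᵀ + I)D^{-1/2}, Λ Gaussian."""
    lam = rng.normal(size=(l, max(1, n_factors)))
    m = lam @ lam.T + np.eye(l)
    d = np.sqrt(np.diag(m))
    sigma = m / np.outer(d, d)
    np.fill_diagonal(sigma, 1.0)
    return sigma


def simulate_zscores(
    config: SimulationConfig,
    truth: SimulationTruth,
    ld: LDProfile | None = None,
) -> SummaryMatrix:
    """Draw the observed Z-score matrix given a causal architecture.

    Per trait column: Z = R·μ + R^{1/2}·ε with μ the latent causal effects
    and R the block AR(1) LD correlation (identity when no LD); then
    optional trait mixing Z ← Z·Aᵀ with AAᵀ the factor-model trait
    correlation. Null entries have marginal variance exactly 1.
    """
    rng = np.random.default_rng(config.seed + 1)
    n, l = config.n_variants, config.n_traits

    if config.literal:
        # shorthand mode: causal Z drawn from N(0, h²) in place of N(0, 1)
        z = rng.normal(size=(n, l))
        z[truth.causal_mask] *= np.sqrt(config.h2)
        base_mu = None
    else:
        z = rng.normal(size=(n, l))
        base_mu = np.zeros((n, l))
        idx = np.nonzero(truth.causal_mask)
        base_mu[idx] = rng.normal(scale=truth.noncentrality_sd, size=len(idx[0]))

    has_ld = config.ld_rho > 0.0 and np.max(config.ld_block_size) > 1
    if has_ld:
        block = (
            ld.pairwise
            if ld is not None and isinstance(ld.pairwise, BlockLD)
            else BlockLD(_variant_ids(n), config.ld_block_size, config.ld_rho)
        )
        z = _propagate_ld(z, base_mu, block)
    elif base_mu is not None:
        z += base_mu

    if config.trait_corr == "factor_model":
        sigma = factor_model_correlation(l, config.n_factors, rng)
        a = np.linalg.cholesky(sigma)
        z = z @ a.T

    variants = _empty_variant_meta(_variant_ids(n))
    variants["chr"] = "1"
    variants["pos"] = np.arange(1, n + 1, dtype=int)
    traits = _empty_trait_meta([f"t{j}" for j in range(l)])
    return SummaryMatrix(z, variants, traits)


def simulate_dataset(config: SimulationConfig):
    """Convenience wrapper: LD structure + causal truth + Z matrix.

    Returns ``(SummaryMatrix, SimulationTruth, LDProfile)``.
    """
    ld = make_ld_structure(config.n_variants, config.ld_block_size, config.ld_rho)
    truth = assign_causal(config)
    m = simulate_zscores(config, truth, ld)
    return m, truth, ld


def evaluate_detection(
    table: pd.DataFrame,
    truth: SimulationTruth,
    alpha: float = 0.05,
    p_columns: tuple[str, ...] = ("p_m", "p_n"),
) -> pd.DataFrame:
    """Power and false-positive rate of each P-value flavour at level alpha.

    Power is the detected fraction of truly pleiotropic variants; FPR the
    detected fraction of all others, including non-pleiotropic causal
    variants (which are causal, but not *pleiotropic*).
    """
    if len(table) != len(truth.pleiotropic):
        raise ValueError("score table and truth are not aligned")
    rows = []
    pleio = truth.pleiotropic
    for col in p_columns:
        if col not in table.columns:
            continue
        p = table[col].to_numpy(float)
        sig = p < alpha
        ok = np.isfinite(p)
        rows.append(
            {
                "p_column": col,
                "alpha": alpha,
                "power": float(sig[pleio & ok].mean()) if (pleio & ok).any() else np.nan,
                "fpr": float(sig[~pleio & ok].mean()) if (~pleio & ok).any() else np.nan,
                "n_pleiotropic": int(pleio.sum()),
                "n_other": int((~pleio).sum()),
            }
        )
    return pd.DataFrame(rows)
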