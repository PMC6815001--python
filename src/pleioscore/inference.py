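"""P values for the pleiotropy score: theoretical and permutation-based.

Theoretical null. After whitening, a non-pleiotropic variant's trait vector
is N(0, Id_l), so the squared magnitude statistic S = (l·Pm/100)² follows
χ²(l), and the trait count k = l·Pn/100 follows Binomial(l, p0) with
p0 = P(|Z| > 2) = 2Φ(−2) ≈ 0.0455. LD-corrected scores can be slightly
negative, so S clamps at 0; corrected trait counts are non-integer, and the
binomial survival is continued to real k through the regularized incomplete
beta function (which reproduces the exact binomial tail at integer k).

Empirical null. Real traits are polygenic: far more variants have real
effects than the theoretical null allows, inflating both components
genome-wide. Permuting each whitened trait column independently across
variants preserves every trait's marginal score distribution (hence its
polygenicity and inflation) while destroying cross-trait alignment — the
signature of pleiotropy. Scores recomputed on permuted data are pooled into
an empirical null; the empirical P of an observed score is the fraction of
pooled permuted scores exceeding it (with add-one smoothing so no P is
exactly 0). Empirical P values convert back to score units (Pm_P, Pn_P)
through the theoretical quantile functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .ld import LDProfile
from .scoring import (
    DEFAULT_PN_THRESHOLD,
    LDCorrection,
    score_table,
)
from .whitening import WhitenedMatrix

__all__ = [
    "DEFAULT_P0",
    "default_p0",
    "pm_theoretical_p",
    "pn_theoretical_p",
    "PermutationNull",
    "build_permutation_null",
    "empirical_p",
    "empirical_to_score",
]


def default_p0(threshold: float = DEFAULT_PN_THRESHOLD) -> float:
    """Per-trait exceedance probability P(|Z| > threshold) under N(0, 1)."""
    return float(2.0 * stats.norm.sf(threshold))


#: Exact two-sided normal tail at |z| = 2 (0.04550026…).
DEFAULT_P0 = default_p0()


def pm_theoretical_p(pm_value, l: int):
    """Upper-tail χ²(l) P value for the magnitude score.

    The statistic is S = max(l·Pm/100, 0)²; negative LD-corrected scores
    clamp to S = 0 and return P = 1. Accepts scalars or arrays.
    """
    if l < 1:
        raise ValueError("l must be >= 1")
    pm = np.asarray(pm_value, dtype=float)
    s = np.maximum(l * pm / 100.0, 0.0) ** 2
    out = stats.chi2.sf(s, df=l)
    return float(out) if np.isscalar(pm_value) else out


def _binom_sf_continuous(k, l: int, p0: float):
    """P(X ≥ k) for X ~ Binomial(l, p0), continued to real k.

    For integer k in [1, l] this equals the exact binomial survival
    I_{p0}(k, l−k+1); k ≤ 0 gives 1 and k > l gives 0.
    """
    k = np.atleast_1d(np.asarray(k, dtype=float))
    out = np.ones_like(k)
    inside = (k > 0) & (k <= l)
    out[k > l] = 0.0
    kk = k[inside]
    out[inside] = special.betainc(kk, l - kk + 1.0, p0)
    return out


def pn_theoretical_p(pn_value, l: int, p0: float = DEFAULT_P0):
    """Binomial-tail P value for the trait-count score.

    k = l·Pn/100 is clamped to [0, l]; non-integer k (LD-corrected scores)
    uses the incomplete-beta continuation of the binomial survival.
    """
    if l < 1:
        raise ValueError("l must be >= 1")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be in (0, 1)")
    pn = np.asarray(pn_value, dtype=float)
    k = np.clip(l * pn / 100.0, 0.0, float(l))
    out = _binom_sf_continuous(k, l, p0)
    return float(out[0]) if np.isscalar(pn_value) else out.reshape(pn.shape)


@dataclass
class PermutationNull:
    """Pooled permuted score distributions (sorted ascending)."""

    n_permutations: int
    seed: int
    pooled_pm: np.ndarray
    pooled_pn: np.ndarray
    pooled_pm_ld: np.ndarray | None = None
    pooled_pn_ld: np.ndarray | None = None

    def save(self, path: str) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(
                {
                    "n_permutations": self.n_permutations,
                    "seed": self.seed,
                    "pooled_pm": self.pooled_pm.tolist(),
                    "pooled_pn": self.pooled_pn.tolist(),
                    "pooled_pm_ld": None
                    if self.pooled_pm_ld is None
                    else self.pooled_pm_ld.tolist(),
                    "pooled_pn_ld": None
                    if self.pooled_pn_ld is None
                    else self.pooled_pn_ld.tolist(),
                },
                fh,
            )

    @classmethod
    def load(cls, path: str) -> "PermutationNull":
        import json

        with open(path) as fh:
            d = json.load(fh)
        return cls(
            n_permutations=d["n_permutations"],
            seed=d["seed"],
            pooled_pm=np.asarray(d["pooled_pm"], dtype=float),
            pooled_pn=np.asarray(d["pooled_pn"], dtype=float),
            pooled_pm_ld=None
            if d["pooled_pm_ld"] is None
            else np.asarray(d["pooled_pm_ld"], dtype=float),
            pooled_pn_ld=None
            if d["pooled_pn_ld"] is None
            else np.asarray(d["pooled_pn_ld"], dtype=float),
        )


def permute_columns(z: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently permute each trait column across variants."""
    out = np.empty_like(z)
    n = z.shape[0]
    for j in range(z.shape[1]):
        out[:, j] = z[rng.permutation(n), j]
    return out


def build_permutation_null(
    w: WhitenedMatrix,
    n_permutations: int = 25,
    seed: int = 0,
    ld: LDProfile | None = None,
    correction: LDCorrection | None = None,
    pn_threshold: float = DEFAULT_PN_THRESHOLD,
) -> PermutationNull:
    """Build the polygenicity-preserving permutation null.

    Each permutation shuffles every whitened trait column independently
    across variants and recomputes both score components. When an LD
    correction is supplied it is re-applied with the originally fitted β
    and each variant's own ℓ (the regression is not refitted per
    permutation), so the null keeps the data's LD-score profile.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    z = w.z
    l = z.shape[1]
    with_ld = correction is not None and ld is not None
    ell = ld.scores.reindex(w.variant_ids).to_numpy(float) if with_ld else None
    pm_all, pn_all, pm_ld_all, pn_ld_all = [], [], [], []
    for _ in range(n_permutations):
        zp = permute_columns(z, rng)
        pm = 100.0 / l * np.sqrt(np.einsum("ij,ij->i", zp, zp))
        pn = 100.0 / l * np.count_nonzero(np.abs(zp) > pn_threshold, axis=1)
        pm_all.append(pm)
        pn_all.append(pn.astype(float))
        if with_ld:
            pm_ld_all.append(pm - correction.beta_m * ell)
            pn_ld_all.append(pn - correction.beta_n * ell)
    return PermutationNull(
        n_permutations=n_permutations,
        seed=seed,
        pooled_pm=np.sort(np.concatenate(pm_all)),
        pooled_pn=np.sort(np.concatenate(pn_all)),
        pooled_pm_ld=np.sort(np.concatenate(pm_ld_all)) if with_ld else None,
        pooled_pn_ld=np.sort(np.concatenate(pn_ld_all)) if with_ld else None,
    )


def empirical_p(observed, pooled: np.ndarray):
    """Rank-based empirical P against a sorted pooled null.

    P = (1 + #{pooled > observed}) / (1 + N): the fraction of permuted
    scores strictly above the observed one, with add-one smoothing so the
    minimum attainable P is 1/(N+1) rather than 0.
    """
    pooled = np.asarray(pooled, dtype=float)
    if pooled.size == 0:
        raise ValueError("pooled null is empty")
    obs = np.asarray(observed, dtype=float)
    n_greater = pooled.size - np.searchsorted(pooled, obs, side="right")
    out = (1.0 + n_greater) / (1.0 + pooled.size)
    return float(out) if np.isscalar(observed) else out


def _binom_isf_continuous(p_emp: float, l: int, p0: float) -> float:
    """Continuous k with P(X ≥ k) = p_emp under Binomial(l, p0)."""
    if p_emp >= 1.0:
        return 0.0
    lo_tail = float(special.betainc(float(l), 1.0, p0))  # P(X >= l) = p0^l
    if p_emp <= lo_tail:
        return float(l)
    f = lambda k: float(special.betainc(k, l - k + 1.0, p0)) - p_emp
    return float(optimize.brentq(f, 1e-12, float(l), xtol=1e-12))


def empirical_to_score(
    p_emp, l: int, component: str, p0: float = DEFAULT_P0
):
    """Convert an empirical P value to the score it maps to under the
    theoretical null: Pm_P = (100/l)·sqrt(χ²(l) isf) or the binomial
    continuous inverse survival for Pn_P.
    """
    if component not in ("magnitude", "ntraits"):
        raise ValueError("component must be 'magnitude' or 'ntraits'")
    scalar = np.isscalar(p_emp)
    p = np.atleast_1d(np.asarray(p_emp, dtype=float))
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("empirical P values must be in (0, 1]")
    if component == "magnitude":
        out = 100.0 / l * np.sqrt(stats.chi2.isf(p, df=l))
    else:
        out = 100.0 / l * np.array([_binom_isf_continuous(x, l, p0) for x in p])
    return float(out[0]) if scalar else out
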