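"""Per-trait polygenicity and the stratified rescoring analysis.

Polygenicity — how much of the genome carries real signal for a trait — is
summarized by the genomic inflation factor λ_GC = median(z²)/median(χ²(1)),
corrected for confounding with the LD-score-regression intercept:

    λ_GC^c = λ_GC − (intercept − 1),

since (intercept − 1) estimates the mean confounding contribution to test-
statistic inflation while the slope on ℓ carries the polygenic part. The
stratified analysis ranks traits into heritability classes and, within each
class, into polygenicity bins; the full whitening + scoring + LD-correction
pipeline is re-run on each bin's trait subset, and the resulting per-bin
QQ curves show how score inflation grows with polygenicity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import SummaryMatrix
from .ld import LDProfile
from .pipeline import ScoreResult, score_summary_matrix

__all__ = [
    "CHI2_1_MEDIAN",
    "PolygenicityEstimate",
    "lambda_gc",
    "ldsc_fit",
    "corrected_lambda",
    "estimate_polygenicity",
    "stratify_and_rescore",
    "qq_table",
]

#: Median of the χ²(1) distribution (0.456 to three decimals).
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))


@dataclass
class PolygenicityEstimate:
    trait_id: str
    lambda_gc: float
    ldsc_intercept: float
    ldsc_slope: float
    lambda_gc_corrected: float
    heritability_proxy: float

    def __post_init__(self) -> None:
        expected = self.lambda_gc - (self.ldsc_intercept - 1.0)
        if np.isfinite(expected) and abs(self.lambda_gc_corrected - expected) > 1e-9:
            raise ValueError("lambda_gc_corrected must equal lambda_gc - (intercept - 1)")


def lambda_gc(z_column) -> float:
    """Genomic inflation factor: median(z²) over the χ²(1) median."""
    z = np.asarray(z_column, dtype=float)
    if z.size == 0:
        raise ValueError("empty Z column")
    return float(np.median(z * z) / CHI2_1_MEDIAN)


def ldsc_fit(chi2_values, ld: LDProfile) -> tuple[float, float]:
    """OLS of per-variant χ² = z² on LD score ℓ → (intercept, slope)."""
    chi2 = np.asarray(chi2_values, dtype=float)
    ell = ld.scores.to_numpy(float)
    if chi2.shape != ell.shape:
        raise ValueError("chi2 and LD scores are not aligned")
    ok = np.isfinite(ell) & np.isfinite(chi2)
    if np.var(ell[ok]) == 0.0:
        raise ValueError("LD scores have zero variance")
    fit = stats.linregress(ell[ok], chi2[ok])
    return float(fit.intercept), float(fit.slope)


def corrected_lambda(est: PolygenicityEstimate) -> float:
    """λ_GC^c = λ_GC − (LD-score-regression intercept − 1)."""
    return est.lambda_gc - (est.ldsc_intercept - 1.0)


def estimate_polygenicity(
    m: SummaryMatrix, ld: LDProfile
) -> list[PolygenicityEstimate]:
    """Per-trait λ_GC, LDSC-style fit, λ_GC^c and a heritability proxy.

    The heritability proxy is slope × n_variants — an unnormalized ranking
    device for synthetic data (the slope of χ² on ℓ scales with per-variant
    signal, so its sum over variants tracks total signal).
    """
    ell = ld.reindex(m.variant_ids)
    out = []
    for j, trait in enumerate(m.trait_ids):
        z = m.z[:, j]
        lam = lambda_gc(z)
        intercept, slope = ldsc_fit(z * z, ell)
        out.append(
            PolygenicityEstimate(
                trait_id=str(trait),
                lambda_gc=lam,
                ldsc_intercept=intercept,
                ldsc_slope=slope,
                lambda_gc_corrected=lam - (intercept - 1.0),
                heritability_proxy=slope * m.n_variants,
            )
        )
    return out


def _equal_size_groups(ordered: list[str], n_groups: int) -> list[list[str]]:
    """Split an ordered list into n_groups contiguous groups of equal size
    (remainder assigned to the last group)."""
    n = len(ordered)
    base = n // n_groups
    if base == 0:
        raise ValueError(f"cannot form {n_groups} nonempty groups from {n} traits")
    groups = [ordered[i * base : (i + 1) * base] for i in range(n_groups)]
    groups[-1].extend(ordered[n_groups * base :])
    return groups


def qq_table(p_values, bin_id: str = "") -> pd.DataFrame:
    """Observed vs expected −log10 P for a QQ plot (ascending P)."""
    p = np.sort(np.asarray(p_values, dtype=float))
    p = p[np.isfinite(p)]
    n = p.size
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    observed = -np.log10(np.maximum(p, 1e-300))
    return pd.DataFrame(
        {"expected_neglog10p": expected, "observed_neglog10p": observed,
         "bin_id": bin_id}
    )


def stratify_and_rescore(
    m: SummaryMatrix,
    estimates: list[PolygenicityEstimate],
    n_h2_classes: int = 4,
    n_poly_bins: int = 5,
    ld: LDProfile | None = None,
    **pipeline_kw,
) -> dict[tuple[int, int], dict]:
    """Heritability × polygenicity stratified rescoring.

    Traits are ranked by heritability proxy into ``n_h2_classes`` equal-size
    classes, then by λ_GC^c into ``n_poly_bins`` equal-size bins within each
    class (ties broken by trait id). The scoring pipeline is re-run
    independently on every bin's trait subset.

    Returns a dict keyed by (h2_class, poly_bin) — both ascending — with
    values ``{"traits": [...], "result": ScoreResult, "qq": DataFrame}``
    where the QQ table uses the magnitude component's theoretical P.
    """
    by_id = {e.trait_id: e for e in estimates}
    missing = [t for t in m.trait_ids if str(t) not in by_id]
    if missing:
        raise ValueError(f"no polygenicity estimate for traits: {missing}")

    ids = [str(t) for t in m.trait_ids]
    h2_order = sorted(ids, key=lambda t: (by_id[t].heritability_proxy, t))
    classes = _equal_size_groups(h2_order, n_h2_classes)

    out: dict[tuple[int, int], dict] = {}
    for ci, cls in enumerate(classes):
        poly_order = sorted(cls, key=lambda t: (by_id[t].lambda_gc_corrected, t))
        bins = _equal_size_groups(poly_order, n_poly_bins)
        for bi, traits in enumerate(bins):
            if not traits:
                raise ValueError(f"empty bin ({ci}, {bi})")
            sub = m.select_traits(traits)
            res = score_summary_matrix(sub, ld=ld, **pipeline_kw)
            out[(ci, bi)] = {
                "traits": traits,
                "result": res,
                "qq": qq_table(res.table["p_m"].to_numpy(), bin_id=f"h2c{ci}_poly{bi}"),
            }
    return out
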