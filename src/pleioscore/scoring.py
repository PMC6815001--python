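"""The two-component pleiotropy score and its LD correction.

For a variant with whitened Z-scores z_1…z_l over l traits:

* magnitude component  Pm = (100/l) · sqrt(Σ z_i²) — the total pleiotropic
  effect size, scaled so the score reads as if measured on 100 traits;
* breadth component    Pn = (100/l) · #{i : |z_i| > 2} — the number of
  traits nominally affected, on the same per-100-trait scale.

Linkage disequilibrium inflates both components (a variant tags its
neighbours' effects), and in the spirit of LD score regression the scores
are regressed on per-variant LD scores ℓ and the slope removed:

    Pm_LD = Pm − β_m·ℓ,    Pn_LD = Pn − β_n·ℓ.

Only the slope term is subtracted — the fitted intercept is retained — so
corrected scores keep the raw score's scale but can go slightly negative;
the inference module clamps the test statistic at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import SummaryMatrix
from .ld import LDProfile
from .whitening import WhitenedMatrix

__all__ = [
    "DEFAULT_PN_THRESHOLD",
    "LDCorrection",
    "score_pm",
    "score_pn",
    "score_table",
    "fit_ld_correction",
    "apply_ld_correction",
]

#: |z| threshold for the breadth component; 2 is the usual nominal-significance
#: Z cutoff (two-sided P < 0.05).
DEFAULT_PN_THRESHOLD = 2.0


def _as_row(z_row) -> np.ndarray:
    z = np.asarray(z_row, dtype=float)
    if z.ndim != 1 or z.size == 0:
        raise ValueError("z_row must be a nonempty 1-d vector")
    if not np.isfinite(z).all():
        raise ValueError("z_row entries must be finite")
    return z


def score_pm(z_row) -> float:
    """Magnitude score Pm = (100/l)·sqrt(Σ z_i²) for one variant."""
    z = _as_row(z_row)
    return 100.0 / z.size * float(np.sqrt(np.sum(z * z)))


def score_pn(z_row, threshold: float = DEFAULT_PN_THRESHOLD) -> float:
    """Breadth score Pn = (100/l)·#{|z_i| > threshold}, strict inequality."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    z = _as_row(z_row)
    return 100.0 / z.size * int(np.count_nonzero(np.abs(z) > threshold))


def score_table(
    w: WhitenedMatrix | SummaryMatrix,
    pn_threshold: float = DEFAULT_PN_THRESHOLD,
) -> pd.DataFrame:
    """Vectorized Pm and Pn for every variant of a (whitened) matrix.

    Returns a score table DataFrame with columns
    ``variant_id, chr, pos, pm, pn``; the remaining score-table columns are
    added by :func:`apply_ld_correction` and the inference module.
    """
    z = w.z
    l = z.shape[1]
    pm = 100.0 / l * np.sqrt(np.einsum("ij,ij->i", z, z))
    pn = 100.0 / l * np.count_nonzero(np.abs(z) > pn_threshold, axis=1)
    meta = w.variants
    return pd.DataFrame(
        {
            "variant_id": meta.index.to_numpy(),
            "chr": meta["chr"].to_numpy() if "chr" in meta else np.nan,
            "pos": meta["pos"].to_numpy() if "pos" in meta else np.nan,
            "pm": pm,
            "pn": pn.astype(float),
        }
    )


@dataclass
class LDCorrection:
    """Fitted LD regression for both score components.

    Slopes are what the correction subtracts; intercepts and standard
    errors are kept for diagnostics.
    """

    beta_m: float
    beta_n: float
    intercept_m: float
    intercept_n: float
    se_beta_m: float = np.nan
    se_beta_n: float = np.nan
    n_variants: int = 0


def _align_ld(table: pd.DataFrame, ld: LDProfile) -> np.ndarray:
    return ld.scores.reindex(table["variant_id"]).to_numpy(float)


def fit_ld_correction(table: pd.DataFrame, ld: LDProfile) -> LDCorrection:
    """Ordinary least squares of each score component on the LD score ℓ."""
    ell = _align_ld(table, ld)
    ok = np.isfinite(ell)
    if ok.sum() < 3:
        raise ValueError("need at least 3 variants with LD scores")
    if np.var(ell[ok]) == 0.0:
        raise ValueError(
            "LD scores have zero variance; skip the correction (no-op)"
        )
    fm = stats.linregress(ell[ok], table["pm"].to_numpy(float)[ok])
    fn = stats.linregress(ell[ok], table["pn"].to_numpy(float)[ok])
    return LDCorrection(
        beta_m=float(fm.slope),
        beta_n=float(fn.slope),
        intercept_m=float(fm.intercept),
        intercept_n=float(fn.intercept),
        se_beta_m=float(fm.stderr),
        se_beta_n=float(fn.stderr),
        n_variants=int(ok.sum()),
    )


def apply_ld_correction(
    table: pd.DataFrame, correction: LDCorrection, ld: LDProfile
) -> pd.DataFrame:
    """Add ``pm_ld = pm − β_m·ℓ`` and ``pn_ld = pn − β_n·ℓ`` columns.

    Variants without an LD score get missing corrected values (a warning
    count is not raised as an exception; inspect the NaNs). The input table
    is returned with new columns, not mutated.
    """
    out = table.copy()
    ell = _align_ld(table, ld)
    out["ld_score"] = ell
    out["pm_ld"] = out["pm"] - correction.beta_m * ell
    out["pn_ld"] = out["pn"] - correction.beta_n * ell
    return out
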