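"""End-to-end scoring pipeline: whiten → score → LD-correct → P values.

This is the composition the tool runs for every dataset: estimate the trait
correlation (optionally on an LD-pruned variant subset), whiten, compute
both score components, regress out LD, attach theoretical P values, and —
when requested — build the polygenicity-preserving permutation null and
convert empirical P values back to corrected scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import inference, scoring, whitening
from .io import SummaryMatrix
from .ld import LDProfile

__all__ = ["ScoreResult", "score_summary_matrix"]


@dataclass
class ScoreResult:
    """Everything produced by one scoring run."""

    table: pd.DataFrame
    model: whitening.TraitCorrelationModel
    whitened: whitening.WhitenedMatrix
    correction: scoring.LDCorrection | None = None
    permutation_null: inference.PermutationNull | None = None


def score_summary_matrix(
    m: SummaryMatrix,
    ld: LDProfile | None = None,
    prune_threshold: float | None = 0.1,
    n_permutations: int = 0,
    seed: int = 0,
    pn_threshold: float = scoring.DEFAULT_PN_THRESHOLD,
    p0: float | None = None,
    correlation_strategy: str | None = None,
    identity_correlation: bool = False,
) -> ScoreResult:
    """Run the full scoring pipeline on a summary-statistics matrix.

    Parameters
    ----------
    m:
        Variants × traits Z-score matrix.
    ld:
        LD profile; enables the LD correction and (when it carries pairwise
        structure and ``prune_threshold`` is set) pruned correlation
        estimation.
    prune_threshold:
        r² threshold for pruning the correlation-estimation subset; ``None``
        estimates on all variants.
    n_permutations:
        If > 0, build the permutation null (this many column permutations),
        attach empirical P values and the polygenicity-corrected scores
        ``pm_p``/``pn_p``.
    identity_correlation:
        Skip correlation estimation and whiten with the identity model
        (scores are then computed on the raw Z directly).
    """
    p0 = inference.default_p0(pn_threshold) if p0 is None else p0
    l = m.n_traits

    if identity_correlation:
        model = whitening.TraitCorrelationModel(
            np.eye(l), trait_ids=m.trait_ids, estimation_strategy="identity"
        )
    else:
        strategy = correlation_strategy
        prune_index = None
        if strategy is None:
            if ld is not None and ld.pairwise is not None and prune_threshold:
                strategy = "pruned_variants"
            else:
                strategy = "all_variants"
        if strategy == "pruned_variants":
            if ld is None or ld.pairwise is None:
                raise ValueError("pruned correlation estimation requires pairwise LD")
            kept = whitening.prune_by_r2(
                ld.pairwise, m.variant_ids, prune_threshold or 0.1
            )
            prune_index = pd.Index(kept)
        model = whitening.estimate_correlation(m, strategy, prune_index)

    w = whitening.whiten(m, model)
    table = scoring.score_table(w, pn_threshold)

    correction = None
    use_ld = ld is not None and not ld.reindex(m.variant_ids).zero_variance
    if use_ld:
        correction = scoring.fit_ld_correction(table, ld)
        table = scoring.apply_ld_correction(table, correction, ld)
        pm_stat, pn_stat = table["pm_ld"], table["pn_ld"]
    else:
        pm_stat, pn_stat = table["pm"], table["pn"]

    table["p_m"] = inference.pm_theoretical_p(pm_stat.to_numpy(), l)
    table["p_n"] = inference.pn_theoretical_p(pn_stat.to_numpy(), l, p0)

    null = None
    if n_permutations > 0:
        null = inference.build_permutation_null(
            w,
            n_permutations=n_permutations,
            seed=seed,
            ld=ld if use_ld else None,
            correction=correction,
            pn_threshold=pn_threshold,
        )
        pooled_m = null.pooled_pm_ld if use_ld else null.pooled_pm
        pooled_n = null.pooled_pn_ld if use_ld else null.pooled_pn
        table["p_m_emp"] = inference.empirical_p(pm_stat.to_numpy(), pooled_m)
        table["p_n_emp"] = inference.empirical_p(pn_stat.to_numpy(), pooled_n)
        table["pm_p"] = inference.empirical_to_score(
            table["p_m_emp"].to_numpy(), l, "magnitude", p0
        )
        table["pn_p"] = inference.empirical_to_score(
            table["p_n_emp"].to_numpy(), l, "ntraits", p0
        )

    return ScoreResult(
        table=table, model=model, whitened=w, correction=correction,
        permutation_null=null,
    )
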