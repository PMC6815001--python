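"""Genome-wide pleiotropy study utilities.

A genome-wide pleiotropy study (GWPS) scans every variant for pleiotropy by
analogy to a GWAS scan for association. The utilities here post-process a
score table: greedy LD clumping of significant variants into loci,
MAF-matched category enrichment of the score, a permutation-calibrated
replication analysis, gene-level score averaging, and per-trait
contribution correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import inference, scoring
from .io import SummaryMatrix
from .ld import LDProfile, PairwiseLD
from .whitening import WhitenedMatrix

__all__ = [
    "Locus",
    "EnrichmentResult",
    "clump",
    "loci_to_bed",
    "enrichment_test",
    "replication_analysis",
    "gene_average",
    "trait_contribution",
]


@dataclass
class Locus:
    """A clumped pleiotropy locus around an index variant."""

    index_variant: str
    chromosome: str
    start: int
    end: int
    member_variants: list[str]
    index_p: float


def clump(
    table: pd.DataFrame,
    pairwise: PairwiseLD | None,
    p_column: str = "p_m",
    p_index: float = 5e-8,
    p_member: float = 0.05,
    r2_min: float = 0.1,
    window_kb: int = 100,
) -> list[Locus]:
    """Greedy LD clumping of score hits into loci.

    Repeatedly takes the unassigned variant with the smallest P ≤ p_index
    as an index, and assigns to its locus every unassigned variant with
    P ≤ p_member, within ``window_kb`` of the index, and r² ≥ r2_min with
    it. Ties in P are broken by position then variant id; pairs absent from
    the LD structure count as r² = 0.
    """
    need = {"variant_id", "chr", "pos", p_column}
    if not need.issubset(table.columns):
        raise ValueError(f"score table lacks columns {sorted(need - set(table.columns))}")
    df = table[["variant_id", "chr", "pos", p_column]].copy()
    df = df[np.isfinite(df[p_column].to_numpy(float))]
    df = df.sort_values(
        [p_column, "pos", "variant_id"], kind="mergesort"
    ).reset_index(drop=True)

    assigned: set[str] = set()
    window = window_kb * 1000
    loci: list[Locus] = []
    candidates = df[df[p_column] <= p_member]
    by_chr = {c: g for c, g in candidates.groupby("chr", sort=False)}
    for row in df.itertuples(index=False):
        p = getattr(row, p_column)
        if p > p_index:
            break
        if row.variant_id in assigned:
            continue
        assigned.add(row.variant_id)
        members = [row.variant_id]
        pool = by_chr.get(row.chr)
        if pool is not None and pairwise is not None:
            near = pool[(pool["pos"] - row.pos).abs() <= window]
            for cand in near.itertuples(index=False):
                if cand.variant_id in assigned:
                    continue
                if pairwise.r2(row.variant_id, cand.variant_id) >= r2_min:
                    assigned.add(cand.variant_id)
                    members.append(cand.variant_id)
        pos = df.set_index("variant_id").loc[members, "pos"]
        loci.append(
            Locus(
                index_variant=row.variant_id,
                chromosome=str(row.chr),
                start=int(pos.min()),
                end=int(pos.max()),
                member_variants=members,
                index_p=float(p),
            )
        )
    return loci


def loci_to_bed(loci: list[Locus], component: str = "pm") -> pd.DataFrame:
    """BED-like frame: chr, start (0-based half-open), end, index, p."""
    return pd.DataFrame(
        {
            "chr": [lo.chromosome for lo in loci],
            "start": [lo.start - 1 for lo in loci],
            "end": [lo.end for lo in loci],
            "index_variant": [lo.index_variant for lo in loci],
            "component": component,
            "index_p": [lo.index_p for lo in loci],
        }
    )


@dataclass
class EnrichmentResult:
    category: str
    reference: str
    score_column: str
    delta_mean: float
    se: float
    t_stat: float
    p: float
    n_query: int
    n_reference: int
    with_replacement: bool = False


def _category_mask(meta: pd.DataFrame, label: str) -> np.ndarray:
    if "categories" not in meta.columns:
        raise ValueError("variant metadata has no 'categories' column")
    return np.array(
        [label in (c if isinstance(c, (set, frozenset, list, tuple)) else ())
         for c in meta["categories"]]
    )


def enrichment_test(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    category: str,
    reference: str,
    score_column: str = "pm_ld",
    n_maf_bins: int = 50,
    seed: int = 0,
) -> EnrichmentResult:
    """MAF-matched two-sample t-test of mean score, category vs reference.

    Reference MAFs are cut into ``n_maf_bins`` quantile bins; for each bin,
    as many reference variants as the query holds in that bin are sampled
    (without replacement when possible, else with replacement and flagged).
    The category labels live in ``meta['categories']`` (a set per variant);
    ``meta`` must be indexed by variant id and carry a ``maf`` column.
    Welch's unequal-variance t-test is used.
    """
    rng = np.random.default_rng(seed)
    scores = table.set_index("variant_id")[score_column]
    meta = meta.loc[meta.index.intersection(scores.index)]
    q_mask = _category_mask(meta, category)
    r_mask = _category_mask(meta, reference)
    if not q_mask.any() or not r_mask.any():
        raise ValueError("query and reference categories must both be nonempty")
    maf = meta["maf"].to_numpy(float)
    if not np.isfinite(maf[q_mask | r_mask]).all():
        raise ValueError("MAF required for all tested variants")

    ref_maf = maf[r_mask]
    edges = np.unique(np.quantile(ref_maf, np.linspace(0, 1, n_maf_bins + 1)))
    edges[0], edges[-1] = -np.inf, np.inf
    q_bins = np.digitize(maf[q_mask], edges[1:-1])
    r_bins = np.digitize(ref_maf, edges[1:-1])

    ref_ids = meta.index.to_numpy()[r_mask]
    sampled: list[str] = []
    with_replacement = False
    for b, count in zip(*np.unique(q_bins, return_counts=True)):
        pool = ref_ids[r_bins == b]
        if pool.size == 0:
            raise ValueError(
                f"no reference variants in MAF bin {b}; try fewer bins"
            )
        if pool.size >= count:
            sampled.extend(rng.choice(pool, size=count, replace=False))
        else:
            with_replacement = True
            sampled.extend(rng.choice(pool, size=count, replace=True))

    q_scores = scores.loc[meta.index[q_mask]].to_numpy(float)
    r_scores = scores.loc[sampled].to_numpy(float)
    t, p = stats.ttest_ind(q_scores, r_scores, equal_var=False)
    se = float(
        np.sqrt(q_scores.var(ddof=1) / q_scores.size + r_scores.var(ddof=1) / r_scores.size)
    )
    return EnrichmentResult(
        category=category,
        reference=reference,
        score_column=score_column,
        delta_mean=float(q_scores.mean() - r_scores.mean()),
        se=se,
        t_stat=float(t),
        p=float(p),
        n_query=int(q_scores.size),
        n_reference=int(r_scores.size),
        with_replacement=with_replacement,
    )


def replication_analysis(
    discovery_loci: list[Locus],
    replication_p: pd.Series,
    w_replication: WhitenedMatrix,
    alpha: float = 0.05,
    n_null_permutations: int = 25,
    seed: int = 0,
    ld: LDProfile | None = None,
    correction: scoring.LDCorrection | None = None,
    component: str = "magnitude",
    pn_threshold: float = scoring.DEFAULT_PN_THRESHOLD,
    p0: float | None = None,
) -> dict:
    """Replication of discovery loci against a permutation-calibrated null.

    A locus replicates when any member variant has replication P < alpha.
    The null expectation permutes each whitened replication trait column
    independently, recomputes scores and theoretical P values (re-applying
    a fixed LD correction when supplied), and re-evaluates the replication
    fraction over the same loci; the mean over permutations is the fraction
    expected under no shared pleiotropy but preserved polygenicity.

    ``replication_p`` is indexed by variant id. Members absent from it are
    dropped (their count reported); loci losing all members are skipped.
    """
    if not discovery_loci:
        return {
            "observed_fraction": np.nan,
            "null_fraction": np.nan,
            "ratio": np.nan,
            "n_loci": 0,
            "n_missing_variants": 0,
        }
    p0 = inference.default_p0(pn_threshold) if p0 is None else p0
    l = w_replication.n_traits
    idx = w_replication.variant_ids

    members: list[list[str]] = []
    n_missing = 0
    for lo in discovery_loci:
        present = [v for v in lo.member_variants if v in replication_p.index and v in idx]
        n_missing += len(lo.member_variants) - len(present)
        if present:
            members.append(present)
    if not members:
        raise ValueError("no discovery-locus variants present in replication data")

    def fraction(p: pd.Series) -> float:
        return float(np.mean([(p.loc[ms].to_numpy(float) < alpha).any() for ms in members]))

    observed = fraction(replication_p)

    ell = (
        ld.scores.reindex(idx).to_numpy(float)
        if (ld is not None and correction is not None)
        else None
    )
    rng = np.random.default_rng(seed)
    null_fracs = []
    for _ in range(n_null_permutations):
        zp = inference.permute_columns(w_replication.z, rng)
        if component == "magnitude":
            s = 100.0 / l * np.sqrt(np.einsum("ij,ij->i", zp, zp))
            if ell is not None:
                s = s - correction.beta_m * ell
            p = inference.pm_theoretical_p(s, l)
        else:
            s = 100.0 / l * np.count_nonzero(np.abs(zp) > pn_threshold, axis=1)
            if ell is not None:
                s = s - correction.beta_n * ell
            p = inference.pn_theoretical_p(s, l, p0)
        null_fracs.append(fraction(pd.Series(p, index=idx)))
    null_fraction = float(np.mean(null_fracs))
    return {
        "observed_fraction": observed,
        "null_fraction": null_fraction,
        "ratio": observed / null_fraction if null_fraction > 0 else np.inf,
        "n_loci": len(members),
        "n_missing_variants": n_missing,
    }


def gene_average(
    table: pd.DataFrame,
    variant_to_gene: dict[str, str] | pd.Series,
    score_columns: tuple[str, ...] = ("pm", "pn", "pm_ld", "pn_ld"),
) -> pd.DataFrame:
    """Mean score per gene over its mapped variants, ranked descending.

    Genes mapping to no scored variant are excluded. Ranking uses the first
    available score column.
    """
    mapping = pd.Series(variant_to_gene)
    df = table.set_index("variant_id")
    df = df.loc[df.index.intersection(mapping.index)]
    if df.empty:
        raise ValueError("gene mapping covers no scored variants")
    cols = [c for c in score_columns if c in df.columns]
    grouped = df.assign(gene=mapping.loc[df.index]).groupby("gene")[cols].mean()
    grouped["n_variants"] = df.assign(gene=mapping.loc[df.index]).groupby("gene").size()
    return grouped.sort_values(cols[0], ascending=False)


def trait_contribution(
    table: pd.DataFrame,
    m: SummaryMatrix,
    score_column: str = "pm_ld",
    p_column: str = "p_m",
    p_threshold: float = 5e-8,
) -> pd.Series:
    """Per-trait Pearson r between |raw Z| and the pleiotropy score among
    score-significant variants.

    Traits whose |Z| is constant over the significant set get NaN.
    """
    sig = table[table[p_column].to_numpy(float) < p_threshold]
    if len(sig) < 3:
        raise ValueError(
            f"only {len(sig)} variants pass {p_column} < {p_threshold}; need >= 3"
        )
    rows = m.variant_ids.get_indexer(sig["variant_id"])
    score = sig[score_column].to_numpy(float)
    out = {}
    for j, trait in enumerate(m.trait_ids):
        az = np.abs(m.z[rows, j])
        out[str(trait)] = (
            np.nan if az.std() == 0 or score.std() == 0
            else float(np.corrcoef(az, score)[0, 1])
        )
    return pd.Series(out, name=f"corr_absZ_{score_column}")
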