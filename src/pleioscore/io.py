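"""Reading, harmonizing and writing GWAS summary statistics and score tables.

The central container is :class:`SummaryMatrix`: a variants × traits matrix
of association Z-scores with variant and trait metadata on labelled axes.
Two input dialects are supported:

* ``ldsc_like`` — a directory of per-trait tab-separated files with columns
  ``SNP  A1  A2  Z  [N]`` (the sumstats dialect used by LD score regression
  tooling); the trait id is the file stem. Alleles are harmonized to the
  orientation of the first trait read: a variant whose A1/A2 are swapped in
  a later file has its Z sign flipped, and a variant whose alleles do not
  match either orientation is treated as missing for that trait.
* ``wide_matrix`` — a single tab-separated file with columns
  ``variant_id  chr  pos`` followed by one Z column per trait.

Variants are restricted to those observed (with compatible alleles) in every
trait: whitening requires complete rows.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ld import LDProfile

__all__ = [
    "SummaryMatrix",
    "read_sumstats_dir",
    "qc_traits",
    "read_ld_scores",
    "write_score_table",
    "read_score_table",
    "SCORE_COLUMNS",
]

#: Fixed serialization order for score tables.
SCORE_COLUMNS = [
    "variant_id", "chr", "pos",
    "pm", "pn", "pm_ld", "pn_ld",
    "p_m", "p_n", "p_m_emp", "p_n_emp",
    "pm_p", "pn_p",
]

_VARIANT_COLUMNS = ["chr", "pos", "ref", "alt", "maf"]
_TRAIT_COLUMNS = ["heritability", "heritability_p", "sample_size"]


class FormatError(ValueError):
    """Raised when an input file does not parse under its declared dialect."""


@dataclass
class SummaryMatrix:
    """Variants × traits Z-score matrix with metadata.

    Attributes
    ----------
    z:
        float array of shape ``(n_variants, n_traits)``; all entries finite.
    variants:
        DataFrame indexed by variant id with columns
        ``chr, pos, ref, alt, maf`` (any may be missing) and optionally
        ``categories`` (set of annotation labels per variant).
    traits:
        DataFrame indexed by trait id with columns
        ``heritability, heritability_p, sample_size`` (any may be missing).
    """

    z: np.ndarray
    variants: pd.DataFrame
    traits: pd.DataFrame

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2:
            raise ValueError("z must be 2-dimensional (variants × traits)")
        if self.z.shape != (len(self.variants), len(self.traits)):
            raise ValueError(
                f"z shape {self.z.shape} does not match "
                f"{len(self.variants)} variants × {len(self.traits)} traits"
            )
        if self.variants.index.has_duplicates:
            raise ValueError("duplicate variant ids")
        if self.traits.index.has_duplicates:
            raise ValueError("duplicate trait ids")
        if not np.isfinite(self.z).all():
            raise ValueError("non-finite Z entries; resolve missing data at load time")

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

    def select_traits(self, trait_ids) -> "SummaryMatrix":
        cols = self.traits.index.get_indexer(trait_ids)
        if (cols < 0).any():
            missing = [t for t, c in zip(trait_ids, cols) if c < 0]
            raise KeyError(f"unknown trait ids: {missing}")
        return SummaryMatrix(self.z[:, cols], self.variants, self.traits.iloc[cols])

    def select_variants(self, variant_ids) -> "SummaryMatrix":
        rows = self.variants.index.get_indexer(variant_ids)
        if (rows < 0).any():
            missing = [v for v, r in zip(variant_ids, rows) if r < 0]
            raise KeyError(f"unknown variant ids: {missing}")
        return SummaryMatrix(self.z[rows], self.variants.iloc[rows], self.traits)

    def to_frame(self) -> pd.DataFrame:
        """Z matrix as a DataFrame (variants × traits, labelled)."""
        return pd.DataFrame(self.z, index=self.variant_ids, columns=self.trait_ids)


def _empty_variant_meta(variant_ids) -> pd.DataFrame:
    df = pd.DataFrame(index=pd.Index(variant_ids, name="variant_id"))
    for c in _VARIANT_COLUMNS:
        df[c] = np.nan
    return df


def _empty_trait_meta(trait_ids) -> pd.DataFrame:
    df = pd.DataFrame(index=pd.Index(trait_ids, name="trait_id"))
    for c in _TRAIT_COLUMNS:
        df[c] = np.nan
    return df


def _read_tsv(path: str, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", compression="infer", **kw)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise FormatError(f"cannot parse {path}: {exc}") from exc


def read_sumstats_dir(path: str, dialect: str = "ldsc_like") -> SummaryMatrix:
    """Read per-trait summary statistics into a :class:`SummaryMatrix`.

    See the module docstring for the two dialects. Returns the matrix
    restricted to variants present (with compatible alleles) in all traits.
    """
    if dialect == "wide_matrix":
        return _read_wide_matrix(path)
    if dialect != "ldsc_like":
        raise ValueError(f"unknown dialect: {dialect!r}")

    if os.path.isdir(path):
        files = sorted(
            os.path.join(path, f)
            for f in os.listdir(path)
            if not f.startswith(".") and os.path.isfile(os.path.join(path, f))
        )
    else:
        files = [path]
    if not files:
        raise FormatError(f"no summary-statistics files found in {path}")

    ref_alleles: pd.DataFrame | None = None
    columns: dict[str, pd.Series] = {}
    sample_sizes: dict[str, float] = {}
    for f in files:
        trait_id = os.path.basename(f)
        for ext in (".gz", ".sumstats", ".tsv", ".txt"):
            if trait_id.endswith(ext):
                trait_id = trait_id[: -len(ext)]
        df = _read_tsv(f)
        required = {"SNP", "A1", "A2", "Z"}
        if not required.issubset(df.columns):
            raise FormatError(
                f"{f}: missing required columns {sorted(required - set(df.columns))}"
            )
        if df["SNP"].duplicated().any():
            dup = df["SNP"][df["SNP"].duplicated()].iloc[0]
            line = int(df.index[df["SNP"] == dup][1]) + 2
            raise FormatError(f"{f}: duplicate variant {dup!r} at line {line}")
        df = df.dropna(subset=["Z"]).set_index("SNP")
        z = pd.to_numeric(df["Z"], errors="coerce")
        a1 = df["A1"].astype(str).str.upper()
        a2 = df["A2"].astype(str).str.upper()
        if ref_alleles is None:
            ref_alleles = pd.DataFrame({"A1": a1, "A2": a2})
            columns[trait_id] = z
        else:
            shared = df.index.intersection(ref_alleles.index)
            ra = ref_alleles.loc[shared]
            same = (a1.loc[shared] == ra["A1"]) & (a2.loc[shared] == ra["A2"])
            swapped = (a1.loc[shared] == ra["A2"]) & (a2.loc[shared] == ra["A1"])
            keep = shared[same | swapped]
            zz = z.loc[keep].copy()
            zz[swapped.loc[keep][swapped.loc[keep]].index] *= -1.0
            columns[trait_id] = zz
        if "N" in df.columns:
            n = pd.to_numeric(df["N"], errors="coerce").dropna()
            if len(n):
                sample_sizes[trait_id] = float(n.median())

    shared = None
    for s in columns.values():
        idx = s.dropna().index
        shared = idx if shared is None else shared.intersection(idx)
    if shared is None or len(shared) == 0:
        raise FormatError("no shared variants across traits after harmonization")
    # preserve the first file's variant order
    shared = ref_alleles.index[ref_alleles.index.isin(shared)]

    z = np.column_stack([columns[t].loc[shared].to_numpy(float) for t in columns])
    variants = _empty_variant_meta(shared)
    variants["ref"] = ref_alleles.loc[shared, "A2"]
    variants["alt"] = ref_alleles.loc[shared, "A1"]
    traits = _empty_trait_meta(list(columns))
    for t, n in sample_sizes.items():
        traits.loc[t, "sample_size"] = n
    return SummaryMatrix(z, variants, traits)


def _read_wide_matrix(path: str) -> SummaryMatrix:
    df = _read_tsv(path)
    fixed = ["variant_id", "chr", "pos"]
    if list(df.columns[:3]) != fixed:
        raise FormatError(
            f"{path}: wide_matrix dialect requires leading columns {fixed}, "
            f"got {list(df.columns[:3])}"
        )
    trait_cols = list(df.columns[3:])
    if not trait_cols:
        raise FormatError(f"{path}: no trait columns")
    df = df.set_index("variant_id")
    z = df[trait_cols].to_numpy(float)
    if not np.isfinite(z).all():
        keep = np.isfinite(z).all(axis=1)
        df, z = df.loc[keep], z[keep]
    if z.shape[0] == 0:
        raise FormatError(f"{path}: no complete variant rows")
    variants = _empty_variant_meta(df.index)
    variants["chr"] = df["chr"].astype(str)
    variants["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    return SummaryMatrix(z, variants, _empty_trait_meta(trait_cols))


def qc_traits(
    m: SummaryMatrix, h2_alpha: float = 0.05, pairwise_r2_max: float = 0.8
) -> SummaryMatrix:
    """Trait-level quality control: heritability filter then pair pruning.

    Keeps traits whose heritability P value passes Bonferroni
    (``heritability_p < h2_alpha / n_traits``); then, for every surviving
    trait pair whose squared Pearson correlation of Z columns exceeds
    ``pairwise_r2_max``, drops the member with lower heritability. Pairs are
    processed in descending r² (ties by trait id) so the result does not
    depend on input trait order.
    """
    if not 0.0 < pairwise_r2_max <= 1.0:
        raise ValueError("pairwise_r2_max must be in (0, 1]")
    h2 = m.traits["heritability"]
    h2p = m.traits["heritability_p"]
    if h2.isna().any() or h2p.isna().any():
        raise ValueError("heritability and heritability_p required for all traits")

    keep = h2p < h2_alpha / m.n_traits
    surviving = list(m.trait_ids[keep])
    if not surviving:
        raise ValueError("all traits removed by the heritability filter")

    sub = m.select_traits(surviving)
    corr = np.corrcoef(sub.z, rowvar=False)
    if corr.ndim == 0:  # single trait
        return sub
    pairs = []
    for i in range(len(surviving)):
        for j in range(i + 1, len(surviving)):
            r2 = corr[i, j] ** 2
            if r2 > pairwise_r2_max:
                a, b = sorted((surviving[i], surviving[j]))
                pairs.append((-r2, a, b))
    pairs.sort()
    removed: set[str] = set()
    for _, a, b in pairs:
        if a in removed or b in removed:
            continue
        # drop the lower-heritability member; tie broken toward the
        # lexicographically later id so the outcome is deterministic
        if h2[a] < h2[b] or (h2[a] == h2[b] and a > b):
            removed.add(a)
        else:
            removed.add(b)
    final = [t for t in surviving if t not in removed]
    if not final:
        raise ValueError("all traits removed by pairwise pruning")
    return m.select_traits(final)


def read_ld_scores(path: str) -> LDProfile:
    """Read per-variant LD scores (tab-separated, columns CHR SNP BP L2).

    Accepts plain or gzip-compressed input; only SNP and L2 are required.
    """
    df = _read_tsv(path)
    for col in ("SNP", "L2"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if df["SNP"].duplicated().any():
        dup = df["SNP"][df["SNP"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate variant id {dup!r}")
    scores = pd.Series(
        pd.to_numeric(df["L2"], errors="coerce").to_numpy(),
        index=pd.Index(df["SNP"], name="variant_id"),
        name="L2",
    )
    return LDProfile(scores)


def write_score_table(table: pd.DataFrame, path: str) -> None:
    """Write a score table as tab-separated text (NA for missing columns).

    Columns are emitted in the fixed order ``SCORE_COLUMNS`` (plus
    ``ld_score`` when present); values round-trip at 10 significant digits.
    """
    if len(table) == 0:
        raise ValueError("refusing to write an empty score table")
    out = pd.DataFrame(index=table.index)
    cols = SCORE_COLUMNS + (["ld_score"] if "ld_score" in table.columns else [])
    for c in cols:
        out[c] = table[c] if c in table.columns else np.nan
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_score_table(path: str) -> pd.DataFrame:
    df = _read_tsv(path, na_values=["NA"])
    missing = [c for c in SCORE_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing score columns {missing}")
    return df
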