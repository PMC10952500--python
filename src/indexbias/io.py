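"""Reading, harmonizing and filtering two-trait GWAS summary statistics.

Summary-statistic tables are carried as :class:`pandas.DataFrame` objects with a
fixed schema.  A *summary-statistics* frame has the columns

``snp_id, chrom, pos, effect_allele, other_allele, beta, se, pvalue, info,
n_studies, eaf``

of which ``snp_id, effect_allele, other_allele, beta, se`` are required; the
rest are optional quality-control fields.  ``beta`` is a log odds ratio for a
disease-risk file and a log hazard ratio for a case-only survival file.

A *harmonized-pairs* frame (the input to the bias-slope regression) has the
columns ``snp_id, beta_gx, se_gx, beta_gy, se_gy, flipped``: one row per SNP
present in both files with reconcilable alleles, with both effect sizes
referring to the same effect allele.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("snp_id", "effect_allele", "other_allele", "beta", "se")
OPTIONAL_COLUMNS = ("chrom", "pos", "pvalue", "info", "n_studies", "eaf")
PAIR_COLUMNS = ("snp_id", "beta_gx", "se_gx", "beta_gy", "se_gy", "flipped")

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SumstatsError(ValueError):
    """Fatal problem with a summary-statistics file or pairing."""


def _complement(allele: str) -> str:
    return _COMPLEMENT[allele]


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True for strand-ambiguous (A/T or C/G) SNPs."""
    return _COMPLEMENT.get(effect_allele) == other_allele


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a delimited summary-statistics file into the standard schema.

    Parameters
    ----------
    path
        Delimited text file with a header row.  Tab- or whitespace-delimited
        files are auto-detected; gzip compression is handled transparently.
    column_map
        Mapping from the file's column names to the standard names, e.g.
        ``{"rsid": "snp_id", "A1": "effect_allele"}``.  Columns already using
        standard names need not be mapped.
    sep
        Explicit field separator; by default the separator is sniffed.

    Returns
    -------
    DataFrame in the standard summary-statistics schema.  Rows with
    unparseable or invalid numerics (``beta``/``se`` not a number, ``se <= 0``)
    or invalid alleles are dropped with a logged count.  Duplicate ``snp_id``
    rows keep the record with the smallest ``se`` (ties broken by file order).
    """
    if sep is None:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str, comment=None)
    else:
        df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[0] == 0:
        raise SumstatsError(f"empty summary-statistics file: {path}")
    if column_map:
        df = df.rename(columns=dict(column_map))
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SumstatsError(f"required column {col!r} missing from {path}")

    keep = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in df.columns]
    df = df[keep].copy()

    n_input = len(df)
    for col in ("beta", "se", "pvalue", "info", "eaf"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "pos" in df.columns:
        df["pos"] = pd.to_numeric(df["pos"], errors="coerce").astype("Int64")
    if "n_studies" in df.columns:
        df["n_studies"] = pd.to_numeric(df["n_studies"], errors="coerce").astype(
            "Int64"
        )
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].str.upper()

    ok = (
        df["beta"].notna()
        & df["se"].notna()
        & (df["se"] > 0)
        & df["snp_id"].notna()
        & (df["snp_id"].str.len() > 0)
        & df["effect_allele"].isin(_VALID_ALLELES)
        & df["other_allele"].isin(_VALID_ALLELES)
        & (df["effect_allele"] != df["other_allele"])
    )
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("%s: dropped %d unparseable/invalid rows", path, n_dropped)
    df = df[ok]

    # duplicated snp_id: keep smallest se, deterministic tie-break by file order
    if df["snp_id"].duplicated().any():
        n_dup = int(df["snp_id"].duplicated().sum())
        logger.warning("%s: dropped %d duplicate snp_id rows (kept smallest se)", path, n_dup)
        df = df.sort_values("se", kind="stable").drop_duplicates("snp_id")
        df = df.sort_index()

    if df.shape[0] == 0:
        raise SumstatsError(f"no usable rows in {path}")
    df.attrs["n_dropped"] = n_dropped
    return df.reset_index(drop=True)


def write_sumstats(df: pd.DataFrame, path) -> None:
    """Write a summary-statistics frame as tab-delimited text (gzip by suffix)."""
    df.to_csv(path, sep="\t", index=False)


def harmonize(
    risk: pd.DataFrame,
    survival: pd.DataFrame,
    drop_palindromic: bool = True,
) -> pd.DataFrame:
    """Pair risk and survival effects so both refer to the same effect allele.

    SNPs are matched by ``snp_id``.  If the survival file reports the effect on
    the opposite allele its beta is negated (``flipped=True``); allele pairs
    that only match after strand complementation are complemented and the same
    rules applied.  Palindromic (A/T, C/G) SNPs are dropped when
    ``drop_palindromic`` is set, since strand cannot be resolved without
    allele-frequency inference.  Irreconcilable allele sets are dropped with a
    logged count.

    Returns a harmonized-pairs frame ordered as in the risk file.
    """
    if len(risk) == 0 or len(survival) == 0:
        raise SumstatsError("harmonize requires non-empty inputs")
    surv = survival.set_index("snp_id")
    merged = risk[risk["snp_id"].isin(surv.index)]
    if len(merged) == 0:
        raise SumstatsError("no SNPs shared between risk and survival files")

    rows = []
    n_dropped = 0
    for row in merged.itertuples(index=False):
        s = surv.loc[row.snp_id]
        r_ea, r_oa = row.effect_allele, row.other_allele
        s_ea, s_oa = s["effect_allele"], s["other_allele"]
        if drop_palindromic and (is_palindromic(r_ea, r_oa) or is_palindromic(s_ea, s_oa)):
            n_dropped += 1
            continue
        beta_gy, flipped = _align_alleles(r_ea, r_oa, s_ea, s_oa, float(s["beta"]))
        if beta_gy is None:
            n_dropped += 1
            continue
        rows.append(
            (row.snp_id, float(row.beta), float(row.se), beta_gy, float(s["se"]), flipped)
        )
    if n_dropped:
        logger.warning("harmonize: dropped %d SNPs with unresolvable alleles", n_dropped)
    if not rows:
        raise SumstatsError("no SNPs with reconcilable alleles")
    pairs = pd.DataFrame(rows, columns=list(PAIR_COLUMNS))
    pairs.attrs["n_dropped"] = n_dropped
    return pairs


def _align_alleles(r_ea, r_oa, s_ea, s_oa, s_beta):
    """Return (survival beta on the risk effect allele, flipped) or (None, None)."""
    if (s_ea, s_oa) == (r_ea, r_oa):
        return s_beta, False
    if (s_ea, s_oa) == (r_oa, r_ea):
        return -s_beta, True
    c_ea, c_oa = _complement(s_ea), _complement(s_oa)
    if (c_ea, c_oa) == (r_ea, r_oa):
        return s_beta, False
    if (c_ea, c_oa) == (r_oa, r_ea):
        return -s_beta, True
    return None, None


def filter_snps(
    pairs: pd.DataFrame,
    records: pd.DataFrame | None = None,
    min_info: float = 0.0,
    min_studies: int = 0,
    keep_list: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Apply imputation-quality, study-count and SNP-list filters to pairs.

    ``records`` supplies the per-SNP QC fields (``info``, ``n_studies``); a SNP
    whose QC field is absent or missing passes that filter, with a logged
    warning.  ``keep_list`` restricts to an externally supplied SNP set (e.g.
    an LD-pruned list produced with genotype-level tools).
    """
    if not 0.0 <= min_info <= 1.0:
        raise ValueError("min_info must be in [0, 1]")
    if min_studies < 0:
        raise ValueError("min_studies must be >= 0")
    out = pairs
    for col, threshold, active in (
        ("info", float(min_info), min_info > 0),
        ("n_studies", int(min_studies), min_studies > 0),
    ):
        if not active:
            continue
        if records is None or col not in records.columns:
            logger.warning("filter_snps: no %r column available; filter passes all", col)
            continue
        values = out["snp_id"].map(records.set_index("snp_id")[col])
        missing = values.isna()
        if missing.any():
            logger.warning(
                "filter_snps: %d SNPs missing %r treated as passing", int(missing.sum()), col
            )
        out = out[missing | (values >= threshold)]
    if keep_list is not None:
        out = out[out["snp_id"].isin(set(keep_list))]
    if len(out) == 0:
        logger.warning("filter_snps: all SNPs removed")
    return out.reset_index(drop=True)


def read_pairs(path) -> pd.DataFrame:
    """Read a harmonized-pairs TSV written by :func:`write_pairs`."""
    df = pd.read_csv(path, sep="\t")
    for col in PAIR_COLUMNS:
        if col not in df.columns:
            raise SumstatsError(f"required column {col!r} missing from {path}")
    df["flipped"] = df["flipped"].astype(bool)
    return df[list(PAIR_COLUMNS)]


def write_pairs(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, sep="\t", index=False)
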