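"""Reading, validation and allele harmonization of GWAS summary statistics.

Two-sample MR combines marginal SNP-exposure and SNP-outcome effect
estimates obtained from different cohorts.  Before any estimator can be
applied, the two files must be expressed for the *same* effect allele at
every shared variant.  This module reads delimited summary-statistic
tables into a validated, canonical column layout and aligns outcome
effects to the exposure's effect allele, flipping signs and frequencies
where the coding differs and excluding variants whose allele sets cannot
be reconciled.

Conventions
-----------
* Variants are matched on rsid; chromosome/position are cross-checked
  when present on both sides.
* Coordinates are 1-based and intervals fully closed.
* Binary-trait effects are natural-log odds ratios.
* Palindromic variants (A/T or C/G) are strand-ambiguous; by default
  they are dropped, or the strand can be inferred from the effect-allele
  frequency when it is far from 0.5 on both sides.
* Indels are matched by exact allele-string equality (no left-alignment
  normalisation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "COLUMNS",
    "DEFAULT_DIALECT",
    "SummaryStatError",
    "HarmonizeResult",
    "read_summary_stats",
    "write_summary_stats",
    "harmonize",
    "is_palindromic",
]

#: canonical column order for an association table
COLUMNS = [
    "rsid", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "info", "n", "trait_id", "trait_type",
]

REQUIRED = ["rsid", "effect_allele", "other_allele", "beta", "se", "pvalue"]

#: identity header map; pass e.g. {"SNP": "rsid", "A1": "effect_allele", ...}
DEFAULT_DIALECT: dict[str, str] = {c: c for c in COLUMNS}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SummaryStatError(ValueError):
    """Raised for malformed summary-statistic input."""


def _complement(allele: str) -> str | None:
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(allele))
    except KeyError:
        return None


def is_palindromic(a1: str, a2: str) -> bool:
    """True when the allele pair is its own reverse complement (A/T or C/G)."""
    comp = _complement(a2)
    return comp is not None and comp == a1


def _validate(df: pd.DataFrame) -> pd.Series:
    """Return a Series of per-row failure reasons ('' when valid)."""
    reason = pd.Series("", index=df.index, dtype=object)

    def flag(mask: pd.Series, code: str) -> None:
        sel = mask & (reason == "")
        reason[sel] = code

    flag(df["rsid"].isna() | (df["rsid"].astype(str).str.len() == 0), "missing_rsid")
    flag(~np.isfinite(df["beta"]), "nonnumeric_beta")
    flag(~np.isfinite(df["se"]) | (df["se"] <= 0), "nonpositive_se")
    flag(~np.isfinite(df["pvalue"]) | (df["pvalue"] <= 0) | (df["pvalue"] > 1), "pvalue_out_of_range")
    ea = df["effect_allele"].astype(str).str.upper()
    oa = df["other_allele"].astype(str).str.upper()
    flag(ea == oa, "identical_alleles")
    flag(~ea.str.fullmatch("[ACGT]+") | ~oa.str.fullmatch("[ACGT]+"), "invalid_allele")
    if "eaf" in df and df["eaf"].notna().any():
        flag(df["eaf"].notna() & ((df["eaf"] < 0) | (df["eaf"] > 1)), "eaf_out_of_range")
    if "pos" in df and df["pos"].notna().any():
        flag(df["pos"].notna() & (df["pos"] < 1), "nonpositive_pos")
    return reason


def read_summary_stats(
    path,
    dialect: dict[str, str] | None = None,
    sep: str | None = None,
    trait_id: str | None = None,
    trait_type: str | None = None,
    on_invalid: str = "error",
) -> pd.DataFrame:
    """Read a delimited GWAS summary-statistic table.

    Parameters
    ----------
    path
        Delimited text file with a header row; ``.gz`` is transparent.
    dialect
        Mapping from file column names to canonical names
        (:data:`COLUMNS`).  Unmapped canonical columns that are optional
        (eaf, info, n, chrom, pos) are filled with NA.
    sep
        Field separator; autodetected (tab or comma) when None.
    trait_id, trait_type
        Defaults applied when the file carries no such columns.
    on_invalid
        ``"error"`` raises :class:`SummaryStatError` listing the failing
        rows; ``"drop"`` removes them and records them in
        ``df.attrs["excluded"]``.

    Returns
    -------
    DataFrame in canonical column order, one row per valid record.
    """
    raw = pd.read_csv(path, sep=sep if sep is not None else None, engine="python")
    if dialect:
        rename = {src: dst for src, dst in dialect.items() if src in raw.columns}
        raw = raw.rename(columns=rename)
    missing = [c for c in REQUIRED if c not in raw.columns]
    if missing:
        raise SummaryStatError(f"missing required column(s): {missing} in {path}")

    df = pd.DataFrame(index=raw.index)
    for col in COLUMNS:
        df[col] = raw[col] if col in raw.columns else pd.NA
    for col in ("beta", "se", "pvalue", "eaf", "info"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce").astype("Int64")
    df["n"] = pd.to_numeric(df["n"], errors="coerce")
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    df["chrom"] = df["chrom"].astype("string")
    if trait_id is not None:
        df["trait_id"] = df["trait_id"].fillna(trait_id) if df["trait_id"].notna().any() else trait_id
    if trait_type is not None:
        df["trait_type"] = df["trait_type"].fillna(trait_type) if df["trait_type"].notna().any() else trait_type
    if df["trait_type"].notna().any():
        bad = df["trait_type"].dropna().unique().tolist()
        bad = [t for t in bad if t not in ("binary", "quantitative")]
        if bad:
            raise SummaryStatError(f"unknown trait_type value(s): {bad}")

    reason = _validate(df)
    invalid = reason != ""
    if invalid.any():
        detail = pd.DataFrame({"row": df.index[invalid], "rsid": df.loc[invalid, "rsid"],
                               "reason": reason[invalid]})
        if on_invalid == "error":
            raise SummaryStatError(
                f"{invalid.sum()} invalid row(s) in {path}:\n{detail.to_string(index=False)}"
            )
        logger.warning("dropped %d invalid row(s) from %s", invalid.sum(), path)
        df = df[~invalid].reset_index(drop=True)
        df.attrs["excluded"] = detail.reset_index(drop=True)
    return df[COLUMNS]


def write_summary_stats(df: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write an association table in the canonical layout."""
    df.to_csv(path, sep=sep, index=False)


@dataclass
class HarmonizeResult:
    """Aligned exposure/outcome pairs plus the exclusion log."""

    pairs: pd.DataFrame
    excluded: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.pairs)


PAIR_COLUMNS = [
    "rsid", "chrom", "pos", "effect_allele", "other_allele",
    "beta_x", "se_x", "beta_y", "se_y", "eaf", "flipped", "palindromic",
]


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindrome_policy: str = "drop",
    eaf_threshold: float = 0.42,
) -> HarmonizeResult:
    """Align outcome effects to the exposure's effect allele per variant.

    For each rsid present in both tables the outcome record is re-expressed
    for the exposure's effect allele: if the outcome's effect allele equals
    the exposure's other allele, the outcome beta is negated and its EAF
    replaced by ``1 - eaf`` (``flipped=True``).  Alleles reported on the
    opposite strand are complemented first.  Strand-ambiguous palindromic
    variants follow ``palindrome_policy``:

    ``"drop"``
        excluded with reason ``"palindromic"``.
    ``"infer_by_eaf"``
        kept when both EAFs lie outside ``[eaf_threshold, 1 - eaf_threshold]``
        (default 0.42, i.e. at least 0.08 away from 0.5); the minor-allele
        side then resolves the strand.  Ambiguous ones are dropped with
        reason ``"palindromic_ambiguous"``.

    Variants with irreconcilable allele sets are excluded with reason
    ``"allele_mismatch"``; duplicated rsids with ``"duplicate_rsid"``;
    discordant chrom/pos (when present on both sides) with
    ``"position_mismatch"``.
    """
    if palindrome_policy not in ("drop", "infer_by_eaf"):
        raise ValueError(f"unknown palindrome_policy: {palindrome_policy!r}")

    exc_rows: list[dict] = []

    def dedup(df: pd.DataFrame, side: str) -> pd.DataFrame:
        dup = df["rsid"].duplicated(keep=False)
        for r in df.loc[dup, "rsid"].unique():
            exc_rows.append({"rsid": r, "reason": "duplicate_rsid", "side": side})
        return df[~dup]

    exp = dedup(exposure, "exposure").set_index("rsid")
    out = dedup(outcome, "outcome").set_index("rsid")
    shared = exp.index.intersection(out.index)

    rows: list[dict] = []
    for rsid in shared:
        e, o = exp.loc[rsid], out.loc[rsid]
        if (
            pd.notna(e["chrom"]) and pd.notna(o["chrom"])
            and pd.notna(e["pos"]) and pd.notna(o["pos"])
            and (str(e["chrom"]) != str(o["chrom"]) or int(e["pos"]) != int(o["pos"]))
        ):
            exc_rows.append({"rsid": rsid, "reason": "position_mismatch", "side": "both"})
            continue

        ea_x, oa_x = e["effect_allele"], e["other_allele"]
        ea_y, oa_y = o["effect_allele"], o["other_allele"]
        palin = is_palindromic(ea_x, oa_x)

        if palin:
            if {ea_y, oa_y} != {ea_x, oa_x}:
                exc_rows.append({"rsid": rsid, "reason": "allele_mismatch", "side": "both"})
                continue
            # for a palindromic pair strand flips are invisible; only the
            # allele labels decide the orientation, optionally sanity-checked
            # against EAF
            if palindrome_policy == "drop":
                exc_rows.append({"rsid": rsid, "reason": "palindromic", "side": "both"})
                continue
            eaf_x, eaf_y = e["eaf"], o["eaf"]
            if (
                pd.isna(eaf_x) or pd.isna(eaf_y)
                or eaf_threshold <= eaf_x <= 1 - eaf_threshold
                or eaf_threshold <= eaf_y <= 1 - eaf_threshold
            ):
                exc_rows.append({"rsid": rsid, "reason": "palindromic_ambiguous", "side": "both"})
                continue
            # orient by allele labels, then let the frequencies veto the
            # strand: after applying the label orientation both EAFs must
            # fall on the same side of 0.5, otherwise the outcome file is
            # on the opposite strand and the orientation is inverted
            label_flip = ea_y == oa_x and oa_y == ea_x
            eaf_y_oriented = 1.0 - eaf_y if label_flip else eaf_y
            same_side = (eaf_x < 0.5) == (eaf_y_oriented < 0.5)
            flipped = label_flip if same_side else not label_flip
        else:
            if ea_y == ea_x and oa_y == oa_x:
                flipped = False
            elif ea_y == oa_x and oa_y == ea_x:
                flipped = True
            else:
                cea, coa = _complement(ea_y), _complement(oa_y)
                if cea == ea_x and coa == oa_x:
                    flipped = False
                elif cea == oa_x and coa == ea_x:
                    flipped = True
                else:
                    exc_rows.append({"rsid": rsid, "reason": "allele_mismatch", "side": "both"})
                    continue

        beta_y = -o["beta"] if flipped else o["beta"]
        eaf_y = o["eaf"]
        if flipped and pd.notna(eaf_y):
            eaf_y = 1.0 - eaf_y
        rows.append({
            "rsid": rsid,
            "chrom": e["chrom"] if pd.notna(e["chrom"]) else o["chrom"],
            "pos": e["pos"] if pd.notna(e["pos"]) else o["pos"],
            "effect_allele": ea_x,
            "other_allele": oa_x,
            "beta_x": float(e["beta"]),
            "se_x": float(e["se"]),
            "beta_y": float(beta_y),
            "se_y": float(o["se"]),
            "eaf": float(e["eaf"]) if pd.notna(e["eaf"]) else (float(eaf_y) if pd.notna(eaf_y) else np.nan),
            "flipped": bool(flipped),
            "palindromic": bool(palin),
        })

    pairs = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    excluded = pd.DataFrame(exc_rows, columns=["rsid", "reason", "side"])
    if len(excluded):
        logger.info("harmonize: excluded %d variant(s)", len(excluded))
    return HarmonizeResult(pairs=pairs, excluded=excluded)
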