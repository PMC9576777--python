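"""pQTL instrument selection: LD clumping, cis/trans classification, strength.

A protein's instruments are the approximately independent genome-wide
significant variants from its pQTL GWAS.  Independence is enforced by
greedy LD clumping against a reference LD correlation matrix: candidates
are ranked by p-value and each selected index variant removes every
remaining candidate within a window that is correlated with it above an
r-squared threshold (defaults r2 >= 0.1 within +/-1 Mb, p <= 5e-8).

Instruments are classified *cis* when they fall within +/-1 Mb of the
gene body encoding the target protein, *trans* otherwise.  Per-variant
strength is summarised by the F-statistic F = (beta/se)^2 and the
variance explained R^2 = F / (F + n - 2), the standard summary-data
approximations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LDMatrix",
    "GeneRegion",
    "InstrumentSet",
    "ld_clump",
    "classify_cis_trans",
    "instrument_strength",
    "build_instrument_set",
]


@dataclass
class LDMatrix:
    """Pairwise LD correlations (signed r) for an ordered set of variants."""

    variants: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.variants)
        if self.r.shape != (m, m):
            raise ValueError(f"LD matrix shape {self.r.shape} does not match {m} variants")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-6):
            raise ValueError("LD matrix diagonal is not 1")
        self._index = {v: i for i, v in enumerate(self.variants)}

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def submatrix(self, rsids: list[str]) -> np.ndarray:
        idx = [self._index[v] for v in rsids]
        return self.r[np.ix_(idx, idx)]

    def r2(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]] ** 2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.variants, columns=self.variants)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LDMatrix":
        return cls(variants=list(df.index.astype(str)), r=df.to_numpy(dtype=float))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="rsid")

    @classmethod
    def from_tsv(cls, path) -> "LDMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t", index_col=0))


@dataclass(frozen=True)
class GeneRegion:
    """Gene body coordinates (1-based, closed) used for cis classification."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")


@dataclass
class InstrumentSet:
    """The clumped, cis/trans-annotated instruments for one protein.

    ``table`` has one row per instrument with the association columns plus
    ``cis`` (bool), ``f_stat`` and ``r2_explained``.
    """

    protein_id: str
    table: pd.DataFrame
    total_r2: float = field(default=np.nan)

    @property
    def n_instruments(self) -> int:
        return len(self.table)

    def subset(self, cis_only: bool) -> "InstrumentSet":
        tab = self.table[self.table["cis"]] if cis_only else self.table
        tab = tab.reset_index(drop=True)
        total = float(tab["r2_explained"].sum()) if len(tab) else 0.0
        return InstrumentSet(self.protein_id, tab, total_r2=total)


def ld_clump(
    assocs: pd.DataFrame,
    ld: LDMatrix,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.1,
    window_bp: int = 1_000_000,
) -> list[str]:
    """Greedy LD clumping; returns retained index-variant rsids in selection order.

    Candidates are the rows with ``pvalue <= p_threshold``.  Repeatedly the
    remaining candidate with the smallest p-value (ties broken by
    chromosome, position, rsid) becomes an index variant; every remaining
    candidate on the same chromosome within ``window_bp`` of it with
    ``r^2 >= r2_threshold`` is assigned to its clump and removed.  A
    candidate absent from the LD matrix is excluded with a warning rather
    than assumed independent.
    """
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must be in (0, 1)")
    cand = assocs.loc[assocs["pvalue"] <= p_threshold].copy()
    missing = [v for v in cand["rsid"] if v not in ld]
    if missing:
        import logging
        logging.getLogger(__name__).warning(
            "ld_clump: %d candidate(s) absent from LD matrix, excluded: %s",
            len(missing), missing[:10],
        )
        cand = cand[~cand["rsid"].isin(missing)]
    if cand.empty:
        return []
    cand = cand.sort_values(
        ["pvalue", "chrom", "pos", "rsid"], kind="mergesort"
    ).reset_index(drop=True)

    alive = np.ones(len(cand), dtype=bool)
    kept: list[str] = []
    rsids = cand["rsid"].to_numpy()
    chroms = cand["chrom"].astype(str).to_numpy()
    pos = cand["pos"].to_numpy(dtype=float)
    for i in range(len(cand)):
        if not alive[i]:
            continue
        alive[i] = False
        kept.append(rsids[i])
        near = alive & (chroms == chroms[i]) & (np.abs(pos - pos[i]) <= window_bp)
        for j in np.nonzero(near)[0]:
            if ld.r2(rsids[i], rsids[j]) >= r2_threshold:
                alive[j] = False
    return kept


def classify_cis_trans(
    chrom: str,
    pos: int,
    region: GeneRegion,
    window_bp: int = 1_000_000,
) -> str:
    """Classify a variant as ``"cis"`` (within +/-window of the gene body) or ``"trans"``."""
    if str(chrom) != str(region.chrom):
        return "trans"
    if region.start - window_bp <= pos <= region.end + window_bp:
        return "cis"
    return "trans"


def instrument_strength(beta: float, se: float, n: float | None) -> tuple[float, float]:
    """Per-instrument F-statistic and variance explained.

    F = (beta/se)^2; R^2 = F / (F + n - 2).  With ``n`` missing, R^2 is
    returned as NaN while F is still computed.
    """
    if se <= 0:
        raise ValueError("se must be positive")
    f = (beta / se) ** 2
    if n is None or not np.isfinite(n):
        return float(f), float("nan")
    if n <= 1:
        raise ValueError("n must exceed 1")
    return float(f), float(f / (f + n - 2))


def build_instrument_set(
    protein_id: str,
    assocs: pd.DataFrame,
    ld: LDMatrix,
    gene_region: GeneRegion | None = None,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.1,
    window_bp: int = 1_000_000,
    cis_window_bp: int = 1_000_000,
) -> InstrumentSet:
    """Clump a protein's pQTL associations and annotate cis/trans and strength."""
    kept = ld_clump(assocs, ld, p_threshold, r2_threshold, window_bp)
    tab = assocs.set_index("rsid").loc[kept].reset_index()
    if gene_region is not None:
        tab["cis"] = [
            classify_cis_trans(c, p, gene_region, cis_window_bp) == "cis"
            for c, p in zip(tab["chrom"], tab["pos"])
        ]
    else:
        tab["cis"] = False
    strengths = [
        instrument_strength(b, s, n if pd.notna(n) else None)
        for b, s, n in zip(tab["beta"], tab["se"], tab.get("n", pd.Series(np.nan, index=tab.index)))
    ]
    tab["f_stat"] = [f for f, _ in strengths]
    tab["r2_explained"] = [r2 for _, r2 in strengths]
    total = float(np.nansum(tab["r2_explained"])) if len(tab) else 0.0
    return InstrumentSet(protein_id=protein_id, table=tab, total_r2=total)
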