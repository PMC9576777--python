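"""Phenome-wide MR screen of proteins across many binary phenotypes.

Each selected protein is tested against every phenotype in a PheCode-like
catalogue using the primary MR dispatch (Wald ratio or IVW).  Phenotypes
with fewer than 500 cases are excluded for power; significance uses a
layered Bonferroni threshold alpha / (n_proteins * n_phenotypes); and
each significant effect is classed *beneficial* when its direction
matches the protein's effect on stroke (intervening on the protein for
stroke would move this phenotype the right way too) and *deleterious*
when it opposes it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimators import MREstimate, select_primary

__all__ = [
    "PhenotypeMeta",
    "ScreenRow",
    "filter_phenotypes",
    "classify_direction",
    "screen_threshold",
    "run_screen",
]


@dataclass(frozen=True)
class PhenotypeMeta:
    """PheCode-like phenotype with case/control counts."""

    phenotype_id: str
    label: str
    n_cases: int
    n_controls: int

    def __post_init__(self) -> None:
        if self.n_cases < 0:
            raise ValueError("n_cases must be >= 0")


@dataclass(frozen=True)
class ScreenRow:
    """One (protein, phenotype) result of the phenome-wide screen."""

    protein_id: str
    phenotype_id: str
    estimate: MREstimate | None
    significant: bool
    direction_class: str  # beneficial | deleterious | not_applicable
    reason: str = ""


def filter_phenotypes(
    metas: list[PhenotypeMeta], min_cases: int = 500
) -> tuple[list[PhenotypeMeta], list[PhenotypeMeta]]:
    """Retain phenotypes with at least ``min_cases`` cases.

    Returns (retained, excluded); "fewer than 500 cases" is read literally,
    so exactly 500 is retained.
    """
    retained = [m for m in metas if m.n_cases >= min_cases]
    excluded = [m for m in metas if m.n_cases < min_cases]
    return retained, excluded


def classify_direction(effect_on_phenotype: float, effect_on_stroke: float) -> str:
    """Beneficial when the phenotype effect points the same way as the stroke effect."""
    if effect_on_stroke == 0 or not np.isfinite(effect_on_stroke):
        return "not_applicable"
    return "beneficial" if effect_on_phenotype * effect_on_stroke > 0 else "deleterious"


def screen_threshold(alpha_family: float, n_proteins: int, n_phenotypes: int) -> float:
    """Layered Bonferroni threshold alpha / n_proteins / n_phenotypes."""
    if n_proteins < 1 or n_phenotypes < 1:
        raise ValueError("counts must be positive")
    return alpha_family / n_proteins / n_phenotypes


def run_screen(
    pairs_by_protein_phenotype: dict[tuple[str, str], pd.DataFrame],
    stroke_effects: dict[str, float],
    phenotypes: list[PhenotypeMeta],
    alpha_family: float = 0.05,
    min_cases: int = 500,
    n_phenotypes_override: int | None = None,
) -> pd.DataFrame:
    """Run the phenome-wide MR screen.

    Parameters
    ----------
    pairs_by_protein_phenotype
        Harmonized pair tables keyed by (protein_id, phenotype_id).
    stroke_effects
        Reference log-OR of each protein on stroke, used for the
        beneficial/deleterious call; proteins missing here get
        ``not_applicable`` throughout.
    phenotypes
        Phenotype catalogue; the case-count filter and the Bonferroni
        denominator are derived from it (post-filter count), unless
        ``n_phenotypes_override`` pins the denominator.

    Returns a long DataFrame, one row per tested (protein, phenotype).
    """
    retained, excluded = filter_phenotypes(phenotypes, min_cases)
    keep_ids = {m.phenotype_id for m in retained}
    proteins = sorted({p for p, _ in pairs_by_protein_phenotype})
    n_phe = n_phenotypes_override if n_phenotypes_override is not None else len(retained)
    threshold = screen_threshold(alpha_family, max(len(proteins), 1), max(n_phe, 1))

    rows = []
    for (protein, phenotype), pairs in sorted(pairs_by_protein_phenotype.items()):
        if phenotype not in keep_ids:
            continue
        stroke_beta = stroke_effects.get(protein, np.nan)
        if pairs is None or len(pairs) == 0:
            rows.append({
                "protein_id": protein, "phenotype_id": phenotype,
                "theta": np.nan, "se": np.nan, "pvalue": np.nan, "n_snps": 0,
                "method": "", "significant": False,
                "direction_class": "not_applicable",
                "reason": "no_overlapping_instruments",
            })
            continue
        est, _ = select_primary(pairs)
        sig = bool(est.pvalue <= threshold)
        direction = classify_direction(est.theta, stroke_beta) if not np.isnan(stroke_beta) \
            else "not_applicable"
        rows.append({
            "protein_id": protein, "phenotype_id": phenotype,
            "theta": est.theta, "se": est.se, "pvalue": est.pvalue,
            "n_snps": est.n_snps, "method": est.method,
            "significant": sig, "direction_class": direction, "reason": "",
        })
    out = pd.DataFrame(rows)
    out.attrs["threshold"] = threshold
    out.attrs["n_proteins"] = len(proteins)
    out.attrs["n_phenotypes"] = n_phe
    out.attrs["excluded_phenotypes"] = [m.phenotype_id for m in excluded]
    return out
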