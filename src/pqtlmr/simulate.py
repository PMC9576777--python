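"""Synthetic GWAS summary statistics with the structure the pipeline assumes.

Summary statistics are simulated directly — no individual-level genotypes
— using the standard multivariate-normal model for LD-correlated marginal
estimates: with joint per-allele effects ``b`` and LD correlation matrix
``R``, the marginal estimates satisfy ``beta_hat ~ MVN(R b, D R D)``
where ``D = diag(se)`` and ``se_j = 1 / sqrt(2 maf_j (1 - maf_j) n)``
for a variance-1 trait.  Binary outcomes use the asymptotic logistic
approximation: the SE gains a factor ``1 / sqrt(case_frac (1-case_frac))``
relative to the effective sample size.

LD is AR(1): ``r_jk = rho^|j-k|``, positive definite by construction.

Default sample sizes mirror a typical proteomic-GWAS-to-disease-GWAS
design: ~5,000 exposure samples (plasma proteome cohort) and ~450,000
outcome samples with ~9% cases (stroke GWAS meta-analysis scale).

Scenarios
---------
``null``, ``causal``, ``pleiotropic`` — one exposure, one outcome, a
configurable causal effect theta and per-variant pleiotropy (balanced or
directional).  ``coloc_shared`` / ``coloc_distinct`` — several traits
driven by one shared or by disjoint causal variants.
``mediation_chain`` — three linked regions realising an
exposure -> mediator -> outcome chain with a residual direct effect.

Every simulation stores a truth record (true theta, causal indices,
pleiotropy draws) so estimators are scored against stored truth, never
against re-derived quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .coloc import RegionalAssoc
from .harmonize import COLUMNS
from .instruments import GeneRegion, LDMatrix

__all__ = [
    "Pleiotropy",
    "ScenarioConfig",
    "Truth",
    "SyntheticRegion",
    "MediationChain",
    "OutcomeSpec",
    "StudyPanel",
    "simulate_ld",
    "simulate_region",
    "simulate_multi_outcome_region",
    "simulate_study_panel",
    "simulate_coloc_scenario",
    "simulate_mediation_chain",
    "simulate_scenario",
]

#: default sample sizes: proteomics cohort / disease GWAS with ~9% cases
N_EXPOSURE = 5_000
N_OUTCOME = 446_696
CASE_FRAC = 40_585 / 446_696


@dataclass(frozen=True)
class Pleiotropy:
    """Per-variant direct effects on the outcome bypassing the exposure."""

    kind: str = "none"  # none | balanced | directional
    mean: float = 0.0
    sd: float = 0.0

    def draw(self, rng: np.random.Generator, m: int) -> np.ndarray:
        if self.kind == "none":
            return np.zeros(m)
        if self.kind == "balanced":
            return rng.normal(0.0, self.sd, m)
        if self.kind == "directional":
            return rng.normal(self.mean, self.sd, m)
        raise ValueError(f"unknown pleiotropy kind {self.kind!r}")


@dataclass(frozen=True)
class ScenarioConfig:
    """Generative settings for one simulated region (seed is mandatory)."""

    seed: int
    scenario: str = "causal"
    n_variants: int = 100
    ld_rho: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_exposure: int = N_EXPOSURE
    n_outcome: int = N_OUTCOME
    case_frac: float = CASE_FRAC
    outcome_binary: bool = True
    causal_variants: tuple[tuple[int, float], ...] = ((10, 0.3), (40, 0.25), (70, 0.2))
    theta: float = 0.0
    pleiotropy: Pleiotropy = Pleiotropy()
    n_traits: int = 2  # colocalization scenarios
    coloc_groups: tuple[int, ...] | None = None  # sizes of distinct-variant trait groups
    z_lead: float = 8.0
    chain_params: tuple[float, float, float] = (0.2, 0.5, 0.1)  # beta_EM, beta_MO, direct_EO
    chrom: str = "1"
    pos_start: int = 1_000_000
    pos_step: int = 5_000

    def __post_init__(self) -> None:
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must be in [0, 1)")
        if self.scenario not in ("coloc_shared", "coloc_distinct"):
            # coloc scenarios place their own causal variants
            for idx, _ in self.causal_variants:
                if not 0 <= idx < self.n_variants:
                    raise ValueError(f"causal index {idx} out of range")
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")


@dataclass(frozen=True)
class Truth:
    """Generative truth for scoring estimators."""

    theta: float
    b: np.ndarray
    causal_indices: tuple[int, ...]
    pleiotropy: np.ndarray
    mafs: np.ndarray
    label: str = ""


@dataclass
class SyntheticRegion:
    """One simulated region: LD, per-trait association tables, truth."""

    ld: LDMatrix
    tables: dict[str, pd.DataFrame]
    truth: Truth
    gene_region: GeneRegion | None = None

    def pairs(self, exposure: str, outcome: str, rsids: list[str] | None = None) -> pd.DataFrame:
        """Aligned harmonized-pair frame (alleles are shared by construction)."""
        e = self.tables[exposure]
        o = self.tables[outcome].set_index("rsid")
        if rsids is not None:
            e = e[e["rsid"].isin(rsids)]
        o = o.loc[e["rsid"]]
        return pd.DataFrame({
            "rsid": e["rsid"].to_numpy(),
            "chrom": e["chrom"].to_numpy(),
            "pos": e["pos"].to_numpy(),
            "effect_allele": e["effect_allele"].to_numpy(),
            "other_allele": e["other_allele"].to_numpy(),
            "beta_x": e["beta"].to_numpy(float),
            "se_x": e["se"].to_numpy(float),
            "beta_y": o["beta"].to_numpy(float),
            "se_y": o["se"].to_numpy(float),
            "eaf": e["eaf"].to_numpy(float),
            "flipped": False,
            "palindromic": False,
        })

    def to_regional_assoc(self, trait_ids: list[str] | None = None) -> RegionalAssoc:
        trait_ids = trait_ids or list(self.tables)
        beta = np.array([self.tables[t]["beta"].to_numpy(float) for t in trait_ids])
        se = np.array([self.tables[t]["se"].to_numpy(float) for t in trait_ids])
        types = [str(self.tables[t]["trait_type"].iloc[0]) for t in trait_ids]
        return RegionalAssoc(
            variants=list(self.tables[trait_ids[0]]["rsid"]),
            trait_ids=trait_ids, trait_types=types, beta=beta, se=se,
        )


@dataclass
class MediationChain:
    """Three linked regions realising an E -> M -> O chain."""

    exposure_region: SyntheticRegion  # traits: E, M, O (E-instrument region)
    mediator_region: SyntheticRegion  # traits: M, O (M-instrument region)
    beta_EM: float
    beta_MO: float
    direct_EO: float

    @property
    def total_EO(self) -> float:
        return self.direct_EO + self.beta_EM * self.beta_MO

    @property
    def true_proportion(self) -> float:
        return self.beta_EM * self.beta_MO / self.total_EO


def simulate_ld(
    n_variants: int, ld_rho: float, seed: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    prefix: str = "rs",
) -> tuple[LDMatrix, np.ndarray]:
    """AR(1) LD matrix ``r_jk = rho^|j-k|`` plus uniform MAFs."""
    if not 0 <= ld_rho < 1:
        raise ValueError("ld_rho must be in [0, 1)")
    idx = np.arange(n_variants)
    r = ld_rho ** np.abs(idx[:, None] - idx[None, :])
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(*maf_range, size=n_variants)
    variants = [f"{prefix}{i + 1}" for i in idx]
    return LDMatrix(variants=variants, r=r), mafs


def _marginal_se(mafs: np.ndarray, n: float, case_frac: float | None = None) -> np.ndarray:
    se = 1.0 / np.sqrt(2 * mafs * (1 - mafs) * n)
    if case_frac is not None:
        se = se / np.sqrt(case_frac * (1 - case_frac))
    return se


def _draw_marginal(
    rng: np.random.Generator,
    chol_r: np.ndarray,
    mean: np.ndarray,
    se: np.ndarray,
) -> np.ndarray:
    """One draw from MVN(mean, D R D) via the LD Cholesky factor."""
    z = rng.standard_normal(len(mean))
    return mean + se * (chol_r @ z)


def _table(
    ld: LDMatrix, mafs: np.ndarray, beta: np.ndarray, se: np.ndarray,
    trait_id: str, trait_type: str, n: float, config: ScenarioConfig,
) -> pd.DataFrame:
    z = beta / se
    p = 2 * stats.norm.sf(np.abs(z))
    m = len(mafs)
    df = pd.DataFrame({
        "rsid": ld.variants,
        "chrom": config.chrom,
        "pos": config.pos_start + config.pos_step * np.arange(m),
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": mafs,
        "beta": beta,
        "se": se,
        "pvalue": np.clip(p, np.finfo(float).tiny, 1.0),
        "info": 1.0,
        "n": n,
        "trait_id": trait_id,
        "trait_type": trait_type,
    })
    return df[COLUMNS]


@dataclass(frozen=True)
class OutcomeSpec:
    """One downstream trait simulated over an exposure's region."""

    trait_id: str
    theta: float = 0.0
    binary: bool = True
    pleiotropy: Pleiotropy = Pleiotropy()
    n: float | None = None
    case_frac: float | None = None


def simulate_multi_outcome_region(
    config: ScenarioConfig,
    outcomes: list[OutcomeSpec],
    label: str = "",
    exposure_id: str = "protein",
) -> SyntheticRegion:
    """Simulate one exposure region with any number of downstream traits.

    The exposure carries the configured causal variants; each outcome's
    marginal mean is its ``theta`` times the exposure's marginal mean plus
    that outcome's per-variant pleiotropy draws.  All traits' estimates are
    drawn with the same LD correlation.
    """
    rng = np.random.default_rng(config.seed)
    ld, mafs = simulate_ld(config.n_variants, config.ld_rho, config.seed,
                           config.maf_range)
    chol = np.linalg.cholesky(ld.r + 1e-10 * np.eye(config.n_variants))

    b = np.zeros(config.n_variants)
    for idx, eff in config.causal_variants:
        b[idx] = eff
    mean_x = ld.r @ b
    se_x = _marginal_se(mafs, config.n_exposure)
    beta_x = _draw_marginal(rng, chol, mean_x, se_x)

    tables = {
        exposure_id: _table(ld, mafs, beta_x, se_x, exposure_id, "quantitative",
                            config.n_exposure, config),
    }
    alpha_main = np.zeros(config.n_variants)
    for spec in outcomes:
        alpha = spec.pleiotropy.draw(rng, config.n_variants)
        if spec.trait_id == "outcome":
            alpha_main = alpha
        n = spec.n if spec.n is not None else config.n_outcome
        cf = spec.case_frac if spec.case_frac is not None else config.case_frac
        mean_y = spec.theta * mean_x + alpha
        se_y = _marginal_se(mafs, n, cf if spec.binary else None)
        beta_y = _draw_marginal(rng, chol, mean_y, se_y)
        tables[spec.trait_id] = _table(
            ld, mafs, beta_y, se_y, spec.trait_id,
            "binary" if spec.binary else "quantitative", n, config,
        )

    theta_main = next((s.theta for s in outcomes if s.trait_id == "outcome"), config.theta)
    truth = Truth(theta=theta_main, b=b,
                  causal_indices=tuple(i for i, _ in config.causal_variants),
                  pleiotropy=alpha_main, mafs=mafs, label=label or config.scenario)
    mid = config.pos_start + config.pos_step * (config.n_variants // 2)
    gene = GeneRegion(f"GENE_{exposure_id}", config.chrom,
                      max(1, mid - 10_000), mid + 10_000)
    return SyntheticRegion(ld=ld, tables=tables, truth=truth, gene_region=gene)


def simulate_region(config: ScenarioConfig, label: str = "") -> SyntheticRegion:
    """One exposure region with a single downstream outcome (see config)."""
    spec = OutcomeSpec(
        trait_id="outcome", theta=config.theta, binary=config.outcome_binary,
        pleiotropy=config.pleiotropy,
    )
    return simulate_multi_outcome_region(config, [spec], label=label)


def simulate_coloc_scenario(config: ScenarioConfig) -> SyntheticRegion:
    """Multi-trait region with one shared or several distinct causal variants.

    ``coloc_shared``: a single causal variant drives all ``n_traits``
    traits, each with lead |z| about ``z_lead``.  ``coloc_distinct``:
    trait t is driven by its own causal variant, spread across the region.
    ``null``: no trait has any causal variant.
    """
    if config.scenario not in ("coloc_shared", "coloc_distinct", "null"):
        raise ValueError(f"not a colocalization scenario: {config.scenario!r}")
    rng = np.random.default_rng(config.seed)
    ld, mafs = simulate_ld(config.n_variants, config.ld_rho, config.seed,
                           config.maf_range)
    m = config.n_variants
    chol = np.linalg.cholesky(ld.r + 1e-10 * np.eye(m))
    se = _marginal_se(mafs, config.n_outcome)

    if config.scenario == "coloc_shared":
        causal = [m // 2] * config.n_traits
    elif config.scenario == "coloc_distinct":
        groups = config.coloc_groups or tuple(1 for _ in range(config.n_traits))
        if sum(groups) != config.n_traits:
            raise ValueError("coloc_groups must sum to n_traits")
        causal = []
        for g, size in enumerate(groups):
            causal += [int(round((g + 0.5) * m / len(groups)))] * size
    else:
        causal = [None] * config.n_traits

    tables: dict[str, pd.DataFrame] = {}
    for t in range(config.n_traits):
        b = np.zeros(m)
        if causal[t] is not None:
            b[causal[t]] = config.z_lead * se[causal[t]]
        mean = ld.r @ b
        beta = _draw_marginal(rng, chol, mean, se)
        tid = f"trait{t + 1}"
        tables[tid] = _table(ld, mafs, beta, se, tid, "quantitative",
                             config.n_outcome, config)
    truth = Truth(theta=np.nan, b=np.zeros(m),
                  causal_indices=tuple(c for c in causal if c is not None),
                  pleiotropy=np.zeros(m), mafs=mafs, label=config.scenario)
    return SyntheticRegion(ld=ld, tables=tables, truth=truth)


def simulate_mediation_chain(config: ScenarioConfig) -> MediationChain:
    """Three linked regions consistent with an E -> M -> O causal chain.

    The exposure-instrument region carries E's pQTLs and, through the
    chain, marginal effects on the mediator (``beta_EM`` per unit E) and
    on the outcome (total ``direct_EO + beta_EM * beta_MO``).  The
    mediator-instrument region is disjoint and carries M's instruments
    and their ``beta_MO``-scaled outcome effects.
    """
    beta_EM, beta_MO, direct_EO = config.chain_params
    total = direct_EO + beta_EM * beta_MO
    seed = np.random.default_rng(config.seed).integers(2**31, size=2)

    cfg_e = replace(config, scenario="causal", theta=total, seed=int(seed[0]))
    region_e = simulate_region(cfg_e, label="mediation_chain:E")
    # add the mediator trait to E's region: marginal mean beta_EM * mean_x
    rng = np.random.default_rng(int(seed[0]) + 1)
    ld = region_e.ld
    m = config.n_variants
    chol = np.linalg.cholesky(ld.r + 1e-10 * np.eye(m))
    mafs = region_e.truth.mafs
    mean_x = ld.r @ region_e.truth.b
    se_m = _marginal_se(mafs, config.n_outcome)  # mediator GWAS at outcome scale
    beta_m = _draw_marginal(rng, chol, beta_EM * mean_x, se_m)
    region_e.tables["mediator"] = _table(ld, mafs, beta_m, se_m, "mediator",
                                         "quantitative", config.n_outcome, cfg_e)

    cfg_m = replace(
        config, scenario="causal", theta=beta_MO, seed=int(seed[1]),
        chrom="2",  # disjoint instrument region
    )
    region_m = simulate_region(cfg_m, label="mediation_chain:M")
    region_m.tables["mediator"] = region_m.tables.pop("protein").assign(trait_id="mediator")

    return MediationChain(
        exposure_region=region_e, mediator_region=region_m,
        beta_EM=beta_EM, beta_MO=beta_MO, direct_EO=direct_EO,
    )


def simulate_scenario(config: ScenarioConfig) -> SyntheticRegion | MediationChain:
    """Dispatch on ``config.scenario``."""
    if config.scenario in ("coloc_shared", "coloc_distinct"):
        return simulate_coloc_scenario(config)
    if config.scenario == "mediation_chain":
        return simulate_mediation_chain(config)
    if config.scenario == "null":
        return simulate_region(replace(config, theta=0.0))
    if config.scenario == "causal":
        return simulate_region(config)
    if config.scenario == "pleiotropic":
        if config.pleiotropy.kind == "none":
            raise ValueError("pleiotropic scenario requires a pleiotropy spec")
        return simulate_region(config)
    raise ValueError(f"unknown scenario {config.scenario!r}")


@dataclass
class StudyPanel:
    """A synthetic multi-protein study for end-to-end pipeline runs.

    ``proteins`` maps protein id to its instrument region, whose tables
    hold the protein itself, every primary outcome and every risk factor.
    ``outcome_instruments`` and ``risk_factor_instruments`` are the
    reverse-direction and step-1 instrument regions; the outcome region's
    tables include each protein (for reverse MR), the risk-factor region's
    tables include each outcome (for risk-factor-to-outcome MR).
    ``labels`` records each protein's generative truth.
    """

    proteins: dict[str, SyntheticRegion]
    labels: dict[str, str]
    outcome_ids: list[str]
    risk_factor_ids: list[str]
    outcome_instruments: dict[str, SyntheticRegion]
    risk_factor_instruments: dict[str, SyntheticRegion]
    seed: int


def simulate_study_panel(
    seed: int,
    labels: dict[str, str],
    outcome_ids: tuple[str, ...] = ("stroke",),
    risk_factor_ids: tuple[str, ...] = ("risk_factor",),
    theta_causal: float = 0.1,
    theta_reverse: float = 0.5,
    beta_EM: float = 0.3,
    beta_MO: float = 0.4,
    direct_EO: float = 0.03,
    pleiotropy_directional: tuple[float, float] = (0.05, 0.05),
    n_variants: int = 60,
    ld_rho: float = 0.6,
) -> StudyPanel:
    """Simulate a labelled protein panel for the full decision procedure.

    ``labels`` maps protein id to one of ``causal`` (direct effect
    ``theta_causal`` on every outcome — a small log-OR, as typical for a
    protein-disease effect), ``null``, ``pleiotropic`` (no causal effect
    but directional per-variant pleiotropy across many instruments — an
    ABO-like pattern the sensitivity gates should catch), ``reverse_causal``
    (carries a forward signal *and* a strong outcome-to-protein effect
    ``theta_reverse`` visible from the outcome's own instruments, so the
    reverse-MR stage must flag it) and ``mediated`` (acts on the outcome
    through the first risk factor: effect ``beta_EM`` on the risk factor
    plus the implied total outcome effect ``direct_EO + beta_EM*beta_MO``).
    Risk factors affect outcomes with effect ``beta_MO``.
    """
    root = np.random.default_rng(seed)
    chroms = iter(str(c) for c in range(1, 23))

    proteins: dict[str, SyntheticRegion] = {}
    for pid, label in labels.items():
        sub = int(root.integers(2**31))
        # cis-pQTL effects are large (often several percent of protein
        # variance each); strong instruments also keep the exposure-side
        # noise from masquerading as heterogeneity downstream
        causal_variants = ((5, 0.6), (n_variants // 2, 0.5), (n_variants - 6, 0.45))
        if label == "pleiotropic":
            # many instruments make the directional-pleiotropy pattern
            # detectable by the Q/Egger/global gates
            step = max(1, n_variants // 8)
            causal_variants = tuple((min(5 + i * step, n_variants - 1), 0.5)
                                    for i in range(8))
        # panel-scale proteomics cohort (large modern pQTL GWAS); keeps the
        # ratio of exposure-side to outcome-side noise realistic for the
        # sensitivity gates
        cfg = ScenarioConfig(
            seed=sub, n_variants=n_variants, ld_rho=ld_rho,
            chrom=next(chroms), causal_variants=causal_variants,
            n_exposure=20_000,
        )
        if label == "causal":
            theta, pleio, rf_theta = theta_causal, Pleiotropy(), 0.0
        elif label == "null":
            theta, pleio, rf_theta = 0.0, Pleiotropy(), 0.0
        elif label == "pleiotropic":
            theta, rf_theta = 0.0, 0.0
            pleio = Pleiotropy("directional", *pleiotropy_directional)
        elif label == "reverse_causal":
            theta, pleio, rf_theta = theta_causal, Pleiotropy(), 0.0
        elif label == "mediated":
            theta, pleio, rf_theta = direct_EO + beta_EM * beta_MO, Pleiotropy(), beta_EM
        else:
            raise ValueError(f"unknown protein label {label!r}")
        specs = [OutcomeSpec(oid, theta=theta, binary=True, pleiotropy=pleio)
                 for oid in outcome_ids]
        specs += [
            OutcomeSpec(rid, theta=rf_theta if i == 0 else 0.0, binary=False)
            for i, rid in enumerate(risk_factor_ids)
        ]
        region = simulate_multi_outcome_region(cfg, specs, label=label)
        proteins[pid] = region

    outcome_instruments: dict[str, SyntheticRegion] = {}
    for oid in outcome_ids:
        sub = int(root.integers(2**31))
        cfg = ScenarioConfig(seed=sub, n_variants=n_variants, ld_rho=ld_rho,
                             chrom="22",
                             causal_variants=((5, 0.15), (n_variants // 2, 0.12),
                                              (n_variants - 6, 0.1)),
                             n_exposure=100_000)
        specs = [
            OutcomeSpec(pid, theta=theta_reverse if labels[pid] == "reverse_causal" else 0.0,
                        binary=False, n=N_EXPOSURE)
            for pid in labels
        ]
        outcome_instruments[oid] = simulate_multi_outcome_region(
            cfg, specs, label=f"instruments:{oid}", exposure_id=oid,
        )

    risk_factor_instruments: dict[str, SyntheticRegion] = {}
    for i, rid in enumerate(risk_factor_ids):
        sub = int(root.integers(2**31))
        cfg = ScenarioConfig(seed=sub, n_variants=n_variants, ld_rho=ld_rho,
                             chrom="21",
                             causal_variants=((5, 0.2), (n_variants // 2, 0.15),
                                              (n_variants - 6, 0.12)),
                             n_exposure=100_000)
        specs = [OutcomeSpec(oid, theta=beta_MO if i == 0 else 0.0, binary=True)
                 for oid in outcome_ids]
        risk_factor_instruments[rid] = simulate_multi_outcome_region(
            cfg, specs, label=f"instruments:{rid}", exposure_id=rid,
        )

    return StudyPanel(
        proteins=proteins, labels=dict(labels),
        outcome_ids=list(outcome_ids), risk_factor_ids=list(risk_factor_ids),
        outcome_instruments=outcome_instruments,
        risk_factor_instruments=risk_factor_instruments, seed=seed,
    )
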