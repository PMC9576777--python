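"""End-to-end orchestration of the proteome-to-outcome MR decision procedure.

The procedure mirrors a proteome-wide drug-target screen:

1. *Primary MR* — for every protein, clump its pQTLs into instruments,
   run the primary estimator (Wald ratio or IVW) plus the sensitivity
   battery against every primary outcome, twice: cis-only instruments,
   then cis+trans.  A protein passes when the causal p-value clears the
   Bonferroni threshold 0.05 / n_proteins *and* none of the sensitivity
   gates (Cochran Q, Egger intercept, global pleiotropy test) fails.
2. *Reverse MR* — outcome-instrumented MR back onto each hit, flagging
   hits explicable by reverse causation.
3. *Two-step MR* — risk-factor-to-outcome (step 1, threshold
   0.05 / n_risk_factors) and protein-to-risk-factor (step 2) MR, with
   mediation decomposition wherever a protein shows effects in both
   steps and on the outcome.
4. *Report* — a deterministic, machine-readable bundle of every table
   and every gate decision with its threshold provenance.

Thresholds are always recomputed from the supplied manifest counts,
never hard-coded.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimators import egger, presso, select_primary
from .instruments import build_instrument_set
from .mediation import mediate
from .simulate import StudyPanel

__all__ = [
    "Thresholds",
    "GateResult",
    "evaluate_gates",
    "run_primary_mr",
    "run_reverse_mr",
    "run_two_step",
    "run_report",
    "run_all",
]


@dataclass(frozen=True)
class Thresholds:
    """Layered Bonferroni thresholds derived from manifest counts."""

    n_proteins: int
    n_risk_factors: int = 7
    n_phenotypes: int = 784
    n_proteins_selected: int = 6
    alpha_family: float = 0.05
    alpha_sensitivity: float = 0.05

    @property
    def alpha_primary(self) -> float:
        return self.alpha_family / self.n_proteins

    @property
    def alpha_riskfactor(self) -> float:
        return self.alpha_family / self.n_risk_factors

    @property
    def alpha_screen(self) -> float:
        return self.alpha_family / self.n_proteins_selected / self.n_phenotypes


@dataclass(frozen=True)
class GateResult:
    """The four decision gates for one estimate."""

    pass_causal: bool
    pass_q: bool
    pass_egger_intercept: bool
    pass_global: bool
    annotations: tuple[str, ...] = ()

    @property
    def verdict(self) -> bool:
        return (self.pass_causal and self.pass_q
                and self.pass_egger_intercept and self.pass_global)


def evaluate_gates(
    pvalue: float,
    alpha_primary: float,
    p_q: float | None,
    p_intercept: float | None,
    p_global: float | None,
    alpha_sensitivity: float = 0.05,
) -> GateResult:
    """Joint evaluation of the causal and sensitivity gates.

    Sensitivity tests that could not run (too few instruments) pass with
    an annotation rather than failing the protein.
    """
    notes = []
    if p_q is None:
        notes.append("q_not_run")
    if p_intercept is None:
        notes.append("egger_not_run")
    if p_global is None:
        notes.append("presso_not_run")
    return GateResult(
        pass_causal=bool(pvalue <= alpha_primary),
        pass_q=bool(p_q is None or p_q >= alpha_sensitivity),
        pass_egger_intercept=bool(p_intercept is None or p_intercept >= alpha_sensitivity),
        pass_global=bool(p_global is None or p_global >= alpha_sensitivity),
        annotations=tuple(notes),
    )


def _battery(pairs: pd.DataFrame, seed: int, presso_sims: int = 600) -> dict:
    """Primary estimate plus the full sensitivity battery for one pair set."""
    est, het = select_primary(pairs)
    out = {
        "method": est.method, "theta": est.theta, "se": est.se,
        "ci_low": est.ci_low, "ci_high": est.ci_high, "pvalue": est.pvalue,
        "n_snps": est.n_snps,
        "q": het.q if het else np.nan,
        "p_q": het.p_q if het else None,
        "i2": het.i2 if het else np.nan,
        "egger_intercept": np.nan, "p_egger_intercept": None,
        "p_presso_global": None, "presso_outliers": "",
    }
    if len(pairs) >= 3:
        _, pleio = egger(pairs)
        out["egger_intercept"] = pleio.egger_intercept
        out["p_egger_intercept"] = pleio.p_intercept
    if len(pairs) >= 4:
        pr = presso(pairs, n_sim=presso_sims, seed=seed)
        out["p_presso_global"] = pr.p_global
        out["presso_outliers"] = ",".join(map(str, pr.outliers))
    return out


def _derive_seed(base: int, *parts: str) -> int:
    h = hashlib.sha256(("|".join(map(str, (base,) + parts))).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_primary_mr(
    panel: StudyPanel,
    thresholds: Thresholds,
    modes: tuple[str, ...] = ("cis", "cis_trans"),
    flagged_pleiotropic_loci: tuple[str, ...] = (),
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.1,
) -> pd.DataFrame:
    """Protein-by-outcome MR with instrument selection and decision gates.

    Run once with cis-only instruments and once with cis+trans.  A protein
    passing all gates in cis-only mode is a *primary hit*; trans-inclusive
    hits whose instruments touch a flagged pleiotropic locus list are
    annotated, not promoted.
    """
    if not panel.outcome_ids:
        raise ValueError("empty outcome manifest")
    rows = []
    for pid, region in panel.proteins.items():
        inst_all = build_instrument_set(
            pid, region.tables[pid] if pid in region.tables else region.tables["protein"],
            region.ld, region.gene_region,
            p_threshold=p_threshold, r2_threshold=r2_threshold,
        )
        for mode in modes:
            inst = inst_all.subset(cis_only=(mode == "cis"))
            for oid in panel.outcome_ids:
                base = {
                    "protein_id": pid, "outcome_id": oid, "mode": mode,
                    "truth_label": panel.labels.get(pid, ""),
                }
                if inst.n_instruments == 0:
                    rows.append({**base, "n_snps": 0, "verdict": False,
                                 "annotations": "no_instruments"})
                    continue
                exposure_key = "protein" if "protein" in region.tables else pid
                pairs = region.pairs(exposure_key, oid, rsids=list(inst.table["rsid"]))
                seed = _derive_seed(panel.seed, pid, oid, mode)
                stats_row = _battery(pairs, seed)
                gates = evaluate_gates(
                    stats_row["pvalue"], thresholds.alpha_primary,
                    stats_row["p_q"], stats_row["p_egger_intercept"],
                    stats_row["p_presso_global"], thresholds.alpha_sensitivity,
                )
                notes = list(gates.annotations)
                if mode == "cis_trans" and flagged_pleiotropic_loci:
                    touched = set(inst.table["rsid"]) & set(flagged_pleiotropic_loci)
                    if touched:
                        notes.append("pleiotropic_locus_instruments")
                rows.append({
                    **base, **stats_row,
                    "total_r2": inst.total_r2,
                    "alpha_primary": thresholds.alpha_primary,
                    "pass_causal": gates.pass_causal, "pass_q": gates.pass_q,
                    "pass_egger_intercept": gates.pass_egger_intercept,
                    "pass_global": gates.pass_global,
                    "verdict": gates.verdict,
                    "annotations": ";".join(notes),
                })
    df = pd.DataFrame(rows)
    df["primary_hit"] = (df["mode"] == "cis") & df["verdict"].fillna(False)
    return df


def run_reverse_mr(
    panel: StudyPanel,
    hits: list[str],
    thresholds: Thresholds,
) -> pd.DataFrame:
    """Outcome-instrumented MR onto each hit protein.

    A hit is flagged ``reverse_flag`` when the reverse estimate itself
    clears the primary causal threshold, indicating the forward signal may
    be reverse causation.
    """
    rows = []
    for pid in hits:
        for oid, region in panel.outcome_instruments.items():
            if pid not in region.tables:
                rows.append({"protein_id": pid, "outcome_id": oid,
                             "testable": False, "reverse_flag": False,
                             "reason": "no_outcome_instruments"})
                continue
            inst = build_instrument_set(oid, region.tables[oid], region.ld, None)
            if inst.n_instruments == 0:
                rows.append({"protein_id": pid, "outcome_id": oid,
                             "testable": False, "reverse_flag": False,
                             "reason": "no_outcome_instruments"})
                continue
            pairs = region.pairs(oid, pid, rsids=list(inst.table["rsid"]))
            est, het = select_primary(pairs)
            rows.append({
                "protein_id": pid, "outcome_id": oid, "testable": True,
                "method": est.method, "theta": est.theta, "se": est.se,
                "pvalue": est.pvalue, "n_snps": est.n_snps,
                "reverse_flag": bool(est.pvalue <= thresholds.alpha_primary),
                "reason": "",
            })
    return pd.DataFrame(rows)


def run_two_step(
    panel: StudyPanel,
    hits: list[str],
    primary: pd.DataFrame,
    thresholds: Thresholds,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Two-step MR and mediation for hit proteins.

    Step 1 tests each risk factor against each outcome (gate
    ``alpha_riskfactor``); step 2 tests each hit protein against each risk
    factor (gate ``alpha_primary``).  Mediation is decomposed only for
    (protein, risk factor, outcome) triples where both steps and the
    protein's total effect pass their gates.
    """
    step1_rows = []
    for rid, region in panel.risk_factor_instruments.items():
        inst = build_instrument_set(rid, region.tables[rid], region.ld, None)
        for oid in panel.outcome_ids:
            pairs = region.pairs(rid, oid, rsids=list(inst.table["rsid"]))
            est, _ = select_primary(pairs)
            step1_rows.append({
                "risk_factor": rid, "outcome_id": oid,
                "theta": est.theta, "se": est.se, "pvalue": est.pvalue,
                "n_snps": est.n_snps,
                "pass": bool(est.pvalue <= thresholds.alpha_riskfactor),
                "alpha": thresholds.alpha_riskfactor,
            })
    step1 = pd.DataFrame(step1_rows)

    step2_rows = []
    for pid in hits:
        region = panel.proteins[pid]
        inst = build_instrument_set(pid, region.tables["protein"], region.ld,
                                    region.gene_region).subset(cis_only=True)
        for rid in panel.risk_factor_ids:
            pairs = region.pairs("protein", rid, rsids=list(inst.table["rsid"]))
            est, _ = select_primary(pairs)
            step2_rows.append({
                "protein_id": pid, "risk_factor": rid,
                "theta": est.theta, "se": est.se, "pvalue": est.pvalue,
                "n_snps": est.n_snps,
                "pass": bool(est.pvalue <= thresholds.alpha_primary),
                "alpha": thresholds.alpha_primary,
            })
    step2 = pd.DataFrame(step2_rows)

    med_rows = []
    cis = primary[(primary["mode"] == "cis") & primary["verdict"].fillna(False)]
    for pid in hits:
        for rid in panel.risk_factor_ids:
            s2 = step2[(step2["protein_id"] == pid) & (step2["risk_factor"] == rid)]
            if s2.empty or not bool(s2["pass"].iloc[0]):
                continue
            for oid in panel.outcome_ids:
                s1 = step1[(step1["risk_factor"] == rid) & (step1["outcome_id"] == oid)]
                tot = cis[(cis["protein_id"] == pid) & (cis["outcome_id"] == oid)]
                if s1.empty or tot.empty or not bool(s1["pass"].iloc[0]):
                    continue
                res = mediate(
                    (float(tot["theta"].iloc[0]), float(tot["se"].iloc[0])),
                    (float(s2["theta"].iloc[0]), float(s2["se"].iloc[0])),
                    (float(s1["theta"].iloc[0]), float(s1["se"].iloc[0])),
                )
                med_rows.append({
                    "protein_id": pid, "risk_factor": rid, "outcome_id": oid,
                    "beta_EO": res.beta_EO, "beta_EM": res.beta_EM,
                    "beta_MO": res.beta_MO,
                    "indirect": res.indirect, "se_indirect": res.se_indirect,
                    "proportion": res.proportion,
                    "sign_mismatch": res.sign_mismatch,
                    "proportion_out_of_range": res.proportion_out_of_range,
                })
    mediation = pd.DataFrame(med_rows)
    return step1, step2, mediation


def run_report(tables: dict[str, pd.DataFrame], meta: dict | None = None) -> dict:
    """Deterministic machine-readable bundle of all pipeline tables.

    The same inputs and seeds produce a byte-identical bundle (and hence
    hash).  Stages that did not run appear with an explicit ``"skipped"``
    marker.
    """
    bundle: dict = {"meta": dict(meta or {})}
    for name in sorted(tables):
        df = tables[name]
        if df is None:
            bundle[name] = "skipped"
        else:
            clean = df.copy()
            for c in clean.columns:
                if clean[c].dtype == object:
                    clean[c] = clean[c].astype(str)
            bundle[name] = json.loads(clean.to_json(orient="records", double_precision=12))
    blob = json.dumps(bundle, sort_keys=True, separators=(",", ":"))
    bundle["hash"] = hashlib.sha256(blob.encode()).hexdigest()
    return bundle


def run_all(panel: StudyPanel, thresholds: Thresholds | None = None) -> dict:
    """Run primary, reverse, two-step and report stages on a study panel."""
    thresholds = thresholds or Thresholds(n_proteins=len(panel.proteins))
    primary = run_primary_mr(panel, thresholds)
    hits = sorted(primary.loc[primary["primary_hit"], "protein_id"].unique())
    reverse = run_reverse_mr(panel, hits, thresholds)
    flagged = set(reverse.loc[reverse["reverse_flag"], "protein_id"]) if len(reverse) else set()
    retained = [h for h in hits if h not in flagged]
    step1, step2, mediation = run_two_step(panel, retained, primary, thresholds)
    report = run_report(
        {"primary": primary, "reverse": reverse, "step1": step1,
         "step2": step2, "mediation": mediation},
        meta={"seed": panel.seed, "alpha_primary": thresholds.alpha_primary,
              "alpha_riskfactor": thresholds.alpha_riskfactor,
              "n_proteins": thresholds.n_proteins,
              "hits": hits, "reverse_flagged": sorted(flagged)},
    )
    return {"primary": primary, "reverse": reverse, "step1": step1,
            "step2": step2, "mediation": mediation, "hits": hits,
            "reverse_flagged": sorted(flagged), "report": report}
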