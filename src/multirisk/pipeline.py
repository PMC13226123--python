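"""End-to-end multimodal risk-modelling pipeline on a synthetic cohort.

Chains every stage the package provides: cohort/expression/bag
generation, normalization and batch adjustment, GSVA TLS scoring, HPV
imputation, per-arm molecular risk signatures, imaging-only and fused
attention-MIL models, and the per-feature-set c-index comparison with
KM risk stratification — the scaled-down analog of the emulated study's
feature-set comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import mil, molrisk, prep, reporting, signatures
from . import survival as sv
from . import synth

__all__ = ["PipelineResult", "run_pipeline", "clinical_risk_model"]

CPS_ORDER = {"negative": 0.0, "low": 1.0, "high": 2.0, "unknown": 1.0}


@dataclass
class PipelineResult:
    cohort: pd.DataFrame
    train_ids: dict[str, pd.Index]
    test_ids: dict[str, pd.Index]
    mol_signatures: dict[str, molrisk.RiskSignature]
    mol_scores: pd.Series
    tls_scores: pd.DataFrame | None
    hpv_imputed: pd.Series
    mil_imaging: mil.TrainedMILModel
    mil_fused: mil.TrainedMILModel
    cindex_table: pd.DataFrame
    km_table: pd.DataFrame
    attention_ratio: float
    bags: synth.PatchBagSet
    extras: dict = field(default_factory=dict)


def clinical_risk_model(
    clinical: pd.DataFrame,
    hpv: pd.Series,
    train_ids: pd.Index,
    test_ids: pd.Index,
) -> pd.Series:
    """Plain Cox baseline on clinical covariates; test linear predictor."""
    design = signatures._build_design(
        clinical, ["age", "sex", "biopsy_site", "tumor_purity"]
    )
    design["hpv_positive"] = (hpv.reindex(clinical.index) == "positive").astype(float)
    fit = sv.fit_coxph(
        sv.SurvivalData(
            clinical.loc[train_ids, "pfs_months"].to_numpy(),
            clinical.loc[train_ids, "event"].to_numpy(),
            design.loc[train_ids].to_numpy(),
            names=list(design.columns),
        )
    )
    lp = design.loc[test_ids].to_numpy() @ fit.coefficients
    return pd.Series(lp, index=test_ids, name="clinical_risk")


def run_pipeline(
    seed: int = 0,
    cohort_config: synth.CohortConfig | None = None,
    expr_config: synth.ExpressionConfig | None = None,
    bag_config: synth.BagConfig | None = None,
    grid: list[mil.MILHyperparams] | None = None,
    include_tls: bool = True,
) -> PipelineResult:
    """Run the full multimodal analysis on one synthetic cohort.

    All randomness derives from ``seed``.  Returns fitted artifacts and
    the Harrell c-index per feature set and arm on held-out patients,
    evaluated on the identical test patients within each arm.
    """
    ccfg = cohort_config or synth.CohortConfig(seed=seed)
    ecfg = expr_config or synth.ExpressionConfig(seed=seed + 1)
    bcfg = bag_config or synth.BagConfig(seed=seed + 2)
    cohort = synth.generate_cohort(ccfg)
    expr, truth = synth.generate_expression(cohort, ecfg)
    bags = synth.generate_patch_bags(cohort, bcfg)

    norm = prep.normalize_counts(expr)
    adj = prep.batch_adjust(norm, cohort["batch"].to_numpy())
    hpv_model, hpv_imputed = prep.impute_hpv(adj, cohort["hpv"], seed=seed)

    tls_scores = None
    if include_tls:
        gene_sets = synth.generate_gene_sets(ecfg, seed=seed + 3)
        tls_scores = prep.gsva_scores(adj, gene_sets).values

    arms = list(synth.ARMS)
    train_ids: dict[str, pd.Index] = {}
    test_ids: dict[str, pd.Index] = {}
    mol_sigs: dict[str, molrisk.RiskSignature] = {}
    mol_scores = pd.Series(index=cohort.index, dtype=float, name="molecular_score")
    screens = {}
    for arm in arms:
        sig, tr, te, screen = molrisk.build_risk_signature(
            adj, cohort, arm, seed=seed + 10
        )
        train_ids[arm], test_ids[arm], mol_sigs[arm] = tr, te, sig
        screens[arm] = screen
        arm_ids = cohort.index[cohort["arm"] == arm]
        arm_expr = synth.ExpressionMatrix(adj.values[arm_ids], state="normalized")
        mol_scores.loc[arm_ids] = molrisk.risk_score(sig, arm_expr)

    all_train = train_ids[arms[0]].append(train_ids[arms[1]])
    all_test = test_ids[arms[0]].append(test_ids[arms[1]])
    mil_imaging = mil.train_mil(
        bags.bags,
        cohort.loc[all_train, "pfs_months"],
        cohort.loc[all_train, "event"],
        cohort.loc[all_train, "arm"],
        molecular_scores=None,
        grid=grid,
        seed=seed,
    )
    mil_fused = mil.train_mil(
        bags.bags,
        cohort.loc[all_train, "pfs_months"],
        cohort.loc[all_train, "event"],
        cohort.loc[all_train, "arm"],
        molecular_scores=mol_scores,
        grid=grid,
        seed=seed,
    )

    risks: dict[str, dict[str, pd.Series]] = {
        "cps": {},
        "clinical": {},
        "molecular": {},
        "imaging": {},
        "imaging+molecular": {},
    }
    if include_tls:
        risks["tls_signature"] = {}
    groupings: dict[str, pd.Series] = {}
    for arm in arms:
        te = test_ids[arm]
        cl = cohort[cohort["arm"] == arm]
        risks["cps"][arm] = pd.Series(
            [-CPS_ORDER[c] for c in cohort.loc[te, "cps_category"]], index=te
        )
        if include_tls:
            agg = tls_scores.loc[synth.TLS_SET_NAMES, te].mean(axis=0)
            risks["tls_signature"][arm] = -agg  # high TLS is protective
        risks["clinical"][arm] = clinical_risk_model(
            cl, hpv_imputed, train_ids[arm], te
        )
        risks["molecular"][arm] = mol_scores.loc[te]
        pred_img = mil.predict_and_stratify(
            mil_imaging, bags.bags, cohort.loc[te, "arm"]
        )
        risks["imaging"][arm] = pred_img["risk"]
        pred_fused = mil.predict_and_stratify(
            mil_fused, bags.bags, cohort.loc[te, "arm"], mol_scores.loc[te]
        )
        risks["imaging+molecular"][arm] = pred_fused["risk"]
        groupings[f"fused_{arm}"] = pd.Series(pred_fused["group"], index=te)
        groupings[f"molecular_{arm}"] = molrisk.binarize_risk(
            mol_scores.loc[te], mol_sigs[arm]
        )

    cindex_table = reporting.cindex_comparison(risks, cohort)
    km_table, km_curves = reporting.km_report(groupings, cohort)

    ratios = []
    for pid in all_test:
        bag = bags[pid]
        info = bags.informative_idx[pid]
        if 0 < len(info) < bag.n_patches:
            a = mil.export_attention(mil_fused, bag)["attention_weight"].to_numpy()
            m = np.zeros(bag.n_patches, dtype=bool)
            m[info] = True
            ratios.append(float(a[m].mean() / a[~m].mean()))
    attention_ratio = float(np.mean(ratios)) if ratios else float("nan")

    return PipelineResult(
        cohort=cohort,
        train_ids=train_ids,
        test_ids=test_ids,
        mol_signatures=mol_sigs,
        mol_scores=mol_scores,
        tls_scores=tls_scores,
        hpv_imputed=hpv_imputed,
        mil_imaging=mil_imaging,
        mil_fused=mil_fused,
        cindex_table=cindex_table,
        km_table=km_table,
        attention_ratio=attention_ratio,
        bags=bags,
        extras={
            "truth": truth,
            "hpv_model": hpv_model,
            "screens": screens,
            "km_curves": km_curves,
        },
    )
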