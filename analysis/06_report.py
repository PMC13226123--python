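"""Evaluation layer: cohort baseline table with between-arm tests,
feature-set c-index comparison on held-out patients (CPS, TLS
signature, clinical, molecular, imaging, imaging+molecular), and the
KM risk-stratification report with BH correction across groupings.

Usage: python analysis/06_report.py [--seed 1]
"""

import argparse
from pathlib import Path

import pandas as pd

from multirisk import mil, pipeline, reporting, synth
from multirisk.prep import SignatureScoreMatrix

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int) -> None:
    res = ROOT / "results"
    clinical = pd.read_csv(
        ROOT / "scratch" / "data" / "clinical.csv", index_col="patient_id"
    )

    table = reporting.baseline_table(clinical)
    table.summary.to_csv(res / "baseline_table.csv", index=False)
    table.tests.to_csv(res / "baseline_tests.csv", index=False)
    print("baseline tests:")
    for _, row in table.tests.iterrows():
        print(f"  {row['characteristic']:<14} {row['test']:<28} p={row['p_display']}")

    mol = pd.read_csv(res / "molecular_scores.csv", index_col=0)
    tls = pd.read_csv(res / "tls_scores.csv", index_col=0)
    hpv = pd.read_csv(res / "hpv_imputed.csv", index_col=0)["hpv_completed"]
    pred_img = pd.read_csv(res / "mil_imaging_predictions.csv", index_col=0)
    pred_fus = pd.read_csv(res / "mil_fused_predictions.csv", index_col=0)

    risks = {k: {} for k in (
        "cps", "tls_signature", "clinical", "molecular", "imaging",
        "imaging+molecular",
    )}
    groupings = {}
    for arm in ("Pembro", "PembroChemo"):
        armc = clinical[clinical["arm"] == arm]
        te = mol.index[(mol["split"] == "test") & mol.index.isin(armc.index)]
        tr = mol.index[(mol["split"] == "train") & mol.index.isin(armc.index)]
        risks["cps"][arm] = pd.Series(
            [-pipeline.CPS_ORDER[c] for c in clinical.loc[te, "cps_category"]],
            index=te,
        )
        risks["tls_signature"][arm] = -tls.loc[synth.TLS_SET_NAMES, te].mean(axis=0)
        risks["clinical"][arm] = pipeline.clinical_risk_model(armc, hpv, tr, te)
        risks["molecular"][arm] = mol.loc[te, "score"]
        risks["imaging"][arm] = pred_img.loc[te, "risk"]
        risks["imaging+molecular"][arm] = pred_fus.loc[te, "risk"]
        groupings[f"fused_{arm}"] = pred_fus.loc[te, "group"]
        groupings[f"molecular_{arm}"] = mol.loc[te, "group"]

    cindex = reporting.cindex_comparison(risks, clinical)
    cindex.to_csv(res / "cindex_comparison.csv")
    print("\nheld-out c-index by feature set:")
    print(cindex.round(3).to_string())

    km, _ = reporting.km_report(groupings, clinical)
    km.to_csv(res / "km_report.csv", index=False)
    print("\nKM risk stratification (BH-adjusted log-rank):")
    print(km[["grouping", "hazard_ratio", "logrank_p", "adjusted_p",
              "significant"]].round(4).to_string(index=False))


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
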