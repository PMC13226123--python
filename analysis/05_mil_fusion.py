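"""Train the attention-MIL survival models on the patch-embedding bags:
imaging-only and imaging+molecular (late fusion), with 5-fold CV
hyperparameter selection, median-threshold risk stratification, and
attention export for the extreme-risk patients.

Writes model weights (scratch), per-patient risks/groups, CV summaries,
and attention tables under results/.

Usage: python analysis/05_mil_fusion.py [--seed 1]
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from multirisk import mil, molrisk, survival as sv, synth

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int) -> None:
    res = ROOT / "results"
    clinical = pd.read_csv(
        ROOT / "scratch" / "data" / "clinical.csv", index_col="patient_id"
    )
    bags = synth.PatchBagSet.read_h5(ROOT / "scratch" / "data" / "bags.h5")
    mol = pd.read_csv(res / "molecular_scores.csv", index_col=0)

    train_ids, test_ids = [], []
    for arm in ("Pembro", "PembroChemo"):
        tr, te = molrisk.stratified_split(
            clinical[clinical["arm"] == arm], seed=seed + 10
        )
        train_ids += list(tr)
        test_ids += list(te)

    outputs = {}
    for label, mol_scores in (("imaging", None), ("fused", mol["score"])):
        model = mil.train_mil(
            bags.bags,
            clinical.loc[train_ids, "pfs_months"],
            clinical.loc[train_ids, "event"],
            clinical.loc[train_ids, "arm"],
            molecular_scores=mol_scores,
            seed=seed,
        )
        model.save(str(ROOT / "scratch" / f"mil_{label}"))
        pred = mil.predict_and_stratify(
            model, bags.bags, clinical["arm"],
            None if mol_scores is None else mol_scores,
        )
        pred["split"] = ["train" if i in set(train_ids) else "test" for i in pred.index]
        pred.to_csv(res / f"mil_{label}_predictions.csv")
        outputs[label] = (model, pred)

        per_arm = {}
        for arm in ("Pembro", "PembroChemo"):
            te = [i for i in test_ids if clinical.loc[i, "arm"] == arm]
            per_arm[arm] = sv.concordance_index(
                pred.loc[te, "risk"],
                clinical.loc[te, "pfs_months"],
                clinical.loc[te, "event"],
            )
        hp = model.chosen_hyperparams
        print(f"{label}: chosen hidden={hp.mlp_hidden} dropout={hp.dropout}; "
              f"held-out c-index "
              + ", ".join(f"{a}={c:.3f}" for a, c in per_arm.items()))
        with open(res / f"mil_{label}_cv.json", "w") as fh:
            json.dump(
                {
                    "chosen": {
                        "mlp_hidden": hp.mlp_hidden,
                        "dropout": hp.dropout,
                        "learning_rate": hp.learning_rate,
                    },
                    "test_cindex": per_arm,
                    "cv_table": model.cv_results.to_dict(orient="records"),
                },
                fh,
                indent=1,
            )

    # attention maps for the extreme-risk held-out patients (fused model)
    model, pred = outputs["fused"]
    test_pred = pred.loc[pred["split"] == "test", "risk"]
    for tag, pid in (("lowest", test_pred.idxmin()), ("highest", test_pred.idxmax())):
        mil.export_attention(model, bags[pid]).to_csv(
            res / f"attention_{tag}_risk_{pid}.csv", index=False
        )
        print(f"attention map for {tag}-risk test patient {pid} exported")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
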