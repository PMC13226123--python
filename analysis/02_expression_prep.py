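"""Normalize the count matrix, adjust for batch, score the six TLS
signatures with GSVA, and impute HPV status from CDKN2A.

Reads the bundle written by 01_simulate.py; writes the TLS score matrix
(sets x samples CSV), the adjusted expression (scratch), and the HPV
imputation report under results/.

Usage: python analysis/02_expression_prep.py [--seed 1]
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from multirisk import prep, synth

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int) -> None:
    data = ROOT / "scratch" / "data"
    res = ROOT / "results"
    clinical = pd.read_csv(data / "clinical.csv", index_col="patient_id")
    counts = synth.ExpressionMatrix(
        pd.read_csv(data / "expression.tsv", sep="\t", index_col="gene_id"),
        state="counts",
    )
    gene_sets = synth.GeneSetCollection.read_gmt(data / "gene_sets.gmt")

    norm = prep.normalize_counts(counts)
    adj = prep.batch_adjust(norm, clinical["batch"].to_numpy())
    adj.values.to_csv(ROOT / "scratch" / "expression_adjusted.tsv", sep="\t")

    scores = prep.gsva_scores(adj, gene_sets)
    scores.values.to_csv(res / "tls_scores.csv")

    model, completed = prep.impute_hpv(adj, clinical["hpv"], seed=seed)
    completed.to_frame("hpv_completed").to_csv(res / "hpv_imputed.csv")
    with open(res / "hpv_imputation_report.json", "w") as fh:
        json.dump(
            {
                "n_labelled": model.n_labelled,
                "test_accuracy": model.test_accuracy,
                "intercept": model.intercept,
                "slope_on_cdkn2a": model.slope,
                "imputed_positive": int((completed == "positive").sum()),
                "imputed_negative": int((completed == "negative").sum()),
            },
            fh,
            indent=1,
        )
    print(f"TLS scores: {scores.values.shape[0]} sets x "
          f"{scores.values.shape[1]} samples, "
          f"range [{scores.values.values.min():.2f}, "
          f"{scores.values.values.max():.2f}]")
    print(f"HPV imputation: {model.n_labelled} labelled, "
          f"test accuracy {model.test_accuracy:.2f}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
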