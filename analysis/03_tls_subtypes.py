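"""TLS signature analyses: covariate-adjusted association scan of the
six TLS signatures with PFS per treatment arm, aggregate-TLS subtyping
via mutual-KNN spectral bisection, and the high-vs-low survival
comparison per arm.

Writes the association table (per-signature HR/CI/p/q), the subtype
assignment, and the group-comparison JSON under results/.

Usage: python analysis/03_tls_subtypes.py
"""

import json
from pathlib import Path

import pandas as pd

from multirisk import signatures
from multirisk.prep import SignatureScoreMatrix
from multirisk.survival import NOT_REACHED

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    res = ROOT / "results"
    clinical = pd.read_csv(
        ROOT / "scratch" / "data" / "clinical.csv", index_col="patient_id"
    )
    scores = SignatureScoreMatrix(pd.read_csv(res / "tls_scores.csv", index_col=0))

    tables = []
    for arm in ("Pembro", "PembroChemo"):
        tables.append(signatures.signature_scan(scores, clinical, arm))
    scan = pd.concat(tables, ignore_index=True)
    scan.to_csv(res / "tls_association_scan.csv", index=False)

    assign = signatures.tls_subtype(scores)
    assign.labels.to_frame().to_csv(res / "tls_subtypes.csv")

    comparison = {}
    for arm in ("Pembro", "PembroChemo"):
        c = signatures.compare_groups(assign.labels, clinical, arm)
        c["median_pfs"] = {
            k: (None if v == NOT_REACHED else v) for k, v in c["median_pfs"].items()
        }
        comparison[arm] = c
        mp = c["median_pfs"]
        print(
            f"{arm}: TLS_high mPFS="
            f"{mp.get('TLS_high') if mp.get('TLS_high') is not None else 'NOT_REACHED'} "
            f"vs TLS_low mPFS="
            f"{mp.get('TLS_low') if mp.get('TLS_low') is not None else 'NOT_REACHED'}; "
            f"HR(TLS_low vs TLS_high)={c['hazard_ratio']:.2f}, "
            f"log-rank p={c['logrank_p']:.3g}"
        )
    with open(res / "tls_group_comparison.json", "w") as fh:
        json.dump(comparison, fh, indent=1)

    sig_rows = scan[scan["significant"]]
    print(f"{len(sig_rows)}/{len(scan)} signature-arm associations significant "
          "(raw p<0.05 or BH q<0.1)")


if __name__ == "__main__":
    main()
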