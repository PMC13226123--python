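"""Generate the synthetic study dataset.

Emulates the structure of the real-world cohort the analysis was built
for: 106 Pembro / 124 Pembro+Chemo patients with right-censored PFS,
clinical covariates, a 20K-gene count matrix with planted prognostic
genes and six TLS-like gene sets, and per-patient bags of WSI patch
embeddings with planted informative patches.

Writes the artifact bundle (clinical CSV, expression TSV, GMT, HDF5
bags, ground-truth JSON) under scratch/data/ and a small summary under
results/.

Usage: python analysis/01_simulate.py [--seed 1]
"""

import argparse
import json
from pathlib import Path

from multirisk import synth

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int) -> None:
    out_data = ROOT / "scratch" / "data"
    out_res = ROOT / "results"
    out_res.mkdir(exist_ok=True)

    cohort = synth.generate_cohort(synth.CohortConfig(seed=seed))
    expr_cfg = synth.ExpressionConfig(seed=seed + 1)
    expr, truth = synth.generate_expression(cohort, expr_cfg)
    gene_sets = synth.generate_gene_sets(expr_cfg, seed=seed + 3)
    bags = synth.generate_patch_bags(cohort, synth.BagConfig(seed=seed + 2))
    synth.write_dataset(out_data, cohort, expr, gene_sets, bags, truth)

    summary = {
        "seed": seed,
        "n_patients": len(cohort),
        "arms": cohort["arm"].value_counts().to_dict(),
        "events": int(cohort["event"].sum()),
        "censored_fraction": float(1 - cohort["event"].mean()),
        "n_genes": expr.shape[0],
        "n_tls_sets": len(gene_sets),
        "median_patches_per_bag": float(
            sorted(bags[p].n_patches for p in cohort.index)[len(cohort) // 2]
        ),
    }
    with open(out_res / "simulation_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    print(f"wrote {out_data} ({summary['n_patients']} patients, "
          f"{summary['events']} events, "
          f"{summary['censored_fraction']:.2f} censored)")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
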