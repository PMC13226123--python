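"""Signature-level survival analyses.

signature_scan  covariate-adjusted Cox association scan of signature
                scores with PFS, one treatment arm at a time, with
                Benjamini–Hochberg control across signatures.
tls_subtype     two-group TLS subtyping of patients from the six TLS
                signature scores via a mutual-KNN graph and spectral
                bisection.
compare_groups  Kaplan–Meier / Cox / log-rank comparison of two groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import survival as sv
from .prep import SignatureScoreMatrix

__all__ = ["signature_scan", "tls_subtype", "compare_groups", "SubtypeAssignment"]


@dataclass
class SubtypeAssignment:
    labels: pd.Series          # sample_id -> {"TLS_high", "TLS_low"}
    knn_k: int

    @property
    def high_samples(self) -> pd.Index:
        return self.labels.index[self.labels == "TLS_high"]


def _build_design(clinical: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Adjustment design matrix.

    ``age`` enters as a binary age group split at the cohort median,
    ``sex`` as an indicator, ``biopsy_site`` as one-hot (first level
    dropped), ``tumor_purity`` as continuous.
    """
    cols = {}
    for cov in covariates:
        if cov in ("age", "age_group"):
            med = clinical["age"].median()
            cols["age_group_high"] = (clinical["age"] > med).astype(float)
        elif cov == "sex":
            cols["sex_M"] = (clinical["sex"] == "M").astype(float)
        elif cov == "biopsy_site":
            levels = sorted(clinical["biopsy_site"].unique())
            for lv in levels[1:]:
                cols[f"site_{lv}"] = (clinical["biopsy_site"] == lv).astype(float)
        elif cov == "tumor_purity":
            cols["tumor_purity"] = clinical["tumor_purity"].astype(float)
        else:
            cols[cov] = clinical[cov].astype(float)
    return pd.DataFrame(cols, index=clinical.index)


def signature_scan(
    scores: SignatureScoreMatrix,
    clinical: pd.DataFrame,
    arm: str,
    covariates: list[str] = ("age", "sex", "biopsy_site", "tumor_purity"),
    raw_alpha: float = 0.05,
    q_alpha: float = 0.1,
) -> pd.DataFrame:
    """One adjusted Cox fit per signature within one treatment arm.

    Signature scores are standardized before fitting so hazard ratios
    are per 1 SD of score and comparable across signatures.  A
    signature is flagged significant when raw p < 0.05 or BH q < 0.1.
    """
    sub = clinical[clinical["arm"] == arm]
    common = sub.index.intersection(scores.samples)
    if len(common) == 0:
        raise ValueError("no overlapping sample ids between scores and clinical")
    sub = sub.loc[common]
    design = _build_design(sub, list(covariates))

    rows = []
    for name in scores.set_names:
        s = scores.values.loc[name, common].to_numpy(dtype=float)
        sd = s.std()
        if sd == 0:
            raise ValueError(f"signature {name!r} has zero variance in arm {arm}")
        s = (s - s.mean()) / sd
        X = np.column_stack([s, design.to_numpy(dtype=float)]) if design.shape[1] else s[:, None]
        data = sv.SurvivalData(
            time=sub["pfs_months"].to_numpy(),
            event=sub["event"].to_numpy(),
            covariates=X,
            names=[name, *design.columns],
        )
        fit = sv.fit_coxph(data)
        lo, hi = fit.ci95()
        rows.append(
            {
                "signature_name": name,
                "arm": arm,
                "hazard_ratio": float(fit.hazard_ratios[0]),
                "ci95_lo": float(lo[0]),
                "ci95_hi": float(hi[0]),
                "raw_p": float(fit.wald_p[0]),
            }
        )
    table = pd.DataFrame(rows)
    table["bh_q"] = sv.bh_adjust(table["raw_p"].to_numpy())
    table["significant"] = (table["raw_p"] < raw_alpha) | (table["bh_q"] < q_alpha)
    return table


def tls_subtype(
    scores6: SignatureScoreMatrix | pd.DataFrame,
    k: int = 15,
) -> SubtypeAssignment:
    """Two-community TLS subtyping from the six TLS signature scores.

    Scores are standardized per signature, a mutual-KNN graph
    (Euclidean, k neighbors) is built over the 6-D sample vectors, and
    the graph Laplacian's Fiedler vector bisects it.  The community with
    the larger mean of the six-signature average is labelled TLS_high.
    """
    vals = scores6.values if isinstance(scores6, SignatureScoreMatrix) else scores6
    if vals.shape[0] != 6:
        raise ValueError("tls_subtype expects exactly six signature rows")
    n = vals.shape[1]
    if n < 2 * k:
        raise ValueError(f"need at least 2k={2 * k} samples, got {n}")
    X = vals.to_numpy(dtype=float).T  # n x 6
    sd = X.std(axis=0)
    if np.all(X.std(axis=0, ddof=0) < 1e-12) or np.allclose(X, X[0]):
        raise ValueError("degenerate geometry: all score vectors identical")
    Xs = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

    d2 = ((Xs[:, None, :] - Xs[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    nn = np.argsort(d2, axis=1, kind="stable")[:, :k]
    A = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), k)
    A[rows, nn.ravel()] = True
    A = A & A.T  # mutual KNN
    W = A.astype(float)

    L = np.diag(W.sum(axis=1)) - W
    evals, evecs = np.linalg.eigh(L)
    fiedler = evecs[:, 1]
    side = fiedler >= np.median(fiedler) if np.all(fiedler == fiedler[0]) else fiedler >= 0
    # guard against an empty side (can happen with strictly positive vectors)
    if side.all() or (~side).all():
        side = fiedler >= np.median(fiedler)
    agg = Xs.mean(axis=1)  # six-signature average per sample (standardized)
    if agg[side].mean() >= agg[~side].mean():
        labels = np.where(side, "TLS_high", "TLS_low")
    else:
        labels = np.where(side, "TLS_low", "TLS_high")
    return SubtypeAssignment(
        labels=pd.Series(labels, index=vals.columns, name="cluster_label"),
        knn_k=k,
    )


def compare_groups(
    labels: pd.Series,
    clinical: pd.DataFrame,
    arm: str | None = None,
) -> dict:
    """KM medians, unadjusted HR and log-rank p between two groups."""
    sub = clinical if arm is None else clinical[clinical["arm"] == arm]
    lab = labels.reindex(sub.index).dropna()
    sub = sub.loc[lab.index]
    levels = sorted(lab.unique())
    if len(levels) != 2:
        raise ValueError("compare_groups requires exactly two group levels")
    time = sub["pfs_months"].to_numpy()
    event = sub["event"].to_numpy()

    medians = {}
    for lv in levels:
        m = lab == lv
        km = sv.km_estimate(time[m], event[m])
        medians[lv] = km.median
    indicator = (lab == levels[1]).astype(float).to_numpy()
    fit = sv.fit_coxph(
        sv.SurvivalData(time, event, indicator[:, None], names=[f"{levels[1]}_vs_{levels[0]}"])
    )
    lo, hi = fit.ci95()
    lr = sv.logrank_test(time, event, lab.to_numpy())
    return {
        "arm": arm,
        "groups": levels,
        "median_pfs": medians,
        "hazard_ratio": float(fit.hazard_ratios[0]),
        "ci95": (float(lo[0]), float(hi[0])),
        "logrank_p": lr["p"],
        "logrank_chi2": lr["chi2"],
        "n": {lv: int((lab == lv).sum()) for lv in levels},
    }
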