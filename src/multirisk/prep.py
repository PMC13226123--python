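"""Expression preprocessing and single-sample gene-set scoring.

normalize_counts   CPM + log2(x+1) library-size normalization.
batch_adjust       per-gene location/scale alignment of batches.
gsva_scores        single-sample enrichment (GSVA, Gaussian-kernel CDF,
                   centered-rank weights, Kolmogorov–Smirnov-like walk).
impute_hpv         logistic imputation of HPV status from CDKN2A.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .synth import ExpressionMatrix, GeneSetCollection

__all__ = [
    "GsvaParams",
    "SignatureScoreMatrix",
    "HPVImputationModel",
    "normalize_counts",
    "batch_adjust",
    "gsva_scores",
    "impute_hpv",
]


@dataclass
class GsvaParams:
    """Conventions of the enrichment scorer (published GSVA defaults)."""

    kcdf: str = "gaussian"   # kernel CDF family (only "gaussian" implemented)
    tau: float = 1.0         # weight exponent of the random walk
    mx_diff: bool = True     # score = max positive + max negative deviation
    bandwidth_factor: float = 4.0  # kernel bandwidth = per-gene sd / factor


@dataclass
class SignatureScoreMatrix:
    """Gene-sets x samples enrichment scores in [-1, 1]."""

    values: pd.DataFrame
    params: GsvaParams = field(default_factory=GsvaParams)

    @property
    def set_names(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class HPVImputationModel:
    intercept: float
    slope: float                 # on normalized CDKN2A expression
    decision_threshold: float
    train_test_fraction: float
    test_accuracy: float
    n_labelled: int


def normalize_counts(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Counts-per-million per sample, then log2(x+1).

    The linear-scale output of each sample sums to 1e6 by construction.
    Refuses already-normalized input and all-zero sample columns.
    """
    if counts.state != "counts":
        raise ValueError("input is already normalized (state flag)")
    vals = counts.values.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError("counts must be non-negative")
    colsums = vals.sum(axis=0)
    zero = np.flatnonzero(colsums == 0)
    if zero.size:
        raise ValueError(
            f"all-zero sample column: {counts.values.columns[zero[0]]!r}"
        )
    cpm = vals / colsums[None, :] * 1e6
    out = np.log2(cpm + 1.0)
    return ExpressionMatrix(
        values=pd.DataFrame(out, index=counts.genes, columns=counts.samples),
        state="normalized",
    )


def batch_adjust(norm: ExpressionMatrix, batch) -> ExpressionMatrix:
    """Per-gene location/scale alignment of batches.

    Each batch's values are standardized to the gene's pooled mean and
    pooled standard deviation (population moments, so the adjustment is
    exactly idempotent).  Genes with zero variance within any batch are
    passed through unchanged with a warning.
    """
    if norm.state != "normalized":
        raise ValueError("batch_adjust expects normalized input")
    batch = np.asarray(batch)
    if batch.shape[0] != norm.shape[1]:
        raise ValueError("batch labels must match the number of samples")
    levels, counts = np.unique(batch, return_counts=True)
    if np.any(counts < 2):
        bad = levels[counts < 2][0]
        raise ValueError(f"batch {bad!r} has fewer than 2 samples")
    vals = norm.values.to_numpy(dtype=float).copy()
    if levels.size == 1:
        return ExpressionMatrix(norm.values.copy(), state="normalized")

    pooled_mean = vals.mean(axis=1)
    pooled_sd = vals.std(axis=1)  # ddof=0: keeps the map idempotent
    skip = np.zeros(vals.shape[0], dtype=bool)
    adj = vals.copy()
    for b in levels:
        cols = batch == b
        m = vals[:, cols].mean(axis=1)
        s = vals[:, cols].std(axis=1)
        bad = (s == 0) | (pooled_sd == 0)
        skip |= bad
        safe = ~bad
        adj[np.ix_(safe, cols)] = (
            (vals[np.ix_(safe, cols)] - m[safe, None]) / s[safe, None]
        ) * pooled_sd[safe, None] + pooled_mean[safe, None]
    if skip.any():
        adj[skip] = vals[skip]
        warnings.warn(
            f"{int(skip.sum())} gene(s) with zero within-batch variance "
            "passed through unchanged",
            RuntimeWarning,
            stacklevel=2,
        )
    return ExpressionMatrix(
        values=pd.DataFrame(adj, index=norm.genes, columns=norm.samples),
        state="normalized",
    )


def _kcdf_gaussian(vals: np.ndarray, bandwidth_factor: float) -> np.ndarray:
    """Per-gene Gaussian-kernel CDF estimate evaluated at each sample.

    F[i, j] = mean_k Phi((x[i,j] - x[i,k]) / h_i), h_i = sd_i / factor.
    Constant genes get F = 0.5 everywhere.
    """
    g, n = vals.shape
    sd = vals.std(axis=1, ddof=1) if n > 1 else np.zeros(g)
    h = sd / bandwidth_factor
    F = np.full((g, n), 0.5)
    ok = h > 0
    # chunked over genes to bound the (chunk, n, n) intermediate
    chunk = max(1, int(2e7 // (n * n)))
    idx = np.flatnonzero(ok)
    for s in range(0, idx.size, chunk):
        rows = idx[s : s + chunk]
        diff = (vals[rows, :, None] - vals[rows, None, :]) / h[rows, None, None]
        F[rows] = ndtr(diff).mean(axis=2)
    return F


def gsva_scores(
    norm: ExpressionMatrix,
    sets: GeneSetCollection,
    params: GsvaParams | None = None,
) -> SignatureScoreMatrix:
    """Single-sample gene-set enrichment scores (GSVA algorithm).

    Per gene, a Gaussian-kernel CDF across samples (bandwidth sd/4)
    produces an expression-level statistic; per sample, genes are ranked
    by that statistic and weighted by the centered-rank magnitude
    |rank - (p+1)/2|^tau; a weighted Kolmogorov–Smirnov-like random walk
    down the ranked list scores each set as the maximum positive plus
    maximum negative deviation (the mx.diff convention).  Scores are
    bounded in [-1, 1] and invariant to per-gene positive affine maps.
    """
    params = params or GsvaParams()
    if params.kcdf != "gaussian":
        raise NotImplementedError("only the Gaussian KCDF is implemented")
    if norm.shape[1] < 3:
        raise ValueError("gsva_scores needs at least 3 samples")

    gene_index = {g: i for i, g in enumerate(norm.genes)}
    memberships = []
    for s in sets:
        present = [gene_index[m] for m in s.members if m in gene_index]
        if len(present) == 0:
            raise ValueError(f"gene set {s.name!r} has no members in the matrix")
        if len(present) < len(s.members):
            warnings.warn(
                f"gene set {s.name!r}: {len(s.members) - len(present)} "
                "absent member(s) dropped",
                RuntimeWarning,
                stacklevel=2,
            )
        memberships.append(np.asarray(present))

    vals = norm.values.to_numpy(dtype=float)
    p, n = vals.shape
    F = _kcdf_gaussian(vals, params.bandwidth_factor)

    # per sample: gene order by decreasing statistic; position ell = rank
    order = np.argsort(-F, axis=0, kind="stable")  # p x n gene indices
    pos_weight = np.abs(np.arange(1, p + 1) - (p + 1) / 2.0) ** params.tau

    scores = np.zeros((len(memberships), n))
    in_set = np.zeros(p, dtype=bool)
    for si, members in enumerate(memberships):
        m = members.size
        if m >= p:
            raise ValueError("gene set cannot contain every gene in the matrix")
        in_set[:] = False
        in_set[members] = True
        mask = in_set[order]  # p x n: is the gene at rank ell in the set
        w = np.where(mask, pos_weight[:, None], 0.0)
        sumw = w.sum(axis=0)
        inc = np.where(mask, w / sumw[None, :], -1.0 / (p - m))
        cum = np.cumsum(inc, axis=0)
        max_pos = np.maximum(cum, 0.0).max(axis=0)
        max_neg = np.minimum(cum, 0.0).min(axis=0)
        if params.mx_diff:
            scores[si] = max_pos + max_neg
        else:
            scores[si] = np.where(max_pos > -max_neg, max_pos, max_neg)
    return SignatureScoreMatrix(
        values=pd.DataFrame(scores, index=[s.name for s in sets], columns=norm.samples),
        params=params,
    )


def impute_hpv(
    norm: ExpressionMatrix,
    known_labels: pd.Series,
    seed: int = 0,
    train_fraction: float = 0.7,
    gene: str = "CDKN2A",
) -> tuple[HPVImputationModel, pd.Series]:
    """Impute missing HPV status from CDKN2A expression.

    A logistic regression of binary HPV status on the single (normalized)
    CDKN2A feature is fitted on a stratified 70% split of the labelled
    patients; test accuracy is recorded on the held-out 30%; patients
    with unknown status are assigned the class with predicted
    probability >= 0.5 of being positive.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import train_test_split

    if gene not in norm.genes:
        raise ValueError(f"{gene!r} absent from the expression matrix")
    known_labels = known_labels.reindex(norm.samples).fillna("unknown")
    labelled = known_labels[known_labels.isin(["positive", "negative"])]
    if len(labelled) < 10:
        raise ValueError("need at least 10 labelled patients")
    y = (labelled == "positive").astype(int).to_numpy()
    if y.min() == y.max():
        raise ValueError("both HPV classes must be present among labels")
    x = norm.values.loc[gene, labelled.index].to_numpy(dtype=float)

    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, train_size=train_fraction, random_state=seed, stratify=y, shuffle=True
    )
    if y_tr.min() == y_tr.max():
        raise ValueError("one HPV class absent in the training split")
    clf = LogisticRegression()
    clf.fit(x_tr[:, None], y_tr)
    acc = float((clf.predict(x_te[:, None]) == y_te).mean())

    completed = known_labels.copy()
    unknown = known_labels.index[~known_labels.isin(["positive", "negative"])]
    if len(unknown):
        xu = norm.values.loc[gene, unknown].to_numpy(dtype=float)
        prob = clf.predict_proba(xu[:, None])[:, 1]
        completed.loc[unknown] = np.where(prob >= 0.5, "positive", "negative")
    model = HPVImputationModel(
        intercept=float(clf.intercept_[0]),
        slope=float(clf.coef_[0, 0]),
        decision_threshold=0.5,
        train_test_fraction=train_fraction,
        test_accuracy=acc,
        n_labelled=int(len(labelled)),
    )
    return model, completed
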