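"""Treatment-specific molecular risk signatures.

Pipeline: stratified 70/30 split -> genome-wide univariate Cox screen
with FDR control -> L1-penalized Cox compression at a fixed penalty ->
weighted linear risk score min-max normalized to [0, 1] on training
patients -> median-threshold binarization into high/low risk groups.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import survival as sv
from .synth import ExpressionMatrix

__all__ = [
    "RiskSignature",
    "ScreenResult",
    "stratified_split",
    "univariate_screen",
    "lasso_compress",
    "risk_score",
    "binarize_risk",
    "build_risk_signature",
]


@dataclass
class RiskSignature:
    """Fitted molecular risk signature for one treatment arm.

    Weights act on standardized gene expression (training means/sds are
    stored); raw weighted sums are mapped to [0, 1] with the training
    min-max and clipped, and the training median score is the high/low
    threshold.
    """

    arm: str
    genes: list[str]
    weights: np.ndarray
    gene_means: np.ndarray
    gene_sds: np.ndarray
    train_min: float
    train_max: float
    train_median_score: float
    screen_gene_count: int
    lasso_penalty: float = 0.1

    def to_json(self, path) -> None:
        d = asdict(self)
        for k in ("weights", "gene_means", "gene_sds"):
            d[k] = np.asarray(d[k]).tolist()
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RiskSignature":
        with open(path) as fh:
            d = json.load(fh)
        for k in ("weights", "gene_means", "gene_sds"):
            d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


@dataclass
class ScreenResult:
    table: pd.DataFrame            # gene, coef, se, p, q, selected
    n_skipped_constant: int
    q_threshold: float

    @property
    def selected_genes(self) -> list[str]:
        return self.table.loc[self.table["selected"], "gene"].tolist()


def stratified_split(
    clinical: pd.DataFrame, fraction: float = 0.7, seed: int = 0
) -> tuple[pd.Index, pd.Index]:
    """Train/test split of patients stratified by PFS event.

    Event proportions in the two parts differ by at most one patient's
    worth; deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    event = clinical["event"].to_numpy()
    train_ids: list = []
    test_ids: list = []
    for cls in (0, 1):
        ids = clinical.index[event == cls].to_numpy()
        if ids.size < 2:
            raise ValueError(
                f"event class {cls} has fewer than 2 patients; cannot stratify"
            )
        perm = rng.permutation(ids)
        n_train = int(np.floor(fraction * ids.size + 0.5))
        n_train = min(max(n_train, 1), ids.size - 1)
        train_ids.extend(perm[:n_train])
        test_ids.extend(perm[n_train:])
    return pd.Index(train_ids), pd.Index(test_ids)


def univariate_screen(
    expr: ExpressionMatrix,
    time,
    event,
    q_threshold: float = 0.05,
    max_iter: int = 25,
    tol: float = 1e-8,
) -> ScreenResult:
    """One single-gene Cox fit per gene, BH-corrected across genes.

    Vectorized Newton–Raphson over all genes simultaneously (Breslow
    risk sets, which coincide with Efron on the tie-free survival times
    this screen is used with).  Genes with zero variance are skipped and
    counted.  Genes with q < 0.05 are selected.
    """
    if expr.state != "normalized":
        raise ValueError("univariate_screen expects normalized expression")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() < 1:
        raise ValueError("no events in the training data")

    vals = expr.values.to_numpy(dtype=float)
    sds = vals.std(axis=1)
    keep = sds > 0
    n_skipped = int((~keep).sum())
    X = ((vals[keep] - vals[keep].mean(axis=1, keepdims=True)) / sds[keep, None]).T
    genes = expr.genes[keep]
    n, G = X.shape

    order = np.argsort(time, kind="stable")
    Xs = X[order]
    ts = time[order]
    ev = event[order].astype(bool)
    # risk set of an event at t includes every sample with time >= t:
    # gather suffix sums at the first index of each tied time block
    first_idx = np.searchsorted(ts, ts, side="left")
    ev_rows = np.flatnonzero(ev)
    gather = first_idx[ev_rows]

    beta = np.zeros(G)
    X2 = Xs**2
    for _ in range(max_iter):
        eta = np.clip(Xs * beta[None, :], -50, 50)
        w = np.exp(eta)
        s0 = np.cumsum(w[::-1], axis=0)[::-1]
        s1 = np.cumsum((Xs * w)[::-1], axis=0)[::-1]
        s2 = np.cumsum((X2 * w)[::-1], axis=0)[::-1]
        mu = s1[gather] / s0[gather]
        score = (Xs[ev_rows] - mu).sum(axis=0)
        info = (s2[gather] / s0[gather] - mu**2).sum(axis=0)
        info = np.maximum(info, 1e-12)
        step = score / info
        beta = np.clip(beta + np.clip(step, -2, 2), -20, 20)
        if np.max(np.abs(score)) < tol:
            break
    se = 1.0 / np.sqrt(info)
    from scipy import stats

    p = 2 * stats.norm.sf(np.abs(beta / se))
    q = sv.bh_adjust(p)
    table = pd.DataFrame(
        {"gene": genes, "coef": beta, "se": se, "p": p, "q": q,
         "selected": q < q_threshold}
    ).reset_index(drop=True)
    return ScreenResult(table=table, n_skipped_constant=n_skipped,
                        q_threshold=q_threshold)


def lasso_compress(
    expr: ExpressionMatrix,
    time,
    event,
    arm: str = "",
    penalty: float = 0.1,
    screen_gene_count: int | None = None,
) -> RiskSignature:
    """L1-penalized Cox on standardized screened genes at a fixed penalty.

    Backed by a pathwise coordinate-descent penalized Cox solver
    (scikit-survival Coxnet, glmnet-style objective).  Genes whose
    coefficient is exactly zero are dropped; weights live on the
    standardized scale together with the training means/sds needed to
    apply them.  ``penalty=0`` is the unpenalized limit (all genes
    retained).
    """
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    if expr.shape[0] < 1:
        raise ValueError("screen produced no genes")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    vals = expr.values.to_numpy(dtype=float)
    means = vals.mean(axis=1)
    sds = vals.std(axis=1)
    if np.any(sds == 0):
        raise ValueError("constant gene passed to lasso_compress")
    Xstd = ((vals - means[:, None]) / sds[:, None]).T  # patients x genes

    alpha = max(penalty, 1e-9)
    model = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, alphas=[alpha], fit_baseline_model=False
    )
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    model.fit(Xstd, y)
    coefs = np.asarray(model.coef_)[:, 0]
    nz = np.flatnonzero(coefs != 0)
    if nz.size == 0:
        raise ValueError(
            f"penalty {penalty} removed every gene; screen produced no usable genes"
        )
    if nz.size < 5 or nz.size > 60:
        warnings.warn(
            f"lasso retained {nz.size} genes at penalty {penalty} "
            "(outside the typical 20-30 range)",
            RuntimeWarning,
            stacklevel=2,
        )
    genes = [expr.genes[i] for i in nz]
    weights = coefs[nz]
    raw = Xstd[:, nz] @ weights
    train_min, train_max = float(raw.min()), float(raw.max())
    if not train_min < train_max:
        raise ValueError("degenerate training scores (train_min == train_max)")
    norm = (raw - train_min) / (train_max - train_min)
    return RiskSignature(
        arm=arm,
        genes=genes,
        weights=weights,
        gene_means=means[nz],
        gene_sds=sds[nz],
        train_min=train_min,
        train_max=train_max,
        train_median_score=float(np.median(norm)),
        screen_gene_count=(
            expr.shape[0] if screen_gene_count is None else screen_gene_count
        ),
        lasso_penalty=penalty,
    )


def risk_score(sig: RiskSignature, expr: ExpressionMatrix) -> pd.Series:
    """Apply a signature: weighted sum of standardized expression,
    min-max normalized with the training bounds and clipped to [0, 1]."""
    missing = [g for g in sig.genes if g not in expr.genes]
    if missing:
        raise ValueError(f"missing signature gene {missing[0]!r}")
    vals = expr.values.loc[sig.genes].to_numpy(dtype=float)
    xstd = (vals - sig.gene_means[:, None]) / sig.gene_sds[:, None]
    raw = sig.weights @ xstd
    norm = (raw - sig.train_min) / (sig.train_max - sig.train_min)
    return pd.Series(np.clip(norm, 0.0, 1.0), index=expr.samples, name="risk_score")


def binarize_risk(scores: pd.Series, sig: RiskSignature) -> pd.Series:
    """High iff score strictly above the training median; ties go low."""
    return pd.Series(
        np.where(scores > sig.train_median_score, "high", "low"),
        index=scores.index,
        name="risk_group",
    )


def build_risk_signature(
    expr_norm: ExpressionMatrix,
    clinical: pd.DataFrame,
    arm: str,
    seed: int = 0,
    penalty: float = 0.1,
    q_threshold: float = 0.05,
) -> tuple[RiskSignature, pd.Index, pd.Index, ScreenResult]:
    """Full builder for one arm: split, screen, compress.

    Returns the fitted signature plus the train/test patient ids and the
    screen table, so downstream evaluation reuses the exact split.
    """
    sub = clinical[clinical["arm"] == arm]
    train_ids, test_ids = stratified_split(sub, seed=seed)
    expr_train = ExpressionMatrix(expr_norm.values[train_ids], state=expr_norm.state)
    screen = univariate_screen(
        expr_train,
        sub.loc[train_ids, "pfs_months"],
        sub.loc[train_ids, "event"],
        q_threshold=q_threshold,
    )
    selected = screen.selected_genes
    if not selected:
        raise ValueError("screen produced no genes")
    expr_sel = ExpressionMatrix(expr_train.values.loc[selected], state="normalized")
    sig = lasso_compress(
        expr_sel,
        sub.loc[train_ids, "pfs_months"],
        sub.loc[train_ids, "event"],
        arm=arm,
        penalty=penalty,
        screen_gene_count=len(selected),
    )
    return sig, train_ids, test_ids, screen
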