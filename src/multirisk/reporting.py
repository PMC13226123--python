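"""Cohort baseline table, c-index comparison and KM reporting.

The baseline table mirrors the conventions of clinical Table-1 software:
Pearson's chi-squared WITHOUT continuity correction for categorical
variables, Fisher's exact test when any observed cell is zero or any
expected count is below 5, the two-sided Wilcoxon rank-sum test for
continuous variables, "unknown" levels displayed but excluded from
tests, and journal-style p-value formatting (one decimal above 0.2,
">0.9" at the top, three decimals below 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from . import survival as sv

__all__ = [
    "BaselineTable",
    "format_pvalue",
    "fisher_exact_rx2",
    "categorical_test",
    "baseline_table",
    "cindex_comparison",
    "km_report",
]

DEFAULT_CATEGORICAL = ["sex", "biopsy_site", "cps_category", "hpv", "ecog", "smoking"]
DEFAULT_CONTINUOUS = ["age", "tumor_purity"]


def format_pvalue(p: float) -> str:
    """Journal-style display: >0.9 top, 1 decimal in (0.2, 0.9],
    2 decimals in [0.01, 0.2), 3 decimals in [0.001, 0.01), else <0.001."""
    if p > 0.9:
        return ">0.9"
    if p >= 0.2:
        return f"{p:.1f}"
    if p >= 0.01:
        return f"{p:.2f}"
    if p >= 0.001:
        return f"{p:.3f}"
    return "<0.001"


def fisher_exact_rx2(table: np.ndarray) -> float:
    """Fisher's exact test for an r x 2 contingency table.

    Conditional on all margins, the first column is multivariate
    hypergeometric; the two-sided p-value sums the probabilities of all
    tables no more probable than the observed one (the convention of
    R's fisher.test).  Exact enumeration — intended for small tables.
    """
    table = np.asarray(table, dtype=int)
    if table.ndim != 2 or table.shape[1] != 2:
        raise ValueError("fisher_exact_rx2 expects an r x 2 table")
    rows = table.sum(axis=1)
    c1 = int(table[:, 0].sum())
    n = int(table.sum())
    if np.prod(rows + 1.0) > 5e7:
        raise ValueError("table too large for exact enumeration")
    denom = comb(n, c1)

    def log_prob(ks):
        num = 1.0
        for r, k in zip(rows, ks):
            num *= comb(int(r), int(k))
        return num / denom

    p_obs = log_prob(table[:, 0])
    total = 0.0
    r = len(rows)

    def recurse(i, remaining, ks):
        nonlocal total
        if i == r - 1:
            if 0 <= remaining <= rows[i]:
                pr = log_prob(ks + [remaining])
                if pr <= p_obs * (1 + 1e-7):
                    total += pr
            return
        lo = max(0, remaining - int(rows[i + 1 :].sum()))
        hi = min(int(rows[i]), remaining)
        for k in range(lo, hi + 1):
            recurse(i + 1, remaining - k, ks + [k])

    recurse(0, c1, [])
    return float(min(total, 1.0))


def categorical_test(table: np.ndarray) -> tuple[str, float]:
    """Chi-squared (no continuity correction), or Fisher's exact when a
    cell is zero or any expected count is below 5."""
    table = np.asarray(table, dtype=float)
    nz_rows = table.sum(axis=1) > 0
    nz_cols = table.sum(axis=0) > 0
    table = table[np.ix_(nz_rows, nz_cols)]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least a 2x2 table after dropping empty levels")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if np.any(table == 0) or np.any(expected < 5):
        if table.shape == (2, 2):
            _, p = stats.fisher_exact(table.astype(int))
        else:
            p = fisher_exact_rx2(table.astype(int))
        return "Fisher's exact test", float(p)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return "Pearson's Chi-squared test", float(p)


@dataclass
class BaselineTable:
    summary: pd.DataFrame   # per characteristic/level: per-arm display cells
    tests: pd.DataFrame     # characteristic, test, p, p_display


def baseline_table(
    cohort: pd.DataFrame,
    categorical: list[str] = tuple(DEFAULT_CATEGORICAL),
    continuous: list[str] = tuple(DEFAULT_CONTINUOUS),
    arm_col: str = "arm",
) -> BaselineTable:
    """Per-arm baseline characteristics with between-arm tests.

    Categorical percentages use the non-missing denominator; "unknown"
    levels are shown as rows but excluded from the tests.
    """
    arms = sorted(cohort[arm_col].unique())
    if len(arms) != 2:
        raise ValueError("baseline_table requires exactly two non-empty arms")
    sub = {a: cohort[cohort[arm_col] == a] for a in arms}

    rows, tests = [], []
    for var in continuous:
        cells = {}
        for a in arms:
            x = sub[a][var].astype(float)
            q1, med, q3 = x.quantile([0.25, 0.5, 0.75])
            cells[a] = f"{med:g} ({q1:g}, {q3:g})"
        _, p = (np.nan, np.nan)
        u = stats.mannwhitneyu(
            sub[arms[0]][var].astype(float),
            sub[arms[1]][var].astype(float),
            alternative="two-sided",
        )
        p = float(u.pvalue)
        rows.append({"characteristic": var, "level": "", **cells})
        tests.append(
            {
                "characteristic": var,
                "test": "Wilcoxon rank sum test",
                "p": p,
                "p_display": format_pvalue(p),
            }
        )
    for var in categorical:
        levels = [lv for lv in sorted(cohort[var].astype(str).unique()) if lv != "unknown"]
        counts = np.zeros((len(levels), 2), dtype=int)
        for j, a in enumerate(arms):
            vc = sub[a][var].astype(str).value_counts()
            denom = sum(int(vc.get(lv, 0)) for lv in levels)
            for i, lv in enumerate(levels):
                counts[i, j] = int(vc.get(lv, 0))
            for i, lv in enumerate(levels):
                pct = 100 * counts[i, j] / denom if denom else 0.0
                rows.append(
                    {
                        "characteristic": var,
                        "level": lv,
                        a: f"{counts[i, j]} ({pct:.0f}%)",
                    }
                )
            unk = int(vc.get("unknown", 0))
            if unk:
                rows.append({"characteristic": var, "level": "unknown", a: str(unk)})
        name, p = categorical_test(counts)
        tests.append(
            {
                "characteristic": var,
                "test": name,
                "p": p,
                "p_display": format_pvalue(p),
            }
        )
    summary = (
        pd.DataFrame(rows)
        .groupby(["characteristic", "level"], sort=False)
        .first()
        .reset_index()
    )
    return BaselineTable(summary=summary, tests=pd.DataFrame(tests))


def cindex_comparison(
    risks: dict[str, dict[str, pd.Series]],
    clinical: pd.DataFrame,
    arm_col: str = "arm",
) -> pd.DataFrame:
    """Harrell c-index per (feature set, arm) on held-out patients.

    ``risks[feature_set][arm]`` is a Series of per-patient risk scores
    on that arm's test patients; every feature set must be evaluated on
    the identical patients within an arm.
    """
    out = {}
    ref_ids: dict[str, pd.Index] = {}
    for fs, per_arm in risks.items():
        out[fs] = {}
        for arm, r in per_arm.items():
            ids = r.index
            if arm in ref_ids:
                if not ref_ids[arm].equals(ids):
                    raise ValueError(
                        f"feature set {fs!r} evaluated on different test patients "
                        f"in arm {arm!r}"
                    )
            else:
                ref_ids[arm] = ids
            cl = clinical.loc[ids]
            if not (cl[arm_col] == arm).all():
                raise ValueError("risk series contains patients from another arm")
            out[fs][arm] = sv.concordance_index(
                r.to_numpy(dtype=float),
                cl["pfs_months"].to_numpy(),
                cl["event"].to_numpy(),
            )
    return pd.DataFrame(out).T


def km_report(
    groupings: dict[str, pd.Series],
    clinical: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Per-grouping KM curves, medians, HR and log-rank p, with BH
    correction across all groupings in the report."""
    if len(groupings) == 0:
        raise ValueError("need at least one grouping")
    rows, curves = [], {}
    for name, labels in groupings.items():
        lab = labels.dropna()
        cl = clinical.loc[lab.index]
        levels = sorted(lab.unique())
        if len(levels) != 2:
            raise ValueError(f"grouping {name!r} must have exactly two levels")
        time = cl["pfs_months"].to_numpy()
        event = cl["event"].to_numpy()
        med = {}
        curves[name] = {}
        for lv in levels:
            m = (lab == lv).to_numpy()
            km = sv.km_estimate(time[m], event[m])
            med[lv] = km.median
            curves[name][lv] = km
        ind = (lab == levels[1]).astype(float).to_numpy()
        fit = sv.fit_coxph(sv.SurvivalData(time, event, ind[:, None]))
        lo, hi = fit.ci95()
        lr = sv.logrank_test(time, event, lab.to_numpy())
        rows.append(
            {
                "grouping": name,
                "group_low": levels[0],
                "group_high": levels[1],
                f"median_{levels[0]}": med[levels[0]],
                f"median_{levels[1]}": med[levels[1]],
                "hazard_ratio": float(fit.hazard_ratios[0]),
                "ci95_lo": float(lo[0]),
                "ci95_hi": float(hi[0]),
                "logrank_p": lr["p"],
            }
        )
    report = pd.DataFrame(rows)
    report["adjusted_p"] = sv.bh_adjust(report["logrank_p"].to_numpy())
    report["significant"] = report["adjusted_p"] < alpha
    return report, curves


def save_km_plot(curves: dict, path, title: str = "") -> None:
    """Step-plot the KM curves of one grouping to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for level, km in curves.items():
        t = np.concatenate([[0.0], km.event_times])
        s = np.concatenate([[1.0], km.survival])
        ax.step(t, s, where="post", label=str(level))
    ax.set_xlabel("months")
    ax.set_ylabel("PFS probability")
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
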