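"""Mass-univariate group comparison and etiology regression.

Every feature is compared between the WS and control groups with a
pooled-variance two-sample t-test; p-values are corrected with the
Benjamini-Hochberg step-up procedure within (family x band/measure x
scope) strata — e.g. the 19 channel-wise theta relative-power tests form
one correction block, mirroring per-band channel-wise reporting. A
global-across-everything correction mode is available.

For the WS group alone, each feature is regressed on the structural and
genetic etiology flags (OLS with intercept); coefficient p-values are
BH-corrected across features separately per predictor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .signal_io import FeatureTable, SubjectMeta

ALPHA_DEFAULT = 0.05


@dataclass
class ComparisonResult:
    feature: str
    mean_ws: float
    mean_ctrl: float
    sd_ws: float
    sd_ctrl: float
    sem_ws: float
    sem_ctrl: float
    t_stat: float
    p_raw: float
    q_value: float
    significant: bool


@dataclass
class RegressionResult:
    feature: str
    beta_structural: float
    beta_genetic: float
    p_structural: float
    p_genetic: float
    q_structural: float = float("nan")
    q_genetic: float = float("nan")
    valid: bool = True


def two_sample_ttest(a, b, equal_var: bool = True) -> tuple[float, float]:
    """Student (pooled-variance) two-sided t-test; Welch via equal_var=False."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 non-missing values per group")
    if equal_var and a.var(ddof=1) + b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("degenerate groups: zero pooled variance")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def parse_feature_name(name: str) -> tuple[str, str, str]:
    """Split a feature name into (family, band-or-measure, scope).

    Scope is "global" for global features, otherwise "channel" (including
    channel pairs).
    """
    family, mid, tail = name.split(".", 2)
    scope = "global" if tail == "global" else "channel"
    return family, mid, scope


def _split_groups(table: FeatureTable, meta: list[SubjectMeta]) -> tuple[np.ndarray, np.ndarray]:
    by_id = {m.subject_id: m for m in meta}
    missing = [s for s in table.subjects if s not in by_id]
    if missing:
        raise ValueError(f"metadata missing for subjects: {missing}")
    is_ws = np.array([by_id[s].group == "WS" for s in table.subjects])
    return table.values[is_ws], table.values[~is_ws]


def ttest_matrix(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise pooled-variance t-tests of two (subjects x features) blocks.

    NaNs are dropped per column. Columns with fewer than two finite values
    in either group, or zero pooled variance, come back NaN.
    """
    t = np.full(a.shape[1], np.nan)
    p = np.full(a.shape[1], np.nan)
    fa, fb = np.isfinite(a), np.isfinite(b)
    na, nb = fa.sum(axis=0), fb.sum(axis=0)
    za, zb = np.where(fa, a, 0.0), np.where(fb, b, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ma = za.sum(axis=0) / na
        mb = zb.sum(axis=0) / nb
        va = (np.where(fa, (a - ma) ** 2, 0.0)).sum(axis=0) / (na - 1)
        vb = (np.where(fb, (b - mb) ** 2, 0.0)).sum(axis=0) / (nb - 1)
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se = np.sqrt(sp2 * (1 / na + 1 / nb))
        ok = (na >= 2) & (nb >= 2) & (se > 0)
        t[ok] = ((ma - mb) / se)[ok]
        p[ok] = 2 * stats.t.sf(np.abs(t[ok]), df[ok])
    return t, p


def compare_groups(table: FeatureTable, meta: list[SubjectMeta], *,
                   alpha: float = ALPHA_DEFAULT, fdr_scope: str = "family",
                   equal_var: bool = True) -> list[ComparisonResult]:
    """Per-feature WS-vs-control t-tests with stratified BH-FDR.

    ``fdr_scope="family"`` corrects within (family, band/measure, scope)
    blocks; ``"global"`` corrects across all testable features at once.
    Degenerate features (too few values or zero variance) are dropped with
    a warning.
    """
    ws, ctrl = _split_groups(table, meta)
    if ws.shape[0] < 2 or ctrl.shape[0] < 2:
        raise ValueError("both groups need at least 2 subjects")
    names = table.feature_names
    if not equal_var:
        t = np.full(len(names), np.nan)
        p = np.full(len(names), np.nan)
        for j in range(len(names)):
            try:
                t[j], p[j] = two_sample_ttest(ws[:, j], ctrl[:, j], equal_var=False)
            except ValueError:
                pass
    else:
        t, p = ttest_matrix(ws, ctrl)

    testable = np.isfinite(p)
    dropped = [names[j] for j in np.nonzero(~testable)[0]]
    if dropped:
        warnings.warn(f"dropped {len(dropped)} degenerate feature(s): "
                      f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}",
                      stacklevel=2)

    q = np.full(len(names), np.nan)
    if fdr_scope == "global":
        idx = np.nonzero(testable)[0]
        q[idx] = bh_fdr(p[idx])
    elif fdr_scope == "family":
        blocks: dict[tuple, list[int]] = {}
        for j, name in enumerate(names):
            if testable[j]:
                blocks.setdefault(parse_feature_name(name), []).append(j)
        for idx in blocks.values():
            q[idx] = bh_fdr(p[idx])
    else:
        raise ValueError("fdr_scope must be 'family' or 'global'")

    results = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for j, name in enumerate(names):
            if not testable[j]:
                continue
            a, b = ws[:, j], ctrl[:, j]
            a, b = a[np.isfinite(a)], b[np.isfinite(b)]
            results.append(ComparisonResult(
                feature=name,
                mean_ws=float(a.mean()), mean_ctrl=float(b.mean()),
                sd_ws=float(a.std(ddof=1)), sd_ctrl=float(b.std(ddof=1)),
                sem_ws=float(a.std(ddof=1) / np.sqrt(a.size)),
                sem_ctrl=float(b.std(ddof=1) / np.sqrt(b.size)),
                t_stat=float(t[j]), p_raw=float(p[j]), q_value=float(q[j]),
                significant=bool(q[j] < alpha),
            ))
    return results


def comparison_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def channel_tmap(results: list[ComparisonResult], family: str, mid: str) -> pd.DataFrame:
    """Channel-wise t-values with non-significant entries set to 0."""
    rows = []
    for r in results:
        fam, m, scope = parse_feature_name(r.feature)
        if fam == family and m == mid and scope == "channel":
            rows.append((r.feature.rsplit(".", 1)[1],
                         r.t_stat if r.significant else 0.0))
    return pd.DataFrame(rows, columns=["channel", "t"])


def regress_etiology(table: FeatureTable, meta: list[SubjectMeta], *,
                     alpha: float = ALPHA_DEFAULT) -> list[RegressionResult]:
    """OLS of each feature on [intercept, structural_flag, genetic_flag].

    Restricted to WS subjects; requires at least 3 more subjects than
    predictors and both flags to vary (a constant flag, or identical
    flags, marks results invalid). BH-FDR runs across features separately
    per predictor.
    """
    by_id = {m.subject_id: m for m in meta}
    keep = [i for i, s in enumerate(table.subjects)
            if by_id[s].group == "WS"]
    if len(keep) < 6:
        raise ValueError("need at least 6 WS subjects for the regression")
    sub = [table.subjects[i] for i in keep]
    y_all = table.values[keep]
    x_s = np.array([by_id[s].structural_flag for s in sub], dtype=float)
    x_g = np.array([by_id[s].genetic_flag for s in sub], dtype=float)
    X = np.column_stack([np.ones_like(x_s), x_s, x_g])
    rank_ok = np.linalg.matrix_rank(X) == 3

    results = []
    n = len(sub)
    if rank_ok:
        XtX_inv = np.linalg.inv(X.T @ X)
    for j, name in enumerate(table.feature_names):
        y = y_all[:, j]
        fin = np.isfinite(y)
        if not rank_ok or fin.sum() < 6:
            results.append(RegressionResult(name, *(float("nan"),) * 4, valid=False))
            continue
        Xf, yf = X[fin], y[fin]
        if fin.sum() == n:
            cov = XtX_inv
        else:
            if np.linalg.matrix_rank(Xf) < 3:
                results.append(RegressionResult(name, *(float("nan"),) * 4, valid=False))
                continue
            cov = np.linalg.inv(Xf.T @ Xf)
        beta = cov @ Xf.T @ yf
        resid = yf - Xf @ beta
        dfree = yf.size - 3
        s2 = resid @ resid / dfree if dfree > 0 else np.nan
        se = np.sqrt(np.maximum(np.diag(cov) * s2, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        pvals = 2 * stats.t.sf(np.abs(tvals), dfree)
        pvals = np.where(np.isfinite(tvals), pvals, 0.0)
        results.append(RegressionResult(
            name, float(beta[1]), float(beta[2]),
            float(pvals[1]), float(pvals[2])))

    valid_idx = [i for i, r in enumerate(results) if r.valid]
    if valid_idx:
        qs = bh_fdr([results[i].p_structural for i in valid_idx])
        qg = bh_fdr([results[i].p_genetic for i in valid_idx])
        for k, i in enumerate(valid_idx):
            results[i].q_structural = float(qs[k])
            results[i].q_genetic = float(qg[k])
    return results


def regression_frame(results: list[RegressionResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
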