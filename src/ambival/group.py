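"""Second-level (group) statistics: symptom correlations, covariate-adjusted
effects, value/saliency group tests with FDR, clinical PCA, and exhaustive
best-subset regression by BIC.

Conventions: Spearman rank correlation for analyses involving CAPS (heavily
tied at zero in trauma cohorts), Pearson for PCL-5 and principal components;
Welch's unequal-variance t test for two-sample comparisons; Benjamini-
Hochberg step-up for FDR.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

import statsmodels.api as sm
import statsmodels.formula.api as smf


@dataclass
class GroupResult:
    """One second-level statistic with its inferential context."""

    analysis: str
    statistic: float
    statistic_type: str  # spearman_rho | pearson_r | t | F | beta_std
    df: float | tuple
    p_raw: float
    n: int
    p_fdr: float | None = None

    def as_row(self) -> dict:
        return {
            "analysis": self.analysis,
            "statistic": self.statistic,
            "statistic_type": self.statistic_type,
            "df": str(self.df),
            "p_raw": self.p_raw,
            "p_fdr": self.p_fdr,
            "n": self.n,
        }


_KIND_METHOD = {"caps": "spearman", "pcl5": "pearson", "pc": "pearson"}


def correlate_with_symptoms(values, scores, score_kind: str, analysis: str = "") -> GroupResult:
    """Correlate a per-subject quantity with a symptom score.

    ``score_kind`` selects the convention: ``caps`` -> Spearman rank
    correlation, ``pcl5``/``pc`` -> Pearson.  Pairs with missing data are
    dropped (complete-case).
    """
    if score_kind not in _KIND_METHOD:
        raise ValueError(f"unknown score kind {score_kind!r}")
    values = np.asarray(values, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if len(values) != len(scores):
        raise ValueError("values and scores must be paired (equal length)")
    keep = ~(np.isnan(values) | np.isnan(scores))
    values, scores = values[keep], scores[keep]
    if len(values) < 4:
        raise ValueError("need at least 4 complete pairs")
    if _KIND_METHOD[score_kind] == "spearman":
        r, p = stats.spearmanr(values, scores)
        stat_type = "spearman_rho"
    else:
        r, p = stats.pearsonr(values, scores)
        stat_type = "pearson_r"
    n = len(values)
    return GroupResult(analysis or f"corr_{score_kind}", float(r), stat_type,
                       df=n - 2, p_raw=float(p), n=n)


def covariate_adjusted_effect(
    data: pd.DataFrame,
    outcome: str,
    symptom: str = "caps_total",
    covariates: tuple = ("age", "C(income_band)", "C(education_band)", "kbit", "bic"),
    analysis: str = "",
) -> GroupResult:
    """Type-II F test of a symptom term controlling for demographic covariates.

    Fits ``outcome ~ symptom + covariates`` by OLS (categorical covariates
    dummy-coded via the formula interface) and tests the symptom term against
    the full-minus-symptom model: F = ((RSS_r - RSS_f)/1) / (RSS_f/df_f).
    Complete-case per analysis.
    """
    plain = [c.removeprefix("C(").removesuffix(")") for c in covariates]
    cols = [outcome, symptom, *plain]
    d = data[cols].dropna()
    if len(d) < len(cols) + 2:
        raise ValueError("too few complete cases for the covariate model")
    rhs = " + ".join([symptom, *covariates])
    full = smf.ols(f"{outcome} ~ {rhs}", data=d).fit()
    reduced = smf.ols(f"{outcome} ~ {' + '.join(covariates)}", data=d).fit()
    if np.linalg.matrix_rank(full.model.exog) < full.model.exog.shape[1]:
        raise ValueError("rank-deficient covariate design; check categorical coding")
    df_f = full.df_resid
    F = (reduced.ssr - full.ssr) / (full.ssr / df_f)
    p = float(stats.f.sf(F, 1, df_f))
    return GroupResult(analysis or f"{outcome}~{symptom}|covariates", float(F), "F",
                       df=(1, float(df_f)), p_raw=p, n=len(d))


def fdr_correct(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (adjusted p, rejection flags)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def value_saliency_group_tests(
    value_betas, saliency_betas, group_labels, q: float = 0.05
) -> list[GroupResult]:
    """Test value and saliency encoding against zero per group, plus a group contrast.

    Four one-sample t tests (value/saliency x control/ptsd) form one FDR
    family (Benjamini-Hochberg across the four); a Welch unequal-variance
    two-sample t test compares saliency betas between groups.
    """
    value_betas = np.asarray(value_betas, float)
    saliency_betas = np.asarray(saliency_betas, float)
    groups = np.asarray(group_labels)
    results = []
    for name, arr in (("value", value_betas), ("saliency", saliency_betas)):
        for g in ("control", "ptsd"):
            x = arr[groups == g]
            if len(x) < 3:
                raise ValueError(f"group {g!r} has fewer than 3 subjects")
            t, p = stats.ttest_1samp(x, 0.0)
            results.append(
                GroupResult(f"{name}_{g}_vs_0", float(t), "t", df=len(x) - 1,
                            p_raw=float(p), n=len(x))
            )
    p_adj, _ = fdr_correct([r.p_raw for r in results], q=q)
    for r, pa in zip(results, p_adj):
        r.p_fdr = float(pa)
    a = saliency_betas[groups == "control"]
    b = saliency_betas[groups == "ptsd"]
    t, p = stats.ttest_ind(a, b, equal_var=False)
    df = _welch_df(a, b)
    results.append(
        GroupResult("saliency_control_vs_ptsd", float(t), "t", df=float(df),
                    p_raw=float(p), n=len(a) + len(b))
    )
    return results


def _welch_df(a, b) -> float:
    va, vb = np.var(a, ddof=1) / len(a), np.var(b, ddof=1) / len(b)
    return (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))


@dataclass
class SubsetSelectionResult:
    """Exhaustive best-subset regression ranked by BIC."""

    table: pd.DataFrame        # one row per non-empty subset: predictors, size, rss, bic
    best_set: tuple            # predictor names attaining the minimum BIC
    best_bic: float
    best_per_size: pd.DataFrame

    def summary(self) -> str:
        lines = ["Exhaustive subset selection (BIC)", "=" * 40,
                 f"best set: {', '.join(self.best_set)}  (BIC = {self.best_bic:.2f})",
                 "-" * 40, "best model per size:"]
        for _, row in self.best_per_size.iterrows():
            lines.append(f"  k={row['size']}: {row['predictors']}  BIC={row['bic']:.2f}")
        return "\n".join(lines)


def exhaustive_subset_selection(y, X: pd.DataFrame) -> SubsetSelectionResult:
    """Enumerate every non-empty predictor subset, fit OLS, rank by BIC.

    BIC convention: ``n*ln(RSS/n) + (k+1)*ln(n)`` with the intercept counted
    in ``k+1``.  Refuses more than 15 predictors (2^p enumeration) and
    collinear/duplicated predictor columns (named in the error).
    """
    y = np.asarray(y, dtype=float)
    names = list(X.columns)
    p = len(names)
    if p > 15:
        raise ValueError(f"refusing exhaustive enumeration over {p} > 15 predictors")
    n = len(y)
    if n <= p + 2:
        raise ValueError("need n > p + 2 observations")
    Xm = X.to_numpy(float)
    full = np.column_stack([np.ones(n), Xm])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        bad = _name_collinear(full, ["(intercept)", *names])
        raise ValueError(f"collinear predictor columns: {bad}")
    rows = []
    for k in range(1, p + 1):
        for combo in itertools.combinations(range(p), k):
            Xs = np.column_stack([np.ones(n), Xm[:, combo]])
            beta, _, _, _ = np.linalg.lstsq(Xs, y, rcond=None)
            rss = float(np.sum((y - Xs @ beta) ** 2))
            bic = n * np.log(rss / n) + (k + 1) * np.log(n)
            rows.append(
                {"predictors": ", ".join(names[j] for j in combo),
                 "subset": tuple(names[j] for j in combo),
                 "size": k, "rss": rss, "bic": float(bic)}
            )
    table = pd.DataFrame(rows).sort_values("bic", kind="mergesort").reset_index(drop=True)
    best = table.iloc[0]
    best_per_size = (
        table.sort_values(["size", "bic"], kind="mergesort").groupby("size").head(1)
        .reset_index(drop=True)
    )
    return SubsetSelectionResult(
        table=table, best_set=tuple(best["subset"]), best_bic=float(best["bic"]),
        best_per_size=best_per_size,
    )


def _name_collinear(X: np.ndarray, names: list[str]) -> list[str]:
    bad, cols, r = [], [], 0
    for j in range(X.shape[1]):
        if np.linalg.matrix_rank(X[:, cols + [j]]) > r:
            cols.append(j)
            r += 1
        else:
            bad.append(names[j])
    return bad


@dataclass
class ClinicalPcaResult:
    """PCA of standardised clinical/trauma measures (correlation matrix)."""

    loadings: pd.DataFrame        # variables x components
    scores: pd.DataFrame          # complete cases x components
    variance_explained: np.ndarray  # percent per component
    n: int

    def summary(self) -> str:
        lines = ["Clinical PCA (correlation matrix)", "=" * 40,
                 f"complete cases: {self.n}",
                 "variance explained (%): "
                 + ", ".join(f"{v:.1f}" for v in self.variance_explained)]
        return "\n".join(lines)


def pca_clinical(measures: pd.DataFrame) -> ClinicalPcaResult:
    """Eigendecomposition of the correlation matrix of clinical measures.

    Complete cases only; each component is signed so its largest-magnitude
    loading is positive.  Scores are standardised-variable projections.
    """
    d = measures.dropna()
    if len(d) < d.shape[1]:
        raise ValueError("fewer complete cases than variables")
    Z = (d - d.mean()) / d.std(ddof=1)
    C = np.corrcoef(Z.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(C)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    for j in range(eigvec.shape[1]):
        if eigvec[np.argmax(np.abs(eigvec[:, j])), j] < 0:
            eigvec[:, j] *= -1
    comp_names = [f"PC{j + 1}" for j in range(len(eigval))]
    loadings = pd.DataFrame(eigvec, index=d.columns, columns=comp_names)
    scores = pd.DataFrame(Z.to_numpy() @ eigvec, index=d.index, columns=comp_names)
    var_exp = 100.0 * eigval / eigval.sum()
    return ClinicalPcaResult(loadings=loadings, scores=scores,
                             variance_explained=var_exp, n=len(d))


def results_frame(results: list[GroupResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in results])
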