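"""One-stage ("mega") multi-site group statistics.

All subject-level features are pooled across sites in a single linear
mixed-effect model with a Gaussian random intercept per site:

    y_ij = b0 + b_group * MDD_ij + b_age * age_ij + b_sex * M_ij
           + b_fd * meanFD_ij + u_j + e_ij,   u_j ~ N(0, s2_site)

fitted by REML.  Dependent features are rank-based inverse normal
transformed by default so that scales are comparable across features and
sites.  Effect sizes are Cohen's d = 2t/sqrt(df); multiplicity is handled
with Bonferroni within each seven-network feature family and with
Benjamini-Hochberg FDR across the edge family.

The module also covers the secondary questions of the same design:
severity-category contrasts against controls, medicated-versus-
unmedicated contrasts (with a Monte-Carlo chi-square balance check), and
the group-by-age interaction on network segregation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import mixedlm, ols
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ModelSpec", "GroupComparisonResult", "inverse_normal_transform",
    "fit_group_lmm", "compare_groups", "cohens_d_from_t", "bonferroni",
    "fdr_bh", "severity_contrasts", "medication_comparison",
    "age_slope_interaction", "edge_group_analysis",
]

_COVARIATES = ("age", "sex", "mean_fd")


@dataclass(frozen=True)
class ModelSpec:
    """Model layout for one mixed-effect comparison."""

    dependent: str
    fixed_effects: tuple[str, ...] = ("group", "age", "sex", "mean_fd")
    random_intercept: str | None = "site_id"  # None: fixed-effects model only
    transform: str = "inverse_normal"  # or "none"

    def __post_init__(self) -> None:
        if self.transform not in ("inverse_normal", "none"):
            raise ValueError("transform must be 'inverse_normal' or 'none'")


@dataclass
class GroupComparisonResult:
    feature: str
    term: str
    estimate: float
    se: float
    t: float
    df: float
    cohens_d: float
    p_raw: float
    p_corrected: float | None = None
    correction: str = "none"
    adjusted_means: dict[str, float] = field(default_factory=dict)
    model_type: str = "mixed"      # "mixed" or "ols" (singular-fit fallback)
    site_variance: float = float("nan")

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "adjusted_means"}
        for g, m in self.adjusted_means.items():
            d[f"adjusted_mean_{g}"] = m
        return d


def inverse_normal_transform(x, c: float = 0.375) -> np.ndarray:
    """Rank-based inverse normal transform with Blom offset c = 3/8.

    Maps the ranks r_i (ties averaged) onto standard-normal quantiles
    Phi^-1((r_i - c) / (n - 2c + 1)); order-preserving by construction.
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D vector")
    if arr.size < 2:
        raise ValueError("need at least two values to rank")
    if not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")
    if np.all(arr == arr[0]):
        raise ValueError("all values identical: no ordering information")
    ranks = stats.rankdata(arr, method="average")
    return stats.norm.ppf((ranks - c) / (arr.size - 2 * c + 1))


def cohens_d_from_t(t: float, df: float) -> float:
    """Effect size d = 2t/sqrt(df) of a model t statistic."""
    if df <= 0:
        raise ValueError("df must be positive")
    return 2.0 * t / np.sqrt(df)


def bonferroni(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni adjustment over a family: p_adj = min(1, m*p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    adj = np.minimum(1.0, p * p.size)
    return adj, adj < alpha


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone-enforced)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# model fitting


def _merged(features: pd.DataFrame, records: pd.DataFrame,
            columns: Sequence[str]) -> pd.DataFrame:
    df = records.merge(features, on="subject_id", validate="one_to_one")
    df = df.dropna(subset=list(columns)).copy()
    df["group"] = pd.Categorical(df["group"], categories=["HC", "MDD"])
    df["sex"] = pd.Categorical(df["sex"], categories=["F", "M"])
    return df


def _maybe_transform(df: pd.DataFrame, feature: str, transform: str) -> pd.DataFrame:
    df = df.copy()
    y = df[feature].to_numpy(dtype=float)
    df["y"] = inverse_normal_transform(y) if transform == "inverse_normal" else y
    return df


def _fit_mixed_or_ols(df: pd.DataFrame, formula: str, groups: str):
    """REML mixed fit; degenerates to OLS when the site variance vanishes.

    Returns ``(result, model_type, site_variance)``.
    """
    if df[groups].nunique() < 2:
        raise ValueError("random grouping factor needs at least 2 levels")
    res = None
    for method in ("bfgs", "lbfgs", "powell"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = mixedlm(formula, df, groups=df[groups]).fit(
                    reml=True, method=method, maxiter=2000)
        except np.linalg.LinAlgError:
            continue
        if res.converged:
            break
    if res is None:
        # variance component on the boundary defeated every optimiser
        return ols(formula, df).fit(), "ols", 0.0
    site_var = float(np.squeeze(res.cov_re.to_numpy()))
    # boundary / singular fit: the random intercept explains nothing
    if site_var <= 1e-8 * max(res.scale, 1e-12):
        return ols(formula, df).fit(), "ols", site_var
    if not res.converged:
        raise RuntimeError(
            f"mixed model did not converge for formula {formula!r}; "
            f"site variance {site_var:.3g}, scale {res.scale:.3g}")
    return res, "mixed", site_var


def _term_test(res, term: str, df_resid: float) -> tuple[float, float, float, float]:
    est = float(res.params[term])
    se = float(res.bse[term])
    t = est / se
    p = 2.0 * stats.t.sf(abs(t), df_resid)
    return est, se, t, p


def _residual_df(res, df: pd.DataFrame) -> float:
    k_fe = len(res.fe_params) if hasattr(res, "fe_params") else len(res.params)
    return float(len(df) - k_fe)


def _adjusted_group_means(res, df: pd.DataFrame, term: str) -> dict[str, float]:
    """Fixed-effect predictions per group at the sample-mean covariates."""
    exog = res.model.exog
    names = (res.model.exog_names if hasattr(res.model, "exog_names") else
             list(res.params.index))
    xbar = exog.mean(axis=0)
    j = names.index(term)
    params = (res.fe_params if hasattr(res, "fe_params") else res.params).to_numpy()
    x_hc, x_mdd = xbar.copy(), xbar.copy()
    x_hc[j], x_mdd[j] = 0.0, 1.0
    return {"HC": float(x_hc @ params), "MDD": float(x_mdd @ params)}


def fit_group_lmm(
    features: pd.DataFrame,
    records: pd.DataFrame,
    spec: ModelSpec,
) -> GroupComparisonResult:
    """Mixed-model MDD-vs-HC comparison for one feature.

    The returned t statistic uses residual degrees of freedom
    (N - #fixed-effect coefficients); for a subject-level contrast such
    as group this is close to any finer-grained df approximation at
    consortium sample sizes.  A singular fit (site variance estimated at
    zero) falls back to the fixed-effects-only model and is flagged via
    ``model_type == "ols"``.
    """
    feature = spec.dependent
    df = _merged(features, records, [feature, *spec.fixed_effects])
    df = _maybe_transform(df, feature, spec.transform)
    rhs = " + ".join(spec.fixed_effects)
    if spec.random_intercept is None:
        res, model_type, site_var = ols(f"y ~ {rhs}", df).fit(), "ols", 0.0
    else:
        res, model_type, site_var = _fit_mixed_or_ols(
            df, f"y ~ {rhs}", spec.random_intercept)
    term = "group[T.MDD]"
    df_resid = _residual_df(res, df)
    est, se, t, p = _term_test(res, term, df_resid)
    return GroupComparisonResult(
        feature=feature, term=term, estimate=est, se=se, t=t, df=df_resid,
        cohens_d=cohens_d_from_t(t, df_resid), p_raw=p,
        adjusted_means=_adjusted_group_means(res, df, term),
        model_type=model_type, site_variance=site_var,
    )


def compare_groups(
    features: pd.DataFrame,
    records: pd.DataFrame,
    feature_names: Sequence[str],
    transform: str = "inverse_normal",
    families: Mapping[str, Sequence[str]] | None = None,
    alpha: float = 0.05,
    random_intercept: str = "site_id",
) -> pd.DataFrame:
    """Group comparison over several features with family-wise Bonferroni.

    By default the within-network FC features (``fc_*``) and the
    segregation features (``seg_*``) form two separate seven-member
    Bonferroni families, mirroring how network-level tables are usually
    corrected.
    """
    if families is None:
        families = {
            "fc": [f for f in feature_names if f.startswith("fc_")],
            "seg": [f for f in feature_names if f.startswith("seg_")],
        }
        families = {k: v for k, v in families.items() if v}
        listed = {f for v in families.values() for f in v}
        rest = [f for f in feature_names if f not in listed]
        if rest:
            families["other"] = rest
    results: dict[str, GroupComparisonResult] = {}
    for feature in feature_names:
        spec = ModelSpec(dependent=feature, transform=transform,
                         random_intercept=random_intercept)
        results[feature] = fit_group_lmm(features, records, spec)
    for fam_features in families.values():
        p = [results[f].p_raw for f in fam_features]
        adj, _ = bonferroni(p, alpha)
        for f, pa in zip(fam_features, adj):
            results[f].p_corrected = float(pa)
            results[f].correction = "bonferroni"
    out = pd.DataFrame([results[f].to_dict() for f in feature_names])
    return out


# ---------------------------------------------------------------------------
# secondary analyses


def severity_contrasts(
    features: pd.DataFrame,
    records: pd.DataFrame,
    feature_names: Sequence[str],
    transform: str = "inverse_normal",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Severity-category analysis against healthy controls.

    Cases with a known severity category and all controls enter one
    mixed model per feature in which the group factor is replaced by the
    six-level factor {HC, remitted, ..., very_severe} (HC reference).
    Reported per feature: the overall Wald test of the five severity
    coefficients, and each level-vs-HC contrast with Bonferroni
    correction across the feature family.  Empty severity cells yield a
    missing row rather than an error.
    """
    from .cohort import SEVERITY_LEVELS

    rows = []
    for feature in feature_names:
        df = _merged(features, records, [feature, "age", "sex", "mean_fd"])
        df = df[(df["group"] == "HC")
                | df["severity"].isin(SEVERITY_LEVELS)].copy()
        df["sevgrp"] = np.where(df["group"] == "HC", "HC", df["severity"])
        cats = ["HC", *SEVERITY_LEVELS]
        present = [c for c in cats if (df["sevgrp"] == c).any()]
        df["sevgrp"] = pd.Categorical(df["sevgrp"], categories=present)
        df = _maybe_transform(df, feature, transform)
        res, model_type, _ = _fit_mixed_or_ols(
            df, "y ~ C(sevgrp) + age + sex + mean_fd", "site_id")
        df_resid = _residual_df(res, df)
        sev_terms = [t for t in res.params.index if t.startswith("C(sevgrp)")]
        # overall factor test (Wald chi-square over all severity contrasts)
        wald = res.wald_test(
            ", ".join(f"{t} = 0" for t in sev_terms), scalar=True)
        rows.append({
            "feature": feature, "contrast": "overall", "level": "",
            "estimate": np.nan, "se": np.nan, "t": np.nan,
            "p_raw": float(wald.pvalue), "p_corrected": np.nan,
            "model_type": model_type, "n": len(df),
        })
        for level in SEVERITY_LEVELS:
            term = f"C(sevgrp)[T.{level}]"
            if term not in res.params.index:
                rows.append({"feature": feature, "contrast": "vs_HC",
                             "level": level, "estimate": np.nan, "se": np.nan,
                             "t": np.nan, "p_raw": np.nan, "p_corrected": np.nan,
                             "model_type": model_type, "n": len(df)})
                continue
            est, se, t, p = _term_test(res, term, df_resid)
            rows.append({"feature": feature, "contrast": "vs_HC", "level": level,
                         "estimate": est, "se": se, "t": t, "p_raw": p,
                         "p_corrected": np.nan, "model_type": model_type,
                         "n": len(df)})
    out = pd.DataFrame(rows)
    # Bonferroni across the feature family, separately per contrast type
    for (_, level), idx in out.groupby(["contrast", "level"]).groups.items():
        sel = out.loc[idx]
        ok = sel["p_raw"].notna()
        if ok.any():
            adj, _ = bonferroni(sel.loc[ok, "p_raw"].to_numpy(), alpha)
            out.loc[sel.index[ok], "p_corrected"] = adj
    return out


def monte_carlo_chi2(table: np.ndarray, b: int = 1000,
                     seed: int | None = None) -> tuple[float, float]:
    """Pearson chi-square with a Monte-Carlo permutation p-value.

    ``b`` label permutations of the second margin approximate the null
    distribution of the statistic under independence with both margins
    fixed; p = (1 + #{sim >= observed}) / (b + 1).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.size == 0:
        raise ValueError("need a 2-D contingency table")
    stat = stats.chi2_contingency(table, correction=False)[0]
    rng = np.random.default_rng(seed)
    rows = np.repeat(np.arange(table.shape[0]), table.sum(axis=1).astype(int))
    cols = np.repeat(np.arange(table.shape[1]), table.sum(axis=0).astype(int))
    n_rows, n_cols = table.shape
    count = 0
    for _ in range(b):
        perm = rng.permutation(cols)
        sim = np.zeros_like(table)
        np.add.at(sim, (rows, perm), 1.0)
        sim_stat = stats.chi2_contingency(sim, correction=False)[0]
        if sim_stat >= stat - 1e-12:
            count += 1
    return float(stat), (1.0 + count) / (b + 1.0)


def medication_comparison(
    features: pd.DataFrame,
    records: pd.DataFrame,
    feature_names: Sequence[str],
    transform: str = "inverse_normal",
    b: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Medicated vs unmedicated cases: balance check plus model contrasts.

    Returns ``(results, balance)`` where ``balance`` reports the
    severity-by-medication Pearson chi-square with a seeded Monte-Carlo
    p-value (no association between medication status and severity means
    the contrast is not confounded by severity), and ``results`` holds
    one mixed-model medicated-vs-unmedicated contrast per feature,
    Bonferroni-corrected within the feature family.
    """
    from .cohort import SEVERITY_LEVELS

    cases = records[(records["group"] == "MDD")
                    & records["medication"].isin(["yes", "no"])].copy()
    if cases.empty:
        raise ValueError("no cases with known medication status")
    known = cases[cases["severity"].isin(SEVERITY_LEVELS)]
    table = pd.crosstab(known["severity"], known["medication"])
    stat, p_mc = monte_carlo_chi2(table.to_numpy(), b=b, seed=seed)
    balance = {"chi2": stat, "p_monte_carlo": p_mc, "b": b,
               "table": table}

    rows = []
    for feature in feature_names:
        df = cases.merge(features, on="subject_id", validate="one_to_one")
        df = df.dropna(subset=[feature, "age", "sex", "mean_fd"]).copy()
        df["sex"] = pd.Categorical(df["sex"], categories=["F", "M"])
        df["medication"] = pd.Categorical(df["medication"],
                                          categories=["no", "yes"])
        df = _maybe_transform(df, feature, transform)
        res, model_type, _ = _fit_mixed_or_ols(
            df, "y ~ medication + age + sex + mean_fd", "site_id")
        df_resid = _residual_df(res, df)
        est, se, t, p = _term_test(res, "medication[T.yes]", df_resid)
        rows.append({"feature": feature, "estimate": est, "se": se, "t": t,
                     "df": df_resid, "p_raw": p, "model_type": model_type,
                     "n": len(df)})
    out = pd.DataFrame(rows)
    adj, _ = bonferroni(out["p_raw"].to_numpy(), alpha)
    out["p_corrected"] = adj
    return out, balance


@dataclass
class AgeSlopeResult:
    feature: str
    slope_hc: float
    se_hc: float
    t_hc: float
    p_hc: float
    slope_mdd: float
    se_mdd: float
    t_mdd: float
    p_mdd: float
    slope_diff: float
    se_diff: float
    t_diff: float
    p_diff: float
    df: float
    model_type: str


def age_slope_interaction(
    features: pd.DataFrame,
    records: pd.DataFrame,
    feature: str,
    transform: str = "inverse_normal",
) -> AgeSlopeResult:
    """Per-group age slopes of a feature and their difference.

    Fits ``y ~ group*age + sex + mean_fd`` with the site random
    intercept; the HC slope is the age coefficient, the MDD slope adds
    the interaction, and the slope difference is the interaction term
    itself.  Slopes are invariant to centring age.
    """
    df = _merged(features, records, [feature, "age", "sex", "mean_fd"])
    if df["group"].nunique() < 2:
        raise ValueError("both groups must be present for a slope comparison")
    df = _maybe_transform(df, feature, transform)
    res, model_type, _ = _fit_mixed_or_ols(
        df, "y ~ group * age + sex + mean_fd", "site_id")
    df_resid = _residual_df(res, df)
    a, g = "age", "group[T.MDD]:age"
    cov = res.cov_params()
    if not isinstance(cov, pd.DataFrame):
        cov = pd.DataFrame(cov, index=res.params.index, columns=res.params.index)
    slope_hc = float(res.params[a])
    se_hc = float(np.sqrt(cov.loc[a, a]))
    slope_mdd = float(res.params[a] + res.params[g])
    se_mdd = float(np.sqrt(cov.loc[a, a] + cov.loc[g, g] + 2 * cov.loc[a, g]))
    slope_diff = float(res.params[g])
    se_diff = float(np.sqrt(cov.loc[g, g]))

    def tp(b, s):
        t = b / s
        return t, 2.0 * stats.t.sf(abs(t), df_resid)

    t_hc, p_hc = tp(slope_hc, se_hc)
    t_mdd, p_mdd = tp(slope_mdd, se_mdd)
    t_diff, p_diff = tp(slope_diff, se_diff)
    return AgeSlopeResult(
        feature=feature,
        slope_hc=float(slope_hc), se_hc=float(se_hc), t_hc=float(t_hc), p_hc=float(p_hc),
        slope_mdd=float(slope_mdd), se_mdd=float(se_mdd), t_mdd=float(t_mdd), p_mdd=float(p_mdd),
        slope_diff=float(slope_diff), se_diff=float(se_diff), t_diff=float(t_diff),
        p_diff=float(p_diff), df=df_resid, model_type=model_type,
    )


# ---------------------------------------------------------------------------
# edge level


def edge_group_analysis(
    edges: np.ndarray,
    subject_ids: Sequence[str],
    records: pd.DataFrame,
    transform: str = "inverse_normal",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Edge-level group tests with site fixed effects and BH-FDR.

    Every edge is modelled as ``z ~ group + age + sex + mean_fd + site``;
    absorbing site as fixed dummies keeps the per-edge fit a single
    vectorised least-squares solve across the whole P(P-1)/2 family,
    which is what makes full-connectome screens tractable.  Adjusted
    p-values are Benjamini-Hochberg across all edges.
    """
    edges = np.asarray(edges, dtype=float)
    meta = pd.DataFrame({"subject_id": list(subject_ids)}).merge(
        records, on="subject_id", validate="one_to_one")
    if len(meta) != edges.shape[0]:
        raise ValueError("edge matrix rows do not match subject metadata")
    if transform == "inverse_normal":
        y = np.apply_along_axis(inverse_normal_transform, 0, edges)
    else:
        y = edges
    group = (meta["group"].to_numpy() == "MDD").astype(float)
    sex = (meta["sex"].to_numpy() == "M").astype(float)
    site_d = pd.get_dummies(meta["site_id"], drop_first=True).to_numpy(float)
    X = np.column_stack([np.ones(len(meta)), group,
                         meta["age"].to_numpy(float), sex,
                         meta["mean_fd"].to_numpy(float), site_d])
    n, k = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k:
        raise ValueError("rank-deficient design matrix in edge analysis")
    resid = y - X @ beta
    df_resid = n - k
    sigma2 = (resid ** 2).sum(axis=0) / df_resid
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    t = beta[1] / se
    p = 2.0 * stats.t.sf(np.abs(t), df_resid)
    out = pd.DataFrame({
        "edge": np.arange(edges.shape[1]),
        "estimate": beta[1], "se": se, "t": t, "df": float(df_resid),
        "p_raw": p, "p_fdr": fdr_bh(p),
    })
    out["significant"] = out["p_fdr"] < alpha
    return out
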