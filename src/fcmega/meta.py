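"""Two-stage cross-check: per-site estimates pooled by fixed-effect meta-analysis.

The one-stage mixed model (``fcmega.mega``) pools subjects; this module
implements the classical alternative — an ordinary least-squares group
contrast adjusted for age, sex and mean FD *within each site*, followed
by inverse-variance-weighted fixed-effect pooling:

    beta_pooled = sum(b_k / se_k^2) / sum(1 / se_k^2)
    se_pooled   = (sum 1/se_k^2)^(-1/2)

Sites with too few subjects per arm, or a rank-deficient within-site
design, are excluded with a logged reason.  ``mega_meta_concordance``
quantifies how closely the two routes agree feature by feature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mega import bonferroni, inverse_normal_transform

MIN_PER_GROUP_DEFAULT = 10


@dataclass(frozen=True)
class SiteEstimate:
    site_id: str
    feature: str
    beta: float
    se: float
    n_cases: int
    n_controls: int

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError("standard error must be positive")


@dataclass
class MetaResult:
    feature: str
    pooled_beta: float
    pooled_se: float
    z: float
    p: float
    included_sites: list[str]
    weights: dict[str, float]  # normalised inverse-variance weights


def site_estimates(
    features: pd.DataFrame,
    records: pd.DataFrame,
    feature: str,
    min_per_group: int = MIN_PER_GROUP_DEFAULT,
    transform: str = "inverse_normal",
) -> tuple[list[SiteEstimate], list[dict]]:
    """Covariate-adjusted OLS group contrast within each eligible site.

    The feature is inverse normal transformed over the whole analysis
    sample (the same scale the one-stage model uses) before splitting by
    site.  Returns the per-site estimates and a log of excluded sites
    with machine-readable reasons.
    """
    df = records.merge(features[["subject_id", feature]], on="subject_id",
                       validate="one_to_one")
    df = df.dropna(subset=[feature, "age", "sex", "mean_fd"]).copy()
    y_all = df[feature].to_numpy(dtype=float)
    df["y"] = inverse_normal_transform(y_all) if transform == "inverse_normal" else y_all

    estimates: list[SiteEstimate] = []
    excluded: list[dict] = []
    for site, sub in df.groupby("site_id", sort=True):
        n_cases = int((sub["group"] == "MDD").sum())
        n_controls = int((sub["group"] == "HC").sum())
        if min(n_cases, n_controls) < min_per_group:
            excluded.append({"site_id": site, "reason": "too_few_per_group",
                             "n_cases": n_cases, "n_controls": n_controls})
            continue
        X = np.column_stack([
            np.ones(len(sub)),
            (sub["group"] == "MDD").to_numpy(float),
            sub["age"].to_numpy(float),
            (sub["sex"] == "M").to_numpy(float),
            sub["mean_fd"].to_numpy(float),
        ])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            excluded.append({"site_id": site, "reason": "rank_deficient",
                             "n_cases": n_cases, "n_controls": n_controls})
            continue
        yv = sub["y"].to_numpy()
        beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
        resid = yv - X @ beta
        dof = len(sub) - X.shape[1]
        sigma2 = float(resid @ resid) / dof
        se = float(np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1]))
        estimates.append(SiteEstimate(str(site), feature, float(beta[1]), se,
                                      n_cases, n_controls))
    return estimates, excluded


def inverse_variance_pool(estimates: Sequence[SiteEstimate]) -> MetaResult:
    """Fixed-effect inverse-variance pooling of per-site estimates."""
    if len(estimates) < 2:
        raise ValueError("need at least two site estimates to pool")
    feats = {e.feature for e in estimates}
    if len(feats) != 1:
        raise ValueError(f"estimates mix features: {sorted(feats)}")
    betas = np.array([e.beta for e in estimates])
    ses = np.array([e.se for e in estimates])
    if np.any(ses <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / ses ** 2
    pooled_beta = float(np.sum(w * betas) / np.sum(w))
    pooled_se = float(1.0 / np.sqrt(np.sum(w)))
    z = pooled_beta / pooled_se
    p = 2.0 * stats.norm.sf(abs(z))
    wn = w / w.sum()
    return MetaResult(
        feature=feats.pop(), pooled_beta=pooled_beta, pooled_se=pooled_se,
        z=float(z), p=float(p),
        included_sites=[e.site_id for e in estimates],
        weights={e.site_id: float(x) for e, x in zip(estimates, wn)},
    )


def dersimonian_laird_pool(estimates: Sequence[SiteEstimate]) -> MetaResult:
    """Random-effects (DerSimonian-Laird) pooling, for sensitivity only."""
    fixed = inverse_variance_pool(estimates)
    betas = np.array([e.beta for e in estimates])
    ses = np.array([e.se for e in estimates])
    w = 1.0 / ses ** 2
    k = len(estimates)
    q = float(np.sum(w * (betas - fixed.pooled_beta) ** 2))
    c = float(np.sum(w) - np.sum(w ** 2) / np.sum(w))
    tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0
    w_re = 1.0 / (ses ** 2 + tau2)
    pooled = float(np.sum(w_re * betas) / np.sum(w_re))
    se = float(1.0 / np.sqrt(np.sum(w_re)))
    z = pooled / se
    wn = w_re / w_re.sum()
    return MetaResult(
        feature=fixed.feature, pooled_beta=pooled, pooled_se=se, z=float(z),
        p=float(2.0 * stats.norm.sf(abs(z))),
        included_sites=[e.site_id for e in estimates],
        weights={e.site_id: float(x) for e, x in zip(estimates, wn)},
    )


def run_meta(
    features: pd.DataFrame,
    records: pd.DataFrame,
    feature_names: Sequence[str],
    min_per_group: int = MIN_PER_GROUP_DEFAULT,
    transform: str = "inverse_normal",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Two-stage analysis over several features.

    Returns the pooled results table (with the same two seven-member
    Bonferroni families as the one-stage analysis), the per-site
    estimate table (forest-plot data), and the site exclusion log.
    """
    pooled_rows, site_rows, excluded_all = [], [], []
    for feature in feature_names:
        ests, excluded = site_estimates(features, records, feature,
                                        min_per_group, transform)
        for ex in excluded:
            excluded_all.append({"feature": feature, **ex})
        for e in ests:
            site_rows.append({
                "feature": feature, "site_id": e.site_id, "beta": e.beta,
                "se": e.se, "n_cases": e.n_cases, "n_controls": e.n_controls,
            })
        if len(ests) < 2:
            pooled_rows.append({"feature": feature, "pooled_beta": np.nan,
                                "pooled_se": np.nan, "z": np.nan, "p_raw": np.nan,
                                "n_sites": len(ests)})
            continue
        m = inverse_variance_pool(ests)
        pooled_rows.append({"feature": feature, "pooled_beta": m.pooled_beta,
                            "pooled_se": m.pooled_se, "z": m.z, "p_raw": m.p,
                            "n_sites": len(m.included_sites)})
    pooled = pd.DataFrame(pooled_rows)
    pooled["p_corrected"] = np.nan
    for prefix in ("fc_", "seg_"):
        mask = pooled["feature"].str.startswith(prefix) & pooled["p_raw"].notna()
        if mask.any():
            adj, _ = bonferroni(pooled.loc[mask, "p_raw"].to_numpy(), alpha)
            pooled.loc[mask, "p_corrected"] = adj
    return pooled, pd.DataFrame(site_rows), excluded_all


def mega_meta_concordance(
    mega_results: pd.DataFrame,
    meta_results: pd.DataFrame,
    alpha: float = 0.05,
) -> dict:
    """Agreement between one-stage and two-stage group effects.

    Expects a ``feature``/``estimate``/``p_corrected`` mega table and a
    ``feature``/``pooled_beta``/``p_corrected`` meta table over the same
    feature set.  Reports the Pearson correlation of the estimates, the
    fraction of features with matching effect sign, and the overlap of
    the significant sets under the matched corrections.
    """
    mg = mega_results.set_index("feature")
    mt = meta_results.set_index("feature")
    if set(mg.index) != set(mt.index):
        raise ValueError(
            f"feature sets differ: {sorted(set(mg.index) ^ set(mt.index))}")
    mt = mt.loc[mg.index]
    a = mg["estimate"].to_numpy(dtype=float)
    b = mt["pooled_beta"].to_numpy(dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    corr = float(np.corrcoef(a[ok], b[ok])[0, 1]) if ok.sum() > 1 else float("nan")
    sign_agree = float(np.mean(np.sign(a[ok]) == np.sign(b[ok]))) if ok.any() else float("nan")
    sig_mega = set(mg.index[(mg["p_corrected"] < alpha).fillna(False)])
    sig_meta = set(mt.index[(mt["p_corrected"] < alpha).fillna(False)])
    union = sig_mega | sig_meta
    jaccard = float(len(sig_mega & sig_meta) / len(union)) if union else 1.0
    return {
        "n_features": int(ok.sum()),
        "estimate_correlation": corr,
        "sign_agreement": sign_agree,
        "significant_mega": sorted(sig_mega),
        "significant_meta": sorted(sig_meta),
        "significant_overlap_jaccard": jaccard,
    }
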