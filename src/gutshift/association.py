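"""Pairwise-site linear models on top-ranked ASVs, diet PCA, and FDR.

The regression design mirrors a staged-adjustment analysis: per ASV and
site pair, the log10-transformed abundance is regressed on a binary
site indicator in three tiers — (1) unadjusted, (2) adjusted for age,
sex, BMI and hypertension, (3) additionally adjusted for the first two
principal components of macronutrient intake.  The second-listed site
of the pair is coded 1, so a positive beta means higher abundance
further along the migration axis.  q-values are Benjamini-Hochberg
within one (site pair x tier) family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

#: Macronutrient variables entering the diet PCA by default.
DIET_VARIABLES = ["protein", "fat", "carbohydrates", "fibre", "sodium"]

TIER_COVARIATES = {
    1: [],
    2: ["age", "sex", "bmi", "hypertension"],
    3: ["age", "sex", "bmi", "hypertension", "diet_pc1", "diet_pc2"],
}


@dataclass
class DietPcaResult:
    loadings: pd.DataFrame            # variables x [pc1, pc2]
    scores: pd.DataFrame              # samples x [diet_pc1, diet_pc2]
    explained_variance_ratio: np.ndarray


def diet_pca(metadata: pd.DataFrame, variables: list[str] | None = None) -> DietPcaResult:
    """PCA of z-scored macronutrient intake; first two components.

    Sign convention: within each component the largest-magnitude loading
    is made positive, so scores are deterministic across runs.
    """
    variables = list(variables or DIET_VARIABLES)
    missing = [v for v in variables if v not in metadata.columns]
    if missing:
        raise ValueError(f"metadata lacks diet variables: {missing}")
    X = metadata[variables].astype(float)
    if X.isna().any().any():
        X = X.dropna()
    if len(X) < 2:
        raise ValueError("need at least two complete samples for PCA")
    sd = X.std(ddof=1)
    flat = sd[sd == 0].index.tolist()
    if flat:
        raise ValueError(f"zero-variance diet variable(s): {flat}")
    Z = (X - X.mean()) / sd
    u, s, vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    evr = s**2 / (s**2).sum()
    comps = vt[:2]
    for k in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[k]))
        if comps[k, j] < 0:
            comps[k] = -comps[k]
    scores = Z.to_numpy() @ comps.T
    return DietPcaResult(
        loadings=pd.DataFrame(comps.T, index=variables, columns=["pc1", "pc2"]),
        scores=pd.DataFrame(scores, index=X.index, columns=["diet_pc1", "diet_pc2"]),
        explained_variance_ratio=evr[:2],
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order preserved against input."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _check_collinearity(design: pd.DataFrame) -> None:
    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name a minimal set of columns whose removal restores full rank
        dependent = []
        cols = list(design.columns)
        for c in cols:
            sub = design.drop(columns=[c]).to_numpy(dtype=float)
            if np.linalg.matrix_rank(sub) == rank:
                dependent.append(c)
        raise ValueError(f"collinear covariates in design: {dependent or cols}")


def fit_site_models(
    log_abund: pd.DataFrame,
    site_pair: tuple[str, str],
    meta: pd.DataFrame,
    diet_pcs: pd.DataFrame | None = None,
    tiers: tuple[int, ...] = (1, 2, 3),
) -> pd.DataFrame:
    """OLS of log10 abundance on a site indicator, per ASV and tier.

    ``site_pair`` lists the two sites in migration order; the second is
    coded 1.  Rows with missing covariates are dropped per tier
    (complete-case) and counted in the ``n`` column.  Returns a tidy
    frame with beta, SE, p and BH q per (site pair x tier) family.
    """
    a, b = site_pair
    in_pair = meta["site"].astype(str).isin([a, b])
    samples = meta.index[in_pair].intersection(log_abund.index)
    if len(samples) < 3:
        raise ValueError(f"too few samples for site pair {site_pair}")
    meta_pair = meta.loc[samples]
    site_ind = (meta_pair["site"].astype(str) == b).astype(float)

    records = []
    for tier in tiers:
        covars = TIER_COVARIATES[tier]
        cov_frame = pd.DataFrame({"site": site_ind})
        for c in covars:
            if c.startswith("diet_pc"):
                if diet_pcs is None:
                    raise ValueError("tier 3 requires diet principal components")
                cov_frame[c] = diet_pcs.reindex(samples)[c].astype(float)
            else:
                if c not in meta_pair.columns:
                    raise ValueError(f"metadata lacks covariate {c!r}")
                cov_frame[c] = meta_pair[c].astype(float)
        complete = cov_frame.dropna()
        n_dropped = len(cov_frame) - len(complete)
        design = sm.add_constant(complete, has_constant="add")
        _check_collinearity(design)
        for asv in log_abund.columns:
            y = log_abund.loc[complete.index, asv].astype(float)
            fit = sm.OLS(y, design).fit()
            records.append({
                "asv": asv, "site_pair": f"{a}-{b}", "tier": tier,
                "beta": float(fit.params["site"]),
                "se": float(fit.bse["site"]),
                "p": float(fit.pvalues["site"]),
                "n": int(len(complete)), "n_dropped": int(n_dropped),
            })
    out = pd.DataFrame(records)
    out["q"] = np.nan
    for tier in tiers:
        mask = out["tier"] == tier
        out.loc[mask, "q"] = bh_fdr(out.loc[mask, "p"].to_numpy())
    return out
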