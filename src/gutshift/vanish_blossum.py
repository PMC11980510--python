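"""Prevalence-shift predictor selection and vanish/blossum group statistics.

Taxa whose prevalence falls along the rural -> urban -> migration axis
are called *vanish* taxa; taxa whose prevalence rises are *blossum*
taxa (after the VANISH / BLoSSUM acronyms for microbes that disappear
with, or bloom in, industrialized societies).  Candidate taxa come from
the union of the top-k feature rankings of the two pairwise
presence-absence site classifiers; their direction is decided by the
endpoint prevalences (rural vs amsterdam).  Samples are then grouped by
how many vanish taxa they lack (>= ``vanish_min_absent``) and how many
blossum taxa they carry (>= ``blossum_min_present``), and the groups
are compared on cardiometabolic outcomes with Mann-Whitney (continuous)
and chi-square (binary) tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

CONTINUOUS_OUTCOMES = ["age", "bmi", "sbp", "dbp", "egfr", "hba1c"]
BINARY_OUTCOMES = ["diabetes", "hypertension", "hypercholesterolemia", "obesity"]

#: Outcome definitions used when the flag is absent from the metadata.
OBESITY_BMI_CUTOFF = 30.0          # kg/m^2
HYPERCHOL_TC_CUTOFF = 5.0          # mmol/L total cholesterol


def union_top_predictors(ranking_a: pd.DataFrame, ranking_b: pd.DataFrame,
                         k: int = 10) -> list[str]:
    """Deduplicated union of two top-k lists, first-seen order (a first)."""
    for name, r in (("a", ranking_a), ("b", ranking_b)):
        if len(r) < k:
            raise ValueError(f"ranking {name} has only {len(r)} features, need {k}")
    seen: dict[str, None] = {}
    for r in (ranking_a, ranking_b):
        for f in r["feature"].head(k):
            seen.setdefault(f, None)
    return list(seen)


def classify_direction(predictors: list[str], pa: pd.DataFrame,
                       meta: pd.DataFrame) -> pd.DataFrame:
    """Per-site prevalence and vanish/blossum direction for each predictor.

    Direction is decided by the migration-axis endpoints: vanish if
    prevalence(amsterdam) < prevalence(rural), blossum if greater.
    Exact endpoint ties are flagged indeterminate and excluded with a
    warning; the intermediate (urban) prevalence is reported but not
    decisive.
    """
    sites = ("rural", "urban", "amsterdam")
    site_labels = meta.loc[pa.index, "site"].astype(str)
    for s in sites:
        if (site_labels == s).sum() == 0:
            raise ValueError(f"no samples at site {s!r}")
    missing = [p for p in predictors if p not in pa.columns]
    if missing:
        raise ValueError(f"predictors absent from presence-absence matrix: {missing}")
    rows = []
    for asv in predictors:
        prev = {s: float(pa.loc[(site_labels == s).to_numpy(), asv].mean()) for s in sites}
        if prev["amsterdam"] < prev["rural"]:
            direction = "vanish"
        elif prev["amsterdam"] > prev["rural"]:
            direction = "blossum"
        else:
            direction = "indeterminate"
        rows.append({"asv": asv, **{f"prevalence_{s}": prev[s] for s in sites},
                     "direction": direction})
    out = pd.DataFrame(rows)
    ties = out.loc[out["direction"] == "indeterminate", "asv"].tolist()
    if ties:
        warnings.warn(f"excluding direction-indeterminate predictors: {ties}",
                      stacklevel=2)
        out = out[out["direction"] != "indeterminate"].reset_index(drop=True)
    return out


@dataclass
class GroupAssignment:
    vanish: pd.Series       # bool per sample: True = vanish group, False = control
    blossum: pd.Series
    vanish_min_absent: int
    blossum_min_present: int
    vanish_taxa: list[str]
    blossum_taxa: list[str]


def assign_groups(pa: pd.DataFrame, predictors: pd.DataFrame,
                  vanish_min_absent: int = 10,
                  blossum_min_present: int = 4) -> GroupAssignment:
    """Threshold group membership from the presence-absence matrix.

    A sample joins the vanish group iff it lacks at least
    ``vanish_min_absent`` of the vanish taxa, and the blossum group iff
    it carries at least ``blossum_min_present`` of the blossum taxa; the
    two axes are independent and each partitions all samples into group
    vs control.
    """
    vanish_taxa = predictors.loc[predictors["direction"] == "vanish", "asv"].tolist()
    blossum_taxa = predictors.loc[predictors["direction"] == "blossum", "asv"].tolist()
    if vanish_min_absent > len(vanish_taxa):
        raise ValueError(f"vanish_min_absent={vanish_min_absent} exceeds "
                         f"{len(vanish_taxa)} vanish taxa")
    if blossum_min_present > len(blossum_taxa):
        raise ValueError(f"blossum_min_present={blossum_min_present} exceeds "
                         f"{len(blossum_taxa)} blossum taxa")
    missing = [t for t in vanish_taxa + blossum_taxa if t not in pa.columns]
    if missing:
        raise ValueError(f"predictor taxa absent from matrix: {missing}")
    n_absent = (pa[vanish_taxa] == 0).sum(axis=1)
    n_present = (pa[blossum_taxa] > 0).sum(axis=1)
    return GroupAssignment(
        vanish=(n_absent >= vanish_min_absent),
        blossum=(n_present >= blossum_min_present),
        vanish_min_absent=vanish_min_absent,
        blossum_min_present=blossum_min_present,
        vanish_taxa=vanish_taxa,
        blossum_taxa=blossum_taxa,
    )


def _derived_outcomes(meta: pd.DataFrame) -> pd.DataFrame:
    meta = meta.copy()
    if "obesity" not in meta.columns and "bmi" in meta.columns:
        meta["obesity"] = (meta["bmi"] >= OBESITY_BMI_CUTOFF).astype(int)
    if "hypercholesterolemia" not in meta.columns and "total_cholesterol" in meta.columns:
        meta["hypercholesterolemia"] = (
            meta["total_cholesterol"] > HYPERCHOL_TC_CUTOFF).astype(int)
    return meta


def compare_outcomes(groups: GroupAssignment, meta: pd.DataFrame,
                     continuous: list[str] | None = None,
                     binary: list[str] | None = None) -> pd.DataFrame:
    """Group-vs-control tests per outcome variable, for both group axes.

    Continuous variables: two-sided Mann-Whitney U.  Binary variables:
    chi-square on the 2x2 table without continuity correction; if any
    expected cell count is zero, a warning is raised and Fisher's exact
    test is used instead.
    """
    meta = _derived_outcomes(meta)
    continuous = [v for v in (continuous or CONTINUOUS_OUTCOMES) if v in meta.columns]
    binary = [v for v in (binary or BINARY_OUTCOMES) if v in meta.columns]
    rows = []
    for axis_name, membership in (("vanish", groups.vanish), ("blossum", groups.blossum)):
        in_group = membership.reindex(meta.index).fillna(False).astype(bool)
        if in_group.sum() == 0 or (~in_group).sum() == 0:
            raise ValueError(f"{axis_name}: one of group/control is empty")
        for var in continuous:
            x = meta.loc[in_group, var].dropna()
            y = meta.loc[~in_group, var].dropna()
            res = sps.mannwhitneyu(x, y, alternative="two-sided")
            rows.append({"group_axis": axis_name, "variable": var, "test": "mann-whitney",
                         "statistic": float(res.statistic), "p": float(res.pvalue),
                         "group_median": float(x.median()), "control_median": float(y.median()),
                         "n_group": len(x), "n_control": len(y)})
        for var in binary:
            v = meta[var].dropna().astype(int)
            g = in_group.reindex(v.index)
            table = np.array([[int(((g) & (v == 1)).sum()), int((g & (v == 0)).sum())],
                              [int((~g & (v == 1)).sum()), int((~g & (v == 0)).sum())]])
            expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
            if (expected == 0).any():
                warnings.warn(f"zero expected cell for {var}; using Fisher's exact test",
                              stacklevel=2)
                stat, p = sps.fisher_exact(table)
                test = "fisher-exact"
            else:
                stat, p, _, _ = sps.chi2_contingency(table, correction=False)
                test = "chi-square"
            rows.append({"group_axis": axis_name, "variable": var, "test": test,
                         "statistic": float(stat), "p": float(p),
                         "group_median": float(table[0, 0] / table[0].sum()),
                         "control_median": float(table[1, 0] / table[1].sum()),
                         "n_group": int(table[0].sum()), "n_control": int(table[1].sum())})
    out = pd.DataFrame(rows)
    out["significant"] = out["p"] < 0.05
    return out
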