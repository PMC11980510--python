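"""Pipeline driver: exclusion -> rarefaction -> diversity -> ML ->
regressions -> vanish/blossum, with tab-separated report writers.

Every stage writes its tables under the output directory and a manifest
records seeds, parameter values and exclusion bookkeeping, so a re-run
with the same configuration and seed reproduces the reports byte for
byte.  Any stage error aborts with a stage-named message and the
manifest flags the run incomplete.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import DIET_VARIABLES, diet_pca, fit_site_models
from .diversity import alpha_diversity, pairwise_group_tests, permanova, weighted_unifrac_matrix
from .io import read_count_table, read_metadata, read_tree
from .ml import SMALL_GRID, MlConfig, run_permuted_control, run_prediction
from .preprocess import (exclude_samples, filter_abundance_asvs, filter_prevalence_asvs,
                         log10_abundance, rarefy, to_presence_absence)
from .synthetic import CohortConfig, generate_cohort
from .vanish_blossum import (assign_groups, classify_direction, compare_outcomes,
                             union_top_predictors)

logger = logging.getLogger(__name__)

STAGES = ("preprocess", "diversity", "predict", "associate", "vanish-blossum")

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-loadable)."""

    simulate: dict | None = None        # CohortConfig keyword overrides
    inputs: dict | None = None          # paths: counts, tree, metadata[, taxonomy]
    depth: int = 2000
    min_count: int = 10
    min_frac: float = 0.30
    min_prev: float = 0.10
    site_pairs: list[tuple[str, str]] = field(
        default_factory=lambda: [("rural", "urban"), ("urban", "amsterdam")])
    ml: dict = field(default_factory=lambda: {
        "n_iterations": 10, "hyperparameter_grid": dict(SMALL_GRID)})
    top_k: int = 10
    vanish_min_absent: int = 10
    blossum_min_present: int = 4
    diet_variables: list[str] = field(default_factory=lambda: list(DIET_VARIABLES))
    n_permutations: int = 999
    seed: int = 0
    threads: int = 1

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("exactly one of 'simulate' / 'inputs' must be given")
        self.site_pairs = [tuple(p) for p in self.site_pairs]

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        doc.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**doc)


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index=index)


def _seed_ints(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def run_pipeline(config: RunConfig, out_dir, through: str = "vanish-blossum") -> dict:
    """Run stages up to and including ``through``; return the report bundle."""
    if through not in STAGES:
        raise ValueError(f"unknown stage {through!r}; choose from {STAGES}")
    last = STAGES.index(through)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"gutshift_version": __version__, "seed": config.seed,
                      "depth": config.depth, "stages": [], "complete": False,
                      "parameters": {
                          "min_count": config.min_count, "min_frac": config.min_frac,
                          "min_prev": config.min_prev, "top_k": config.top_k,
                          "vanish_min_absent": config.vanish_min_absent,
                          "blossum_min_present": config.blossum_min_present,
                          "site_pairs": [list(p) for p in config.site_pairs],
                          "n_permutations": config.n_permutations}}
    bundle: dict = {}
    (rarefy_seed, perm_seed, *ml_seeds) = _seed_ints(config.seed, 2 + 4 * len(config.site_pairs))
    stage = "load"
    try:
        # ---- load / simulate --------------------------------------------
        if config.simulate is not None:
            cohort = generate_cohort(CohortConfig(**{**config.simulate, "seed": config.seed}))
            counts, tree, meta = cohort.counts, cohort.tree, cohort.metadata
            bundle["truth"] = cohort.truth
        else:
            counts = read_count_table(config.inputs["counts"])
            tree = read_tree(config.inputs["tree"])
            meta = read_metadata(config.inputs["metadata"])

        # ---- preprocess --------------------------------------------------
        stage = "preprocess"
        kept = exclude_samples(counts, meta, config.depth)
        manifest["exclusions"] = kept.attrs["exclusions"]
        rarefied = rarefy(kept, config.depth, seed=rarefy_seed)
        meta = meta.loc[rarefied.index]
        abund = filter_abundance_asvs(rarefied, config.min_count, config.min_frac)
        logab = log10_abundance(abund)
        pa = filter_prevalence_asvs(to_presence_absence(rarefied), config.min_prev)
        bundle.update(rarefied=rarefied, metadata=meta, log_abundance=logab,
                      presence_absence=pa)
        _write(rarefied, out / "counts_rarefied.tsv")
        _write(logab, out / "abundance_log10.tsv")
        _write(pa, out / "presence_absence.tsv")
        manifest["stages"].append(stage)

        # ---- diversity ----------------------------------------------------
        if last >= STAGES.index("diversity"):
            stage = "diversity"
            alpha = alpha_diversity(rarefied, tree)
            alpha["site"] = meta["site"].astype(str)
            tests = []
            for metric in ("shannon", "richness", "faith_pd"):
                t = pairwise_group_tests(alpha[metric], alpha["site"])
                t.insert(0, "metric", metric)
                tests.append(t)
            alpha_tests = pd.concat(tests, ignore_index=True)
            dist = weighted_unifrac_matrix(rarefied, tree)
            perm = permanova(dist, meta["site"].astype(str),
                             n_permutations=config.n_permutations, seed=perm_seed)
            perm_df = pd.DataFrame([{"pseudo_f": perm.pseudo_f, "r_squared": perm.r_squared,
                                     "p_value": perm.p_value,
                                     "n_permutations": perm.n_permutations}])
            bundle.update(alpha=alpha, alpha_tests=alpha_tests, unifrac=dist,
                          permanova=perm_df)
            _write(alpha, out / "diversity_alpha.tsv")
            _write(alpha_tests, out / "diversity_alpha_tests.tsv", index=False)
            _write(dist, out / "beta_unifrac.tsv")
            _write(perm_df, out / "permanova.tsv", index=False)
            manifest["stages"].append(stage)

        # ---- predict ------------------------------------------------------
        if last >= STAGES.index("predict"):
            stage = "predict"
            metrics_rows, rankings = [], {}
            seed_iter = iter(ml_seeds)
            for pair in config.site_pairs:
                pair_mask = meta["site"].astype(str).isin(pair)
                y = (meta.loc[pair_mask, "site"].astype(str) == pair[1]).astype(int)
                for route, feats in (("abundance", logab), ("prevalence", pa)):
                    X = feats.loc[pair_mask.to_numpy()]
                    cfg = MlConfig(task="classification", seed=next(seed_iter),
                                   n_jobs=config.threads, **config.ml)
                    summary = run_prediction(X, y, cfg)
                    cfg_perm = MlConfig(task="classification", seed=next(seed_iter),
                                        n_jobs=config.threads, **config.ml)
                    control = run_permuted_control(X, y, cfg_perm)
                    key = f"{pair[0]}-{pair[1]}_{route}"
                    rankings[key] = summary.ranking
                    metrics_rows.append({
                        "site_pair": f"{pair[0]}-{pair[1]}", "route": route,
                        "metric": summary.metric_name,
                        "mean": summary.metric_mean, "sd": summary.metric_sd,
                        "permuted_mean": control.metric_mean,
                        "n_iterations": cfg.n_iterations,
                        "n_redraws": summary.n_redraws})
                    _write(summary.ranking, out / f"ml_ranking_{key}.tsv", index=False)
            ml_metrics = pd.DataFrame(metrics_rows)
            bundle.update(ml_metrics=ml_metrics, rankings=rankings)
            _write(ml_metrics, out / "ml_metrics.tsv", index=False)
            manifest["stages"].append(stage)

        # ---- associate ----------------------------------------------------
        if last >= STAGES.index("associate"):
            stage = "associate"
            pca = diet_pca(meta, config.diet_variables)
            regs = []
            for pair in config.site_pairs:
                key = f"{pair[0]}-{pair[1]}_abundance"
                top = rankings[key]["feature"].head(config.top_k).tolist()
                regs.append(fit_site_models(logab[top], pair, meta, pca.scores))
            regressions = pd.concat(regs, ignore_index=True)
            bundle.update(diet_pca=pca, regressions=regressions)
            _write(pca.scores, out / "diet_pca_scores.tsv")
            _write(pca.loadings, out / "diet_pca_loadings.tsv")
            _write(regressions, out / "regressions.tsv", index=False)
            manifest["stages"].append(stage)

        # ---- vanish / blossum --------------------------------------------
        if last >= STAGES.index("vanish-blossum"):
            stage = "vanish-blossum"
            pa_rankings = [rankings[f"{p[0]}-{p[1]}_prevalence"] for p in config.site_pairs[:2]]
            union = union_top_predictors(pa_rankings[0], pa_rankings[1], k=config.top_k)
            predictors = classify_direction(union, pa, meta)
            groups = assign_groups(pa, predictors,
                                   vanish_min_absent=config.vanish_min_absent,
                                   blossum_min_present=config.blossum_min_present)
            outcomes = compare_outcomes(groups, meta)
            groups_df = pd.DataFrame({
                "vanish": groups.vanish.astype(int),
                "blossum": groups.blossum.astype(int)})
            bundle.update(predictors=predictors, groups=groups, outcomes=outcomes)
            _write(predictors, out / "predictors.tsv", index=False)
            _write(groups_df, out / "groups.tsv")
            _write(outcomes, out / "outcome_comparisons.tsv", index=False)
            manifest["group_sizes"] = {
                "vanish": int(groups.vanish.sum()),
                "vanish_control": int((~groups.vanish).sum()),
                "blossum": int(groups.blossum.sum()),
                "blossum_control": int((~groups.blossum).sum())}
            manifest["stages"].append(stage)

        manifest["complete"] = True
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    bundle["manifest"] = manifest
    return bundle
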