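"""Synthetic three-site cohort generator with a documented planted truth.

The generator emulates a gut-microbiota cohort observed at three sites
along an urbanization/migration axis (rural < urban < amsterdam):

* **Composition model** — each taxon has a log-normal expected relative
  abundance; a per-sample, per-taxon log-normal noise term supplies the
  overdispersion (heteroskedasticity and zero inflation) typical of 16S
  count tables; observed counts are one multinomial draw per sample at
  a sequencing depth at or above the rarefaction depth.
* **Gradient taxa** — a configurable number of taxa shift monotonically
  by ``effect_size`` log-units per site step, with alternating sign.
* **Vanish / blossum taxa** — planted prevalence-shift taxa whose
  per-sample presence is Bernoulli at a per-site target prevalence
  (declining along the axis for vanish taxa, rising for blossum taxa);
  an absent taxon contributes zero expected abundance.
* **Covariates** — age, sex, BMI, blood pressure, HbA1c, eGFR,
  macronutrient intakes and disease flags drawn per site with means and
  spreads realistic for a West-African rural/urban/European migration
  cohort; selected diet covariates (protein, sodium) are linked to
  specific gradient taxa so that diet mediates part of the site effect.

Everything is reproducible: one global seed feeds an explicit
per-component seed sequence (tree, metadata, counts), and the planted
truth — taxon roles, effect sizes, expected log10 abundance shifts per
site pair, prevalence targets — is returned alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io import SITE_ORDER, write_count_table, write_metadata, write_tree

LOG_NOISE_SD = 0.6          # per-sample per-taxon log-normal overdispersion
BACKGROUND_MU_SD = 1.5      # spread of background log relative abundances
GRADIENT_MU_MEAN = 2.0      # planted gradient taxa sit well above zero counts
GRADIENT_MU_SD = 0.3
PLANTED_PREV_MU_MEAN = 1.0  # abundance level of vanish/blossum taxa when present
PLANTED_PREV_MU_SD = 0.3


# ---------------------------------------------------------------------------
# tree


def generate_tree(n_taxa: int, seed: int) -> TreeNode:
    """Random rooted, fully bifurcating tree with exponential branch lengths.

    Leaves are labelled ``ASV_0001 .. ASV_n``; topology is built by
    random sequential joins and is bit-reproducible given the seed.
    """
    if n_taxa < 2:
        raise ValueError(f"need at least 2 taxa, got {n_taxa}")
    rng = np.random.default_rng(seed)
    nodes = []
    for i in range(n_taxa):
        leaf = TreeNode(name=f"ASV_{i + 1:04d}")
        leaf.length = float(rng.exponential(0.1)) + 1e-6
        nodes.append(leaf)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode()
        parent.length = float(rng.exponential(0.1)) + 1e-6
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent.extend([left, right])
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class CovariateSpec:
    """One metadata covariate: per-site location, spread and taxon links."""

    site_means: tuple[float, float, float]   # rural, urban, amsterdam
    sd: float = 0.0
    kind: str = "normal"                     # normal | bernoulli | lognormal
    linked_taxa: tuple[int, ...] = ()        # indices into the gradient taxa
    link_strength: float = 0.0               # log-units per SD of the covariate


def default_covariates() -> dict[str, CovariateSpec]:
    """Site-wise covariate distributions for the default synthetic cohort."""
    return {
        "age": CovariateSpec((54.4, 52.6, 53.6), 11.0),
        "sex": CovariateSpec((0.616, 0.709, 0.601), kind="bernoulli"),  # 1 = female
        "bmi": CovariateSpec((23.0, 28.3, 29.2), 5.0),
        "sbp": CovariateSpec((131.9, 131.9, 133.3), 21.0),
        "dbp": CovariateSpec((77.4, 78.7, 81.8), 12.0),
        "total_cholesterol": CovariateSpec((4.3, 5.1, 5.1), 1.2),
        "hba1c": CovariateSpec((33.2, 41.9, 40.0), 12.0),
        "egfr": CovariateSpec((94.0, 91.9, 84.4), 16.0),
        "calories": CovariateSpec((2461.0, 2256.0, 2678.0), 850.0),
        "carbohydrates": CovariateSpec((364.0, 306.0, 321.0), 125.0),
        "protein": CovariateSpec((68.2, 75.6, 96.8), 27.0,
                                 linked_taxa=(0, 2), link_strength=0.25),
        "fat": CovariateSpec((80.0, 80.3, 103.0), 38.0),
        "fibre": CovariateSpec((40.1, 36.1, 40.5), 13.0),
        "sodium": CovariateSpec((2.2, 3.3, 2.9), 1.0,
                                linked_taxa=(4, 6), link_strength=0.25),
        "physical_activity": CovariateSpec((3500.0, 6440.0, 1920.0), 0.9,
                                           kind="lognormal"),
        "hypertension": CovariateSpec((0.363, 0.470, 0.626), kind="bernoulli"),
        "diabetes": CovariateSpec((0.066, 0.117, 0.165), kind="bernoulli"),
        "antibiotic": CovariateSpec((0.0, 0.0, 0.0), kind="bernoulli"),
    }


@dataclass
class CohortConfig:
    """Study conditions of one synthetic cohort."""

    n_per_site: tuple[int, int, int] = (474, 460, 243)
    n_taxa: int = 120
    rarefaction_depth: int = 2000
    n_gradient_taxa: int = 10
    n_vanish_taxa: int = 5
    n_blossum_taxa: int = 4
    effect_size: float = 1.0   # ln-units per site step
    vanish_prevalence: tuple[float, float, float] = (0.9, 0.5, 0.1)
    blossum_prevalence: tuple[float, float, float] = (0.1, 0.5, 0.9)
    prevalence_profiles: dict[str, tuple[float, float, float]] | None = None
    covariate_effects: dict[str, CovariateSpec] = field(default_factory=default_covariates)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_site):
            raise ValueError("n_per_site entries must be >= 0")
        for n in (self.n_taxa, self.rarefaction_depth):
            if n <= 0:
                raise ValueError("n_taxa and rarefaction_depth must be positive")
        for n in (self.n_gradient_taxa, self.n_vanish_taxa, self.n_blossum_taxa):
            if n < 0:
                raise ValueError("planted taxon counts must be >= 0")
        if self.n_gradient_taxa + self.n_vanish_taxa + self.n_blossum_taxa > self.n_taxa:
            raise ValueError("planted taxa exceed n_taxa")
        for prof in (self.vanish_prevalence, self.blossum_prevalence):
            if any(not (0 <= p <= 1) for p in prof):
                raise ValueError("prevalence targets must lie in [0, 1]")
        if self.prevalence_profiles:
            for asv, prof in self.prevalence_profiles.items():
                if len(prof) != 3 or any(not (0 <= p <= 1) for p in prof):
                    raise ValueError(f"bad prevalence profile for {asv}")


@dataclass
class PlantedTruth:
    """What the generator planted, for recovery tests."""

    gradient: pd.DataFrame            # asv, sign, effect_size
    expected_log10_shift: pd.DataFrame  # asv, site_pair, delta
    vanish: pd.DataFrame              # asv + per-site prevalence targets
    blossum: pd.DataFrame
    linked_covariates: dict[str, list[str]]


@dataclass
class SyntheticCohort:
    counts: pd.DataFrame
    tree: TreeNode
    taxonomy: pd.DataFrame
    metadata: pd.DataFrame
    truth: PlantedTruth
    config: CohortConfig

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_count_table(self.counts, outdir / "counts.tsv")
        write_count_table(self.counts, outdir / "counts.biom.json", format="biom-json")
        write_tree(self.tree, outdir / "tree.nwk")
        self.taxonomy.to_csv(outdir / "taxonomy.tsv", sep="\t")
        write_metadata(self.metadata, outdir / "metadata.tsv")
        self.truth.gradient.to_csv(outdir / "truth_gradient.tsv", sep="\t", index=False)
        self.truth.vanish.to_csv(outdir / "truth_vanish.tsv", sep="\t", index=False)
        self.truth.blossum.to_csv(outdir / "truth_blossum.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# generation


def _synthetic_taxonomy(asv_ids: list[str]) -> pd.DataFrame:
    """Deterministic ranked lineage (synthetic labels, not real taxa)."""
    rows = []
    for j, asv in enumerate(asv_ids):
        rows.append({
            "kingdom": "Bacteria",
            "phylum": f"Phylum_{j % 6 + 1:02d}",
            "class": f"Class_{j % 9 + 1:02d}",
            "order": f"Order_{j % 12 + 1:02d}",
            "family": f"Family_{j % 17 + 1:02d}",
            "genus": f"Genus_{j % 40 + 1:02d}",
        })
    out = pd.DataFrame(rows, index=asv_ids)
    out.index.name = "asv_id"
    return out


def _draw_covariate(spec: CovariateSpec, site_idx: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    means = np.asarray(spec.site_means)[site_idx]
    if spec.kind == "bernoulli":
        return (rng.uniform(size=len(site_idx)) < means).astype(int)
    if spec.kind == "lognormal":
        return means * np.exp(spec.sd * rng.standard_normal(len(site_idx)))
    return means + spec.sd * rng.standard_normal(len(site_idx))


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Draw one synthetic cohort; bit-identical for identical config+seed."""
    config = config or CohortConfig()
    ss = np.random.SeedSequence(config.seed)
    tree_ss, meta_ss, counts_ss = ss.spawn(3)
    tree_seed = int(tree_ss.generate_state(1)[0] % (2**31))
    tree = generate_tree(config.n_taxa, tree_seed)
    asv_ids = [f"ASV_{i + 1:04d}" for i in range(config.n_taxa)]

    # -- sites and metadata ------------------------------------------------
    n_total = sum(config.n_per_site)
    site_idx = np.repeat([0, 1, 2], config.n_per_site)
    sample_ids = [f"S{i + 1:05d}" for i in range(n_total)]
    rng_meta = np.random.default_rng(meta_ss)
    meta = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    meta["site"] = pd.Categorical(np.asarray(SITE_ORDER)[site_idx],
                                  categories=SITE_ORDER, ordered=True)
    for name, spec in config.covariate_effects.items():
        meta[name] = _draw_covariate(spec, site_idx, rng_meta)

    # -- planted roles -----------------------------------------------------
    g, v, b = config.n_gradient_taxa, config.n_vanish_taxa, config.n_blossum_taxa
    gradient_ids = asv_ids[:g]
    vanish_ids = asv_ids[g:g + v]
    blossum_ids = asv_ids[g + v:g + v + b]
    signs = np.array([1 if j % 2 == 0 else -1 for j in range(g)])

    profiles: dict[str, tuple[float, float, float]] = {}
    for asv in vanish_ids:
        profiles[asv] = config.vanish_prevalence
    for asv in blossum_ids:
        profiles[asv] = config.blossum_prevalence
    if config.prevalence_profiles:
        unknown = set(config.prevalence_profiles) - set(vanish_ids) - set(blossum_ids)
        if unknown:
            raise ValueError(f"prevalence profile for non-planted taxa: {sorted(unknown)}")
        profiles.update(config.prevalence_profiles)

    # -- expected log relative abundances per site -------------------------
    rng_counts = np.random.default_rng(counts_ss)
    mu = rng_counts.normal(0.0, BACKGROUND_MU_SD, size=config.n_taxa)
    mu[:g] = rng_counts.normal(GRADIENT_MU_MEAN, GRADIENT_MU_SD, size=g)
    mu[g:g + v + b] = rng_counts.normal(PLANTED_PREV_MU_MEAN, PLANTED_PREV_MU_SD,
                                        size=v + b)
    mu_site = np.tile(mu, (3, 1))                      # sites x taxa
    for jj, sign in enumerate(signs):
        mu_site[:, jj] += sign * config.effect_size * np.arange(3)

    # diet-taxon links: covariate z-score adds to linked gradient taxa
    linked: dict[str, list[str]] = {}
    link_z = np.zeros((n_total, config.n_taxa))
    extra_var = np.zeros(config.n_taxa)                # link-induced variance
    mean_shift = np.zeros((3, config.n_taxa))          # link-induced site shift
    for name, spec in config.covariate_effects.items():
        if not spec.linked_taxa or spec.link_strength == 0.0:
            continue
        taxa = [gradient_ids[t] for t in spec.linked_taxa if t < g]
        if not taxa:
            continue
        linked[name] = taxa
        center = float(np.mean(spec.site_means))
        scale = spec.sd if spec.sd > 0 else 1.0
        z = (meta[name].to_numpy(dtype=float) - center) / scale
        for asv in taxa:
            jj = asv_ids.index(asv)
            link_z[:, jj] += spec.link_strength * z
            extra_var[jj] += spec.link_strength**2
            for s in range(3):
                mean_shift[s, jj] += spec.link_strength * (
                    (spec.site_means[s] - center) / scale)
    mu_site = mu_site + mean_shift

    # -- presence draws for planted prevalence taxa ------------------------
    presence = np.ones((n_total, config.n_taxa), dtype=bool)
    for asv, prof in profiles.items():
        jj = asv_ids.index(asv)
        p = np.asarray(prof)[site_idx]
        presence[:, jj] = rng_counts.uniform(size=n_total) < p

    # -- counts ------------------------------------------------------------
    depth = config.rarefaction_depth
    totals = rng_counts.integers(depth, 2 * depth + 1, size=n_total)
    # link_z already carries the site-mean part of each linked covariate, so
    # the deterministic mean_shift is removed from mu_site here to avoid
    # double counting; mu_site keeps it for the expected-shift bookkeeping.
    eta = ((mu_site - mean_shift)[site_idx]
           + link_z
           + rng_counts.normal(0.0, LOG_NOISE_SD, size=(n_total, config.n_taxa)))
    w = np.exp(eta)
    w[~presence] = 0.0
    counts = np.empty((n_total, config.n_taxa), dtype=np.int64)
    for i in range(n_total):
        p = w[i] / w[i].sum()
        counts[i] = rng_counts.multinomial(totals[i], p)
    counts_df = pd.DataFrame(counts, index=meta.index, columns=asv_ids)

    # -- planted truth -----------------------------------------------------
    sigma2 = LOG_NOISE_SD**2 + extra_var               # per-taxon total log-noise var
    ew_site = np.exp(mu_site + sigma2[None, :] / 2.0)  # E[w] per site x taxon
    for asv, prof in profiles.items():
        jj = asv_ids.index(asv)
        ew_site[:, jj] *= np.asarray(prof)
    z_norm = ew_site.sum(axis=1)
    pairs = [("rural", "urban", 0, 1), ("urban", "amsterdam", 1, 2),
             ("rural", "amsterdam", 0, 2)]
    shift_rows = []
    for asv in gradient_ids:
        jj = asv_ids.index(asv)
        exp_log10 = [
            _expected_log10_rarefied(mu_site[s, jj], sigma2[jj], z_norm[s], depth)
            for s in range(3)
        ]
        for a, bname, s1, s2 in pairs:
            shift_rows.append({"asv": asv, "site_pair": f"{a}-{bname}",
                               "delta_log10": exp_log10[s2] - exp_log10[s1]})
    truth = PlantedTruth(
        gradient=pd.DataFrame({"asv": gradient_ids, "sign": signs,
                               "effect_size": config.effect_size}),
        expected_log10_shift=pd.DataFrame(shift_rows),
        vanish=pd.DataFrame([{"asv": a, "prev_rural": profiles[a][0],
                              "prev_urban": profiles[a][1],
                              "prev_amsterdam": profiles[a][2]} for a in vanish_ids]),
        blossum=pd.DataFrame([{"asv": a, "prev_rural": profiles[a][0],
                               "prev_urban": profiles[a][1],
                               "prev_amsterdam": profiles[a][2]} for a in blossum_ids]),
        linked_covariates=linked,
    )
    return SyntheticCohort(counts=counts_df, tree=tree,
                           taxonomy=_synthetic_taxonomy(asv_ids),
                           metadata=meta, truth=truth, config=config)


def _expected_log10_poisson(lam: float) -> float:
    """E[log10(N + 1)] for N ~ Poisson(lam), exact sum / Taylor tail."""
    if lam > 400.0:
        # second-order Taylor of log10(x+1) around lam
        return float(np.log10(lam + 1.0) - lam / (2.0 * (lam + 1.0) ** 2 * np.log(10.0)))
    k_max = int(lam + 12.0 * np.sqrt(lam) + 25.0)
    k = np.arange(k_max + 1)
    log_pmf = k * np.log(lam) - lam - _LOG_FACTORIALS[k]
    return float(np.exp(log_pmf) @ np.log10(k + 1.0))


_LOG_FACTORIALS = np.concatenate([[0.0], np.cumsum(np.log(np.arange(1, 800)))])

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(41)


def _expected_log10_rarefied(mu: float, sigma2: float, z_norm: float,
                             depth: int) -> float:
    """Model expectation of log10(count + 1) after rarefaction to ``depth``.

    The taxon's relative abundance is e^(mu + eps)/Z with eps ~ N(0, sigma2)
    and Z approximated by its expectation; the rarefied count is Poisson at
    depth * relative abundance.  Integrated by Gauss-Hermite quadrature, so
    the planted truth lives on exactly the scale the regressions analyse.
    """
    sigma = np.sqrt(sigma2)
    vals = np.array([
        _expected_log10_poisson(depth * np.exp(mu + sigma * np.sqrt(2.0) * x) / z_norm)
        for x in _GH_NODES
    ])
    return float((_GH_WEIGHTS @ vals) / np.sqrt(np.pi))


# ---------------------------------------------------------------------------
# exclusion fixture


def generate_exclusion_fixture(
    n_total: int, n_low_count: int, n_antibiotic: int, depth: int, seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count table + metadata with planted exclusion reasons (disjoint).

    Exactly ``n_low_count`` samples total below ``depth`` and
    ``n_antibiotic`` other samples flagged antibiotic-positive; all
    remaining samples are clean with totals at or above depth.
    """
    if n_low_count + n_antibiotic > n_total:
        raise ValueError("overlapping exclusion sets requested: "
                         f"{n_low_count}+{n_antibiotic} > {n_total}")
    rng = np.random.default_rng(seed)
    n_taxa = 20
    asv_ids = [f"ASV_{i + 1:04d}" for i in range(n_taxa)]
    sample_ids = [f"S{i + 1:05d}" for i in range(n_total)]
    totals = rng.integers(depth, 2 * depth + 1, size=n_total)
    low = rng.choice(n_total, size=n_low_count + n_antibiotic, replace=False)
    low_idx, anti_idx = low[:n_low_count], low[n_low_count:]
    totals[low_idx] = rng.integers(max(1, depth // 10), depth, size=n_low_count)
    p = rng.dirichlet(np.ones(n_taxa))
    counts = np.vstack([rng.multinomial(t, p) for t in totals])
    table = pd.DataFrame(counts, index=pd.Index(sample_ids, name="sample_id"),
                         columns=asv_ids)
    meta = pd.DataFrame(index=table.index)
    meta["site"] = pd.Categorical(
        np.asarray(SITE_ORDER)[np.arange(n_total) % 3],
        categories=SITE_ORDER, ordered=True)
    anti = np.zeros(n_total, dtype=int)
    anti[anti_idx] = 1
    meta["antibiotic"] = anti
    return table, meta
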