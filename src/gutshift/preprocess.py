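"""Sample/taxon filters and transformations applied ahead of all analyses.

The canonical order, enforced by the pipeline driver, is
exclude -> rarefy -> abundance filter (abundance route) or
exclude -> rarefy -> presence/absence -> prevalence filter (prevalence
route).  All threshold comparisons are boundary-inclusive and fractional
thresholds use ceil(n * frac).
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd

from .io import validate_count_table

logger = logging.getLogger(__name__)


def exclude_samples(
    table: pd.DataFrame, meta: pd.DataFrame, depth: int
) -> pd.DataFrame:
    """Drop samples with total counts below ``depth`` or with antibiotic use.

    A sample failing both criteria is counted once, under low-count (the
    first-listed reason).  The removal bookkeeping is attached to the
    returned table as ``table.attrs["exclusions"]`` and logged.
    """
    missing = table.index.difference(meta.index)
    if len(missing):
        raise ValueError(f"metadata missing for samples: {missing.tolist()[:10]}")
    if "antibiotic" not in meta.columns:
        raise ValueError("metadata lacks an 'antibiotic' column")
    anti = meta.loc[table.index, "antibiotic"]
    if anti.isna().any():
        bad = table.index[anti.isna().to_numpy()].tolist()
        raise ValueError(f"antibiotic flag missing for samples: {bad[:10]}")
    totals = table.sum(axis=1)
    low = totals < depth
    antibiotic = anti.astype(bool).to_numpy() & ~low.to_numpy()
    keep = ~(low.to_numpy() | antibiotic)
    n_low = int(low.sum())
    n_anti = int(antibiotic.sum())
    logger.info(
        "exclude_samples: removed %d low-count (<%d) and %d antibiotic samples; %d retained",
        n_low, depth, n_anti, int(keep.sum()),
    )
    if keep.sum() == 0:
        warnings.warn("exclude_samples removed every sample", stacklevel=2)
    out = table.loc[keep].copy()
    out.attrs["exclusions"] = {
        "low_count": n_low,
        "antibiotic": n_anti,
        "retained": int(keep.sum()),
        "depth": int(depth),
    }
    return out


def rarefy(table: pd.DataFrame, depth: int, seed: int) -> pd.DataFrame:
    """Subsample every sample to ``depth`` counts without replacement.

    Each sample's counts are treated as a multiset of reads and ``depth``
    reads are drawn without replacement (one multivariate hypergeometric
    draw per sample), so every returned row sums exactly to ``depth`` and
    a taxon absent before rarefaction stays absent.  Samples below depth
    raise; run :func:`exclude_samples` first.
    """
    table = validate_count_table(table)
    totals = table.sum(axis=1)
    short = totals[totals < depth]
    if len(short):
        raise ValueError(
            f"{len(short)} sample(s) below rarefaction depth {depth}: "
            f"{short.index.tolist()[:10]}"
        )
    rng = np.random.default_rng(seed)
    values = table.to_numpy()
    out = np.empty_like(values)
    for i in range(values.shape[0]):
        if totals.iloc[i] == depth:
            out[i] = values[i]
        else:
            out[i] = rng.multivariate_hypergeometric(values[i], depth)
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def filter_abundance_asvs(
    table: pd.DataFrame, min_count: int = 10, min_frac: float = 0.30
) -> pd.DataFrame:
    """Keep ASVs with >= min_count counts in >= ceil(min_frac * n) samples."""
    if not (0 < min_frac <= 1):
        raise ValueError(f"min_frac must be in (0, 1], got {min_frac}")
    n_required = math.ceil(min_frac * len(table))
    keep = (table >= min_count).sum(axis=0) >= n_required
    return table.loc[:, keep].copy()


def to_presence_absence(table: pd.DataFrame) -> pd.DataFrame:
    """Binary matrix: 1 iff the count is greater than zero."""
    return (table > 0).astype(np.int64)


def filter_prevalence_asvs(pa: pd.DataFrame, min_prev: float = 0.10) -> pd.DataFrame:
    """Keep ASVs present in >= ceil(min_prev * n) samples (inclusive)."""
    if not (0 < min_prev <= 1):
        raise ValueError(f"min_prev must be in (0, 1], got {min_prev}")
    n_required = math.ceil(min_prev * len(pa))
    keep = (pa > 0).sum(axis=0) >= n_required
    return pa.loc[:, keep].copy()


def log10_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """log10(count + 1); zeros map to zero and order is preserved."""
    if (table.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    return np.log10(table.astype(float) + 1.0)
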