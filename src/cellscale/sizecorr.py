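"""Per-feature size-correlation statistics.

For every transcript or metabolite the engine computes the Pearson
correlation r between abundance and relative nuclear radius over all
samples, a two-sided p-value from the t statistic
``r * sqrt((n - 2) / (1 - r^2))`` on ``n - 2`` degrees of freedom, a
Fisher-z confidence interval (90% by default), a Benjamini-Hochberg
adjusted p, the log2 fold change between the largest- and smallest-cell
groups, and the feature's mean abundance.

Correlation is computed on abundances as provided (linear scale) by
default; an opt-in log2 transform is available.  Features with zero
abundance variance have undefined r and are excluded from the adjustment.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    CORRELATION_COLUMNS,
    FeatureMatrix,
    SampleTable,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Reported instead of 0 when |r| = 1, keeping log-scale summaries finite.
MIN_P = np.nextafter(0.0, 1.0)


def normalize_radius(
    samples: SampleTable, reference: Tuple[str, str] = ("control", "pre")
) -> SampleTable:
    """Divide every relative radius by the reference group's mean radius.

    After normalization the reference group mean is exactly 1; the
    operation is idempotent.
    """
    genotype, timepoint = reference
    df = samples.data
    mask = (df["genotype"] == genotype) & (df["timepoint"] == timepoint)
    if not mask.any():
        raise ValidationError(f"reference group {reference!r} has no samples")
    ref_mean = df.loc[mask, "relative_radius"].mean()
    return samples.with_radii(samples.radii / ref_mean)


def correlate_features(
    matrix: FeatureMatrix,
    samples: SampleTable,
    ci_level: float = 0.90,
    log2_transform: bool = False,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Pearson correlation of each feature's abundance with relative radius.

    Returns a DataFrame with columns ``feature_id, r, ci_low, ci_high, p,
    mean_abundance``.  Zero-variance features get NaN r/CI/p.  The CI uses
    the Fisher z transform (requires n >= 4; NaN otherwise).
    """
    if not (0.0 < ci_level < 1.0):
        raise ValidationError(f"ci_level must be in (0, 1), got {ci_level}")
    mat = matrix.align(samples)
    n = len(samples)
    if n < 3:
        raise ValidationError(f"need >= 3 samples to correlate, got {n}")
    x = samples.radii
    values = mat.values
    y = np.log2(values + pseudocount) if log2_transform else values

    xc = x - x.mean()
    sx = math.sqrt(float(xc @ xc))
    if sx == 0.0:
        raise ValidationError("all samples share one radius; correlation undefined")
    yc = y - y.mean(axis=1, keepdims=True)
    sy = np.sqrt((yc**2).sum(axis=1))
    # zero variance up to float cancellation: mean subtraction of a constant
    # row can leave a ~1-ulp residue, so compare against the row magnitude
    scale = np.sqrt((y**2).sum(axis=1))
    defined = sy > scale * 1e-12
    if not defined.any():
        raise ValidationError("every feature has zero variance across samples")

    r = np.full(len(sy), np.nan)
    r[defined] = np.clip((yc[defined] @ xc) / (sy[defined] * sx), -1.0, 1.0)

    p = np.full_like(r, np.nan)
    perfect = defined & (np.abs(r) >= 1.0)
    regular = defined & ~perfect
    with np.errstate(divide="ignore"):
        t = r[regular] * np.sqrt((n - 2) / (1.0 - r[regular] ** 2))
    p[regular] = np.maximum(2.0 * stats.t.sf(np.abs(t), df=n - 2), MIN_P)
    p[perfect] = MIN_P

    ci_low = np.full_like(r, np.nan)
    ci_high = np.full_like(r, np.nan)
    if n >= 4:
        half = stats.norm.ppf(0.5 + ci_level / 2.0) / math.sqrt(n - 3)
        z = np.arctanh(np.clip(r[regular], -1 + 1e-15, 1 - 1e-15))
        ci_low[regular] = np.tanh(z - half)
        ci_high[regular] = np.tanh(z + half)
        ci_low[perfect] = r[perfect]
        ci_high[perfect] = r[perfect]
    else:
        logger.warning("n = 3: Fisher-z interval undefined, CIs reported as NaN")

    n_dropped = int((~defined).sum())
    if n_dropped:
        logger.info("correlate_features: %d zero-variance features flagged", n_dropped)
    return pd.DataFrame(
        {
            "feature_id": mat.feature_ids,
            "r": r,
            "ci_low": ci_low,
            "ci_high": ci_high,
            "p": p,
            "mean_abundance": values.mean(axis=1),
        }
    )


def adjust_pvalues(p: Iterable[float], method: str = "BH") -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, capped at 1."""
    if method != "BH":
        raise ValidationError(f"unknown adjustment method {method!r}")
    arr = np.asarray(list(p), dtype=float)
    if arr.size and (np.any(~np.isfinite(arr)) or np.any(arr <= 0) or np.any(arr > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    if arr.size == 0:
        return arr
    return multipletests(arr, method="fdr_bh")[1]


def size_fold_change(
    matrix: FeatureMatrix, samples: SampleTable, pseudocount: float = 1.0
) -> pd.Series:
    """log2 fold change of group-mean abundance, largest vs smallest cells.

    Group means of the relative radius pick the largest- and smallest-cell
    (genotype, timepoint) groups; a tie is an error and calls for explicit
    group selection upstream.
    """
    mat = matrix.align(samples)
    means = samples.group_means()
    if (means == means.max()).sum() > 1 or (means == means.min()).sum() > 1:
        raise ValidationError(
            "tie for the largest or smallest group mean radius; subset the "
            "sample table to the intended groups explicitly"
        )
    largest = means.idxmax()
    smallest = means.idxmin()
    df = mat.to_frame()
    m_large = df[samples.samples_in_group(*largest)].mean(axis=1)
    m_small = df[samples.samples_in_group(*smallest)].mean(axis=1)
    with np.errstate(divide="ignore"):
        fc = np.log2(m_large + pseudocount) - np.log2(m_small + pseudocount)
    fc.name = "log2_fc_size"
    return fc


def correlation_density(
    r_values: Iterable[float], bin_width: float = 0.1
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Histogram of correlation values over [-1, 1] plus their median.

    Bins are left-closed/right-open with a closed terminal bin, so r = 1 is
    counted exactly once.  NaN values (undefined r) are ignored; an empty
    defined set is an error.
    """
    if bin_width <= 0 or bin_width > 2:
        raise ValidationError(f"bin_width must be in (0, 2], got {bin_width}")
    arr = np.asarray(list(r_values), dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValidationError("no defined correlation values")
    n_bins = max(1, round(2.0 / bin_width))
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(arr, bins=edges)
    return edges, counts, float(np.median(arr))


def abundance_stratified_summary(
    table: pd.DataFrame, n_strata: int = 5
) -> pd.DataFrame:
    """Mean r and mean log2 size fold change per abundance stratum.

    Features are ranked by ``mean_abundance`` (ties broken stably by table
    order) and split into ``n_strata`` quantile strata; stratum 1 holds the
    least abundant features.
    """
    if n_strata < 1:
        raise ValidationError("n_strata must be >= 1")
    required = {"mean_abundance", "r", "log2_fc_size"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"summary needs columns {sorted(missing)}")
    t = table.loc[np.isfinite(table["mean_abundance"])].reset_index(drop=True)
    if len(t) < n_strata:
        raise ValidationError(
            f"only {len(t)} features with defined abundance for {n_strata} strata"
        )
    order = np.argsort(t["mean_abundance"].to_numpy(), kind="stable")
    chunks = np.array_split(order, n_strata)
    rows = []
    for i, idx in enumerate(chunks, start=1):
        sub = t.iloc[idx]
        rows.append(
            {
                "stratum": i,
                "n": len(sub),
                "abundance_low": float(sub["mean_abundance"].min()),
                "abundance_high": float(sub["mean_abundance"].max()),
                "mean_r": float(np.nanmean(sub["r"].to_numpy(float))),
                "mean_log2_fc": float(np.nanmean(sub["log2_fc_size"].to_numpy(float))),
            }
        )
    return pd.DataFrame(rows)


def build_correlation_table(
    matrix: FeatureMatrix,
    samples: SampleTable,
    ci_level: float = 0.90,
    log2_transform: bool = False,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Assemble the full per-feature table: r/CI/p + BH-adjusted p + size
    fold change + mean abundance, in the canonical column order."""
    tab = correlate_features(
        matrix,
        samples,
        ci_level=ci_level,
        log2_transform=log2_transform,
        pseudocount=pseudocount if log2_transform else 0.0,
    )
    p_adj = np.full(len(tab), np.nan)
    defined = np.isfinite(tab["p"].to_numpy(float))
    if defined.any():
        p_adj[defined] = adjust_pvalues(tab.loc[defined, "p"])
    tab["p_adj"] = p_adj
    fc = size_fold_change(matrix, samples, pseudocount=pseudocount)
    tab["log2_fc_size"] = tab["feature_id"].map(fc).astype(float)
    return tab.loc[:, CORRELATION_COLUMNS]
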