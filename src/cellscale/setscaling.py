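"""Gene-set level scaling summaries.

A *scaling profile* bins a gene set's per-feature statistic (size
correlation by default, or a per-gene log2 fold change for two-condition
designs) and overlays the whole-background histogram rescaled to the set's
measured size, so shapes are directly comparable.  Set-vs-background shifts
are tested with the two-sample Kolmogorov-Smirnov statistic.

The same machinery serves subcellular components, transcription-factor
families, and (via :func:`lipid_class_summary`) metabolite lipid classes.
"""

from __future__ import annotations

import logging
import math
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    GeneSetCollection,
    ScalingProfile,
    ValidationError,
)
from .sizecorr import adjust_pvalues

logger = logging.getLogger(__name__)

#: Both samples at or below this size use the exact two-sample KS p-value.
KS_EXACT_MAX_N = 25


def ks_compare(
    set_values: Iterable[float], background_values: Iterable[float]
) -> Tuple[float, float]:
    """Two-sample two-sided KS test: D = sup |ECDF_A - ECDF_B| and its p.

    Uses the exact small-sample p when both samples have <= 25 values, the
    asymptotic formula otherwise.  p is clipped into (0, 1].
    """
    a = np.asarray(list(set_values), dtype=float)
    b = np.asarray(list(background_values), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("ks_compare requires two non-empty samples")
    method = "exact" if (a.size <= KS_EXACT_MAX_N and b.size <= KS_EXACT_MAX_N) else "asymp"
    res = stats.ks_2samp(a, b, alternative="two-sided", method=method)
    p = min(1.0, max(float(res.pvalue), float(np.nextafter(0.0, 1.0))))
    return float(res.statistic), p


def _bin_edges(
    values: np.ndarray, bin_width: float, statistic_mode: str
) -> np.ndarray:
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    if statistic_mode == "correlation":
        n_bins = max(1, round(2.0 / bin_width))
        return np.linspace(-1.0, 1.0, n_bins + 1)
    # log2fc values are unbounded: tile a symmetric range covering the data
    m = float(np.max(np.abs(values))) if values.size else bin_width
    half = max(1, math.ceil(m / bin_width + 1e-9))
    return np.linspace(-half * bin_width, half * bin_width, 2 * half + 1)


def set_scaling_profile(
    stat_table: pd.DataFrame,
    sets: GeneSetCollection,
    background: str = "annotated_union",
    bin_width: float = 0.1,
    statistic_mode: str = "correlation",
    min_set_size: int = 2,
    exclude_set_from_background: bool = False,
    set_names: Optional[Sequence[str]] = None,
) -> List[ScalingProfile]:
    """Build a scaling profile per gene set.

    ``stat_table`` must carry ``feature_id`` plus the statistic column
    (``r`` for correlation mode, ``log2_fc_size`` for log2fc mode).  The
    background is the union of all annotated measured features
    (``annotated_union``) or every measured feature (``all_features``);
    its histogram is rescaled by set size / background size so that the
    normalized background counts sum to the set's measured size.  Sets with
    fewer than ``min_set_size`` measured members are skipped with a logged
    warning.  KS p-values are BH-adjusted across the returned profiles.
    """
    if statistic_mode not in ("correlation", "log2fc"):
        raise ValidationError(f"unknown statistic_mode {statistic_mode!r}")
    if background not in ("annotated_union", "all_features"):
        raise ValidationError(f"unknown background {background!r}")
    col = "r" if statistic_mode == "correlation" else "log2_fc_size"
    if col not in stat_table.columns:
        raise ValidationError(f"statistic table lacks column {col!r}")
    values = pd.Series(
        stat_table[col].to_numpy(dtype=float),
        index=stat_table["feature_id"].astype(str),
    )
    values = values[np.isfinite(values.to_numpy())]
    measured = set(values.index)

    names = list(set_names) if set_names is not None else sets.names()
    if background == "annotated_union":
        annotated: set = set()
        for name in names:
            annotated |= set(sets.sets[name])
        bg_features = sorted(annotated & measured)
    else:
        bg_features = sorted(measured)
    if not bg_features:
        raise ValidationError("empty background: no annotated feature was measured")
    bg_values = values.loc[bg_features].to_numpy()

    edges = _bin_edges(
        np.concatenate([bg_values, values.to_numpy()]), bin_width, statistic_mode
    )
    profiles: List[ScalingProfile] = []
    for name in names:
        members = sorted(set(sets.sets[name]) & measured)
        if len(members) < min_set_size:
            logger.warning(
                "set %r skipped: %d measured members (< %d)",
                name,
                len(members),
                min_set_size,
            )
            continue
        vals = values.loc[members].to_numpy()
        if exclude_set_from_background:
            bg_here = values.loc[sorted(set(bg_features) - set(members))].to_numpy()
            if bg_here.size == 0:
                raise ValidationError(
                    f"background is empty after excluding set {name!r}"
                )
        else:
            bg_here = bg_values
        set_counts, _ = np.histogram(vals, bins=edges)
        bg_counts, _ = np.histogram(bg_here, bins=edges)
        scale = len(vals) / len(bg_here)
        D, p = ks_compare(vals, bg_here)
        profiles.append(
            ScalingProfile(
                set_name=name,
                n_members_measured=len(vals),
                median_stat=float(np.median(vals)),
                bin_edges=edges,
                set_counts=set_counts,
                background_counts_normalized=bg_counts * scale,
                ks_D=D,
                ks_p=p,
                statistic_mode=statistic_mode,
            )
        )
    if profiles:
        adj = adjust_pvalues([pr.ks_p for pr in profiles])
        for pr, a in zip(profiles, adj):
            pr.ks_p_adj = float(a)
    return profiles


def profiles_long_frame(profiles: Sequence[ScalingProfile]) -> pd.DataFrame:
    """Long-format bins table: set, bin_left, bin_right, set_count,
    background_normalized."""
    rows = []
    for pr in profiles:
        for left, right, c, b in zip(
            pr.bin_edges[:-1],
            pr.bin_edges[1:],
            pr.set_counts,
            pr.background_counts_normalized,
        ):
            rows.append(
                {
                    "set": pr.set_name,
                    "bin_left": float(left),
                    "bin_right": float(right),
                    "set_count": int(c),
                    "background_normalized": float(b),
                }
            )
    return pd.DataFrame(
        rows, columns=["set", "bin_left", "bin_right", "set_count", "background_normalized"]
    )


def profiles_summary_frame(profiles: Sequence[ScalingProfile]) -> pd.DataFrame:
    """Per-set summary: n, median statistic, KS D, raw and adjusted KS p."""
    return pd.DataFrame(
        [
            {
                "set": pr.set_name,
                "n": pr.n_members_measured,
                "median": pr.median_stat,
                "ks_D": pr.ks_D,
                "ks_p": pr.ks_p,
                "ks_p_adj": pr.ks_p_adj,
                "statistic_mode": pr.statistic_mode,
            }
            for pr in profiles
        ],
        columns=["set", "n", "median", "ks_D", "ks_p", "ks_p_adj", "statistic_mode"],
    )


def lipid_class_summary(
    stat_table: pd.DataFrame,
    class_map: Dict[str, str],
    min_class_size: int = 5,
) -> pd.DataFrame:
    """Median size correlation and mean log2 fold change per lipid class.

    Only classes with at least ``min_class_size`` measured members are
    reported (the default keeps classes with more than four metabolites).
    Rows are sorted by median r, best-correlating class first.
    """
    t = stat_table.loc[:, ["feature_id", "r", "log2_fc_size"]].copy()
    t["lipid_class"] = t["feature_id"].map(class_map)
    t = t[t["lipid_class"].notna() & np.isfinite(t["r"].to_numpy(float))]
    rows = []
    for name, sub in t.groupby("lipid_class", sort=True):
        if len(sub) < min_class_size:
            continue
        rows.append(
            {
                "lipid_class": name,
                "n": len(sub),
                "median_r": float(np.median(sub["r"])),
                "mean_log2_fc": float(np.nanmean(sub["log2_fc_size"].to_numpy(float))),
            }
        )
    if not rows:
        logger.warning("no lipid class passed the size filter (>= %d)", min_class_size)
        return pd.DataFrame(columns=["lipid_class", "n", "median_r", "mean_log2_fc"])
    out = pd.DataFrame(rows).sort_values(
        ["median_r", "lipid_class"], ascending=[False, True]
    )
    return out.reset_index(drop=True)


def surface_volume_expectation(relative_radii: Iterable[float]) -> np.ndarray:
    """Expected relative surface-area-to-volume ratio per sample.

    For a cell scaling isometrically with radius r, surface grows as r^2
    and volume as r^3, so membrane demand per unit volume falls as 1/r
    (normalized to 1 at the reference radius 1).
    """
    r = np.asarray(list(relative_radii), dtype=float)
    if r.size == 0 or np.any(~np.isfinite(r)) or np.any(r <= 0):
        raise ValidationError("relative radii must be positive and finite")
    return 1.0 / r
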