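"""Disentangling genotype (Cdk1-deletion) effects from cell-size effects.

Genotype-responsive genes are screened with a per-feature Welch two-sample
t-test on log2 abundance between genotypes at a chosen timepoint (default:
before hepatectomy, which isolates the deletion response from the
regeneration/size program), BH-adjusted, with an effect-size gate.  The
overlap of that set with the size-correlated sets quantifies how much of
the size signature is attributable to the deletion itself.

With 2-3 replicates per group this is a screening statistic, not an
inferential claim; thresholds are configurable and echoed in the output.
"""

from __future__ import annotations

import logging
import math
from typing import FrozenSet, Iterable, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    FeatureMatrix,
    OverlapResult,
    SampleTable,
    ValidationError,
)
from .sizecorr import MIN_P, adjust_pvalues

logger = logging.getLogger(__name__)

DEFAULT_FC_THRESHOLD = math.log2(1.5)


def genotype_effect_genes(
    matrix: FeatureMatrix,
    samples: SampleTable,
    timepoint: str = "pre",
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
) -> Tuple[FrozenSet[str], pd.DataFrame]:
    """Features differing between genotypes at a timepoint.

    Returns the selected feature set (Welch adjusted p < alpha and
    |log2 FC| >= fc_threshold, knockout vs control) plus the full
    per-feature statistics table.  ``timepoint`` may be ``pre``, ``post``
    or ``both`` (pool both timepoints).
    """
    if timepoint not in ("pre", "post", "both"):
        raise ValidationError(f"timepoint must be pre|post|both, got {timepoint!r}")
    if not (0.0 < alpha <= 1.0):
        raise ValidationError(f"alpha must be in (0, 1], got {alpha}")
    mat = matrix.align(samples)
    df = samples.data
    tp_mask = np.ones(len(df), dtype=bool) if timepoint == "both" else (
        df["timepoint"] == timepoint
    ).to_numpy()
    ko = tp_mask & (df["genotype"] == "knockout").to_numpy()
    ctrl = tp_mask & (df["genotype"] == "control").to_numpy()
    if ko.sum() < 2 or ctrl.sum() < 2:
        raise ValidationError(
            f"need >= 2 replicates per genotype at timepoint {timepoint!r} "
            f"(got knockout={int(ko.sum())}, control={int(ctrl.sum())})"
        )
    y = np.log2(mat.values + pseudocount)
    a, b = y[:, ko], y[:, ctrl]
    log2_fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # zero variance in both groups: identical means are a non-effect,
    # differing means an (effectively noiseless) extreme effect
    degenerate = ~np.isfinite(p)
    p[degenerate & (np.abs(log2_fc) > 0)] = MIN_P
    p[degenerate & (log2_fc == 0)] = 1.0
    p = np.clip(p, MIN_P, 1.0)
    p_adj = adjust_pvalues(p)
    selected = (p_adj < alpha) & (np.abs(log2_fc) >= fc_threshold)
    table = pd.DataFrame(
        {
            "feature_id": mat.feature_ids,
            "log2_fc_genotype": log2_fc,
            "p": p,
            "p_adj": p_adj,
            "selected": selected,
        }
    )
    logger.info(
        "genotype contrast (%s): %d of %d features selected",
        timepoint,
        int(selected.sum()),
        len(table),
    )
    return frozenset(table.loc[selected, "feature_id"]), table


def overlap_stats(
    set_a: Iterable[str],
    set_b: Iterable[str],
    name_a: str = "A",
    name_b: str = "B",
) -> OverlapResult:
    """Intersection size and the percentage of set B that it covers.

    ``n_shared`` is symmetric in the arguments; ``pct_of_b`` is not — it is
    always reported relative to set B.
    """
    a, b = set(set_a), set(set_b)
    if not b:
        raise ValidationError("set B is empty; percentage of B is undefined")
    n_shared = len(a & b)
    pct = 100.0 * n_shared / len(b)
    return OverlapResult(
        set_a=name_a,
        size_a=len(a),
        set_b=name_b,
        size_b=len(b),
        n_shared=n_shared,
        pct_of_b=pct,
        pct_of_b_rounded=int(round(pct)),
    )
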