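"""Core data containers and validation for the cell-size scaling pipeline.

The study design is a 2x2 layout: genotype (``control``, a Cdk1-floxed
liver, vs ``knockout``, a liver-specific Cdk1 deletion whose hepatocytes
regenerate by hypertrophy) crossed with timepoint (``pre`` vs ``post``
partial hepatectomy).  Each sample carries a *relative nuclear radius* —
the per-sample proxy for cell size, expressed relative to the mean of the
control/pre reference group.

All tabular data ride on :class:`pandas.DataFrame`; interaction networks
are :class:`networkx.Graph` objects.  The dataclasses here add the
domain-specific invariants and convenience accessors the pipeline relies
on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

GENOTYPES = ("control", "knockout")
TIMEPOINTS = ("pre", "post")
#: Canonical group order: reference group first, largest cells last.
GROUP_ORDER: Tuple[Tuple[str, str], ...] = (
    ("control", "pre"),
    ("control", "post"),
    ("knockout", "pre"),
    ("knockout", "post"),
)

SAMPLE_COLUMNS = ["sample_id", "genotype", "timepoint", "replicate", "relative_radius"]

CORRELATION_COLUMNS = [
    "feature_id",
    "r",
    "ci_low",
    "ci_high",
    "p",
    "p_adj",
    "log2_fc_size",
    "mean_abundance",
]

SET_CATEGORIES = (
    "subcellular_component",
    "transcription_factor_family",
    "lipid_class",
    "other",
)


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


@dataclass
class SampleTable:
    """Per-sample design: genotype, timepoint, replicate and relative radius.

    ``data`` has columns ``sample_id, genotype, timepoint, replicate,
    relative_radius``.  Radii are unitless, positive, and interpreted as
    relative to the control/pre group mean (which need not be exactly 1
    until :func:`cellscale.sizecorr.normalize_radius` is applied).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"sample table is missing columns: {missing}")
        df = df.loc[:, SAMPLE_COLUMNS].reset_index(drop=True)
        dup = df["sample_id"][df["sample_id"].duplicated()].tolist()
        if dup:
            raise ValidationError(f"duplicate sample_id values: {sorted(set(dup))}")
        bad_g = sorted(set(df["genotype"]) - set(GENOTYPES))
        if bad_g:
            raise ValidationError(f"unknown genotype values: {bad_g}")
        bad_t = sorted(set(df["timepoint"]) - set(TIMEPOINTS))
        if bad_t:
            raise ValidationError(f"unknown timepoint values: {bad_t}")
        radii = pd.to_numeric(df["relative_radius"], errors="coerce")
        bad = df.index[~np.isfinite(radii) | (radii <= 0)]
        if len(bad):
            row = int(bad[0])
            raise ValidationError(
                f"non-positive or non-numeric relative_radius in row {row} "
                f"(sample_id={df.at[row, 'sample_id']!r})"
            )
        reps = pd.to_numeric(df["replicate"], errors="coerce")
        if (~np.isfinite(reps) | (reps < 1)).any():
            raise ValidationError("replicate must be a positive integer")
        df = df.assign(relative_radius=radii.astype(float), replicate=reps.astype(int))
        if df["relative_radius"].nunique() < 2:
            raise ValidationError(
                "all samples share one relative_radius; a size gradient needs "
                "at least two distinct values"
            )
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    @property
    def sample_ids(self) -> List[str]:
        return self.data["sample_id"].tolist()

    @property
    def radii(self) -> np.ndarray:
        return self.data["relative_radius"].to_numpy(dtype=float)

    def group_means(self) -> pd.Series:
        """Mean relative radius per (genotype, timepoint) group."""
        return self.data.groupby(["genotype", "timepoint"], sort=True)[
            "relative_radius"
        ].mean()

    def samples_in_group(self, genotype: str, timepoint: str) -> List[str]:
        df = self.data
        mask = (df["genotype"] == genotype) & (df["timepoint"] == timepoint)
        return df.loc[mask, "sample_id"].tolist()

    def with_radii(self, radii: np.ndarray) -> "SampleTable":
        return SampleTable(self.data.assign(relative_radius=np.asarray(radii, float)))


@dataclass
class FeatureMatrix:
    """Features x samples abundance grid (normalized expression or ion
    intensity, arbitrary units, non-negative)."""

    feature_ids: List[str]
    sample_ids: List[str]
    values: np.ndarray
    kind: str  # "gene" | "metabolite"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"value grid shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if self.kind not in ("gene", "metabolite"):
            raise ValidationError(f"unknown feature kind {self.kind!r}")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            counts = pd.Series(self.feature_ids).value_counts()
            dups = counts.index[counts > 1].tolist()[:5]
            raise ValidationError(f"duplicate feature_ids in matrix, e.g. {dups}")
        if not np.isfinite(self.values).all():
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at (feature={self.feature_ids[i]}, "
                f"sample={self.sample_ids[j]})"
            )
        if (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative abundance at (feature={self.feature_ids[i]}, "
                f"sample={self.sample_ids[j]})"
            )

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def align(self, samples: SampleTable) -> "FeatureMatrix":
        """Reorder columns to match a sample table; error on any mismatch."""
        want, have = samples.sample_ids, self.sample_ids
        if set(want) != set(have):
            only_samples = sorted(set(want) - set(have))
            only_matrix = sorted(set(have) - set(want))
            raise ValidationError(
                "matrix columns do not match the sample table; "
                f"only in sample table: {only_samples}; only in matrix: {only_matrix}"
            )
        if want == have:
            return self
        order = [have.index(s) for s in want]
        return FeatureMatrix(list(self.feature_ids), list(want), self.values[:, order], self.kind)


@dataclass
class GeneSetCollection:
    """Named feature-id sets with an optional category per set."""

    sets: Dict[str, FrozenSet[str]]
    categories: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            self.sets[name] = frozenset(members)
        for name, cat in self.categories.items():
            if cat not in SET_CATEGORIES:
                raise ValidationError(f"unknown set category {cat!r} for {name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> List[str]:
        return list(self.sets)

    def by_category(self, category: str) -> Dict[str, FrozenSet[str]]:
        return {
            n: s
            for n, s in self.sets.items()
            if self.categories.get(n, "other") == category
        }

    def all_members(self) -> FrozenSet[str]:
        out: set = set()
        for members in self.sets.values():
            out |= members
        return frozenset(out)


@dataclass
class ScalingProfile:
    """Binned distribution of a per-feature statistic for one gene set,
    with a size-normalized background histogram and a two-sample KS
    comparison of set vs background values."""

    set_name: str
    n_members_measured: int
    median_stat: float
    bin_edges: np.ndarray
    set_counts: np.ndarray
    background_counts_normalized: np.ndarray
    ks_D: float
    ks_p: float
    statistic_mode: str  # "correlation" | "log2fc"
    ks_p_adj: float = math.nan

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.set_counts = np.asarray(self.set_counts, dtype=int)
        self.background_counts_normalized = np.asarray(
            self.background_counts_normalized, dtype=float
        )
        if int(self.set_counts.sum()) != self.n_members_measured:
            raise ValidationError(
                f"profile for {self.set_name!r}: bin counts sum to "
                f"{int(self.set_counts.sum())}, expected {self.n_members_measured}"
            )
        if not (0.0 <= self.ks_D <= 1.0):
            raise ValidationError(f"ks_D out of [0, 1]: {self.ks_D}")


@dataclass
class ConnectivityResult:
    """Observed induced-edge connectivity of a gene set vs a random-set null.

    ``edges_per_gene`` is the induced-subgraph edge count divided by the
    set size (genes missing from the network stay in the denominator).
    """

    gene_set: str
    set_size: int
    observed_edges: int
    observed_edges_per_gene: float
    null_mean_edges_per_gene: float
    null_sd_edges_per_gene: float
    enrichment_ratio: float
    empirical_p: float
    n_iterations: int
    seed: Optional[int]
    exhaustive: bool = False
    null_values: Optional[np.ndarray] = None

    def as_row(self) -> pd.DataFrame:
        d = {
            k: getattr(self, k)
            for k in (
                "gene_set",
                "set_size",
                "observed_edges",
                "observed_edges_per_gene",
                "null_mean_edges_per_gene",
                "null_sd_edges_per_gene",
                "enrichment_ratio",
                "empirical_p",
                "n_iterations",
                "seed",
                "exhaustive",
            )
        }
        return pd.DataFrame([d])


@dataclass
class OverlapResult:
    """Intersection of two feature sets, with the share of set B covered."""

    set_a: str
    size_a: int
    set_b: str
    size_b: int
    n_shared: int
    pct_of_b: float
    pct_of_b_rounded: int

    def as_row(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def validate_correlation_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check SizeCorrelationTable invariants and return the canonical column
    order.  Missing r (NaN) is allowed only alongside missing CI/p."""
    missing = [c for c in CORRELATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"correlation table is missing columns: {missing}")
    t = table.loc[:, CORRELATION_COLUMNS].reset_index(drop=True)
    r = t["r"].to_numpy(float)
    ok = np.isfinite(r)
    if np.any(np.abs(r[ok]) > 1 + 1e-12):
        raise ValidationError("correlation r outside [-1, 1]")
    lo, hi = t["ci_low"].to_numpy(float), t["ci_high"].to_numpy(float)
    band = ok & np.isfinite(lo) & np.isfinite(hi)
    if np.any(lo[band] > r[band] + 1e-9) or np.any(hi[band] < r[band] - 1e-9):
        raise ValidationError("confidence band does not bracket r")
    p, padj = t["p"].to_numpy(float), t["p_adj"].to_numpy(float)
    both = np.isfinite(p) & np.isfinite(padj)
    if np.any(padj[both] < p[both] - 1e-12):
        raise ValidationError("adjusted p below raw p")
    return t
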