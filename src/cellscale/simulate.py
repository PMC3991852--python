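"""Synthetic multi-omics data with planted size-scaling structure.

The generator emulates the in-vivo study design: four nearly isogenic
sample groups (control and Cdk1-knockout livers, before and after partial
hepatectomy) whose mean relative nuclear radii span roughly 1 to 2.5 —
knockout hepatocytes regenerate by hypertrophy, so the knockout/post group
carries the largest cells.

Signal model (per feature)::

    log2(abundance) = baseline + slope * relative_radius + Normal(0, noise_sd)

Features fall in three scaling classes: ``positive`` (cytoskeleton-like,
slope > 0), ``negative`` (mitochondria-like, slope < 0) and ``null``
(slope 0).  Class baselines differ so that abundance strata exist: the
negative class sits among the most abundant features and the positive class
among the least abundant, mirroring the observation that size-coupled
upregulation is carried by many lowly expressed genes while abundant genes
are on average slightly repressed.

A subset of null-class genes additionally carries a genotype-specific
shift, applied in knockout samples before hepatectomy only: a deletion
response that the regeneration program overrides post-hepatectomy.  This
keeps genotype effects statistically separable from the size gradient.

One global seed drives independent named substreams (design, gene matrix,
metabolite matrix, annotations, lipid classes, network), so each artifact
can be regenerated on its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import (
    GROUP_ORDER,
    FeatureMatrix,
    GeneSetCollection,
    SampleTable,
    ValidationError,
)

#: Substream indices; combined with the user seed via SeedSequence.
_STREAMS = {
    "design": 11,
    "gene_matrix": 23,
    "metabolite_matrix": 37,
    "annotations": 51,
    "lipid_classes": 67,
    "network": 83,
}

#: Default mean relative radii for (control/pre, control/post, knockout/pre,
#: knockout/post).  Control cells barely change after hepatectomy; knockout
#: post-hepatectomy nuclei are 2-3x larger than control, 2.5 is used here.
DEFAULT_GROUP_RADII = (1.0, 1.05, 1.3, 2.5)

#: Class baselines on the log2-abundance scale (see module docstring).
DEFAULT_BASELINE_LOG2 = {"positive": 4.0, "negative": 8.0, "null": 6.0}

SCALING_CLASSES = ("positive", "negative", "null")


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


@dataclass
class SyntheticTruth:
    """Planted ground truth for one generated feature matrix.

    ``features`` columns: feature_id, scaling_class, true_slope,
    baseline_log2, genotype_shift (log2 shift applied in knockout/pre).
    """

    features: pd.DataFrame
    kind: str
    noise_sd: float
    seed: int

    def ids_of_class(self, scaling_class: str) -> List[str]:
        f = self.features
        return f.loc[f["scaling_class"] == scaling_class, "feature_id"].tolist()

    def genotype_shifted_ids(self) -> List[str]:
        f = self.features
        return f.loc[f["genotype_shift"] != 0.0, "feature_id"].tolist()


def generate_design(
    n_replicates: int = 3,
    group_radii: Sequence[float] = DEFAULT_GROUP_RADII,
    radius_cv: float = 0.05,
    seed: int = 0,
) -> SampleTable:
    """Generate the 2x2 design with per-sample relative radii.

    Radii are drawn lognormally around each group mean with coefficient of
    variation ``radius_cv`` and renormalized so the control/pre group mean
    is exactly 1.  ``radius_cv = 0`` reproduces the group means exactly.
    """
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    group_radii = tuple(float(g) for g in group_radii)
    if len(group_radii) != 4 or any(g <= 0 for g in group_radii):
        raise ValidationError("group_radii must be 4 positive values")
    if radius_cv < 0:
        raise ValidationError("radius_cv must be >= 0")
    rng = _rng(seed, "design")
    rows = []
    for (genotype, timepoint), mean_radius in zip(GROUP_ORDER, group_radii):
        for rep in range(1, n_replicates + 1):
            if radius_cv == 0:
                radius = mean_radius
            else:
                sigma = math.sqrt(math.log1p(radius_cv**2))
                mu = math.log(mean_radius) - sigma**2 / 2
                radius = float(rng.lognormal(mean=mu, sigma=sigma))
            rows.append(
                {
                    "sample_id": f"{genotype}_{timepoint}_{rep}",
                    "genotype": genotype,
                    "timepoint": timepoint,
                    "replicate": rep,
                    "relative_radius": radius,
                }
            )
    df = pd.DataFrame(rows)
    ref = (df["genotype"] == "control") & (df["timepoint"] == "pre")
    df["relative_radius"] = df["relative_radius"] / df.loc[ref, "relative_radius"].mean()
    return SampleTable(df)


def generate_matrix(
    design: SampleTable,
    n_positive: int = 300,
    n_negative: int = 120,
    n_null: int = 580,
    slope_positive: float = 1.0,
    slope_negative: float = -1.0,
    noise_sd: float = 0.25,
    baseline_log2: Optional[Mapping[str, float]] = None,
    baseline_log2_sd: float = 2.0,
    n_genotype_shifted: int = 40,
    genotype_log2fc: float = 2.5,
    kind: str = "gene",
    prefix: Optional[str] = None,
    seed: int = 0,
) -> Tuple[FeatureMatrix, SyntheticTruth]:
    """Generate an abundance matrix plus its planted truth.

    Genotype-shifted features are drawn from the null class (their slope
    stays 0) and shifted by ``genotype_log2fc`` in knockout/pre samples
    only; see the module docstring for the rationale.
    """
    if len(design) < 2:
        raise ValidationError("design must have at least 2 samples")
    if min(n_positive, n_negative, n_null) < 0:
        raise ValidationError("class counts must be >= 0")
    if n_genotype_shifted > n_null:
        raise ValidationError(
            f"n_genotype_shifted ({n_genotype_shifted}) exceeds the null-class "
            f"count ({n_null})"
        )
    baselines = dict(DEFAULT_BASELINE_LOG2 if baseline_log2 is None else baseline_log2)
    prefix = prefix or ("gene" if kind == "gene" else "met")
    stream = "gene_matrix" if kind == "gene" else "metabolite_matrix"
    rng = _rng(seed, stream)

    n_total = n_positive + n_negative + n_null
    classes = np.array(
        ["positive"] * n_positive + ["negative"] * n_negative + ["null"] * n_null
    )
    rng.shuffle(classes)
    width = max(4, len(str(n_total)))
    feature_ids = [f"{prefix}_{i:0{width}d}" for i in range(n_total)]

    slopes = np.where(
        classes == "positive",
        slope_positive,
        np.where(classes == "negative", slope_negative, 0.0),
    )
    base_mean = np.array([baselines[c] for c in classes])
    base = base_mean + rng.normal(0.0, baseline_log2_sd, size=n_total)

    shift = np.zeros(n_total)
    null_idx = np.flatnonzero(classes == "null")
    shifted_idx = rng.choice(null_idx, size=n_genotype_shifted, replace=False)
    shift[shifted_idx] = genotype_log2fc

    radii = design.radii
    ko_pre = (
        (design.data["genotype"] == "knockout") & (design.data["timepoint"] == "pre")
    ).to_numpy()
    log2 = (
        base[:, None]
        + slopes[:, None] * radii[None, :]
        + shift[:, None] * ko_pre[None, :]
    )
    if noise_sd > 0:
        log2 = log2 + rng.normal(0.0, noise_sd, size=log2.shape)
    matrix = FeatureMatrix(
        feature_ids=feature_ids,
        sample_ids=design.sample_ids,
        values=np.exp2(log2),
        kind=kind,
    )
    truth = SyntheticTruth(
        features=pd.DataFrame(
            {
                "feature_id": feature_ids,
                "scaling_class": classes,
                "true_slope": slopes,
                "baseline_log2": base,
                "genotype_shift": shift,
            }
        ),
        kind=kind,
        noise_sd=noise_sd,
        seed=seed,
    )
    return matrix, truth


#: Default planted gene sets: (size, scaling class drawn from, category).
DEFAULT_SET_SPEC = {
    "mito_like": (60, "negative", "subcellular_component"),
    "cytoskeleton_like": (60, "positive", "subcellular_component"),
    "decoy_component_1": (60, "null", "subcellular_component"),
    "decoy_component_2": (60, "null", "subcellular_component"),
    "srebp_like_family": (10, "negative", "transcription_factor_family"),
    "e2f_like_family": (10, "positive", "transcription_factor_family"),
    "decoy_tf_family": (10, "null", "transcription_factor_family"),
}


def generate_annotations(
    truth: SyntheticTruth,
    set_spec: Optional[Mapping[str, Tuple[int, str, str]]] = None,
    overlap_fraction: float = 0.0,
    seed: int = 0,
) -> GeneSetCollection:
    """Generate gene sets planted on the scaling classes.

    Each set draws ``round(size * (1 - overlap_fraction))`` members from
    its own class pool (without replacement across sets sharing a class)
    and the remainder uniformly from the leftover features, so
    ``overlap_fraction = 0`` yields class-pure, mutually disjoint sets.
    An ``all_tfs`` union set is added over the transcription-factor
    families.
    """
    if not (0.0 <= overlap_fraction <= 1.0):
        raise ValidationError("overlap_fraction must be in [0, 1]")
    spec = dict(DEFAULT_SET_SPEC if set_spec is None else set_spec)
    rng = _rng(seed, "annotations")
    pools: Dict[str, List[str]] = {
        c: list(rng.permutation(truth.ids_of_class(c))) for c in SCALING_CLASSES
    }
    taken: set = set()
    sets: Dict[str, frozenset] = {}
    categories: Dict[str, str] = {}
    for name, (size, scaling_class, category) in spec.items():
        if size < 1:
            raise ValidationError(f"set {name!r}: size must be >= 1")
        n_own = round(size * (1.0 - overlap_fraction))
        pool = pools[scaling_class]
        if len(pool) < n_own:
            raise ValidationError(
                f"set {name!r} requests {n_own} {scaling_class}-class members "
                f"but only {len(pool)} remain"
            )
        members = [pool.pop() for _ in range(n_own)]
        n_rest = size - n_own
        if n_rest:
            universe = [
                f
                for f in truth.features["feature_id"]
                if f not in taken and f not in members
            ]
            if len(universe) < n_rest:
                raise ValidationError(
                    f"set {name!r}: not enough unassigned features for overlap draw"
                )
            members += list(rng.choice(universe, size=n_rest, replace=False))
        sets[name] = frozenset(members)
        categories[name] = category
        taken |= sets[name]
    tf_names = [n for n, c in categories.items() if c == "transcription_factor_family"]
    if tf_names:
        union: set = set()
        for n in tf_names:
            union |= sets[n]
        sets["all_tfs"] = frozenset(union)
        categories["all_tfs"] = "transcription_factor_family"
    return GeneSetCollection(sets=sets, categories=categories)


#: Default lipid classes: (size, scaling class drawn from).  The
#: triacylglycerol analog is the planted storage-lipid class whose members
#: scale positively with cell size; membrane-lipid analogs are null.  The
#: prenol class is deliberately below the "more than four metabolites"
#: reporting cutoff.
DEFAULT_LIPID_CLASS_SPEC = {
    "triacylglycerol_like": (20, "positive"),
    "glycerophospholipid_like": (30, "null"),
    "sphingolipid_like": (15, "null"),
    "sterol_like": (10, "null"),
    "fatty_acyl_like": (8, "null"),
    "prenol_like": (4, "null"),
}


def generate_lipid_classes(
    truth: SyntheticTruth,
    class_spec: Optional[Mapping[str, Tuple[int, str]]] = None,
    seed: int = 0,
) -> Dict[str, str]:
    """Assign metabolite features to lipid classes (feature_id -> class)."""
    spec = dict(DEFAULT_LIPID_CLASS_SPEC if class_spec is None else class_spec)
    rng = _rng(seed, "lipid_classes")
    pools: Dict[str, List[str]] = {
        c: list(rng.permutation(truth.ids_of_class(c))) for c in SCALING_CLASSES
    }
    mapping: Dict[str, str] = {}
    for name, (size, scaling_class) in spec.items():
        pool = pools[scaling_class]
        if len(pool) < size:
            raise ValidationError(
                f"lipid class {name!r} requests {size} {scaling_class}-class "
                f"metabolites but only {len(pool)} remain"
            )
        for _ in range(size):
            mapping[pool.pop()] = name
    return mapping


def generate_network(
    truth: SyntheticTruth,
    p_within_module: float = 0.3,
    p_background: float = 0.02,
    seed: int = 0,
) -> nx.Graph:
    """Sample an undirected interaction network over all gene features.

    The planted module is the full negative scaling class; pairs inside it
    connect with probability ``p_within_module``, all other pairs with
    ``p_background``.
    """
    if not (0.0 <= p_background <= p_within_module <= 1.0):
        raise ValidationError(
            "need 0 <= p_background <= p_within_module <= 1, got "
            f"({p_background}, {p_within_module})"
        )
    rng = _rng(seed, "network")
    nodes = truth.features["feature_id"].tolist()
    in_module = (truth.features["scaling_class"] == "negative").to_numpy()
    n = len(nodes)
    iu, ju = np.triu_indices(n, k=1)
    probs = np.where(in_module[iu] & in_module[ju], p_within_module, p_background)
    keep = rng.random(len(probs)) < probs
    g = nx.Graph()
    g.add_nodes_from(nodes)
    node_arr = np.array(nodes)
    g.add_edges_from(zip(node_arr[iu[keep]], node_arr[ju[keep]]))
    return g
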