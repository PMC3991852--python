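"""Readers and writers for every on-disk format the pipeline touches.

All tables are UTF-8 TSV (Unix or Windows newlines); gene sets are GMT;
networks are whitespace- or tab-delimited edge lists in the STRING-links
style (``node1 node2 [score]``).  Floats are serialized with 6 significant
digits, so write/read roundtrips agree to about one part in 1e6.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Dict, Optional, Union

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import (
    CORRELATION_COLUMNS,
    GENOTYPES,
    SAMPLE_COLUMNS,
    SET_CATEGORIES,
    TIMEPOINTS,
    FeatureMatrix,
    GeneSetCollection,
    SampleTable,
    ValidationError,
    validate_correlation_table,
)

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


def _read_tsv(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, comment=None)


def read_sample_table(path: Union[str, Path]) -> SampleTable:
    """Read a sample design table (TSV with header ``sample_id genotype
    timepoint replicate relative_radius``).  Genotype/timepoint labels are
    matched case-insensitively."""
    df = _read_tsv(path)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    df = df.loc[:, SAMPLE_COLUMNS].copy()
    df["genotype"] = df["genotype"].str.strip().str.lower()
    df["timepoint"] = df["timepoint"].str.strip().str.lower()
    for col, allowed in (("genotype", GENOTYPES), ("timepoint", TIMEPOINTS)):
        bad = df.index[~df[col].isin(allowed)]
        if len(bad):
            row = int(bad[0])
            raise ValidationError(
                f"{path}: row {row} has unknown {col} {df.at[row, col]!r} "
                f"(allowed: {list(allowed)})"
            )
    df["replicate"] = pd.to_numeric(df["replicate"], errors="coerce")
    df["relative_radius"] = pd.to_numeric(df["relative_radius"], errors="coerce")
    try:
        return SampleTable(df)
    except ValidationError as err:
        raise ValidationError(f"{path}: {err}") from None


def write_sample_table(samples: SampleTable, path: Union[str, Path]) -> None:
    samples.data.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_feature_matrix(
    path: Union[str, Path],
    kind: str,
    samples: Optional[SampleTable] = None,
    missing: str = "error",
) -> FeatureMatrix:
    """Read a feature x sample TSV (first column ``feature_id``).

    ``missing`` policy: ``"error"`` rejects any empty/non-numeric cell with
    its coordinates; ``"drop-feature"`` silently (but logged) excludes
    features containing such cells.  When ``samples`` is given, columns are
    reordered to match its sample order.
    """
    if missing not in ("error", "drop-feature"):
        raise ValidationError(f"unknown missing-value policy {missing!r}")
    raw = pd.read_csv(path, sep="\t", index_col=0)
    raw.index = raw.index.astype(str)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = ~np.isfinite(numeric.to_numpy(dtype=float))
    if bad.any():
        if missing == "error":
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"{path}: non-numeric or missing value at "
                f"(feature={numeric.index[i]!r}, sample={numeric.columns[j]!r})"
            )
        keep = ~bad.any(axis=1)
        logger.warning(
            "%s: dropped %d features with missing values", path, int((~keep).sum())
        )
        numeric = numeric.loc[keep]
    mat = FeatureMatrix(
        feature_ids=numeric.index.tolist(),
        sample_ids=[str(c) for c in numeric.columns],
        values=numeric.to_numpy(dtype=float),
        kind=kind,
    )
    if samples is not None:
        mat = mat.align(samples)
    return mat


def write_feature_matrix(matrix: FeatureMatrix, path: Union[str, Path]) -> None:
    df = matrix.to_frame()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format="%.8g")


def read_gene_sets(path: Union[str, Path]) -> GeneSetCollection:
    """Read a GMT file (``name <tab> description <tab> member...``).

    A description matching a known category name is kept as the set's
    category; anything else maps to ``other``.  Duplicate members within a
    set are stored once."""
    sets: Dict[str, frozenset] = {}
    categories: Dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields "
                    f"(got {len(fields)})"
                )
            name, desc = fields[0], fields[1]
            members = frozenset(m for m in fields[2:] if m)
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            if not members:
                raise ValidationError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = members
            categories[name] = desc if desc in SET_CATEGORIES else "other"
    if not sets:
        logger.warning("%s: empty gene-set file", path)
    return GeneSetCollection(sets=sets, categories=categories)


def write_gene_sets(collection: GeneSetCollection, path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection.names():
            cat = collection.categories.get(name, "other")
            members = sorted(collection.sets[name])
            fh.write("\t".join([name, cat, *members]) + "\n")


def read_network(path: Union[str, Path], min_score: float = 0.0) -> nx.Graph:
    """Read an undirected edge list (``node1 node2 [score]``).

    Edges listed in both orientations collapse to one; self-loops are
    dropped (count logged); edges with a score below ``min_score`` are
    discarded.  Lines starting with ``#`` are comments."""
    g = nx.Graph()
    n_self = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValidationError(
                    f"{path}:{lineno}: edge line needs at least 2 fields"
                )
            a, b = fields[0], fields[1]
            if len(fields) >= 3:
                try:
                    score = float(fields[2])
                except ValueError:
                    raise ValidationError(
                        f"{path}:{lineno}: non-numeric score {fields[2]!r}"
                    ) from None
                if score < min_score:
                    continue
            if a == b:
                n_self += 1
                continue
            g.add_edge(a, b)
    if n_self:
        logger.warning("%s: dropped %d self-loops", path, n_self)
    return g


def write_network(graph: nx.Graph, path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{a}\t{b}\n")


def read_lipid_classes(path: Union[str, Path]) -> Dict[str, str]:
    """Read a two-column TSV mapping metabolite feature_id -> lipid class."""
    df = _read_tsv(path)
    for col in ("feature_id", "lipid_class"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    dup = df["feature_id"][df["feature_id"].duplicated()].tolist()
    if dup:
        raise ValidationError(f"{path}: duplicate feature_id values {sorted(set(dup))[:5]}")
    return dict(zip(df["feature_id"], df["lipid_class"]))


def write_lipid_classes(mapping: Dict[str, str], path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        {"feature_id": list(mapping), "lipid_class": [mapping[k] for k in mapping]}
    )
    df.to_csv(path, sep="\t", index=False)


def read_correlation_table(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_correlation_table(df)


def write_table(obj, path: Union[str, Path]) -> None:
    """Write any result table (DataFrame, or a result dataclass with an
    ``as_row`` method) as a TSV with a header and 6-significant-digit
    floats.  An empty table yields a header-only file."""
    if hasattr(obj, "as_row"):
        df = obj.as_row()
    elif isinstance(obj, pd.DataFrame):
        df = obj
    elif dataclasses.is_dataclass(obj):
        df = pd.DataFrame([dataclasses.asdict(obj)])
    else:
        raise TypeError(f"cannot serialize object of type {type(obj)!r}")
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
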