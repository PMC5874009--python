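"""CSV / JSON / Newick readers and writers.

CSV is the canonical tabular format, JSON the results format, Newick the
dendrogram format.  All readers validate on ingest and raise errors that name
the offending row or cell; all writers round-trip losslessly at the precision
the sources print (isotope ratios at six decimals).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.cluster.hierarchy import to_tree

from .records import (
    AnalysisConfig,
    BinaryArtifactMatrix,
    GroupTraitFrequencies,
    IsotopeSample,
    parse_tooth,
)

__all__ = [
    "read_isotope_table",
    "write_isotope_table",
    "read_artifact_matrix",
    "write_artifact_matrix",
    "read_frequency_table",
    "write_dendrogram",
    "read_config",
    "write_config",
    "write_json",
    "packaged_data",
]

_ISOTOPE_COLS = ["individual_id", "material", "tooth", "ratio", "two_se"]


def packaged_data(name: str) -> Path:
    """Path to a data file shipped with the package."""
    return Path(__file__).parent / "data" / name


def read_isotope_table(path) -> list[IsotopeSample]:
    """Read an isotope sample CSV (individual_id, material, tooth, ratio, two_se)."""
    samples: list[IsotopeSample] = []
    seen = set()
    with open(path, newline="") as f:
        reader = csv.DictReader(f)
        if reader.fieldnames is None or [
            c.strip() for c in reader.fieldnames
        ] != _ISOTOPE_COLS:
            raise ValueError(
                f"{path}: expected header {_ISOTOPE_COLS}, got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                ratio = float(row["ratio"])
                two_se = float(row["two_se"])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed number ({exc})") from exc
            tooth_code = row["tooth"].strip()
            tooth = parse_tooth(tooth_code) if tooth_code else None
            try:
                sample = IsotopeSample(
                    individual_id=row["individual_id"].strip(),
                    material=row["material"].strip(),
                    tooth=tooth,
                    ratio=ratio,
                    two_se=two_se,
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            key = (sample.individual_id, str(sample.tooth) if sample.tooth else "bone")
            if key in seen and sample.material == "enamel":
                raise ValueError(
                    f"{path}:{lineno}: duplicate sample for individual "
                    f"{sample.individual_id!r}, tooth {tooth_code!r}"
                )
            seen.add(key)
            samples.append(sample)
    return samples


def write_isotope_table(samples: Iterable[IsotopeSample], path) -> None:
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(_ISOTOPE_COLS)
        for s in samples:
            w.writerow(
                [
                    s.individual_id,
                    s.material,
                    str(s.tooth) if s.tooth else "",
                    f"{s.ratio:.6f}",
                    f"{s.two_se:.6f}",
                ]
            )


def read_artifact_matrix(path) -> BinaryArtifactMatrix:
    """Read a grave-good incidence CSV.

    Layout: ``individual_id`` column, the metadata columns sex / age_class /
    ritual / origin_code, then one {0,1} column per artifact type, in file
    order (preserved).
    """
    df = pd.read_csv(path, index_col="individual_id")
    meta_cols = list(BinaryArtifactMatrix.METADATA_COLS)
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    goods = [c for c in df.columns if c not in meta_cols]
    try:
        return BinaryArtifactMatrix(df[goods], df[meta_cols])
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_artifact_matrix(matrix: BinaryArtifactMatrix, path) -> None:
    meta = matrix.metadata[list(BinaryArtifactMatrix.METADATA_COLS)]
    out = pd.concat([meta, matrix.presence], axis=1)
    out.index.name = "individual_id"
    out.to_csv(path)


def read_frequency_table(path) -> tuple[list[GroupTraitFrequencies], list[str]]:
    """Read a group x trait frequency CSV (trait, breakpoint, mmd_panel, group, percent, n).

    Returns the per-group frequency records (counts recovered from percent and
    n, see :func:`necropop.biodistance.counts_from_percentages`) and the list
    of traits flagged for the MMD panel.
    """
    from .biodistance import counts_from_percentages

    df = pd.read_csv(path)
    required = {"trait", "group", "percent", "n"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    groups = []
    for group, sub in df.groupby("group", sort=False):
        counts = {}
        for _, row in sub.iterrows():
            n = int(row["n"])
            k = counts_from_percentages(float(row["percent"]), n) if n > 0 else 0
            counts[row["trait"]] = (k, n)
        groups.append(GroupTraitFrequencies(group=group, counts=counts))
    panel = []
    if "mmd_panel" in df.columns:
        panel = list(df.loc[df["mmd_panel"] == 1, "trait"].drop_duplicates())
    return groups, panel


def linkage_to_newick(linkage_matrix: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths.

    Branch lengths are derived from merge heights (parent height minus child
    height), so the tree is ultrametric in the linkage's own height scale.
    """
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate leaf labels")
    tree = to_tree(linkage_matrix)

    def build(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = build(node.left, node.dist)
        right = build(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    left = build(tree.left, tree.dist)
    right = build(tree.right, tree.dist)
    return f"({left},{right});"


def write_dendrogram(linkage_matrix: np.ndarray, labels: Sequence[str], path) -> None:
    """Write a hierarchical clustering result as a Newick file."""
    Path(path).write_text(linkage_to_newick(linkage_matrix, labels) + "\n")


def read_config(path) -> AnalysisConfig:
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    if raw.get("local_range_bounds") is not None:
        raw["local_range_bounds"] = tuple(raw["local_range_bounds"])
    if raw.get("faunal_range") is not None:
        raw["faunal_range"] = tuple(raw["faunal_range"])
    return AnalysisConfig(**raw)


def write_config(config: AnalysisConfig, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config.to_dict(), f, sort_keys=False)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "value"):  # enums
            return o.value
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as f:
        json.dump(obj, f, indent=2, sort_keys=False, default=default)
        f.write("\n")
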