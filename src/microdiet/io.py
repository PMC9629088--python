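"""On-disk formats: abundance TSV, metadata TSV, Newick trees, clinical CSV,
nutrient-response matrices, and JSON artifacts.

Conventions
-----------
* Abundance tables are tab-separated, samples as rows: first column sample ID,
  header row of taxon names. Counts or proportions are both accepted; with
  ``normalize=True`` rows are closed to sum to 1.
* Clinical scores are comma-separated with columns
  ``sample_id, pain, pain_freq, distension, dissatisfaction, qol``.
* Trees are Newick with named leaves and non-negative branch lengths.
* Every reader/writer pair round-trips losslessly to float precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .compositions import closure

SCHEMA_VERSION = "1"

CLINICAL_ITEMS = ("pain", "pain_freq", "distension", "dissatisfaction", "qol")


@dataclass
class AbundanceTable:
    """A samples x taxa relative-abundance matrix on the simplex.

    ``data`` is a DataFrame indexed by sample ID with taxon-name columns.
    The central container every analysis stage consumes.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate taxon names: {dups}")
        vals = self.data.to_numpy(dtype=float)
        if np.any(vals < 0):
            i, j = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative abundance {vals[i, j]} at sample "
                f"{self.data.index[i]!r}, taxon {self.data.columns[j]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index.astype(str))

    @property
    def taxon_names(self) -> list[str]:
        return list(self.data.columns.astype(str))

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    def normalized(self) -> "AbundanceTable":
        """Close every row to sum to 1."""
        return AbundanceTable(
            pd.DataFrame(closure(self.values), index=self.data.index, columns=self.data.columns)
        )

    def is_normalized(self, tol: float = 1e-6) -> bool:
        return bool(np.allclose(self.values.sum(axis=1), 1.0, atol=tol))

    def subset(self, sample_ids) -> "AbundanceTable":
        return AbundanceTable(self.data.loc[list(sample_ids)])


def read_abundance(path, normalize: bool = False) -> AbundanceTable:
    """Read a samples x taxa TSV; optionally close rows to the simplex.

    Raises ``ValueError`` naming the offending sample/taxon for negative
    entries or duplicate labels, and for ragged rows.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().to_numpy().any():
        i, j = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: missing/ragged value at sample {df.index[i]!r}, column {df.columns[j]!r}"
        )
    try:
        table = AbundanceTable(df.astype(float))
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
    return table.normalized() if normalize else table


def write_abundance(table: AbundanceTable, path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path) -> pd.DataFrame:
    """Read the sample metadata TSV (sample_id, group, optional arm/timepoint/pair_id)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise ValueError(f"{path}: metadata requires sample_id and group columns")
    bad = set(df["group"]) - {"healthy", "ibs"}
    if bad:
        raise ValueError(f"{path}: unknown group labels {sorted(bad)}")
    return df.set_index("sample_id")


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_tree(path_or_str) -> TreeNode:
    """Parse a Newick tree; validate named leaves and non-negative branch lengths."""
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # skbio sniffer warns before raising
            tree = TreeNode.read(
                [str(path_or_str)] if str(path_or_str).rstrip().endswith(";")
                else str(path_or_str),
                format="newick",
            )
    except Exception as exc:  # skbio raises NewickFormatError with position info
        raise ValueError(f"malformed Newick: {exc}") from exc
    for tip in tree.tips():
        if tip.name is None or str(tip.name).strip() == "":
            raise ValueError("tree contains an unnamed leaf")
        if tip.length is not None and tip.length < 0:
            raise ValueError(f"negative branch length {tip.length} at leaf {tip.name!r}")
    for node in tree.non_tips(include_self=True):
        if node.length is not None and node.length < 0:
            raise ValueError(f"negative branch length {node.length} at internal node")
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_clinical(path) -> pd.DataFrame:
    """Read the five-item symptom-severity CSV, indexed by sample_id."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in ("sample_id", *CLINICAL_ITEMS) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing clinical columns {missing}")
    return df.set_index("sample_id")


def write_clinical(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index_label="sample_id", columns=list(CLINICAL_ITEMS))


def read_nutrient_response(matrix_path, bounds_path):
    """Read the taxon x nutrient response matrix TSV plus its dose-bounds sidecar.

    Returns ``(B_dataframe, bounds_series)`` with bounds in g/day.
    """
    B = pd.read_csv(matrix_path, sep="\t", index_col=0).astype(float)
    bounds = pd.read_csv(bounds_path, sep="\t", index_col=0)["max_dose_g_per_day"].astype(float)
    if list(bounds.index) != list(B.columns):
        raise ValueError("bounds sidecar nutrients do not match response-matrix columns")
    if (bounds < 0).any():
        raise ValueError("negative dose bound")
    return B, bounds


def write_nutrient_response(B: pd.DataFrame, bounds: pd.Series, matrix_path, bounds_path) -> None:
    B.to_csv(matrix_path, sep="\t", index_label="taxon")
    bounds.rename("max_dose_g_per_day").to_csv(bounds_path, sep="\t", index_label="nutrient")


def write_json(obj, path) -> None:
    """Write a JSON artifact with a schema-version stamp, deterministically ordered."""
    payload = {"schema_version": SCHEMA_VERSION}
    payload.update(obj)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
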