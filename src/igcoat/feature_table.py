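"""Feature-table container and delimited-text / BIOM-style JSON I/O.

The table is features x samples with non-negative integer counts, the
substrate of every sequence-side stage. Sample metadata travels as a
pandas DataFrame with a fixed required column set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Columns every metadata table must carry.
METADATA_COLUMNS = (
    "sample_id",
    "dog_id",
    "cohort",
    "stage",
    "ig_class",
    "fraction",
    "run",
    "replicate",
    "is_control",
)

COHORTS = ("healthy", "DRE", "ARE", "IRE")
STAGES = ("before", "after")
IG_CLASSES = ("IgA", "IgG")
FRACTIONS = ("presort", "ig_pos", "ig_neg")


@dataclass
class FeatureTable:
    """Features x samples count matrix with unique string identifiers."""

    counts: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.feature_ids = list(self.feature_ids)
        self.sample_ids = list(self.sample_ids)
        self.validate()

    def validate(self) -> None:
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        nf, ns = self.counts.shape
        if nf != len(self.feature_ids) or ns != len(self.sample_ids):
            raise ValueError(
                f"shape {self.counts.shape} does not match "
                f"{len(self.feature_ids)} features / {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != nf:
            raise ValueError("feature IDs are not unique")
        if len(set(self.sample_ids)) != ns:
            raise ValueError("sample IDs are not unique")
        if self.counts.size and (self.counts < 0).any():
            raise ValueError("negative counts are not allowed")

    # -- basic accessors -------------------------------------------------
    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def feature_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.counts.copy(), list(self.feature_ids), list(self.sample_ids))

    def select_samples(self, keep: Sequence[str] | np.ndarray) -> "FeatureTable":
        """Subset columns; `keep` is a list of sample IDs or a boolean mask."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {s: i for i, s in enumerate(self.sample_ids)}
            missing = [s for s in keep if s not in pos]
            if missing:
                raise KeyError(f"unknown sample IDs: {missing[:5]}")
            idx = np.array([pos[s] for s in keep], dtype=int)
        return FeatureTable(
            self.counts[:, idx],
            list(self.feature_ids),
            [self.sample_ids[i] for i in idx],
        )

    def select_features(self, keep: Sequence[str] | np.ndarray) -> "FeatureTable":
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {f: i for i, f in enumerate(self.feature_ids)}
            missing = [f for f in keep if f not in pos]
            if missing:
                raise KeyError(f"unknown feature IDs: {missing[:5]}")
            idx = np.array([pos[f] for f in keep], dtype=int)
        return FeatureTable(
            self.counts[idx, :],
            [self.feature_ids[i] for i in idx],
            list(self.sample_ids),
        )

    # -- pandas / disk round trips --------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureTable":
        return cls(df.to_numpy(), [str(i) for i in df.index], [str(c) for c in df.columns])

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df.index.name = "feature_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_dataframe(df)

    def write_biom_json(self, path: str | Path) -> None:
        """Minimal dense BIOM-format (v1-style) JSON export."""
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "type": "OTU table",
            "matrix_type": "dense",
            "matrix_element_type": "int",
            "shape": [self.n_features, self.n_samples],
            "rows": [{"id": f, "metadata": None} for f in self.feature_ids],
            "columns": [{"id": s, "metadata": None} for s in self.sample_ids],
            "data": self.counts.astype(int).tolist(),
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def read_biom_json(cls, path: str | Path) -> "FeatureTable":
        doc = json.loads(Path(path).read_text())
        feature_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        if doc.get("matrix_type") == "sparse":
            counts = np.zeros(doc["shape"], dtype=np.int64)
            for i, j, v in doc["data"]:
                counts[int(i), int(j)] = v
        else:
            counts = np.asarray(doc["data"], dtype=np.int64)
        return cls(counts, feature_ids, sample_ids)


def validate_metadata(metadata: pd.DataFrame) -> None:
    """Raise if the metadata frame is missing required columns or IDs clash."""
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    if metadata["sample_id"].duplicated().any():
        dup = metadata.loc[metadata["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id in metadata: {dup!r}")


def read_metadata(path: str | Path) -> pd.DataFrame:
    md = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "dog_id": str})
    if "is_control" in md.columns:
        md["is_control"] = md["is_control"].astype(bool)
    validate_metadata(md)
    return md


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    validate_metadata(metadata)
    metadata.to_csv(path, sep="\t", index=False)


def align_to_metadata(table: FeatureTable, metadata: pd.DataFrame) -> pd.DataFrame:
    """Return metadata rows reordered to the table's sample order.

    Every table sample must be present in the metadata.
    """
    validate_metadata(metadata)
    md = metadata.set_index("sample_id", drop=False)
    missing = [s for s in table.sample_ids if s not in md.index]
    if missing:
        raise KeyError(f"samples in table but not metadata: {missing[:5]}")
    return md.loc[table.sample_ids].reset_index(drop=True)
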