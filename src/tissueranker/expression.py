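"""Tissue-labelled expression compendia: reading, validation, filtering.

The compendium is a gene x sample matrix of continuous (typically
log-scale) expression values, with per-sample tissue and condition labels.
Values are consumed exactly as provided: no renormalization and no log
transform happen here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionCompendium",
    "TissueCategoryMap",
    "read_expression",
    "read_category_map",
    "filter_tissues",
]


@dataclass
class ExpressionCompendium:
    """Gene x sample expression values plus sample -> tissue/condition maps.

    ``values`` is a DataFrame indexed by gene id with sample ids as
    columns; all entries must be finite.
    """

    values: pd.DataFrame
    tissue_of: dict[str, str]
    condition_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")
        missing = [s for s in self.values.columns if s not in self.tissue_of]
        if missing:
            raise ValueError(f"samples without tissue label: {missing[:5]}")
        if not self.condition_of:
            self.condition_of = {s: "normal" for s in self.values.columns}

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def tissues(self) -> list[str]:
        """Distinct tissue labels in sorted order."""
        return sorted({self.tissue_of[s] for s in self.values.columns})

    def samples_of_tissue(self, tissue: str) -> list[str]:
        return [s for s in self.values.columns if self.tissue_of[s] == tissue]

    def n_samples(self, tissue: str) -> int:
        return len(self.samples_of_tissue(tissue))

    def tissue_values(self, tissue: str) -> pd.DataFrame:
        """Gene x sample sub-matrix for one tissue."""
        return self.values[self.samples_of_tissue(tissue)]


@dataclass(frozen=True)
class TissueCategoryMap:
    """Total map from tissue label to coarse category label."""

    category_of: dict[str, str]

    def __post_init__(self) -> None:
        for t, c in self.category_of.items():
            if not c:
                raise ValueError(f"empty category for tissue {t!r}")

    def __getitem__(self, tissue: str) -> str:
        try:
            return self.category_of[tissue]
        except KeyError:
            raise KeyError(f"tissue {tissue!r} has no category mapping") from None

    @classmethod
    def identity(cls, tissues) -> "TissueCategoryMap":
        return cls({t: t for t in tissues})


def read_expression(matrix_path: str | Path, metadata_path: str | Path) -> ExpressionCompendium:
    """Read a gene x sample TSV matrix plus a sample metadata TSV.

    The matrix's first column holds gene ids and its header row sample
    ids.  Metadata must have ``sample``, ``tissue`` and ``condition``
    columns.  Samples present in the matrix but missing from the metadata
    are an error; metadata rows for absent samples are ignored (logged).
    """
    matrix_path, metadata_path = Path(matrix_path), Path(metadata_path)
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{matrix_path}: duplicate gene id {dup!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(~np.isfinite(numeric.to_numpy()))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"{matrix_path}: non-numeric or missing value at gene "
            f"{df.index[i]!r}, sample {df.columns[j]!r}"
        )

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"sample", "tissue", "condition"}
    if not required.issubset(meta.columns):
        raise ValueError(f"{metadata_path}: needs columns {sorted(required)}")
    tissue_of = dict(zip(meta["sample"], meta["tissue"]))
    condition_of = dict(zip(meta["sample"], meta["condition"]))

    unknown = [s for s in numeric.columns if s not in tissue_of]
    if unknown:
        raise ValueError(f"{matrix_path}: samples missing from metadata: {unknown}")
    extra = set(tissue_of) - set(numeric.columns)
    if extra:
        logger.info("ignoring %d metadata-only sample(s)", len(extra))
    tissue_of = {s: tissue_of[s] for s in numeric.columns}
    condition_of = {s: condition_of[s] for s in numeric.columns}
    return ExpressionCompendium(numeric.astype(float), tissue_of, condition_of)


def read_category_map(path: str | Path) -> TissueCategoryMap:
    """Read a two-column TSV (tissue, category)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"tissue", "category"}.issubset(df.columns):
        raise ValueError(f"{path}: needs columns ['tissue', 'category']")
    return TissueCategoryMap(dict(zip(df["tissue"], df["category"])))


def filter_tissues(
    c: ExpressionCompendium,
    min_replicates: int = 5,
    exclude: set[str] | None = None,
    condition: str = "normal",
) -> ExpressionCompendium:
    """Keep samples of one condition in non-excluded, well-replicated tissues.

    A tissue survives only if, after restricting to the requested
    condition and dropping excluded tissue labels, it retains at least
    ``min_replicates`` samples.  The gene set is unchanged.  Applying the
    filter twice is a no-op.
    """
    if min_replicates < 2:
        raise ValueError("min_replicates must be >= 2")
    exclude = exclude or set()
    qualifying = [
        s
        for s in c.samples
        if c.condition_of[s] == condition and c.tissue_of[s] not in exclude
    ]
    counts: dict[str, int] = {}
    for s in qualifying:
        counts[c.tissue_of[s]] = counts.get(c.tissue_of[s], 0) + 1
    kept = [s for s in qualifying if counts[c.tissue_of[s]] >= min_replicates]
    if not kept:
        raise ValueError("no tissue satisfies the replicate filter")
    dropped = len(c.samples) - len(kept)
    if dropped:
        logger.info(
            "filter_tissues: kept %d/%d samples in %d tissue(s)",
            len(kept), len(c.samples), len({c.tissue_of[s] for s in kept}),
        )
    return ExpressionCompendium(
        c.values[kept],
        {s: c.tissue_of[s] for s in kept},
        {s: c.condition_of[s] for s in kept},
    )
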