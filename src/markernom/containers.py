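"""Core in-memory containers shared across pipeline stages.

Thin dataclass wrappers around pandas objects: the DataFrame stays the
workhorse, the wrapper enforces the invariants (unique feature ids, complete
labels, valid intervals, beta range) once at construction.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "PeakSet",
    "GeneAnnotation",
    "GeneSet",
    "MethylationMatrix",
    "IRSRecord",
]

BED_COLUMNS = ["chrom", "start", "end", "name", "score"]


@dataclass
class ExpressionMatrix:
    """log2 expression, genes x samples, with one entity label per sample."""

    values: pd.DataFrame                 # index: feature ids, columns: samples
    entity_labels: pd.Series             # sample -> entity

    def __post_init__(self) -> None:
        idx = self.values.index
        if idx.duplicated().any():
            dups = sorted(set(idx[idx.duplicated()]))
            raise ValueError(f"duplicate feature ids: {', '.join(map(str, dups))}")
        if self.values.isna().any().any():
            bad = self.values.columns[self.values.isna().any()].tolist()
            raise ValueError(f"missing expression values in samples: {bad}")
        labels = self.entity_labels
        unlabeled = [s for s in self.values.columns if s not in labels.index]
        extra = [s for s in labels.index if s not in self.values.columns]
        if unlabeled or extra:
            raise ValueError(
                "sample/label mismatch; unlabeled samples: "
                f"{unlabeled}; labels without samples: {extra}")
        self.entity_labels = labels.reindex(self.values.columns)

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def entities(self) -> list[str]:
        return sorted(self.entity_labels.unique())

    def samples_of(self, entity: str) -> list[str]:
        mask = self.entity_labels == entity
        if not mask.any():
            raise KeyError(f"unknown entity: {entity!r}")
        return list(self.entity_labels.index[mask])


@dataclass
class PeakSet:
    """Signal-bearing genomic intervals, BED convention (0-based half-open)."""

    df: pd.DataFrame                     # columns: chrom, start, end, name, score

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True).copy()
        if "name" not in df:
            df["name"] = [f"peak_{i}" for i in range(len(df))]
        if "score" not in df:
            df["score"] = 0.0
        df = df[BED_COLUMNS]
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["score"] = df["score"].astype(float)
        bad = df.index[df["start"] >= df["end"]]
        if len(bad):
            raise ValueError(f"empty or inverted interval at rows {list(bad)}")
        if (df["score"] < 0).any():
            raise ValueError("peak scores must be >= 0")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def sorted(self) -> "PeakSet":
        return PeakSet(self.df.sort_values(["chrom", "start", "end"],
                                           kind="mergesort"))


@dataclass
class GeneAnnotation:
    """Gene coordinates with a strand-aware TSS.

    ``tss`` is the annotation ``start`` for plus-strand genes and the
    annotation ``end`` for minus-strand genes (BED convention throughout).
    """

    df: pd.DataFrame                     # columns: gene_id, chrom, start, end, strand

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True).copy()
        required = {"gene_id", "chrom", "start", "end", "strand"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"gene annotation missing columns: {sorted(missing)}")
        if df["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids in annotation")
        if not df["strand"].isin(["+", "-"]).all():
            raise ValueError("strand must be '+' or '-'")
        if (df["start"] >= df["end"]).any():
            raise ValueError("gene start must be < end")
        df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"])
        self.df = df

    def tss_frame(self) -> pd.DataFrame:
        return self.df[["gene_id", "chrom", "tss", "start", "end"]]


@dataclass
class GeneSet:
    """Named ordered set of gene ids, optionally direction-annotated."""

    name: str
    members: list[str]
    description: str = ""
    direction: str | None = None         # "up" | "down" | None

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        for m in self.members:
            seen.setdefault(m, None)
        self.members = list(seen)
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")
        if self.direction not in (None, "up", "down"):
            raise ValueError("direction must be 'up', 'down' or None")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class MethylationMatrix:
    """CpG beta values (rows) by labeled samples (columns)."""

    beta: pd.DataFrame                   # index: cpg ids, columns: samples
    coords: pd.DataFrame                 # columns: cpg_id, chrom, position
    entity_labels: pd.Series             # sample -> entity

    def __post_init__(self) -> None:
        if ((self.beta < 0) | (self.beta > 1)).any().any():
            raise ValueError("beta values must lie in [0, 1]")
        coords = self.coords.reset_index(drop=True).copy()
        if coords["cpg_id"].duplicated().any():
            raise ValueError("duplicate CpG ids in coordinates")
        missing = set(self.beta.index) - set(coords["cpg_id"])
        if missing:
            raise ValueError(f"CpGs without coordinates: {sorted(missing)[:5]}")
        labels = self.entity_labels.reindex(self.beta.columns)
        if labels.isna().any():
            raise ValueError("every methylation sample needs an entity label")
        self.coords = coords
        self.entity_labels = labels


# banding of percent positive cells -> proportion category (0..4)
_IRS_BANDS = (0.0, 10.0, 50.0, 80.0)


@dataclass
class IRSRecord:
    """One immunohistochemistry scoring record.

    irs = staining intensity (0-3) x proportion category (0-4), range 0-12.
    """

    sample_id: str
    entity: str
    intensity: int
    percent_positive: float
    proportion_category: int = field(init=False)
    irs: int = field(init=False)

    def __post_init__(self) -> None:
        if self.intensity not in (0, 1, 2, 3):
            raise ValueError("intensity must be an integer in {0,1,2,3}")
        if not (0.0 <= self.percent_positive <= 100.0):
            raise ValueError("percent_positive must lie in [0, 100]")
        self.proportion_category = proportion_category(self.percent_positive)
        self.irs = self.intensity * self.proportion_category


def proportion_category(percent_positive: float,
                        bands: tuple[float, float, float, float] = _IRS_BANDS,
                        ) -> int:
    """Band % positive cells into the 0-4 proportion category.

    0 for 0%, 1 for (0,10)%, 2 for [10,50]%, 3 for (50,80]%, 4 for (80,100]%.
    Band edges are exposed so a variant banding can be dialed in.
    """
    zero, low, mid, high = bands
    if not (0.0 <= percent_positive <= 100.0):
        raise ValueError("percent_positive must lie in [0, 100]")
    if percent_positive <= zero:
        return 0
    if percent_positive < low:
        return 1
    if percent_positive <= mid:
        return 2
    if percent_positive <= high:
        return 3
    return 4


def irs_frame(records: list[IRSRecord]) -> pd.DataFrame:
    """Tabulate IRS records (sample, entity, intensity, %, category, irs)."""
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "entity": r.entity,
                "intensity": r.intensity,
                "percent_positive": r.percent_positive,
                "proportion_category": r.proportion_category,
                "irs": r.irs,
            }
            for r in records
        ]
    )
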