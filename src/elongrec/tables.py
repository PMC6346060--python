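"""Exon-by-specimen count tables with specimen metadata sidecars.

A CountsTable pairs a non-negative integer matrix, indexed by
``(transcript_id, exon_index)`` with one column per specimen, with a
metadata frame (group, condition, replicate) keyed by specimen id.
Exon indices follow genomic exon order within each transcript.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["SpecimenMeta", "CountsTable", "read_counts", "write_counts"]

GROUPS = ("WT", "AT")
CONDITIONS = ("Untr", "R0", "R15", "R30")
META_COLUMNS = ("group", "condition", "replicate")


@dataclass(frozen=True)
class SpecimenMeta:
    """Design coordinates of one specimen (library)."""

    specimen_id: str
    group: str
    condition: str
    replicate: int

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"specimen {self.specimen_id}: group must be one of {GROUPS}, "
                f"got {self.group!r}"
            )
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"specimen {self.specimen_id}: condition must be one of "
                f"{CONDITIONS}, got {self.condition!r}"
            )
        if int(self.replicate) < 1:
            raise ValidationError(
                f"specimen {self.specimen_id}: replicate must be >= 1"
            )


def _validate_meta(meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"specimen metadata missing columns: {missing}")
    if meta.index.has_duplicates:
        dups = meta.index[meta.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate specimen ids in metadata: {dups}")
    for sid, row in meta.iterrows():
        SpecimenMeta(str(sid), row["group"], row["condition"], int(row["replicate"]))
    triplets = meta[list(META_COLUMNS)].apply(tuple, axis=1)
    if triplets.duplicated().any():
        bad = triplets[triplets.duplicated()].tolist()
        raise ValidationError(f"duplicate (group, condition, replicate) triplets: {bad}")
    return meta.assign(replicate=meta["replicate"].astype(int))


class CountsTable:
    """Validated exon counts plus specimen metadata.

    Parameters
    ----------
    counts
        DataFrame with a ``(transcript_id, exon_index)`` MultiIndex and one
        integer column per specimen.
    meta
        DataFrame indexed by specimen id with columns group / condition /
        replicate.
    """

    def __init__(self, counts: pd.DataFrame, meta: pd.DataFrame):
        if counts.index.nlevels != 2:
            raise ValidationError(
                "counts index must be a (transcript_id, exon_index) MultiIndex"
            )
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            rounded = np.asarray(values, dtype=float)
            if not np.all(np.isfinite(rounded)) or np.any(rounded != np.floor(rounded)):
                bad = np.argwhere(
                    ~np.isfinite(np.asarray(values, dtype=float))
                    | (np.asarray(values, dtype=float) != np.floor(rounded))
                )
                r, c = bad[0]
                raise ValidationError(
                    f"non-integer count at row {counts.index[r]}, "
                    f"column {counts.columns[c]!r}"
                )
            counts = counts.astype(np.int64)
            values = counts.to_numpy()
        if np.any(values < 0):
            r, c = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at row {counts.index[r]}, column {counts.columns[c]!r}"
            )
        meta = _validate_meta(meta)
        meta_ids = set(map(str, meta.index))
        col_ids = set(map(str, counts.columns))
        if meta_ids != col_ids:
            raise ValidationError(
                "specimen mismatch between counts and metadata: "
                f"counts-only={sorted(col_ids - meta_ids)}, "
                f"meta-only={sorted(meta_ids - col_ids)}"
            )
        counts.index = counts.index.set_names(["transcript_id", "exon_index"])
        self.counts = counts
        self.meta = meta.loc[list(counts.columns)]

    @property
    def specimens(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.counts.index.get_level_values("transcript_id").unique())

    def select_specimens(self, **criteria) -> list[str]:
        """Specimen ids matching all metadata criteria (e.g. group='WT')."""
        mask = pd.Series(True, index=self.meta.index)
        for key, value in criteria.items():
            if key not in self.meta.columns:
                raise ValidationError(f"unknown metadata column {key!r}")
            mask &= self.meta[key] == value
        return list(self.meta.index[mask])

    def transcript_totals(self) -> pd.DataFrame:
        """Sum exon counts within each transcript (transcript x specimen)."""
        return self.counts.groupby(level="transcript_id", sort=False).sum()

    def validate_against(self, annotation: Mapping) -> None:
        """Check that every exon row exists in the annotation."""
        for tid, sub in self.counts.groupby(level="transcript_id", sort=False):
            if tid not in annotation:
                raise ValidationError(f"transcript {tid} present in counts but not annotation")
            n = annotation[tid].n_exons
            idx = sorted(sub.index.get_level_values("exon_index"))
            if idx != list(range(n)):
                raise ValidationError(
                    f"transcript {tid}: counts exon indices {idx} do not match "
                    f"annotation with {n} exons"
                )


def read_counts(path: str | Path, meta_path: str | Path) -> CountsTable:
    """Read a counts TSV plus its specimen-metadata sidecar TSV.

    The counts file carries ``transcript_id`` and ``exon_index`` columns
    followed by one column per specimen; the sidecar has one row per
    specimen with group / condition / replicate.
    """
    raw = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    for col in ("transcript_id", "exon_index"):
        if col not in raw.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    counts = raw.set_index(["transcript_id", "exon_index"])
    meta = pd.read_csv(meta_path, sep="\t", dtype={"specimen_id": str})
    if "specimen_id" not in meta.columns:
        raise ValidationError(f"{meta_path}: missing required column 'specimen_id'")
    meta = meta.set_index("specimen_id")
    return CountsTable(counts, meta)


def write_counts(table: CountsTable, path: str | Path, meta_path: str | Path) -> None:
    """Write the counts TSV and metadata sidecar (inverse of read_counts)."""
    table.counts.reset_index().to_csv(path, sep="\t", index=False)
    table.meta.reset_index(names="specimen_id").to_csv(meta_path, sep="\t", index=False)
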