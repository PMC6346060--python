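"""Normalized per-transcript exon coverage profiles.

The profile of a transcript in a specimen is its vector of per-exon
densities, ``count / exon_length / size_factor``, ordered 5'->3' (genomic
exon order reversed on the minus strand). Density rather than raw count is
the unit so that exon-length artifacts do not dominate profile correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .annotation import LengthStrata, TranscriptAnnotation, annotation_index
from .errors import ValidationError
from .tables import CountsTable

__all__ = [
    "CoverageProfile",
    "ProfileSet",
    "size_factors",
    "build_profiles",
    "coverage_groups_filter",
]


@dataclass(frozen=True)
class CoverageProfile:
    """Ordered 5'->3' per-exon density vector for one transcript/specimen."""

    transcript_id: str
    specimen_id: str
    values: np.ndarray
    exon_lengths: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        lens = np.asarray(self.exon_lengths, dtype=float)
        if values.shape != lens.shape:
            raise ValidationError(
                f"profile {self.transcript_id}/{self.specimen_id}: values and "
                "exon_lengths differ in shape"
            )
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise ValidationError(
                f"profile {self.transcript_id}/{self.specimen_id}: densities "
                "must be finite and >= 0"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "exon_lengths", lens)

    @property
    def midpoints(self) -> np.ndarray:
        """Exon midpoint positions in transcript coordinates (nt from TSS)."""
        bounds = np.concatenate([[0.0], np.cumsum(self.exon_lengths)])
        return (bounds[:-1] + bounds[1:]) / 2.0


def _size_factors_matrix(matrix: np.ndarray, specimens: list[str]) -> pd.Series:
    if matrix.size == 0 or not np.any(matrix):
        raise ValidationError("cannot compute size factors from an all-zero table")
    with np.errstate(divide="ignore"):
        logm = np.log(matrix.astype(float))
    all_pos = np.all(np.isfinite(logm), axis=1)
    if not np.any(all_pos):
        raise ValidationError(
            "no row with nonzero counts in every specimen; size factors undefined"
        )
    log_geo = logm[all_pos].mean(axis=1, keepdims=True)
    log_sf = np.median(logm[all_pos] - log_geo, axis=0)
    log_sf = log_sf - log_sf.mean()  # normalize to geometric mean 1
    return pd.Series(np.exp(log_sf), index=specimens, name="size_factor")


def size_factors(counts: CountsTable | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, normalized to geometric mean 1.

    The reference is the per-row geometric mean over specimens, computed on
    rows with nonzero counts everywhere; each specimen's factor is the
    median of its count/reference ratios.
    """
    df = counts.counts if isinstance(counts, CountsTable) else counts
    return _size_factors_matrix(df.to_numpy(), list(df.columns))


@dataclass
class ProfileSet:
    """Coverage profiles for many transcripts and specimens.

    ``densities[tid]`` is an (n_specimens, n_exons) array in 5'->3' exon
    order, with rows following ``specimens``.
    """

    densities: dict[str, np.ndarray]
    exon_lengths: dict[str, np.ndarray]
    specimens: list[str]
    meta: pd.DataFrame
    factors: pd.Series = field(repr=False, default=None)

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.densities)

    def profile(self, transcript_id: str, specimen_id: str) -> CoverageProfile:
        row = self.specimens.index(specimen_id)
        return CoverageProfile(
            transcript_id=transcript_id,
            specimen_id=specimen_id,
            values=self.densities[transcript_id][row],
            exon_lengths=self.exon_lengths[transcript_id],
        )

    def mean_profile(self, transcript_id: str, specimen_ids: Iterable[str]) -> CoverageProfile:
        """Average profile over several specimens (e.g. replicates)."""
        rows = [self.specimens.index(s) for s in specimen_ids]
        return CoverageProfile(
            transcript_id=transcript_id,
            specimen_id="+".join(str(s) for s in specimen_ids),
            values=self.densities[transcript_id][rows].mean(axis=0),
            exon_lengths=self.exon_lengths[transcript_id],
        )

    def select_specimens(self, **criteria) -> list[str]:
        mask = pd.Series(True, index=self.meta.index)
        for key, value in criteria.items():
            mask &= self.meta[key] == value
        return list(self.meta.index[mask])

    def restrict(self, transcript_ids: Iterable[str]) -> "ProfileSet":
        keep = [t for t in self.transcript_ids if t in set(transcript_ids)]
        return ProfileSet(
            densities={t: self.densities[t] for t in keep},
            exon_lengths={t: self.exon_lengths[t] for t in keep},
            specimens=self.specimens,
            meta=self.meta,
            factors=self.factors,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (transcript_id, specimen_id, exon_index, density)."""
        records = []
        for tid, mat in self.densities.items():
            for row, sid in enumerate(self.specimens):
                for j, d in enumerate(mat[row]):
                    records.append((tid, sid, j, d))
        return pd.DataFrame(
            records, columns=["transcript_id", "specimen_id", "exon_index", "density"]
        )


def build_profiles(
    counts: CountsTable,
    annotation: Iterable[TranscriptAnnotation] | Mapping[str, TranscriptAnnotation],
    min_exons: int = 4,
    min_mean_count: float = 5.0,
) -> tuple[ProfileSet, list[tuple[str, str]]]:
    """Turn exon counts into ordered normalized coverage profiles.

    Transcripts with fewer than ``min_exons`` exons (a Pearson correlation
    over very few exons is unstable) or with mean raw count below
    ``min_mean_count`` are excluded and reported with a reason.

    Returns
    -------
    (ProfileSet, excluded)
        ``excluded`` is a list of ``(transcript_id, reason)`` with reasons
        ``"too_few_exons"`` or ``"low_expression"``.
    """
    ann = annotation_index(annotation)
    counts.validate_against(ann)
    factors = size_factors(counts)
    sf = factors[counts.specimens].to_numpy()

    densities: dict[str, np.ndarray] = {}
    exon_lengths: dict[str, np.ndarray] = {}
    excluded: list[tuple[str, str]] = []
    for tid, sub in counts.counts.groupby(level="transcript_id", sort=False):
        t = ann[tid]
        sub = sub.droplevel("transcript_id").sort_index()
        raw = sub.to_numpy(dtype=float)  # exons (genomic order) x specimens
        if t.n_exons < min_exons:
            excluded.append((tid, "too_few_exons"))
            continue
        if raw.mean() < min_mean_count:
            excluded.append((tid, "low_expression"))
            continue
        lens_gen = np.array([e - s for s, e in t.exons], dtype=float)
        dens = raw / lens_gen[:, None] / sf[None, :]
        order = t.genomic_to_transcript_order()
        densities[tid] = dens[order].T  # specimens x exons, 5'->3'
        exon_lengths[tid] = lens_gen[order]
    pset = ProfileSet(
        densities=densities,
        exon_lengths=exon_lengths,
        specimens=counts.specimens,
        meta=counts.meta,
        factors=factors,
    )
    return pset, excluded


def coverage_groups_filter(profiles: ProfileSet, strata: LengthStrata) -> ProfileSet:
    """Restrict profiles to the long length stratum.

    Coverage comparison is meaningful only for transcripts long enough that
    an elongation block reshapes the profile; with the default boundaries
    this keeps transcripts longer than 1300 nt.
    """
    long_ids = strata.members("long")
    return profiles.restrict(long_ids)
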