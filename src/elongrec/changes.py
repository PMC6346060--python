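"""Coverage-profile change detection, cross-group dissimilarity comparison,
and recovery-wavefront estimation.

A transcript's profile is called *changed* by treatment when the Pearson
correlation between treated and untreated replicate profiles falls below a
threshold (default 0.2) for **every** (treated, untreated) replicate pair.
Recovery dissimilarity per transcript is ``1 - mean Pearson`` between
untreated and recovery profiles; the integrative-correlation comparison
(ICC) then asks whether two genotype groups agree in these per-transcript
dissimilarities, with permutation nulls for both the correlation band and
the mean group difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .profiles import CoverageProfile, ProfileSet

__all__ = [
    "ChangeCall",
    "ICCResult",
    "profile_pearson",
    "detect_changed",
    "changed_set",
    "dissimilarities",
    "icc_compare",
    "estimate_wavefront",
    "BEYOND_TRANSCRIPT_END",
]

BEYOND_TRANSCRIPT_END = float("inf")


def _pearson(x: np.ndarray, y: np.ndarray) -> float | None:
    """Pearson r, or None when either vector has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc**2))
    sy = np.sqrt(np.sum(yc**2))
    if sx == 0.0 or sy == 0.0:
        return None
    return float(np.clip(np.sum(xc * yc) / (sx * sy), -1.0, 1.0))


def profile_pearson(p: CoverageProfile, q: CoverageProfile) -> float | None:
    """Pearson correlation between two profiles of the same transcript.

    Returns None (undefined) when either profile has zero variance.
    """
    if p.transcript_id != q.transcript_id:
        raise ValidationError(
            f"profiles belong to different transcripts: {p.transcript_id} vs "
            f"{q.transcript_id}"
        )
    if p.values.shape != q.values.shape:
        raise ValidationError(
            f"transcript {p.transcript_id}: profile lengths differ"
        )
    if p.values.size < 2:
        raise ValidationError(
            f"transcript {p.transcript_id}: need >= 2 exons for a correlation"
        )
    return _pearson(p.values, q.values)


@dataclass(frozen=True)
class ChangeCall:
    """Replicate-pair Pearson screen for one transcript in one group.

    ``r_values`` has one row per treated replicate and one column per
    untreated replicate; NaN marks an undefined correlation (zero-variance
    profile). ``changed`` requires every pair to be defined and below the
    threshold — an undefined correlation vetoes the call.
    """

    transcript_id: str
    group: str
    r_values: np.ndarray
    threshold: float
    changed: bool

    @property
    def min_r(self) -> float:
        return float(np.nanmin(self.r_values)) if np.any(~np.isnan(self.r_values)) else float("nan")

    @property
    def max_r(self) -> float:
        return float(np.nanmax(self.r_values)) if np.any(~np.isnan(self.r_values)) else float("nan")


def detect_changed(
    profiles: ProfileSet,
    group: str,
    threshold: float = 0.2,
    treated: str = "R0",
    untreated: str = "Untr",
) -> list[ChangeCall]:
    """Screen every transcript for a treatment-altered coverage profile.

    For each transcript, Pearson r is computed for every (treated replicate,
    untreated replicate) pair; the transcript is flagged when all pairs are
    defined and strictly below ``threshold``.
    """
    treated_ids = profiles.select_specimens(group=group, condition=treated)
    untr_ids = profiles.select_specimens(group=group, condition=untreated)
    if not treated_ids or not untr_ids:
        raise ParameterError(
            f"group {group!r} lacks specimens for condition "
            f"{treated if not treated_ids else untreated!r}"
        )
    t_rows = [profiles.specimens.index(s) for s in treated_ids]
    u_rows = [profiles.specimens.index(s) for s in untr_ids]
    calls = []
    for tid in profiles.transcript_ids:
        mat = profiles.densities[tid]
        r = np.full((len(t_rows), len(u_rows)), np.nan)
        for i, tr in enumerate(t_rows):
            for j, ur in enumerate(u_rows):
                val = _pearson(mat[tr], mat[ur])
                if val is not None:
                    r[i, j] = val
        changed = bool(np.all(np.isfinite(r)) and np.all(r < threshold))
        calls.append(
            ChangeCall(
                transcript_id=tid,
                group=group,
                r_values=r,
                threshold=threshold,
                changed=changed,
            )
        )
    return calls


def changed_set(calls: Iterable[ChangeCall]) -> set[str]:
    return {c.transcript_id for c in calls if c.changed}


def calls_to_frame(calls: Iterable[ChangeCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "transcript_id": c.transcript_id,
                "group": c.group,
                "min_r": c.min_r,
                "max_r": c.max_r,
                "n_undefined": int(np.sum(np.isnan(c.r_values))),
                "changed": c.changed,
            }
            for c in calls
        ]
    )


def dissimilarities(
    profiles: ProfileSet,
    group: str,
    recovery: str = "R15",
    untreated: str = "Untr",
    transcripts: Sequence[str] | None = None,
) -> pd.Series:
    """Per-transcript recovery dissimilarity ``d = 1 - mean pair Pearson``.

    The mean runs over all (untreated, recovery) replicate pairs with a
    defined correlation; a transcript where every pair is undefined gets NaN.
    ``d`` lies in [0, 2].
    """
    u_ids = profiles.select_specimens(group=group, condition=untreated)
    r_ids = profiles.select_specimens(group=group, condition=recovery)
    if not u_ids or not r_ids:
        raise ParameterError(f"group {group!r} lacks {untreated!r} or {recovery!r} specimens")
    u_rows = [profiles.specimens.index(s) for s in u_ids]
    r_rows = [profiles.specimens.index(s) for s in r_ids]
    tids = list(transcripts) if transcripts is not None else profiles.transcript_ids
    out = {}
    for tid in tids:
        mat = profiles.densities[tid]
        rs = [
            v
            for ur in u_rows
            for rr in r_rows
            if (v := _pearson(mat[ur], mat[rr])) is not None
        ]
        out[tid] = 1.0 - float(np.mean(rs)) if rs else float("nan")
    return pd.Series(out, name=f"d_{group}_{untreated}_vs_{recovery}")


@dataclass(frozen=True)
class ICCResult:
    """Cross-group agreement of per-transcript recovery dissimilarities."""

    icc: float
    per_transcript_delta: pd.Series = field(repr=False)
    null_band: tuple[float, float]
    mean_delta: float
    delta_band: tuple[float, float]
    consistent_difference: bool
    n_transcripts: int


def icc_compare(
    d_a: pd.Series,
    d_b: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
) -> ICCResult:
    """Compare two groups' recovery-dissimilarity vectors.

    ``icc`` is the Pearson correlation across shared transcripts between the
    two vectors; its ``null_band`` is the central 95% interval under random
    permutation of group-B transcript labels. ``consistent_difference`` is
    a paired permutation test on the mean of ``d_a - d_b``: group labels are
    swapped independently per transcript (equivalently the deltas are
    sign-flipped) and the observed mean must fall outside the null's central
    95% interval.
    """
    shared = d_a.index.intersection(d_b.index)
    a = d_a.loc[shared].to_numpy(dtype=float)
    b = d_b.loc[shared].to_numpy(dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    kept = shared[ok]
    if len(a) < 3:
        raise ParameterError(
            f"icc_compare needs >= 3 shared transcripts with defined "
            f"dissimilarities, got {len(a)}"
        )
    rng = np.random.default_rng(seed)
    icc = _pearson(a, b)
    icc = float("nan") if icc is None else icc

    # Null band for the correlation: permute B's transcript labels.
    perm_r = np.empty(n_perm)
    for k in range(n_perm):
        pb = rng.permutation(b)
        v = _pearson(a, pb)
        perm_r[k] = np.nan if v is None else v
    null_band = (
        float(np.nanpercentile(perm_r, 2.5)),
        float(np.nanpercentile(perm_r, 97.5)),
    )

    delta = a - b
    mean_delta = float(delta.mean())
    signs = rng.choice([-1.0, 1.0], size=(n_perm, len(delta)))
    null_means = (signs * delta[None, :]).mean(axis=1)
    delta_band = (
        float(np.percentile(null_means, 2.5)),
        float(np.percentile(null_means, 97.5)),
    )
    consistent = bool(mean_delta < delta_band[0] or mean_delta > delta_band[1])
    return ICCResult(
        icc=icc,
        per_transcript_delta=pd.Series(delta, index=kept, name="delta"),
        null_band=null_band,
        mean_delta=mean_delta,
        delta_band=delta_band,
        consistent_difference=consistent,
        n_transcripts=len(a),
    )


def estimate_wavefront(untr: CoverageProfile, rec: CoverageProfile) -> float:
    """Estimate the recovery wavefront position (nt from the TSS).

    Fits a one-changepoint step (high plateau, then low plateau) to the
    per-exon ratio recovery/untreated over exon midpoints by exhaustive
    least-squares changepoint search, and returns the changepoint
    interpolated midway between the flanking exon midpoints. Returns
    ``BEYOND_TRANSCRIPT_END`` (inf) when no exon drops below half the high
    plateau, i.e. the transcript looks fully recovered.
    """
    if untr.transcript_id != rec.transcript_id:
        raise ValidationError("wavefront estimation needs profiles of one transcript")
    if untr.values.size < 4:
        raise ValidationError(
            f"transcript {untr.transcript_id}: need >= 4 exons for changepoint fit"
        )
    defined = untr.values > 0
    if np.sum(~defined) > untr.values.size / 2:
        raise ValidationError(
            f"transcript {untr.transcript_id}: untreated density is zero on "
            "more than half of the exons; ratio profile unstable"
        )
    ratio = rec.values[defined] / untr.values[defined]
    pos = untr.midpoints[defined]
    m = ratio.size
    if m < 4:
        raise ValidationError(
            f"transcript {untr.transcript_id}: fewer than 4 exons with "
            "defined ratios"
        )
    # O(m) exhaustive scan via prefix sums: split after exon j has
    # SSE = SS_total(left) + SS_total(right) around the two segment means.
    cs = np.concatenate([[0.0], np.cumsum(ratio)])
    cs2 = np.concatenate([[0.0], np.cumsum(ratio**2)])
    j = np.arange(1, m)
    left_n, right_n = j, m - j
    left_sum, right_sum = cs[j], cs[m] - cs[j]
    left_ss = cs2[j] - left_sum**2 / left_n
    right_ss = (cs2[m] - cs2[j]) - right_sum**2 / right_n
    sse = left_ss + right_ss
    best = int(np.argmin(sse))
    high = left_sum[best] / left_n[best]
    if not np.any(ratio < high / 2.0):
        return BEYOND_TRANSCRIPT_END
    split = j[best]
    return float((pos[split - 1] + pos[split]) / 2.0)
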