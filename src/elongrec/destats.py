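"""Differential expression, gene-length association, and pattern clustering.

The differential test is a generic negative-binomial Wald test: counts are
size-factor normalized, per-feature dispersions are method-of-moments
estimates shrunk 50% toward the global mean dispersion, and the Wald
statistic is the log2 fold change over its delta-method standard error.
Benjamini-Hochberg is the multiple-testing adjustment throughout; calls are
made by named threshold presets with inclusive comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

from .annotation import TranscriptAnnotation, annotation_index
from .errors import ParameterError, ValidationError
from .profiles import size_factors
from .tables import CountsTable

__all__ = [
    "ThresholdPreset",
    "PRESETS",
    "PatternCluster",
    "nb_de_test",
    "apply_preset",
    "length_association",
    "log2ratio_matrix",
    "cluster_patterns",
]

PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class ThresholdPreset:
    """A named call rule over (fold change, adjusted p)."""

    name: str
    max_padj: float
    min_abs_log2fc: float | None = None
    min_abs_fc: float | None = None

    def called(self, log2fc: np.ndarray, padj: np.ndarray) -> np.ndarray:
        if self.min_abs_log2fc is not None:
            fc_ok = np.abs(log2fc) >= self.min_abs_log2fc
        elif self.min_abs_fc is not None:
            # linear fold change: |FC| = 2**|log2FC|
            fc_ok = 2.0 ** np.abs(log2fc) >= self.min_abs_fc
        else:
            raise ParameterError(f"preset {self.name}: no fold-change bound")
        return fc_ok & (padj <= self.max_padj)


PRESETS: Mapping[str, ThresholdPreset] = {
    # transcript-level nascent RNA-seq rule: |log2FC| >= 1 and adjusted p <= 0.1
    "transcript_preset": ThresholdPreset(
        name="transcript_preset", max_padj=0.1, min_abs_log2fc=1.0
    ),
    # depolarization RNA-seq rule: |FC| >= 1.5 and FDR <= 0.05
    "kcl_preset": ThresholdPreset(name="kcl_preset", max_padj=0.05, min_abs_fc=1.5),
}


def _select(meta: pd.DataFrame, selector: Mapping[str, object]) -> list[str]:
    mask = pd.Series(True, index=meta.index)
    for key, value in selector.items():
        if key not in meta.columns:
            raise ParameterError(f"unknown metadata column {key!r} in selector")
        mask &= meta[key] == value
    return list(meta.index[mask])


def nb_de_test(
    counts: CountsTable | pd.DataFrame,
    group_a: Mapping[str, object] | Sequence[str],
    group_b: Mapping[str, object] | Sequence[str],
    meta: pd.DataFrame | None = None,
    min_mean: float = 5.0,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Negative-binomial Wald differential test between two specimen sets.

    Parameters
    ----------
    counts
        A CountsTable (features = exon rows) or a plain feature-by-specimen
        integer DataFrame (e.g. transcript totals).
    group_a, group_b
        Either metadata selectors (``{"group": "WT", "condition": "R0"}``)
        or explicit specimen-id lists. ``log2fc`` is b over a.
    min_mean
        Independent filter: features with mean normalized count below this
        across the selected specimens are excluded before testing.

    Returns
    -------
    DataFrame indexed by feature id with columns mean_a, mean_b, log2fc,
    stat, p, padj.
    """
    if isinstance(counts, CountsTable):
        df = counts.transcript_totals() if counts.counts.index.nlevels == 2 else counts.counts
        meta = counts.meta
    else:
        df = counts
    if isinstance(group_a, Mapping) or isinstance(group_b, Mapping):
        if meta is None:
            raise ParameterError("metadata required when selecting by criteria")
        ids_a = _select(meta, group_a) if isinstance(group_a, Mapping) else list(group_a)
        ids_b = _select(meta, group_b) if isinstance(group_b, Mapping) else list(group_b)
    else:
        ids_a, ids_b = list(group_a), list(group_b)
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ParameterError(
            f"each side needs >= 2 replicates, got {len(ids_a)} and {len(ids_b)}"
        )
    sub = df[ids_a + ids_b]
    sf = size_factors(sub)
    norm = sub.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    na, nb = len(ids_a), len(ids_b)
    xa, xb = norm[:, :na], norm[:, na:]

    keep = norm.mean(axis=1) >= min_mean
    features = df.index[keep]
    xa, xb = xa[keep], xb[keep]
    if len(features) == 0:
        raise ValidationError("no feature passed the mean-count filter")

    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    va = xa.var(axis=1, ddof=1)
    vb = xb.var(axis=1, ddof=1)

    # Method-of-moments dispersion per group, averaged, then shrunk 50%
    # toward the global mean dispersion (a deliberately simple stabilizer).
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_a = np.where(ma > 0, (va - ma) / ma**2, 0.0)
        phi_b = np.where(mb > 0, (vb - mb) / mb**2, 0.0)
    phi = np.clip((phi_a + phi_b) / 2.0, 0.0, None)
    phi = 0.5 * phi + 0.5 * phi.mean()

    log2fc = np.log2((mb + pseudocount) / (ma + pseudocount))
    var_ma = (ma + phi * ma**2) / na
    var_mb = (mb + phi * mb**2) / nb
    ln2 = np.log(2.0)
    se = np.sqrt(
        var_ma / ((ma + pseudocount) * ln2) ** 2
        + var_mb / ((mb + pseudocount) * ln2) ** 2
    )
    stat = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * sps.norm.sf(np.abs(stat))
    padj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "mean_a": ma,
            "mean_b": mb,
            "log2fc": log2fc,
            "stat": stat,
            "p": p,
            "padj": padj,
        },
        index=pd.Index(features, name="feature_id"),
    )


def apply_preset(
    results: pd.DataFrame, preset: ThresholdPreset | str
) -> tuple[set, set]:
    """Call features under a threshold preset; returns (up set, down set).

    Adds ``called`` and ``direction`` columns to ``results`` in place.
    Comparisons are inclusive exactly as the rules are printed; direction is
    the sign of the log2 fold change.
    """
    if isinstance(preset, str):
        if preset not in PRESETS:
            raise ParameterError(f"unknown preset {preset!r}; have {sorted(PRESETS)}")
        preset = PRESETS[preset]
    called = preset.called(results["log2fc"].to_numpy(), results["padj"].to_numpy())
    up = called & (results["log2fc"].to_numpy() > 0)
    down = called & (results["log2fc"].to_numpy() < 0)
    results["called"] = called
    results["direction"] = np.where(up, "up", np.where(down, "down", "none"))
    return set(results.index[up]), set(results.index[down])


def length_association(
    results: pd.DataFrame,
    annotation: Iterable[TranscriptAnnotation] | Mapping[str, TranscriptAnnotation] | Mapping[str, int],
    direction: str = "down",
) -> dict:
    """Association between gene length and the differential statistic.

    Within the called features of ``direction``, computes Pearson R between
    log10 length and the Wald statistic; also reports the mean length of the
    up- and down-called sets and a two-sided rank-sum test on their log10
    lengths.
    """
    if direction not in ("up", "down"):
        raise ParameterError("direction must be 'up' or 'down'")
    if "direction" not in results.columns:
        raise ParameterError("results must be annotated by apply_preset first")
    ann = annotation if isinstance(annotation, Mapping) else annotation_index(annotation)
    lengths = {
        k: (v.length if isinstance(v, TranscriptAnnotation) else int(v))
        for k, v in ann.items()
    }
    sets = {
        d: results.index[(results["direction"] == d)].tolist() for d in ("up", "down")
    }
    sel = sets[direction]
    if len(sel) < 3:
        raise ValidationError(
            f"need >= 3 {direction}-called features for the length association, "
            f"got {len(sel)}"
        )
    loglen = np.log10([lengths[f] for f in sel])
    stat = results.loc[sel, "stat"].to_numpy()
    r = float(np.corrcoef(loglen, stat)[0, 1])
    len_up = np.array([lengths[f] for f in sets["up"]], dtype=float)
    len_down = np.array([lengths[f] for f in sets["down"]], dtype=float)
    if len(len_up) and len(len_down):
        p_loc = float(
            sps.ranksums(np.log10(len_down), np.log10(len_up)).pvalue
        )
    else:
        p_loc = float("nan")
    return {
        "R": r,
        "n": len(sel),
        "mean_length_up": float(len_up.mean()) if len(len_up) else float("nan"),
        "mean_length_down": float(len_down.mean()) if len(len_down) else float("nan"),
        "location_test_p": p_loc,
    }


def log2ratio_matrix(
    counts: CountsTable,
    baseline: str = "Untr",
    conditions: Sequence[str] = ("R0", "R15", "R30"),
    pseudocount: float = PSEUDOCOUNT,
    features: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Feature x (group, condition) matrix of log2 treated/baseline ratios.

    Transcript totals are size-factor normalized and averaged over
    replicates within each (group, condition) before the ratio.
    """
    totals = counts.transcript_totals()
    sf = size_factors(totals)
    norm = totals / sf
    cols = {}
    for group in counts.meta["group"].unique():
        base_ids = counts.select_specimens(group=group, condition=baseline)
        if not base_ids:
            raise ParameterError(f"group {group!r} lacks baseline {baseline!r}")
        base = norm[base_ids].mean(axis=1)
        for cond in conditions:
            ids = counts.select_specimens(group=group, condition=cond)
            if not ids:
                continue
            treated = norm[ids].mean(axis=1)
            cols[(group, cond)] = np.log2(
                (treated + pseudocount) / (base + pseudocount)
            )
    mat = pd.DataFrame(cols, index=totals.index)
    mat.columns = pd.MultiIndex.from_tuples(mat.columns, names=["group", "condition"])
    if features is not None:
        mat = mat.loc[[f for f in features if f in mat.index]]
    return mat


ARCHETYPES = (
    "similar_both",
    "up_in_AT",
    "up_in_AT_after_washout",
    "down_in_AT",
    "other",
)


@dataclass(frozen=True)
class PatternCluster:
    """One expression-pattern cluster with its archetype label."""

    cluster_id: int
    members: tuple[str, ...]
    mean_profile: pd.Series = field(repr=False)
    archetype: str


def _archetype(mean_profile: pd.Series, delta: float) -> str:
    groups = mean_profile.index.get_level_values("group").unique()
    if not {"WT", "AT"}.issubset(set(groups)):
        return "other"
    conditions = mean_profile.loc["WT"].index
    diff = mean_profile.loc["AT"].reindex(conditions) - mean_profile.loc["WT"]
    washout = [c for c in conditions if c in ("R15", "R30")]
    immediate = [c for c in conditions if c not in ("R15", "R30")]
    if (diff.abs() < delta).all():
        return "similar_both"
    if (diff > delta).all():
        return "up_in_AT"
    if (diff < -delta).all():
        return "down_in_AT"
    if washout and (diff[washout] > delta).all() and (diff[immediate].abs() <= delta).all():
        return "up_in_AT_after_washout"
    return "other"


def cluster_patterns(
    matrix: pd.DataFrame, k: int = 4, delta: float = 0.5
) -> list[PatternCluster]:
    """Hierarchical clustering of expression-pattern profiles.

    Agglomerative clustering with Euclidean distance and average linkage,
    cut into ``k`` flat clusters; each cluster is labelled with an archetype
    by comparing its mean AT and WT profiles condition-wise against a
    ``delta`` log2-unit margin.
    """
    values = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValidationError("pattern matrix contains non-finite entries")
    if len(matrix) < k:
        raise ParameterError(f"cannot cut {len(matrix)} features into {k} clusters")
    if len(matrix) == k:
        labels = np.arange(1, k + 1)
    else:
        z = linkage(values, method="average", metric="euclidean")
        labels = fcluster(z, t=k, criterion="maxclust")
    clusters = []
    for cid in sorted(np.unique(labels)):
        idx = np.where(labels == cid)[0]
        members = tuple(matrix.index[idx])
        mean_profile = matrix.iloc[idx].mean(axis=0)
        clusters.append(
            PatternCluster(
                cluster_id=int(cid),
                members=members,
                mean_profile=mean_profile,
                archetype=_archetype(mean_profile, delta)
                if isinstance(matrix.columns, pd.MultiIndex)
                else "other",
            )
        )
    return clusters
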