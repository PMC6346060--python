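"""Reproducible in-silico studies of the pipeline's operating characteristics.

Each function runs the full analysis path (simulate -> profiles -> screen /
compare / test) under a declared study condition and measures an operating
characteristic: null calibration and power of the cross-group recovery
comparison, sensitivity and false-positive rate of the coverage screen,
wavefront-recovery error, the gene-length association signature, and the
type-I error of the differential test.

Study conditions are fixed here, once, as the package's reference
conditions; problem sizes are chosen so each study completes in minutes on
one CPU.
"""

from __future__ import annotations

import numpy as np

from . import changes, destats
from .annotation import stratify_by_length
from .profiles import build_profiles, coverage_groups_filter
from .sim import SimConfig, simulate

__all__ = [
    "coverage_study_config",
    "screening_study_config",
    "icc_study",
    "icc_rejection_rate",
    "screening_rates",
    "wavefront_study",
    "length_association_study",
    "de_null_study",
]

WT_VELOCITY = 1500.0  # nt/min
RECOVERY_TIME = {"R15": 15.0, "R30": 30.0}


def coverage_study_config(
    seed: int, n_transcripts: int = 300, velocity_ratio: float = 1.0
) -> SimConfig:
    """Long-transcript condition for recovery-dissimilarity comparisons.

    Genes of ~25-60 kb, so the 15 min wavefront (22.5 kb in WT) falls inside
    most gene bodies; ``velocity_ratio`` scales the AT group's recovery
    velocity (1.0 = null, 0.5 = halved recovery).
    """
    return SimConfig(
        n_transcripts=n_transcripts,
        length_log10_mean=4.6,
        length_log10_sd=0.2,
        recovery_velocity_wt=WT_VELOCITY,
        recovery_velocity_at=WT_VELOCITY * velocity_ratio,
        seed=seed,
    )


def screening_study_config(seed: int, n_transcripts: int = 100, blocked: bool = True) -> SimConfig:
    """Very long genes (~70-140 kb) for the profile-change screen.

    ``blocked=False`` sets the lesion density to zero in both groups, giving
    the unaffected condition used to measure the false-positive rate.
    """
    lam = SimConfig().lesion_density_wt if blocked else 0.0
    return SimConfig(
        n_transcripts=n_transcripts,
        length_log10_mean=5.0,
        length_log10_sd=0.15,
        lesion_density_wt=lam,
        lesion_density_at=lam,
        seed=seed,
    )


def _long_profiles(config: SimConfig):
    result = simulate(config)
    pset, _ = build_profiles(result.counts, result.annotation)
    strata = stratify_by_length({t.transcript_id: t.length for t in result.annotation})
    return result, coverage_groups_filter(pset, strata)


def icc_study(seed: int, velocity_ratio: float = 1.0, recovery: str = "R15",
              n_transcripts: int = 300, n_perm: int = 1000) -> changes.ICCResult:
    """One simulated experiment pushed through screen + ICC comparison.

    The compared transcript set is the union of the per-group changed calls,
    as in the analysis pipeline.
    """
    config = coverage_study_config(seed, n_transcripts, velocity_ratio)
    _, long_pset = _long_profiles(config)
    union = sorted(
        changes.changed_set(changes.detect_changed(long_pset, "WT"))
        | changes.changed_set(changes.detect_changed(long_pset, "AT"))
    )
    d_at = changes.dissimilarities(long_pset, "AT", recovery=recovery, transcripts=union)
    d_wt = changes.dissimilarities(long_pset, "WT", recovery=recovery, transcripts=union)
    return changes.icc_compare(d_at, d_wt, n_perm=n_perm, seed=seed + 1)


def icc_rejection_rate(
    n_runs: int, seed: int, velocity_ratio: float = 1.0, n_transcripts: int = 300
) -> float:
    """Fraction of seeded runs reporting a consistent group difference."""
    hits = [
        icc_study(seed + k, velocity_ratio, n_transcripts=n_transcripts).consistent_difference
        for k in range(n_runs)
    ]
    return float(np.mean(hits))


def screening_rates(n_seeds: int, seed: int) -> tuple[float, float]:
    """(sensitivity, false-positive rate) of the all-pairs r<0.2 screen.

    Sensitivity: fraction of profiled long transcripts flagged in a blocked
    simulation. FPR: fraction flagged when the lesion density is zero.
    Rates are pooled over ``n_seeds`` independent simulations.
    """
    flagged_b, total_b, flagged_u, total_u = 0, 0, 0, 0
    for k in range(n_seeds):
        _, pset = _long_profiles(screening_study_config(seed + k, blocked=True))
        calls = changes.detect_changed(pset, "WT")
        flagged_b += sum(c.changed for c in calls)
        total_b += len(calls)
        _, pset0 = _long_profiles(screening_study_config(seed + k, blocked=False))
        calls0 = changes.detect_changed(pset0, "WT")
        flagged_u += sum(c.changed for c in calls0)
        total_u += len(calls0)
    return flagged_b / total_b, flagged_u / total_u


def wavefront_study(seed: int, noiseless: bool = False, n_transcripts: int = 60) -> dict:
    """Recovery-wavefront estimation error against the simulator's truth.

    Estimates the 15 min wavefront (truth ``v * t`` = 22.5 kb in WT) on
    transcripts long enough to contain it, from replicate-averaged profiles.
    Returns the per-transcript errors plus summary statistics: the maximum
    absolute error in units of the transcript's widest exon (noiseless runs)
    and the median relative error (noisy runs).
    """
    w_true = WT_VELOCITY * RECOVERY_TIME["R15"]
    if noiseless:
        config = SimConfig(
            n_transcripts=n_transcripts,
            length_log10_mean=4.6,
            length_log10_sd=0.1,
            depth=2000.0,
            dispersion=0.0,
            exon_bias_log_sd=0.0,
            init_log10_sd=0.0,
            n_reps=1,
            seed=seed,
        )
    else:
        config = SimConfig(
            n_transcripts=n_transcripts,
            length_log10_mean=4.6,
            length_log10_sd=0.1,
            seed=seed,
        )
    result, pset = _long_profiles(SimConfig(**{**config.__dict__}))
    untr_ids = pset.select_specimens(group="WT", condition="Untr")
    rec_ids = pset.select_specimens(group="WT", condition="R15")
    abs_err_exons, rel_err = [], []
    for tid in pset.transcript_ids:
        if result.truth.transcripts.loc[tid, "length"] < 1.3 * w_true:
            continue
        est = changes.estimate_wavefront(
            pset.mean_profile(tid, untr_ids), pset.mean_profile(tid, rec_ids)
        )
        if not np.isfinite(est):
            continue
        abs_err_exons.append(abs(est - w_true) / pset.exon_lengths[tid].max())
        rel_err.append(abs(est - w_true) / w_true)
    return {
        "n": len(rel_err),
        "max_abs_err_exon_spans": float(np.max(abs_err_exons)) if abs_err_exons else float("nan"),
        "median_rel_err": float(np.median(rel_err)) if rel_err else float("nan"),
    }


def length_association_study(seed: int) -> dict:
    """CPT-response differential expression and its gene-length signature.

    Runs the transcript-level NB test (R0 vs Untr in WT) on a default
    simulated experiment and returns the down-set length-association
    summary: Pearson R between log10 length and the Wald statistic within
    down-called transcripts, and the mean lengths of the up and down sets.
    """
    result = simulate(SimConfig(seed=seed))
    res = destats.nb_de_test(
        result.counts,
        {"group": "WT", "condition": "Untr"},
        {"group": "WT", "condition": "R0"},
    )
    destats.apply_preset(res, "transcript_preset")
    lengths = result.truth.transcripts["length"].to_dict()
    return destats.length_association(res, lengths, "down")


def de_null_study(seed: int, n_features: int = 2000) -> dict:
    """Type-I error of the NB Wald test on a null comparison.

    Simulates ``n_features`` unperturbed transcripts and compares the two
    genotypes' untreated triplicates (identically distributed by
    construction). Reports the empirical rate of raw p < 0.05 and the number
    of calls under each threshold preset.
    """
    config = SimConfig(
        n_transcripts=n_features,
        length_log10_mean=3.3,
        length_log10_sd=0.3,
        lesion_density_wt=0.0,
        lesion_density_at=0.0,
        ieg_fraction=0.0,
        seed=seed,
    )
    result = simulate(config)
    res = destats.nb_de_test(
        result.counts,
        {"group": "WT", "condition": "Untr"},
        {"group": "AT", "condition": "Untr"},
    )
    out = {"n_tested": len(res), "type1_at_0.05": float((res["p"] < 0.05).mean())}
    for name in destats.PRESETS:
        up, down = destats.apply_preset(res.copy(), name)
        out[f"calls_{name}"] = len(up) + len(down)
    return out
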