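"""Generative model for nascent-RNA exon counts under Top1cc block and recovery.

The model tracks RNA Pol II density along each transcript (position x in
transcript coordinates, nt from the TSS):

* untreated: uniform density ``a`` (steady-state elongation);
* under a 1 hr camptothecin pulse (condition R0): polymerases survive past
  independently placed Top1cc lesions of density ``lam`` per nt, giving
  ``d(x) = a * exp(-lam * x)``;
* t minutes after washout (R15/R30): a new initiation wave has re-elongated
  to the wavefront ``w = v * t``, so ``d(x) = a`` for ``x <= w`` and a
  residual branch ``d(x) = a * (r + (1 - r) * exp(-lam * x))`` beyond it;
* short immediate-early genes are induced ``ieg_fold``-fold in every treated
  condition.

Exon counts are negative binomial with mean ``c * integral of d over the
exon`` (times per-exon capture bias and per-specimen depth) and variance
``mu + phi * mu**2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd

from .annotation import TranscriptAnnotation
from .errors import ParameterError, ValidationError
from .tables import CountsTable, CONDITIONS, GROUPS

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimResult",
    "DensityParams",
    "expected_density",
    "exon_expected_signal",
    "simulate",
    "RECOVERY_MINUTES",
]

RECOVERY_MINUTES = {"R15": 15.0, "R30": 30.0}

# Specimens are generated in this fixed order; the random stream is consumed
# in the same order, so a given seed always yields the same table.
SPECIMEN_ORDER = [
    (g, c) for g in GROUPS for c in CONDITIONS
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator.

    Defaults emulate human iPSC-derived neurons given a 1 hr camptothecin
    pulse then sampled untreated / at washout / 15 and 30 min into recovery,
    in two genotypes (WT and ATM-deficient), three replicates each.

    Parameters
    ----------
    n_transcripts
        Number of simulated transcripts.
    length_log10_mean, length_log10_sd
        Transcript lengths are drawn log-normal (base 10) and floored at
        ``min_length`` nt.
    exon_target_len
        Transcripts are split into exons of approximately this many nt.
    init_density
        Baseline polymerase density ``a`` (polymerases per nt); per-transcript
        baselines vary log-normally around it with ``init_log10_sd``.
    lesion_density_wt, lesion_density_at
        Top1cc lesion density ``lam`` per nt under CPT, per genotype.
    recovery_velocity_wt, recovery_velocity_at
        Post-washout elongation velocity ``v`` in nt per minute.
    residual_fraction
        Fraction ``r`` of baseline density persisting beyond the recovery
        wavefront.
    ieg_fraction, ieg_fold, ieg_max_length
        Proportion of transcripts no longer than ``ieg_max_length`` nt that
        behave as immediate-early genes, and their fold induction under
        treatment.
    depth
        Expected reads per unit of (density * nt), the sequencing depth scale.
    dispersion
        Negative-binomial dispersion ``phi`` (0 degenerates to Poisson).
    exon_bias_log_sd
        SD (natural log) of the per-exon multiplicative capture/mappability
        bias, shared by all specimens; this is what makes replicate coverage
        profiles of an unperturbed transcript correlate.
    specimen_depth_log_sd
        SD (natural log) of per-specimen library-depth factors. The default
        keeps depth fixed: a depth effect is shared by every transcript in a
        specimen, which correlates dissimilarities across transcripts and
        invalidates transcript-level permutation nulls (see the methods
        note); enable it only to stress size-factor estimation.
    n_reps
        Replicates per (group, condition).
    seed
        Seed for the single random stream governing lengths, exonization,
        biases and counts.
    """

    n_transcripts: int = 200
    length_log10_mean: float = 3.9
    length_log10_sd: float = 0.7
    min_length: int = 200
    exon_target_len: int = 300
    init_density: float = 0.01
    init_log10_sd: float = 0.5
    lesion_density_wt: float = 1e-3
    lesion_density_at: float = 1e-3
    recovery_velocity_wt: float = 1500.0
    recovery_velocity_at: float = 1500.0
    residual_fraction: float = 0.1
    ieg_fraction: float = 0.1
    ieg_fold: float = 8.0
    ieg_max_length: int = 2000
    depth: float = 20.0
    dispersion: float = 0.05
    exon_bias_log_sd: float = 0.5
    specimen_depth_log_sd: float = 0.0
    n_reps: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts < 1:
            raise ParameterError("n_transcripts must be >= 1")
        if self.lesion_density_wt < 0 or self.lesion_density_at < 0:
            raise ParameterError("lesion densities must be >= 0")
        if self.recovery_velocity_wt <= 0 or self.recovery_velocity_at <= 0:
            raise ParameterError("recovery velocities must be > 0")
        if not 0.0 <= self.residual_fraction <= 1.0:
            raise ParameterError("residual_fraction must lie in [0, 1]")
        if self.dispersion < 0:
            raise ParameterError("dispersion must be >= 0")
        if self.depth <= 0:
            raise ParameterError("depth must be > 0")
        if self.n_reps < 1:
            raise ParameterError("n_reps must be >= 1")
        if not 0.0 <= self.ieg_fraction <= 1.0:
            raise ParameterError("ieg_fraction must lie in [0, 1]")

    def group_params(self, group: str) -> tuple[float, float]:
        if group == "WT":
            return self.lesion_density_wt, self.recovery_velocity_wt
        if group == "AT":
            return self.lesion_density_at, self.recovery_velocity_at
        raise ParameterError(f"unknown group {group!r}")


@dataclass(frozen=True)
class DensityParams:
    """Per-(transcript, group) slice of the generative parameters."""

    a: float
    lam: float
    v: float
    r: float
    length: float
    is_ieg: bool = False
    ieg_fold: float = 1.0


def expected_density(x, condition: str, params: DensityParams):
    """Expected polymerase density (per nt) at position(s) ``x`` from the TSS.

    Vectorized over ``x``; raises for positions outside ``[0, length)``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x >= params.length):
        raise ParameterError(
            f"position out of range [0, {params.length}): {x[(x < 0) | (x >= params.length)]}"
        )
    fold = params.ieg_fold if (params.is_ieg and condition != "Untr") else 1.0
    if condition == "Untr":
        d = np.full_like(x, params.a)
    elif condition == "R0":
        d = params.a * np.exp(-params.lam * x)
    elif condition in RECOVERY_MINUTES:
        w = params.v * RECOVERY_MINUTES[condition]
        residual = params.a * (
            params.r + (1.0 - params.r) * np.exp(-params.lam * x)
        )
        d = np.where(x <= w, params.a, residual)
    else:
        raise ParameterError(f"unknown condition {condition!r}")
    d = fold * d
    return float(d) if d.ndim == 0 else d


def _survival_integral(s, e, lam):
    """Integral of exp(-lam x) over [s, e), elementwise."""
    s = np.asarray(s, dtype=float)
    e = np.asarray(e, dtype=float)
    if lam == 0.0:
        return e - s
    return (np.exp(-lam * s) - np.exp(-lam * e)) / lam


def exon_expected_signal(s, e, condition: str, params: DensityParams):
    """Integral of the expected density over exon [s, e) in transcript coords."""
    s = np.asarray(s, dtype=float)
    e = np.asarray(e, dtype=float)
    fold = params.ieg_fold if (params.is_ieg and condition != "Untr") else 1.0
    if condition == "Untr":
        out = params.a * (e - s)
    elif condition == "R0":
        out = params.a * _survival_integral(s, e, params.lam)
    elif condition in RECOVERY_MINUTES:
        w = params.v * RECOVERY_MINUTES[condition]
        rec_len = np.clip(np.minimum(e, w) - s, 0.0, None)
        blk_lo = np.maximum(s, w)
        blk_len = np.clip(e - blk_lo, 0.0, None)
        blocked = np.where(
            blk_len > 0,
            params.r * blk_len
            + (1.0 - params.r) * _survival_integral(blk_lo, np.maximum(e, blk_lo), params.lam),
            0.0,
        )
        out = params.a * (rec_len + blocked)
    else:
        raise ParameterError(f"unknown condition {condition!r}")
    out = fold * out
    return float(out) if np.ndim(out) == 0 else out


@dataclass
class SimTruth:
    """Ground-truth generative parameters for parameter-recovery tests."""

    transcripts: pd.DataFrame  # index transcript_id
    groups: pd.DataFrame  # index group: lesion_density, recovery_velocity, residual_fraction
    config: SimConfig

    def params_for(self, transcript_id: str, group: str) -> DensityParams:
        t = self.transcripts.loc[transcript_id]
        g = self.groups.loc[group]
        return DensityParams(
            a=float(t["init_density"]),
            lam=float(g["lesion_density"]),
            v=float(g["recovery_velocity"]),
            r=float(g["residual_fraction"]),
            length=float(t["length"]),
            is_ieg=bool(t["is_ieg"]),
            ieg_fold=float(self.config.ieg_fold),
        )

    def write(self, path) -> None:
        self.transcripts.reset_index().to_csv(path, sep="\t", index=False)


@dataclass
class SimResult:
    annotation: list[TranscriptAnnotation]
    counts: CountsTable
    truth: SimTruth


def _split_exons(length: int, target: int) -> np.ndarray:
    """Split ``length`` nt into roughly equal exons of ~``target`` nt."""
    m = max(1, int(round(length / target)))
    base, extra = divmod(length, m)
    return np.array([base + 1] * extra + [base] * (m - extra), dtype=int)


def simulate(config: SimConfig) -> SimResult:
    """Generate annotation, counts and ground truth for one experiment.

    The random stream is consumed in a fixed documented order (lengths,
    strands, per-transcript baselines, exon biases, IEG flags, specimen
    depth factors, then counts specimen by specimen), so identical configs
    give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_transcripts

    lengths = np.maximum(
        config.min_length,
        np.round(10 ** rng.normal(config.length_log10_mean, config.length_log10_sd, n)),
    ).astype(int)
    strands = rng.choice(["+", "-"], size=n)
    init = config.init_density * 10 ** rng.normal(0.0, config.init_log10_sd, n)

    exon_lens = [_split_exons(L, config.exon_target_len) for L in lengths]
    exon_bias = [
        np.exp(rng.normal(0.0, config.exon_bias_log_sd, len(el))) for el in exon_lens
    ]
    eligible = lengths <= config.ieg_max_length
    is_ieg = eligible & (rng.random(n) < config.ieg_fraction)

    specimens = []
    for group, condition in SPECIMEN_ORDER:
        for rep in range(1, config.n_reps + 1):
            specimens.append((f"{group}_{condition}_{rep}", group, condition, rep))
    depth_factors = np.exp(
        rng.normal(0.0, config.specimen_depth_log_sd, len(specimens))
    )

    # Build annotation: transcripts laid head-to-tail on one chromosome with
    # 100 nt introns and 1000 nt intergenic gaps; exon splits are defined in
    # 5'->3' transcript order and mirrored into genomic order on '-'.
    annotation = []
    cursor = 0
    index_tuples = []
    for i in range(n):
        tid = f"T{i:05d}"
        el_tx = exon_lens[i]
        el_gen = el_tx[::-1] if strands[i] == "-" else el_tx
        exons = []
        pos = cursor
        for ln in el_gen:
            exons.append((pos, pos + int(ln)))
            pos += int(ln) + 100
        cursor = pos + 1000
        annotation.append(
            TranscriptAnnotation(
                transcript_id=tid,
                gene_id=f"G{i:05d}",
                chrom="chrS",
                strand=str(strands[i]),
                exons=tuple(exons),
            )
        )
        index_tuples.extend((tid, j) for j in range(len(el_tx)))

    # Expected signal per exon, per (group, condition), in transcript order.
    groups_df = pd.DataFrame(
        {
            "lesion_density": [config.lesion_density_wt, config.lesion_density_at],
            "recovery_velocity": [config.recovery_velocity_wt, config.recovery_velocity_at],
            "residual_fraction": [config.residual_fraction] * 2,
        },
        index=pd.Index(GROUPS, name="group"),
    )
    truth_df = pd.DataFrame(
        {
            "length": lengths,
            "n_exons": [len(el) for el in exon_lens],
            "strand": strands,
            "is_ieg": is_ieg,
            "init_density": init,
        },
        index=pd.Index([f"T{i:05d}" for i in range(n)], name="transcript_id"),
    )
    truth = SimTruth(transcripts=truth_df, groups=groups_df, config=config)

    base_mu = {}  # (group, condition) -> concatenated exon means, genomic order
    for group in GROUPS:
        for condition in CONDITIONS:
            parts = []
            for i in range(n):
                params = DensityParams(
                    a=float(init[i]),
                    lam=config.group_params(group)[0],
                    v=config.group_params(group)[1],
                    r=config.residual_fraction,
                    length=float(lengths[i]),
                    is_ieg=bool(is_ieg[i]),
                    ieg_fold=config.ieg_fold,
                )
                bounds = np.concatenate([[0], np.cumsum(exon_lens[i])]).astype(float)
                sig = exon_expected_signal(bounds[:-1], bounds[1:], condition, params)
                mu_tx = config.depth * exon_bias[i] * np.atleast_1d(sig)
                if strands[i] == "-":
                    mu_tx = mu_tx[::-1]  # store in genomic exon order
                parts.append(mu_tx)
            base_mu[(group, condition)] = np.concatenate(parts)

    columns = {}
    for j, (sid, group, condition, _rep) in enumerate(specimens):
        mu = base_mu[(group, condition)] * depth_factors[j]
        if config.dispersion == 0.0:
            draw = rng.poisson(mu)
        else:
            size = 1.0 / config.dispersion
            p = size / (size + mu)
            draw = rng.negative_binomial(size, p)
        columns[sid] = draw.astype(np.int64)

    counts_df = pd.DataFrame(
        columns,
        index=pd.MultiIndex.from_tuples(index_tuples, names=["transcript_id", "exon_index"]),
    )
    meta = pd.DataFrame(
        [(sid, g, c, r) for sid, g, c, r in specimens],
        columns=["specimen_id", "group", "condition", "replicate"],
    ).set_index("specimen_id")
    counts = CountsTable(counts_df, meta)
    return SimResult(annotation=annotation, counts=counts, truth=truth)
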