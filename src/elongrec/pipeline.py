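"""End-to-end orchestration: simulate -> profiles -> screening -> ICC ->
differential expression -> length association -> clustering -> report.

Every stage writes flat text artifacts (GTF / TSV / JSON) into the run
directory and registers them in a manifest with content hashes, so a rerun
with the same config and seed reproduces identical hashes and any stage can
be re-run standalone on externally supplied tables of the same shape.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict, fields
from pathlib import Path

import pandas as pd
import yaml

from . import annotation as ann_mod
from . import changes, destats, profiles as prof_mod, sim as sim_mod, tables
from .errors import ParameterError, ValidationError

__all__ = ["RunConfig", "run_pipeline", "write_report", "load_config"]

log = logging.getLogger("elongrec")


@dataclass
class RunConfig:
    """Resolved parameters for one pipeline run.

    Defaults equal the analysis constants used throughout: Pearson threshold
    0.2, length strata at 175/1300 nt, |log2FC| >= 1 with adjusted p <= 0.1
    (transcript preset), archetype margin 0.5 log2 units.
    """

    outdir: str = "elongrec_run"
    seed: int = 0
    simulate: bool = True
    sim: dict = field(default_factory=dict)
    gtf: str | None = None
    counts: str | None = None
    counts_meta: str | None = None
    pearson_threshold: float = 0.2
    strata_b1: int = 175
    strata_b2: int = 1300
    min_exons: int = 4
    min_mean_count: float = 5.0
    recovery_conditions: tuple = ("R15", "R30")
    n_perm: int = 1000
    de_preset: str = "transcript_preset"
    cluster_k: int = 4
    archetype_delta: float = 0.5
    log_level: str = "INFO"

    def resolved_sim_config(self) -> sim_mod.SimConfig:
        params = dict(self.sim)
        params.setdefault("seed", self.seed)
        return sim_mod.SimConfig(**params)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["recovery_conditions"] = list(self.recovery_conditions)
        return d

    def validate(self) -> None:
        if not self.simulate:
            missing = [
                name
                for name, path in (
                    ("gtf", self.gtf),
                    ("counts", self.counts),
                    ("counts_meta", self.counts_meta),
                )
                if path is None or not Path(path).exists()
            ]
            if missing:
                raise ParameterError(
                    "simulation disabled but input paths missing or absent: "
                    f"{missing}"
                )
        if self.strata_b1 >= self.strata_b2:
            raise ParameterError("strata_b1 must be < strata_b2")


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML run config; unknown keys raise."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ParameterError(f"unknown config keys: {sorted(unknown)}")
    if "recovery_conditions" in raw:
        raw["recovery_conditions"] = tuple(raw["recovery_conditions"])
    return RunConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.artifacts: dict[str, str] = {}
        self.summary: dict = {}

    def register(self, path: Path) -> None:
        self.artifacts[path.name] = _sha256(path)

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        with open(path, "w") as fh:
            json.dump(
                {"artifacts": self.artifacts, "summary": self.summary},
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")
        return path


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages in dependency order; returns the manifest dict.

    A stage failure raises after the partial manifest is written; the run
    log names the failing stage.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir)

    resolved = config.to_dict()
    log.info("resolved config: %s", json.dumps(resolved, sort_keys=True))
    cfg_path = outdir / "resolved_config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(resolved, fh, sort_keys=True)
    manifest.register(cfg_path)

    stage = "inputs"
    try:
        if config.simulate:
            stage = "simulate"
            sim_cfg = config.resolved_sim_config()
            result = sim_mod.simulate(sim_cfg)
            annotation = result.annotation
            counts = result.counts
            gtf_path = outdir / "annotation.gtf"
            ann_mod.write_gtf(annotation, gtf_path)
            tables.write_counts(counts, outdir / "counts.tsv", outdir / "specimens.tsv")
            result.truth.write(outdir / "truth.tsv")
            for name in ("annotation.gtf", "counts.tsv", "specimens.tsv", "truth.tsv"):
                manifest.register(outdir / name)
        else:
            stage = "load_inputs"
            annotation = ann_mod.read_gtf(config.gtf)
            counts = tables.read_counts(config.counts, config.counts_meta)

        stage = "profiles"
        pset, excluded = prof_mod.build_profiles(
            counts, annotation, config.min_exons, config.min_mean_count
        )
        pd.DataFrame(excluded, columns=["transcript_id", "reason"]).to_csv(
            outdir / "excluded_transcripts.tsv", sep="\t", index=False
        )
        manifest.register(outdir / "excluded_transcripts.tsv")
        strata = ann_mod.stratify_by_length(
            annotation, config.strata_b1, config.strata_b2
        )
        long_pset = prof_mod.coverage_groups_filter(pset, strata)
        manifest.summary["strata_sizes"] = strata.sizes()
        manifest.summary["n_profiled"] = len(pset.transcript_ids)
        manifest.summary["n_long_profiled"] = len(long_pset.transcript_ids)

        stage = "detect"
        groups = sorted(counts.meta["group"].unique())
        changed = {}
        all_calls = []
        for group in groups:
            calls = changes.detect_changed(
                long_pset, group, threshold=config.pearson_threshold
            )
            all_calls.extend(calls)
            changed[group] = changes.changed_set(calls)
        changes.calls_to_frame(all_calls).to_csv(
            outdir / "change_calls.tsv", sep="\t", index=False
        )
        manifest.register(outdir / "change_calls.tsv")
        if len(groups) == 2:
            ov = ann_mod.set_overlap(changed[groups[0]], changed[groups[1]])
            manifest.summary["changed_overlap"] = {
                f"only_{groups[0]}": len(ov.only_a),
                f"only_{groups[1]}": len(ov.only_b),
                "common": len(ov.common),
                "union": ov.union_count,
                f"n_{groups[0]}": len(changed[groups[0]]),
                f"n_{groups[1]}": len(changed[groups[1]]),
            }
            union = sorted(set.union(*changed.values()))
        else:
            union = sorted(set.union(*changed.values())) if changed else []

        stage = "icc"
        icc_rows = []
        if len(groups) == 2 and len(union) >= 3:
            for recovery in config.recovery_conditions:
                d_a = changes.dissimilarities(
                    long_pset, groups[0], recovery=recovery, transcripts=union
                )
                d_b = changes.dissimilarities(
                    long_pset, groups[1], recovery=recovery, transcripts=union
                )
                icc = changes.icc_compare(
                    d_a, d_b, n_perm=config.n_perm, seed=config.seed
                )
                icc_rows.append(
                    {
                        "condition_pair": f"Untr_vs_{recovery}",
                        "icc": icc.icc,
                        "null_lo": icc.null_band[0],
                        "null_hi": icc.null_band[1],
                        "mean_delta": icc.mean_delta,
                        "delta_lo": icc.delta_band[0],
                        "delta_hi": icc.delta_band[1],
                        "consistent_difference": icc.consistent_difference,
                        "n_transcripts": icc.n_transcripts,
                    }
                )
        pd.DataFrame(
            icc_rows,
            columns=[
                "condition_pair", "icc", "null_lo", "null_hi", "mean_delta",
                "delta_lo", "delta_hi", "consistent_difference", "n_transcripts",
            ],
        ).to_csv(outdir / "icc_summary.tsv", sep="\t", index=False)
        manifest.register(outdir / "icc_summary.tsv")
        manifest.summary["icc"] = icc_rows

        stage = "de"
        de_counts = {}
        length_assoc = {}
        ann_idx = ann_mod.annotation_index(annotation)
        de_union = set()
        for group in groups:
            res = destats.nb_de_test(
                counts,
                {"group": group, "condition": "Untr"},
                {"group": group, "condition": "R0"},
            )
            up, down = destats.apply_preset(res, config.de_preset)
            res.reset_index().to_csv(
                outdir / f"de_{group}_R0_vs_Untr.tsv", sep="\t", index=False
            )
            manifest.register(outdir / f"de_{group}_R0_vs_Untr.tsv")
            de_counts[group] = {"up": len(up), "down": len(down)}
            de_union |= up | down
            try:
                length_assoc[group] = destats.length_association(res, ann_idx, "down")
            except (ValidationError, ParameterError) as exc:
                length_assoc[group] = {"error": str(exc)}
        manifest.summary["de_counts"] = de_counts
        manifest.summary["length_association"] = length_assoc

        stage = "cluster"
        cluster_rows = []
        if len(de_union) >= config.cluster_k:
            mat = destats.log2ratio_matrix(counts, features=sorted(de_union))
            clusters = destats.cluster_patterns(
                mat, k=config.cluster_k, delta=config.archetype_delta
            )
            for c in clusters:
                for m in c.members:
                    cluster_rows.append(
                        {"feature_id": m, "cluster_id": c.cluster_id, "archetype": c.archetype}
                    )
            manifest.summary["cluster_archetypes"] = {
                str(c.cluster_id): {"archetype": c.archetype, "n": len(c.members)}
                for c in clusters
            }
        pd.DataFrame(
            cluster_rows, columns=["feature_id", "cluster_id", "archetype"]
        ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
        manifest.register(outdir / "clusters.tsv")
    except Exception:
        log.error("pipeline failed at stage %r", stage)
        manifest.summary["failed_stage"] = stage
        manifest.write()
        raise

    manifest_path = manifest.write()
    report_path = write_report(manifest_path)
    # report is registered in a second manifest pass so its hash is stable
    manifest.register(report_path)
    manifest.write()
    return {"artifacts": manifest.artifacts, "summary": manifest.summary}


def write_report(manifest_path: str | Path) -> Path:
    """Render the human-readable run report from a manifest file."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    summary = manifest.get("summary", {})
    out = []
    out.append("# elongrec run report\n")
    strata = summary.get("strata_sizes", {})
    if strata:
        total = sum(strata.values())
        out.append("## Length strata\n")
        out.append(f"- short: {strata.get('short', 0)}")
        out.append(f"- mid: {strata.get('mid', 0)}")
        out.append(f"- long: {strata.get('long', 0)}")
        out.append(f"- total: {total}\n")
    out.append("## Coverage-profile screening\n")
    ov = summary.get("changed_overlap")
    if ov:
        for key, val in sorted(ov.items()):
            out.append(f"- {key}: {val}")
        out.append("")
    else:
        out.append("- changed transcripts per group: 0\n")
    out.append("## Recovery dissimilarity (ICC)\n")
    icc_rows = summary.get("icc", [])
    if icc_rows:
        for row in icc_rows:
            verdict = (
                "consistent difference" if row["consistent_difference"] else "no consistent change"
            )
            out.append(
                f"- {row['condition_pair']}: icc={row['icc']:.3f} "
                f"null=({row['null_lo']:.3f}, {row['null_hi']:.3f}) "
                f"mean_delta={row['mean_delta']:.4f} -> {verdict} "
                f"(n={row['n_transcripts']})"
            )
        out.append("")
    else:
        out.append("- not computed (fewer than 3 changed transcripts)\n")
    out.append("## Differential expression\n")
    for group, cts in sorted(summary.get("de_counts", {}).items()):
        out.append(f"- {group}: {cts['up']} up, {cts['down']} down")
    out.append("")
    out.append("## Gene-length association (down-called set)\n")
    for group, la in sorted(summary.get("length_association", {}).items()):
        if "error" in la:
            out.append(f"- {group}: not computed ({la['error']})")
        else:
            out.append(
                f"- {group}: R={la['R']:.3f} (n={la['n']}), "
                f"mean length down={la['mean_length_down']:.0f} nt vs "
                f"up={la['mean_length_up']:.0f} nt, "
                f"rank-sum p={la['location_test_p']:.3g}"
            )
    out.append("")
    out.append("## Expression-pattern clusters\n")
    arch = summary.get("cluster_archetypes", {})
    if arch:
        for cid, info in sorted(arch.items()):
            out.append(f"- cluster {cid}: {info['archetype']} (n={info['n']})")
    else:
        out.append("- not computed (too few differential features)")
    out.append("")
    report_path = manifest_path.parent / "report.md"
    report_path.write_text("\n".join(out))
    return report_path
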