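"""End-to-end orchestration: simulate -> derive -> score -> SE -> motif -> dynamics.

``run_all`` executes every stage on freshly simulated data, writes all
artifacts under an output directory and records a manifest with the config
hash, the seed, and a sha256 digest per output file.  All randomness flows
from one seed through stage-salted substreams, so identical config + seed
produce digest-identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import dynamics, enhancers, io, motifs, signature
from .errors import AdrnMesError, ConfigurationError
from .simulate import (
    Scenario,
    SimulationConfig,
    TrajectoryConfig,
    default_genome,
    simulate_chip_landscape,
    simulate_expression_panel,
    simulate_timecourse,
)

__all__ = ["PipelineConfig", "LandscapeConfig", "RunManifest", "run_all", "load_config"]

VERSION = "0.1.0"


@dataclass(frozen=True)
class LandscapeConfig:
    """Geometry and thresholds of the ChIP landscape stage."""

    n_mes_se: int = 8
    n_adrn_se: int = 8
    n_typical: int = 200
    lib_factor_a: float = 1.0
    lib_factor_b: float = 1.0
    peak_threshold_multiple: float = 2.0
    min_peak_width: int = 200
    stitch_distance: int = enhancers.DEFAULT_STITCH_DISTANCE
    top_n_induced: int = 500
    surface_z: float = 3.0
    score_fraction: float = 0.8


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of a full run in one document; no hidden defaults."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    traj: TrajectoryConfig = field(default_factory=TrajectoryConfig)
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    derivation: signature.DerivationParams = field(
        default_factory=signature.DerivationParams
    )
    lfc_threshold: float = 1.0
    z_threshold: float = 1.5
    score_margin: float = 0.0

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


def load_config(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML/JSON document of nested sections."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigurationError(f"{path}: config document must be a mapping")

    def build(cls, data: dict[str, Any]):
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ConfigurationError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
        return cls(**data)

    kwargs: dict[str, Any] = {}
    if "sim" in doc:
        kwargs["sim"] = build(SimulationConfig, doc["sim"])
    if "traj" in doc:
        traj = dict(doc["traj"])
        if "scenarios" in traj:
            traj["scenarios"] = tuple(
                Scenario(
                    s["name"],
                    tuple(tuple(w) for w in s.get("induction_windows", ())),
                    bool(s.get("gsi_active", False)),
                )
                for s in traj["scenarios"]
            )
        if "timepoints" in traj:
            traj["timepoints"] = tuple(traj["timepoints"])
        kwargs["traj"] = build(TrajectoryConfig, traj)
    if "landscape" in doc:
        kwargs["landscape"] = build(LandscapeConfig, doc["landscape"])
    if "derivation" in doc:
        kwargs["derivation"] = build(signature.DerivationParams, doc["derivation"])
    for key in ("lfc_threshold", "z_threshold", "score_margin"):
        if key in doc:
            kwargs[key] = doc[key]
    return PipelineConfig(**kwargs)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: list[dict]

    def output_digests(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for st in self.stages:
            out.update(st["outputs"])
        return out

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


class _StageRecorder:
    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.stages: list[dict] = []

    def record(self, name: str, paths: dict[str, Path], t0: float, note: str = "") -> None:
        self.stages.append(
            {
                "name": name,
                "outputs": {
                    str(p.relative_to(self.out_dir)): io.sha256_file(p)
                    for p in paths.values()
                },
                "seconds": round(time.perf_counter() - t0, 3),
                **({"note": note} if note else {}),
            }
        )


def run_all(
    config: PipelineConfig, out_dir: str | Path, seed: int | None = None
) -> RunManifest:
    """Run every stage on freshly simulated data and write a manifest.

    ``seed`` overrides ``config.sim.seed`` when given.  Any stage failure
    aborts the run with the failing stage named; downstream degenerate
    inputs (e.g. a landscape without planted enhancers) skip the dependent
    stage gracefully and note it in the manifest.
    """

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = (
        dataclasses.replace(config.sim, seed=int(seed)) if seed is not None else config.sim
    )
    rec = _StageRecorder(out_dir)

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            result, paths, note = fn()
        except AdrnMesError as exc:
            raise AdrnMesError(f"stage {name!r} failed: {exc}") from exc
        rec.record(name, paths, t0, note)
        return result

    # ---- panel simulation + signature derivation + scoring
    def stage_panel():
        em, truth = simulate_expression_panel(sim)
        paths = io.write_expression(em, out_dir, "panel")
        return (em, truth), paths, ""

    panel, _ = run_stage("simulate-panel", stage_panel)

    def stage_derive():
        sig = signature.derive_signature(panel, config.derivation)
        path = io.write_signature_tsv(sig, out_dir / "signature.tsv")
        return sig, {"signature": path}, ""

    sig = run_stage("derive-signature", stage_derive)

    def stage_score_panel():
        scores = signature.score_panel(panel, sig)
        path = out_dir / "panel_scores.tsv"
        scores.to_csv(path, sep="\t", float_format="%.10g")
        return scores, {"scores": path}, ""

    run_stage("score-panel", stage_score_panel)

    # ---- time course: scoring, verdicts, regulation, onsets
    def stage_timecourse():
        em, truth = simulate_timecourse(sim, config.traj)
        paths = io.write_expression(em, out_dir, "timecourse")
        annot_path = out_dir / "probe_annotation.tsv"
        truth.probe_annotation.to_csv(annot_path, sep="\t")
        paths["annotation"] = annot_path
        return (em, truth), paths, ""

    tc, tc_truth = run_stage("simulate-timecourse", stage_timecourse)

    def stage_dynamics():
        scorable = sorted(set(sig.mes_genes) | set(sig.adrn_genes))
        missing = [g for g in scorable if g not in tc.values.index]
        usable_sig = sig
        if missing:
            usable_sig = signature.SignatureGeneSet(
                frozenset(g for g in sig.mes_genes if g in tc.values.index),
                frozenset(g for g in sig.adrn_genes if g in tc.values.index),
            )
        scores = signature.score_panel(tc, usable_sig)
        scores = scores.join(tc.samples[["scenario", "day", "dox", "gsi"]])
        verdicts = dynamics.classify_scenarios(
            scores,
            {s.name: s for s in config.traj.scenarios},
            margin=config.score_margin,
        )
        crc = dynamics.CRCSets(
            frozenset(tc_truth.adrn_tfs), frozenset(tc_truth.mes_tfs)
        )
        final_day = config.traj.timepoints[-1]
        induced = tc.samples.index[
            (tc.samples["scenario"] == "persistent") & (tc.samples["day"] == final_day)
        ]
        control = tc.samples.index[
            (tc.samples["scenario"] == "control") & (tc.samples["day"] == final_day)
        ]
        calls_path = out_dir / "regulation_calls.tsv"
        counts: dict[str, str] = {}
        if len(induced) and len(control):
            calls, counts = dynamics.regulation_summary(
                tc, crc, list(induced), list(control), config.lfc_threshold
            )
            pd.DataFrame([dataclasses.asdict(c) for c in calls]).to_csv(
                calls_path, sep="\t", index=False, float_format="%.10g"
            )
        else:
            calls_path.write_text("gene\tlog2_fold_change\tcall\n")
        persistent_ids = tc.samples.index[tc.samples["scenario"] == "persistent"]
        onsets: dict[str, float | None] = {}
        if len(persistent_ids) >= 3:
            onsets = dynamics.onset_times(
                tc.subset_samples(persistent_ids),
                sorted(tc_truth.adrn_tfs) + sorted(tc_truth.mes_tfs),
                config.z_threshold,
            )
        onset_path = out_dir / "onsets.tsv"
        with open(onset_path, "w") as fh:
            fh.write("gene\tonset_day\n")
            for g, d in sorted(onsets.items()):
                fh.write(f"{g}\t{'none' if d is None else f'{d:g}'}\n")
        verdict_path = out_dir / "scenario_verdicts.tsv"
        with open(verdict_path, "w") as fh:
            fh.write("scenario\tverdict\n")
            for name, v in sorted(verdicts.items()):
                fh.write(f"{name}\t{v}\n")
        scores_path = out_dir / "timecourse_scores.tsv"
        scores.to_csv(scores_path, sep="\t", float_format="%.10g")
        paths = {
            "scores": scores_path,
            "verdicts": verdict_path,
            "regulation": calls_path,
            "onsets": onset_path,
        }
        counts_path = out_dir / "crc_counts.json"
        with open(counts_path, "w") as fh:
            json.dump(counts, fh, indent=2, sort_keys=True)
            fh.write("\n")
        paths["counts"] = counts_path
        return verdicts, paths, ""

    run_stage("timecourse-dynamics", stage_dynamics)

    # ---- ChIP landscape: SE calls, differential surfaces, motif enrichment
    genome = default_genome(
        n_mes_se=config.landscape.n_mes_se,
        n_adrn_se=config.landscape.n_adrn_se,
        n_typical=config.landscape.n_typical,
    )

    def stage_chip():
        track_a, track_b, genome_seq, truth = simulate_chip_landscape(
            sim,
            genome,
            lib_factor_a=config.landscape.lib_factor_a,
            lib_factor_b=config.landscape.lib_factor_b,
        )
        paths = {
            "track_a": io.write_bedgraph(track_a, out_dir / "h3k27ac_adrn.bedgraph", "ADRN"),
            "track_b": io.write_bedgraph(track_b, out_dir / "h3k27ac_mes.bedgraph", "MES"),
            "fasta": io.write_fasta(genome_seq.chrom_name, genome_seq.sequence, out_dir / "genome.fa"),
            "truth_bed": io.write_bed(
                (
                    (s, e, cls, 0.0, ".")
                    for cls in ("MES-SE", "ADRN-SE", "typical")
                    for s, e in truth.planted_se.get(cls, [])
                ),
                out_dir / "planted_regions.bed",
                genome_seq.chrom_name,
            ),
        }
        return (track_a, track_b, genome_seq, truth), paths, ""

    track_a, track_b, genome_seq, chip_truth = run_stage("simulate-chip", stage_chip)

    def se_pipeline(track):
        norm = enhancers.normalize_track(track)
        threshold = enhancers.auto_threshold(norm, config.landscape.peak_threshold_multiple)
        peaks = enhancers.call_peaks(norm, threshold, config.landscape.min_peak_width)
        regions = enhancers.stitch_peaks(peaks, config.landscape.stitch_distance)
        return norm, enhancers.call_superenhancers(regions, norm), regions

    def stage_se():
        norm_a, call_a, _ = se_pipeline(track_a)
        norm_b, call_b, regions_b = se_pipeline(track_b)
        paths = {}
        for state, call in (("adrn", call_a), ("mes", call_b)):
            paths[f"se_{state}"] = io.write_bed(
                (
                    (r.start, r.end, f"region_{i}", r.signal, "+" if s else ".")
                    for i, (r, s) in enumerate(zip(call.regions, call.is_super))
                ),
                out_dir / f"superenhancers_{state}.bed",
                genome.chrom_name,
            )
        return (norm_a, norm_b, call_a, call_b, regions_b), paths, ""

    norm_a, norm_b, call_a, call_b, regions_b = run_stage("call-se", stage_se)

    def stage_diff():
        # union of both states' regions for the differential table ...
        union_regions = sorted(
            {r.interval for r in call_a.regions} | {r.interval for r in call_b.regions}
        )
        regs = [enhancers.EnhancerRegion(s, e) for s, e in union_regions]
        diffs = enhancers.differential_surface(norm_a, norm_b, regs)
        diffs = enhancers.poisson_direction_filter(
            diffs, track_a, track_b, config.landscape.surface_z
        )
        path = out_dir / "differential_surfaces.tsv"
        with open(path, "w") as fh:
            fh.write("start\tend\tsurface\tdirection\n")
            for d in diffs:
                fh.write(f"{d.start}\t{d.end}\t{d.surface:.10g}\t{d.direction}\n")
        # ... but induced/background for motif analysis come from the
        # induced-state region set alone, so foreground and background are
        # drawn from one stitching of one state and never near-duplicates.
        diffs_b = enhancers.poisson_direction_filter(
            enhancers.differential_surface(norm_a, norm_b, regions_b),
            track_a,
            track_b,
            config.landscape.surface_z,
        )
        induced = enhancers.select_induced_regions(diffs_b, config.landscape.top_n_induced)
        bed = io.write_bed(
            ((s, e, f"induced_{i}", 0.0, ".") for i, (s, e) in enumerate(induced)),
            out_dir / "induced_regions.bed",
            genome.chrom_name,
        )
        background = [
            r.interval
            for r in regions_b
            if not any(r.start < e and s < r.end for s, e in induced)
        ]
        return (diffs, induced, background), {"surfaces": path, "induced": bed}, ""

    diffs, induced, background = run_stage("differential-surface", stage_diff)

    def stage_motif():
        path = out_dir / "motif_enrichment.tsv"
        if not induced or not background:
            path.write_text("motif_id\tfg_hit\tfg_miss\tbg_hit\tbg_miss\tp_raw\tp_bonferroni\tenriched\n")
            return None, {"enrichment": path}, "empty foreground: motif stage skipped"
        pwms = motifs.load_jaspar(motifs.demo_motif_path())
        hitsets = [
            motifs.scan_motif(genome_seq.sequence, p, config.landscape.score_fraction)
            for p in pwms
        ]
        results = motifs.motif_enrichment(induced, background, hitsets)
        with open(path, "w") as fh:
            fh.write("motif_id\tfg_hit\tfg_miss\tbg_hit\tbg_miss\tp_raw\tp_bonferroni\tenriched\n")
            for r in results:
                fh.write(
                    f"{r.motif_id}\t{r.fg_hit}\t{r.fg_miss}\t{r.bg_hit}\t{r.bg_miss}"
                    f"\t{r.p_raw:.6g}\t{r.p_bonferroni:.6g}\t{r.enriched}\n"
                )
        return results, {"enrichment": path}, ""

    run_stage("motif-enrichment", stage_motif)

    manifest = RunManifest(
        config_hash=config.config_hash(), seed=sim.seed, version=VERSION, stages=rec.stages
    )
    manifest.to_json(out_dir / "manifest.json")
    return manifest
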