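"""End-to-end orchestration: simulate -> quantify -> consequence ->
baseedit -> offtarget -> transloc -> report, driven by one YAML/JSON
config, with a run manifest for reproducibility.

The manifest records the seed, the full effective configuration, input and
output checksums, and per-stage read counters; two runs with the same
config and seed produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .baseedit import indel_rate, substitution_matrix, targeted_transition_fraction
from .consequence import classify_table, mutation_spectrum, null_allele_stats
from .offtarget import (
    compare_groups,
    heatmap_table,
    read_panel_tsv,
    select_be_panel,
    site_mutation_frequency,
)
from .quantify import align_reads, build_allele_table, qc_filter, top_alleles
from .refmodel import ConfigurationError, GuideTarget, RunConfig, load_targets
from .simdata import (
    ErrorModel,
    be3_profile,
    cas9_profile,
    make_synthetic_target,
    read_fastq,
    simulate_fusion_library,
    simulate_reads,
    write_fastq,
)
from .transloc import (
    ACENTRIC_ASSUMPTION,
    build_fusion_templates,
    detect_junction_reads,
    translocation_report,
)


@dataclass
class RunManifest:
    seed: int
    config: dict
    version: str = __version__
    input_checksums: dict[str, str] = field(default_factory=dict)
    output_checksums: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, dict] = field(default_factory=dict)

    def write(self, path: Path) -> None:
        payload = {
            "tool_version": self.version,
            "seed": self.seed,
            "config": self.config,
            "input_checksums": self.input_checksums,
            "stage_counts": self.stage_counts,
            "output_checksums": self.output_checksums,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _build_target(entry: dict) -> GuideTarget:
    if "synthetic" in entry:
        syn = entry["synthetic"]
        return make_synthetic_target(
            guide=str(syn["guide"]).upper(),
            target_id=entry["target_id"],
            flank=int(syn.get("flank", 75)),
            seed=int(syn.get("seed", 101)),
            quant_halfwidth=int(entry.get("quant_halfwidth", 15)),
            edit_window=tuple(entry.get("edit_window", (4, 8))),
        )
    return GuideTarget(
        target_id=entry["target_id"],
        amplicon_seq=str(entry["amplicon_seq"]).upper(),
        protospacer=str(entry["protospacer"]).upper(),
        pam=str(entry["pam"]).upper(),
        strand=str(entry["strand"]),
        protospacer_start=int(entry["protospacer_start"]),
        frame_anchor=entry.get("frame_anchor"),
        cds_bounds=tuple(entry["cds_bounds"]) if "cds_bounds" in entry else None,
        quant_halfwidth=int(entry.get("quant_halfwidth", 15)),
        edit_window=tuple(entry.get("edit_window", (4, 8))),
    )


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return config


def _profile_for(sample: dict, target: GuideTarget):
    sim = sample["simulate"]
    kind = sim.get("profile", "cas9")
    if kind == "be3":
        kwargs = {
            k: float(sim[k])
            for k in ("purity", "byproduct_weight", "indel_weight")
            if k in sim
        }
        return be3_profile(target, p_edit=float(sim.get("p_edit", 0.2)), **kwargs)
    if kind == "cas9":
        return cas9_profile(target, p_edit=float(sim.get("p_edit", 0.2)))
    if kind == "control":
        return cas9_profile(target, p_edit=0.0)
    raise ConfigurationError(f"unknown simulate profile {kind!r}")


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> RunManifest:
    """Execute the configured stages for every sample; returns the manifest.

    Fails fast on the first stage error, naming the sample and target.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    run_cfg = RunConfig(**config.get("run_config", {}))
    stages = config.get("stages", ["quantify", "consequence", "baseedit"])

    if "consequence" in stages:
        for entry in config.get("targets", []):
            if "synthetic" not in entry and entry.get("frame_anchor") is None:
                raise ConfigurationError(
                    f"target {entry.get('target_id')!r}: consequence stage "
                    "enabled but frame_anchor missing"
                )

    manifest = RunManifest(seed=seed, config=config)
    targets: dict[str, GuideTarget] = {}
    if "targets_fasta" in config:
        manifest.input_checksums[str(config["targets_fasta"])] = _sha256(
            Path(config["targets_fasta"])
        )
        for t in load_targets(config["targets_fasta"], config["targets_config"]):
            targets[t.target_id] = t
    for entry in config.get("targets", []):
        t = _build_target(entry)
        targets[t.target_id] = t

    report_sections: dict[str, dict] = {}
    sample_reads: dict[str, list] = {}
    for i, sample in enumerate(config.get("samples", [])):
        sid = sample["sample_id"]
        t = targets[sample["target"]]
        try:
            reads = _stage_reads(sample, t, seed + i, out, manifest)
            sample_reads[sid] = reads
            section = _analyse_sample(sid, reads, t, run_cfg, stages, out, manifest)
            report_sections[sid] = section
        except (ConfigurationError,):
            raise
        except Exception as exc:
            raise RuntimeError(
                f"stage failure for sample {sid!r}, target {t.target_id!r}: {exc}"
            ) from exc

    if "offtarget" in stages and "offtarget" in config:
        report_sections["__offtarget__"] = _stage_offtarget(
            config["offtarget"], run_cfg, seed, out, manifest
        )
    if "transloc" in stages and "transloc" in config:
        report_sections["__transloc__"] = _stage_transloc(
            config["transloc"], targets, seed, out, manifest
        )

    report_path = out / "report.json"
    report_path.write_text(
        json.dumps(report_sections, indent=2, sort_keys=True, default=str) + "\n"
    )
    manifest.output_checksums["report.json"] = _sha256(report_path)
    manifest_path = out / "manifest.json"
    manifest.write(manifest_path)
    return manifest


def _stage_reads(sample, t, seed, out, manifest):
    sid = sample["sample_id"]
    if "fastq" in sample:
        manifest.input_checksums[str(sample["fastq"])] = _sha256(Path(sample["fastq"]))
        return read_fastq(sample["fastq"])
    sim = sample["simulate"]
    prof = _profile_for(sample, t)
    err = ErrorModel(
        per_base_error=float(sim.get("per_base_error", 0.0002)),
        quality_mean=float(sim.get("quality_mean", 37.0)),
        quality_sd=float(sim.get("quality_sd", 2.0)),
    )
    n = int(sim.get("n", 10000))
    reads, truth = simulate_reads(t, prof, err, n, seed, read_prefix=sid)
    fq = out / f"{sid}.fastq"
    write_fastq(reads, fq)
    truth.to_tsv(out / f"{sid}.truth.tsv")
    manifest.output_checksums[fq.name] = _sha256(fq)
    manifest.output_checksums[f"{sid}.truth.tsv"] = _sha256(out / f"{sid}.truth.tsv")
    return reads


def _analyse_sample(sid, reads, t, run_cfg, stages, out, manifest):
    section: dict = {"target": t.target_id, "n_reads": len(reads)}
    if "quantify" not in stages:
        return section
    table = build_allele_table(reads, t, run_cfg, sample_id=sid)
    table.check_conservation()
    table_path = out / f"{sid}.alleles.tsv"
    table.to_tsv(table_path)
    manifest.output_checksums[table_path.name] = _sha256(table_path)
    manifest.stage_counts[sid] = {
        "total_reads": table.total_reads,
        "qc_discarded": table.qc_discarded,
        "unalignable": table.unalignable,
        "non_spanning": table.non_spanning,
        "tabled_denominator": table.qc_passing_reads,
    }
    section["editing_frequency"] = sum(
        r.frequency for r in table.records if not r.is_reference
    )
    section["n_alleles"] = len(table.records)

    if "consequence" in stages:
        calls = classify_table(table, t)
        spectrum = mutation_spectrum(table, calls)
        nulls = null_allele_stats(table, calls)
        section["mutation_spectrum"] = spectrum
        section["null_alleles"] = nulls
        top = top_alleles(table, run_cfg.top_n_alleles)
        calls_by_id = {c.allele_id: c for c in calls}
        rows = []
        for i, rec in enumerate(table.records[: len(top)]):
            call = calls_by_id[f"allele_{i}"]
            rows.append(
                "\t".join(
                    [
                        call.allele_id,
                        rec.window_seq,
                        f"{rec.frequency:.6f}",
                        call.klass,
                        str(call.is_null),
                        str(call.carries_targeted_stop),
                        str(call.novel_residue_count),
                    ]
                )
            )
        cpath = out / f"{sid}.consequences.tsv"
        cpath.write_text(
            "# coords=1-based-inclusive\n"
            "allele_id\twindow_seq\tfrequency\tclass\tis_null\t"
            "carries_targeted_stop\tnovel_residue_count\n" + "\n".join(rows) + "\n"
        )
        manifest.output_checksums[cpath.name] = _sha256(cpath)

    if "baseedit" in stages:
        kept, _, _ = qc_filter(reads, run_cfg.min_mean_quality)
        alns, _ = align_reads(kept, t)
        matrix = substitution_matrix(alns, t)
        mpath = out / f"{sid}.substitutions.tsv"
        matrix.to_tsv(mpath, numbering=run_cfg.position_numbering)
        manifest.output_checksums[mpath.name] = _sha256(mpath)
        frac = targeted_transition_fraction(matrix, t)
        section["targeted_transition_fraction"] = frac
        section["indel_rate"] = indel_rate(table)["indel_rate"]
    return section


def _stage_offtarget(ot_cfg, run_cfg, seed, out, manifest):
    panel_path = ot_cfg["panel"]
    manifest.input_checksums[str(panel_path)] = _sha256(Path(panel_path))
    candidates = read_panel_tsv(panel_path)
    guide = str(ot_cfg["guide"]).upper()
    panel, log = select_be_panel(
        candidates,
        guide,
        max_mismatches=int(ot_cfg.get("max_mismatches", 3)),
        edit_window=tuple(ot_cfg.get("edit_window", (4, 8))),
    )
    per_site = {}
    for k, site in enumerate(panel):
        target = make_synthetic_target(
            site.sequence, target_id=site.site_id, seed=seed + 1000 + k, coding=False
        )
        treated, control = [], []
        n = int(ot_cfg.get("n_reads", 5000))
        p = float(ot_cfg.get("true_edit_rate", 0.0))
        for s in range(int(ot_cfg.get("samples_per_group", 4))):
            for group, bucket in (("treated", treated), ("control", control)):
                prof = (
                    be3_profile(target, p_edit=p)
                    if p > 0 and group == "treated"
                    else cas9_profile(target, p_edit=0.0)
                )
                reads, _ = simulate_reads(
                    target, prof, ErrorModel(), n, seed + 7 * k + s + (0 if group == "treated" else 500)
                )
                counts = site_mutation_frequency(reads, target, run_cfg)
                if counts is not None:
                    bucket.append(counts)
        per_site[site.site_id] = (treated, control)
    comparisons = compare_groups(per_site, method=ot_cfg.get("method", "fisher"))
    table = heatmap_table(panel, comparisons, numbering=run_cfg.position_numbering)
    opath = out / "offtarget.tsv"
    with open(opath, "w") as fh:
        fh.write("# coords=1-based-inclusive\n")
        table.to_csv(fh, sep="\t", index=False)
    manifest.output_checksums[opath.name] = _sha256(opath)
    return {
        "panel_size": len(panel),
        "selection_log": log,
        "n_significant": int(sum(c.significant for c in comparisons)),
    }


def _stage_transloc(tl_cfg, targets, seed, out, manifest):
    tA = targets[tl_cfg["locus_a"]]
    tB = targets[tl_cfg["locus_b"]]
    templates = build_fusion_templates(tA, tB)
    samples = {}
    for si, sample in enumerate(tl_cfg.get("samples", [])):
        sid = sample["sample_id"]
        per_geom = {}
        for gi, geometry in enumerate(("balanced", "acentric")):
            reads, truth = simulate_fusion_library(
                tA,
                tB,
                geometry,
                p_fusion=float(sample.get("p_fusion", 0.0)),
                n=int(sample.get("n", 2000)),
                seed=seed + 31 * si + gi,
            )
            count, _ = detect_junction_reads(reads, templates[geometry])
            per_geom[geometry] = (count, len(reads))
        samples[sid] = per_geom
    report = translocation_report(
        samples, expected_products=tl_cfg.get("expected_products")
    )
    tpath = out / "translocations.tsv"
    with open(tpath, "w") as fh:
        fh.write(f"# assumption: {ACENTRIC_ASSUMPTION}\n")
        report.to_csv(fh, sep="\t", index=False)
    manifest.output_checksums[tpath.name] = _sha256(tpath)
    return {"samples": {sid: {g: list(v) for g, v in per.items()} for sid, per in samples.items()}}
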