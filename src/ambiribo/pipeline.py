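"""Config-driven end-to-end runs: simulate -> quantify -> profile ->
null-model -> context.

All randomness flows from one root seed through named substreams, so a
report is a pure function of its config.  The machine-readable report
carries every estimate next to the simulation truth it should recover.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from ambiribo import __version__
from ambiribo import ambigram, mnase, readquant, riboprof, smallrna
from ambiribo.synthetic import (
    SimConfig,
    make_ambigram_genome,
    simulate_footprints,
    simulate_small_rnas,
    simulate_stranded_reads,
    inject_snvs,
)

REPORT_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Root configuration: seed, simulation parameters, stage toggles and
    analysis thresholds."""

    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    n_mngs_reads: int = 50_000
    n_footprints: int = 10_000
    n_sirna_reads: int = 10_000
    stages: tuple[str, ...] = (
        "genomes",
        "mngs",
        "snv",
        "footprints",
        "smallrna",
        "mnase_null",
    )
    biallelic_band: tuple[float, float] = readquant.DEFAULT_BIALLELIC_BAND
    subgenomic_threshold: float = readquant.DEFAULT_SUBGENOMIC_THRESHOLD
    welch_nperseg: int = riboprof.WELCH_PARAMS["nperseg"]
    welch_noverlap: int = riboprof.WELCH_PARAMS["noverlap"]
    mnase_runs: int = mnase.DEFAULT_RUNS
    mnase_n: int = mnase.DEFAULT_N_FOOTPRINTS

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        self.sim.seed = self.seed

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


class MissingStageError(RuntimeError):
    """A stage needs an artifact from a stage that was not enabled."""


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute enabled stages in dependency order; return the report."""
    report: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }
    sim = config.sim
    artifacts: dict[str, Any] = {}

    def require(stage: str) -> None:
        if stage not in artifacts:
            raise MissingStageError(
                f"stage requires '{stage}' output but '{stage}' was not enabled"
            )

    if "genomes" in config.stages:
        rdrp = make_ambigram_genome(sim.rdrp_length, sim.seed, "rdrp")
        robin = make_ambigram_genome(sim.robin_length, sim.seed, "robin")
        artifacts["genomes"] = {"rdrp": rdrp, "robin": robin}
        out = {}
        for name, seg in artifacts["genomes"].items():
            out[name] = {
                "length": len(seg),
                "overlap_fraction": ambigram.ambigram_overlap_fraction(seg),
                "codon_avoidance": ambigram.codon_avoidance_stats(seg),
            }
        report["stages"]["genomes"] = out

    if "mngs" in config.stages:
        require("genomes")
        genomes = artifacts["genomes"]
        alns = simulate_stranded_reads(genomes, sim, config.n_mngs_reads)
        artifacts["mngs"] = alns
        out = {}
        for name, a in alns.items():
            out[name] = {
                "n_reads": len(a),
                "strand_ratio": readquant.strand_ratio(a),
                "truth_strand_ratio": sim.strand_ratio.get(name),
            }
        out["copy_ratio"] = {
            "estimate": readquant.length_normalized_copy_ratio(
                alns["robin"],
                len(genomes["robin"]),
                alns["rdrp"],
                len(genomes["rdrp"]),
            ),
            "truth": sim.copy_ratio,
        }
        report["stages"]["mngs"] = out

    if "snv" in config.stages:
        require("mngs")
        genomes = artifacts["genomes"]
        out = {}
        for label, name, mode, truth in (
            ("rdrp_viral", "rdrp", "viral_quasispecies", "quasispecies"),
            ("robin_viral", "robin", "viral_quasispecies", "quasispecies"),
            ("host_control", "rdrp", "host_biallelic", "host_biallelic"),
        ):
            a = inject_snvs(artifacts["mngs"][name], genomes[name].sequence, mode, sim)
            snvs = readquant.call_snvs(a, genomes[name].sequence)
            cls = readquant.classify_snv_pattern(snvs, config.biallelic_band)
            out[label] = {"verdict": cls.verdict, "truth": truth, "n_sites": cls.n_sites}
        report["stages"]["snv"] = out

    if "footprints" in config.stages:
        require("genomes")
        genomes = artifacts["genomes"]
        fp_sets = {
            "host": simulate_footprints(genomes["rdrp"], "host", sim, config.n_footprints),
            "viral": simulate_footprints(
                genomes["rdrp"], "viral_plateau", sim, config.n_footprints
            ),
        }
        artifacts["footprints"] = fp_sets
        cds = genomes["rdrp"].fwd_orf[:2]
        out = {}
        for kind, fps in fp_sets.items():
            collapsed, dedup = riboprof.umi_collapse(fps)
            center = riboprof.footprint_coverage(collapsed, "center")
            five = riboprof.footprint_coverage(collapsed, "fiveprime")
            psd = riboprof.welch_periodicity(
                five, cds, nperseg=config.welch_nperseg, noverlap=config.welch_noverlap
            )
            plateau = riboprof.plateau_concentration(center, cds)
            out[kind] = {
                "n_footprints": len(fps),
                "umi_depletion": dedup.depletion,
                "length_mode": riboprof.length_distribution(collapsed).mode,
                "psd_peak_frequency": psd.peak_frequency,
                "gini": plateau.gini,
                "mass90_fraction": plateau.mass90_fraction,
            }
        report["stages"]["footprints"] = out

    if "smallrna" in config.stages:
        require("genomes")
        genomes = artifacts["genomes"]
        sirna = simulate_small_rnas(genomes["rdrp"], sim, config.n_sirna_reads)
        artifacts["smallrna"] = sirna
        hist = smallrna.sirna_length_mode(sirna)
        entry = {"length_mode": hist.modal_length, "tie": hist.tie}
        if "footprints" in artifacts:
            fp_cov = riboprof.footprint_coverage(artifacts["footprints"]["viral"], "center")
            si_cov = readquant.coverage_profile(sirna)
            corr = smallrna.coverage_correlation(
                fp_cov.values, si_cov["+"] + si_cov["-"]
            )
            entry["footprint_correlation_r"] = corr.r
            entry["footprint_correlation_p"] = corr.pvalue
        report["stages"]["smallrna"] = entry

    if "mnase_null" in config.stages:
        require("footprints")
        genomes = artifacts["genomes"]
        seq = genomes["rdrp"].sequence
        fps = artifacts["footprints"]["viral"]
        # cut bias is fitted on the host-like footprints (the empirical
        # across-transcript preference), then asked to explain the viral
        # plateau profile
        model = mnase.estimate_cut_bias(artifacts["footprints"]["host"], seq)
        observed = riboprof.footprint_coverage(fps, "center")
        pred = mnase.generate_null_footprints(
            model, seq, config.mnase_n, config.mnase_runs, seed=config.seed
        )
        scrambled = mnase.scramble_sequence(seq, seed=config.seed)
        pred_scr = mnase.generate_null_footprints(
            model, scrambled, config.mnase_n, config.mnase_runs, seed=config.seed + 1
        )
        cmp_ = mnase.model_vs_observed(pred, observed, pred_scr)
        report["stages"]["mnase_null"] = {
            "verdict": cmp_.verdict,
            "pvalue": cmp_.pvalue,
            "mean_r_actual": float(np.mean(cmp_.r_actual)),
            "mean_r_scrambled": float(np.mean(cmp_.r_scrambled)),
        }

    return report


def write_report(report: dict, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "report.json"
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    summary = out_dir / "summary.txt"
    with open(summary, "w") as fh:
        fh.write(render_summary(report))
    return path


def render_summary(report: dict) -> str:
    lines = [
        f"ambiribo v{report['package_version']} report "
        f"(schema {report['schema_version']}, seed {report['seed']}, "
        f"config {report['config_hash']})",
    ]
    for stage, payload in report["stages"].items():
        lines.append(f"\n[{stage}]")
        lines.append(json.dumps(payload, indent=2, sort_keys=True, default=str))
    return "\n".join(lines) + "\n"
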