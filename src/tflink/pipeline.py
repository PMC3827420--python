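"""End-to-end orchestration of the analysis stages.

``run`` executes an ordered subset of stages -- simulate, callpeaks,
annotate, motifs, de, integrate, gsea, report -- against either a
simulated study or user-supplied files, carrying intermediate results in
a state dict and enforcing stage dependencies.  Outputs are deterministic
per (config, seed); the final report collects every overlap count,
fraction, ratio, Z and ES/NES the stages computed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from tflink import annotate as ann
from tflink import diffexpr as de_mod
from tflink import gsea as gsea_mod
from tflink import integrate as integ
from tflink import motifs as motif_mod
from tflink import peakcall
from tflink import simulate as sim
from tflink.core import read_bed, read_expression, read_gene_table

logger = logging.getLogger("tflink")

STAGES = ("simulate", "callpeaks", "annotate", "motifs", "de",
          "integrate", "gsea", "report")

DEPENDENCIES: dict[str, tuple[str, ...]] = {
    "callpeaks": ("simulate",),
    "motifs": ("annotate",),
    "integrate": ("annotate", "motifs", "de"),
    "gsea": ("annotate", "de"),
    "report": (),
}


class StageDependencyError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "tflink_out"
    simulation: sim.SimulationConfig = field(
        default_factory=sim.SimulationConfig)
    peak_caller: peakcall.PeakCallerConfig = field(
        default_factory=peakcall.PeakCallerConfig)
    domains: ann.DomainConfig = field(default_factory=ann.DomainConfig)
    de: de_mod.DEConfig = field(default_factory=de_mod.DEConfig)
    gsea: gsea_mod.GseaConfig = field(default_factory=gsea_mod.GseaConfig)
    motif_definitions: dict[str, str] = field(
        default_factory=lambda: dict(motif_mod.DEFAULT_MOTIFS))
    n_background_sets: int = 100
    # external inputs (used instead of simulation when provided)
    genome_fasta: str | None = None
    gene_table: str | None = None
    peak_beds: dict[str, str] = field(default_factory=dict)
    expression: dict[str, tuple[str, str]] = field(default_factory=dict)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _require(state: dict, stage: str) -> None:
    for dep in DEPENDENCIES.get(stage, ()):
        if dep not in state["completed"]:
            raise StageDependencyError(
                f"stage '{stage}' requires prior stage '{dep}'"
            )


def run(config: PipelineConfig,
        stages: Sequence[str] | None = None) -> dict[str, Any]:
    """Run the requested stages in canonical order; returns the report."""
    stages = list(stages) if stages is not None else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    state: dict[str, Any] = {"completed": set(), "report": {
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }}
    # seed flows into every stochastic stage config
    config.simulation.seed = config.seed
    config.gsea.seed = config.seed

    for stage in stages:
        _require(state, stage)
        logger.info("stage %s", stage)
        _STAGE_FUNCS[stage](config, state, outdir)
        state["completed"].add(stage)
    return state["report"]


def _load_inputs(config: PipelineConfig, state: dict) -> None:
    """Populate state from external files when no simulation ran."""
    if "genome" in state:
        return
    if config.genome_fasta:
        from pyfaidx import Fasta

        fa = Fasta(config.genome_fasta)
        state["genome"] = {name: str(fa[name][:]) for name in fa.keys()}
        state["chrom_sizes"] = {c: len(s) for c, s in
                                state["genome"].items()}
    if config.gene_table:
        state["genes"] = read_gene_table(config.gene_table)
    if config.peak_beds:
        state["peaks"] = {
            sample: read_bed(path, sample=sample)
            for sample, path in config.peak_beds.items()
        }
    if config.expression:
        state["expression"] = {
            sample: read_expression(mpath, spath)
            for sample, (mpath, spath) in config.expression.items()
        }


def _stage_simulate(config: PipelineConfig, state: dict,
                    outdir: Path) -> None:
    study = sim.simulate_study(config.simulation)
    state["study"] = study
    state["genome"] = study.genome
    state["chrom_sizes"] = study.chrom_sizes
    state["genes"] = study.genes
    state["peaks"] = study.peaks
    state["expression"] = study.expression
    state["histone_track"] = study.histone_track
    manifest = sim.write_study(study, outdir / "sim")
    state["report"]["simulate"] = {
        "n_genes": len(study.genes),
        "n_peaks": {s: len(p) for s, p in study.peaks.items()},
        "manifest": manifest,
    }


def _stage_callpeaks(config: PipelineConfig, state: dict,
                     outdir: Path) -> None:
    study: sim.SimulatedStudy = state["study"]
    sample = sorted(study.peaks)[0]
    treatment, control = sim.generate_study_tags(study, sample=sample)
    called = peakcall.call_peaks(treatment, control, config.peak_caller,
                                 chrom_sizes=study.chrom_sizes,
                                 sample=sample)
    from tflink.core import write_bed

    write_bed([c.peak for c in called], outdir / f"called_{sample}.bed")
    truth_peaks = [
        (chrom, s, e) for _, chrom, s, e in study.truth.peaks[sample]
    ]
    recovered = 0
    for chrom, s, e in truth_peaks:
        if any(c.peak.chrom == chrom and c.peak.start < e
               and c.peak.end > s for c in called):
            recovered += 1
    state["called_peaks"] = called
    state["report"]["callpeaks"] = {
        "sample": sample,
        "n_called": len(called),
        "n_truth": len(truth_peaks),
        "sensitivity": recovered / len(truth_peaks) if truth_peaks else None,
    }


def _stage_annotate(config: PipelineConfig, state: dict,
                    outdir: Path) -> None:
    _load_inputs(config, state)
    genes = state["genes"]
    chrom_sizes = state["chrom_sizes"]
    domains = ann.build_domains(genes, chrom_sizes, config.domains)
    state["domains"] = domains
    assignments: dict[str, list] = {}
    rep: dict[str, Any] = {}
    for sample, peaks in state["peaks"].items():
        assigned = ann.assign_peaks(peaks, domains)
        assignments[sample] = assigned
        _write_assignments(assigned, outdir / f"assignments_{sample}.tsv")
        rep[sample] = {
            "n_peaks": len(peaks),
            "n_assignments": len(assigned),
            "n_bound_genes": len(ann.bound_genes(assigned)),
            "bin_fractions": ann.bin_fractions(assigned) if assigned else {},
        }
    state["assignments"] = assignments
    samples = sorted(state["peaks"])
    overlaps = {}
    for i, a in enumerate(samples):
        for b in samples[i + 1:]:
            key = f"{a}|{b}"
            overlaps[key] = {
                "peaks": ann.peak_set_overlap(state["peaks"][a],
                                              state["peaks"][b]),
                "genes": ann.gene_set_overlap(
                    ann.bound_genes(assignments[a]),
                    ann.bound_genes(assignments[b])),
            }
    rep["overlaps"] = overlaps
    if state.get("histone_track"):
        sample = samples[0]
        rep["histone_overlap"] = ann.track_overlap_fraction(
            state["peaks"][sample], state["histone_track"],
            assignments[sample])
    state["report"]["annotate"] = rep


def _write_assignments(assigned, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("peak\tgene\tdistance\tbin\n")
        for a in assigned:
            fh.write(f"{a.peak_id}\t{a.gene_id}\t{a.distance}\t{a.bin}\n")


def _stage_motifs(config: PipelineConfig, state: dict,
                  outdir: Path) -> None:
    genome = state["genome"]
    motifs = {name: motif_mod.MotifConsensus(name, iupac)
              for name, iupac in config.motif_definitions.items()}
    runx = motifs.get("RUNX", next(iter(motifs.values())))
    rep: dict[str, Any] = {}
    state["motif_hits"] = {}
    for sample, peaks in state["peaks"].items():
        counts, fraction, hits = motif_mod.region_motif_summary(
            peaks, genome, [runx])
        state["motif_hits"][sample] = hits
        rep[sample] = {"fraction_with_motif": fraction}
    sample0 = sorted(state["peaks"])[0]
    peaks0 = state["peaks"][sample0]
    lengths = [p.interval.length for p in peaks0]
    exclusion = [p.interval for pk in state["peaks"].values() for p in pk]
    rng = np.random.default_rng(config.seed + 17)
    background_sets = [
        motif_mod.sample_background(genome, len(peaks0), lengths,
                                    seed=int(rng.integers(2**31)),
                                    exclusion=exclusion)
        for _ in range(config.n_background_sets)
    ]
    z = motif_mod.motif_zscore(peaks0, genome, runx, background_sets,
                               seed=config.seed)
    rep["zscore"] = {
        "sample": sample0, "motif": z.name, "observed": z.observed,
        "background_mean": z.background_mean,
        "background_sd": z.background_sd, "z": z.z,
    }
    (outdir / "motif_report.json").write_text(json.dumps(rep, indent=1))
    state["report"]["motifs"] = rep


def _stage_de(config: PipelineConfig, state: dict, outdir: Path) -> None:
    _load_inputs(config, state)
    state["de"] = {}
    rep: dict[str, Any] = {}
    de_config = config.de
    for sample, matrix in state["expression"].items():
        wt = matrix.group_columns("WT")
        ko = matrix.group_columns("KO")
        result = de_mod.differential_genes(wt, ko, de_config)
        result.to_csv(outdir / f"de_{sample}.tsv", sep="\t")
        state["de"][sample] = result
        n_resp = int((result["status"] != "ns").sum())
        rep[sample] = {"n_responsive": n_resp}
        if n_resp:
            rep[sample].update(de_mod.direction_split(result))
    state["report"]["de"] = rep


def _stage_integrate(config: PipelineConfig, state: dict,
                     outdir: Path) -> None:
    rep: dict[str, Any] = {}
    gene_sets: dict[str, integ.GeneSets] = {}
    for sample, de_table in state["de"].items():
        if sample not in state["assignments"]:
            continue
        universe = set(de_table.index)
        sets = integ.derive_gene_sets(
            state["assignments"][sample],
            state["motif_hits"].get(sample, {}),
            de_table, universe)
        gene_sets[sample] = sets
        assoc = integ.contingency_association(
            sets.responsive, sets.bound_with_motif, sets.universe)
        rep[sample] = {
            "n_bound": len(sets.bound),
            "n_bound_with_motif": len(sets.bound_with_motif),
            "n_responsive": len(sets.responsive),
            "n_regulated": len(sets.regulated),
            "association_chi2_p": assoc.chi_square_p,
            "association_fisher_p": assoc.fisher_p,
        }
    state["gene_sets"] = gene_sets
    samples = sorted(gene_sets)
    cross = {}
    for i, a in enumerate(samples):
        for b in samples[i + 1:]:
            common_universe = gene_sets[a].universe & gene_sets[b].universe
            ra = gene_sets[a].regulated & common_universe
            rb = gene_sets[b].regulated & common_universe
            if not ra or not rb:
                continue
            stat = integ.expected_overlap(ra, rb, common_universe)
            entry = {
                "n1": stat.n1, "n2": stat.n2, "universe": stat.universe,
                "observed": stat.observed, "expected": stat.expected,
                "p": stat.p_value,
            }
            common = sorted(ra & rb)
            if common:
                try:
                    entry["direction_concordance"] = integ.direction_concordance(
                        common, state["de"][a], state["de"][b])
                except ValueError:
                    pass
            cross[f"{a}|{b}"] = entry
    rep["cross_sample"] = cross
    for sets in gene_sets.values():
        sets.validate()
    (outdir / "integration_report.json").write_text(
        json.dumps(rep, indent=1, default=str))
    state["report"]["integrate"] = rep


def _stage_gsea(config: PipelineConfig, state: dict, outdir: Path) -> None:
    rep: dict[str, Any] = {}
    for sample, de_table in state["de"].items():
        if sample not in state["assignments"]:
            continue
        bound = ann.bound_genes(state["assignments"][sample])
        bound &= set(de_table.index)
        if not bound or len(bound) >= len(de_table):
            continue
        ranked = gsea_mod.rank_by_abs_fc(de_table)
        result = gsea_mod.nes_and_pvalue(ranked, bound, config.gsea)
        rep[sample] = {
            "es": result.es, "nes": result.nes,
            "nominal_p": result.nominal_p,
            "p_is_upper_bound": result.p_is_bound,
            "n_hits": result.n_hits,
        }
    state["report"]["gsea"] = rep


def _stage_report(config: PipelineConfig, state: dict,
                  outdir: Path) -> None:
    report = state["report"]
    path = outdir / "report.json"
    path.write_text(json.dumps(report, indent=1, sort_keys=True,
                               default=str))
    report["report_path"] = str(path)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "callpeaks": _stage_callpeaks,
    "annotate": _stage_annotate,
    "motifs": _stage_motifs,
    "de": _stage_de,
    "integrate": _stage_integrate,
    "gsea": _stage_gsea,
    "report": _stage_report,
}
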