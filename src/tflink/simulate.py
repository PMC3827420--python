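"""Synthetic study generator with planted ground truth.

Emulates a two-cell-type x two-state TF occupancy + knockout
transcriptome design on a toy genome: uniform-random chromosomes, genes
placed without overlap on alternating strands, per-sample peak sets with
a controlled cross-sample overlap fraction, consensus motifs planted
into a controlled fraction of peaks (peak footprints are scrubbed of
incidental consensus occurrences first, so motif truth is exact), tag
libraries with fold-enriched rates inside peaks, and WT/KO expression
matrices with planted fold-change effects on (mostly) bound genes.

Every generator is a pure function of its inputs and the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from tflink.core import (
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    Peak,
    TagLibrary,
    write_bed,
    write_expression,
    write_fasta,
    write_gene_table,
)
from tflink.motifs import (
    MotifConsensus,
    RUNX_VARIANTS,
    reverse_complement,
    scan,
)

BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic scenario.

    Defaults mirror the emulated design at desk scale: two biological
    ChIP samples per state with 62% cross-sample peak overlap, a 90%
    consensus-motif rate among peaks, 10x tag enrichment over a matched
    control, and 3-replicate WT/KO expression with planted fold effects
    (the emulated study spans ~1.5-4x; the default plants the mid-range
    2.5x) and a 60/40 down/up split.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    n_genes: int = 400
    gene_length_min: int = 2_000
    gene_length_max: int = 6_000
    n_peaks: int = 240
    peak_length_mean: float = 300.0
    peak_length_sd: float = 80.0
    peak_length_min: int = 100
    intergenic_peak_fraction: float = 0.15
    cross_sample_peak_overlap_fraction: float = 0.62
    motif_plant_rate: float = 0.9
    planted_motifs: tuple[str, ...] = RUNX_VARIANTS
    tag_enrichment: float = 10.0
    background_tag_rate: float = 0.01
    de_fraction: float = 0.5
    null_de_fraction: float = 0.02
    de_effect: float = 2.5
    fraction_down: float = 0.6
    replicate_sd: float = 0.25
    n_replicates: int = 3
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    above_background_floor: float = 4.0
    below_floor_fraction: float = 0.08
    basal_upstream: int = 5000
    basal_downstream: int = 1000

    def __post_init__(self) -> None:
        for name in ("cross_sample_peak_overlap_fraction",
                     "motif_plant_rate", "de_fraction", "null_de_fraction",
                     "fraction_down", "below_floor_fraction",
                     "intergenic_peak_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.de_fraction > 1:
            raise ValueError("de_fraction > 1")
        if min(self.chrom_length, self.n_peaks, self.peak_length_min) <= 0:
            raise ValueError("lengths and counts must be positive")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per group")


@dataclass
class TruthTables:
    """Planted ground truth, keyed by sample label where applicable."""

    peaks: dict[str, list[tuple[str, str, int, int]]] = field(
        default_factory=dict)  # sample -> (peak_id, chrom, start, end)
    peak_target_gene: dict[str, dict[str, str | None]] = field(
        default_factory=dict)
    motif_positions: dict[str, list[tuple[str, str, int, str, str]]] = field(
        default_factory=dict)  # sample -> (peak, chrom, pos, variant, strand)
    motif_peaks: dict[str, set[str]] = field(default_factory=dict)
    bound_genes: dict[str, set[str]] = field(default_factory=dict)
    bound_with_motif_genes: dict[str, set[str]] = field(default_factory=dict)
    de_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    below_floor_genes: dict[str, set[str]] = field(default_factory=dict)
    regulated_genes: dict[str, set[str]] = field(default_factory=dict)

    def to_json(self) -> str:
        def convert(obj):
            if isinstance(obj, set):
                return sorted(obj)
            if isinstance(obj, dict):
                return {str(k): convert(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [convert(v) for v in obj]
            return obj

        return json.dumps(convert(asdict(self)), indent=1)


# ---------------------------------------------------------------------------
# genome and annotation
# ---------------------------------------------------------------------------

def generate_genome(config: SimulationConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[dict[str, bytearray], list[GeneModel]]:
    """Uniform A/C/G/T chromosomes with non-overlapping, alternately
    stranded genes placed on an evenly spaced grid with jitter."""
    rng = rng or np.random.default_rng(config.seed)
    genome: dict[str, bytearray] = {}
    for i in range(config.n_chroms):
        seq = rng.choice(BASES, size=config.chrom_length)
        genome[f"chr{i + 1}"] = bytearray(seq.tobytes())

    genes: list[GeneModel] = []
    per_chrom = int(np.ceil(config.n_genes / config.n_chroms))
    gid = 0
    for i in range(config.n_chroms):
        chrom = f"chr{i + 1}"
        n_here = min(per_chrom, config.n_genes - gid)
        if n_here <= 0:
            break
        slot = config.chrom_length // max(n_here, 1)
        if slot < config.gene_length_max + 2000:
            raise ValueError(
                f"genes do not fit: slot {slot} bp < gene length "
                f"{config.gene_length_max} bp + margin"
            )
        for j in range(n_here):
            length = int(rng.integers(config.gene_length_min,
                                      config.gene_length_max + 1))
            lo = j * slot + 1000
            hi = (j + 1) * slot - length - 1000
            start = int(rng.integers(lo, max(hi, lo + 1)))
            strand = "+" if (gid % 2 == 0) else "-"
            tss, tes = (start, start + length) if strand == "+" \
                else (start + length, start)
            gid += 1
            genes.append(GeneModel(f"g{gid:04d}", f"Sym{gid:04d}", chrom,
                                   strand, tss, tes))
    return genome, genes


def chrom_sizes_of(genome: Mapping[str, bytearray | str]) -> dict[str, int]:
    return {c: len(s) for c, s in genome.items()}


def finalize_genome(genome: Mapping[str, bytearray]) -> dict[str, str]:
    return {c: bytes(s).decode("ascii") for c, s in genome.items()}


def _basal_span(gene: GeneModel, config: SimulationConfig
                ) -> tuple[int, int]:
    if gene.strand == "+":
        return (max(0, gene.tss - config.basal_upstream),
                gene.tss + config.basal_downstream)
    return (max(0, gene.tss - config.basal_downstream),
            gene.tss + config.basal_upstream)


# ---------------------------------------------------------------------------
# peaks and motifs
# ---------------------------------------------------------------------------

def _draw_length(config: SimulationConfig, rng: np.random.Generator) -> int:
    length = rng.normal(config.peak_length_mean, config.peak_length_sd)
    return int(max(config.peak_length_min, round(length)))


def _overlaps_any(chrom: str, start: int, end: int,
                  occupied: dict[str, list[tuple[int, int]]]) -> bool:
    return any(s < end and e > start
               for s, e in occupied.get(chrom, ()))


def plant_peaks_and_motifs(genome: dict[str, bytearray],
                           genes: Sequence[GeneModel],
                           config: SimulationConfig,
                           rng: np.random.Generator | None = None,
                           samples: tuple[str, str] = ("sampleA", "sampleB"),
                           truth: TruthTables | None = None
                           ) -> tuple[dict[str, list[Peak]], TruthTables]:
    """Plant a pair of peak sets with controlled overlap, then motifs.

    Sample A peaks anchor to gene basal windows (a configured fraction
    are intergenic); a fraction ``cross_sample_peak_overlap_fraction`` of
    A peaks get an overlapping B partner, the rest of B is placed clear
    of A.  All peak footprints are scrubbed of incidental planted-motif
    consensus occurrences, then a fraction ``motif_plant_rate`` of each
    sample's peaks receives one planted variant (uniform variant and
    strand), so motif truth is exact.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    truth = truth or TruthTables()
    sizes = chrom_sizes_of(genome)
    name_a, name_b = samples
    occupied: dict[str, list[tuple[int, int]]] = {}

    n_intergenic = int(round(config.n_peaks * config.intergenic_peak_fraction))
    n_genic = config.n_peaks - n_intergenic
    gene_order = rng.permutation(len(genes))

    peaks_a: list[Peak] = []
    targets_a: dict[str, str | None] = {}
    gi = 0
    attempts = 0
    while len(peaks_a) < n_genic and attempts < 50 * n_genic:
        attempts += 1
        gene = genes[gene_order[gi % len(genes)]]
        gi += 1
        length = _draw_length(config, rng)
        b_start, b_end = _basal_span(gene, config)
        mid = int(rng.integers(b_start + 1, b_end - 1))
        start = max(0, mid - length // 2)
        end = min(sizes[gene.chrom], start + length)
        if end - start < config.peak_length_min:
            continue
        if _overlaps_any(gene.chrom, start - 200, end + 200, occupied):
            continue
        pid = f"{name_a}_pk{len(peaks_a) + 1:04d}"
        peaks_a.append(Peak(GenomicInterval(gene.chrom, start, end),
                            name=pid, sample=name_a))
        targets_a[pid] = gene.gene_id
        occupied.setdefault(gene.chrom, []).append((start, end))
    while len(peaks_a) < config.n_peaks and attempts < 100 * config.n_peaks:
        attempts += 1
        length = _draw_length(config, rng)
        chrom = f"chr{int(rng.integers(1, config.n_chroms + 1))}"
        start = int(rng.integers(0, sizes[chrom] - length))
        end = start + length
        near_gene = any(
            g.chrom == chrom and _basal_span(g, config)[0] - length
            <= (start + end) // 2 < _basal_span(g, config)[1] + length
            for g in genes
        )
        if near_gene or _overlaps_any(chrom, start - 200, end + 200,
                                      occupied):
            continue
        pid = f"{name_a}_pk{len(peaks_a) + 1:04d}"
        peaks_a.append(Peak(GenomicInterval(chrom, start, end),
                            name=pid, sample=name_a))
        targets_a[pid] = None
        occupied.setdefault(chrom, []).append((start, end))
    if len(peaks_a) < config.n_peaks:
        raise RuntimeError("requested peaks exceed genome capacity")

    # sample B: overlapping partners for a controlled fraction of A
    n_pair = int(round(config.cross_sample_peak_overlap_fraction
                       * len(peaks_a)))
    pair_idx = set(rng.choice(len(peaks_a), size=n_pair,
                              replace=False).tolist())
    peaks_b: list[Peak] = []
    targets_b: dict[str, str | None] = {}
    occupied_b: dict[str, list[tuple[int, int]]] = {}
    for i, pa in enumerate(peaks_a):
        if i not in pair_idx:
            continue
        length = _draw_length(config, rng)
        # shift keeps >= 1 bp shared with the partner
        shift = int(rng.integers(-length // 2, pa.interval.length // 2))
        start = max(0, pa.start + shift)
        end = min(sizes[pa.chrom], start + length)
        if end <= pa.start:  # clamped away; pin to partner start
            start, end = pa.start, min(sizes[pa.chrom],
                                       pa.start + length)
        pid = f"{name_b}_pk{len(peaks_b) + 1:04d}"
        peaks_b.append(Peak(GenomicInterval(pa.chrom, start, end),
                            name=pid, sample=name_b))
        targets_b[pid] = targets_a[pa.name]
        occupied_b.setdefault(pa.chrom, []).append((start, end))
    attempts = 0
    while len(peaks_b) < config.n_peaks and attempts < 100 * config.n_peaks:
        attempts += 1
        length = _draw_length(config, rng)
        chrom = f"chr{int(rng.integers(1, config.n_chroms + 1))}"
        start = int(rng.integers(0, sizes[chrom] - length))
        end = start + length
        if _overlaps_any(chrom, start, end, occupied):
            continue  # must not touch any A peak
        if _overlaps_any(chrom, start - 200, end + 200, occupied_b):
            continue
        pid = f"{name_b}_pk{len(peaks_b) + 1:04d}"
        target = next(
            (g.gene_id for g in genes if g.chrom == chrom
             and _basal_span(g, config)[0] <= (start + end) // 2
             < _basal_span(g, config)[1]),
            None,
        )
        peaks_b.append(Peak(GenomicInterval(chrom, start, end),
                            name=pid, sample=name_b))
        targets_b[pid] = target
        occupied_b.setdefault(chrom, []).append((start, end))
    if len(peaks_b) < config.n_peaks:
        raise RuntimeError("requested peaks exceed genome capacity")

    # scrub every footprint first (protecting previously planted motifs
    # from earlier calls on this genome), then plant per sample.  The
    # planted subsets are drawn up front so planting can steer clear of
    # unplanted footprints (overlapping peaks would otherwise inherit a
    # neighbour's motif and push the recovered fraction above the rate).
    protected = _planted_windows(truth)
    scrub_motifs(genome, peaks_a + peaks_b, config.planted_motifs,
                 protected=protected)
    chosen: dict[str, set[int]] = {}
    for sample, peaks in ((name_a, peaks_a), (name_b, peaks_b)):
        n_plant = int(round(config.motif_plant_rate * len(peaks)))
        chosen[sample] = set(
            rng.choice(len(peaks), size=n_plant, replace=False).tolist())
    avoid = _unplanted_footprints(truth)
    for sample, peaks in ((name_a, peaks_a), (name_b, peaks_b)):
        avoid.extend((p.chrom, p.start, p.end)
                     for i, p in enumerate(peaks)
                     if i not in chosen[sample])
    for sample, peaks, targets in ((name_a, peaks_a, targets_a),
                                   (name_b, peaks_b, targets_b)):
        planted = plant_motifs(genome, peaks, sorted(chosen[sample]),
                               config, rng, protected=protected,
                               avoid=avoid)
        protected.extend((c, pos, pos + len(v))
                         for _, c, pos, v, _ in planted)
        truth.peaks[sample] = [(p.name, p.chrom, p.start, p.end)
                               for p in peaks]
        truth.peak_target_gene[sample] = dict(targets)
        truth.motif_positions[sample] = planted
        truth.bound_genes[sample] = {
            g for g in targets.values() if g is not None
        }
    refresh_motif_truth(truth)
    return {name_a: peaks_a, name_b: peaks_b}, truth


def _unplanted_footprints(truth: TruthTables) -> list[tuple[str, int, int]]:
    out = []
    for sample, recs in truth.peaks.items():
        with_motif = truth.motif_peaks.get(sample, set())
        out.extend((chrom, s, e) for pid, chrom, s, e in recs
                   if pid not in with_motif)
    return out


def _planted_windows(truth: TruthTables) -> list[tuple[str, int, int]]:
    return [
        (chrom, pos, pos + len(variant))
        for recs in truth.motif_positions.values()
        for _, chrom, pos, variant, _ in recs
    ]


def refresh_motif_truth(truth: TruthTables) -> None:
    """Recompute motif-bearing truth across all samples.

    A peak counts as motif-bearing when any planted window (from any
    sample -- footprints can overlap across samples and states) lies
    fully inside its span.
    """
    windows = _planted_windows(truth)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in windows:
        by_chrom.setdefault(chrom, []).append((s, e))
    for sample, recs in truth.peaks.items():
        motif_peaks = {
            pid
            for pid, chrom, start, end in recs
            if any(s >= start and e <= end
                   for s, e in by_chrom.get(chrom, ()))
        }
        truth.motif_peaks[sample] = motif_peaks
        targets = truth.peak_target_gene[sample]
        truth.bound_with_motif_genes[sample] = {
            g for pid, g in targets.items()
            if g is not None and pid in motif_peaks
        }


def scrub_motifs(genome: dict[str, bytearray], peaks: Sequence[Peak],
                 variants: Sequence[str],
                 protected: Sequence[tuple[str, int, int]] = ()) -> None:
    """Destroy incidental consensus occurrences inside peak footprints.

    Each occurrence (either strand) gets its central base swapped (pyrimidine
    <-> A, purine <-> C breaks every listed variant) and the footprint is
    rescanned until clean.  Windows in ``protected`` (already-planted
    motifs) are left untouched.
    """
    probes = [MotifConsensus(f"v{i}", v) for i, v in enumerate(variants)]

    def is_protected(chrom: str, s: int, e: int) -> bool:
        return any(c == chrom and s < pe and e > ps
                   for c, ps, pe in protected)

    for p in peaks:
        seq_bytes = genome[p.chrom]
        for _ in range(30):
            seq = bytes(seq_bytes[p.start:p.end]).decode("ascii")
            hits = []
            for probe in probes:
                hits += scan(seq, probe, both_strands=True)
            hits = [h for h in hits
                    if not is_protected(p.chrom, p.start + h.offset,
                                        p.start + h.end)]
            if not hits:
                break
            for h in hits:
                pos = p.start + h.offset + len(h.matched) // 2
                current = chr(seq_bytes[pos])
                seq_bytes[pos] = ord("A" if current in "GT" else "T")
        else:
            raise RuntimeError(f"could not scrub motifs in {p.name}")


def plant_motifs(genome: dict[str, bytearray], peaks: Sequence[Peak],
                 chosen_idx: Sequence[int] | None,
                 config: SimulationConfig, rng: np.random.Generator,
                 protected: Sequence[tuple[str, int, int]] = (),
                 avoid: Sequence[tuple[str, int, int]] = ()
                 ) -> list[tuple[str, str, int, str, str]]:
    """Overwrite one consensus instance into the chosen peaks.

    ``chosen_idx`` defaults to a fresh ``motif_plant_rate`` draw.
    Planting overwrites reference bases (no insertion) so coordinates
    stay fixed; positions avoid windows already holding a planted motif
    and, where possible, footprints of unplanted peaks.  Returns
    (peak_id, chrom, pos, variant, strand) records.
    """
    if chosen_idx is None:
        n_plant = int(round(config.motif_plant_rate * len(peaks)))
        chosen_idx = sorted(
            rng.choice(len(peaks), size=n_plant, replace=False).tolist())
    planted = []
    local_protected = list(protected)
    for i in chosen_idx:
        p = peaks[i]
        variant = str(rng.choice(config.planted_motifs))
        strand = "+" if rng.random() < 0.5 else "-"
        word = variant if strand == "+" else reverse_complement(variant)
        pos = None
        for tries in range(100):
            cand = int(rng.integers(p.start, p.end - len(word)))
            span = (p.chrom, cand, cand + len(word))
            if any(c == span[0] and span[1] < pe and span[2] > ps
                   for c, ps, pe in local_protected):
                continue
            clear_of_avoid = not any(
                c == span[0] and span[1] < pe and span[2] > ps
                for c, ps, pe in avoid)
            if clear_of_avoid or tries >= 80:
                # after 80 tries accept an avoid clash (peak may sit
                # entirely inside an unplanted neighbour)
                pos = cand
                break
        if pos is None:
            pos = int(rng.integers(p.start, p.end - len(word)))
        genome[p.chrom][pos:pos + len(word)] = word.encode("ascii")
        local_protected.append((p.chrom, pos, pos + len(word)))
        planted.append((p.name, p.chrom, pos, variant, strand))
    return planted


# ---------------------------------------------------------------------------
# tags
# ---------------------------------------------------------------------------

def generate_tags(peaks: Sequence[Peak], config: SimulationConfig,
                  chrom_sizes: Mapping[str, int],
                  rng: np.random.Generator | None = None
                  ) -> tuple[TagLibrary, TagLibrary]:
    """Treatment and control tag libraries.

    Control: homogeneous Poisson at ``background_tag_rate`` per bp.
    Treatment: the same background plus (enrichment - 1) x background
    extra rate inside peak footprints, so enrichment=1 is an exact null.
    Totals differ, exercising library scaling downstream.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    rate = config.background_tag_rate

    def uniform_tags(n_by_chrom: dict[str, int]) -> dict[str, np.ndarray]:
        return {
            c: np.sort(rng.integers(0, chrom_sizes[c], size=n))
            for c, n in n_by_chrom.items()
        }

    control_n = {c: rng.poisson(rate * size)
                 for c, size in chrom_sizes.items()}
    control_pos = uniform_tags(control_n)

    treat_n = {c: rng.poisson(rate * size)
               for c, size in chrom_sizes.items()}
    treat_pos = {c: list(p) for c, p in uniform_tags(treat_n).items()}
    extra_rate = rate * (config.tag_enrichment - 1.0)
    for p in peaks:
        n_extra = rng.poisson(extra_rate * p.interval.length)
        if n_extra:
            extra = rng.integers(p.start, p.end, size=n_extra)
            treat_pos[p.chrom].extend(extra.tolist())
    treatment = TagLibrary(
        positions={c: np.sort(np.asarray(v, dtype=np.int64))
                   for c, v in treat_pos.items()},
        chrom_sizes=dict(chrom_sizes),
    )
    control = TagLibrary(
        positions={c: np.asarray(v, dtype=np.int64)
                   for c, v in control_pos.items()},
        chrom_sizes=dict(chrom_sizes),
    )
    for lib in (treatment, control):
        lib.strands = {
            c: np.where(rng.random(len(pos)) < 0.5, "+", "-")
            for c, pos in lib.positions.items()
        }
    return treatment, control


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def generate_expression(genes: Sequence[GeneModel],
                        bound_with_motif: set[str],
                        config: SimulationConfig,
                        rng: np.random.Generator | None = None,
                        label: str = "cellA_rest"
                        ) -> tuple[ExpressionMatrix, dict[str, float],
                                   set[str]]:
    """WT/KO log2 matrices with planted effects.

    A ``de_fraction`` of motif-bearing bound genes (and a small
    ``null_de_fraction`` of the remaining genes) get a +-log2(de_effect)
    shift in KO, with ``fraction_down`` of the shifts negative.
    Replicate noise is Normal(0, replicate_sd) on the log2 scale.  A
    ``below_floor_fraction`` of unbound, unshifted genes sits below the
    above-background floor in every sample.

    Returns the matrix, {gene: signed linear effect} truth, and the
    below-floor gene set.
    """
    if config.de_fraction > 1:
        raise ValueError("de_fraction > 1")
    rng = rng or np.random.default_rng(config.seed + 3)
    gene_ids = [g.gene_id for g in genes]
    n = len(gene_ids)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    baseline = np.maximum(baseline, config.above_background_floor + 0.5)

    bound_list = sorted(bound_with_motif)
    n_de_bound = int(round(config.de_fraction * len(bound_list)))
    de_bound = set(
        np.array(bound_list)[
            rng.choice(len(bound_list), size=n_de_bound, replace=False)
        ].tolist()
    ) if bound_list else set()
    others = [g for g in gene_ids if g not in bound_with_motif]
    n_de_null = int(round(config.null_de_fraction * len(others)))
    de_null = set(
        np.array(others)[
            rng.choice(len(others), size=n_de_null, replace=False)
        ].tolist()
    ) if others else set()

    eligible_floor = [g for g in others
                      if g not in de_null]
    n_floor = int(round(config.below_floor_fraction * n))
    n_floor = min(n_floor, len(eligible_floor))
    below_floor = set(
        np.array(eligible_floor)[
            rng.choice(len(eligible_floor), size=n_floor, replace=False)
        ].tolist()
    ) if n_floor else set()

    effects: dict[str, float] = {}
    delta = np.zeros(n)
    for i, g in enumerate(gene_ids):
        if g in below_floor:
            baseline[i] = config.above_background_floor - 1.5
            continue
        if g in de_bound or g in de_null:
            sign = -1.0 if rng.random() < config.fraction_down else 1.0
            delta[i] = sign * np.log2(config.de_effect)
            effects[g] = sign * config.de_effect

    reps = config.n_replicates
    wt = baseline[:, None] + rng.normal(0, config.replicate_sd, (n, reps))
    ko = (baseline + delta)[:, None] + rng.normal(
        0, config.replicate_sd, (n, reps))
    wt_cols = [f"{label}_WT_r{i + 1}" for i in range(reps)]
    ko_cols = [f"{label}_KO_r{i + 1}" for i in range(reps)]
    values = pd.DataFrame(np.hstack([wt, ko]), index=gene_ids,
                          columns=wt_cols + ko_cols)
    cell_type, _, state = label.partition("_")
    samples = pd.DataFrame(
        {
            "group": ["WT"] * reps + ["KO"] * reps,
            "cell_type": cell_type,
            "state": state or "resting",
        },
        index=wt_cols + ko_cols,
    )
    return ExpressionMatrix(values, samples), effects, below_floor


# ---------------------------------------------------------------------------
# full scenario
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    config: SimulationConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    chrom_sizes: dict[str, int]
    peaks: dict[str, list[Peak]]
    expression: dict[str, ExpressionMatrix]
    histone_track: list[GenomicInterval]
    truth: TruthTables


def simulate_study(config: SimulationConfig | None = None) -> SimulatedStudy:
    """Generate the default two-cell-type, two-state scenario.

    Sample labels are ``{cellA,cellB}_{rest,act}``; peak overlap between
    the two cell types is controlled per state.  Expression matrices are
    generated per sample from that sample's motif-bearing bound genes.
    A histone-mark-like track covers 85% of cellA resting peaks plus
    background intervals.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    genome_b, genes = generate_genome(config, rng)
    sizes = chrom_sizes_of(genome_b)
    truth = TruthTables()
    peaks: dict[str, list[Peak]] = {}
    for state in ("rest", "act"):
        pair, truth = plant_peaks_and_motifs(
            genome_b, genes, config, rng,
            samples=(f"cellA_{state}", f"cellB_{state}"), truth=truth)
        peaks.update(pair)

    expression: dict[str, ExpressionMatrix] = {}
    for sample in peaks:
        matrix, effects, floor = generate_expression(
            genes, truth.bound_with_motif_genes[sample], config, rng,
            label=sample)
        expression[sample] = matrix
        truth.de_effects[sample] = effects
        truth.below_floor_genes[sample] = floor
        truth.regulated_genes[sample] = (
            set(effects) & truth.bound_with_motif_genes[sample]
        )

    anchor = peaks["cellA_rest"]
    n_cover = int(round(0.85 * len(anchor)))
    covered = rng.choice(len(anchor), size=n_cover, replace=False)
    track = [
        GenomicInterval(p.chrom,
                        max(0, p.start - int(rng.integers(0, 200))),
                        min(sizes[p.chrom],
                            p.end + int(rng.integers(0, 200))))
        for p in (anchor[i] for i in sorted(covered.tolist()))
    ]
    for _ in range(len(anchor) // 2):
        chrom = f"chr{int(rng.integers(1, config.n_chroms + 1))}"
        length = int(rng.integers(500, 2000))
        start = int(rng.integers(0, sizes[chrom] - length))
        if not any(p.chrom == chrom and p.start < start + length
                   and p.end > start for p in anchor):
            track.append(GenomicInterval(chrom, start, start + length))
    track.sort(key=lambda iv: (iv.chrom, iv.start))

    return SimulatedStudy(
        config=config,
        genome=finalize_genome(genome_b),
        genes=genes,
        chrom_sizes=sizes,
        peaks=peaks,
        expression=expression,
        histone_track=track,
        truth=truth,
    )


def write_study(study: SimulatedStudy, outdir: str | Path) -> dict[str, str]:
    """Write FASTA, BEDs, expression TSVs and the truth JSON; returns a
    manifest of paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    fasta = outdir / "genome.fa"
    write_fasta(study.genome, fasta)
    manifest["genome"] = str(fasta)
    gene_path = outdir / "genes.tsv"
    write_gene_table(study.genes, gene_path)
    manifest["genes"] = str(gene_path)
    for sample, pk in study.peaks.items():
        path = outdir / f"peaks_{sample}.bed"
        write_bed(sorted(pk, key=lambda p: (p.chrom, p.start)), path)
        manifest[f"peaks:{sample}"] = str(path)
    for sample, matrix in study.expression.items():
        mpath = outdir / f"expr_{sample}.tsv"
        spath = outdir / f"samples_{sample}.tsv"
        write_expression(matrix, mpath, spath)
        manifest[f"expression:{sample}"] = str(mpath)
        manifest[f"samples:{sample}"] = str(spath)
    track_path = outdir / "histone_track.bed"
    write_bed([Peak(iv) for iv in study.histone_track], track_path)
    manifest["histone_track"] = str(track_path)
    truth_path = outdir / "truth.json"
    truth_path.write_text(study.truth.to_json())
    manifest["truth"] = str(truth_path)
    sizes_path = outdir / "chrom_sizes.tsv"
    with open(sizes_path, "w") as fh:
        for c, s in sorted(study.chrom_sizes.items()):
            fh.write(f"{c}\t{s}\n")
    manifest["chrom_sizes"] = str(sizes_path)
    return manifest


def generate_study_tags(study: SimulatedStudy, sample: str = "cellA_rest",
                        seed: int | None = None
                        ) -> tuple[TagLibrary, TagLibrary]:
    """Tag libraries for one sample of an existing study."""
    rng = np.random.default_rng(
        study.config.seed + 2 if seed is None else seed)
    return generate_tags(study.peaks[sample], study.config,
                         study.chrom_sizes, rng)
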