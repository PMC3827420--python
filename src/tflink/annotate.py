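"""Peak-to-gene association via basal-plus-extension regulatory domains.

Each gene gets a basal domain around its TSS (5 kb upstream / 1 kb
downstream by default, oriented by strand) extended on each side to the
nearest neighbouring basal domain, capped at a maximum extension and at
chromosome ends.  A peak is assigned to every gene whose regulatory
domain contains the peak midpoint (at most two under this construction),
and classified by absolute midpoint-to-TSS distance into promoter-
proximal and increasingly distal bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

from tflink.core import (
    GenomicInterval,
    GeneModel,
    Peak,
    intersect_sets,
    is_sorted,
    sort_peaks,
)

DISTANCE_BINS = ("<1kb", "1-5kb", "5-50kb", ">50kb")


@dataclass
class DomainConfig:
    basal_upstream: int = 5000
    basal_downstream: int = 1000
    max_extension: int = 1_000_000

    def __post_init__(self) -> None:
        if min(self.basal_upstream, self.basal_downstream,
               self.max_extension) <= 0:
            raise ValueError("domain parameters must be positive")
        if self.max_extension < self.basal_upstream:
            raise ValueError("max_extension must cover the basal domain")


@dataclass(frozen=True)
class RegulatoryDomain:
    gene_id: str
    interval: GenomicInterval
    basal: GenomicInterval
    tss: int


@dataclass(frozen=True)
class PeakGeneAssignment:
    peak_id: str
    gene_id: str
    distance: int
    bin: str


@dataclass
class StateComparison:
    """Partition of resting vs activated items into maintained/lost/de-novo."""

    maintained: set
    lost: set
    de_novo: set


def distance_bin(distance: int) -> str:
    if distance < 1000:
        return "<1kb"
    if distance < 5000:
        return "1-5kb"
    if distance < 50_000:
        return "5-50kb"
    return ">50kb"


def basal_domain(gene: GeneModel, config: DomainConfig) -> GenomicInterval:
    if gene.strand == "+":
        start = gene.tss - config.basal_upstream
        end = gene.tss + config.basal_downstream
    else:
        start = gene.tss - config.basal_downstream
        end = gene.tss + config.basal_upstream
    return GenomicInterval(gene.chrom, max(0, start), end)


def build_domains(genes: Sequence[GeneModel],
                  chrom_sizes: Mapping[str, int],
                  config: DomainConfig | None = None
                  ) -> list[RegulatoryDomain]:
    """Basal-plus-extension domains for all genes (sorted by chrom, TSS)."""
    config = config or DomainConfig()
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out: list[RegulatoryDomain] = []
    for chrom in sorted(by_chrom):
        size = chrom_sizes[chrom]
        chrom_genes = sorted(by_chrom[chrom], key=lambda g: g.tss)
        basals = [basal_domain(g, config) for g in chrom_genes]
        for i, g in enumerate(chrom_genes):
            b = basals[i]
            cap_left = max(0, g.tss - config.max_extension)
            cap_right = min(size, g.tss + config.max_extension)
            left_neighbour = max(
                (basals[j].end for j in range(i) if basals[j].end <= b.start),
                default=0,
            )
            right_neighbour = min(
                (basals[j].start for j in range(i + 1, len(chrom_genes))
                 if basals[j].start >= b.end),
                default=size,
            )
            start = min(b.start, max(cap_left, left_neighbour))
            end = max(b.end, min(cap_right, right_neighbour))
            end = min(end, size)
            out.append(RegulatoryDomain(
                g.gene_id,
                GenomicInterval(chrom, start, end),
                GenomicInterval(chrom, b.start, min(b.end, size)),
                g.tss,
            ))
    return out


def assign_peaks(peaks: Sequence[Peak], domains: Sequence[RegulatoryDomain],
                 mode: Literal["domains", "nearest"] = "domains"
                 ) -> list[PeakGeneAssignment]:
    """Assign each peak to genes whose domain contains its midpoint.

    ``mode='nearest'`` keeps only the assignment with the smallest
    TSS distance per peak.
    """
    by_chrom: dict[str, list[RegulatoryDomain]] = {}
    for d in domains:
        by_chrom.setdefault(d.interval.chrom, []).append(d)
    out: list[PeakGeneAssignment] = []
    for i, p in enumerate(peaks):
        pid = p.name or f"peak_{i + 1}"
        mid = p.midpoint
        matches = [
            d for d in by_chrom.get(p.chrom, ())
            if d.interval.start <= mid < d.interval.end
        ]
        assignments = [
            PeakGeneAssignment(pid, d.gene_id, abs(mid - d.tss),
                               distance_bin(abs(mid - d.tss)))
            for d in matches
        ]
        if mode == "nearest" and assignments:
            assignments = [min(assignments, key=lambda a: a.distance)]
        out.extend(assignments)
    return out


def bin_fractions(assignments: Sequence[PeakGeneAssignment]
                  ) -> dict[str, float]:
    """Distribution of assigned peaks over TSS-distance bins.

    Each peak contributes once, via its nearest assigned TSS.
    """
    nearest: dict[str, int] = {}
    for a in assignments:
        cur = nearest.get(a.peak_id)
        if cur is None or a.distance < cur:
            nearest[a.peak_id] = a.distance
    n = len(nearest)
    if n == 0:
        raise ValueError("no assignments")
    out = {b: 0.0 for b in DISTANCE_BINS}
    for d in nearest.values():
        out[distance_bin(d)] += 1
    return {b: v / n for b, v in out.items()}


def bound_genes(assignments: Sequence[PeakGeneAssignment]) -> set[str]:
    return {a.gene_id for a in assignments}


def peak_set_overlap(a: Sequence[Peak], b: Sequence[Peak]) -> dict:
    """Fraction of A peaks sharing >= 1 bp with any B peak."""
    if not a:
        raise ValueError("empty A peak set: overlap fraction undefined")
    a_sorted = a if is_sorted(a) else sort_peaks(a)
    b_sorted = b if is_sorted(b) else sort_peaks(b)
    pairs = intersect_sets(a_sorted, b_sorted)
    hit_a = {id(pa) for pa, _ in pairs}
    n_overlap = sum(1 for p in a_sorted if id(p) in hit_a)
    return {
        "n_A": len(a),
        "n_B": len(b),
        "n_A_overlapping": n_overlap,
        "fraction": n_overlap / len(a),
    }


def gene_set_overlap(a: set[str], b: set[str]) -> dict:
    """Exact intersection with the percentage-of-A rounded for reporting."""
    inter = a & b
    fraction = len(inter) / len(a) if a else float("nan")
    return {
        "n_A": len(a),
        "n_B": len(b),
        "n_intersection": len(inter),
        "fraction_of_A": fraction,
        "percent_of_A": round(100 * fraction) if a else None,
    }


def compare_states(resting, activated,
                   level: Literal["region", "gene"] = "gene",
                   ) -> StateComparison:
    """Maintained / lost / de-novo partition between two states.

    At gene level the inputs are id sets.  At region level they are peak
    lists and membership is the >= 1 bp overlap rule: maintained =
    resting peaks overlapping any activated peak, plus activated peaks
    overlapping any resting peak (keyed by interval).
    """
    if level == "gene":
        resting_set, activated_set = set(resting), set(activated)
        return StateComparison(
            maintained=resting_set & activated_set,
            lost=resting_set - activated_set,
            de_novo=activated_set - resting_set,
        )
    r_sorted = sort_peaks(resting)
    a_sorted = sort_peaks(activated)
    pairs = intersect_sets(r_sorted, a_sorted)
    r_hit = {(p.chrom, p.start, p.end) for p, _ in pairs}
    a_hit = {(p.chrom, p.start, p.end) for _, p in pairs}
    r_keys = {(p.chrom, p.start, p.end) for p in resting}
    a_keys = {(p.chrom, p.start, p.end) for p in activated}
    return StateComparison(
        maintained=r_hit | a_hit,
        lost=r_keys - r_hit,
        de_novo=a_keys - a_hit,
    )


def track_overlap_fraction(peaks: Sequence[Peak],
                           track: Sequence[GenomicInterval],
                           assignments: Sequence[PeakGeneAssignment] = (),
                           ) -> dict:
    """Fraction of peaks overlapping a second track (histone mark, p300...).

    When peak-gene assignments are supplied, also reports the fraction of
    bound genes with >= 1 overlapping peak.
    """
    track_peaks = sort_peaks(Peak(iv) for iv in track)
    p_sorted = sort_peaks(peaks)
    pairs = intersect_sets(p_sorted, track_peaks)
    hit = {(p.chrom, p.start, p.end) for p, _ in pairs}
    n_hit = sum(1 for p in peaks if (p.chrom, p.start, p.end) in hit)
    out = {
        "n_peaks": len(peaks),
        "n_overlapping": n_hit,
        "fraction": n_hit / len(peaks) if peaks else 0.0,
    }
    if assignments:
        name_of = {}
        for i, p in enumerate(peaks):
            name_of[p.name or f"peak_{i + 1}"] = (p.chrom, p.start, p.end)
        genes_all = {a.gene_id for a in assignments}
        genes_hit = {
            a.gene_id for a in assignments
            if name_of.get(a.peak_id) in hit
        }
        out["n_genes"] = len(genes_all)
        out["gene_fraction"] = (len(genes_hit) / len(genes_all)
                                if genes_all else 0.0)
    return out
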