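"""IUPAC consensus scanning, background-sampled Z-score enrichment, and
two-motif module detection.

The canonical RUNX recognition sequence is the degenerate hexamer TGYGGY
(variants TGTGGT, TGTGGC, TGCGGT, TGCGGC).  Scanning is consensus-based:
every start position on either strand whose window matches the IUPAC
pattern is a hit; overlapping occurrences count separately and distinct
(position, strand) pairs are distinct hits.  Enrichment is measured as a
Z-score of the observed hit total against totals in length-matched
regions sampled from the genomic background.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from tflink.core import GenomicInterval, Peak

IUPAC_SETS: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    # N in a pattern matches any base including an N in the sequence;
    # every other code rejects sequence Ns.
    "N": "ACGTN",
}

COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: Published core consensi used for module analysis; all configurable.
DEFAULT_MOTIFS: dict[str, str] = {
    "RUNX": "TGYGGY",
    "ETS": "MGGAA",
    "AP1": "TGASTCA",
}

RUNX_VARIANTS = ("TGTGGT", "TGTGGC", "TGCGGT", "TGCGGC")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifConsensus:
    """A named IUPAC consensus."""

    name: str
    iupac: str

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ValueError("empty consensus")
        bad = set(self.iupac.upper()) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"invalid IUPAC letters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.iupac)

    def expand(self) -> list[str]:
        """All concrete ACGT words matching the consensus."""
        words = [""]
        for code in self.iupac.upper():
            bases = [b for b in IUPAC_SETS[code] if b != "N"]
            words = [w + b for w in words for b in bases]
        return words


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence inside a region's local coordinate frame."""

    region_id: str
    motif: str
    offset: int
    strand: str
    matched: str

    @property
    def end(self) -> int:
        return self.offset + len(self.matched)


@dataclass(frozen=True)
class ModuleHit:
    """Two motif occurrences in one region within ``gap`` bp edge-to-edge."""

    hit_a: MotifHit
    hit_b: MotifHit
    gap: int


@dataclass
class EnrichmentZ:
    name: str
    observed: int
    background_mean: float
    background_sd: float
    z: float | None
    n_background_samples: int
    seed: int | None = None


def _compile(motif: MotifConsensus) -> re.Pattern[str]:
    classes = []
    for code in motif.iupac.upper():
        bases = IUPAC_SETS[code]
        classes.append(bases if len(bases) == 1 else f"[{bases}]")
    # lookahead so overlapping occurrences are all reported
    return re.compile("(?=(" + "".join(classes) + "))")


def scan(seq: str, motif: MotifConsensus, region_id: str = "region",
         both_strands: bool = True) -> list[MotifHit]:
    """All occurrences of ``motif`` in ``seq`` (both strands by default).

    Minus-strand hit offsets refer to the forward-strand coordinate of the
    occurrence's left edge; ``matched`` is the motif-strand word.
    """
    seq = seq.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError("sequence must be over ACGTN")
    pattern = _compile(motif)
    hits = [
        MotifHit(region_id, motif.name, m.start(), "+", m.group(1))
        for m in pattern.finditer(seq)
    ]
    if both_strands:
        rc = reverse_complement(seq)
        n, m_len = len(seq), len(motif)
        hits += [
            MotifHit(region_id, motif.name, n - m.start() - m_len, "-",
                     m.group(1))
            for m in pattern.finditer(rc)
        ]
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def region_sequences(peaks: Sequence[Peak], genome: Mapping[str, str]
                     ) -> dict[str, str]:
    """Extract per-peak sequences; errors name the offending peak."""
    out: dict[str, str] = {}
    for i, p in enumerate(peaks):
        rid = p.name or f"peak_{i + 1}"
        chrom_seq = genome[p.chrom]
        if p.end > len(chrom_seq):
            raise ValueError(
                f"peak {rid} ({p.chrom}:{p.start}-{p.end}) beyond "
                f"chromosome end {len(chrom_seq)}"
            )
        out[rid] = str(chrom_seq[p.start:p.end]).upper()
    return out


def region_motif_summary(peaks: Sequence[Peak], genome: Mapping[str, str],
                         motifs: Iterable[MotifConsensus],
                         both_strands: bool = True):
    """Per-region per-variant hit counts plus the fraction of regions with
    >= 1 hit of any listed motif.

    Returns ``(counts, fraction, hits_by_region)`` where ``counts`` maps
    region id -> {matched variant -> n}.
    """
    motifs = list(motifs)
    seqs = region_sequences(peaks, genome)
    counts: dict[str, dict[str, int]] = {}
    hits_by_region: dict[str, list[MotifHit]] = {}
    n_with_hit = 0
    for rid, seq in seqs.items():
        region_hits: list[MotifHit] = []
        for motif in motifs:
            region_hits += scan(seq, motif, region_id=rid,
                                both_strands=both_strands)
        hits_by_region[rid] = region_hits
        per_variant: dict[str, int] = {}
        for h in region_hits:
            per_variant[h.matched] = per_variant.get(h.matched, 0) + 1
        counts[rid] = per_variant
        if region_hits:
            n_with_hit += 1
    fraction = n_with_hit / len(seqs) if seqs else 0.0
    return counts, fraction, hits_by_region


def sample_background(genome: Mapping[str, str], n_regions: int,
                      length_source: Sequence[int], seed: int,
                      exclusion: Sequence[GenomicInterval] = (),
                      max_tries_per_region: int = 1000) -> list[Peak]:
    """Length-matched control regions placed uniformly outside ``exclusion``.

    Lengths are resampled with replacement from ``length_source``;
    placement is uniform over chromosomes weighted by length.  Raises if a
    region cannot be placed within the retry budget.
    """
    rng = np.random.default_rng(seed)
    chroms = sorted(genome)
    sizes = np.array([len(genome[c]) for c in chroms], dtype=float)
    if not len(length_source):
        raise ValueError("length_source is empty")
    excl_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in exclusion:
        excl_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for c in excl_by_chrom:
        excl_by_chrom[c].sort()
    excl_starts = {c: np.array([s for s, _ in v])
                   for c, v in excl_by_chrom.items()}
    excl_ends = {c: np.array([e for _, e in v])
                 for c, v in excl_by_chrom.items()}

    def clashes(chrom: str, start: int, end: int) -> bool:
        if chrom not in excl_starts:
            return False
        i = np.searchsorted(excl_starts[chrom], end, side="left")
        return bool(np.any(excl_ends[chrom][:i] > start))

    lengths = rng.choice(np.asarray(length_source, dtype=np.int64),
                         size=n_regions, replace=True)
    out: list[Peak] = []
    for i, length in enumerate(lengths):
        placed = False
        for _ in range(max_tries_per_region):
            ci = rng.choice(len(chroms), p=sizes / sizes.sum())
            chrom = chroms[ci]
            limit = len(genome[chrom]) - int(length)
            if limit <= 0:
                continue
            start = int(rng.integers(0, limit))
            if clashes(chrom, start, start + int(length)):
                continue
            out.append(Peak(GenomicInterval(chrom, start, start + int(length)),
                            name=f"bg_{i + 1}"))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place background region {i + 1} after "
                f"{max_tries_per_region} tries (exclusion too dense?)"
            )
    return out


def count_hits(peaks: Sequence[Peak], genome: Mapping[str, str],
               motif: MotifConsensus, both_strands: bool = True) -> int:
    seqs = region_sequences(peaks, genome)
    return sum(len(scan(s, motif, both_strands=both_strands))
               for s in seqs.values())


def motif_zscore(observed_regions: Sequence[Peak],
                 genome: Mapping[str, str], motif: MotifConsensus,
                 background_sets: Sequence[Sequence[Peak]],
                 both_strands: bool = True,
                 seed: int | None = None) -> EnrichmentZ:
    """Z of observed hit total vs totals over B background region sets."""
    if len(background_sets) < 30:
        raise ValueError("need >= 30 background sets for a stable Z")
    observed = count_hits(observed_regions, genome, motif, both_strands)
    totals = np.array([
        count_hits(bg, genome, motif, both_strands)
        for bg in background_sets
    ], dtype=float)
    mean, sd = float(totals.mean()), float(totals.std(ddof=1))
    z = (observed - mean) / sd if sd > 0 else None
    return EnrichmentZ(motif.name, observed, mean, sd, z,
                       len(background_sets), seed)


def find_modules(hits_a: Sequence[MotifHit], hits_b: Sequence[MotifHit],
                 max_gap: int = 50) -> list[ModuleHit]:
    """All same-region pairs with edge-to-edge gap <= ``max_gap``.

    Overlapping occurrences have gap 0.  When both lists are the same
    motif, a module needs two distinct hits and each unordered pair is
    reported once.
    """
    same = (list(hits_a) == list(hits_b))
    by_region: dict[str, list[MotifHit]] = {}
    for h in hits_b:
        by_region.setdefault(h.region_id, []).append(h)
    out: list[ModuleHit] = []
    seen: set[tuple] = set()
    for ha in hits_a:
        for hb in by_region.get(ha.region_id, ()):
            if ha == hb:
                continue
            gap = max(0, max(ha.offset, hb.offset)
                      - min(ha.end, hb.end))
            if gap > max_gap:
                continue
            if same:
                key = tuple(sorted([(ha.offset, ha.strand, ha.matched),
                                    (hb.offset, hb.strand, hb.matched)]))
                full_key = (ha.region_id,) + key
                if full_key in seen:
                    continue
                seen.add(full_key)
            out.append(ModuleHit(ha, hb, gap))
    return out


def module_density_per_kb(n_modules: int, regions: Sequence[Peak]) -> float:
    total_bp = sum(p.interval.length for p in regions)
    if total_bp == 0:
        raise ValueError("empty region set")
    return n_modules / (total_bp / 1000.0)


def module_enrichment(partitions: Mapping[str, Sequence[Peak]],
                      genome: Mapping[str, str],
                      motif_a: MotifConsensus, motif_b: MotifConsensus,
                      background: Sequence[Peak],
                      max_gap: int = 50) -> dict[str, float | None]:
    """Per-partition fold enrichment of the (a, b) module density (per kb)
    over the matched background density.  Empty partitions report None."""
    def modules_in(regions: Sequence[Peak]) -> int:
        seqs = region_sequences(regions, genome)
        total = 0
        for rid, seq in seqs.items():
            ha = scan(seq, motif_a, region_id=rid)
            hb = (ha if motif_a == motif_b
                  else scan(seq, motif_b, region_id=rid))
            total += len(find_modules(ha, hb, max_gap=max_gap))
        return total

    bg_density = module_density_per_kb(modules_in(background), background)
    out: dict[str, float | None] = {}
    for name, regions in partitions.items():
        if not regions:
            out[name] = None
            continue
        dens = module_density_per_kb(modules_in(regions), regions)
        out[name] = dens / bg_density if bg_density > 0 else None
    return out


def read_motif_table(path) -> list[MotifConsensus]:
    """Read a two-column TSV (name, iupac) of motif definitions."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, iupac = line.split("\t")[:2]
            if name.lower() == "name":
                continue
            out.append(MotifConsensus(name, iupac))
    return out
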