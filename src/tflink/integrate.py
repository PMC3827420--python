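"""Gene-set derivation and overlap statistics.

The integration step crosses three annotations of each gene -- bound
(>= 1 assigned peak), motif-bearing bound (>= 1 assigned peak carrying a
consensus motif hit) and responsive (passes the DE filter) -- into the
headline set of *regulated* genes (responsive AND motif-bearing bound).
Associations between sets are tested with 2x2 contingency tables
(Pearson chi-square and two-sided Fisher); the overlap between two gene
lists drawn from a common universe of size N has expectation n1*n2/N
with an exact hypergeometric upper-tail p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats


@dataclass
class GeneSets:
    """Derived gene sets with the invariant chain
    regulated <= responsive and regulated <= bound_with_motif <= bound <= universe."""

    universe: set[str]
    bound: set[str]
    bound_with_motif: set[str]
    responsive: set[str]
    regulated: set[str] = field(default_factory=set)
    provenance: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.regulated:
            self.regulated = self.responsive & self.bound_with_motif
        self.validate()

    def validate(self) -> None:
        if not self.bound <= self.universe:
            raise ValueError("bound genes outside universe")
        if not self.bound_with_motif <= self.bound:
            raise ValueError("motif-bearing bound genes not a subset of bound")
        if not self.responsive <= self.universe:
            extra = sorted(self.responsive - self.universe)[:5]
            raise ValueError(f"DE genes absent from universe: {extra}")
        if not self.regulated <= self.responsive:
            raise ValueError("regulated genes must be responsive")
        if not self.regulated <= self.bound_with_motif:
            raise ValueError("regulated genes must be motif-bearing bound")


@dataclass
class ContingencyResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    chi_square: float
    chi_square_p: float
    fisher_p: float
    odds_ratio: float


@dataclass
class OverlapStat:
    n1: int
    n2: int
    universe: int
    observed: int
    expected: float
    p_value: float


def derive_gene_sets(assignments, motif_hits_by_region: Mapping[str, list],
                     de_results, universe: set[str]) -> GeneSets:
    """Cross peak assignments, per-region motif hits and DE results.

    ``assignments`` are PeakGeneAssignment records; a gene is
    motif-bearing bound when at least one of its assigned peaks has at
    least one motif hit.  Provenance (peaks and matched variants) is kept
    for every regulated gene.
    """
    bound: set[str] = set()
    bound_with_motif: set[str] = set()
    gene_peaks: dict[str, list[str]] = {}
    for a in assignments:
        bound.add(a.gene_id)
        gene_peaks.setdefault(a.gene_id, []).append(a.peak_id)
    for gene, peaks in gene_peaks.items():
        if any(motif_hits_by_region.get(pid) for pid in peaks):
            bound_with_motif.add(gene)
    responsive = set(de_results.index[de_results["status"] != "ns"])
    sets = GeneSets(universe=universe, bound=bound & universe,
                    bound_with_motif=bound_with_motif & universe,
                    responsive=responsive)
    for gene in sets.regulated:
        variants = sorted({
            h.matched
            for pid in gene_peaks.get(gene, ())
            for h in motif_hits_by_region.get(pid, ())
        })
        sets.provenance[gene] = {
            "peaks": sorted(set(gene_peaks.get(gene, ()))),
            "motif_variants": variants,
            "status": str(de_results.loc[gene, "status"]),
        }
    return sets


# ---------------------------------------------------------------------------
# 2x2 statistics
# ---------------------------------------------------------------------------

def fisher_exact_grid(a: np.ndarray, r1: np.ndarray, c1: np.ndarray,
                      n: np.ndarray) -> np.ndarray:
    """Vectorised two-sided Fisher p for tables [[a, r1-a], [c1-a, n-r1-c1+a]].

    Sums hypergeometric point masses not exceeding the observed mass
    (with a small relative tolerance against float round-off), the same
    definition scipy uses.  Grouping by identical margins keeps the
    support enumeration shared.
    """
    a = np.atleast_1d(np.asarray(a, dtype=np.int64))
    r1 = np.broadcast_to(np.asarray(r1, dtype=np.int64), a.shape)
    c1 = np.broadcast_to(np.asarray(c1, dtype=np.int64), a.shape)
    n = np.broadcast_to(np.asarray(n, dtype=np.int64), a.shape)
    out = np.empty(len(a), dtype=float)
    margins: dict[tuple[int, int, int], list[int]] = {}
    for i in range(len(a)):
        margins.setdefault((int(n[i]), int(r1[i]), int(c1[i])), []).append(i)
    for (nn, rr, cc), idx in margins.items():
        lo = max(0, rr + cc - nn)
        hi = min(rr, cc)
        support = np.arange(lo, hi + 1)
        pmf = stats.hypergeom.pmf(support, nn, rr, cc)
        for i in idx:
            obs = pmf[int(a[i]) - lo]
            out[i] = float(pmf[pmf <= obs * (1 + 1e-10)].sum())
    return np.minimum(out, 1.0)


def contingency_association(set_a: set[str], set_b: set[str],
                            universe: set[str]) -> ContingencyResult:
    """Pearson chi-square (no continuity correction) and two-sided Fisher
    for membership of A vs membership of B over a finite universe."""
    if not (set_a <= universe and set_b <= universe):
        raise ValueError("sets must be subsets of the universe")
    n = len(universe)
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = n - a - b - c
    return contingency_from_table(((a, b), (c, d)))


def contingency_from_table(table: tuple[tuple[int, int], tuple[int, int]]
                           ) -> ContingencyResult:
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    arr = np.array(table, dtype=float)
    if arr.sum() == 0:
        raise ValueError("empty table")
    chi2, chi_p = _pearson_chi_square(arr)
    fisher_p = float(fisher_exact_grid(
        np.array([a]), np.array([a + b]), np.array([a + c]),
        np.array([a + b + c + d]))[0])
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return ContingencyResult(table, chi2, chi_p, fisher_p, odds)


def _pearson_chi_square(arr: np.ndarray) -> tuple[float, float]:
    row = arr.sum(axis=1, keepdims=True)
    col = arr.sum(axis=0, keepdims=True)
    expected = row @ col / arr.sum()
    if np.any(expected == 0):
        return float("nan"), float("nan")
    chi2 = float(((arr - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def expected_overlap(list1: set[str] | int, list2: set[str] | int,
                     universe: set[str] | int,
                     observed: int | None = None) -> OverlapStat:
    """Expected-by-chance overlap n1*n2/N and exact hypergeometric tail.

    Accepts either explicit sets (observed inferred from intersection)
    or printed sizes n1, n2, N with an explicit observed count.
    """
    if isinstance(universe, int):
        n_universe = universe
        n1, n2 = int(list1), int(list2)
        if observed is None:
            raise ValueError("observed count required with size-only input")
        k = observed
    else:
        n_universe = len(universe)
        set1, set2 = set(list1), set(list2)
        if not (set1 <= universe and set2 <= universe):
            raise ValueError("lists must be subsets of the universe")
        n1, n2 = len(set1), len(set2)
        k = len(set1 & set2) if observed is None else observed
    if k > min(n1, n2):
        raise ValueError(f"observed overlap {k} exceeds min(n1, n2)")
    if max(n1, n2) > n_universe:
        raise ValueError("list larger than universe")
    expected = n1 * n2 / n_universe
    p = float(stats.hypergeom.sf(k - 1, n_universe, n1, n2))
    return OverlapStat(n1, n2, n_universe, k, expected, p)


def overlap_p_monte_carlo(n1: int, n2: int, n_universe: int, observed: int,
                          n_draws: int = 100_000, seed: int = 0) -> float:
    """Monte-Carlo cross-check of the hypergeometric tail."""
    rng = np.random.default_rng(seed)
    draws = rng.hypergeometric(n1, n_universe - n1, n2, size=n_draws)
    return float((draws >= observed).mean())


def direction_concordance(common: Sequence[str], de_a, de_b) -> dict:
    """Fraction of shared regulated genes moving the same way in both
    cell types; reported with numerator and denominator."""
    same = 0
    for gene in common:
        sa = de_a.loc[gene, "status"]
        sb = de_b.loc[gene, "status"]
        if sa == "ns" or sb == "ns":
            raise ValueError(f"gene {gene} has status 'ns' in one input")
        same += int(sa == sb)
    n = len(common)
    if n == 0:
        raise ValueError("empty common gene list")
    return {
        "n_same_direction": same,
        "n_common": n,
        "fraction": same / n,
        "percent": round(100 * same / n),
    }


def category_fraction_test(n_in_set: int, set_total: int,
                           genome_fraction: float,
                           genome_total: int) -> ContingencyResult:
    """Is a category (e.g. transcription factors) over-represented in a
    gene set relative to its genome-wide frequency?"""
    if genome_total is None or genome_total <= 0:
        raise ValueError("genome gene total required")
    if not (0 < genome_fraction < 1):
        raise ValueError("genome_fraction must lie in (0, 1)")
    genome_in_cat = round(genome_fraction * genome_total)
    table = (
        (n_in_set, set_total - n_in_set),
        (genome_in_cat - n_in_set,
         genome_total - set_total - genome_in_cat + n_in_set),
    )
    return contingency_from_table(table)


def summarize_ratios(counts: Mapping[str, int],
                     pairs: Sequence[tuple[str, str]]) -> dict[str, dict]:
    """Printed-style ratios (one decimal) and percentages (nearest int)
    between named set sizes; full precision retained alongside."""
    out: dict[str, dict] = {}
    for num_key, den_key in pairs:
        num, den = counts[num_key], counts[den_key]
        if den == 0:
            raise ValueError(f"division by zero for {num_key}/{den_key}")
        ratio = num / den
        out[f"{num_key}/{den_key}"] = {
            "numerator": num,
            "denominator": den,
            "ratio": ratio,
            "ratio_1dp": round(ratio, 1),
            "percent": round(100 * ratio),
        }
    return out
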