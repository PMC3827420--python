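"""Pre-ranked gene-set enrichment analysis.

Genes are ranked by descending absolute linear fold change; the
enrichment score (ES) is the signed extremum of a running sum that
increments by |w_i|^p / sum_hits |w|^p at gene-set hits and decrements
by 1/(N - N_H) at misses.  Significance comes from a permutation null of
random same-size gene sets: NES is ES divided by the mean null ES of
matching sign, and the nominal p is the matching-sign tail fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class GseaConfig:
    weight_exponent: float = 1.0
    n_permutations: int = 1000
    seed: int = 0
    tie_policy: str = "stable-input-order"

    def __post_init__(self) -> None:
        if self.weight_exponent < 0:
            raise ValueError("weight exponent must be >= 0")
        if self.n_permutations < 100:
            raise ValueError("need >= 100 permutations")


@dataclass
class GseaResult:
    es: float
    nes: float | None
    nominal_p: float
    p_is_bound: bool
    leading_edge: int
    n_hits: int
    n_genes: int
    seed: int


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets from GMT (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 3:
                sets[fields[0]] = set(fields[2:])
    return sets


def write_gmt(sets: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na"] + sorted(members)) + "\n")


def rank_by_abs_fc(de: pd.DataFrame) -> pd.DataFrame:
    """Ranked table (descending |linear fold change|) with weights.

    Ties keep the stable input order of the DE table.  Missing fold
    changes are an error.
    """
    if "linear_fc" not in de.columns:
        raise ValueError("DE results lack a linear_fc column")
    if de["linear_fc"].isna().any():
        missing = list(de.index[de["linear_fc"].isna()])[:5]
        raise ValueError(f"missing fold change for {missing}")
    weights = de["linear_fc"].to_numpy(dtype=float)
    order = np.argsort(-weights, kind="stable")
    ranked = pd.DataFrame(
        {"weight": weights[order]},
        index=de.index[order],
    )
    fully_tied = bool(np.all(weights == weights[0]))
    ranked.attrs["fully_tied"] = fully_tied
    ranked.attrs["tie_policy"] = "stable-input-order"
    return ranked


def _running_sum(weights: np.ndarray, hits: np.ndarray,
                 p: float) -> np.ndarray:
    """Running-sum profile for one hit-indicator vector."""
    w = np.abs(weights) ** p
    hit_w = np.where(hits, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        raise ValueError("gene set does not intersect the ranked list")
    n_miss = len(weights) - int(hits.sum())
    if n_miss == 0:
        raise ValueError("gene set equals the whole ranked list")
    steps = hit_w / denom - np.where(hits, 0.0, 1.0 / n_miss)
    return np.cumsum(steps)


def enrichment_score(ranked: pd.DataFrame, gene_set: set[str],
                     config: GseaConfig | None = None
                     ) -> tuple[float, np.ndarray]:
    """ES (signed extremum of the running sum) plus the full profile."""
    config = config or GseaConfig()
    hits = ranked.index.isin(gene_set)
    profile = _running_sum(ranked["weight"].to_numpy(), hits,
                           config.weight_exponent)
    i = int(np.argmax(np.abs(profile)))
    return float(profile[i]), profile


def _null_es(weights: np.ndarray, n_hits: int, n_perm: int, p: float,
             rng: np.random.Generator, batch: int = 250) -> np.ndarray:
    """Null ES from random same-size gene sets, computed in batches."""
    n = len(weights)
    w = np.abs(weights) ** p
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        hit_mat = np.zeros((b, n), dtype=bool)
        for row in range(b):
            hit_mat[row, rng.choice(n, size=n_hits, replace=False)] = True
        hit_w = np.where(hit_mat, w[None, :], 0.0)
        denom = hit_w.sum(axis=1, keepdims=True)
        steps = hit_w / denom - (~hit_mat) / (n - n_hits)
        profiles = np.cumsum(steps, axis=1)
        idx = np.argmax(np.abs(profiles), axis=1)
        out[done:done + b] = profiles[np.arange(b), idx]
        done += b
    return out


def nes_and_pvalue(ranked: pd.DataFrame, gene_set: set[str],
                   config: GseaConfig | None = None) -> GseaResult:
    """ES, NES and nominal p against a seeded random-gene-set null."""
    config = config or GseaConfig()
    rng = np.random.default_rng(config.seed)
    es, profile = enrichment_score(ranked, gene_set, config)
    hits = ranked.index.isin(gene_set)
    n_hits = int(hits.sum())
    null = _null_es(ranked["weight"].to_numpy(), n_hits,
                    config.n_permutations, config.weight_exponent, rng)
    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    p_is_bound = False
    if len(same_sign) == 0:
        nominal_p = 1.0 / config.n_permutations
        p_is_bound = True
        nes = None
    else:
        nominal_p = float((np.abs(same_sign) >= abs(es)).mean())
        if nominal_p == 0.0:
            nominal_p = 1.0 / config.n_permutations
            p_is_bound = True
        nes = float(es / np.abs(same_sign).mean())
    extremum = int(np.argmax(np.abs(profile)))
    if es >= 0:
        leading = int(hits[: extremum + 1].sum())
    else:
        leading = int(hits[extremum:].sum())
    return GseaResult(es, nes, nominal_p, p_is_bound, leading, n_hits,
                      len(ranked), config.seed)
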