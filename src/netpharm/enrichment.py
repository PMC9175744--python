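"""Hypergeometric validation of gene sets and overlap bookkeeping.

The validation statistic is the upper-tail (inclusive) hypergeometric
probability P(X >= k): drawing n genes from a population of N that contains
K "validation" genes, how surprising is an overlap of k?  Raw p-values are
reported by default, with an optional Benjamini-Hochberg adjustment for
multi-set runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

from scipy.stats import hypergeom

from netpharm.graph_io import GeneSet


@dataclass
class EnrichmentResult:
    """Hypergeometric test bookkeeping: N, K, n, k and the p-value."""

    population_size: int
    validation_size: int
    selection_size: int
    overlap: int
    p_value: float
    dropped_selected: int = 0
    dropped_validation: int = 0


@dataclass
class OverlapSummary:
    """Cardinalities of named sets, their global intersection, and percentages."""

    set_sizes: dict[str, int]
    intersection_size: int
    percentages: dict[str, float]
    percentage_strings: dict[str, str]


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k) for Hypergeom(N, K, n).

    Computed via scipy's survival function (log-combinatorics internally,
    numerically stable for large N).
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(
            f"invalid hypergeometric bounds: N={N}, K={K}, n={n}, k={k}"
        )
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich_validate(
    selected: GeneSet, validation: GeneSet, population: GeneSet
) -> EnrichmentResult:
    """Test whether ``selected`` is enriched for ``validation`` genes.

    Both sets are intersected with the population first; the number of
    genes dropped from each is reported.
    """
    pop = population.members
    if not pop:
        raise ValueError("population is empty")
    sel = selected.members & pop
    val = validation.members & pop
    k = len(sel & val)
    p = hypergeom_upper(len(pop), len(val), len(sel), k)
    return EnrichmentResult(
        population_size=len(pop),
        validation_size=len(val),
        selection_size=len(sel),
        overlap=k,
        p_value=p,
        dropped_selected=len(selected) - len(sel),
        dropped_validation=len(validation) - len(val),
    )


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """BH step-up adjusted p-values, preserving input order."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    prev = 1.0
    for rank_from_top, idx in enumerate(reversed(order)):
        rank = m - rank_from_top
        adj = min(prev, p_values[idx] * m / rank)
        adjusted[idx] = adj
        prev = adj
    return adjusted


def _round_half_up(value: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def format_percentage(value: float, decimals: int = 2) -> str:
    """Round half-up to ``decimals`` then trim trailing zeros (48.10 -> 48.1)."""
    rounded = _round_half_up(value, decimals)
    text = f"{rounded:.{decimals}f}"
    if "." in text:
        text = text.rstrip("0").rstrip(".")
    return text


def overlap_summary(
    sets: Mapping[str, GeneSet] | Sequence[GeneSet], decimals: int = 2
) -> OverlapSummary:
    """Global intersection of >=2 sets with per-set percentage shares.

    Each percentage is 100 * |intersection| / |set|, rounded half-up to
    ``decimals`` places (trailing zeros trimmed in the string form).
    """
    if not isinstance(sets, Mapping):
        sets = {s.name: s for s in sets}
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    names = list(sets)
    inter = set(sets[names[0]].members)
    for name in names[1:]:
        inter &= sets[name].members
    sizes = {name: len(sets[name]) for name in names}
    pcts: dict[str, float] = {}
    strs: dict[str, str] = {}
    for name in names:
        raw = 100.0 * len(inter) / sizes[name] if sizes[name] else 0.0
        pcts[name] = _round_half_up(raw, decimals)
        strs[name] = format_percentage(raw, decimals)
    return OverlapSummary(
        set_sizes=sizes,
        intersection_size=len(inter),
        percentages=pcts,
        percentage_strings=strs,
    )
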