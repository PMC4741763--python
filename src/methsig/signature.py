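"""Cross-pair concordant signatures, gene mapping, and enrichment tests.

The invasiveness signature is the set of CpGs called in the same
direction in all three tissue pairs; its probe universe is the set of
probes actually tested in all three pairs.  Genomic-context enrichment
(enhancers, 5' regions, island relation) is assessed with the exact
hypergeometric upper tail against that universe, reported in log10 so
extreme significance survives underflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .errors import InputError, ParameterError
from .io import PROMOTER_REGIONS, ProbeAnnotation
from .stats import TailTestResult, hypergeometric_tail

__all__ = [
    "SignatureSet", "GeneMapping", "EnrichmentResult", "MultiwayOverlapResult",
    "intersect_concordant", "signature_from_tables", "probes_to_genes",
    "filter_promoter_probes", "category_enrichment", "multiway_overlap_significance",
]


@dataclass(frozen=True)
class SignatureSet:
    """Concordant cross-pair probe sets plus the universe they came from."""

    common_hyper_probes: frozenset
    common_hypo_probes: frozenset
    universe: frozenset
    mean_delta_beta: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.common_hyper_probes & self.common_hypo_probes:
            raise InputError("a probe cannot be both commonly hyper- and hypomethylated")
        stray = (self.common_hyper_probes | self.common_hypo_probes) - self.universe
        if stray:
            raise InputError(f"signature probes outside the universe: {sorted(stray)[:5]}")


@dataclass(frozen=True)
class GeneMapping:
    """CpG-set to gene-set collapse with bookkeeping."""

    genes: frozenset
    probe_counts: Mapping[str, int]  # gene -> number of contributing probes
    n_intergenic: int


@dataclass(frozen=True)
class EnrichmentResult:
    """Category enrichment of a probe subset against its universe."""

    subset_size: int
    hits: int
    category_size: int
    universe_size: int
    fraction: float
    fold_enrichment: float
    test: TailTestResult


@dataclass(frozen=True)
class MultiwayOverlapResult:
    observed: int
    expected: float
    permutation_p: float
    n_permutations: int
    pairwise_p: tuple  # ((i, j, TailTestResult), ...)


def intersect_concordant(pair_calls: Sequence[tuple[Iterable, Iterable]],
                         universes: Sequence[Iterable],
                         delta_beta: Sequence[Mapping[str, float]] | None = None,
                         ) -> SignatureSet:
    """Three-way direction-concordant intersection of per-pair DMP calls.

    ``pair_calls`` holds one (hyper, hypo) set pair per tissue pair;
    ``universes`` the corresponding tested-probe sets.  The signature
    universe is the intersection of the three tested sets, and the common
    sets are intersections of same-direction calls, so a probe hyper in
    two pairs and hypo in the third lands in neither.
    """
    if len(pair_calls) < 3 or len(universes) < 3:
        raise InputError("three tissue pairs are required")
    hyper_sets = [frozenset(h) for h, _ in pair_calls]
    hypo_sets = [frozenset(h) for _, h in pair_calls]
    for i, (hy, ho) in enumerate(zip(hyper_sets, hypo_sets)):
        if hy & ho:
            raise InputError(f"pair {i}: hyper and hypo sets overlap")
    universe = frozenset.intersection(*[frozenset(u) for u in universes])
    common_hyper = frozenset.intersection(*hyper_sets) & universe
    common_hypo = frozenset.intersection(*hypo_sets) & universe
    mean_delta = {}
    if delta_beta is not None:
        for probe in common_hyper | common_hypo:
            vals = [float(d[probe]) for d in delta_beta if probe in d]
            mean_delta[probe] = float(np.mean(vals)) if vals else 0.0
    return SignatureSet(common_hyper, common_hypo, universe, mean_delta)


def signature_from_tables(tables, **call_kwargs) -> SignatureSet:
    """Convenience: call DMPs on three pair tables and intersect them."""
    from .diffmeth import call_dmps
    calls = [call_dmps(t, **call_kwargs) for t in tables]
    universes = [t.tested_probes() for t in tables]
    deltas = [t.data["delta_beta"].to_dict() for t in tables]
    return intersect_concordant(calls, universes, deltas)


def probes_to_genes(probes: Iterable, annotation: ProbeAnnotation) -> GeneMapping:
    """Collapse a CpG set to the union of its annotated gene symbols.

    Probes without gene annotation contribute nothing to the gene set
    but are counted as intergenic.
    """
    probes = sorted(set(probes))
    annotation.require_probes(probes)
    counts: dict[str, int] = {}
    n_intergenic = 0
    symbol_lists = annotation.data["gene_symbols"]
    for probe in probes:
        symbols = set(symbol_lists.loc[probe])
        if not symbols:
            n_intergenic += 1
            continue
        for gene in symbols:
            counts[gene] = counts.get(gene, 0) + 1
    return GeneMapping(frozenset(counts), counts, n_intergenic)


def filter_promoter_probes(probes: Iterable, annotation: ProbeAnnotation,
                           regions: frozenset = PROMOTER_REGIONS) -> frozenset:
    """Keep probes with at least one 5'/promoter region label.

    A probe annotated e.g. TSS200 for one gene and Body for another is
    kept (any-match rule).
    """
    if not regions:
        raise ParameterError("regions set must not be empty")
    probes = sorted(set(probes))
    annotation.require_probes(probes)
    region_lists = annotation.data["gene_region"]
    return frozenset(p for p in probes if set(region_lists.loc[p]) & regions)


def category_enrichment(subset: Iterable, category, universe: Iterable,
                        annotation: ProbeAnnotation) -> EnrichmentResult:
    """Hypergeometric enrichment of a probe subset in an annotation category.

    ``category`` is either the name of a boolean annotation column (e.g.
    ``"enhancer"``) or a predicate applied to annotation rows.  The test
    conditions on the universe: P(hits >= observed) drawing |subset|
    probes from a universe containing |category in universe| positives.
    """
    subset = frozenset(subset)
    universe = frozenset(universe)
    if not subset <= universe:
        raise InputError("subset must be contained in the universe")
    annotation.require_probes(universe)
    if isinstance(category, str):
        col = annotation.data[category].astype(bool)
        members = frozenset(annotation.data.index[col])
    elif callable(category):
        members = frozenset(p for p in universe if category(annotation.data.loc[p]))
    else:
        raise ParameterError("category must be a column name or predicate")
    K = len(universe & members)
    hits = len(subset & members)
    N, n = len(universe), len(subset)
    test = hypergeometric_tail(N, K, n, hits)
    fraction = hits / n if n else 0.0
    background = K / N if N else 0.0
    fold = (fraction / background) if (n and background) else 0.0
    return EnrichmentResult(subset_size=n, hits=hits, category_size=K,
                            universe_size=N, fraction=fraction,
                            fold_enrichment=fold, test=test)


def multiway_overlap_significance(sets: Sequence[Iterable], universe: Iterable,
                                  n_permutations: int = 1000, seed: int = 0,
                                  ) -> MultiwayOverlapResult:
    """k-way overlap significance by seeded permutation.

    Compares the observed k-way intersection with same-size random draws
    from the universe; the permutation p uses the add-one correction
    (b + 1) / (n + 1).  The expectation under independence,
    |U| * prod(|S_i| / |U|), and exact pairwise hypergeometric tails are
    reported alongside.
    """
    universe = np.array(sorted(set(universe)), dtype=object)
    N = universe.size
    if N == 0:
        raise InputError("empty universe")
    if n_permutations < 100:
        raise ParameterError("need at least 100 permutations")
    sets = [frozenset(s) for s in sets]
    for i, s in enumerate(sets):
        if not s <= set(universe.tolist()):
            raise InputError(f"set {i} is not contained in the universe")
    sizes = [len(s) for s in sets]
    observed = len(frozenset.intersection(*sets)) if sets else 0
    expected = N * float(np.prod([s / N for s in sizes])) if sets else 0.0

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        mask = np.ones(N, dtype=bool)
        for s in sizes:
            draw = np.zeros(N, dtype=bool)
            draw[rng.choice(N, size=s, replace=False)] = True
            mask &= draw
        if int(mask.sum()) >= observed:
            exceed += 1
    perm_p = (exceed + 1) / (n_permutations + 1)

    pairwise = []
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            k = len(sets[i] & sets[j])
            pairwise.append((i, j, hypergeometric_tail(N, sizes[i], sizes[j], k)))
    return MultiwayOverlapResult(observed=observed, expected=expected,
                                 permutation_p=perm_p,
                                 n_permutations=n_permutations,
                                 pairwise_p=tuple(pairwise))
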