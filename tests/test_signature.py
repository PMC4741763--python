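import itertools

import numpy as np
import pytest

from methsig.errors import InputError, ParameterError
from methsig.signature import (SignatureSet, category_enrichment,
                               filter_promoter_probes, intersect_concordant,
                               multiway_overlap_significance, probes_to_genes,
                               signature_from_tables)
from methsig.stats import hypergeometric_tail


class TestIntersectConcordant:
    UNIVERSES = [{"x", "y", "z"}] * 3

    def test_basic_intersection(self):
        calls = [({"x"}, {"y"})] * 3
        sig = intersect_concordant(calls, self.UNIVERSES)
        assert sig.common_hyper_probes == {"x"}
        assert sig.common_hypo_probes == {"y"}
        assert sig.universe == {"x", "y", "z"}

    def test_direction_discordance_excludes(self):
        calls = [({"x"}, set()), ({"x"}, set()), (set(), {"x"})]
        sig = intersect_concordant(calls, self.UNIVERSES)
        assert sig.common_hyper_probes == frozenset()
        assert sig.common_hypo_probes == frozenset()

    def test_disjoint_calls(self):
        calls = [({"x"}, set()), ({"y"}, set()), ({"z"}, set())]
        sig = intersect_concordant(calls, self.UNIVERSES)
        assert sig.common_hyper_probes == frozenset()

    def test_order_independent(self):
        calls = [({"x", "y"}, {"z"}), ({"x"}, {"z"}), ({"x", "y"}, set())]
        results = [intersect_concordant(list(perm), self.UNIVERSES)
                   for perm in itertools.permutations(calls)]
        assert len({(r.common_hyper_probes, r.common_hypo_probes) for r in results}) == 1

    def test_requires_three_pairs(self):
        with pytest.raises(InputError, match="three"):
            intersect_concordant([({"x"}, set())] * 2, [{"x"}] * 2)

    def test_overlapping_hyper_hypo_rejected(self):
        with pytest.raises(InputError, match="overlap"):
            intersect_concordant([({"x"}, {"x"})] * 3, self.UNIVERSES)

    def test_mean_delta_beta_averaged(self):
        calls = [({"x"}, set())] * 3
        deltas = [{"x": 0.3}, {"x": 0.4}, {"x": 0.5}]
        sig = intersect_concordant(calls, self.UNIVERSES, deltas)
        assert sig.mean_delta_beta["x"] == pytest.approx(0.4)


class TestProbesToGenes:
    def test_two_probes_one_gene(self, small_dataset):
        ann = small_dataset.annotation
        # construct via synthetic annotation: find a gene with >= 2 probes
        counts = {}
        for probe, syms in ann.data["gene_symbols"].items():
            for g in syms:
                counts.setdefault(g, []).append(probe)
        gene, probes = next((g, p) for g, p in counts.items() if len(p) >= 2)
        mapping = probes_to_genes(probes[:2], ann)
        assert mapping.genes == {gene}
        assert mapping.probe_counts[gene] == 2

    def test_intergenic_probes_counted(self, small_dataset):
        ann = small_dataset.annotation
        intergenic = [p for p, s in ann.data["gene_symbols"].items() if not s][:3]
        mapping = probes_to_genes(intergenic, ann)
        assert mapping.genes == frozenset()
        assert mapping.n_intergenic == len(intergenic)

    def test_unknown_probe(self, small_dataset):
        with pytest.raises(InputError):
            probes_to_genes({"cg_nope"}, small_dataset.annotation)


class TestFilterPromoterProbes:
    def test_any_match_rule(self, small_dataset):
        ann = small_dataset.annotation
        kept = filter_promoter_probes(set(ann.probe_ids), ann)
        promoter = {"TSS1500", "TSS200", "5UTR", "1stExon"}
        for probe in list(kept)[:20]:
            assert set(ann.data.loc[probe, "gene_region"]) & promoter
        excluded = set(ann.probe_ids) - kept
        for probe in list(excluded)[:20]:
            assert not set(ann.data.loc[probe, "gene_region"]) & promoter

    def test_empty_input(self, small_dataset):
        assert filter_promoter_probes(set(), small_dataset.annotation) == frozenset()

    def test_empty_region_set_rejected(self, small_dataset):
        with pytest.raises(ParameterError):
            filter_promoter_probes(set(), small_dataset.annotation, regions=frozenset())


class TestCategoryEnrichment:
    def test_counts_delegate_to_hypergeometric(self, small_dataset):
        ann = small_dataset.annotation
        universe = frozenset(ann.probe_ids)
        enh = ann.enhancer_probes()
        subset = frozenset(list(enh)[:50] + [p for p in universe if p not in enh][:50])
        res = category_enrichment(subset, "enhancer", universe, ann)
        expected = hypergeometric_tail(len(universe), len(enh), 100, 50)
        assert res.test.p_value == pytest.approx(expected.p_value, rel=1e-12)
        assert res.fold_enrichment == pytest.approx(
            (50 / 100) / (len(enh) / len(universe)))

    def test_depends_only_on_counts(self, small_dataset):
        """Relabeling invariance: two different subsets with identical
        (N, K, n, k) give identical p."""
        ann = small_dataset.annotation
        universe = frozenset(ann.probe_ids)
        enh = sorted(ann.enhancer_probes())
        non = sorted(universe - set(enh))
        s1 = frozenset(enh[:20] + non[:30])
        s2 = frozenset(enh[20:40] + non[30:60])
        r1 = category_enrichment(s1, "enhancer", universe, ann)
        r2 = category_enrichment(s2, "enhancer", universe, ann)
        assert r1.test.p_value == r2.test.p_value

    def test_category_equals_universe(self, small_dataset):
        ann = small_dataset.annotation
        universe = frozenset(ann.probe_ids)
        res = category_enrichment(frozenset(list(universe)[:10]),
                                  lambda row: True, universe, ann)
        assert res.fold_enrichment == pytest.approx(1.0)
        assert res.test.p_value == 1.0

    def test_zero_hits(self, small_dataset):
        ann = small_dataset.annotation
        universe = frozenset(ann.probe_ids)
        non = [p for p in universe if not ann.data.loc[p, "enhancer"]][:10]
        res = category_enrichment(frozenset(non), "enhancer", universe, ann)
        assert res.test.p_value == 1.0
        assert res.fold_enrichment == 0.0

    def test_subset_outside_universe_rejected(self, small_dataset):
        ann = small_dataset.annotation
        probes = sorted(ann.probe_ids)
        with pytest.raises(InputError):
            category_enrichment({probes[0]}, "enhancer", set(probes[1:5]), ann)


class TestMultiwayOverlap:
    UNIVERSE = [f"p{i}" for i in range(150)]

    def test_identical_sets_minimal_p(self):
        s = frozenset(self.UNIVERSE[:25])
        res = multiway_overlap_significance([s, s, s], self.UNIVERSE,
                                            n_permutations=200, seed=1)
        assert res.observed == 25
        assert res.permutation_p == pytest.approx(1 / 201)

    def test_expected_under_independence(self):
        sets = [frozenset(self.UNIVERSE[:30]), frozenset(self.UNIVERSE[30:60]),
                frozenset(self.UNIVERSE[60:90])]
        res = multiway_overlap_significance(sets, self.UNIVERSE,
                                            n_permutations=100, seed=2)
        assert res.observed == 0
        assert res.expected == pytest.approx(150 * (30 / 150) ** 3)

    def test_two_sets_agree_with_exact_tail(self):
        rng = np.random.default_rng(0)
        a = frozenset(rng.choice(self.UNIVERSE, 40, replace=False))
        b = frozenset(rng.choice(self.UNIVERSE, 40, replace=False))
        res = multiway_overlap_significance([a, b], self.UNIVERSE,
                                            n_permutations=2000, seed=3)
        exact = hypergeometric_tail(150, 40, 40, res.observed)
        # permutation estimate within Monte-Carlo error of the exact tail
        se = np.sqrt(exact.p_value * (1 - exact.p_value) / 2000)
        assert abs(res.permutation_p - exact.p_value) < 4 * se + 1e-3
        ((_, _, pairwise),) = res.pairwise_p
        assert pairwise.p_value == exact.p_value

    def test_null_calibration(self):
        """Under independent random sets the permutation p rejects at 0.05
        about 5% of the time across seeds."""
        n_seeds, rejections, pvals = 60, 0, []
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            sets = [frozenset(rng.choice(self.UNIVERSE, 30, replace=False))
                    for _ in range(3)]
            res = multiway_overlap_significance(sets, self.UNIVERSE,
                                                n_permutations=200, seed=seed)
            pvals.append(res.permutation_p)
            rejections += res.permutation_p <= 0.05
        tol = 3 * np.sqrt(0.05 * 0.95 / n_seeds)
        assert rejections / n_seeds <= 0.05 + tol
        assert 0.3 < np.mean(pvals) < 0.85

    def test_validation(self):
        with pytest.raises(InputError):
            multiway_overlap_significance([{"p0"}], [], n_permutations=100, seed=0)
        with pytest.raises(ParameterError):
            multiway_overlap_significance([{"p0"}], self.UNIVERSE,
                                          n_permutations=10, seed=0)


def test_signature_from_tables_matches_manual(small_dataset):
    from methsig.diffmeth import call_dmps, test_pair as run_pair
    tables = [run_pair(small_dataset.beta, small_dataset.samples, t)
              for t in small_dataset.samples.tissues]
    sig = signature_from_tables(tables)
    calls = [call_dmps(t) for t in tables]
    manual = intersect_concordant(calls, [t.tested_probes() for t in tables])
    assert sig.common_hyper_probes == manual.common_hyper_probes
    assert sig.common_hypo_probes == manual.common_hypo_probes
    assert sig.universe == manual.universe
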