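"""Overlap-score matching, s-measure bookkeeping, enrichment, f-measure."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

from gsmod import (
    AnnotationSet,
    Clustering,
    ComplexCatalog,
    Module,
    hypergeom_pvalue,
    match_complexes,
    module_enrichment,
    module_fmeasure,
    overlap_score,
    s_measure_stats,
)


def plain_clustering(sets) -> Clustering:
    return Clustering(
        modules=[
            Module(i, unlabelled=frozenset(s)) for i, s in enumerate(sets, start=1)
        ]
    )


class TestOverlapScore:
    def test_identical_sets_score_one(self):
        s = set("ABCDEFG")
        assert overlap_score(s, set(s)) == 1.0

    def test_disjoint_sets_score_zero(self):
        assert overlap_score({"A"}, {"B", "C"}) == 0.0

    def test_boundary_arithmetic(self):
        p, b = set("ABCD"), set("CDEFG")  # i=2, |p|=4, |b|=5
        assert overlap_score(p, b) == pytest.approx(0.2)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        universe = [f"P{i}" for i in range(20)]
        for _ in range(20):
            p = set(rng.choice(universe, size=rng.integers(1, 10), replace=False))
            b = set(rng.choice(universe, size=rng.integers(1, 10), replace=False))
            assert overlap_score(p, b) == overlap_score(b, p)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            overlap_score(set(), {"A"})


class TestSMeasureStats:
    def test_equal_ratios_give_their_common_value(self):
        stats = s_measure_stats(10, 30, 30)
        assert stats.sensitivity == stats.specificity == stats.s_measure == 0.25

    def test_harmonic_mean_is_between_the_ratios(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            tp, fn, fp = (int(x) for x in rng.integers(0, 400, size=3))
            stats = s_measure_stats(tp, fn, fp)
            lo = min(stats.sensitivity, stats.specificity)
            hi = max(stats.sensitivity, stats.specificity)
            assert lo - 1e-12 <= stats.s_measure <= hi + 1e-12

    def test_all_zero_counts_flagged_degenerate(self):
        stats = s_measure_stats(0, 0, 0)
        assert stats == (0.0, 0.0, 0.0, True)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            s_measure_stats(-1, 0, 0)


class TestMatchComplexes:
    def test_exact_copies_score_one_everywhere(self):
        benchmark = ComplexCatalog(
            {f"c{i}": frozenset({f"P{i}a", f"P{i}b", f"P{i}c"}) for i in range(5)}
        )
        predicted = plain_clustering(benchmark.complexes.values())
        report = match_complexes(predicted, benchmark)
        assert report.sensitivity == report.specificity == report.s_measure == 1.0
        assert not report.fn_complexes and not report.fp_modules

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(2)
        universe = [f"P{i}" for i in range(40)]
        for _ in range(10):
            pred_sets = [
                set(rng.choice(universe, size=rng.integers(3, 9), replace=False))
                for _ in range(6)
            ]
            bench = ComplexCatalog(
                {
                    f"b{j}": frozenset(
                        rng.choice(universe, size=rng.integers(3, 9), replace=False)
                    )
                    for j in range(5)
                }
            )
            report = match_complexes(plain_clustering(pred_sets), bench, omega=0.2)
            # brute force over the full OS matrix
            tp = {
                i + 1
                for i, p in enumerate(pred_sets)
                if any(overlap_score(p, b) >= 0.2 for b in bench.complexes.values())
            }
            tb = {
                cid
                for cid, b in bench.items()
                if any(overlap_score(p, b) >= 0.2 for p in pred_sets)
            }
            assert report.tp_modules == tp
            assert report.tb_complexes == tb
            assert report.fp_modules == set(range(1, 7)) - tp
            assert report.fn_complexes == set(bench.complexes) - tb

    def test_raising_omega_never_gains_matches(self):
        rng = np.random.default_rng(3)
        universe = [f"P{i}" for i in range(30)]
        pred = plain_clustering(
            set(rng.choice(universe, size=6, replace=False)) for _ in range(5)
        )
        bench = ComplexCatalog(
            {
                f"b{j}": frozenset(rng.choice(universe, size=6, replace=False))
                for j in range(5)
            }
        )
        previous_tp = previous_tb = math.inf
        for omega in (0.1, 0.2, 0.4, 0.8, 1.0):
            report = match_complexes(pred, bench, omega=omega)
            assert len(report.tp_modules) <= previous_tp
            assert len(report.tb_complexes) <= previous_tb
            previous_tp, previous_tb = len(report.tp_modules), len(report.tb_complexes)

    def test_empty_benchmark_rejected(self):
        with pytest.raises(ValueError):
            match_complexes(plain_clustering([{"A", "B"}]), ComplexCatalog({}))


def enumerate_tail(N: int, M: int, n: int, m: int) -> Fraction:
    """Exhaustive oracle: draw every n-subset of an N-element population
    whose first M elements are 'annotated'; count draws with >= m hits."""
    population = range(N)
    hits = total = 0
    for subset in itertools.combinations(population, n):
        total += 1
        if sum(1 for x in subset if x < M) >= m:
            hits += 1
    return Fraction(hits, total)


class TestHypergeomPValue:
    def test_zero_overlap_is_certain(self):
        assert hypergeom_pvalue(100, 10, 5, 0) == 1.0

    def test_exact_binomial_arithmetic(self):
        assert hypergeom_pvalue(10, 5, 4, 4) == pytest.approx(5 / 210, rel=1e-12)

    def test_matches_exhaustive_enumeration_on_small_grids(self):
        for N in (5, 8):
            for M in range(N + 1):
                for n in range(N + 1):
                    for m in range(n + 1):
                        expected = float(enumerate_tail(N, M, n, m))
                        assert hypergeom_pvalue(N, M, n, m) == pytest.approx(
                            expected, abs=1e-12
                        )

    def test_non_increasing_in_m(self):
        previous = 1.1
        for m in range(0, 7):
            p = hypergeom_pvalue(30, 12, 6, m)
            assert p <= previous + 1e-15
            previous = p

    def test_point_mass_at_maximal_overlap(self):
        # m = min(n, M): only the fully-annotated draw remains
        assert hypergeom_pvalue(12, 4, 6, 4) == pytest.approx(
            float(enumerate_tail(12, 4, 6, 4))
        )

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_pvalue(10, 11, 5, 2)
        with pytest.raises(ValueError):
            hypergeom_pvalue(10, 5, 11, 2)
        with pytest.raises(ValueError):
            hypergeom_pvalue(10, 5, 4, 5)


def fixture_annotations() -> AnnotationSet:
    terms = {
        "T1": frozenset({"A", "B", "C"}),
        "T2": frozenset({"D", "E", "F", "G"}),
        "T3": frozenset({"H", "I"}),
    }
    return AnnotationSet(terms, background_size=50)


class TestModuleEnrichment:
    def test_module_equal_to_term_is_significant(self):
        clustering = plain_clustering([{"A", "B", "C"}])
        results, summary = module_enrichment(clustering, fixture_annotations())
        assert results[0].term_id == "T1"
        assert results[0].p_value == pytest.approx(
            float(enumerate_tail(50, 3, 3, 3))
        )
        assert results[0].significant
        assert summary.n_significant == 1

    def test_summary_average_matches_hand_computation(self):
        clustering = plain_clustering([{"A", "B", "C"}, {"D", "E"}, {"H", "Z"}])
        results, summary = module_enrichment(clustering, fixture_annotations())
        expected = [
            float(enumerate_tail(50, 3, 3, 3)),  # module 1 vs T1
            float(enumerate_tail(50, 4, 2, 2)),  # module 2 vs T2
            float(enumerate_tail(50, 2, 1, 1)),  # module 3 vs T3 (Z unannotated)
        ]
        for r, p in zip(results, expected):
            assert r.p_value == pytest.approx(p, rel=1e-9)
        assert summary.avg_neglog10_p == pytest.approx(
            sum(-math.log10(p) for p in expected) / 3
        )
        assert summary.n_scored == 3

    def test_unannotated_module_is_flagged_and_excluded(self):
        clustering = plain_clustering([{"A", "B", "C"}, {"X", "Y"}])
        results, summary = module_enrichment(clustering, fixture_annotations())
        assert results[1].p_value is None and results[1].term_id is None
        assert summary.n_unannotated == 1 and summary.n_scored == 1

    def test_background_rate_module_is_not_significant(self):
        # members spread uniformly across many same-size terms
        rng = np.random.default_rng(8)
        proteins = [f"P{i:03d}" for i in range(300)]
        terms = {
            f"T{j}": frozenset(proteins[10 * j : 10 * (j + 1)]) for j in range(30)
        }
        annotations = AnnotationSet(terms, background_size=300)
        members = {proteins[10 * j] for j in range(8)}  # one protein per term
        _, summary = module_enrichment(plain_clustering([members]), annotations)
        assert summary.n_significant == 0

    def test_bonferroni_scales_p(self):
        clustering = plain_clustering([{"D", "E"}])
        raw, _ = module_enrichment(clustering, fixture_annotations())
        adjusted, _ = module_enrichment(
            clustering, fixture_annotations(), bonferroni=True
        )
        assert adjusted[0].p_value == pytest.approx(min(1.0, raw[0].p_value * 3))

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ValueError):
            module_enrichment(plain_clustering([{"A"}]), fixture_annotations(), cutoff=0)


class TestModuleFMeasure:
    def test_module_equal_to_term_scores_one(self):
        results, average = module_fmeasure(
            plain_clustering([{"A", "B", "C"}]), fixture_annotations()
        )
        assert results[0].best_term_id == "T1"
        assert (results[0].recall, results[0].precision, results[0].f_measure) == (1.0, 1.0, 1.0)
        assert average == 1.0

    def test_arithmetic_oracle(self):
        terms = {"F": frozenset({"A", "B", "C", "D", "E", "G"})}  # |F| = 6
        annotations = AnnotationSet(terms, background_size=20)
        module = {"A", "B", "C", "X"}  # |M| = 4, overlap 3
        results, _ = module_fmeasure(plain_clustering([module]), annotations)
        assert results[0].recall == pytest.approx(0.5)
        assert results[0].precision == pytest.approx(0.75)
        assert results[0].f_measure == pytest.approx(0.6)

    def test_best_term_matches_brute_force_scan(self):
        rng = np.random.default_rng(4)
        universe = [f"P{i}" for i in range(40)]
        terms = {
            f"T{j}": frozenset(rng.choice(universe, size=rng.integers(3, 12), replace=False))
            for j in range(8)
        }
        annotations = AnnotationSet(terms, background_size=40)
        modules = [
            set(rng.choice(universe, size=rng.integers(3, 10), replace=False))
            for _ in range(5)
        ]
        results, average = module_fmeasure(plain_clustering(modules), annotations)
        for module, got in zip(modules, results):
            best_f = 0.0
            for proteins in terms.values():
                i = len(module & proteins)
                if i:
                    r, p = i / len(proteins), i / len(module)
                    best_f = max(best_f, 2 * r * p / (r + p))
            assert got.f_measure == pytest.approx(best_f)
        assert average == pytest.approx(
            sum(r.f_measure for r in results) / len(results)
        )

    def test_module_without_any_term_overlap_scores_zero(self):
        results, average = module_fmeasure(
            plain_clustering([{"Q", "R"}]), fixture_annotations()
        )
        assert results[0].f_measure == 0.0 and results[0].best_term_id is None
        assert average == 0.0
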