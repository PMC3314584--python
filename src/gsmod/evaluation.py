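"""Assessment stack: benchmark matching, s-measure, enrichment, f-measure.

A predicted module p and a benchmark complex b match when their overlap
score ``OS(p, b) = i^2 / (|p| * |b|)`` (i = intersection size) reaches the
threshold omega, conventionally 0.20.  From the matching:

* TP — predicted modules matching at least one benchmark complex,
* FP — the remaining predicted modules,
* TB — benchmark complexes matched by at least one predicted module,
* FN — the remaining benchmark complexes,

and sensitivity = |TP|/(|TP|+|FN|), specificity = |TP|/(|TP|+|FP|), with
the s-measure their harmonic mean.  Note the asymmetric bookkeeping:
sensitivity mixes predicted-side TP with benchmark-side FN, which is the
convention these counts are reported in.

Functional significance is assessed per module by the upper-tail
hypergeometric probability of its overlap with each annotation term, and
by the best f-measure (harmonic mean of recall and precision) over terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Set

from scipy.stats import hypergeom

from .model import AnnotationSet, Clustering, ComplexCatalog

#: floor for p-values entering -log10 (guards log of an underflowed 0.0)
_P_FLOOR = 1e-300


def overlap_score(p: Set[str], b: Set[str]) -> float:
    """``|p ∩ b|^2 / (|p| * |b|)`` in [0, 1]; equals 1 iff the sets are equal."""
    if not p or not b:
        raise ValueError("overlap score is undefined for empty sets")
    i = len(set(p) & set(b))
    return i * i / (len(p) * len(b))


class SMeasureStats(NamedTuple):
    sensitivity: float
    specificity: float
    s_measure: float
    degenerate: bool


def s_measure_stats(tp: int, fn: int, fp: int) -> SMeasureStats:
    """Sensitivity, specificity and their harmonic mean from the counts.

    Zero denominators yield 0 for the affected ratio and set the
    ``degenerate`` flag instead of raising.
    """
    if min(tp, fn, fp) < 0:
        raise ValueError("counts must be non-negative")
    degenerate = (tp + fn == 0) or (tp + fp == 0)
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    specificity = tp / (tp + fp) if tp + fp else 0.0
    if sensitivity + specificity == 0:
        return SMeasureStats(sensitivity, specificity, 0.0, True)
    s = 2 * sensitivity * specificity / (sensitivity + specificity)
    return SMeasureStats(sensitivity, specificity, s, degenerate)


@dataclass(frozen=True)
class MatchReport:
    """Outcome of matching a predicted clustering against a benchmark."""

    omega: float
    n_predicted: int
    n_benchmark: int
    tp_modules: frozenset
    fp_modules: frozenset
    fn_complexes: frozenset
    tb_complexes: frozenset
    sensitivity: float
    specificity: float
    s_measure: float
    degenerate: bool

    def to_dict(self) -> dict:
        return {
            "omega": self.omega,
            "n_predicted": self.n_predicted,
            "n_benchmark": self.n_benchmark,
            "tp": len(self.tp_modules),
            "fp": len(self.fp_modules),
            "fn": len(self.fn_complexes),
            "tb": len(self.tb_complexes),
            "tp_modules": sorted(self.tp_modules, key=str),
            "fp_modules": sorted(self.fp_modules, key=str),
            "fn_complexes": sorted(self.fn_complexes, key=str),
            "tb_complexes": sorted(self.tb_complexes, key=str),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "s_measure": self.s_measure,
            "degenerate": self.degenerate,
        }


def match_complexes(
    predicted: Clustering, benchmark: ComplexCatalog, omega: float = 0.20
) -> MatchReport:
    """Match every predicted module against every benchmark complex."""
    if not 0 < omega <= 1:
        raise ValueError(f"omega must lie in (0, 1], got {omega}")
    if not len(benchmark):
        raise ValueError("benchmark catalog is empty")
    tp: set = set()
    tb: set = set()
    for module in predicted.modules:
        members = module.members
        for cid, complex_members in benchmark.items():
            if overlap_score(members, complex_members) >= omega:
                tp.add(module.module_id)
                tb.add(cid)
    all_modules = {m.module_id for m in predicted.modules}
    all_complexes = set(benchmark.complexes)
    stats = s_measure_stats(
        len(tp), len(all_complexes) - len(tb), len(all_modules) - len(tp)
    )
    return MatchReport(
        omega=omega,
        n_predicted=len(all_modules),
        n_benchmark=len(all_complexes),
        tp_modules=frozenset(tp),
        fp_modules=frozenset(all_modules - tp),
        fn_complexes=frozenset(all_complexes - tb),
        tb_complexes=frozenset(tb),
        sensitivity=stats.sensitivity,
        specificity=stats.specificity,
        s_measure=stats.s_measure,
        degenerate=stats.degenerate,
    )


def hypergeom_pvalue(N: int, M: int, n: int, m: int) -> float:
    """Upper-tail hypergeometric probability of observing ``m`` or more
    annotated proteins in a module of ``n``, when ``M`` of the ``N``
    background proteins carry the annotation.

    The sum runs over the supported range ``i = m .. min(n, M)``; ``m = 0``
    gives exactly 1.  Evaluated through the log-space survival function of
    the hypergeometric distribution for numerical stability.
    """
    for name, value in (("N", N), ("M", M), ("n", n), ("m", m)):
        if int(value) != value or value < 0:
            raise ValueError(f"{name} must be a non-negative integer")
    if M > N or n > N:
        raise ValueError("M and n cannot exceed the background size N")
    if m > n:
        raise ValueError("overlap m cannot exceed the module size n")
    if m == 0:
        return 1.0
    if m > min(n, M):
        return 0.0
    p = float(hypergeom.sf(m - 1, N, M, n))
    return min(max(p, 0.0), 1.0)


@dataclass(frozen=True)
class EnrichmentResult:
    """Best-term enrichment of one module.

    ``n`` counts only module members inside the annotation background;
    a module with no annotated member carries ``term_id=None`` and
    ``p_value=None`` and is excluded from summary averages.
    """

    module_id: int | str
    term_id: str | None
    N: int
    M: int
    n: int
    m: int
    p_value: float | None
    significant: bool


class EnrichmentSummary(NamedTuple):
    n_modules: int
    n_scored: int
    n_unannotated: int
    n_significant: int
    avg_neglog10_p: float


def module_enrichment(
    clustering: Clustering,
    annotations: AnnotationSet,
    cutoff: float = 0.01,
    bonferroni: bool = False,
    core_only: bool = False,
) -> tuple[list[EnrichmentResult], EnrichmentSummary]:
    """Map each module to its lowest-p annotation term.

    A module is significant when its best raw p-value (or, with
    ``bonferroni=True``, p times the number of terms, capped at 1) is
    strictly below ``cutoff``.  The summary reports the significant count
    and the mean of -log10(best p) over scored modules.
    """
    if not 0 < cutoff < 1:
        raise ValueError(f"cutoff must lie in (0, 1), got {cutoff}")
    N = annotations.background_size
    annotated = annotations.annotated_proteins
    results: list[EnrichmentResult] = []
    for module in clustering.modules:
        members = module.core if (core_only and module.core) else module.members
        annotated_members = members & annotated
        n = len(annotated_members)
        if n == 0:
            results.append(
                EnrichmentResult(module.module_id, None, N, 0, 0, 0, None, False)
            )
            continue
        best: tuple[float, str, int, int] | None = None  # (p, term, M, m)
        for term in sorted(annotations.terms):
            proteins = annotations.terms[term]
            m = len(annotated_members & proteins)
            if m == 0:
                continue
            p = hypergeom_pvalue(N, len(proteins), n, m)
            if bonferroni:
                p = min(1.0, p * len(annotations.terms))
            if best is None or (p, term) < (best[0], best[1]):
                best = (p, term, len(proteins), m)
        # annotated_members is nonempty, so at least one term overlaps
        p, term, M, m = best
        results.append(
            EnrichmentResult(
                module.module_id, term, N, M, n, m, p, p < cutoff
            )
        )
    scored = [r for r in results if r.p_value is not None]
    avg = (
        sum(-math.log10(max(r.p_value, _P_FLOOR)) for r in scored) / len(scored)
        if scored
        else 0.0
    )
    summary = EnrichmentSummary(
        n_modules=len(results),
        n_scored=len(scored),
        n_unannotated=len(results) - len(scored),
        n_significant=sum(r.significant for r in scored),
        avg_neglog10_p=avg,
    )
    return results, summary


@dataclass(frozen=True)
class FMeasureResult:
    """Best functional-category f-measure of one module."""

    module_id: int | str
    best_term_id: str | None
    recall: float
    precision: float
    f_measure: float


def module_fmeasure(
    clustering: Clustering,
    annotations: AnnotationSet,
    core_only: bool = False,
) -> tuple[list[FMeasureResult], float]:
    """Map each module to the term with the highest f-measure.

    recall = |M ∩ F| / |F| and precision = |M ∩ F| / |M| for module member
    set M and term protein set F.  Modules overlapping no term score 0 and
    still enter the reported average over all modules.
    """
    results: list[FMeasureResult] = []
    for module in clustering.modules:
        members = module.core if (core_only and module.core) else module.members
        best: FMeasureResult | None = None
        for term in sorted(annotations.terms):
            proteins = annotations.terms[term]
            i = len(members & proteins)
            if i == 0:
                continue
            recall = i / len(proteins)
            precision = i / len(members)
            f = 2 * recall * precision / (recall + precision)
            if best is None or f > best.f_measure:
                best = FMeasureResult(module.module_id, term, recall, precision, f)
        if best is None:
            best = FMeasureResult(module.module_id, None, 0.0, 0.0, 0.0)
        results.append(best)
    average = (
        sum(r.f_measure for r in results) / len(results) if results else 0.0
    )
    return results, average
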