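"""Alu/IRF co-occurrence enrichment, cumulative curves and element topology.

A promoter is "in tandem" when its window contains at least one Alu repeat
and at least one IRF binding site; enrichment of each category in a gene set
is tested against a background universe of annotated promoters with a
one-sided hypergeometric tail (over-representation).  Topology statistics
summarise where the two elements sit relative to the TSS and to each other.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from statistics import median
from typing import Mapping, Sequence

from .promoters import (
    CATEGORIES,
    CATEGORY_ALU_ONLY,
    CATEGORY_BOTH,
    PromoterAnnotation,
)
from .stats import hypergeom_tail


@dataclass
class CooccurrenceReport:
    set_counts: dict[str, int]
    background_counts: dict[str, int]
    set_fractions: dict[str, float]
    background_fractions: dict[str, float]
    hypergeom_p: dict[str, float]
    set_size: int
    background_size: int
    config: dict = field(default_factory=dict)


def category_enrichment(
    gene_set: Mapping[str, PromoterAnnotation],
    background: Mapping[str, PromoterAnnotation],
    max_spacing: int | None = None,
    config: dict | None = None,
) -> CooccurrenceReport:
    """Category counts in a gene set vs background with hypergeometric p-values.

    The gene set must be contained in the background (the background plays
    the role of the platform universe).  For each category the p-value is the
    over-representation tail P(X >= x) with X ~ Hypergeometric(N, K, n),
    N = background size, K = background count of the category, n = set size.

    ``max_spacing``, when given, demotes "both" promoters whose closest
    Alu/IRF pair is farther apart than the cutoff to their dominant single
    category (off by default: tandem means co-presence only).
    """
    missing = sorted(set(gene_set) - set(background))
    if missing:
        raise ValueError(f"gene set not contained in background: {missing[:10]}")
    if not background:
        raise ValueError("background is empty")

    def cat(ann: PromoterAnnotation) -> str:
        c = ann.category
        if c == CATEGORY_BOTH and max_spacing is not None:
            rec = _gene_topology(ann)
            if rec["spacing"] > max_spacing:
                return CATEGORY_ALU_ONLY
        return c

    bg_counts = {c: 0 for c in CATEGORIES}
    for ann in background.values():
        bg_counts[cat(ann)] += 1
    set_counts = {c: 0 for c in CATEGORIES}
    for gid in gene_set:
        set_counts[cat(background[gid])] += 1

    N, n = len(background), len(gene_set)
    return CooccurrenceReport(
        set_counts=set_counts,
        background_counts=bg_counts,
        set_fractions={c: set_counts[c] / n if n else 0.0 for c in CATEGORIES},
        background_fractions={c: bg_counts[c] / N for c in CATEGORIES},
        hypergeom_p={
            c: hypergeom_tail(set_counts[c], N, bg_counts[c], n) for c in CATEGORIES
        },
        set_size=n,
        background_size=N,
        config=dict(config or {}),
    )


def extract_signature(
    gene_set_up: Sequence[str],
    annotations: Mapping[str, PromoterAnnotation],
) -> list[str]:
    """The signature: genes of the (ordered) set whose promoter is tandem.

    Returns exactly the genes with category "both", preserving input order.
    """
    missing = [g for g in gene_set_up if g not in annotations]
    if missing:
        raise ValueError(f"genes without annotation: {missing[:10]}")
    return [g for g in gene_set_up if annotations[g].category == CATEGORY_BOTH]


@dataclass
class CumulativeCurve:
    k_values: list[int]
    frac_alu_at_k: list[float]
    frac_tandem_at_k: list[float]


def cumulative_curve(
    ranked_genes: Sequence[str],
    annotations: Mapping[str, PromoterAnnotation],
    k_values: Sequence[int] | None = None,
) -> CumulativeCurve:
    """Fraction of Alu-bearing and tandem promoters among the top-k genes.

    ``frac_alu_at_k`` counts categories {both, alu_only}; ``frac_tandem_at_k``
    counts "both" only, so the tandem curve can never exceed the Alu curve.
    """
    n = len(ranked_genes)
    if k_values is None:
        k_values = list(range(1, n + 1))
    missing = [g for g in ranked_genes if g not in annotations]
    if missing:
        raise ValueError(f"genes without annotation: {missing[:10]}")
    alu_flags = [
        annotations[g].category in (CATEGORY_BOTH, CATEGORY_ALU_ONLY) for g in ranked_genes
    ]
    tandem_flags = [annotations[g].category == CATEGORY_BOTH for g in ranked_genes]
    frac_alu, frac_tandem = [], []
    for k in k_values:
        if not (1 <= k <= n):
            raise ValueError(f"k={k} outside [1, {n}]")
        frac_alu.append(sum(alu_flags[:k]) / k)
        frac_tandem.append(sum(tandem_flags[:k]) / k)
    return CumulativeCurve(
        k_values=list(k_values), frac_alu_at_k=frac_alu, frac_tandem_at_k=frac_tandem
    )


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

def _edge_distance(iv: tuple[int, int]) -> int:
    """TSS distance of a TSS-relative interval: 0 if it spans the TSS, else
    the distance of its TSS-facing boundary (edge-based, integer bases)."""
    a, b = iv
    if a <= 0 < b:
        return 0
    return min(abs(a), abs(b))


def _proximal_edge(iv: tuple[int, int]) -> int:
    """Signed coordinate of the TSS-closest covered base (0 if spanning)."""
    a, b = iv
    if a <= 0 < b:
        return 0
    return b - 1 if b <= 0 else a


def _spacing(iv1: tuple[int, int], iv2: tuple[int, int]) -> int:
    """Gap between the facing edges of two intervals, 0 when they overlap."""
    return max(0, max(iv1[0], iv2[0]) - min(iv1[1], iv2[1]))


def _gene_topology(ann: PromoterAnnotation) -> dict:
    alu = min(ann.alu_elements, key=_edge_distance)
    irf = min(ann.irf_elements, key=_edge_distance)
    return {
        "gene_id": ann.gene_id,
        "alu_tss_distance": _edge_distance(alu),
        "irf_tss_distance": _edge_distance(irf),
        "alu_upstream_of_tss": _proximal_edge(alu) < 0,
        "alu_upstream_of_irf": _proximal_edge(alu) < _proximal_edge(irf),
        "spacing": _spacing(alu, irf),
    }


@dataclass
class TopologySummary:
    median_irf_tss_distance: float
    median_alu_tss_distance: float
    frac_alu_upstream_of_tss: float
    frac_alu_upstream_of_irf: float
    spacing_min_observed: int
    spacing_max_observed: int
    per_gene_records: list[dict]


def topology_summary(
    annotations: Mapping[str, PromoterAnnotation] | Sequence[PromoterAnnotation],
) -> TopologySummary:
    """Distance/ordering/spacing statistics over tandem promoters.

    Every gene must carry both element classes; for genes with several
    elements of a class the TSS-nearest instance is used.  Distances are
    edge-based in integer bases.
    """
    anns = list(annotations.values()) if isinstance(annotations, Mapping) else list(annotations)
    bad = [a.gene_id for a in anns if not (a.alu_elements and a.irf_elements)]
    if bad:
        raise ValueError(f"genes without both element classes: {bad[:10]}")
    if not anns:
        raise ValueError("no annotations given")
    records = [_gene_topology(a) for a in anns]
    spacings = [r["spacing"] for r in records]
    return TopologySummary(
        median_irf_tss_distance=median(r["irf_tss_distance"] for r in records),
        median_alu_tss_distance=median(r["alu_tss_distance"] for r in records),
        frac_alu_upstream_of_tss=sum(r["alu_upstream_of_tss"] for r in records) / len(records),
        frac_alu_upstream_of_irf=sum(r["alu_upstream_of_irf"] for r in records) / len(records),
        spacing_min_observed=min(spacings),
        spacing_max_observed=max(spacings),
        per_gene_records=records,
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_report_json(report: CooccurrenceReport, path) -> None:
    payload = {
        "set_size": report.set_size,
        "background_size": report.background_size,
        "set_counts": report.set_counts,
        "background_counts": report.background_counts,
        "set_fractions": report.set_fractions,
        "background_fractions": report.background_fractions,
        "hypergeom_p": report.hypergeom_p,
        "config": report.config,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def write_report_tsv(report: CooccurrenceReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("category\tset_count\tset_fraction\tbackground_count\t"
                 "background_fraction\thypergeom_p\n")
        for c in CATEGORIES:
            fh.write(
                f"{c}\t{report.set_counts[c]}\t{report.set_fractions[c]:.6g}\t"
                f"{report.background_counts[c]}\t{report.background_fractions[c]:.6g}\t"
                f"{report.hypergeom_p[c]:.6g}\n"
            )


def write_curve_tsv(curve: CumulativeCurve, path) -> None:
    with open(path, "w") as fh:
        fh.write("k\tfrac_alu\tfrac_tandem\n")
        for k, fa, ft in zip(curve.k_values, curve.frac_alu_at_k, curve.frac_tandem_at_k):
            fh.write(f"{k}\t{fa:.6g}\t{ft:.6g}\n")
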