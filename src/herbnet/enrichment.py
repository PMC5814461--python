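"""Hypergeometric term enrichment and greedy functional-module clustering.

For a query protein set of size n drawn from a background of size N, a term
covering K background proteins with k of them in the query gets the upper-tail
hypergeometric probability

    p = sum_{i=k}^{min(K, n)} C(K, i) C(N-K, n-i) / C(N, n),

i.e. the chance of seeing at least k hits by uniform sampling without
replacement. Terms with p below the cutoff (default 0.05, unadjusted, as is
conventional for annotation-browsing pipelines; Benjamini-Hochberg optional)
are kept and grouped into functional modules by single-linkage on the Jaccard
index of their protein sets.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy.stats import hypergeom

from .errors import ValidationError

log = logging.getLogger(__name__)

DEFAULT_P_CUTOFF = 0.05
DEFAULT_JACCARD = 0.5


@dataclass
class AnnotationDB:
    """term_id -> (name, protein set) annotation over a fixed background."""

    terms: dict[str, tuple[str, frozenset[str]]]
    background: frozenset[str]

    def __post_init__(self):
        self.background = frozenset(self.background)
        for tid, (name, prots) in self.terms.items():
            prots = frozenset(prots)
            if not prots:
                raise ValidationError(f"term {tid!r} has no proteins")
            if not prots <= self.background:
                raise ValidationError(f"term {tid!r} has proteins outside the background")
            self.terms[tid] = (name, prots)

    def proteins_of(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id][1]

    @classmethod
    def from_gmt(cls, gmt_path: str | Path, background: Iterable[str] | None = None) -> "AnnotationDB":
        """Load a GMT file (term_id, term_name, members...).

        With no explicit background, the union of all term members is used.
        """
        terms: dict[str, tuple[str, frozenset[str]]] = {}
        for line in Path(gmt_path).read_text().splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValidationError(f"GMT line with fewer than 3 fields: {line!r}")
            terms[parts[0]] = (parts[1], frozenset(p for p in parts[2:] if p))
        bg = frozenset(background) if background is not None else frozenset(
            p for _, s in terms.values() for p in s
        )
        return cls(terms, bg)

    def write_gmt(self, path: str | Path) -> None:
        lines = []
        for tid, (name, prots) in self.terms.items():
            lines.append("\t".join([tid, name] + sorted(prots)))
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # query hits in the term
    K: int  # term size
    n: int  # query size
    N: int  # background size
    p_value: float

    def __post_init__(self):
        if not (0 <= self.k <= min(self.K, self.n)):
            raise ValidationError(f"{self.term_id}: impossible overlap k={self.k}")
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError(f"{self.term_id}: p-value out of range: {self.p_value}")


@dataclass
class FunctionalModule:
    module_id: str
    label: str  # name of the most significant member term
    terms: list[str]
    proteins: frozenset[str]  # union over member terms


# ---------------------------------------------------------------------------

def hypergeom_enrich(
    query: Iterable[str],
    db: AnnotationDB,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    fdr: bool = False,
) -> list[EnrichmentResult]:
    """Terms over-represented in the query at p < p_cutoff, most significant first.

    Query ids outside the background are dropped with a logged count. With
    ``fdr`` true, Benjamini-Hochberg adjusted p-values are compared to the
    cutoff instead of the raw ones (the reported p stays raw).
    """
    query = set(query)
    inside = query & db.background
    if len(inside) < len(query):
        log.info("hypergeom_enrich: dropped %d query id(s) outside background",
                 len(query) - len(inside))
    if not inside:
        raise ValidationError("query is empty after intersecting with the background")
    N, n = len(db.background), len(inside)
    results = []
    for tid, (name, prots) in db.terms.items():
        K = len(prots)
        k = len(prots & inside)
        p = float(hypergeom.sf(k - 1, N, K, n))
        results.append(EnrichmentResult(tid, name, k, K, n, N, min(p, 1.0)))
    results.sort(key=lambda r: (r.p_value, r.term_id))
    if fdr:
        m = len(results)
        raw = np.array([r.p_value for r in results])
        adj = np.minimum.accumulate((raw * m / np.arange(1, m + 1))[::-1])[::-1]
        return [r for r, a in zip(results, adj) if a < p_cutoff]
    return [r for r in results if r.p_value < p_cutoff]


def _jaccard(a: frozenset, b: frozenset) -> float:
    return len(a & b) / len(a | b) if (a or b) else 0.0


def cluster_terms(
    results: list[EnrichmentResult],
    db: AnnotationDB,
    jaccard_threshold: float = DEFAULT_JACCARD,
) -> list[FunctionalModule]:
    """Single-linkage modules: terms join when protein-set Jaccard >= threshold.

    Deterministic: terms are processed sorted by (p, term_id); modules are the
    connected components of the threshold graph, labelled by their most
    significant term and numbered in order of that term's rank.
    """
    if not results:
        raise ValidationError("no enrichment results to cluster")
    if not (0.0 < jaccard_threshold <= 1.0):
        raise ValidationError(f"jaccard threshold must be in (0, 1], got {jaccard_threshold}")
    ordered = sorted(results, key=lambda r: (r.p_value, r.term_id))
    ids = [r.term_id for r in ordered]
    parent = list(range(len(ids)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    sets = [db.proteins_of(t) for t in ids]
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if _jaccard(sets[i], sets[j]) >= jaccard_threshold:
                parent[find(j)] = find(i)
    groups: dict[int, list[int]] = {}
    for i in range(len(ids)):
        groups.setdefault(find(i), []).append(i)
    modules = []
    for rank, members in enumerate(sorted(groups.values(), key=lambda ms: ms[0]), start=1):
        lead = ordered[members[0]]
        modules.append(
            FunctionalModule(
                module_id=f"M{rank}",
                label=lead.term_name,
                terms=[ids[i] for i in members],
                proteins=frozenset().union(*(sets[i] for i in members)),
            )
        )
    return modules


def write_enrichment_tsv(results: list[EnrichmentResult], path: str | Path) -> None:
    lines = ["term_id\tname\tk\tK\tn\tN\tp"]
    for r in results:
        lines.append(f"{r.term_id}\t{r.term_name}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t{r.p_value:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_modules_tsv(modules: list[FunctionalModule], path: str | Path) -> None:
    lines = ["module_id\tlabel\tterms\tproteins"]
    for m in modules:
        lines.append(f"{m.module_id}\t{m.label}\t{','.join(m.terms)}\t{','.join(sorted(m.proteins))}")
    Path(path).write_text("\n".join(lines) + "\n")


def module_annotation(
    modules: list[FunctionalModule], targets: Iterable[str]
) -> dict[str, set[str]]:
    """target_id -> module ids whose protein union contains the target."""
    annot: dict[str, set[str]] = {}
    for t in targets:
        hit = {m.module_id for m in modules if t in m.proteins}
        if hit:
            annot[t] = hit
    return annot
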