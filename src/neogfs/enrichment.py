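"""Annotation-density-adjusted resampling enrichment over GO-style terms.

Terms linked to fewer than ``min_families`` background families are merged
into a ``SMALL_BP`` bucket and families with no annotation at all form a
``NOT_ANNOTATED`` bucket, so every background family carries at least one
annotation and the buckets are testable like ordinary terms.

Because families differ in how densely they are annotated, a raw per-term
family count would reward samples that happen to contain heavily-annotated
families. Each sample's counts are therefore divided by the sample's mean
number of annotations per family before comparison. Significance is the
empirical upper tail of the adjusted count over ``n_samples`` equally sized
random family sets drawn without replacement from the background, with the
add-one correction ``p = (1 + #{null >= observed}) / (1 + n_samples)`` so a
finite resample never reports p = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .association import bh_fdr
from .data_io import AnnotationMap

SMALL_TERMS_BUCKET = "SMALL_BP"
UNANNOTATED_BUCKET = "NOT_ANNOTATED"


@dataclass(frozen=True)
class TermMap:
    """Retained terms (plus buckets) -> family sets over a fixed background."""

    terms: Mapping[str, frozenset[str]]
    background: frozenset[str]
    min_families: int

    def annotation_counts(self) -> dict[str, int]:
        """Annotations per family; each bucket membership counts as one."""
        counts = dict.fromkeys(self.background, 0)
        for families in self.terms.values():
            for f in families:
                counts[f] += 1
        return counts


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    n_background: int
    observed_adjusted_count: float
    null_mean: float
    p_empirical: float
    q: float


def build_term_map(annotations: AnnotationMap, background: Iterable[str],
                   min_families: int = 200) -> TermMap:
    """Bucket the annotation map over ``background``.

    Terms with at least ``min_families`` background families are retained;
    families annotated only to smaller terms join ``SMALL_BP`` and families
    with no annotation join ``NOT_ANNOTATED``.
    """
    bg = frozenset(str(f) for f in background)
    if not bg:
        raise ValueError("background is empty")
    by_term: dict[str, set[str]] = {}
    for family, term in annotations.pairs:
        if family in bg:
            by_term.setdefault(term, set()).add(family)
    terms: dict[str, frozenset[str]] = {}
    small: set[str] = set()
    for term, families in by_term.items():
        if len(families) >= min_families:
            terms[term] = frozenset(families)
        else:
            small |= families
    if small:
        terms[SMALL_TERMS_BUCKET] = frozenset(small)
    annotated = set().union(*terms.values()) if terms else set()
    unannotated = bg - annotated
    if unannotated:
        terms[UNANNOTATED_BUCKET] = frozenset(unannotated)
    return TermMap(terms, bg, min_families)


def adjusted_count(sample: Iterable[str], term: str, term_map: TermMap) -> float:
    """Family count of ``term`` within the sample, divided by the sample's mean
    number of annotations per family."""
    sample = set(sample)
    if not sample:
        raise ValueError("sample is empty")
    if not sample <= term_map.background:
        raise ValueError("sample is not a subset of the background")
    counts = term_map.annotation_counts()
    density = float(np.mean([counts[f] for f in sample]))
    return len(sample & term_map.terms.get(term, frozenset())) / density


def enrichment_test(test_set: Iterable[str], background: Iterable[str],
                    term_map: TermMap, n_samples: int = 1000,
                    seed: int | None = None) -> list[EnrichmentResult]:
    """Density-adjusted resampling enrichment of ``test_set`` against uniform
    random family sets of the same size.

    One result per retained term and bucket, BH-corrected jointly.
    """
    bg = sorted(set(str(f) for f in background))
    test = set(str(f) for f in test_set)
    if not test:
        raise ValueError("test set is empty")
    if not test <= set(bg):
        raise ValueError("test set is not a subset of the background")
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")

    index = {f: i for i, f in enumerate(bg)}
    terms = sorted(term_map.terms)
    M = np.zeros((len(terms), len(bg)), dtype=np.float64)
    for t, term in enumerate(terms):
        for f in term_map.terms[term]:
            if f in index:
                M[t, index[f]] = 1.0
    ann = np.zeros(len(bg))
    for f, c in term_map.annotation_counts().items():
        if f in index:
            ann[index[f]] = c

    k = len(test)
    t_ind = np.zeros(len(bg))
    t_ind[[index[f] for f in test]] = 1.0
    observed = (M @ t_ind) / float(ann @ t_ind / k)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    S = np.zeros((len(bg), n_samples))
    # without-replacement samples via a random-key partial sort per replicate
    keys = rng.random((n_samples, len(bg)))
    chosen = np.argpartition(keys, k - 1, axis=1)[:, :k]
    rows = chosen.T
    S[rows, np.arange(n_samples)[None, :].repeat(k, axis=0)] = 1.0
    null_counts = M @ S
    null_density = (ann @ S) / k
    null_adjusted = null_counts / null_density[None, :]

    p = (1 + (null_adjusted >= observed[:, None]).sum(axis=1)) / (1 + n_samples)
    q = bh_fdr(p)
    return [
        EnrichmentResult(
            term=term,
            n_background=int(M[t].sum()),
            observed_adjusted_count=float(observed[t]),
            null_mean=float(null_adjusted[t].mean()),
            p_empirical=float(p[t]),
            q=float(q[t]),
        )
        for t, term in enumerate(terms)
    ]


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """Jaccard index |a & b| / |a | b| of two sets."""
    a, b = set(a), set(b)
    if not a and not b:
        raise ValueError("both sets are empty")
    return len(a & b) / len(a | b)
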