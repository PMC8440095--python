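"""Interaction and functional-similarity scores against the seed genes.

Two per-gene evidence scores complement the diffusion Z-score:

* MIS, the maximum interaction score: the largest STRING confidence score
  between a candidate and any seed gene (0 if no seed is adjacent). Scores
  above 900 sit in STRING's "highest confidence" band.
* MFS, the maximum function score: the largest cosine similarity between the
  candidate's functional-annotation vector and any seed's vector, measuring
  how many GO terms / KEGG pathways the candidate shares with a seed.

The annotation encoding is binary term membership by default (cosine then
measures pure annotation overlap); a per-term weighting hook is provided for
alternative encodings such as inverse-frequency weights.
"""

from __future__ import annotations

from typing import Callable, Mapping

import numpy as np

from .ppi_io import AnnotationTable, PPINetwork, SeedSet, ValidationError

TermWeights = Mapping[str, float] | Callable[[str], float] | None


def mis(gene: str, seeds: SeedSet, network: PPINetwork) -> int:
    """Maximum edge confidence score between ``gene`` and any seed."""
    if not network.has_node(gene):
        raise ValidationError(f"gene {gene!r} not in network")
    best = 0
    for s in seeds.members:
        score = network.score(gene, s)
        if score > best:
            best = score
    return best


def _weight(term: str, weights: TermWeights) -> float:
    if weights is None:
        return 1.0
    if callable(weights):
        return float(weights(term))
    return float(weights.get(term, 1.0))


def enrichment_vector(
    gene: str,
    annotations: AnnotationTable,
    weights: TermWeights = None,
) -> dict[str, float]:
    """Sparse annotation vector of ``gene``: weight > 0 on each term whose
    gene set contains it (weight 1 by default). Unannotated genes get {}."""
    vec = {}
    for term in annotations.terms_of(gene):
        w = _weight(term, weights)
        if w < 0:
            raise ValidationError(f"negative weight for term {term!r}")
        if w > 0:
            vec[term] = w
    return vec


def cosine_similarity(e1: Mapping[str, float], e2: Mapping[str, float]) -> float:
    """Cosine of two sparse nonnegative vectors; 0 if either is empty."""
    if not e1 or not e2:
        return 0.0
    if len(e2) < len(e1):
        e1, e2 = e2, e1
    dot = sum(w * e2[t] for t, w in e1.items() if t in e2)
    n1 = np.sqrt(sum(w * w for w in e1.values()))
    n2 = np.sqrt(sum(w * w for w in e2.values()))
    return float(dot / (n1 * n2))


def mfs(
    gene: str,
    seeds: SeedSet,
    annotations: AnnotationTable,
    weights: TermWeights = None,
) -> float:
    """Maximum cosine similarity between ``gene`` and any seed's annotation
    vector; 0 when the gene or every seed is unannotated."""
    eg = enrichment_vector(gene, annotations, weights)
    if not eg:
        return 0.0
    best = 0.0
    for s in seeds.members:
        sim = cosine_similarity(eg, enrichment_vector(s, annotations, weights))
        if sim > best:
            best = sim
    return best
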