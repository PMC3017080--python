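"""Network-neighborhood GO enrichment scores.

The functional context of a gene is summarized by its direct network
neighborhood (the gene plus its interactors).  For each GO term the score is
the -log10 upper-tail hypergeometric p-value of the overlap between that
neighborhood and the term's annotated gene set, over a fixed ORF universe:

    p = P(X >= x),  X ~ Hypergeometric(N, K, m)

with N the universe size, K the term size, m the neighborhood size and x the
observed overlap.  Larger scores mean stronger over-representation.  Scores
are used as features, so no multiple-testing correction is applied.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom

from .datatypes import EnrichmentQuery, FeatureMatrix, GoAnnotationSet, Network
from .errors import UnknownFeatureError, ValidationError

#: p-values are floored here before the log so feature values stay finite.
P_FLOOR = 1e-300


def neighborhood(gene: str, network: Network) -> set[str]:
    """The gene itself plus its direct network neighbors."""
    return {gene} | network.neighbors(gene)


def hypergeom_upper_p(query: EnrichmentQuery) -> float:
    """Upper-tail probability P(X >= overlap); in (0, 1]."""
    # EnrichmentQuery validates its invariants on construction
    p = float(
        hypergeom.sf(
            query.overlap - 1,
            query.universe_size,
            query.term_size,
            query.neighborhood_size,
        )
    )
    return min(max(p, 0.0), 1.0)


def enrichment_score(
    gene: str,
    term: str,
    network: Network,
    annotations: GoAnnotationSet,
) -> float:
    """-log10 of the neighborhood over-representation p-value for one term."""
    if term not in annotations.term_to_genes:
        raise UnknownFeatureError(f"unknown GO term {term!r}")
    nb = neighborhood(gene, network) & annotations.universe
    term_genes = annotations.term_to_genes[term]
    query = EnrichmentQuery(
        universe_size=len(annotations.universe),
        term_size=len(term_genes),
        neighborhood_size=len(nb),
        overlap=len(nb & term_genes),
    )
    return -np.log10(max(hypergeom_upper_p(query), P_FLOOR))


def enrichment_matrix(
    genes: list[str],
    network: Network,
    annotations: GoAnnotationSet,
    terms: list[str] | None = None,
) -> FeatureMatrix:
    """Enrichment scores for every (gene, term) pair as a FeatureMatrix.

    Columns are term ids in sorted order (deterministic); rows follow the
    input gene order.  Neighborhoods are intersected with the universe so
    the hypergeometric counts stay consistent.
    """
    if terms is None:
        terms = annotations.terms
    if not terms:
        raise ValidationError("term list must be nonempty")
    unknown = [t for t in terms if t not in annotations.term_to_genes]
    if unknown:
        raise UnknownFeatureError(f"unknown GO terms: {unknown[:5]}")
    terms = sorted(terms)
    universe = sorted(annotations.universe)
    index = {g: i for i, g in enumerate(universe)}
    n_universe = len(universe)

    # term membership as a boolean matrix over the universe
    term_matrix = np.zeros((len(terms), n_universe), dtype=bool)
    term_sizes = np.empty(len(terms), dtype=int)
    for t, term in enumerate(terms):
        for g in annotations.term_to_genes[term]:
            term_matrix[t, index[g]] = True
        term_sizes[t] = term_matrix[t].sum()

    nb_sizes = np.empty(len(genes), dtype=int)
    overlaps = np.empty((len(genes), len(terms)), dtype=int)
    for i, gene in enumerate(genes):
        nb = neighborhood(gene, network)
        nb_vec = np.zeros(n_universe, dtype=bool)
        for g in nb:
            j = index.get(g)
            if j is not None:
                nb_vec[j] = True
        nb_sizes[i] = nb_vec.sum()
        overlaps[i] = term_matrix @ nb_vec.astype(int)

    p = hypergeom.sf(
        overlaps - 1, n_universe, term_sizes[None, :], nb_sizes[:, None]
    )
    scores = -np.log10(np.clip(p, P_FLOOR, 1.0))
    return FeatureMatrix(genes, terms, scores)
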