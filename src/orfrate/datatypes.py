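"""Core in-memory containers.

The pipeline passes a small set of typed containers between stages: one ORF's
sequences and annotations (:class:`OrfRecord`), a samples x named-features
matrix with an explicit missing-value mask (:class:`FeatureMatrix`), the
binary class labels (:class:`LabelVector`), an undirected gene network
(:class:`Network`), GO term annotations (:class:`GoAnnotationSet`), and the
result objects of feature ranking and evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import UnknownFeatureError, ValidationError

LOW = "low"
HIGH = "high"

_DNA = frozenset("ACGT")
_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
_SS = frozenset("HEC")  # helix / strand / coil
_ACC = frozenset("EB")  # exposed / buried


@dataclass
class OrfRecord:
    """One ORF: coding sequence, optional UTR/protein data and auxiliary values.

    ``ss_annotation`` uses one letter per residue from {H, E, C} (helix,
    strand, coil); ``acc_annotation`` uses {E, B} (exposed, buried).  Both
    must match the protein length when present.  ``auxiliary`` holds named
    per-ORF real values (UTR lengths, free energies, abundance, half-lives,
    binding-protein counts); any entry may be absent.
    """

    orf_id: str
    cds: str
    upstream_utr: str = ""
    protein: str = ""
    ss_annotation: str | None = None
    acc_annotation: str | None = None
    auxiliary: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.orf_id:
            raise ValidationError("orf_id must be nonempty")
        self.cds = self.cds.upper()
        self.upstream_utr = self.upstream_utr.upper()
        self.protein = self.protein.upper()
        bad = set(self.cds) - _DNA
        if bad:
            raise ValidationError(
                f"ORF {self.orf_id}: CDS contains non-DNA characters {sorted(bad)}"
            )
        bad = set(self.upstream_utr) - _DNA
        if bad:
            raise ValidationError(
                f"ORF {self.orf_id}: UTR contains non-DNA characters {sorted(bad)}"
            )
        if self.protein:
            bad = set(self.protein) - _AA
            if bad:
                raise ValidationError(
                    f"ORF {self.orf_id}: protein contains illegal residues {sorted(bad)}"
                )
        for name, alphabet, ann in (
            ("ss_annotation", _SS, self.ss_annotation),
            ("acc_annotation", _ACC, self.acc_annotation),
        ):
            if ann is None:
                continue
            if len(ann) != len(self.protein):
                raise ValidationError(
                    f"ORF {self.orf_id}: {name} length {len(ann)} != protein "
                    f"length {len(self.protein)}"
                )
            bad = set(ann) - alphabet
            if bad:
                raise ValidationError(
                    f"ORF {self.orf_id}: {name} contains illegal symbols {sorted(bad)}"
                )


class FeatureMatrix:
    """Samples x named features, with an explicit missing-value mask.

    Values at masked cells are stored as NaN and are excluded from all
    statistics downstream.  Feature names must be unique.
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        feature_names: Sequence[str],
        values: np.ndarray,
        missing_mask: np.ndarray | None = None,
    ) -> None:
        self.sample_ids = list(sample_ids)
        self.feature_names = list(feature_names)
        values = np.asarray(values, dtype=float)
        if values.shape != (len(self.sample_ids), len(self.feature_names)):
            raise ValidationError(
                f"values shape {values.shape} does not match "
                f"({len(self.sample_ids)}, {len(self.feature_names)})"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            seen: set[str] = set()
            dups = [n for n in self.feature_names if n in seen or seen.add(n)]
            raise ValidationError(f"duplicate feature names: {sorted(set(dups))}")
        if missing_mask is None:
            missing_mask = np.isnan(values)
        else:
            missing_mask = np.asarray(missing_mask, dtype=bool)
            if missing_mask.shape != values.shape:
                raise ValidationError("missing_mask shape does not match values")
            values = values.copy()
            values[missing_mask] = np.nan
        self.values = values
        self.missing_mask = missing_mask
        self._index = {n: j for j, n in enumerate(self.feature_names)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def column(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (values, missing_mask) for one feature."""
        try:
            j = self._index[name]
        except KeyError:
            raise UnknownFeatureError(name) from None
        return self.values[:, j], self.missing_mask[:, j]

    def subset(self, names: Sequence[str]) -> "FeatureMatrix":
        missing = [n for n in names if n not in self._index]
        if missing:
            raise UnknownFeatureError(
                f"features not in matrix: {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )
        idx = [self._index[n] for n in names]
        return FeatureMatrix(
            self.sample_ids,
            [self.feature_names[j] for j in idx],
            self.values[:, idx],
            self.missing_mask[:, idx],
        )

    @staticmethod
    def hstack(blocks: Sequence["FeatureMatrix"]) -> "FeatureMatrix":
        if not blocks:
            raise ValidationError("hstack requires at least one block")
        ids = blocks[0].sample_ids
        for b in blocks[1:]:
            if b.sample_ids != ids:
                raise ValidationError("hstack blocks must share sample ids")
        names = [n for b in blocks for n in b.feature_names]
        values = np.hstack([b.values for b in blocks])
        mask = np.hstack([b.missing_mask for b in blocks])
        return FeatureMatrix(ids, names, values, mask)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_names
        )
        df.index.name = "sample"
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureMatrix":
        return cls(
            [str(i) for i in df.index],
            [str(c) for c in df.columns],
            df.to_numpy(dtype=float),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.feature_names == other.feature_names
            and np.array_equal(self.missing_mask, other.missing_mask)
            and np.array_equal(
                self.values[~self.missing_mask], other.values[~other.missing_mask]
            )
        )


@dataclass
class LabelVector:
    """Per-sample class label, ``low`` or ``high``, plus the split rule used."""

    labels: np.ndarray
    rule: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        bad = set(self.labels) - {LOW, HIGH}
        if bad:
            raise ValidationError(f"labels must be '{LOW}' or '{HIGH}', got {bad}")

    def __len__(self) -> int:
        return len(self.labels)

    def as_binary(self) -> np.ndarray:
        """0/1 encoding with high = 1."""
        return (self.labels == HIGH).astype(int)

    @property
    def n_high(self) -> int:
        return int((self.labels == HIGH).sum())

    @property
    def n_low(self) -> int:
        return int((self.labels == LOW).sum())

    def require_both_classes(self) -> None:
        if self.n_high == 0 or self.n_low == 0:
            raise ValidationError(
                f"both classes required: n_low={self.n_low}, n_high={self.n_high}"
            )


class Network:
    """Undirected gene-gene network (no self-loops stored)."""

    def __init__(self, graph: nx.Graph) -> None:
        self.graph = graph

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], nodes: Iterable[str] = ()
    ) -> tuple["Network", int]:
        """Build from an edge iterable; returns (network, n_self_loops_dropped).

        Duplicate and reversed edges collapse; self-loops are dropped.
        """
        g = nx.Graph()
        g.add_nodes_from(nodes)
        dropped = 0
        for a, b in edges:
            if a == b:
                dropped += 1
                g.add_node(a)
                continue
            g.add_edge(a, b)
        return cls(g), dropped

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}

    def neighbors(self, gene: str) -> set[str]:
        if gene not in self.graph:
            return set()
        return set(self.graph.neighbors(gene))


@dataclass
class GoAnnotationSet:
    """Gene Ontology annotations: term -> annotated genes, over a fixed universe.

    The universe is the full ORF list of the organism (the population size of
    the hypergeometric test), supplied explicitly rather than inferred from
    annotation coverage.
    """

    term_to_genes: dict[str, frozenset]
    universe: frozenset

    def __post_init__(self) -> None:
        self.universe = frozenset(self.universe)
        self.term_to_genes = {
            t: frozenset(g) for t, g in self.term_to_genes.items()
        }
        for term, genes in self.term_to_genes.items():
            if not genes:
                raise ValidationError(f"term {term} has no annotated genes")
            extra = genes - self.universe
            if extra:
                raise ValidationError(
                    f"term {term}: annotated genes outside universe, "
                    f"e.g. {sorted(extra)[:3]}"
                )

    @property
    def terms(self) -> list[str]:
        return sorted(self.term_to_genes)


@dataclass
class EnrichmentQuery:
    """The four counts of one hypergeometric over-representation test."""

    universe_size: int
    term_size: int
    neighborhood_size: int
    overlap: int

    def __post_init__(self) -> None:
        n, k, m, x = (
            self.universe_size,
            self.term_size,
            self.neighborhood_size,
            self.overlap,
        )
        if not (0 <= x <= min(k, m)):
            raise ValidationError(
                f"overlap {x} outside [0, min(term_size={k}, neighborhood_size={m})]"
            )
        if m > n or k > n:
            raise ValidationError(
                f"term_size ({k}) and neighborhood_size ({m}) must not exceed "
                f"universe_size ({n})"
            )
        if n <= 0:
            raise ValidationError("universe_size must be positive")


@dataclass
class RankedFeatures:
    """Output of greedy relevance/redundancy ranking.

    ``order`` lists feature names in selection order (rank 1 first);
    ``relevance`` maps every candidate feature to its mutual information with
    the class; ``score_at_selection`` maps each selected feature to the
    criterion value of the round in which it was picked.
    """

    order: list[str]
    relevance: dict[str, float]
    score_at_selection: dict[str, float]

    def __post_init__(self) -> None:
        if len(set(self.order)) != len(self.order):
            raise ValidationError("ranking contains duplicate features")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.order) + 1),
                "feature": self.order,
                "relevance": [self.relevance[f] for f in self.order],
                "criterion_score": [self.score_at_selection[f] for f in self.order],
            }
        )


@dataclass
class EvalResult:
    """Jackknife evaluation counts and overall accuracy."""

    correct_high: int
    correct_low: int
    n_high: int
    n_low: int

    @property
    def accuracy(self) -> float:
        return (self.correct_high + self.correct_low) / (self.n_high + self.n_low)


@dataclass
class IfsCurve:
    """Accuracy as a function of nested feature-subset size along a ranking."""

    points: list[tuple[int, EvalResult]]
    ranking: RankedFeatures | None

    @property
    def sizes(self) -> np.ndarray:
        return np.array([k for k, _ in self.points])

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([r.accuracy for _, r in self.points])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": [k for k, _ in self.points],
                "accuracy": [r.accuracy for _, r in self.points],
                "correct_high": [r.correct_high for _, r in self.points],
                "correct_low": [r.correct_low for _, r in self.points],
            }
        )
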