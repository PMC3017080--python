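"""Readers and writers for the external formats the toolkit touches.

FASTA (DNA or protein) via Biopython; tab-separated tables with header rows
for auxiliary features, per-residue annotations and translation rates; a
two-column whitespace/tab edge list for the network; one gene/term pair per
line for GO annotations.  Feature matrices serialize as TSV with the sample
id in the first column and empty cells meaning missing.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import FeatureMatrix, GoAnnotationSet, Network
from .errors import ParseError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

_ALPHABETS = {
    "dna": frozenset("ACGT"),
    "protein": frozenset("ACDEFGHIKLMNPQRSTVWY"),
}


def read_fasta(path: str | Path, alphabet: str = "dna") -> list[tuple[str, str]]:
    """Read a FASTA file; sequences are uppercased and validated.

    ``alphabet`` is ``"dna"`` (A/C/G/T only; U is rejected) or ``"protein"``
    (the 20 standard residues).
    """
    if alphabet not in _ALPHABETS:
        raise ValidationError(f"unknown alphabet {alphabet!r}")
    allowed = _ALPHABETS[alphabet]
    out: list[tuple[str, str]] = []
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # malformed record
        raise ParseError(f"{path}: {exc}") from exc
    for rec in records:
        if not rec.id:
            raise ParseError(f"{path}: record with empty header")
        seq = str(rec.seq).upper()
        bad = set(seq) - allowed
        if bad:
            raise ValidationError(
                f"{path}: record {rec.id!r} has characters {sorted(bad)} "
                f"illegal for {alphabet} alphabet"
            )
        out.append((rec.id, seq))
    return out


def write_fasta(path: str | Path, records: Sequence[tuple[str, str]]) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_table(
    path: str | Path, required_columns: Sequence[str] = ()
) -> pd.DataFrame:
    """Read a tab-separated table with a header row.

    Missing cells come back as NaN (marked missing, never silently zero).
    Raises :class:`SchemaError` listing any absent required columns.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=None, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    # gene/sample identifiers are matched case-sensitively after trimming
    for col in df.columns:
        if df[col].dtype == object:
            df[col] = df[col].str.strip()
    return df


def read_network(path: str | Path) -> Network:
    """Read a two-column edge list (whitespace- or tab-delimited).

    Duplicate and reversed edges collapse to one undirected edge; self-loops
    are dropped (a count is logged).
    """
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 fields, got {len(fields)}"
                )
            edges.append((fields[0], fields[1]))
    network, dropped = Network.from_edges(edges)
    if dropped:
        logger.warning("%s: dropped %d self-loop(s)", path, dropped)
    return network


def write_network(path: str | Path, network: Network) -> None:
    with open(path, "w") as fh:
        for edge in sorted(tuple(sorted(e)) for e in network.edges):
            fh.write(f"{edge[0]}\t{edge[1]}\n")


def read_go_annotations(
    path: str | Path, universe: Sequence[str]
) -> GoAnnotationSet:
    """Read gene/term pairs (TSV, columns ``gene`` and ``term``).

    The term universe is the provided ORF list, not annotation coverage.
    Annotations for genes outside the universe are dropped with a log notice.
    """
    df = read_table(path, required_columns=("gene", "term"))
    universe_set = frozenset(str(g).strip() for g in universe)
    term_to_genes: dict[str, set] = {}
    dropped = 0
    for gene, term in zip(df["gene"], df["term"]):
        if gene not in universe_set:
            dropped += 1
            continue
        term_to_genes.setdefault(term, set()).add(gene)
    if dropped:
        logger.warning("%s: dropped %d annotation(s) outside universe", path, dropped)
    return GoAnnotationSet(
        {t: frozenset(g) for t, g in term_to_genes.items()}, universe_set
    )


def write_go_annotations(path: str | Path, annotations: GoAnnotationSet) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tterm\n")
        for term in annotations.terms:
            for gene in sorted(annotations.term_to_genes[term]):
                fh.write(f"{gene}\t{term}\n")


def read_rates(path: str | Path) -> dict[str, float]:
    """Read per-ORF continuous translation rates (TSV: orf, rate)."""
    df = read_table(path, required_columns=("orf", "rate"))
    return {
        str(o): float(r) for o, r in zip(df["orf"], df["rate"]) if pd.notna(r)
    }


def write_rates(path: str | Path, rates: dict[str, float]) -> None:
    with open(path, "w") as fh:
        fh.write("orf\trate\n")
        for orf, rate in rates.items():
            fh.write(f"{orf}\t{rate!r}\n")


def write_feature_matrix(path: str | Path, matrix: FeatureMatrix) -> None:
    """TSV with the sample id first; empty cells mean missing."""
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(matrix.feature_names) + "\n")
        for i, sid in enumerate(matrix.sample_ids):
            cells = [
                "" if matrix.missing_mask[i, j] else repr(float(matrix.values[i, j]))
                for j in range(matrix.n_features)
            ]
            fh.write(sid + "\t" + "\t".join(cells) + "\n")


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    values = df.to_numpy(dtype=float)
    return FeatureMatrix(
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
        values,
        np.isnan(values),
    )
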