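"""Nucleotide-level feature encoders.

Codon usage frequencies over the full 64-codon table (stop codons included),
one-hot encoding of the 3 nt flanking the start codon on each side, coding
sequence length, and extraction of the 42 nt window across the translation
start site whose folding energy is a known correlate of protein output.
"""

from __future__ import annotations

import logging

from .errors import ValidationError

logger = logging.getLogger(__name__)

BASES = "ACGT"

#: The 64 codons in fixed lexicographic (A<C<G<T) order.
CODONS: tuple[str, ...] = tuple(
    a + b + c for a in BASES for b in BASES for c in BASES
)

_DNA = frozenset(BASES)

# window across the translation start site: 4 nt upstream of the A of ATG
# plus the first 38 nt of the CDS = 42 nt total
TSS_WINDOW_UPSTREAM = 4
TSS_WINDOW_DOWNSTREAM = 38


def codon_usage(cds: str) -> dict[str, float]:
    """Relative frequency of each of the 64 codons in a coding sequence.

    A trailing partial codon is dropped with a warning (annotation slippage
    is tolerated, not fatal).  Frequencies sum to 1.
    """
    cds = cds.upper()
    if len(cds) < 3:
        raise ValidationError(f"CDS too short for codon counting: {len(cds)} nt")
    bad = set(cds) - _DNA
    if bad:
        raise ValidationError(f"CDS contains non-DNA characters {sorted(bad)}")
    remainder = len(cds) % 3
    if remainder:
        logger.warning(
            "CDS length %d not divisible by 3; dropping trailing %d nt",
            len(cds),
            remainder,
        )
        cds = cds[: len(cds) - remainder]
    n = len(cds) // 3
    counts = dict.fromkeys(CODONS, 0)
    for i in range(0, len(cds), 3):
        counts[cds[i : i + 3]] += 1
    return {codon: counts[codon] / n for codon in CODONS}


def start_codon_context(upstream3: str, downstream3: str) -> dict[str, int]:
    """One-hot encoding of the 3 nt before and after the start codon.

    Returns 24 binary values: six positions (u3, u2, u1 upstream of the A of
    ATG; d1, d2, d3 immediately after the G), each as a 4-vector in fixed
    A, C, G, T order.  Exactly six of the 24 outputs are 1.
    """
    upstream3 = upstream3.upper()
    downstream3 = downstream3.upper()
    for name, seq in (("upstream3", upstream3), ("downstream3", downstream3)):
        if len(seq) != 3:
            raise ValidationError(f"{name} must be length 3, got {len(seq)}")
        bad = set(seq) - _DNA
        if bad:
            raise ValidationError(f"{name} contains non-DNA characters {sorted(bad)}")
    positions = [
        ("u3", upstream3[0]),
        ("u2", upstream3[1]),
        ("u1", upstream3[2]),
        ("d1", downstream3[0]),
        ("d2", downstream3[1]),
        ("d3", downstream3[2]),
    ]
    out: dict[str, int] = {}
    for pos, base in positions:
        for b in BASES:
            out[f"start.{pos}.{b}"] = int(base == b)
    return out


def cds_length(cds: str) -> int:
    """Coding sequence length in nucleotides."""
    if not cds:
        raise ValidationError("empty CDS has no length feature")
    return len(cds)


def tss_window(upstream_utr: str, cds: str, orf_id: str = "?") -> str:
    """The 42 nt window spanning the translation start site.

    Convention: the 4 nt immediately upstream of the A of ATG plus the first
    38 nt of the CDS, giving exactly 42 nt.  (Stating the window by its
    endpoints is ambiguous when no position 0 exists; this package fixes the
    4 + 38 split and documents it.)
    """
    if len(upstream_utr) < TSS_WINDOW_UPSTREAM:
        raise ValidationError(
            f"ORF {orf_id}: upstream UTR too short for the 42 nt window "
            f"({len(upstream_utr)} < {TSS_WINDOW_UPSTREAM} nt)"
        )
    if len(cds) < TSS_WINDOW_DOWNSTREAM:
        raise ValidationError(
            f"ORF {orf_id}: CDS too short for the 42 nt window "
            f"({len(cds)} < {TSS_WINDOW_DOWNSTREAM} nt)"
        )
    window = upstream_utr[-TSS_WINDOW_UPSTREAM:] + cds[:TSS_WINDOW_DOWNSTREAM]
    assert len(window) == 42
    return window
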