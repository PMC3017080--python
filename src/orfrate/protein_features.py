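"""Biochemical/physicochemical protein descriptors (132 per protein).

A protein of any length is encoded by 20 amino-acid composition fractions
plus composition-transition-distribution (CTD) blocks for six per-residue
properties.  For each property every residue is mapped to one of 2 or 3
pseudo groups; the CTD block then summarizes the group sequence by

* composition - the fraction of residues in each group,
* transition - the frequency of adjacent group changes (unordered pairs,
  divided by L-1),
* distribution - the relative position (fraction of L) at which the first,
  25%, 50%, 75% and last occurrence of each group falls.

Secondary structure (helix/strand/coil) and solvent accessibility
(exposed/buried) are per-residue predictions.  When real predictor output is
unavailable, a deterministic per-residue propensity table assigns each amino
acid its most typical state so the full vector stays computable; supplied
annotations always override the fallback.

Three-group properties yield 3 + 3 + 15 = 21 features.  The two-group
solvent-accessibility block yields 7: composition (2), transition (1) and
the first group's first/25%/50%/75% distribution landmarks (4) - the
documented convention this package uses to arrive at a 7-value block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import OrfRecord
from .errors import ConfigurationError, ValidationError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA = frozenset(AMINO_ACIDS)


@dataclass(frozen=True)
class PropertyScheme:
    """An ordered partition of an alphabet into 2 or 3 pseudo groups."""

    name: str
    groups: tuple[str, ...]
    alphabet: str  # "protein", "ss" or "acc"

    def __post_init__(self) -> None:
        letters = [c for g in self.groups for c in g]
        if len(letters) != len(set(letters)):
            raise ValidationError(f"{self.name}: groups overlap")
        if self.alphabet == "protein" and set(letters) != _AA:
            raise ValidationError(f"{self.name}: groups must partition the 20 residues")

    @property
    def group_count(self) -> int:
        return len(self.groups)

    def group_index(self, symbol: str) -> int:
        for i, g in enumerate(self.groups, start=1):
            if symbol in g:
                return i
        raise ValidationError(f"{self.name}: symbol {symbol!r} not in any group")


# residue group lists for the four sequence-derived properties
HYDROPHOBICITY = PropertyScheme(
    "hydrophobicity", ("CVFLIMW", "GPHASTY", "QERKDN"), "protein"
)
POLARIZABILITY = PropertyScheme(
    "polarizability", ("YMKRHFW", "CQIPNVEL", "SDGAT"), "protein"
)
VDW_VOLUME = PropertyScheme(
    "van_der_waals_volume", ("KFMHRYW", "EQNVIL", "SCGATPD"), "protein"
)
POLARITY = PropertyScheme("polarity", ("KNHQRED", "TGPAS", "WCLIFMVY"), "protein")
# annotation-driven properties: group symbols are the annotation letters
SECONDARY_STRUCTURE = PropertyScheme("secondary_structure", ("H", "E", "C"), "ss")
SOLVENT_ACCESSIBILITY = PropertyScheme("solvent_accessibility", ("E", "B"), "acc")

SCHEMES = {
    s.name: s
    for s in (
        SECONDARY_STRUCTURE,
        SOLVENT_ACCESSIBILITY,
        HYDROPHOBICITY,
        POLARIZABILITY,
        VDW_VOLUME,
        POLARITY,
    )
}

# Deterministic per-residue fallback when no structure predictor output is
# supplied: each residue maps to its most typical secondary-structure state
# (Chou-Fasman-like propensities) and burial state.
SS_FALLBACK = {
    **{aa: "H" for aa in "AELMQKRH"},
    **{aa: "E" for aa in "VIYCWFT"},
    **{aa: "C" for aa in "GNPSD"},
}
ACC_FALLBACK = {
    **{aa: "E" for aa in "RKDENQHSTPGY"},
    **{aa: "B" for aa in "ACFILMVW"},
}

_SHORT = {
    "secondary_structure": "ss",
    "solvent_accessibility": "acc",
    "hydrophobicity": "hydro",
    "polarizability": "polz",
    "van_der_waals_volume": "vdw",
    "polarity": "polar",
}


def aa_composition(protein: str) -> dict[str, float]:
    """Fraction of each of the 20 amino acids; fractions sum to 1."""
    protein = protein.upper()
    if not protein:
        raise ValidationError("empty protein sequence")
    for pos, residue in enumerate(protein):
        if residue not in _AA:
            raise ValidationError(f"illegal residue {residue!r} at position {pos}")
    n = len(protein)
    return {f"aa.{aa}": protein.count(aa) / n for aa in AMINO_ACIDS}


def to_group_sequence(
    protein: str,
    scheme: PropertyScheme,
    annotation: str | None = None,
    fallback: bool = True,
) -> np.ndarray:
    """Map a protein to per-residue group indices (1..group_count).

    For annotation-driven schemes (secondary structure, solvent
    accessibility) an annotation string of matching length is used when
    given; otherwise the deterministic propensity fallback applies when
    enabled, and a :class:`ConfigurationError` is raised when it is not.
    """
    protein = protein.upper()
    if not protein:
        raise ValidationError("empty protein sequence")
    if scheme.alphabet == "protein":
        symbols = protein
    else:
        if annotation is not None:
            if len(annotation) != len(protein):
                raise ValidationError(
                    f"{scheme.name}: annotation length {len(annotation)} != "
                    f"protein length {len(protein)}"
                )
            symbols = annotation.upper()
        elif fallback:
            table = SS_FALLBACK if scheme.alphabet == "ss" else ACC_FALLBACK
            symbols = "".join(table[aa] for aa in protein)
        else:
            raise ConfigurationError(
                f"{scheme.name} requires a per-residue annotation "
                "(or the propensity fallback enabled)"
            )
    return np.array([scheme.group_index(s) for s in symbols], dtype=int)


_LANDMARKS = ("first", "q25", "q50", "q75", "last")
_QUANTILES = (0.25, 0.50, 0.75)


def _distribution(group_seq: np.ndarray, group: int) -> list[float]:
    """first/25%/50%/75%/last landmark positions of one group, as fractions of L.

    The q-quantile landmark among n occurrences is occurrence number
    ceil(q*n); positions are 1-based over L.  Absent group -> all zeros.
    """
    length = len(group_seq)
    positions = np.flatnonzero(group_seq == group) + 1  # 1-based
    n = len(positions)
    if n == 0:
        return [0.0] * 5
    landmarks = [positions[0]]
    for q in _QUANTILES:
        landmarks.append(positions[int(np.ceil(q * n)) - 1])
    landmarks.append(positions[-1])
    return [p / length for p in landmarks]


def ctd_block(group_seq: np.ndarray, group_count: int) -> dict[str, float]:
    """CTD descriptor of a group-index sequence.

    21 named values for three groups (3 composition + 3 transition +
    15 distribution); 7 for two groups (2 + 1 + the first group's
    first/25/50/75 landmarks).
    """
    group_seq = np.asarray(group_seq, dtype=int)
    if group_seq.size < 2:
        raise ValidationError("group sequence must have length >= 2")
    if group_count not in (2, 3):
        raise ValidationError("group_count must be 2 or 3")
    if group_seq.min() < 1 or group_seq.max() > group_count:
        raise ValidationError("group indices must lie in 1..group_count")
    length = len(group_seq)
    out: dict[str, float] = {}
    for g in range(1, group_count + 1):
        out[f"comp.g{g}"] = float((group_seq == g).sum()) / length
    pairs = (
        [(1, 2)] if group_count == 2 else [(1, 2), (1, 3), (2, 3)]
    )
    a, b = group_seq[:-1], group_seq[1:]
    for i, j in pairs:
        changes = ((a == i) & (b == j)) | ((a == j) & (b == i))
        out[f"trans.g{i}{j}"] = float(changes.sum()) / (length - 1)
    dist_groups = range(1, group_count + 1) if group_count == 3 else (1,)
    n_landmarks = 5 if group_count == 3 else 4
    for g in dist_groups:
        values = _distribution(group_seq, g)
        for name, value in zip(_LANDMARKS[:n_landmarks], values[:n_landmarks]):
            out[f"dist.g{g}.{name}"] = value
    return out


def protein_feature_vector(
    record: OrfRecord, fallback: bool = True
) -> dict[str, float]:
    """The full 132-value descriptor of one protein.

    20 amino-acid composition fractions, a 21-value CTD block each for
    secondary structure, hydrophobicity, polarizability, van der Waals
    volume and polarity, and the 7-value solvent-accessibility block.
    """
    if not record.protein:
        raise ValidationError(f"ORF {record.orf_id}: no protein sequence")
    out = aa_composition(record.protein)
    annotations = {
        "secondary_structure": record.ss_annotation,
        "solvent_accessibility": record.acc_annotation,
    }
    for name in (
        "secondary_structure",
        "solvent_accessibility",
        "hydrophobicity",
        "polarizability",
        "van_der_waals_volume",
        "polarity",
    ):
        scheme = SCHEMES[name]
        seq = to_group_sequence(
            record.protein, scheme, annotations.get(name), fallback=fallback
        )
        block = ctd_block(seq, scheme.group_count)
        prefix = _SHORT[name]
        for key, value in block.items():
            out[f"{prefix}.{key}"] = value
    assert len(out) == 132
    return out
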