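"""Deterministic ORF dataset generator with planted, tunable signal.

The generator emulates the statistical structure of a yeast translation-rate
study without any downloads: continuous translation rates are drawn first
and dichotomized at the median; coding sequences are then sampled
codon-by-codon from class-conditional codon distributions in which a set of
designated codons is up-weighted in the high class *within its synonymous
family* (so amino-acid composition carries no class signal - the planted
effect is pure codon bias); a gene module enriched for the high class sits
on a random interaction network and is preferentially annotated to
designated GO terms; auxiliary features are class mean shifts plus Gaussian
noise with missing cells masked at a configurable rate.

Everything is drawn from one :class:`numpy.random.Generator` seeded once, so
a fixed seed reproduces the dataset byte-for-byte.

Default condition: 300 ORFs; a within-family log-odds shift of 0.4 on eight
designated codons from eight distinct >= 4-fold synonymous families (sized
so the point-biserial correlation of each planted codon frequency with the
class is about 0.3 at typical CDS lengths); a 30-gene module with a 4:1
high:low membership odds ratio annotated to 3 designated terms; auxiliary
shifts of 0.7 within-class standard deviations on four of the nine table
features; 10% missing auxiliary cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
from Bio.Seq import Seq

from .datatypes import (
    FeatureMatrix,
    GoAnnotationSet,
    HIGH,
    LabelVector,
    Network,
    OrfRecord,
)
from .errors import ValidationError
from . import io as orfio
from .stats import median_split

STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(
    c
    for c in (a + b + d for a in "ACGT" for b in "ACGT" for d in "ACGT")
    if c not in STOP_CODONS
)

#: designated codons, one per synonymous family, from families with >= 2
#: synonyms (the first eight come from >= 4-fold families)
DESIGNATED_CODONS = (
    "TCT",  # Ser
    "ACC",  # Thr
    "GCT",  # Ala
    "CCA",  # Pro
    "GGT",  # Gly
    "CGT",  # Arg
    "GTC",  # Val
    "CTA",  # Leu
    "ATC",  # Ile
    "AAG",  # Lys
    "GAA",  # Glu
    "GAT",  # Asp
)

DESIGNATED_GO_TERMS = ("GO:SIM0001", "GO:SIM0002", "GO:SIM0003")

#: auxiliary table columns: (location, scale, carries class signal)
AUX_SPECS: dict[str, tuple[float, float, bool]] = {
    "mfe.42nt": (-8.0, 2.0, False),
    "utr5.length": (60.0, 25.0, False),
    "utr3.length": (100.0, 40.0, False),
    "tf.count": (3.0, 2.0, False),
    "rbp.count": (4.0, 2.0, True),
    "protein.abundance": (2000.0, 900.0, True),
    "mrna.halflife": (20.0, 8.0, True),
    "protein.halflife": (60.0, 25.0, False),
    "utr5.energy": (-25.0, 7.0, True),
}

#: standardized class mean shift of signal-carrying auxiliary features
AUX_EFFECT_D = 0.7


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated dataset."""

    n_orfs: int = 300
    seed: int = 0
    codon_effect: float = 0.4
    n_informative_codons: int = 8
    go_module_size: int = 30
    go_effect: float = 0.3
    n_go_terms: int = 40
    network_model: str = "planted_module"
    network_p: float = 0.02
    module_p: float = 0.35
    aux_noise_sd: float = 1.0
    aux_effect: float = AUX_EFFECT_D
    missing_rate: float = 0.1
    mean_cds_codons: float = 300.0
    sigma_log_cds: float = 0.35

    def __post_init__(self) -> None:
        if self.n_orfs < 4:
            raise ValidationError("n_orfs must be at least 4")
        if self.codon_effect < 0:
            raise ValidationError("codon_effect must be nonnegative")
        if not 0 <= self.n_informative_codons <= len(DESIGNATED_CODONS):
            raise ValidationError(
                f"n_informative_codons must be in 0..{len(DESIGNATED_CODONS)}"
            )
        if self.go_module_size > self.n_orfs:
            raise ValidationError("module larger than gene count")
        if not 0 <= self.go_effect < 0.5:
            raise ValidationError("go_effect must lie in [0, 0.5)")
        if self.n_go_terms < len(DESIGNATED_GO_TERMS):
            raise ValidationError(
                f"need at least {len(DESIGNATED_GO_TERMS)} GO terms"
            )
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing_rate must lie in [0, 1)")
        if self.network_model not in ("planted_module", "erdos_renyi"):
            raise ValidationError(f"unknown network model {self.network_model!r}")


@dataclass
class GroundTruth:
    """What was planted: labels, signal-carrying feature names, latent rates."""

    true_labels: LabelVector
    informative_features: list[str]
    latent_rates: np.ndarray


@dataclass
class SimulatedDataset:
    records: list[OrfRecord]
    network: Network
    annotations: GoAnnotationSet
    rates: dict[str, float]
    truth: GroundTruth
    config: SimulationConfig

    def write(self, outdir: str | Path) -> None:
        """Write the exact formats the io module reads."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        orfio.write_fasta(
            outdir / "cds.fasta", [(r.orf_id, r.cds) for r in self.records]
        )
        orfio.write_fasta(
            outdir / "protein.fasta", [(r.orf_id, r.protein) for r in self.records]
        )
        with open(outdir / "utr5.tsv", "w") as fh:
            fh.write("orf\tutr5\n")
            for r in self.records:
                fh.write(f"{r.orf_id}\t{r.upstream_utr}\n")
        aux_names = list(AUX_SPECS)
        with open(outdir / "aux.tsv", "w") as fh:
            fh.write("orf\t" + "\t".join(aux_names) + "\n")
            for r in self.records:
                cells = [
                    "" if name not in r.auxiliary else repr(r.auxiliary[name])
                    for name in aux_names
                ]
                fh.write(r.orf_id + "\t" + "\t".join(cells) + "\n")
        orfio.write_network(outdir / "network.tsv", self.network)
        orfio.write_go_annotations(outdir / "annotations.tsv", self.annotations)
        orfio.write_rates(outdir / "rates.tsv", self.rates)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(
                {
                    "true_labels": list(self.truth.true_labels.labels),
                    "informative_features": self.truth.informative_features,
                    "latent_rates": [float(x) for x in self.truth.latent_rates],
                },
                fh,
                indent=1,
            )


def _codon_family_map() -> dict[str, tuple[str, ...]]:
    """codon -> its synonymous family (standard genetic code, sense codons)."""
    by_aa: dict[str, list[str]] = {}
    for codon in SENSE_CODONS:
        aa = str(Seq(codon).translate())
        by_aa.setdefault(aa, []).append(codon)
    return {c: tuple(fam) for fam in by_aa.values() for c in fam}


_FAMILY = _codon_family_map()


def class_codon_distributions(
    codon_effect: float, n_informative: int
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """(low-class probs, high-class probs, informative codons) over SENSE_CODONS.

    The low class is uniform over the 61 sense codons.  In the high class
    each designated codon's within-family log-odds rise by ``codon_effect``,
    with the family's total probability held fixed - amino-acid usage is
    identical between classes by construction.
    """
    informative = DESIGNATED_CODONS[:n_informative]
    low = np.full(len(SENSE_CODONS), 1.0 / len(SENSE_CODONS))
    weights = {c: 1.0 for c in SENSE_CODONS}
    for codon in informative:
        weights[codon] = float(np.exp(codon_effect))
    high = np.empty_like(low)
    index = {c: i for i, c in enumerate(SENSE_CODONS)}
    for codon in SENSE_CODONS:
        family = _FAMILY[codon]
        fam_weight = sum(weights[c] for c in family)
        fam_mass = len(family) / len(SENSE_CODONS)
        high[index[codon]] = fam_mass * weights[codon] / fam_weight
    assert abs(high.sum() - 1.0) < 1e-12
    return low, high, informative


def generate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate one reproducible dataset with the configured planted signal."""
    rng = np.random.default_rng(config.seed)
    n = config.n_orfs
    orf_ids = [f"ORF{i:04d}" for i in range(n)]

    # latent rates first; labels follow from the median split by construction
    rates = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    labels = median_split(rates)
    is_high = labels.as_binary().astype(bool)

    low_p, high_p, informative_codons = class_codon_distributions(
        config.codon_effect, config.n_informative_codons
    )

    records: list[OrfRecord] = []
    aux_names = list(AUX_SPECS)
    for i, orf_id in enumerate(orf_ids):
        n_codons = max(
            45,
            int(
                round(
                    rng.lognormal(
                        mean=np.log(config.mean_cds_codons),
                        sigma=config.sigma_log_cds,
                    )
                )
            ),
        )
        probs = high_p if is_high[i] else low_p
        body = rng.choice(len(SENSE_CODONS), size=n_codons - 1, p=probs)
        cds = (
            "ATG"
            + "".join(SENSE_CODONS[j] for j in body)
            + STOP_CODONS[rng.integers(len(STOP_CODONS))]
        )
        protein = str(Seq(cds).translate()).rstrip("*")
        utr_len = int(rng.integers(20, 61))
        utr = "".join("ACGT"[b] for b in rng.integers(0, 4, size=utr_len))
        aux: dict[str, float] = {}
        for name in aux_names:
            loc, scale, informative = AUX_SPECS[name]
            shift = (
                config.aux_effect * scale * config.aux_noise_sd
                if informative and is_high[i]
                else 0.0
            )
            value = loc + shift + scale * config.aux_noise_sd * rng.standard_normal()
            if rng.random() >= config.missing_rate:
                aux[name] = float(value)
        records.append(
            OrfRecord(
                orf_id=orf_id,
                cds=cds,
                upstream_utr=utr,
                protein=protein,
                auxiliary=aux,
            )
        )

    network, module = _generate_network(config, orf_ids, is_high, rng)
    annotations = _generate_annotations(config, orf_ids, module, rng)

    informative_features = (
        list(informative_codons)
        + list(DESIGNATED_GO_TERMS)
        + (
            [name for name, (_, _, inf) in AUX_SPECS.items() if inf]
            if config.aux_effect > 0
            else []
        )
    )
    if config.codon_effect == 0:
        informative_features = [
            f for f in informative_features if f not in informative_codons
        ]
    if config.go_effect == 0:
        informative_features = [
            f for f in informative_features if f not in DESIGNATED_GO_TERMS
        ]
    truth = GroundTruth(
        true_labels=labels,
        informative_features=informative_features,
        latent_rates=rates,
    )
    return SimulatedDataset(
        records=records,
        network=network,
        annotations=annotations,
        rates=dict(zip(orf_ids, (float(r) for r in rates))),
        truth=truth,
        config=config,
    )


def _generate_network(
    config: SimulationConfig,
    orf_ids: list[str],
    is_high: np.ndarray,
    rng: np.random.Generator,
) -> tuple[Network, frozenset]:
    n = len(orf_ids)
    g = nx.Graph()
    g.add_nodes_from(orf_ids)
    # background Erdos-Renyi edges
    upper = np.triu_indices(n, k=1)
    keep = rng.random(len(upper[0])) < config.network_p
    for a, b in zip(upper[0][keep], upper[1][keep]):
        g.add_edge(orf_ids[a], orf_ids[b])
    module: np.ndarray = np.array([], dtype=int)
    if config.network_model == "planted_module" and config.go_module_size > 0:
        # module members drawn with class-dependent odds (0.5 +/- go_effect)
        weights = np.where(is_high, 0.5 + config.go_effect, 0.5 - config.go_effect)
        weights = weights / weights.sum()
        module = rng.choice(n, size=config.go_module_size, replace=False, p=weights)
        for ii, a in enumerate(module):
            for b in module[ii + 1 :]:
                if rng.random() < config.module_p:
                    g.add_edge(orf_ids[a], orf_ids[b])
    return Network(g), frozenset(orf_ids[i] for i in module)


def _generate_annotations(
    config: SimulationConfig,
    orf_ids: list[str],
    module: frozenset,
    rng: np.random.Generator,
) -> GoAnnotationSet:
    term_to_genes: dict[str, frozenset] = {}
    for term in DESIGNATED_GO_TERMS:
        genes = {
            orf
            for orf in orf_ids
            if rng.random() < (0.9 if orf in module else 0.02)
        }
        if not genes:
            genes = {orf_ids[int(rng.integers(len(orf_ids)))]}
        term_to_genes[term] = frozenset(genes)
    for t in range(len(DESIGNATED_GO_TERMS), config.n_go_terms):
        genes = {orf for orf in orf_ids if rng.random() < 0.08}
        if not genes:
            genes = {orf_ids[int(rng.integers(len(orf_ids)))]}
        term_to_genes[f"GO:SIM{t + 1:04d}"] = frozenset(genes)
    return GoAnnotationSet(term_to_genes, frozenset(orf_ids))


def null_config(n_orfs: int = 300, seed: int = 0, **overrides) -> SimulationConfig:
    """A no-signal configuration: every planted effect switched off."""
    return SimulationConfig(
        n_orfs=n_orfs,
        seed=seed,
        codon_effect=0.0,
        go_effect=0.0,
        aux_effect=0.0,
        **overrides,
    )


def worked_example_tables() -> dict:
    """The small fixed fixtures used throughout the documentation and tests.

    * ``mrmr_matrix``/``mrmr_labels``: a 6-sample, 4-binary-feature table.
    * ``nna_matrix``/``nna_labels``: four 2-D points, two per class.
    * ``enrichment_query``: universe 10, term size 5, neighborhood 4,
      overlap 4 (upper-tail p = 5/210).
    """
    from .datatypes import EnrichmentQuery

    mrmr_matrix = FeatureMatrix(
        [f"s{i}" for i in range(1, 7)],
        ["f1", "f2", "f3", "f4"],
        np.array(
            [
                [0, 0, 0, 0],
                [0, 0, 0, 1],
                [0, 0, 1, 0],
                [1, 1, 1, 1],
                [1, 1, 1, 0],
                [1, 1, 0, 1],
            ],
            dtype=float,
        ),
    )
    mrmr_labels = LabelVector(
        np.array(["low", "low", "low", "high", "high", "high"], dtype=object)
    )
    nna_matrix = FeatureMatrix(
        ["a", "b", "c", "d"],
        ["x", "y"],
        np.array([[1.0, 0.0], [0.9, 0.1], [0.0, 1.0], [0.1, 0.9]]),
    )
    nna_labels = LabelVector(np.array(["low", "low", "high", "high"], dtype=object))
    return {
        "mrmr_matrix": mrmr_matrix,
        "mrmr_labels": mrmr_labels,
        "nna_matrix": nna_matrix,
        "nna_labels": nna_labels,
        "enrichment_query": EnrichmentQuery(
            universe_size=10, term_size=5, neighborhood_size=4, overlap=4
        ),
    }
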