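"""Stage orchestration: feature assembly and the end-to-end workflow.

``featurize`` concatenates the feature families in a fixed, documented
column order - codon usage (64), GO enrichment (one per term), protein
(132), start-codon context (24), auxiliary (10) - so feature indices are
stable across runs.  ``run_all`` reproduces the full workflow: median-split
labeling, mRMR ranking, incremental feature selection under jackknife
cross-validation, optimal-set extraction and the point-biserial report,
writing every artifact plus a run manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import ifs, optimal_feature_set
from .datatypes import (
    FeatureMatrix,
    GoAnnotationSet,
    IfsCurve,
    LabelVector,
    Network,
    OrfRecord,
    RankedFeatures,
)
from .errors import ConfigurationError, ValidationError
from .go_enrichment import enrichment_matrix
from .mrmr import DiscretizationRule, mrmr_rank
from .protein_features import protein_feature_vector
from .sequence_features import CODONS, cds_length, codon_usage, start_codon_context
from .stats import correlation_report, median_split

logger = logging.getLogger(__name__)

#: fixed family order of the assembled feature matrix
FAMILIES = ("codon", "go", "protein", "start", "aux")

#: auxiliary block columns; cds.length is computed from the sequence, the
#: rest are ingested from the auxiliary table
AUX_COLUMNS = (
    "cds.length",
    "mfe.42nt",
    "utr5.length",
    "utr3.length",
    "tf.count",
    "rbp.count",
    "protein.abundance",
    "mrna.halflife",
    "protein.halflife",
    "utr5.energy",
)


def featurize(
    records: list[OrfRecord],
    network: Network | None = None,
    annotations: GoAnnotationSet | None = None,
    families: tuple[str, ...] = FAMILIES,
    go_terms: list[str] | None = None,
    ss_fallback: bool = True,
) -> FeatureMatrix:
    """Assemble the named feature matrix for a list of ORF records."""
    unknown = [f for f in families if f not in FAMILIES]
    if unknown:
        raise ConfigurationError(f"unknown feature families: {unknown}")
    if not records:
        raise ValidationError("no ORF records")
    ids = [r.orf_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate ORF ids")
    blocks: list[FeatureMatrix] = []
    for family in FAMILIES:
        if family not in families:
            continue
        if family == "codon":
            rows = [codon_usage(r.cds) for r in records]
            blocks.append(
                FeatureMatrix(
                    ids,
                    list(CODONS),
                    np.array([[row[c] for c in CODONS] for row in rows]),
                )
            )
        elif family == "go":
            if network is None or annotations is None:
                raise ConfigurationError(
                    "GO family enabled but network/annotations missing"
                )
            blocks.append(enrichment_matrix(ids, network, annotations, go_terms))
        elif family == "protein":
            rows = [protein_feature_vector(r, fallback=ss_fallback) for r in records]
            names = list(rows[0])
            blocks.append(
                FeatureMatrix(
                    ids, names, np.array([[row[n] for n in names] for row in rows])
                )
            )
        elif family == "start":
            rows = []
            for r in records:
                if len(r.upstream_utr) < 3 or len(r.cds) < 6:
                    raise ValidationError(
                        f"ORF {r.orf_id}: needs >=3 nt upstream UTR and >=6 nt "
                        "CDS for start-codon context"
                    )
                rows.append(start_codon_context(r.upstream_utr[-3:], r.cds[3:6]))
            names = list(rows[0])
            blocks.append(
                FeatureMatrix(
                    ids, names, np.array([[row[n] for n in names] for row in rows], dtype=float)
                )
            )
        elif family == "aux":
            values = np.full((len(records), len(AUX_COLUMNS)), np.nan)
            for i, r in enumerate(records):
                values[i, 0] = cds_length(r.cds)
                for j, name in enumerate(AUX_COLUMNS[1:], start=1):
                    if name in r.auxiliary:
                        values[i, j] = r.auxiliary[name]
            blocks.append(FeatureMatrix(ids, list(AUX_COLUMNS), values))
    matrix = FeatureMatrix.hstack(blocks)
    logger.info(
        "featurized %d ORFs into %d features (%s)",
        matrix.n_samples,
        matrix.n_features,
        ", ".join(f"{f}" for f in families),
    )
    return matrix


@dataclass
class RunReport:
    """Everything ``run_all`` computes, plus where it was written."""

    matrix: FeatureMatrix
    labels: LabelVector
    ranking: RankedFeatures
    curve: IfsCurve
    optimal_k: int
    optimal_accuracy: float
    optimal_features: list[str]
    correlations: pd.DataFrame
    outdir: Path | None = None
    timings: dict[str, float] = field(default_factory=dict)


def attach_rates(
    records: list[OrfRecord], rates: dict[str, float]
) -> tuple[list[OrfRecord], np.ndarray]:
    """Align records with the rate table; ORFs without a rate are dropped."""
    kept = [r for r in records if r.orf_id in rates]
    dropped = len(records) - len(kept)
    if dropped:
        logger.warning("dropped %d ORF(s) without a translation rate", dropped)
    if len(kept) < 2:
        raise ValidationError("fewer than 2 ORFs have translation rates")
    return kept, np.array([rates[r.orf_id] for r in kept])


def run_all(
    records: list[OrfRecord],
    rates: dict[str, float],
    network: Network | None = None,
    annotations: GoAnnotationSet | None = None,
    families: tuple[str, ...] = FAMILIES,
    top_k: int = 500,
    k_max: int | None = None,
    scale: str = "minmax",
    rule: DiscretizationRule = DiscretizationRule(),
    outdir: str | Path | None = None,
    make_plot: bool = True,
) -> RunReport:
    """The full workflow on in-memory inputs; optionally writes artifacts."""
    timings: dict[str, float] = {}

    def stage(name):
        timings[name] = time.perf_counter()
        logger.info("stage %s", name)

    def done(name):
        timings[name] = time.perf_counter() - timings[name]

    stage("featurize")
    records, rate_values = attach_rates(records, rates)
    matrix = featurize(records, network, annotations, families)
    done("featurize")

    stage("label")
    labels = median_split(rate_values)
    done("label")

    top_k = min(top_k, matrix.n_features)
    if k_max is None:
        k_max = top_k
    if top_k < k_max:
        raise ConfigurationError(f"top_k ({top_k}) must be >= k_max ({k_max})")

    stage("rank")
    ranking = mrmr_rank(matrix, labels, top_k=top_k, rule=rule)
    done("rank")

    stage("ifs")
    curve = ifs(matrix, labels, ranking, k_max=k_max, scale=scale)
    done("ifs")

    k_star, accuracy, features = optimal_feature_set(curve)
    correlations = correlation_report(matrix, labels, features)

    report = RunReport(
        matrix=matrix,
        labels=labels,
        ranking=ranking,
        curve=curve,
        optimal_k=k_star,
        optimal_accuracy=accuracy,
        optimal_features=features,
        correlations=correlations,
        timings=timings,
    )
    if outdir is not None:
        report.outdir = write_report(
            report,
            outdir,
            manifest={
                "families": list(families),
                "top_k": top_k,
                "k_max": k_max,
                "scale": scale,
                "discretization": {"scheme": rule.scheme, "alpha": rule.alpha},
            },
            make_plot=make_plot,
        )
    return report


def write_report(
    report: RunReport,
    outdir: str | Path,
    manifest: dict | None = None,
    make_plot: bool = True,
) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.ranking.to_dataframe().to_csv(
        outdir / "ranking.tsv", sep="\t", index=False
    )
    report.curve.to_dataframe().to_csv(
        outdir / "ifs_curve.tsv", sep="\t", index=False
    )
    with open(outdir / "optimal_features.txt", "w") as fh:
        fh.write("\n".join(report.optimal_features) + "\n")
    report.correlations.to_csv(
        outdir / "point_biserial.tsv", sep="\t", index=False
    )
    full = dict(manifest or {})
    full.update(
        {
            "package_version": __version__,
            "numpy_version": np.__version__,
            "n_samples": report.matrix.n_samples,
            "n_features": report.matrix.n_features,
            "optimal_k": report.optimal_k,
            "optimal_accuracy": report.optimal_accuracy,
            "stage_seconds": {k: round(v, 3) for k, v in report.timings.items()},
        }
    )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(full, fh, indent=1, sort_keys=True)
    if make_plot:
        plot_ifs_curve(report.curve, outdir / "ifs_curve.png")
    return outdir


def plot_ifs_curve(curve: IfsCurve, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.sizes, curve.accuracies, lw=1.2)
    k_star, acc, _ = optimal_feature_set(curve)
    ax.axvline(k_star, color="crimson", ls="--", lw=0.8)
    ax.annotate(
        f"peak {acc:.1%} @ k={k_star}",
        xy=(k_star, acc),
        xytext=(5, -12),
        textcoords="offset points",
        fontsize=8,
    )
    ax.set_xlabel("number of top-ranked features")
    ax.set_ylabel("jackknife accuracy")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
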