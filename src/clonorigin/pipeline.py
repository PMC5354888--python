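"""End-to-end orchestration: clonality reports and tissue-of-origin runs.

Two entry points compose the library modules over files on disk:

* :func:`run_clonality` reads a patient's mutation, interval-CNV and
  gene-CNV tables, applies the inclusion filters, computes the shared-
  event Venn decomposition and infers the relatedness ordering.
* :func:`run_origin` builds the aligned region matrix from a labelled
  cohort, selects signature regions, trains the discriminant, reports
  cross-validated and resubstitution accuracy, and classifies the
  patient's lesions projected onto the cohort's region set.

Patient samples never participate in cohort region construction or
signature selection; they are projected post hoc onto the trained model
(the classic add-new-samples-to-a-fitted-model protocol). Every output
embeds the seed and a hash of the configuration, and reruns with the
same configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io
from .concordance import infer_route, venn_counts
from .core import LesionProfile, ValidationError
from .discriminant import (
    DiagonalDiscriminant,
    cross_validate_origin,
    resubstitution_report,
)
from .filters import FilterPolicy, filter_mutations
from .regions import build_regions, fill_matrix, project_segments
from .signatures import CnvSignatureSelector

logger = logging.getLogger("clonorigin")

__all__ = ["PipelineConfig", "run_clonality", "run_origin", "load_config"]


@dataclass
class PipelineConfig:
    """Flat configuration shared by the pipeline entry points."""

    # clonality inputs
    mutations: str | None = None
    cnv_intervals: str | None = None
    gene_cnvs: str | None = None
    # origin inputs
    cohort_seg: str | None = None
    cohort_labels: str | None = None
    patient_seg: str | None = None
    # knobs
    alpha: float = 1e-12
    cv_folds: int = 5
    seed: int = 0
    strict_mutation_match: bool = True
    scoring_method: str = "logistic"
    priors: str = "empirical"
    filter_policy: FilterPolicy = field(default_factory=FilterPolicy)
    out_dir: str = "."

    def digest(self) -> str:
        payload = {k: (asdict(v) if isinstance(v, FilterPolicy) else v)
                   for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """Load a flat YAML key-value config; filter fields live under ``filter:``."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    policy = FilterPolicy(**data.pop("filter", {}))
    return PipelineConfig(filter_policy=policy, **data)


def _write_json(payload: dict, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def assemble_lesions(
    mutations, cnv_intervals, gene_cnvs, policy: FilterPolicy
) -> list[LesionProfile]:
    """Group per-sample records into filtered :class:`LesionProfile` objects."""
    samples = sorted(
        {m.sample for m in mutations}
        | {s for s, _, _ in cnv_intervals}
        | {g.sample for g in gene_cnvs}
    )
    lesions = []
    for sample in samples:
        kept = filter_mutations([m for m in mutations if m.sample == sample], policy)
        lesions.append(
            LesionProfile(
                lesion_id=sample,
                tissue_label=sample,
                mutations=kept,
                cnv_intervals=[
                    (iv, d) for s, iv, d in cnv_intervals if s == sample
                ],
                gene_cnvs=[g for g in gene_cnvs if g.sample == sample],
            )
        )
    return lesions


def run_clonality(config: PipelineConfig) -> dict:
    """Filter events, compute the Venn decomposition, infer the route."""
    mutations = io.read_mutation_table(config.mutations) if config.mutations else []
    cnvs = (
        io.read_cnv_interval_table(config.cnv_intervals)
        if config.cnv_intervals
        else []
    )
    genes = io.read_gene_cnv_table(config.gene_cnvs) if config.gene_cnvs else []
    logger.info(
        "clonality: read %d mutations, %d interval CNVs, %d gene CNVs",
        len(mutations), len(cnvs), len(genes),
    )
    lesions = assemble_lesions(mutations, cnvs, genes, config.filter_policy)
    if len(lesions) < 2:
        raise ValidationError("clonality analysis needs at least two lesions")
    logger.info(
        "clonality: %d lesions after filtering (%s)",
        len(lesions), ", ".join(l.lesion_id for l in lesions),
    )
    report = venn_counts(lesions, strict=config.strict_mutation_match)
    ordering = infer_route(lesions, strict=config.strict_mutation_match)
    payload = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "shared_events": report.to_dict(),
        "relatedness": ordering.to_dict(),
    }
    out = Path(config.out_dir) / "clonality_report.json"
    _write_json(payload, out)
    summary = Path(config.out_dir) / "clonality_summary.txt"
    with open(summary, "w") as fh:
        fh.write(f"# config {config.digest()} seed {config.seed}\n")
        fh.write(f"lesions: {', '.join(report.lesion_ids)}\n")
        fh.write(f"mutation union: {report.union_size}\n")
        fh.write(
            f"inferred route: {' -> '.join(ordering.inferred_route)}"
            f"{' (ties broken lexicographically)' if ordering.tie_flag else ''}\n"
        )
    return payload


def run_origin(config: PipelineConfig) -> dict:
    """Train on the cohort, report accuracy, classify the patient's lesions."""
    if not (config.cohort_seg and config.cohort_labels):
        raise ValidationError("origin analysis needs cohort segments and labels")
    from .core import CohortSample

    segments = io.read_seg(config.cohort_seg)
    labels = io.read_cohort_labels(config.cohort_labels)
    by_sample: dict[str, list] = {}
    for seg in segments:
        by_sample.setdefault(seg.sample, []).append(seg)
    missing = sorted(set(by_sample) - set(labels))
    if missing:
        raise ValidationError(f"cohort samples without labels: {missing[:5]}")
    if len(set(labels.values())) < 2:
        raise ValidationError("label file must cover at least two classes")
    cohort = [
        CohortSample(s, labels[s], segs) for s, segs in sorted(by_sample.items())
    ]
    logger.info("origin: %d cohort samples, %d classes",
                len(cohort), len(set(labels.values())))

    region_set = build_regions(cohort)
    matrix = fill_matrix(cohort, region_set)
    matrix.labels = {s: labels[s] for s in matrix.samples}
    X = matrix.feature_matrix()
    y = matrix.label_array()
    logger.info("origin: %d aligned regions", matrix.n_regions)

    if config.alpha <= 0:
        raise ValidationError("alpha must be positive; no region can be selected")
    cv = cross_validate_origin(
        X, y, alpha=config.alpha, n_splits=config.cv_folds,
        seed=config.seed, method=config.scoring_method, priors=config.priors,
    )
    resub = resubstitution_report(
        X, y, alpha=config.alpha, method=config.scoring_method,
        priors=config.priors,
    )

    selector = CnvSignatureSelector(
        alpha=config.alpha, method=config.scoring_method
    ).fit(X, y)
    mask = selector._get_support_mask()
    if not mask.any():
        raise ValidationError("no signature region passed the cutoff")
    model = DiagonalDiscriminant(priors=config.priors).fit(X[:, mask], y)
    logger.info("origin: %d signature regions selected", int(mask.sum()))

    origin_calls = {}
    if config.patient_seg:
        patient_segments = io.read_seg(config.patient_seg)
        by_lesion: dict[str, list] = {}
        for seg in patient_segments:
            by_lesion.setdefault(seg.sample, []).append(seg)
        for lesion_id, segs in sorted(by_lesion.items()):
            values = project_segments(segs, region_set)[mask]
            label, scores, ties = model.predict_verbose(values[None, :])
            origin_calls[lesion_id] = {
                "predicted_class": str(label[0]),
                "tie": bool(ties[0]),
                "scores": {
                    str(c): float(s) for c, s in zip(model.classes_, scores[0])
                },
            }
        logger.info("origin: classified %d patient lesions", len(origin_calls))

    payload = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "n_regions": matrix.n_regions,
        "n_signatures": int(mask.sum()),
        "cross_validation": cv.to_dict(),
        "resubstitution": resub.to_dict(),
        "patient_origin_calls": origin_calls,
    }
    _write_json(payload, Path(config.out_dir) / "origin_report.json")
    return payload
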