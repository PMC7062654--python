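"""End-to-end orchestration: cohort -> features -> selection -> classification.

The pipeline always computes features on the ADC map; the configured mask
variant only changes which ROI delineation is used, mirroring the two
historical segmentation approaches (directly on the ADC map vs. propagated
from high-b DWI).  Every report embeds the full configuration, the package
version and per-lesion exclusions, so no result travels without provenance.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classification import (
    CLINICAL_THRESHOLD,
    FULL,
    ClassifierConfig,
    run_all_tasks,
)
from .errors import ConfigError, DwiRadiomicsError
from .io_formats import (
    MASK_ADC,
    MASK_VARIANTS,
    CohortManifest,
    FeatureTable,
    LesionRecord,
    load_cohort,
    write_feature_table,
)
from .texture_features import TextureConfig, extract_all, feature_catalogue

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All module configurations in one serializable object."""

    texture: TextureConfig = field(default_factory=TextureConfig)
    selection_k: int = 10
    mi_bins: int = 8
    knn_k: int = 1
    mode: str = FULL
    mask_variant: str = MASK_ADC
    clinical_threshold: float = CLINICAL_THRESHOLD
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mask_variant not in MASK_VARIANTS:
            raise ConfigError(
                f"mask_variant must be one of {MASK_VARIANTS}, got {self.mask_variant!r}"
            )
        # delegate k/mode validation
        self.classifier_config()

    def classifier_config(self) -> ClassifierConfig:
        return ClassifierConfig(
            k=self.knn_k, mode=self.mode, selection_k=self.selection_k, mi_bins=self.mi_bins
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["version"] = __version__
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d.pop("version", None)
        tex = d.pop("texture", {})
        if isinstance(tex, dict):
            tex = {
                k: tuple(v) if isinstance(v, list) else v for k, v in tex.items()
            }
            tex = TextureConfig(**tex)
        return cls(texture=tex, **d)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class PipelineResult:
    """Artifacts of one pipeline run."""

    feature_table: FeatureTable
    report: dict
    exclusions: dict[str, str]
    config: PipelineConfig

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_feature_table(self.feature_table, outdir / "features.csv")
        (outdir / "report.json").write_text(json.dumps(self.report, indent=2) + "\n")
        grid_to_csv(self.report, outdir / "grid.csv")


def extract_features(
    records: list[LesionRecord],
    config: PipelineConfig = PipelineConfig(),
) -> tuple[FeatureTable, dict[str, str]]:
    """Run the extractor on every lesion's ADC map with the configured mask.

    Per-lesion failures are logged and excluded with their reason rather than
    aborting the cohort.
    """
    catalogue = feature_catalogue(config.texture)
    rows, ids, labels = [], [], []
    exclusions: dict[str, str] = {}
    for rec in records:
        if config.mask_variant not in rec.masks:
            exclusions[rec.lesion_id] = f"no {config.mask_variant} mask"
            continue
        t0 = time.perf_counter()
        try:
            fv = extract_all(
                rec.image, rec.masks[config.mask_variant], config.texture, rec.lesion_id
            )
        except DwiRadiomicsError as exc:
            logger.warning("lesion %s excluded: %s", rec.lesion_id, exc)
            exclusions[rec.lesion_id] = str(exc)
            continue
        logger.debug(
            "lesion %s: %d features in %.1f ms",
            rec.lesion_id, len(fv.values), 1e3 * (time.perf_counter() - t0),
        )
        rows.append([fv.values[n] for n in catalogue])
        ids.append(rec.lesion_id)
        labels.append(rec.label)
    if not rows:
        raise DwiRadiomicsError("no lesion could be processed")
    X = np.asarray(rows, dtype=float)
    table = FeatureTable.from_records(
        ids, labels, {n: X[:, j] for j, n in enumerate(catalogue)}
    )
    return table, exclusions


def run_pipeline(
    cohort,
    config: PipelineConfig = PipelineConfig(),
    outdir=None,
    contrasts: dict[str, tuple[str, ...]] | None = None,
    classes: tuple[str, ...] | None = None,
) -> PipelineResult:
    """Manifest/cohort -> feature table -> full classification report.

    ``cohort`` may be a :class:`CohortManifest`, a list of
    :class:`LesionRecord`, or a :class:`~dwiradiomics.synthetic_data.SyntheticCohort`.
    """
    records, classes, contrasts = _coerce_cohort(cohort, classes, contrasts)
    table, exclusions = extract_features(records, config)
    report = run_all_tasks(
        table,
        classes=classes,
        config=config.classifier_config(),
        contrasts=contrasts,
        clinical_threshold=config.clinical_threshold,
    )
    report["config"] = config.to_dict()
    report["mask_variant"] = config.mask_variant
    report["n_lesions"] = len(table)
    report["excluded_lesions"] = exclusions
    result = PipelineResult(table, report, exclusions, config)
    if outdir is not None:
        result.write(outdir)
    return result


def compare_mask_variants(
    cohort,
    config: PipelineConfig = PipelineConfig(),
    outdir=None,
    contrasts: dict[str, tuple[str, ...]] | None = None,
) -> dict[str, PipelineResult]:
    """Run both segmentation variants on the same lesion subset (paired).

    Lesions missing either variant are excluded from both runs so the two
    grids are directly comparable.
    """
    from dataclasses import replace

    records, classes, contrasts = _coerce_cohort(cohort, None, contrasts)
    paired = [r for r in records if all(v in r.masks for v in MASK_VARIANTS)]
    results = {}
    for variant in MASK_VARIANTS:
        cfg = replace(config, mask_variant=variant)
        results[variant] = run_pipeline(paired, cfg, contrasts=contrasts, classes=classes)
    if outdir is not None:
        outdir = Path(outdir)
        for variant, res in results.items():
            res.write(outdir / variant.lower())
        _write_side_by_side(results, outdir / "comparison.csv")
    return results


def _coerce_cohort(cohort, classes, contrasts):
    from .synthetic_data import SyntheticCohort

    if isinstance(cohort, SyntheticCohort):
        records = cohort.records()
        classes = classes or cohort.classes
        contrasts = contrasts or cohort.contrasts or None
    elif isinstance(cohort, CohortManifest):
        records = load_cohort(cohort)
        classes = classes or cohort.classes
        contrasts = contrasts or cohort.contrasts or None
    else:
        records = list(cohort)
        if classes is None:
            classes = tuple(dict.fromkeys(r.label for r in records))
    return records, classes, contrasts


def grid_to_frame(report: dict) -> pd.DataFrame:
    """The symmetric accuracy grid as 'accuracy % (criterion)' cells."""
    groups: list[str] = []
    for cell in report["cells"]:
        for g in cell["task"]:
            if g not in groups:
                groups.append(g)
    frame = pd.DataFrame("-", index=groups, columns=groups)
    for cell in report["cells"]:
        a, b = cell["task"]
        if not cell.get("computable", False):
            text = "n/a"
        else:
            text = f"{cell['best_accuracy_pct']:.1f} % ({cell['best_criterion']})"
        frame.loc[a, b] = text
        frame.loc[b, a] = text
    return frame


def grid_to_csv(report: dict, path) -> None:
    grid_to_frame(report).to_csv(path, index_label="group")


def _write_side_by_side(results: dict[str, PipelineResult], path) -> None:
    rows = []
    variants = list(results)
    by_task = {}
    for variant in variants:
        for cell in results[variant].report["cells"]:
            key = tuple(cell["task"])
            by_task.setdefault(key, {})[variant] = cell
    for key, cells in by_task.items():
        row = {"task": " vs ".join(key)}
        for variant in variants:
            cell = cells.get(variant)
            if cell and cell.get("computable"):
                row[f"{variant}_accuracy_pct"] = cell["best_accuracy_pct"]
                row[f"{variant}_criterion"] = cell["best_criterion"]
            else:
                row[f"{variant}_accuracy_pct"] = float("nan")
                row[f"{variant}_criterion"] = "n/a"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
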