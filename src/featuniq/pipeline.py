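"""End-to-end orchestration: phantoms (or images) -> translocation ->
feature extraction -> CV/CCC statistics -> uniqueness decision.

Every random draw derives from the master seed through a stable
per-(cohort, patient) seed sequence, so a rerun with the same config and
seed is bit-identical on all CSV outputs.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FeatuniqError, ImageVolume, RoiMask
from .decision import DecisionConfig, UniquenessReport, ccc_verdicts, combine, cv_verdicts
from .features.extract import ExtractionParams, extract_all
from .features.registry import default_registry
from .io import write_feature_table, write_mask
from .phantom import NON_TUMOR_TISSUES, PhantomSpec, generate_phantom
from .stats import PatientFeatureTable, cohort_ccc_panel, cohort_cv_matrix
from .translocate import find_placements

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    cohorts: dict[str, int] = field(default_factory=lambda: {"A": 5, "B": 5})
    phantom_spec: PhantomSpec = field(default_factory=PhantomSpec)
    extraction: ExtractionParams = field(default_factory=ExtractionParams)
    decision: DecisionConfig = field(default_factory=DecisionConfig)
    ccc_mode: str = "grouped"
    master_seed: int = 0
    render_heatmaps: bool = False  # PNG renderings of the CV/CCC matrices

    def __post_init__(self) -> None:
        if not self.cohorts or any(n < 1 for n in self.cohorts.values()):
            raise FeatuniqError("every cohort needs at least one patient")


def patient_seed(master_seed: int, cohort: str, index: int) -> int:
    """Stable sub-seed for one patient, independent of enumeration order."""
    ss = np.random.SeedSequence(
        [int(master_seed), *(ord(c) for c in cohort), int(index)]
    )
    return int(ss.generate_state(1)[0] % (2**31))


def analyze_patient(
    volume: ImageVolume,
    tumor: RoiMask,
    labels: np.ndarray,
    patient_id: str,
    cohort: str,
    seed: int,
    extraction: ExtractionParams | None = None,
) -> tuple[PatientFeatureTable, list]:
    """Translocate the tumor ROI into the four tissues and extract features."""
    placements = find_placements(tumor, labels, list(NON_TUMOR_TISSUES), seed)
    placed = {p.tissue for p in placements}
    missing = set(NON_TUMOR_TISSUES) - placed
    if missing:
        raise FeatuniqError(
            f"patient {patient_id}: unplaceable tissue regions {sorted(missing)}"
        )
    vectors = {"tumor": extract_all(volume, tumor, params=extraction, roi_id=f"{patient_id}:tumor")}
    for p in placements:
        vectors[p.tissue] = extract_all(
            volume, p.mask, params=extraction, roi_id=f"{patient_id}:{p.tissue}"
        )
    table = PatientFeatureTable(patient_id=patient_id, cohort=cohort, vectors=vectors)
    return table, placements


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> UniquenessReport:
    """Phantom-mode pipeline over the configured cohorts; optionally writes artifacts."""
    registry = default_registry()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    cv_by, ccc_by = {}, {}
    placement_rows = []
    for cohort, n_patients in config.cohorts.items():
        tables = []
        for i in range(n_patients):
            pid = f"{cohort}{i:02d}"
            seed = patient_seed(config.master_seed, cohort, i)
            spec = replace(config.phantom_spec, seed=seed)
            phantom = generate_phantom(spec)
            table, placements = analyze_patient(
                phantom.volume, phantom.nodule_mask, phantom.labels,
                pid, cohort, seed, config.extraction,
            )
            tables.append(table)
            for p in placements:
                placement_rows.append(
                    {
                        "patient": pid,
                        "tissue": p.tissue,
                        "offset_z": p.offset[0],
                        "offset_y": p.offset[1],
                        "offset_x": p.offset[2],
                        "voxel_count": p.mask.voxel_count,
                        "used_z_fallback": p.used_z_fallback,
                        "seed": seed,
                    }
                )
            if out is not None:
                write_feature_table(
                    pd.concat([table.to_frame()], ignore_index=True),
                    out / f"features_{pid}.csv",
                    overwrite=True,
                )
                for p in placements:
                    write_mask(p.mask, phantom.volume.spacing, out / f"roi_{pid}_{p.tissue}.nii.gz")
        cv_matrix = cohort_cv_matrix(tables)
        ccc_panel = cohort_ccc_panel(tables, mode=config.ccc_mode)
        cv_by[cohort] = cv_verdicts(cv_matrix, config.decision, cohort)
        ccc_by[cohort] = ccc_verdicts(ccc_panel, config.decision, cohort)
        if out is not None:
            cv_matrix.to_csv(out / f"cv_matrix_{cohort}.csv", float_format="%.17g")
            ccc_panel.to_csv(out / f"ccc_matrix_{cohort}.csv", float_format="%.17g")
            if config.render_heatmaps:
                from .viz import render_ccc_heatmap, render_cv_heatmap

                render_cv_heatmap(cv_matrix, out / f"cv_heatmap_{cohort}.png",
                                  config.decision.cv_threshold)
                render_ccc_heatmap(ccc_panel, out / f"ccc_heatmap_{cohort}.png",
                                   config.decision.ccc_threshold)

    report = combine(cv_by, ccc_by, registry.keys(), config.decision)
    if out is not None:
        pd.DataFrame(placement_rows).to_csv(out / "placements.csv", index=False)
        report.to_frame().to_csv(out / "uniqueness_report.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(report.summary() | {"master_seed": config.master_seed}, fh, indent=2)
    return report
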