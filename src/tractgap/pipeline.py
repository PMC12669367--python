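"""End-to-end phantom pipeline: simulate -> threshold -> measure -> normalization -> report.

Each stage is also reachable individually through the CLI; this module wires
them together deterministically (a fixed config + seed reproduces every
artifact byte for byte) and writes provenance sidecars next to the main
outputs.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .distance_measurement import (
    MeasurementRecord,
    TractMasks,
    measure_contact,
    records_to_frame,
    write_measurements_csv,
)
from .error_analysis import (
    SENSITIVITY_CSV_COLUMNS,
    build_report,
    manual_vs_auto,
    normalization_summary,
    render_text,
    threshold_sensitivity,
    write_report,
)
from .normalization_error import (
    LandmarkMeasurement,
    exclude_outliers,
    landmark_error,
    write_landmark_csv,
)
from .synthetic_data import TRACT_LABELS, PhantomCohort, PhantomPatient, generate_cohort, write_cohort
from .thresholding import ThresholdSelection, select_discrimination_threshold

logger = logging.getLogger("tractgap")

__all__ = [
    "select_patient_threshold",
    "measure_cohort",
    "normalization_measurements",
    "run_pipeline",
]


def write_provenance(path: Union[str, Path], config: RunConfig, seed: int) -> None:
    """Sidecar recording what produced an artifact (config hash, seed, version)."""
    p = Path(path)
    sidecar = {
        "artifact": p.name,
        "config_sha256": config.sha256(),
        "seed": int(seed),
        "package_version": __version__,
    }
    p.with_name(p.name + ".prov.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")


def select_patient_threshold(
    patient: PhantomPatient, candidates, nonzero_only: bool = False
) -> ThresholdSelection:
    """Whole-brain discrimination threshold for one patient (both hemispheres)."""
    return select_discrimination_threshold(
        c_left=patient.volumes[("left", "c-DRTT")],
        c_right=patient.volumes[("right", "c-DRTT")],
        nd_left=patient.volumes[("left", "nd-DRTT")],
        nd_right=patient.volumes[("right", "nd-DRTT")],
        candidates=candidates,
        nonzero_only=nonzero_only,
    )


def measure_cohort(
    cohort: PhantomCohort, config: RunConfig, seed: Optional[int] = None
) -> tuple[pd.DataFrame, list, dict]:
    """Threshold sweep + final measurements for every contact x tract.

    Returns the long-form sensitivity table (one row per contact x tract x
    realized threshold), the measurement records taken at each patient's
    selected threshold (with the step-down rule applied), and the per-patient
    threshold selections.
    """
    master = int(config.seed if seed is None else seed)
    candidates = config.candidate_percents
    sens_rows: list[dict] = []
    records: list[MeasurementRecord] = []
    selections: dict[str, ThresholdSelection] = {}

    for pidx, patient in enumerate(cohort.patients):
        t0 = time.perf_counter()
        sel = select_patient_threshold(
            patient, candidates, nonzero_only=config.robust_range_nonzero_only
        )
        selections[patient.patient_id] = sel
        # jitter stream is separate from the simulation streams
        rng = np.random.default_rng([master, 10_000 + pidx])

        masks: dict[str, dict[str, TractMasks]] = {}
        for hemi in ("left", "right"):
            masks[hemi] = {
                label: TractMasks(
                    patient.volumes[(hemi, label)],
                    candidates,
                    source_id=f"{patient.patient_id}_{hemi}_{label}",
                    nonzero_only=config.robust_range_nonzero_only,
                )
                for label in TRACT_LABELS
            }

        for contact in patient.contacts:
            tms = masks[contact.hemisphere]
            for label, tm in tms.items():
                for p in candidates:
                    d = tm.auto_distance(p, contact.position)
                    if d is not None:
                        sens_rows.append(
                            {
                                "patient_id": contact.patient_id,
                                "hemisphere": contact.hemisphere,
                                "tract": label,
                                "contact_index": contact.contact_index,
                                "percent": float(p),
                                "d_auto_mm": d,
                            }
                        )
            records.extend(
                measure_contact(
                    tms,
                    contact,
                    p_selected=sel.percent,
                    candidates=candidates,
                    cutoff_mm=config.step_down_cutoff_mm,
                    jitter_mm=config.jitter_mm,
                    rng=rng,
                )
            )
        logger.info(
            "measured %s (threshold %g%%) in %.1fs",
            patient.patient_id,
            sel.percent,
            time.perf_counter() - t0,
        )

    sens_df = pd.DataFrame(sens_rows, columns=SENSITIVITY_CSV_COLUMNS)
    return sens_df, records, selections


def normalization_measurements(cohort: PhantomCohort) -> list:
    """One landmark measurement per patient: left electrode tip to left RN."""
    out: list[LandmarkMeasurement] = []
    for patient in cohort.patients:
        tips = [
            c for c in patient.contacts if c.hemisphere == "left" and c.contact_index == 0
        ]
        if not tips:
            raise ValueError(f"{patient.patient_id}: no left-hemisphere tip contact")
        out.append(
            landmark_error(
                tip_native=tips[0].position,
                rn_native=patient.rn_native["left"],
                t=patient.transform,
                rn_atlas=patient.rn_atlas["left"],
                patient_id=patient.patient_id,
            )
        )
    return out


def run_pipeline(
    config: RunConfig, out_dir: Union[str, Path], seed: Optional[int] = None
) -> dict:
    """Run every stage in order, writing all intermediate artifacts.

    Deterministic for a fixed (config, seed): repeated runs produce
    byte-identical CSVs, JSONs and volumes.  Returns the final report dict.
    """
    master = int(config.seed if seed is None else seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    logger.info("stage simulate: %d patients on %s grid", config.n_patients, config.grid_shape)
    cohort = generate_cohort(config, seed=master)
    cohort_dir = out / "cohort"
    write_cohort(cohort, cohort_dir)
    write_provenance(cohort_dir / "contacts.csv", config, master)
    logger.info("stage simulate done in %.1fs", time.perf_counter() - t0)

    t0 = time.perf_counter()
    sens_df, records, selections = measure_cohort(cohort, config, seed=master)
    sens_path = out / "sensitivity.csv"
    sens_df.to_csv(sens_path, index=False)
    write_provenance(sens_path, config, master)
    meas_path = out / "measurements.csv"
    write_measurements_csv(records, meas_path)
    write_provenance(meas_path, config, master)
    sel_path = out / "thresholds.json"
    sel_path.write_text(
        json.dumps(
            {
                pid: {"percent": s.percent, "feasible": s.feasible, "mean_dice": s.mean_dice}
                for pid, s in selections.items()
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    logger.info("stage measure done in %.1fs (%d records)", time.perf_counter() - t0, len(records))

    t0 = time.perf_counter()
    landmark = normalization_measurements(cohort)
    retained, excluded = exclude_outliers(landmark, cutoff_mm=config.outlier_cutoff_mm)
    norm_path = out / "normerror.csv"
    write_landmark_csv(retained + excluded, norm_path)
    write_provenance(norm_path, config, master)
    logger.info(
        "stage normerror done in %.1fs (%d retained, %d excluded)",
        time.perf_counter() - t0,
        len(retained),
        len(excluded),
    )

    _, sens_stats = threshold_sensitivity(sens_df)
    _, ma_stats, n_unmeasurable, n_measured = manual_vs_auto(records)
    norm_stats = normalization_summary(retained)
    report = build_report(
        sens_stats,
        ma_stats,
        norm_stats,
        n_manual_unmeasurable=n_unmeasurable,
        n_manual_measured=n_measured,
        n_norm_excluded=len(excluded),
    )
    report_path = out / "report.json"
    write_report(report, report_path)
    write_provenance(report_path, config, master)
    (out / "report.txt").write_text(render_text(report))
    logger.info("pipeline complete: %s", report_path)
    return report
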