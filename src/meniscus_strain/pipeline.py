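"""Per-specimen and per-study orchestration.

One specimen = one segmented meniscus (plus root attachments) with an
unloaded reference image and one input per load level: either a loaded
image to be registered, or — in phantom mode — a ground-truth
displacement field that skips registration entirely, so meshing,
geometry, strain and statistics can be validated independently of
registration quality.

Stage order per specimen: (rigid) → crop → non-rigid → hex mesh →
cylindrical frame + regions → strains → regional medians. A study is a
list of specimens with group metadata; their summaries concatenate into
the cohort table that feeds the nonparametric battery.

Everything is deterministic given (config, seed): the only randomness
in the package lives in the phantom generator, and each specimen draws
a sub-seed from the study seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geometry, hexmesh, registration, strain, summaries
from .registration import RegistrationConfig
from .stats import StatsConfig, run_study_stats
from .volumes import DisplacementField, ImageVolume, LabelMask, RoiBox, crop_to_roi, read_field, read_mask, read_volume

__all__ = ["SpecimenInputs", "SpecimenResult", "run_specimen", "run_study",
           "load_study_config", "run_study_from_config"]

log = logging.getLogger(__name__)


@dataclass
class SpecimenInputs:
    """Everything the pipeline needs for one meniscus.

    ``loads`` maps load level (fraction of body weight) to either an
    ImageVolume (will be registered to the unloaded image) or a
    DisplacementField (ground truth, registration skipped).
    ``circle_points`` are outer-rim points (world mm, axial plane) for
    the cylindrical origin; if None the rim is auto-extracted from the
    mesh. Separation line angles are radians about that origin.
    """

    specimen_id: str
    mask: LabelMask
    unloaded: ImageVolume
    loads: "dict[float, ImageVolume | DisplacementField]"
    line_anterior: float
    line_posterior: float
    group: str = ""
    side: str = "medial"
    kl_grade: int = 0
    circle_points: np.ndarray | None = None
    roi: RoiBox | None = None
    tibia_mask: LabelMask | None = None


@dataclass
class SpecimenResult:
    specimen_id: str
    summaries: pd.DataFrame            # load, region, zone, direction, median, ...
    fields: "dict[float, DisplacementField]"
    mesh: "hexmesh.HexMesh"
    frame: "geometry.CylindricalFrame"
    labeling: pd.DataFrame
    stage_log: "list[dict]" = dc_field(default_factory=list)


def run_specimen(
    inputs: SpecimenInputs,
    reg_config: RegistrationConfig = RegistrationConfig(),
    measure: str = "infinitesimal",
    inner_fraction: float = 2.0 / 3.0,
    angular_bin_deg: float = 5.0,
) -> SpecimenResult:
    """Run the full image-to-strain chain for one specimen."""
    stage_log: list[dict] = []

    def tick(stage: str, t0: float, **extra) -> None:
        entry = {"stage": stage, "seconds": round(time.perf_counter() - t0, 3), **extra}
        stage_log.append(entry)
        log.info("%s: %s", inputs.specimen_id, entry)

    mask, unloaded = inputs.mask, inputs.unloaded
    loads = dict(inputs.loads)

    if inputs.tibia_mask is not None:
        t0 = time.perf_counter()
        for level, item in list(loads.items()):
            if isinstance(item, ImageVolume):
                _, resampled = registration.rigid_register(inputs.tibia_mask, item, reg_config,
                                                           fixed_intensity=unloaded)
                loads[level] = resampled
        tick("rigid", t0)

    if inputs.roi is not None:
        t0 = time.perf_counter()
        mask = crop_to_roi(mask, inputs.roi)
        unloaded = crop_to_roi(unloaded, inputs.roi)
        loads = {lv: crop_to_roi(item, inputs.roi) for lv, item in loads.items()}
        tick("crop", t0, roi=[*inputs.roi.lower, *inputs.roi.upper])

    t0 = time.perf_counter()
    mesh = hexmesh.mask_to_hexmesh(mask)
    tick("mesh", t0, n_elements=mesh.n_elements, n_nodes=mesh.n_nodes)

    t0 = time.perf_counter()
    pts = inputs.circle_points
    if pts is None:
        guess = mesh.element_centroids()[:, :2].mean(axis=0)
        pts = geometry.outer_rim_points(mesh, guess, angular_bin_deg)
    center, radius = geometry.fit_circle(pts)
    frame = geometry.build_frame(center, radius)
    line_a = geometry.SeparationLine(angle=inputs.line_anterior, side="anterior")
    line_p = geometry.SeparationLine(angle=inputs.line_posterior, side="posterior")
    labeling = geometry.label_regions(mesh, frame, line_a, line_p,
                                      inner_fraction, angular_bin_deg)
    tick("frame_regions", t0, center=[round(c, 3) for c in center], radius=round(radius, 3))

    all_rows = []
    fields: dict[float, DisplacementField] = {}
    for level in sorted(loads):
        item = loads[level]
        if isinstance(item, DisplacementField):
            fld = item if inputs.roi is None else item  # already cropped above
        else:
            t0 = time.perf_counter()
            fld = registration.nonrigid_register(unloaded, item, reg_config)
            tick(f"nonrigid_{level:g}", t0)
        fields[level] = fld
        t0 = time.perf_counter()
        nodal = hexmesh.sample_nodal_displacements(fld, mesh)
        sf = strain.compute_strain_field(mesh, nodal, frame, measure)
        summ = summaries.regional_medians(sf, labeling)
        summ.insert(0, "load", level)
        all_rows.append(summ)
        tick(f"strain_{level:g}", t0)

    result = pd.concat(all_rows, ignore_index=True) if all_rows else pd.DataFrame()
    return SpecimenResult(specimen_id=inputs.specimen_id, summaries=result,
                          fields=fields, mesh=mesh, frame=frame,
                          labeling=labeling, stage_log=stage_log)


def run_study(
    specimens: "list[SpecimenInputs]",
    reg_config: RegistrationConfig = RegistrationConfig(),
    stats_config: StatsConfig = StatsConfig(),
    measure: str = "infinitesimal",
    second_labelings: "dict[str, LabelMask] | None" = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame | None, "list[SpecimenResult]"]:
    """Process a cohort: per-specimen summaries → cohort table → stats.

    A specimen whose pipeline fails is reported and skipped; statistics
    run on the survivors. If ``second_labelings`` provides a repeat
    segmentation per specimen id, a Dice agreement table is produced.
    Returns (cohort_table, stats_report, dice_table_or_None, results).
    """
    results: list[SpecimenResult] = []
    rows = []
    for sp in specimens:
        try:
            res = run_specimen(sp, reg_config, measure)
        except Exception as exc:  # keep the cohort alive
            log.error("specimen %s failed: %s", sp.specimen_id, exc)
            continue
        results.append(res)
        tab = res.summaries.rename(columns={"median": "strain_pct"})
        tab = tab[["load", "region", "zone", "direction", "strain_pct"]].copy()
        tab.insert(0, "specimen", sp.specimen_id)
        tab.insert(1, "group", sp.group)
        tab.insert(2, "kl_grade", sp.kl_grade)
        tab.insert(3, "side", sp.side)
        rows.append(tab)
    if not rows:
        raise RuntimeError("every specimen failed — no cohort to analyze")
    cohort = pd.concat(rows, ignore_index=True)

    n_groups = cohort["group"].nunique()
    if n_groups < 2:
        log.warning("single-group study: group contrasts are skipped; "
                    "location and load contrasts still run")
    report = run_study_stats(cohort, stats_config)

    dice_table = None
    if second_labelings:
        parts = []
        for sp in specimens:
            if sp.specimen_id in second_labelings:
                t = summaries.dice_report(sp.mask, second_labelings[sp.specimen_id])
                t.insert(0, "specimen", sp.specimen_id)
                parts.append(t)
        if parts:
            dice_table = pd.concat(parts, ignore_index=True)
    return cohort, report, dice_table, results


# ---------------------------------------------------------------------------
# file-driven study configuration (YAML/JSON)


def load_study_config(path) -> dict:
    """Read a study config; YAML and JSON both work."""
    path = Path(path)
    text = path.read_text()
    cfg = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    if "specimens" not in cfg:
        raise ValueError("study config must contain a 'specimens' list")
    base = path.parent
    for sp in cfg["specimens"]:
        for key in ("mask", "unloaded", "tibia_mask"):
            if key in sp and sp[key] is not None:
                p = base / sp[key]
                if not p.exists():
                    raise FileNotFoundError(f"specimen {sp.get('id')}: missing {key} file {p}")
    return cfg


def _specimen_from_entry(entry: dict, base: Path) -> SpecimenInputs:
    loads: dict[float, ImageVolume | DisplacementField] = {}
    for lv in entry.get("loads", []):
        level = float(lv["level"])
        if lv.get("field"):
            loads[level] = read_field(base / lv["field"])
        else:
            loads[level] = read_volume(base / lv["volume"])
    pts = entry.get("circle_points")
    roi = entry.get("roi")
    return SpecimenInputs(
        specimen_id=str(entry["id"]),
        mask=read_mask(base / entry["mask"]),
        unloaded=read_volume(base / entry["unloaded"]),
        loads=loads,
        line_anterior=float(entry["line_anterior"]),
        line_posterior=float(entry["line_posterior"]),
        group=entry.get("group", ""),
        side=entry.get("side", "medial"),
        kl_grade=int(entry.get("kl_grade", 0)),
        circle_points=None if pts is None else np.asarray(pts, dtype=float),
        roi=None if roi is None else RoiBox.from_sequence(roi),
        tibia_mask=read_mask(base / entry["tibia_mask"]) if entry.get("tibia_mask") else None,
    )


def run_study_from_config(path, out_dir=None):
    """Run a full study from a YAML/JSON config file; write cohort,
    stats and per-specimen summaries as CSV under ``out_dir``."""
    cfg = load_study_config(path)
    base = Path(path).parent
    reg_kwargs = cfg.get("registration", {})
    if "iterations_per_level" in reg_kwargs:
        reg_kwargs["iterations_per_level"] = tuple(reg_kwargs["iterations_per_level"])
    reg_config = RegistrationConfig(**reg_kwargs)
    stats_config = StatsConfig(**cfg.get("stats", {}))
    measure = cfg.get("strain", {}).get("measure", "infinitesimal")
    specimens = [_specimen_from_entry(e, base) for e in cfg["specimens"]]
    cohort, report, dice_table, results = run_study(
        specimens, reg_config, stats_config, measure)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cohort.to_csv(out / "cohort.csv", index=False)
        report.to_csv(out / "stats_report.csv", index=False)
        if dice_table is not None:
            dice_table.to_csv(out / "dice.csv", index=False)
        for res in results:
            res.summaries.to_csv(out / f"summary_{res.specimen_id}.csv", index=False)
        with (out / "run_log.json").open("w") as fh:
            json.dump({r.specimen_id: r.stage_log for r in results}, fh, indent=2)
    return cohort, report, dice_table, results
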