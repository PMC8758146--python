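"""End-to-end pipeline: simulate -> segment -> measure -> classify -> summarize.

The pipeline is deterministic given the seeds in its configuration; rerunning
the same config writes byte-identical summaries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import constats, io, membranes, synthdata
from .connectors import ThresholdRamp, segment_pair
from .constats import (ConnectorMeasurement, DiskGeometry, classify_rim_interior,
                       density_estimates, ks_two_sample, membrane_area,
                       nn_distances)

log = logging.getLogger("diskconnect")

_REQUIRED_KEYS = ("seed",)


def validate_config(config: dict) -> dict:
    """Check required keys and fill defaults; returns a completed config."""
    cfg = dict(config)
    for key in _REQUIRED_KEYS:
        if key not in cfg:
            raise ValueError(f"pipeline config missing required key {key!r}")
    cfg.setdefault("stack", {})
    cfg.setdefault("connectors", None)
    cfg.setdefault("ramp", {})
    cfg.setdefault("use_watershed", True)
    cfg.setdefault("classification_threshold_nm", 40.0)
    cfg.setdefault("disk_geometry", {})
    return cfg


def _build_specs(cfg: dict):
    stack_kw = dict(cfg["stack"])
    if "volume_shape" in stack_kw:
        stack_kw["volume_shape"] = tuple(stack_kw["volume_shape"])
    if stack_kw.get("incisure") is not None:
        stack_kw["incisure"] = synthdata.IncisureSpec(**stack_kw["incisure"])
    spec = synthdata.StackSpec(seed=int(cfg["seed"]), **stack_kw)
    conn = cfg["connectors"]
    if conn is not None:
        conn = [synthdata.ConnectorSpec(**c) for c in conn]
    ramp = ThresholdRamp(**cfg["ramp"])
    geom = DiskGeometry(**cfg["disk_geometry"])
    return spec, conn, ramp, geom


def segment_volume(
    volume: io.GrayVolume,
    label_volume: io.LabelVolume,
    pair_table: pd.DataFrame,
    ramp: ThresholdRamp | None = None,
    use_watershed: bool = True,
    cytosolic_gap_nm: float = 14.0,
):
    """Segment and measure all membrane pairs of one volume.

    Returns (measurements, pairs, connectors).
    """
    if ramp is None:
        ramp = ThresholdRamp()
    pairs = membranes.pairs_from_labels(
        label_volume, pair_table, cytosolic_gap_nm=cytosolic_gap_nm
    )
    measurements: list[ConnectorMeasurement] = []
    all_connectors = []
    next_id = 1
    for pair in pairs:
        gray = membranes.normalize_pair(volume, pair)
        conns = segment_pair(gray, pair, ramp=ramp, use_watershed=use_watershed,
                             id_start=next_id)
        next_id += len(conns)
        for c in conns:
            measurements.append(constats.measure_connector(c, pair, gray))
        all_connectors.extend(conns)
        log.info("pair %d: %d connectors (region %d voxels)",
                 pair.pair_id, len(conns), int(pair.region.sum()))
    return measurements, pairs, all_connectors


def classify_and_annotate(
    measurements: list[ConnectorMeasurement],
    rim_periphery_nm: np.ndarray,
    threshold_nm: float = 40.0,
) -> None:
    """Assign rim/interior classes and within-class nearest-neighbor distances."""
    for m in measurements:
        m.class_label = classify_rim_interior(m.c_con_nm, rim_periphery_nm,
                                              threshold_nm)
    for cls in (constats.RIM, constats.INTERIOR):
        group = [m for m in measurements if m.class_label == cls]
        if len(group) >= 2:
            dists = nn_distances([m.c_con_nm for m in group])
            for m, d in zip(group, dists):
                m.nn_dist_nm = float(d)


def class_statistics(measurements: list[ConnectorMeasurement]) -> dict:
    """Per-class counts, medians of Fig-2E-G style quantities and KS tests."""
    out: dict = {"n_total": len(measurements)}
    samples: dict[str, dict[str, np.ndarray]] = {}
    for cls in (constats.RIM, constats.INTERIOR):
        group = [m for m in measurements if m.class_label == cls]
        out[f"n_{cls}"] = len(group)
        samples[cls] = {
            "nn_dist_nm": np.array([m.nn_dist_nm for m in group
                                    if m.nn_dist_nm is not None]),
            "l_con_nm": np.array([m.l_con_nm for m in group]),
            "mean_gray": np.array([m.mean_gray for m in group]),
        }
        out[f"median_{cls}"] = {
            k: (float(np.median(v)) if v.size else None)
            for k, v in samples[cls].items()
        }
    out["ks"] = {}
    for key in ("nn_dist_nm", "l_con_nm", "mean_gray"):
        x, y = samples[constats.RIM][key], samples[constats.INTERIOR][key]
        if x.size and y.size:
            d, p = ks_two_sample(x, y)
            out["ks"][key] = {"D": d, "p": p}
    return out


def recovery_metrics(
    measurements: list[ConnectorMeasurement],
    ground_truth: synthdata.GroundTruth,
    match_radius_nm: float = 4.0,
) -> dict:
    """Recall and coordinate error of segmented vs planted connectors.

    A planted connector is recovered when a segmented connector's central
    coordinate lies within ``match_radius_nm`` of its planted midpoint; the
    coordinate error is the matched distance.
    """
    from scipy.spatial import cKDTree

    planted = ground_truth.connectors[["mz", "my", "mx"]].to_numpy(dtype=float)
    if len(planted) == 0:
        raise ValueError("ground truth contains no planted connectors")
    found = np.array([m.c_con_nm for m in measurements], dtype=float)
    if len(found) == 0:
        return {"n_planted": int(len(planted)), "n_recovered": 0,
                "recall_percent": 0.0, "mean_c_con_error_nm": None,
                "n_segmented": 0}
    tree = cKDTree(found)
    d, _ = tree.query(planted, k=1)
    matched = d <= match_radius_nm
    return {
        "n_planted": int(len(planted)),
        "n_segmented": int(len(found)),
        "n_recovered": int(matched.sum()),
        "recall_percent": float(100.0 * matched.mean()),
        "mean_c_con_error_nm": float(d[matched].mean()) if matched.any() else None,
    }


def run_pipeline(config: dict, output_dir) -> dict:
    """Execute the full phantom pipeline and write volumes, tables and summary.

    Returns the summary dict (also written as ``summary.json``).
    """
    cfg = validate_config(config)
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec, conn_specs, ramp, geom = _build_specs(cfg)

    stage = "simulate"
    try:
        volume, label_volume, gt = synthdata.generate_disk_stack(spec, conn_specs)
        io.write_volume(volume, outdir / "volume.mrc")
        io.write_labels(label_volume, outdir / "membranes.mrc")
        gt.connectors.to_csv(outdir / "truth.csv", index=False)
        gt.pair_table.to_csv(outdir / "pairs.csv", index=False)

        stage = "segment"
        measurements, pairs, connectors = segment_volume(
            volume, label_volume, gt.pair_table, ramp=ramp,
            use_watershed=bool(cfg["use_watershed"]),
            cytosolic_gap_nm=spec.cytosolic_gap_nm,
        )

        stage = "analyze"
        classify_and_annotate(measurements, gt.rim_periphery_nm,
                              float(cfg["classification_threshold_nm"]))
        io.write_table(measurements, outdir / "measurements.csv")
        stats = class_statistics(measurements)

        # Surface densities against tilt-corrected analyzed membrane area,
        # split at the 40 nm rim-zone boundary.
        areas = _fraction_areas(label_volume, gt,
                                float(cfg["classification_threshold_nm"]))
        counts = {cls: stats[f"n_{cls}"] for cls in (constats.RIM, constats.INTERIOR)}
        dens = density_estimates(counts, areas, geom)
        stats["density_per_um2"] = {
            d.fraction: {"rho": d.rho_um2, "rho_tot": d.rho_tot_um2,
                         "n": d.n_fraction, "area_um2": d.area_um2}
            for d in dens
        }
        stats["recovery"] = recovery_metrics(measurements, gt)
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary = {
        "config": {k: cfg[k] for k in sorted(cfg)},
        "ramp": asdict(ramp),
        "results": stats,
    }
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_json_default)
    )
    return summary


def _fraction_areas(label_volume, gt, threshold_nm: float) -> dict:
    """Analyzed membrane area (um^2) per fraction from the central planes."""
    labels = label_volume.labels
    vox = label_volume.voxel_size_nm
    periph = gt.rim_periphery_nm
    from scipy.spatial import cKDTree

    tree = cKDTree(periph)
    areas = {constats.RIM: 0.0, constats.INTERIOR: 0.0}
    for label in np.unique(labels):
        if label == 0:
            continue
        plane = labels == label
        idx = np.argwhere(plane) * vox
        d, _ = tree.query(idx, k=1)
        rim_sel = d <= threshold_nm
        full = membrane_area(plane, vox)
        frac_rim = float(rim_sel.mean())
        areas[constats.RIM] += full * frac_rim
        areas[constats.INTERIOR] += full * (1.0 - frac_rim)
    return areas


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")
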