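"""End-to-end orchestration: simulate → register → mask → analyze → report.

The analyze stage runs per patient and timepoint: the follow-up scan is
deformably registered into the planning frame (or identity-resampled when the
data are already aligned), the analysis mask is built on the planning CT, the
voxel-wise ΔHU/dose pairs are extracted, and the cohort statistics are
written as tidy CSVs plus a JSON summary.  Per-patient failures are logged
and skipped; the run only aborts on configuration errors.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import masking, stats
from .registration import RegistrationParams, RegistrationResult, register_deformable
from .synthetic import CohortTemplate, generate_cohort
from .volumes import (
    BinaryMask,
    CohortManifest,
    PatientRecord,
    load_cohort,
    resample_to_reference,
)

__all__ = ["RunConfig", "run_simulate", "run_analyze", "cohort_report", "load_config"]

log = logging.getLogger("lungdelta")

TIMEPOINTS = ("12w", "6m")


@dataclass
class RunConfig:
    """Fully serializable run configuration; echoed into the output directory."""

    out_dir: str = "lungdelta_out"
    cohort_manifest: str | None = None
    master_seed: int = 0
    identity_registration: bool = False
    weighting: str = "voxel"
    synthetic: dict[str, Any] = field(default_factory=dict)
    registration: dict[str, Any] = field(default_factory=dict)
    masking: dict[str, Any] = field(default_factory=dict)
    stats: dict[str, Any] = field(default_factory=dict)
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _template_from_config(cfg: RunConfig) -> tuple[CohortTemplate, int]:
    syn = dict(cfg.synthetic)
    n = int(syn.pop("n_patients", 12))
    if "extent" in syn:
        syn["extent"] = tuple(syn["extent"])
    if "spacing" in syn:
        syn["spacing"] = tuple(syn["spacing"])
    return CohortTemplate(**syn), n


def run_simulate(cfg: RunConfig) -> CohortManifest:
    """Generate a synthetic cohort per the config's ``synthetic`` block."""
    template, n_patients = _template_from_config(cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config_effective.yaml")
    t0 = time.perf_counter()
    manifest, _truth = generate_cohort(
        out / "cohort", n_patients=n_patients, template=template, master_seed=cfg.master_seed
    )
    log.info(
        "simulated %d patients in %.1f s (12w: %d, 6m: %d available)",
        n_patients,
        time.perf_counter() - t0,
        manifest.n_available("12w"),
        manifest.n_available("6m"),
    )
    return manifest


def _build_analysis_mask(record: PatientRecord, cfg: RunConfig) -> BinaryMask:
    recipe = masking.MaskRecipe(**cfg.masking) if cfg.masking else masking.MaskRecipe()
    if recipe.lung_source == "threshold_segmentation":
        lung = masking.segment_lung(record.planning_ct, recipe.lung_threshold_hu)
    else:
        lung = record.masks["lung"]
    exclusion = masking.build_exclusion_mask(
        record.planning_ct,
        lung,
        tumor=record.masks.get("tumor"),
        hu_parenchyma_max=recipe.hu_parenchyma_max,
    )
    return masking.build_analysis_mask(lung, exclusion, recipe.margin_mm)


def _align_followup(
    record: PatientRecord, timepoint: str, cfg: RunConfig
) -> RegistrationResult | None:
    followup = record.followups.get(timepoint)
    if followup is None:
        return None
    if cfg.identity_registration:
        aligned = resample_to_reference(followup, record.planning_ct, interp="linear")
        from .registration import DisplacementField
        from .volumes import OUT_OF_EXTENT

        valid = BinaryMask(
            values=aligned.values > OUT_OF_EXTENT + 1,
            spacing=aligned.spacing,
            origin=aligned.origin,
            label="analysis",
        )
        mad = float(
            np.abs(
                aligned.values[record.masks["lung"].values & valid.values]
                - record.planning_ct.values[record.masks["lung"].values & valid.values]
            ).mean()
        )
        return RegistrationResult(
            aligned=aligned,
            displacement=DisplacementField.zero(
                aligned.shape, aligned.spacing, aligned.origin
            ),
            validity=valid,
            pre_mad=mad,
            post_mad=mad,
        )
    reg_cfg = dict(cfg.registration)
    for key in ("pyramid_shrinks", "iterations_per_level", "smoothing_sigmas"):
        if key in reg_cfg:
            reg_cfg[key] = tuple(reg_cfg[key])
    params = RegistrationParams(**reg_cfg)
    return register_deformable(record.planning_ct, followup, record.masks["lung"], params)


def run_analyze(cfg: RunConfig) -> dict[str, Any]:
    """Run the full analysis over a cohort manifest; write the report bundle.

    Outputs under ``cfg.out_dir``: ``bins.csv`` (5-Gy dose strata, per scope),
    ``per_patient.csv``, ``pooled.csv``, ``comparisons.csv``,
    ``exclusions.csv`` and ``summary.json``; plus the echoed effective config.
    """
    if not cfg.cohort_manifest:
        raise ValueError("config must set cohort_manifest for analyze")
    manifest = load_cohort(cfg.cohort_manifest)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config_effective.yaml")

    tables: dict[str, dict[str, stats.VoxelPairTable]] = {tp: {} for tp in TIMEPOINTS}
    registration_rows = []
    skips: list[dict[str, str]] = []
    for pid in manifest.patient_ids:
        try:
            record = manifest.load_patient(pid)
            analysis = _build_analysis_mask(record, cfg)
            for tp in TIMEPOINTS:
                t0 = time.perf_counter()
                reg = _align_followup(record, tp, cfg)
                if reg is None:
                    continue
                pairs = stats.compute_delta(
                    record.planning_ct,
                    reg.aligned,
                    analysis,
                    record.dose_grid,
                    validity=reg.validity,
                    patient_id=pid,
                    timepoint=tp,
                )
                tables[tp][pid] = pairs
                registration_rows.append(
                    {
                        "patient_id": pid,
                        "timepoint": tp,
                        "pre_mad_hu": reg.pre_mad,
                        "post_mad_hu": reg.post_mad,
                        "converged": reg.converged,
                        "jacobian_positive": reg.jacobian_positive,
                        "n_voxels": pairs.n,
                        "seconds": time.perf_counter() - t0,
                    }
                )
                log.info(
                    "%s %s: %d voxels, MAD %.1f -> %.1f HU (%.1f s)",
                    pid,
                    tp,
                    pairs.n,
                    reg.pre_mad,
                    reg.post_mad,
                    time.perf_counter() - t0,
                )
        except Exception as exc:  # per-patient failures never abort the run
            log.warning("skipping patient %s: %s", pid, exc)
            skips.append({"patient_id": pid, "reason": str(exc)})

    entity_by_pid = dict(zip(manifest.rows["patient_id"], manifest.rows["entity"]))
    report = _build_report(tables, entity_by_pid, weighting=cfg.weighting)
    report["skipped_patients"] = skips
    _write_report(report, tables, out)
    return report


def _scoped_tables(
    tables: dict[str, dict[str, stats.VoxelPairTable]],
) -> dict[str, list[stats.VoxelPairTable]]:
    scoped = {tp: list(tables[tp].values()) for tp in TIMEPOINTS}
    scoped["all"] = scoped["12w"] + scoped["6m"]
    return scoped


def _build_report(
    tables: dict[str, dict[str, stats.VoxelPairTable]],
    entity_by_pid: dict[str, str],
    weighting: str = "voxel",
) -> dict[str, Any]:
    report: dict[str, Any] = {"pooled": {}, "per_patient": {}, "bins": {}, "comparisons": {}}
    scoped = _scoped_tables(tables)

    for scope, tabs in scoped.items():
        tabs = [t for t in tabs if t.n]
        if not tabs:
            continue
        reg, cor, mean_delta = stats.pooled_results(tabs, weighting=weighting)
        pooled_pairs = stats.VoxelPairTable.concat(tabs)
        delta = pooled_pairs.data["delta_hu"].to_numpy()
        report["pooled"][scope] = {
            "slope_hu_per_gy": reg.slope,
            "slope_stderr": reg.stderr,
            "slope_p": reg.p_value,
            "spearman_rho": cor.rho,
            "spearman_p": cor.p_value,
            "mean_delta_hu": mean_delta,
            "frac_delta_0_300": float(((delta >= 0) & (delta <= 300)).mean()),
            "frac_delta_negative": float((delta < 0).mean()),
            "n_voxels": pooled_pairs.n,
            "n_scans": len(tabs),
        }
        report["bins"][scope] = [asdict(b) for b in stats.bin_by_dose(pooled_pairs)]

    for tp in TIMEPOINTS:
        if tables[tp]:
            df = stats.per_patient_results(tables[tp], timepoint=tp)
            df["entity"] = df["patient_id"].map(entity_by_pid)
            report["per_patient"][tp] = df

    # 12w vs 6m comparison on per-patient mean ΔHU
    a = [float(t.data["delta_hu"].mean()) for t in tables["12w"].values() if t.n]
    b = [float(t.data["delta_hu"].mean()) for t in tables["6m"].values() if t.n]
    if len(a) >= 2 and len(b) >= 2:
        t, p = stats.compare_groups(np.array(a), np.array(b), kind="timepoint")
        report["comparisons"]["12w_vs_6m"] = {"t": t, "p": p, "n_a": len(a), "n_b": len(b)}

    # entity comparisons on per-patient mean ΔHU, per timepoint
    for tp in TIMEPOINTS:
        means: dict[str, list[float]] = {}
        for pid, tab in tables[tp].items():
            if tab.n:
                means.setdefault(entity_by_pid.get(pid, "?"), []).append(
                    float(tab.data["delta_hu"].mean())
                )
        entities = sorted(means)
        for i, e1 in enumerate(entities):
            for e2 in entities[i + 1 :]:
                if len(means[e1]) >= 2 and len(means[e2]) >= 2:
                    t, p = stats.compare_groups(
                        np.array(means[e1]), np.array(means[e2]), kind="entity"
                    )
                    report["comparisons"][f"{tp}:{e1}_vs_{e2}"] = {
                        "t": t,
                        "p": p,
                        "n_a": len(means[e1]),
                        "n_b": len(means[e2]),
                    }
        report.setdefault("entity_mean_delta", {})[tp] = {
            e: float(np.mean(v)) for e, v in means.items()
        }
    return report


def _write_report(
    report: dict[str, Any],
    tables: dict[str, dict[str, stats.VoxelPairTable]],
    out: Path,
) -> None:
    bin_rows = []
    for scope, bins in report["bins"].items():
        for b in bins:
            bin_rows.append({"scope": scope, **b})
    pd.DataFrame(bin_rows).to_csv(out / "bins.csv", index=False)

    pp = [df for df in report["per_patient"].values()]
    if pp:
        pd.concat(pp, ignore_index=True).to_csv(out / "per_patient.csv", index=False)
    else:
        pd.DataFrame().to_csv(out / "per_patient.csv", index=False)

    pooled_rows = [{"scope": scope, **vals} for scope, vals in report["pooled"].items()]
    pd.DataFrame(pooled_rows).to_csv(out / "pooled.csv", index=False)

    comp_rows = [{"comparison": k, **v} for k, v in report["comparisons"].items()]
    pd.DataFrame(comp_rows).to_csv(out / "comparisons.csv", index=False)

    excl_rows = []
    for tp, by_pid in tables.items():
        for pid, tab in by_pid.items():
            for reason, n in tab.excluded.items():
                excl_rows.append(
                    {"patient_id": pid, "timepoint": tp, "reason": reason, "n_voxels": n}
                )
    pd.DataFrame(excl_rows).to_csv(out / "exclusions.csv", index=False)

    serializable = {
        k: v for k, v in report.items() if k not in ("per_patient",)
    }
    (out / "summary.json").write_text(json.dumps(serializable, indent=2, default=float))


def cohort_report(results_dir: str | Path) -> str:
    """Human-readable summary of an analyze run's output directory."""
    out = Path(results_dir)
    summary = json.loads((out / "summary.json").read_text())
    lines = ["Cohort dose-response summary", "=" * 30]
    for scope, vals in summary.get("pooled", {}).items():
        lines.append(
            f"[{scope:>3}] mean ΔHU {vals['mean_delta_hu']:7.2f} HU | "
            f"slope {vals['slope_hu_per_gy']:6.3f} HU/Gy (p={vals['slope_p']:.3g}) | "
            f"Spearman rho {vals['spearman_rho'] if vals['spearman_rho'] is not None else float('nan'):.3f} | "
            f"{vals['n_voxels']} voxels / {vals['n_scans']} scans"
        )
    for name, c in summary.get("comparisons", {}).items():
        lines.append(f"t-test {name}: t={c['t']:.2f}, p={c['p']:.3g}")
    return "\n".join(lines)
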