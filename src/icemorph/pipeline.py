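"""End-to-end orchestration: segment, localize, measure, aggregate, report.

A run takes one or more grey volumes per condition (e.g. ``"fast"`` /
``"slow"`` freezing), pushes each through segmentation and the morphometric
descriptors, and aggregates per-condition statistics as the arithmetic mean
± standard deviation of the per-volume fractions (never ratios of pooled
voxel counts). Outputs are CSV tables (fractions, SSA, profiles,
distributions) and a JSON summary; given the same config the outputs are
bit-identical across reruns.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import morphometry as mm
from .phantom import PhantomSpec, generate_phantom
from .segmentation import SegmentationConfig, segment
from .volio import GreyVolume, LabelVolume, read_volume, write_volume

__all__ = ["RunConfig", "VolumeReport", "ConditionReport", "run_pipeline", "derived_ratio"]

log = logging.getLogger(__name__)

#: SSA interfaces reported by default: wall ice against air, embedded ice
#: against starch.
DEFAULT_SSA_INTERFACES = (("air", "ice_outside"), ("ice_inside", "starch"))


@dataclass
class RunConfig:
    """Everything needed for a reproducible analysis run.

    ``conditions`` maps a condition label to a list of inputs; each input may
    be a :class:`GreyVolume`, a :class:`PhantomSpec` (generated on the fly),
    or a TIFF path (read with ``voxel_size``).
    """

    conditions: dict[str, list]
    voxel_size: float = 1.0
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    profile_selectors: tuple[str, ...] = ("porosity", "ice_in_solid", "ice_inside_in_solid")
    profile_slab_vx: int = 10
    ssa_interfaces: tuple = DEFAULT_SSA_INTERFACES
    thickness_phases: tuple[str, ...] = ("ice_inside", "ice_outside")
    curvature_phase: tuple[str, ...] | None = ("ice_inside", "ice_outside", "starch")
    curvature_sigma_vx: float = 2.0
    output_dir: str | Path | None = None
    write_labels: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.conditions or any(not v for v in self.conditions.values()):
            raise ValueError("each condition needs at least one input volume")


@dataclass
class VolumeReport:
    name: str
    fractions: mm.PhaseFractions
    ssa: dict[str, mm.SSAResult] = field(default_factory=dict)
    profiles: dict[str, mm.VerticalProfile] = field(default_factory=dict)
    thickness: dict[str, mm.Distribution] = field(default_factory=dict)
    curvature: mm.Distribution | None = None
    curvature_mean: float | None = None


@dataclass
class ConditionReport:
    label: str
    volumes: list[VolumeReport]
    failed: list[str] = field(default_factory=list)

    def _collect(self, getter) -> list[float]:
        vals = [getter(v) for v in self.volumes]
        return [v for v in vals if v is not None]

    def mean_std(self, getter) -> tuple[float | None, float | None]:
        """Arithmetic mean ± std of a per-volume scalar; std absent when n=1."""
        vals = self._collect(getter)
        if not vals:
            return None, None
        mean = float(np.mean(vals))
        std = float(np.std(vals, ddof=1)) if len(vals) > 1 else None
        return mean, std

    @property
    def mean_fractions(self) -> dict[str, float | None]:
        keys = {
            "air": lambda v: v.fractions.phi_air,
            "ice": lambda v: v.fractions.phi_ice_in_solid,
            "ice_inside": lambda v: v.fractions.phi_ice_inside_in_solid,
            "ice_outside": lambda v: (
                v.fractions.V_ice_outside / (v.fractions.V_ice + v.fractions.V_starch)
                if (v.fractions.V_ice + v.fractions.V_starch) else None
            ),
            "starch": lambda v: v.fractions.phi_starch_in_solid,
        }
        return {k: self.mean_std(g)[0] for k, g in keys.items()}


def _load_input(item, config: RunConfig, index: int) -> tuple[str, GreyVolume]:
    if isinstance(item, PhantomSpec):
        return f"phantom_{item.seed}", generate_phantom(item).grey
    if isinstance(item, GreyVolume):
        return f"volume_{index}", item
    return Path(item).stem, read_volume(item, config.voxel_size)


def _analyse_volume(
    name: str, grey: GreyVolume, config: RunConfig
) -> tuple[VolumeReport, LabelVolume]:
    seg = segment(grey, config.segmentation)
    labels = seg.labels
    report = VolumeReport(name=name, fractions=mm.volume_fractions(labels))
    for sel in config.profile_selectors:
        report.profiles[sel] = mm.vertical_profile(labels, sel, config.profile_slab_vx)
    for a, b in config.ssa_interfaces:
        res = mm.specific_surface_area(labels, a, b)
        report.ssa[f"{a}-{b}"] = res
    for phase in config.thickness_phases:
        phase_mask = labels.mask(phase)
        if not phase_mask.any():
            log.info("%s: phase %s empty, thickness skipped", name, phase)
            continue
        tmap = mm.local_thickness(phase_mask, labels.voxel_size)
        report.thickness[phase] = mm.thickness_distribution(tmap)
    if config.curvature_phase is not None:
        mask = np.zeros(labels.shape, dtype=bool)
        for p in config.curvature_phase:
            mask |= labels.mask(p)
        if mask.any() and not mask.all():
            fld = mm.mean_curvature_field(mask, labels.voxel_size, config.curvature_sigma_vx)
            report.curvature = mm.curvature_distribution(fld)
            report.curvature_mean = fld.area_weighted_mean
    return report, labels


def run_pipeline(config: RunConfig) -> dict[str, ConditionReport]:
    """Run all enabled stages on every volume of every condition.

    A failing volume is logged, recorded in ``ConditionReport.failed`` and
    skipped; it never aborts the run. If ``config.output_dir`` is set, CSV
    tables and ``summary.json`` are written there.
    """
    reports: dict[str, ConditionReport] = {}
    for label, items in config.conditions.items():
        vol_reports, failed = [], []
        for i, item in enumerate(items):
            name = "?"
            try:
                name, grey = _load_input(item, config, i)
                report, labels = _analyse_volume(f"{label}/{name}", grey, config)
                vol_reports.append(report)
                if config.output_dir is not None and config.write_labels:
                    write_volume(labels, Path(config.output_dir) / f"labels_{label}_{name}.tif")
            except Exception:
                log.exception("condition %s, volume %s failed", label, name)
                failed.append(f"{label}/{name}")
        reports[label] = ConditionReport(label=label, volumes=vol_reports, failed=failed)
    if config.output_dir is not None:
        _write_outputs(reports, config)
    return reports


def derived_ratio(report, numerator_phase: str, denominator_phase: str) -> int | None:
    """Headline percentage: 100 x mean(numerator fraction) / mean(denominator).

    ``report`` is a :class:`ConditionReport` or a plain mapping of mean
    fractions. Rounded to the nearest integer percent; absent when the
    denominator is zero or missing.
    """
    fractions = report.mean_fractions if isinstance(report, ConditionReport) else report
    num = fractions.get(numerator_phase)
    den = fractions.get(denominator_phase)
    if num is None or not den:
        return None
    return round(100.0 * num / den)


# ---------------------------------------------------------------------------
# reporting


def _fractions_frame(reports: dict[str, ConditionReport]) -> pd.DataFrame:
    rows = []
    for label, rep in reports.items():
        for v in rep.volumes:
            row = {"condition": label, "volume": v.name}
            row.update(v.fractions.as_dict())
            rows.append(row)
        means = rep.mean_fractions
        rows.append({
            "condition": label, "volume": "MEAN",
            "phi_air": means["air"], "phi_ice_in_solid": means["ice"],
            "phi_ice_inside_in_solid": means["ice_inside"],
            "phi_starch_in_solid": means["starch"],
        })
    return pd.DataFrame(rows)


def _write_outputs(reports: dict[str, ConditionReport], config: RunConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _fractions_frame(reports).to_csv(out / "fractions.csv", index=False, float_format="%.6f")

    ssa_rows = []
    for label, rep in reports.items():
        for v in rep.volumes:
            for key, res in v.ssa.items():
                ssa_rows.append({
                    "condition": label, "volume": v.name, "interface": key,
                    "area_um2": res.area_um2, "ssa_mm": res.ssa_mm,
                })
    if ssa_rows:
        pd.DataFrame(ssa_rows).to_csv(out / "ssa.csv", index=False, float_format="%.6f")

    for sel in config.profile_selectors:
        rows = []
        for label, rep in reports.items():
            for v in rep.volumes:
                prof = v.profiles.get(sel)
                if prof is None:
                    continue
                for z, val in zip(prof.z_um, prof.values):
                    rows.append({"condition": label, "volume": v.name, "z_um": z, "value": val})
        if rows:
            pd.DataFrame(rows).to_csv(out / f"profiles_{sel}.csv", index=False,
                                      float_format="%.6f")

    for phase in config.thickness_phases:
        rows = []
        for label, rep in reports.items():
            for v in rep.volumes:
                dist = v.thickness.get(phase)
                if dist is None:
                    continue
                for edge, val in zip(dist.bin_edges[1:], dist.values):
                    rows.append({"condition": label, "volume": v.name,
                                 "thickness_um": edge, "cumulative_pct": val})
        if rows:
            pd.DataFrame(rows).to_csv(out / f"thickness_{phase}.csv", index=False,
                                      float_format="%.6f")

    curv_rows = []
    for label, rep in reports.items():
        for v in rep.volumes:
            if v.curvature is None:
                continue
            for lo, hi, val in zip(v.curvature.bin_edges[:-1], v.curvature.bin_edges[1:],
                                   v.curvature.values):
                curv_rows.append({"condition": label, "volume": v.name,
                                  "bin_lo_mm": lo, "bin_hi_mm": hi, "occurrence_pct": val})
    if curv_rows:
        pd.DataFrame(curv_rows).to_csv(out / "curvature.csv", index=False, float_format="%.6f")

    summary = {}
    for label, rep in reports.items():
        means = rep.mean_fractions
        ssa_means = {}
        for key in {k for v in rep.volumes for k in v.ssa}:
            mean, std = rep.mean_std(lambda v, k=key: v.ssa[k].ssa_mm if k in v.ssa else None)
            ssa_means[key] = {"mean": mean, "std": std}
        curv_mean, curv_std = rep.mean_std(lambda v: v.curvature_mean)
        summary[label] = {
            "n_volumes": len(rep.volumes),
            "failed": rep.failed,
            "mean_fractions": means,
            "ice_inside_share_pct": derived_ratio(rep, "ice_inside", "ice"),
            "ice_outside_share_pct": derived_ratio(rep, "ice_outside", "ice"),
            "ssa_mm": ssa_means,
            "mean_curvature_mm": {"mean": curv_mean, "std": curv_std},
        }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
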