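"""End-to-end planning study on a synthetic phantom.

Reproduces the three-scheme comparison: uniform-margin plans (2 mm and
5 mm OTVs), the beam-specific WET-margin plan, and the robust minimax
plan on the GTV — then evaluates all of them with the same robustness
machinery (42-scenario passing rate, 8-scenario DVH bandwidths, dose
spread function at the duodenum abutment) and checks the serial-OAR
constraints (duodenum V33 < 1 cm^3, V20 < 20 cm^3, V15 < 15 cm^3).

Everything is deterministic given the config seed: the only randomness
in the pipeline is the phantom blob jitter.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .beams import Beam, BeamWETMap
from .dose import NOMINAL, BeamDoseOperator, place_spots
from .grid import StructureSet, VoxelGrid
from .metrics import (
    compute_dvh,
    dose_at_volume,
    volume_at_dose,
    bandwidth,
    dose_spread_function,
    locate_abutment_line,
    sample_line_dose,
)
from .optimization import ObjectiveSpec, ObjectiveTerm, Plan, optimize_robust, optimize_sfo
from .phantom import PhantomConfig, hu_to_rsp, make_phantom
from .scenarios import DoseRecomputer, make_scenarios
from .target_volumes import OTVSpec, exclude_overlap, expand_beam_specific, expand_uniform

log = logging.getLogger("pbsplan")


@dataclass
class StudyConfig:
    """One config drives the whole study."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    gantry_angles: tuple = (210.0, 150.0)
    prescription_gy: float = 33.0
    fractions: int = 5
    uniform_margins_mm: tuple = (2.0, 5.0)
    lateral_margin_mm: float = 2.0
    range_fraction: float = 0.035
    setup_mm: float = 2.0
    lateral_sigma_mm: float = 5.0
    lateral_spacing_mm: float = 5.0
    layer_spacing_wet_mm: float = 5.0
    eval_set: str = "eval42"
    ro_set: str = "ro21"
    schemes: tuple = ("OTV_2mm", "OTV_5mm", "OTV_WET", "RO")
    # structures carved out of the OTVs before optimization; empty by
    # default — margin plans deliberately carry full dose into the
    # margin even where it overlaps the duodenum
    exclude_oars: tuple = ()
    # whether the beam-specific margin also covers the setup component
    # along the beam axis (union-of-scenarios construction)
    wet_axial_setup: bool = True
    # objective shape (per-beam reference doses are fractions of the
    # per-beam prescription share); the optimization goals sit slightly
    # above the evaluation goal so the achieved minimum clears the
    # prescription, as in clinical practice
    target_min_level: float = 1.03
    target_min_weight: float = 1000.0
    target_uniform_weight: float = 10.0
    target_uniform_level: float = 1.05
    target_max_weight: float = 5.0
    target_max_level: float = 1.15
    oar_max_level: float = 0.6
    oar_max_weight: float = 2.0
    oar_constraints: dict = field(
        default_factory=lambda: {"duodenum": {"V33": 1.0, "V20": 20.0, "V15": 15.0}}
    )
    dvh_bin_gy: float = 0.05
    iter_cap: int = 500
    rel_tol: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.gantry_angles) < 1:
            raise ValueError("at least one beam is required")
        self.phantom.seed = self.seed

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "phantom" in d and isinstance(d["phantom"], dict):
            d["phantom"] = PhantomConfig.from_dict(d["phantom"])
        for k in ("gantry_angles", "uniform_margins_mm", "schemes", "exclude_oars"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class StudyContext:
    """Shared geometry products: phantom, RSP, beams, WET maps, OTVs, spots."""

    config: StudyConfig
    hu: VoxelGrid
    rsp: VoxelGrid
    structures: StructureSet
    beams: list[Beam]
    wetmaps: list[BeamWETMap]
    otvs: dict  # scheme -> list of per-beam OTV masks
    spots: dict  # scheme -> list of per-beam spot lists


@dataclass
class PlanReport:
    scheme: str
    passing_rate_pct: float
    scenario_table: pd.DataFrame
    nominal_metrics: dict
    bandwidths: dict
    dsf: dict
    constraints: pd.DataFrame


@dataclass
class StudyResult:
    context: StudyContext
    plans: dict
    reports: dict

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for scheme, rep in self.reports.items():
            row = {"scheme": scheme, "passing_rate_pct": rep.passing_rate_pct}
            row.update({f"nominal_{k}": v for k, v in rep.nominal_metrics.items()})
            row.update({f"Wd_{k}_pct": v for k, v in rep.bandwidths.items()})
            row.update({f"dsf_{k}": v for k, v in rep.dsf.items()
                        if isinstance(v, (int, float))})
            rows.append(row)
        return pd.DataFrame(rows)


def build_context(config: StudyConfig | None = None) -> StudyContext:
    """Phantom -> RSP -> beams -> WET maps -> OTVs -> spot lattices."""
    cfg = config or StudyConfig()
    log.info("phantom: grid %s @ %s mm, seed %d", cfg.phantom.shape, cfg.phantom.spacing, cfg.seed)
    hu, structures = make_phantom(cfg.phantom)
    rsp = hu_to_rsp(hu)
    gtv = structures["gtv"]
    iso = rsp.index_to_position(np.argwhere(gtv).mean(axis=0))
    beams = [Beam(g, iso) for g in cfg.gantry_angles]
    log.info("beams: gantry %s, isocenter %s", cfg.gantry_angles, np.round(iso, 1))

    roi = gtv | structures["duodenum"]
    wetmaps = [BeamWETMap.for_mask(rsp, b, roi, pad_mm=45.0) for b in beams]

    otvs: dict = {}
    spots: dict = {}
    excl = list(cfg.exclude_oars)
    for margin in cfg.uniform_margins_mm:
        name = f"OTV_{margin:g}mm"
        otv = expand_uniform(gtv, margin, rsp.spacing)
        otv = exclude_overlap(otv, structures, excl, gtv=gtv)
        otvs[name] = [otv for _ in beams]
    wet_spec = OTVSpec(
        scheme="beam_specific",
        lateral_margin_mm=cfg.lateral_margin_mm,
        range_fraction=cfg.range_fraction,
        axial_setup_margin_mm=cfg.setup_mm if cfg.wet_axial_setup else 0.0,
    )
    otv_wet = []
    for b, wm in zip(beams, wetmaps):
        m = expand_beam_specific(gtv, b, rsp, wet_spec, wetmap=wm)
        otv_wet.append(exclude_overlap(m, structures, excl, gtv=gtv))
    otvs["OTV_WET"] = otv_wet
    # robust plans carry no explicit margin volume; the spot lattice must
    # still reach every position the scenarios may demand, so RO reuses
    # the beam-specific placement volume
    otvs["RO"] = otv_wet

    for scheme, per_beam in otvs.items():
        spots[scheme] = [
            place_spots(
                m, b, rsp,
                lateral_spacing_mm=cfg.lateral_spacing_mm,
                layer_spacing_wet_mm=cfg.layer_spacing_wet_mm,
                beam_index=bi, wetmap=wm,
            )
            for bi, (m, b, wm) in enumerate(zip(per_beam, beams, wetmaps))
        ]
        log.info("spots[%s]: %s", scheme, [len(s) for s in spots[scheme]])
    return StudyContext(cfg, hu, rsp, structures, beams, wetmaps, otvs, spots)


def _target_objective(cfg: StudyConfig, structure: str, share: float) -> ObjectiveSpec:
    return ObjectiveSpec(
        [
            ObjectiveTerm(structure, "min", cfg.target_min_level * share,
                          cfg.target_min_weight),
            ObjectiveTerm(structure, "uniform", cfg.target_uniform_level * share,
                          cfg.target_uniform_weight),
            ObjectiveTerm(structure, "max", cfg.target_max_level * share,
                          cfg.target_max_weight),
            ObjectiveTerm("duodenum", "max", cfg.oar_max_level * share,
                          cfg.oar_max_weight),
        ]
    )


def optimize_scheme(ctx: StudyContext, scheme: str) -> Plan:
    """Optimize one scheme's plan on the shared study context."""
    cfg = ctx.config
    rsp, structures = ctx.rsp, ctx.structures
    share = cfg.prescription_gy / len(ctx.beams)
    duo_pos = rsp.index_to_position(np.argwhere(structures["duodenum"]))

    if scheme != "RO":
        spec = _target_objective(cfg, "target", share)
        per_beam_ops = []
        for b, (otv, spots_b, wm) in enumerate(
            zip(ctx.otvs[scheme], ctx.spots[scheme], ctx.wetmaps)
        ):
            pos = rsp.index_to_position(np.argwhere(otv))
            per_beam_ops.append(
                {
                    "target": BeamDoseOperator(spots_b, wm, pos, NOMINAL, cfg.lateral_sigma_mm),
                    "duodenum": BeamDoseOperator(spots_b, wm, duo_pos, NOMINAL, cfg.lateral_sigma_mm),
                }
            )
        plan = optimize_sfo(
            per_beam_ops, spec, beams=ctx.beams, spots=ctx.spots[scheme],
            scheme=scheme, prescription_gy=cfg.prescription_gy,
            iter_cap=cfg.iter_cap, rel_tol=cfg.rel_tol,
        )
    else:
        spec = _target_objective(cfg, "gtv", share)
        gtv_pos = rsp.index_to_position(np.argwhere(structures["gtv"]))
        ro_set = make_scenarios(cfg.ro_set, cfg.setup_mm, cfg.range_fraction)
        scenario_beam_ops = []
        for sc in ro_set:
            beam_ops = []
            for spots_b, wm in zip(ctx.spots["RO"], ctx.wetmaps):
                beam_ops.append(
                    {
                        "gtv": BeamDoseOperator(spots_b, wm, gtv_pos, sc, cfg.lateral_sigma_mm),
                        "duodenum": BeamDoseOperator(spots_b, wm, duo_pos, sc, cfg.lateral_sigma_mm),
                    }
                )
            scenario_beam_ops.append(beam_ops)
        plan = optimize_robust(
            scenario_beam_ops, spec, beams=ctx.beams, spots=ctx.spots["RO"],
            scheme="RO", prescription_gy=cfg.prescription_gy,
            iter_cap=cfg.iter_cap, rel_tol=cfg.rel_tol,
        )
        plan.info["ro_scenarios"] = len(ro_set)
    # record optimized weights on the spot objects
    for spots_b, w in zip(plan.spots, plan.weights):
        for sp, wi in zip(spots_b, w):
            sp.weight = float(wi)
    return plan


def _nominal_dose_box(ctx: StudyContext, plan: Plan, pad_mm: float = 25.0) -> VoxelGrid:
    """Nominal total dose on a bounding box around GTV + duodenum."""
    rsp = ctx.rsp
    roi = ctx.structures["gtv"] | ctx.structures["duodenum"]
    idx = np.argwhere(roi)
    pad = np.ceil(pad_mm / rsp.spacing).astype(int)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, rsp.shape)
    sub = np.indices(tuple(hi - lo), dtype=float)
    pos = np.stack(
        [rsp.origin[a] + (sub[a] + lo[a]) * rsp.spacing[a] for a in range(3)], axis=-1
    ).reshape(-1, 3)
    total = np.zeros(len(pos))
    for spots_b, w, wm in zip(plan.spots, plan.weights, ctx.wetmaps):
        op = BeamDoseOperator(spots_b, wm, pos, NOMINAL, ctx.config.lateral_sigma_mm)
        total += op.dose(np.asarray(w))
    vals = total.reshape(tuple(hi - lo)).astype(np.float32)
    origin = rsp.origin + lo * rsp.spacing
    return VoxelGrid(vals, rsp.spacing, origin, "Gy(RBE)")


def evaluate_plan(ctx: StudyContext, plan: Plan) -> PlanReport:
    """Full robustness and dosimetric evaluation of one plan."""
    cfg = ctx.config
    rx = cfg.prescription_gy
    rc = DoseRecomputer(plan, ctx.rsp, ctx.structures, cfg.lateral_sigma_mm, ctx.wetmaps)

    from .scenarios import evaluate_passing, perturbed_dvh_family  # cycle-free

    eval_set = make_scenarios(cfg.eval_set, cfg.setup_mm, cfg.range_fraction)
    rate, table = evaluate_passing(
        plan, ctx.rsp, ctx.structures, eval_set, prescription_gy=rx, recomputer=rc
    )

    # nominal DVH metrics
    vox_ml = ctx.rsp.voxel_volume_ml
    d_gtv = rc.dose("gtv", NOMINAL)
    d_duo = rc.dose("duodenum", NOMINAL)
    dvh_gtv = compute_dvh(d_gtv, bin_width_gy=cfg.dvh_bin_gy, voxel_volume_ml=vox_ml)
    dvh_duo = compute_dvh(d_duo, bin_width_gy=cfg.dvh_bin_gy, voxel_volume_ml=vox_ml)
    nominal = {
        "gtv_v_rx_pct": volume_at_dose(dvh_gtv, rx)[0],
        "gtv_d98_gy": dose_at_volume(dvh_gtv, 98.0),
        "gtv_d50_gy": dose_at_volume(dvh_gtv, 50.0),
        "gtv_dmax_gy": float(d_gtv.max()),
        "duodenum_v33_cm3": volume_at_dose(dvh_duo, 33.0)[1],
        "duodenum_v20_cm3": volume_at_dose(dvh_duo, 20.0)[1],
        "duodenum_v15_cm3": volume_at_dose(dvh_duo, 15.0)[1],
    }

    # 8-scenario bandwidths
    band_set = make_scenarios("bandwidth8", cfg.setup_mm, cfg.range_fraction)
    bands = {}
    gtv_d98, gtv_d50, duo_v20 = [], [], []
    for sc in band_set:
        dvh_g = compute_dvh(rc.dose("gtv", sc), bin_width_gy=cfg.dvh_bin_gy,
                            voxel_volume_ml=vox_ml)
        dvh_d = compute_dvh(rc.dose("duodenum", sc), bin_width_gy=cfg.dvh_bin_gy,
                            voxel_volume_ml=vox_ml)
        gtv_d98.append(dose_at_volume(dvh_g, 98.0))
        gtv_d50.append(dose_at_volume(dvh_g, 50.0))
        duo_v20.append(volume_at_dose(dvh_d, 20.0)[0])
    bands["gtv_D98"] = bandwidth(nominal["gtv_d98_gy"], gtv_d98)
    bands["gtv_D50"] = bandwidth(nominal["gtv_d50_gy"], gtv_d50)
    v20_nom = volume_at_dose(dvh_duo, 20.0)[0]
    bands["duodenum_V20"] = bandwidth(v20_nom, duo_v20) if v20_nom > 0 else float("nan")

    # dose spread function at the duodenum abutment
    dose_box = _nominal_dose_box(ctx, plan)
    dsf_summary: dict = {}
    try:
        p0, p1 = locate_abutment_line(dose_box, rx, _crop_like(ctx.structures["duodenum"], ctx.rsp, dose_box))
        profile = sample_line_dose(dose_box, p0, p1, step_mm=0.5)
        res = dose_spread_function(profile)
        dsf_summary = {
            "fwhm_mm": res.fwhm_mm,
            "fw20m_mm": res.fw20m_mm,
            "w_100_50_mm": res.w_100_50_mm,
            "w_100_20_mm": res.w_100_20_mm,
            "error_flag": res.error_flag,
            "profile": profile.assign(fitted=res.fitted_dose, dsf=res.dsf),
        }
    except ValueError as exc:
        dsf_summary = {"error": str(exc)}

    # OAR constraint compliance
    crows = []
    limits = cfg.oar_constraints.get("duodenum", {})
    measured = {
        "V33": nominal["duodenum_v33_cm3"],
        "V20": nominal["duodenum_v20_cm3"],
        "V15": nominal["duodenum_v15_cm3"],
    }
    for key, lim in limits.items():
        crows.append(
            {"structure": "duodenum", "metric": key, "limit_cm3": lim,
             "value_cm3": measured[key], "pass": measured[key] < lim}
        )
    constraints = pd.DataFrame(crows)

    return PlanReport(
        scheme=plan.scheme,
        passing_rate_pct=rate,
        scenario_table=table,
        nominal_metrics=nominal,
        bandwidths=bands,
        dsf=dsf_summary,
        constraints=constraints,
    )


def _crop_like(mask: np.ndarray, full: VoxelGrid, box: VoxelGrid) -> np.ndarray:
    lo = np.round((box.origin - full.origin) / full.spacing).astype(int)
    hi = lo + np.array(box.shape)
    return mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]


def run_study(config: StudyConfig | None = None, out_dir: str | Path | None = None) -> StudyResult:
    """Execute the full study; optionally write all artifacts to ``out_dir``."""
    cfg = config or StudyConfig()
    ctx = build_context(cfg)
    plans, reports = {}, {}
    for scheme in cfg.schemes:
        log.info("optimizing %s", scheme)
        try:
            plans[scheme] = optimize_scheme(ctx, scheme)
            reports[scheme] = evaluate_plan(ctx, plans[scheme])
        except Exception as exc:  # annotate the failing stage
            raise RuntimeError(
                f"study stage {scheme!r} failed (seed={cfg.seed}): {exc}"
            ) from exc
    result = StudyResult(ctx, plans, reports)
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def load_plan_csv(path: str | Path, ctx: StudyContext, scheme: str) -> Plan:
    """Rebuild a Plan from a spots+weights CSV written by ``write_outputs``."""
    from .dose import Spot

    df = pd.read_csv(path)
    spots, weights = [], []
    for b in range(len(ctx.beams)):
        rows = df[df["beam"] == b]
        spots.append(
            [Spot(b, r.u_mm, r.v_mm, r.range_wet_mm) for r in rows.itertuples()]
        )
        weights.append(rows["weight"].to_numpy())
    return Plan(beams=ctx.beams, spots=spots, weights=weights, scheme=scheme,
                prescription_gy=ctx.config.prescription_gy)


def write_outputs(result: StudyResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = result.summary_frame()
    summary.to_csv(out / "study_summary.csv", index=False)
    metrics_json = {}
    for scheme, rep in result.reports.items():
        rep.scenario_table.to_csv(out / f"scenarios_{scheme}.csv", index=False)
        rep.constraints.to_csv(out / f"constraints_{scheme}.csv", index=False)
        if "profile" in rep.dsf:
            rep.dsf["profile"].to_csv(out / f"dsf_profile_{scheme}.csv", index=False)
        plan = result.plans[scheme]
        rows = []
        for b, (spots_b, w) in enumerate(zip(plan.spots, plan.weights)):
            for sp, wi in zip(spots_b, w):
                rows.append({"beam": b, "gantry_deg": plan.beams[b].gantry_deg,
                             "u_mm": sp.u, "v_mm": sp.v,
                             "range_wet_mm": sp.range_wet, "weight": wi})
        pd.DataFrame(rows).to_csv(out / f"plan_{scheme}.csv", index=False)
        metrics_json[scheme] = {
            "passing_rate_pct": rep.passing_rate_pct,
            "nominal": rep.nominal_metrics,
            "bandwidths_pct": rep.bandwidths,
            "dsf": {k: v for k, v in rep.dsf.items() if isinstance(v, (int, float, bool, str))},
        }
    (out / "metrics.json").write_text(json.dumps(metrics_json, indent=2, default=float))
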