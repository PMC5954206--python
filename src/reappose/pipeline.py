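"""End-to-end studies: pressure sweeps, sensitivity, mesh convergence.

A *sweep* runs the two-step re-apposition simulation over the static-pressure
ladder 70..140 mmHg in 10-mmHg increments for one region and one flap
parameter set.  Sweeps are warm-started: the fully apposed terminal state of
one pressure point is carried to the next (pressure ramped with the member
held, then a short member adjustment), which keeps the per-point cost small
and yields a smooth, path-consistent pressure curve.

The sensitivity study mirrors the bench study's design: a baseline with
Sample #1 material properties everywhere, wall-material variants (surrogate
+/-20 % perturbations of c10 and k1 for the TL and FL walls), and a
flap-variation arm using the per-pig flap parameter sets, each evaluated at
70/100/140 mmHg.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constitutive import (GOHParameters, load_flap_parameters,
                           load_wall_parameters)
from .geometry import DissectionGeometry, build_cross_section
from .simulation import (EquilibriumState, FEModel, ReappositionResult,
                         SolverError, SolverOptions, advance_pressure,
                         expand_member, pressurize, run_reapposition)
from .synthetic import generate_material_variants

DEFAULT_PRESSURES = tuple(range(70, 150, 10))
SENSITIVITY_PRESSURES = (70, 100, 140)


def materials_for_region(region: str, flap_label: str | None = None,
                         flap_params: GOHParameters | None = None,
                         wall_overrides: dict | None = None) -> dict:
    """Assemble the three-layer material set for a region.

    The flap comes from the per-pig table (or an explicit parameter set);
    walls default to the single TL/FL wall characterization used throughout.
    """
    walls = load_wall_parameters()
    if flap_params is None:
        flap_params = load_flap_parameters()[flap_label or f"{region}_1"]
    mats = {
        "flap": flap_params,
        "fl_wall": walls[f"{region}_fl_wall"],
        "tl_wall": walls["tl_wall"],
    }
    if wall_overrides:
        mats.update(wall_overrides)
    return mats


def geometry_for(region: str, materials: dict, **kw) -> DissectionGeometry:
    return DissectionGeometry.for_region(
        region,
        flap_thickness_mm=materials["flap"].thickness_mm,
        fl_wall_thickness_mm=materials["fl_wall"].thickness_mm,
        tl_wall_thickness_mm=materials["tl_wall"].thickness_mm, **kw)


@dataclass
class SweepResult:
    """Radial-pressure curve over the aortic-pressure ladder for one case."""

    region: str
    flap_label: str
    results: list                     # ReappositionResult per pressure point
    valid: bool = True
    config_hash: str = ""
    assumptions: dict = field(default_factory=dict)

    @property
    def pressures(self):
        return [r.p_aorta_mmhg for r in self.results if r is not None]

    @property
    def radial_pressures(self):
        return [r.radial_pressure_mmhg for r in self.results if r is not None]

    @property
    def diameters(self):
        return [r.final_inner_diameter_mm for r in self.results if r is not None]

    def summary(self) -> dict:
        p = np.asarray(self.pressures, float)
        q = np.asarray(self.radial_pressures, float)
        out = dict(region=self.region, flap_label=self.flap_label,
                   n_points=len(p), valid=self.valid,
                   mean_radial_pressure_mmhg=float(q.mean()) if len(q) else np.nan)
        if len(p) >= 2:
            out["slope_mmhg_per_mmhg"] = float(np.polyfit(p, q, 1)[0])
        else:
            out["slope_mmhg_per_mmhg"] = np.nan  # undefined for a single point
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            if r is None:
                continue
            rows.append(dict(region=self.region, flap_label=self.flap_label,
                             p_aorta_mmhg=r.p_aorta_mmhg,
                             radial_pressure_mmhg=r.radial_pressure_mmhg,
                             final_diameter_mm=r.final_inner_diameter_mm,
                             member_radius_mm=r.member_radius_mm,
                             converged=r.converged,
                             assumed_inner_radius_mm=self.assumptions.get(
                                 "inner_radius_mm")))
        return pd.DataFrame(rows)


def _config_hash(*parts) -> str:
    text = json.dumps([repr(p) for p in parts], sort_keys=True)
    return hashlib.sha1(text.encode()).hexdigest()[:12]


def run_sweep(region: str, flap_label: str | None = None,
              flap_params: GOHParameters | None = None,
              wall_overrides: dict | None = None,
              pressures=DEFAULT_PRESSURES,
              options: SolverOptions = SolverOptions(member_step_mm=0.3,
                                                     newton_tol=1e-6,
                                                     flap_drape_bias_mmhg=0.5),
              h: float = 0.45, inner_radius_mm: float | None = None) -> SweepResult:
    """Warm-started pressure sweep for one region / flap parameter set.

    Individual failed points are recorded as ``None``; a sweep with more than
    two failures is marked invalid.
    """
    mats = materials_for_region(region, flap_label, flap_params, wall_overrides)
    gkw = {} if inner_radius_mm is None else dict(inner_radius_mm=inner_radius_mm)
    geom = geometry_for(region, mats, **gkw)
    mesh = build_cross_section(geom, h)
    model = FEModel(mesh, mats, options)

    results, state = [], None
    n_fail = 0
    for p in pressures:
        try:
            if state is None:
                res, state = run_reapposition(geom, mats, p, options, h=h,
                                              mesh=mesh, model=model,
                                              return_state=True)
            else:
                state = advance_pressure(state, p, options)
                res = expand_member(state, options=options)
                res.flap_label = mats["flap"].label
        except SolverError:
            results.append(None)
            n_fail += 1
            state = None  # cold restart at the next point
            continue
        results.append(res)
    sw = SweepResult(region=region, flap_label=mats["flap"].label,
                     results=results, valid=n_fail <= 2,
                     config_hash=_config_hash(region, mats["flap"], h, options),
                     assumptions=dict(inner_radius_mm=geom.inner_radius_mm,
                                      plane_strain_cross_section=True))
    return sw


def run_sensitivity(region: str, pressures=SENSITIVITY_PRESSURES,
                    n_variants: int = 4, rel_range: float = 0.2, seed: int = 0,
                    options: SolverOptions = SolverOptions(member_step_mm=0.3,
                                                           newton_tol=1e-6,
                                                           flap_drape_bias_mmhg=0.5),
                    h: float = 0.45) -> dict:
    """Wall-material sensitivity vs the Sample #1 baseline.

    Wall variants jointly perturb c10 and k1 of the TL wall and the region's
    FL wall by seeded uniform +/-``rel_range``; the flap-variation arm swaps
    in the other pigs' flap parameter sets.  Reports relative changes in
    radial pressure at each pressure and their averages.
    """
    flaps = load_flap_parameters()
    walls = load_wall_parameters()
    base_sweep = run_sweep(region, f"{region}_1", pressures=pressures,
                           options=options, h=h)
    base_q = np.array(base_sweep.radial_pressures, float)
    if len(base_q) != len(pressures):
        raise SolverError("baseline sensitivity sweep incomplete")

    ranges = {"c10": rel_range, "k1": rel_range}
    tl_vars = generate_material_variants(walls["tl_wall"], ranges,
                                         n_variants + 1, seed=seed)[1:]
    fl_vars = generate_material_variants(walls[f"{region}_fl_wall"], ranges,
                                         n_variants + 1, seed=seed + 1)[1:]

    wall_rows = []
    for i, (tl_v, fl_v) in enumerate(zip(tl_vars, fl_vars)):
        sw = run_sweep(region, f"{region}_1", pressures=pressures,
                       wall_overrides={"tl_wall": tl_v, "fl_wall": fl_v},
                       options=options, h=h)
        q = np.array(sw.radial_pressures, float)
        if len(q) != len(pressures):
            continue
        wall_rows.append(q)
    wall_rows = np.array(wall_rows)

    flap_rows, flap_labels = [], []
    for lbl, fp in flaps.items():
        if not lbl.startswith(region) or lbl == f"{region}_1":
            continue
        sw = run_sweep(region, lbl, pressures=pressures, options=options, h=h)
        q = np.array(sw.radial_pressures, float)
        if len(q) == len(pressures):
            flap_rows.append(q)
            flap_labels.append(lbl)
    flap_rows = np.array(flap_rows)

    report = dict(region=region, pressures=list(pressures),
                  baseline_radial_mmhg=base_q.tolist(),
                  n_wall_variants=len(wall_rows),
                  n_flap_variants=len(flap_rows))
    if len(wall_rows):
        mean_wall = wall_rows.mean(axis=0)
        report["wall_variant_mean_radial_mmhg"] = mean_wall.tolist()
        report["wall_mean_abs_rel_change"] = float(
            np.mean(np.abs(mean_wall - base_q) / base_q))
        report["wall_spread"] = float(
            np.mean((wall_rows.max(axis=0) - wall_rows.min(axis=0)) / base_q))
    if len(flap_rows):
        allf = np.vstack([flap_rows, base_q])
        report["flap_spread"] = float(
            np.mean((allf.max(axis=0) - allf.min(axis=0)) / base_q))
        report["flap_labels"] = flap_labels
    return report


def run_mesh_convergence(region: str = "mid", p_aorta_mmhg: float = 100.0,
                         h: float = 0.3, ratios=(1.0, 1.5, 2.0),
                         options: SolverOptions = SolverOptions(
                             member_step_mm=0.3, newton_tol=1e-6,
                             flap_drape_bias_mmhg=0.5)) -> dict:
    """Radial pressure at one point across element sizes {h, h/1.5, h/2}."""
    if len(set(ratios)) != len(ratios):
        raise ValueError("refinement ratios must be distinct")
    mats = materials_for_region(region, f"{region}_1")
    geom = geometry_for(region, mats)
    sizes = [h / r for r in ratios]
    qs = []
    for hh in sizes:
        res = run_reapposition(geom, mats, p_aorta_mmhg, options, h=hh)
        qs.append(res.radial_pressure_mmhg)
    finest = qs[-1]
    rel = [abs(q - finest) / finest for q in qs]
    report = dict(region=region, p_aorta_mmhg=p_aorta_mmhg, sizes_mm=sizes,
                  radial_pressures_mmhg=qs, rel_diff_vs_finest=rel,
                  coarse_vs_fine_pct=100.0 * rel[0])
    report["converging"] = bool(np.all(np.diff(rel[:-1]) <= 1e-12) or rel[0] <= 0.025)
    return report


def sweep_to_csv(sweeps, path) -> None:
    pd.concat([s.to_frame() for s in sweeps], ignore_index=True).to_csv(
        path, index=False)


def plot_sweeps(sweeps, path=None):
    """Radial pressure and final diameter vs aortic pressure (one figure)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    for s in sweeps:
        ax1.plot(s.pressures, s.radial_pressures, "o-",
                 label=f"{s.region} {s.flap_label}")
        ax2.plot(s.pressures, s.diameters, "s-")
    ax1.set_xlabel("aortic pressure (mmHg)")
    ax1.set_ylabel("radial re-apposition pressure (mmHg)")
    ax2.set_xlabel("aortic pressure (mmHg)")
    ax2.set_ylabel("final inner diameter (mm)")
    ax1.legend(fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
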