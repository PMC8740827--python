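"""End-to-end processing driver.

Runs the standard reduction sequence — import, spot finding, indexing,
static then scan-varying refinement, integration — per sweep, then joint
symmetry determination (with cosym alignment when several sweeps are
present), scaling, optional delta-CC1/2 filtering, merging and export.
Decisions are deliberately minimal: the driver wires the per-stage modules
together and records what each stage found in an incremental report.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import index as _index
from . import integrate as _integrate
from . import model as _model
from . import post as _post
from . import refine as _refine
from . import scale as _scale
from . import spotfind as _spotfind
from . import symmetry as _symmetry
from .reflections import INDEXED, ReflectionTable


@dataclass
class PipelineConfig:
    space_group: str | None = None
    unit_cell: tuple | None = None
    anomalous: bool = False
    d_min: float | None = None
    failover: bool = False
    multi_sweep_indexing: bool = False
    filtering: str | None = None  # "deltacchalf" or None
    exclude_images: list = field(default_factory=list)  # (dataset, start, end)
    scan_varying: bool = True
    profile_fitting: bool = True
    seed: int = 0
    min_spot_size: int = 3


def validate_config(config):
    """Enforce invariants and normalize: a unit cell requires a space group."""
    if config.unit_cell is not None and config.space_group is None:
        raise ValueError("if the unit cell is given, the space group must also be given")
    if config.space_group is not None:
        from .simulate import SUPPORTED_SPACE_GROUPS

        if config.space_group not in SUPPORTED_SPACE_GROUPS:
            raise ValueError(
                f"unsupported space group '{config.space_group}'"
            )
    return config


@dataclass
class SweepResult:
    experiment: object
    strong: ReflectionTable
    integrated: ReflectionTable | None
    profile_model: object
    refine_result: object
    error: str | None = None


def process_sweep(experiment, images, config):
    """Spot finding through integration for one sweep (no symmetry yet)."""
    params = _spotfind.SpotFindParams(min_spot_size=config.min_spot_size,
                                      d_min=config.d_min)
    strong = _spotfind.find_spots(experiment, images, params)
    strong = _spotfind.filter_spots(strong, d_min=config.d_min,
                                    min_spot_size=config.min_spot_size)
    if len(strong) < 20:
        raise RuntimeError(f"too few strong spots ({len(strong)})")

    crystals, table, info = _index.index(
        experiment, strong, _index.IndexParams(space_group="P1")
    )
    crystal = crystals[0]
    if config.space_group is not None:
        # constrain to the declared symmetry setting right away
        cands = _index.bravais_candidates(crystal, max_delta=2.0)
        want = _refine.SYSTEM_OF_SG[config.space_group]
        match = [c for c in cands
                 if _index._SYSTEM_OF_BRAVAIS[c.bravais_symbol] == want]
        if match:
            table, crystal = _index.reindex(table, crystal, match[0].transform)
        crystal = _model.Crystal(A=crystal.A_matrix, space_group=config.space_group)

    expt = replace(experiment, crystal=crystal)
    expt, static_res = _refine.static_refine(expt, table)
    refine_res = static_res
    if config.scan_varying:
        try:
            expt, refine_res = _refine.scan_varying_refine(expt, table)
        except Exception as err:
            warnings.warn(f"scan-varying refinement failed ({err}); keeping static")

    # re-index strong spots against the refined model for bookkeeping
    hkl, ok, _ = _index.assign_indices(
        expt.crystal.A_matrix, _index.map_to_reciprocal(expt, table)
    )
    table.set_hkl(hkl)
    table["flags"] = table["flags"] & ~INDEXED
    table.set_flags(ok, INDEXED)

    integrated, pm = _integrate.integrate(
        expt, images, strong_table=table, d_min=config.d_min,
        profile_fitting=config.profile_fitting,
    )
    integrated["id"] = 0
    integrated["phi_deg"] = integrated["phi_cal_deg"]
    if "z_frame" not in integrated:
        integrated["z_frame"] = integrated["z_cal_frame"]
    return SweepResult(
        experiment=expt, strong=table, integrated=integrated,
        profile_model=pm, refine_result=refine_res,
    ), info


def run_pipeline(experiments, image_stacks, config=None, out_dir=None):
    """Process one or more sweeps end to end.

    ``experiments``: crystal-free Experiment models; ``image_stacks``: the
    matching pixel arrays.  Returns a result dict with per-sweep products,
    the symmetry decision, scaling models, merged data and the report.
    """
    config = validate_config(config or PipelineConfig())
    if not isinstance(experiments, (list, tuple)):
        experiments = [experiments]
        image_stacks = [image_stacks]

    sweeps, errors, index_infos = [], [], []
    for i, (e, imgs) in enumerate(zip(experiments, image_stacks)):
        try:
            res, info = process_sweep(e, imgs, config)
            res.integrated["id"] = i
            sweeps.append(res)
            index_infos.append(info)
        except Exception as err:
            if config.failover:
                errors.append((i, str(err)))
                warnings.warn(f"sweep {i} failed: {err}")
            else:
                raise
    if not sweeps:
        raise RuntimeError(
            "all sweeps failed: " + "; ".join(f"{i}: {m}" for i, m in errors)
        )

    tables = [s.integrated for s in sweeps]

    # cosym alignment across sweeps
    cosym_ops = None
    if len(sweeps) >= 2:
        cell0 = sweeps[0].experiment.crystal.cell
        try:
            cosym_ops, _obj = _symmetry.cosym_align(
                tables, cell=cell0, seed=config.seed
            )
            for i, (t, op) in enumerate(zip(tables, cosym_ops)):
                t2, cr2 = _index.reindex(t, sweeps[i].experiment.crystal, op)
                tables[i] = t2
                sweeps[i].experiment = replace(sweeps[i].experiment, crystal=cr2)
        except Exception as err:
            warnings.warn(f"cosym alignment failed: {err}")

    # symmetry determination on the pooled data
    if config.space_group is None:
        cell0 = sweeps[0].experiment.crystal.cell
        elements = _symmetry.lattice_group_elements(cell0)
        pooled = ReflectionTable.concat(tables)
        scores = _symmetry.score_all_elements(pooled, elements=elements,
                                              seed=config.seed)
        subgroup = _symmetry.choose_subgroup(scores)
        new_tables = []
        for i, t in enumerate(tables):
            t2, cr2, laue, acentric = _symmetry.apply_symmetry(
                t, sweeps[i].experiment.crystal, subgroup
            )
            new_tables.append(t2)
            sweeps[i].experiment = replace(sweeps[i].experiment, crystal=cr2)
        tables = new_tables
        space_group = sweeps[0].experiment.crystal.space_group
        symmetry_payload = {
            "elements": [
                {
                    "operator": s.element.label, "cc": s.cc, "n": s.n,
                    "z_cc": s.z_cc, "likelihood": s.likelihood,
                    "stars": "*" * s.stars,
                }
                for s in scores
            ],
            "chosen": {"acentric": acentric, "laue": laue,
                       "score": subgroup.score},
        }
    else:
        space_group = config.space_group
        scores = None
        symmetry_payload = {"elements": [],
                            "chosen": {"acentric": space_group,
                                       "laue": _symmetry.LAUE_OF_ACENTRIC.get(
                                           space_group.replace("P", ""), "?")}}

    # exclusions, scaling, optional filtering
    for ds, start, end in config.exclude_images:
        for i, t in enumerate(tables):
            tables[i] = _scale.exclude_images(t, ds, start, end)

    sp = _scale.ScaleParams(space_group=space_group, anomalous=config.anomalous)
    history = []
    kept_ids = list(range(len(tables)))
    if config.filtering == "deltacchalf" and len(tables) >= 3:
        tables, kept_ids, history = _scale.scale_and_filter(
            tables, sp, seed=config.seed
        )
    scaled, models = _scale.scale_datasets(tables, sp)

    stats = _scale.merge_stats(
        scaled, n_bins=8, anomalous=config.anomalous, seed=config.seed,
        space_group=space_group, cell=sweeps[0].experiment.crystal.cell,
    )
    try:
        d_limit, d_flag = _scale.resolution_limit(stats)
    except _scale.ScalingError:
        d_limit, d_flag = None, "unavailable"

    tt = None
    try:
        tt = _post.two_theta_refine(
            [s for s in scaled],
            [sw.experiment for sw in sweeps[: len(scaled)]],
        )
    except Exception as err:
        warnings.warn(f"two-theta refinement failed: {err}")

    merged = _post.merge(scaled, space_group=space_group,
                         anomalous=config.anomalous)

    # delta-CC1/2 diagnostics (reported even when not filtering)
    deltas = []
    try:
        deltas, _cc = _scale.delta_cc_half(
            scaled, seed=config.seed, space_group=space_group,
            anomalous=config.anomalous,
        )
    except Exception:
        pass

    report = _build_report(sweeps, index_infos, symmetry_payload, stats,
                           models, deltas, config)

    result = {
        "sweeps": sweeps,
        "sweep_errors": errors,
        "tables": scaled,
        "kept_ids": kept_ids,
        "space_group": space_group,
        "symmetry": symmetry_payload,
        "scaling_models": models,
        "merge_stats": stats,
        "resolution_limit": (d_limit, d_flag),
        "two_theta": tt,
        "merged": merged,
        "filter_history": history,
        "report": report,
    }

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for i, sw in enumerate(sweeps):
            _model.write_experiment(sw.experiment,
                                    os.path.join(out_dir, f"refined_{i}.expt.json"))
        for i, t in enumerate(scaled):
            t.write(os.path.join(out_dir, f"scaled_{i}.refl"))
        _post.export_hklf4(merged, os.path.join(out_dir, "merged.hkl"))
        for i, (t, sw) in enumerate(zip(scaled, sweeps)):
            _post.export_unmerged_text(
                t, sw.experiment, os.path.join(out_dir, f"unmerged_{i}.txt")
            )
        _post.write_report(report, os.path.join(out_dir, "report.json"))
    return result


def _build_report(sweeps, index_infos, symmetry_payload, stats, models,
                  deltas, config):
    per_image_counts = []
    per_image_frac = []
    for sw in sweeps:
        n_img = sw.experiment.scan.n_images
        z = np.clip(sw.strong["z_frame"].astype(int), 0, n_img - 1)
        counts = np.bincount(z, minlength=n_img)
        indexed = np.bincount(z[sw.strong.get_flags(INDEXED)], minlength=n_img)
        per_image_counts.append(counts.tolist())
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(counts > 0, indexed / np.maximum(counts, 1), 0.0)
        per_image_frac.append(frac.tolist())
    rr = sweeps[0].refine_result
    report = _post.build_report(
        spotfinding={
            "n_spots": int(sum(len(sw.strong) for sw in sweeps)),
            "per_image_spot_count": per_image_counts,
        },
        indexing={
            "fraction_indexed": float(np.mean([i["fraction_indexed"]
                                               for i in index_infos])),
            "per_image_indexed_fraction": per_image_frac,
            "cells": [list(sw.experiment.crystal.cell) for sw in sweeps],
        },
        refinement={
            "rmsd_x_mm": float(rr.rmsd_x_after),
            "rmsd_y_mm": float(rr.rmsd_y_after),
            "rmsd_phi_deg": float(rr.rmsd_phi_after),
        },
        integration={
            "n_integrated": int(sum(len(sw.integrated) for sw in sweeps)),
            "sigma_b_deg": float(sweeps[0].profile_model.sigma_b),
            "sigma_m_deg": float(sweeps[0].profile_model.sigma_m),
        },
        symmetry=symmetry_payload,
        scaling={
            "overall": {k: (None if isinstance(v, float) and not np.isfinite(v)
                            else v)
                        for k, v in stats.overall.items()},
            "bins": stats.bins.to_dict("records"),
            "error_model": {"a": models[0].a, "b": models[0].b},
        },
        delta_cc_half={"groups": [list(d) for d in deltas]},
    )
    return report
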