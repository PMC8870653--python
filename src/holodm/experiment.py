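"""Seeded end-to-end virtual experiment runner.

Composes phantom -> holosim -> recon -> background -> drymass for every
(condition, experiment, FOV, timepoint), then aggregates per-FOV 24-h
increments and compares each treated arm against the single medium
control with the Bonferroni-corrected t-test.  The whole run is a pure
function of the config (master seed included); a failed FOV is logged
and excluded, never imputed.

Also provides :func:`simulate_endpoint_increments`, a fast analytic
endpoint simulator (scenario mass laws plus measurement noise, no
optics) used for power studies over many replicates.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .background import rolling_ball_subtract
from .config import ConditionSpec, ExperimentConfig
from .core import PhaseMap
from .drymass import (
    DryMassSeries,
    compare_conditions,
    dm_course,
    dm_increment,
)
from .errors import ConfigError
from .background import BackgroundParams
from .drymass import DryMassParams
from .holosim import Hologram, OpticalConfig, acquire_timepoint
from .phantom import ScenarioSpec, evolve, random_scene, scenario_mass
from .recon import ReconstructionParams, reconstruct_stack
from .stackio import read_stack, write_phase_stack, write_stack

__all__ = [
    "run_virtual_experiment",
    "process_fov",
    "simulate_holograms",
    "reconstruct_directory",
    "drymass_directory",
    "ball_radius_sensitivity",
    "simulate_endpoint_increments",
]

logger = logging.getLogger(__name__)


def _fov_seed(master: int, cond_idx: int, exp_id: int, fov_id: int) -> int:
    ss = np.random.SeedSequence((int(master), int(cond_idx), int(exp_id), int(fov_id)))
    return int(ss.generate_state(1, dtype=np.uint64)[0])


def _conjugate_for_carrier(carrier: tuple[float, float]) -> bool:
    fx, fy = carrier
    return fx > 0 or (fx == 0 and fy > 0)


def process_fov(
    config: ExperimentConfig,
    condition: ConditionSpec,
    cond_idx: int,
    exp_id: int,
    fov_id: int,
) -> tuple[DryMassSeries, list[PhaseMap]]:
    """Simulate, reconstruct and quantify one FOV's full time course."""
    seed = _fov_seed(config.master_seed, cond_idx, exp_id, fov_id)
    rng = np.random.default_rng(seed)
    scene_kwargs = dict(config.scene_kwargs)
    scene_kwargs.setdefault("shape", config.optical.shape)
    scene_kwargs.setdefault("pixel_pitch_um", config.optical.pixel_pitch_um)
    base = random_scene(rng, **scene_kwargs)
    scenario = dataclasses.replace(condition.scenario, seed=seed % (2**31))

    recon_params = config.recon
    if recon_params.refocus_z_um == 0.0 and config.optical.defocus_um != 0.0:
        recon_params = dataclasses.replace(
            recon_params, refocus_z_um=-config.optical.defocus_um
        )
    conjugate = _conjugate_for_carrier(config.optical.carrier_cyc_per_px)

    maps: list[PhaseMap] = []
    for t in config.timepoints_h:
        scene_t = evolve(base, scenario, t, config.drymass.alpha_ml_per_g)
        holos = acquire_timepoint(scene_t, config.optical, t, seed)
        pm = reconstruct_stack(holos, recon_params, conjugate=conjugate)
        pm = rolling_ball_subtract(pm, config.background)
        pm.time_h = t
        maps.append(pm)
    series = dm_course(
        maps,
        config.drymass,
        condition=condition.name,
        concentration_ug_per_ml=condition.concentration_ug_per_ml,
        fov_id=fov_id,
        experiment_id=exp_id,
    )
    return series, maps


def _courses_frame(courses: list[DryMassSeries]) -> pd.DataFrame:
    rows = []
    for s in courses:
        for t, m in zip(s.times_h, s.mass_ng):
            rows.append(
                {
                    "experiment": s.experiment_id,
                    "condition": s.condition,
                    "concentration_ug_per_ml": s.concentration_ug_per_ml,
                    "fov_id": s.fov_id,
                    "time_h": t,
                    "dry_mass_ng": m,
                }
            )
    return pd.DataFrame(rows)


def _plot_outputs(
    outdir: Path, courses: list[DryMassSeries], increments: pd.DataFrame
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    frame = _courses_frame(courses)
    for name, grp in frame.groupby("condition"):
        mean = grp.groupby("time_h")["dry_mass_ng"].mean()
        ax.plot(mean.index, mean.values, marker="o", ms=3, label=str(name))
    ax.set_xlabel("time (h)")
    ax.set_ylabel("dry mass (ng)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(outdir / "dry_mass_courses.png", dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    labels = list(dict.fromkeys(increments["condition"]))
    for i, name in enumerate(labels):
        vals = increments.loc[increments["condition"] == name, "increment_ng"]
        jitter = np.linspace(-0.15, 0.15, len(vals))
        ax.plot(i + jitter, vals, "o", ms=4)
    ax.axhline(0.0, color="0.6", lw=0.8)
    ax.set_xticks(range(len(labels)), labels, rotation=30, ha="right", fontsize=8)
    ax.set_ylabel("24-h dry mass increment (ng)")
    fig.tight_layout()
    fig.savefig(outdir / "dry_mass_increments.png", dpi=150)
    plt.close(fig)


def run_virtual_experiment(config: ExperimentConfig, outdir: str | Path) -> Path:
    """Run the full virtual experiment; returns the result directory.

    Writes ``courses.csv`` (one row per FOV sample), ``increments.csv``
    (one row per FOV), ``stats.csv`` (one row per treated arm vs the
    control), a reproducibility ``manifest.json``, optional TIFF stacks
    and plots.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    courses: list[DryMassSeries] = []
    failed: list[dict[str, Any]] = []
    for cond_idx, condition in enumerate(config.conditions):
        for exp_id in range(1, config.n_experiments + 1):
            for fov_id in range(1, config.fovs_per_condition + 1):
                try:
                    series, maps = process_fov(
                        config, condition, cond_idx, exp_id, fov_id
                    )
                except Exception as exc:
                    logger.error(
                        "FOV failed (condition=%s exp=%d fov=%d): %s",
                        condition.name, exp_id, fov_id, exc,
                    )
                    failed.append(
                        {
                            "condition": condition.name,
                            "experiment": exp_id,
                            "fov_id": fov_id,
                            "error": str(exc),
                        }
                    )
                    continue
                courses.append(series)
                if config.save_phase_maps:
                    write_phase_stack(
                        outdir
                        / "phase"
                        / f"{condition.name}_e{exp_id}_f{fov_id}.tif",
                        maps,
                        condition=condition.name,
                        concentration_ug_per_ml=condition.concentration_ug_per_ml,
                        experiment=exp_id,
                        fov_id=fov_id,
                    )
    if config.save_holograms:
        simulate_holograms(config, outdir / "holograms")

    frame = _courses_frame(courses)
    frame.to_csv(outdir / "courses.csv", index=False)

    t_end = float(config.timepoints_h[-1])
    inc_rows = []
    for s in courses:
        inc_rows.append(
            {
                "experiment": s.experiment_id,
                "condition": s.condition,
                "concentration_ug_per_ml": s.concentration_ug_per_ml,
                "fov_id": s.fov_id,
                "increment_ng": dm_increment(s, t_end_h=t_end),
            }
        )
    increments = pd.DataFrame(inc_rows)
    increments.to_csv(outdir / "increments.csv", index=False)

    control_name = config.control.name
    treated_arms = [c for c in config.conditions if not c.is_control]
    ctrl = increments.loc[
        increments["condition"] == control_name, "increment_ng"
    ].to_numpy()
    stats_rows = []
    for arm in treated_arms:
        vals = increments.loc[
            increments["condition"] == arm.name, "increment_ng"
        ].to_numpy()
        if len(vals) < 2 or len(ctrl) < 2:
            logger.warning("too few FOVs to test arm %s", arm.name)
            continue
        st = compare_conditions(
            vals,
            ctrl,
            n_comparisons=max(1, len(treated_arms)),
            condition=arm.name,
            concentration_ug_per_ml=arm.concentration_ug_per_ml,
        )
        stats_rows.append(
            {
                "condition": st.condition,
                "concentration_ug_per_ml": st.concentration_ug_per_ml,
                "n": len(vals),
                "mean_ng": st.mean_ng,
                "std_ng": st.std_ng,
                "control_mean_ng": st.control_mean_ng,
                "control_std_ng": st.control_std_ng,
                "t_statistic": st.t_statistic,
                "p_value": st.p_value,
                "p_adjusted": st.p_adjusted,
                "stars": st.stars,
            }
        )
    pd.DataFrame(stats_rows).to_csv(outdir / "stats.csv", index=False)

    manifest = {
        "config": config.to_dict(),
        "master_seed": config.master_seed,
        "failed_fovs": failed,
        "versions": {
            "holodm": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    if config.make_plots and courses:
        try:
            _plot_outputs(outdir, courses, increments)
        except Exception as exc:  # plotting must never fail the run
            logger.warning("plotting failed: %s", exc)
    return outdir


def ball_radius_sensitivity(
    maps: list[PhaseMap],
    radii: list[int],
    dm_params: DryMassParams | None = None,
    base: BackgroundParams | None = None,
) -> pd.DataFrame:
    """Diagnostic: dry-mass increment of one FOV course vs rolling-ball radius.

    The assay's exact ball radius is a fixed-but-unpublished choice, so
    the sensitivity of the endpoint to it is reported rather than
    guessed.  ``maps`` are the *uncorrected* time-ordered phase maps of
    one FOV (must span t = 0 and the endpoint).
    """
    from .drymass import phase_map_dry_mass

    dm_params = dm_params or DryMassParams()
    base = base or BackgroundParams()
    rows = []
    for radius in radii:
        params = dataclasses.replace(base, ball_radius_px=int(radius))
        corrected = [rolling_ball_subtract(m, params) for m in maps]
        masses = [phase_map_dry_mass(m, dm_params) for m in corrected]
        rows.append(
            {
                "ball_radius_px": int(radius),
                "dm_start_ng": masses[0],
                "dm_end_ng": masses[-1],
                "increment_ng": masses[-1] - masses[0],
            }
        )
    return pd.DataFrame(rows)


def simulate_endpoint_increments(
    scenario: ScenarioSpec,
    n_experiments: int = 3,
    fovs_per_experiment: int = 4,
    m0_ng: float = 2.0,
    m0_cv: float = 0.10,
    noise_sd_ng: float = 0.15,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Analytic per-FOV 24-h increments for one arm (no optics).

    Each FOV draws a baseline mass ``m0_ng * (1 + cv * N(0,1))``, follows
    the scenario mass law exactly, and both endpoint samples receive
    independent measurement noise — the fast path for power studies.
    """
    if n_experiments < 1 or fovs_per_experiment < 1:
        raise ConfigError("need at least one experiment and one FOV")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for _ in range(n_experiments * fovs_per_experiment):
        m0 = m0_ng * max(1.0 + m0_cv * rng.standard_normal(), 0.05)
        m_start = sum(scenario_mass(scenario, 0.0, m0))
        m_end = sum(scenario_mass(scenario, 24.0, m0))
        noise = noise_sd_ng * rng.standard_normal(2)
        out.append((m_end + noise[1]) - (m_start + noise[0]))
    return np.asarray(out)


def simulate_holograms(config: ExperimentConfig, outdir: str | Path) -> list[Path]:
    """Write the raw hologram stacks of the virtual experiment to TIFF."""
    outdir = Path(outdir)
    paths: list[Path] = []
    for cond_idx, condition in enumerate(config.conditions):
        for exp_id in range(1, config.n_experiments + 1):
            for fov_id in range(1, config.fovs_per_condition + 1):
                seed = _fov_seed(config.master_seed, cond_idx, exp_id, fov_id)
                rng = np.random.default_rng(seed)
                sk = dict(config.scene_kwargs)
                sk.setdefault("shape", config.optical.shape)
                sk.setdefault("pixel_pitch_um", config.optical.pixel_pitch_um)
                base = random_scene(rng, **sk)
                scenario = dataclasses.replace(condition.scenario, seed=seed % (2**31))
                for t in config.timepoints_h:
                    scene_t = evolve(base, scenario, t, config.drymass.alpha_ml_per_g)
                    holos = acquire_timepoint(scene_t, config.optical, t, seed)
                    path = write_stack(
                        outdir / f"{condition.name}_e{exp_id}_f{fov_id}_t{t:06.2f}.tif",
                        [h.intensity for h in holos],
                        {
                            "kind": "hologram",
                            "pixel_pitch_um": config.optical.pixel_pitch_um,
                            "wavelength_nm": config.optical.wavelength_nm,
                            "time_h": t,
                            "condition": condition.name,
                            "concentration_ug_per_ml": condition.concentration_ug_per_ml,
                            "experiment": exp_id,
                            "fov_id": fov_id,
                            "optical": config.optical.to_dict(),
                        },
                    )
                    paths.append(path)
    return paths


def reconstruct_directory(
    indir: str | Path,
    outdir: str | Path,
    recon: ReconstructionParams | None = None,
    background: BackgroundParams | None = None,
    apply_background: bool = True,
) -> list[Path]:
    """Reconstruct every hologram TIFF stack in ``indir`` to a phase TIFF."""
    indir, outdir = Path(indir), Path(outdir)
    paths: list[Path] = []
    for tif in sorted(indir.glob("*.tif")):
        stack, meta = read_stack(tif)
        optical = (
            OpticalConfig.from_dict(meta["optical"]) if "optical" in meta else None
        )
        params = recon or ReconstructionParams(
            wavelength_nm=float(meta.get("wavelength_nm", 532.0)),
            pixel_pitch_um=float(meta["pixel_pitch_um"]),
        )
        conjugate: bool | str = "auto"
        if optical is not None:
            if params.refocus_z_um == 0.0 and optical.defocus_um != 0.0:
                params = dataclasses.replace(params, refocus_z_um=-optical.defocus_um)
            conjugate = _conjugate_for_carrier(optical.carrier_cyc_per_px)
            holos = [
                Hologram(frame, optical, time_h=float(meta.get("time_h", 0.0)), frame_index=i)
                for i, frame in enumerate(stack)
            ]
            pm = reconstruct_stack(holos, params, conjugate=conjugate)
        else:
            pm = reconstruct_stack(
                [
                    Hologram(
                        frame,
                        OpticalConfig(
                            wavelength_nm=params.wavelength_nm,
                            pixel_pitch_um=params.pixel_pitch_um,
                            shape=frame.shape,
                        ),
                        time_h=float(meta.get("time_h", 0.0)),
                        frame_index=i,
                    )
                    for i, frame in enumerate(stack)
                ],
                params,
                conjugate=conjugate,
            )
        if apply_background:
            pm = rolling_ball_subtract(pm, background or BackgroundParams())
        pm.time_h = float(meta.get("time_h", 0.0))
        paths.append(
            write_phase_stack(
                outdir / tif.name,
                [pm],
                condition=meta.get("condition", ""),
                concentration_ug_per_ml=meta.get("concentration_ug_per_ml", 0.0),
                experiment=meta.get("experiment", 0),
                fov_id=meta.get("fov_id", 0),
            )
        )
    return paths


def drymass_directory(
    indir: str | Path,
    params: DryMassParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dry-mass courses and 24-h increments from a directory of phase TIFFs.

    Phase maps are grouped into FOV time courses by their (condition,
    experiment, fov_id) metadata; returns (courses, increments) frames.
    """
    from .stackio import read_phase_stack

    indir = Path(indir)
    params = params or DryMassParams()
    groups: dict[tuple, list[PhaseMap]] = {}
    labels: dict[tuple, dict[str, Any]] = {}
    for tif in sorted(indir.glob("*.tif")):
        maps, meta = read_phase_stack(tif)
        key = (
            str(meta.get("condition", "")),
            int(meta.get("experiment", 0)),
            int(meta.get("fov_id", 0)),
        )
        groups.setdefault(key, []).extend(maps)
        labels[key] = {
            "concentration_ug_per_ml": float(meta.get("concentration_ug_per_ml", 0.0))
        }
    courses = []
    for key, maps in sorted(groups.items()):
        maps = sorted(maps, key=lambda m: m.time_h if m.time_h is not None else 0.0)
        courses.append(
            dm_course(
                maps,
                params,
                condition=key[0],
                concentration_ug_per_ml=labels[key]["concentration_ug_per_ml"],
                experiment_id=key[1],
                fov_id=key[2],
            )
        )
    frame = _courses_frame(courses)
    t_end = max((float(s.times_h[-1]) for s in courses), default=24.0)
    inc_rows = [
        {
            "experiment": s.experiment_id,
            "condition": s.condition,
            "concentration_ug_per_ml": s.concentration_ug_per_ml,
            "fov_id": s.fov_id,
            "increment_ng": dm_increment(s, t_end_h=t_end),
        }
        for s in courses
    ]
    return frame, pd.DataFrame(inc_rows)
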