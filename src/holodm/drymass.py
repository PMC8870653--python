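"""Dry-mass quantification and endpoint statistics.

The population dry mass in the FOV is

    dm = lambda / (2 pi alpha) * mean_phase * S_FOV

with lambda the wavelength, alpha the specific refractive increment
(0.19 mL/g = 0.19 um^3/pg for cellular protein) and S_FOV the FOV area.
The mean phase runs over *all* pixels of the background-corrected map
(cell and background alike).  Time courses per FOV yield the 24-h
increment dm(24 h) - dm(0 h) — negative under lysis — which is compared
across conditions with a two-sided two-sample t-test, Bonferroni
correction, and the star convention p < 0.005 (***), p < 0.01 (**),
p < 0.05 (*) on the adjusted p.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .core import PhaseMap
from .errors import ConfigError, DataError

__all__ = [
    "DryMassParams",
    "DryMassSeries",
    "IncrementStats",
    "fov_area",
    "mean_phase",
    "dry_mass",
    "phase_map_dry_mass",
    "dm_course",
    "dm_increment",
    "star_label",
    "compare_conditions",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DryMassParams:
    """Constants of the phase-to-mass conversion."""

    wavelength_nm: float = 532.0
    alpha_ml_per_g: float = 0.19
    fov_area_um2: float | None = None  #: None -> derive from the map grid

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ConfigError("wavelength must be > 0")
        if self.alpha_ml_per_g <= 0:
            raise ConfigError("alpha must be > 0")
        if self.fov_area_um2 is not None and self.fov_area_um2 <= 0:
            raise ConfigError("FOV area must be > 0")

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    @classmethod
    def from_dict(cls, d: dict) -> "DryMassParams":
        return cls(**d)


def fov_area(width_um: float, height_um: float) -> float:
    """FOV area in um^2 (e.g. 450 x 338 -> 152,100)."""
    if width_um <= 0 or height_um <= 0:
        raise ConfigError("FOV dimensions must be > 0")
    return width_um * height_um


def mean_phase(phase: PhaseMap) -> float:
    """Arithmetic mean phase over every pixel of the FOV, in radians."""
    if phase.values.size == 0:
        raise DataError("cannot average an empty phase raster")
    return float(phase.values.mean())


def dry_mass(mean_phase_rad: float, params: DryMassParams) -> float:
    """Population dry mass in ng from the FOV-mean phase shift.

    Units: wavelength nm -> um; alpha mL/g == um^3/pg; area um^2;
    lambda/(2 pi alpha) is then pg/um^2 per radian and the result is
    converted pg -> ng.
    """
    if params.fov_area_um2 is None:
        raise ConfigError("fov_area_um2 is required (or use phase_map_dry_mass)")
    lam_um = params.wavelength_nm / 1000.0
    pg = lam_um / (2.0 * math.pi * params.alpha_ml_per_g) * mean_phase_rad * params.fov_area_um2
    return pg / 1000.0


def phase_map_dry_mass(phase: PhaseMap, params: DryMassParams) -> float:
    """Dry mass of one phase map; S_FOV defaults to the map's own grid area."""
    area = params.fov_area_um2 if params.fov_area_um2 is not None else phase.fov_area_um2
    p = DryMassParams(params.wavelength_nm, params.alpha_ml_per_g, area)
    return dry_mass(mean_phase(phase), p)


@dataclass
class DryMassSeries:
    """Per-FOV dry-mass time course (times in h, masses in ng)."""

    times_h: np.ndarray
    mass_ng: np.ndarray
    condition: str = ""
    concentration_ug_per_ml: float = 0.0
    fov_id: int = 0
    experiment_id: int = 0

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.mass_ng = np.asarray(self.mass_ng, dtype=float)
        if self.times_h.shape != self.mass_ng.shape:
            raise ConfigError("times and masses must have equal length")
        if np.any(np.diff(self.times_h) <= 0):
            raise ConfigError("sample times must be strictly increasing")


def dm_course(
    maps: list[PhaseMap],
    params: DryMassParams,
    condition: str = "",
    concentration_ug_per_ml: float = 0.0,
    fov_id: int = 0,
    experiment_id: int = 0,
) -> DryMassSeries:
    """Dry-mass time course from time-ordered phase maps of one FOV."""
    if len(maps) < 2:
        raise ConfigError("a dry-mass course needs at least two timepoints")
    first = maps[0]
    for m in maps:
        if not first.same_geometry(m):
            raise DataError("inconsistent phase-map geometry across timepoints")
        if m.time_h is None:
            raise DataError("phase map is missing its acquisition time")
    times = np.array([m.time_h for m in maps], dtype=float)
    mass = np.array([phase_map_dry_mass(m, params) for m in maps])
    return DryMassSeries(
        times, mass, condition, concentration_ug_per_ml, fov_id, experiment_id
    )


def dm_increment(series: DryMassSeries, t_end_h: float = 24.0, atol: float = 1e-6) -> float:
    """24-h increment dm(t_end) - dm(0); negative under lysis (no clipping)."""
    t = series.times_h
    i0 = np.where(np.isclose(t, 0.0, atol=atol))[0]
    i1 = np.where(np.isclose(t, t_end_h, atol=atol))[0]
    if len(i0) == 0 or len(i1) == 0:
        raise DataError(
            f"series lacks samples at t = 0 and t = {t_end_h} h (has {t.min()}..{t.max()})"
        )
    return float(series.mass_ng[i1[0]] - series.mass_ng[i0[0]])


def star_label(p_adjusted: float) -> str:
    """Printed significance-star convention, applied to the adjusted p."""
    if p_adjusted < 0.005:
        return "***"
    if p_adjusted < 0.01:
        return "**"
    if p_adjusted < 0.05:
        return "*"
    return "ns"


@dataclass
class IncrementStats:
    """Endpoint comparison of one treated arm against the control arm."""

    treated_increments_ng: np.ndarray
    control_increments_ng: np.ndarray
    mean_ng: float
    std_ng: float
    control_mean_ng: float
    control_std_ng: float
    t_statistic: float
    p_value: float
    p_adjusted: float
    stars: str
    n_comparisons: int = 1
    condition: str = ""
    concentration_ug_per_ml: float = 0.0
    pretest_p: float | None = field(default=None, repr=False)


def compare_conditions(
    treated: np.ndarray,
    control: np.ndarray,
    n_comparisons: int = 1,
    condition: str = "",
    concentration_ug_per_ml: float = 0.0,
    variance_pretest: bool = True,
) -> IncrementStats:
    """Two-sided two-sample Student's t-test with Bonferroni correction.

    The optional variance-homogeneity pre-test (Levene) only logs a
    warning and never changes the reported test.  Two zero-variance
    groups with equal means yield p = 1 by contract.
    """
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if treated.size < 2 or control.size < 2:
        raise ConfigError("each group needs at least two increments")
    if n_comparisons < 1:
        raise ConfigError("n_comparisons must be >= 1")

    pretest_p: float | None = None
    if variance_pretest and (treated.std() > 0 or control.std() > 0):
        try:
            pretest_p = float(sps.levene(treated, control).pvalue)
            if pretest_p < 0.05:
                logger.warning(
                    "variance-homogeneity pre-test p = %.3g < 0.05; "
                    "reporting the standard t-test regardless", pretest_p,
                )
        except Exception:  # degenerate inputs
            pretest_p = None

    if treated.std(ddof=1) == 0.0 and control.std(ddof=1) == 0.0:
        if np.isclose(treated.mean(), control.mean()):
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = math.inf * np.sign(treated.mean() - control.mean()), 0.0
    else:
        res = sps.ttest_ind(treated, control, equal_var=True)
        t_stat, p = float(res.statistic), float(res.pvalue)

    p_adj = min(1.0, p * n_comparisons)
    return IncrementStats(
        treated_increments_ng=treated,
        control_increments_ng=control,
        mean_ng=float(treated.mean()),
        std_ng=float(treated.std(ddof=1)),
        control_mean_ng=float(control.mean()),
        control_std_ng=float(control.std(ddof=1)),
        t_statistic=t_stat,
        p_value=p,
        p_adjusted=p_adj,
        stars=star_label(p_adj),
        n_comparisons=n_comparisons,
        condition=condition,
        concentration_ug_per_ml=concentration_ug_per_ml,
        pretest_p=pretest_p,
    )
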