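"""Phantom subjects for every downstream stage of the pipeline.

Patient data behind this kind of study are not publicly deposited, so the
package ships a generator that emulates their statistical structure:

* baseline chromophore compositions drawn per menopausal group from
  truncated normals whose means/SDs reproduce the published group summary
  statistics (premenopausal n = 17, postmenopausal n = 11);
* neoadjuvant-chemotherapy (NAC) trajectories expressed as percent change
  from baseline, anchored at day 90 and interpolated linearly from day 0;
* rectangular 10-mm optical measurement grids with an areolar region of
  higher water/hemoglobin and lower lipid, forward-modeled through
  :mod:`dosidensity.tissue_optics` with multiplicative amplitude noise and
  additive phase noise;
* axial T1-weighted MRI phantoms — half-ellipsoid breast on a thorax band,
  embedded fibroglandular compartment hitting a target volume fraction,
  skin rim, smooth multiplicative bias field, additive noise — with ground
  truth stored alongside;
* longitudinal cohorts (subjects × visits) with visit-day jitter inside the
  published interval ranges and per-interval attendance, written as tidy
  CSV.

All generators are pure functions of (configuration, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .tissue_optics import (
    BroadbandReflectance,
    ExtinctionTable,
    FDGeometry,
    FDMeasurement,
    OpticalProperties,
    ScatterPowerFit,
    TissueComposition,
    fd_reflectance,
    mua_from_composition,
    steady_state_reflectance,
)

__all__ = [
    "PRE", "POST",
    "GroupParameters", "NacTrajectory", "GridSpec", "NoiseModel", "GridScan",
    "MriPhantomSpec", "MriPhantom", "CohortConfig",
    "BASELINE_PRE", "BASELINE_POST", "DEFAULT_TRAJECTORY", "DEFAULT_AREOLA",
    "sample_baseline", "apply_trajectory", "generate_grid_scan",
    "generate_mri_phantom", "generate_cohort",
    "write_grid_scan", "read_grid_scan", "write_cohort", "read_cohort",
    "save_phantom",
]

PRE = "premenopausal"
POST = "postmenopausal"

_PARAMS = ("ct_hhb", "ct_o2hb", "water", "lipid")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class GroupParameters:
    """Baseline chromophore distribution of one menopausal group.

    ``means`` and ``ses`` map parameter name -> group mean and standard
    error; the sampling SD is recovered as ``SE * sqrt(n)`` because only
    standard errors of the group means are published.
    """

    group: str
    means: Mapping[str, float]
    ses: Mapping[str, float]
    n: int

    def __post_init__(self) -> None:
        if self.group not in (PRE, POST):
            raise ValueError(f"unknown group {self.group!r}")
        for p in _PARAMS:
            if p not in self.means or p not in self.ses:
                raise ValueError(f"missing parameter {p!r}")
            if self.ses[p] < 0:
                raise ValueError("standard errors must be non-negative")

    def sd(self, param: str) -> float:
        return self.ses[param] * math.sqrt(self.n)


#: published baseline summaries: mean (SE) per group
BASELINE_PRE = GroupParameters(
    group=PRE,
    means={"water": 24.4, "lipid": 67.0, "ct_o2hb": 18.9, "ct_hhb": 5.3},
    ses={"water": 1.8, "lipid": 1.6, "ct_o2hb": 1.7, "ct_hhb": 0.2},
    n=17,
)
BASELINE_POST = GroupParameters(
    group=POST,
    means={"water": 16.6, "lipid": 74.0, "ct_o2hb": 16.6, "ct_hhb": 4.5},
    ses={"water": 0.7, "lipid": 1.4, "ct_o2hb": 1.5, "ct_hhb": 0.2},
    n=11,
)

#: areolar tissue is a concentrated fibroglandular region: more water and
#: hemoglobin, less lipid than the surrounding breast
DEFAULT_AREOLA = TissueComposition(ct_hhb=8.0, ct_o2hb=28.0, water=45.0, lipid=40.0)


@dataclass(frozen=True)
class NacTrajectory:
    """Percent change from baseline during NAC, anchored at day 90.

    ``pct_day90[group][param]`` is the estimated percent change at the
    day-90 anchor.  Between day 0 (change 0 by definition) and ``day_ref``
    the change ramps linearly; after ``day_ref`` it is held constant.
    The ``st_o2`` entries are the published day-90 estimates for oxygen
    saturation; they are carried for users modeling stO2 percent change
    directly, but the composition generator derives stO2 from the sampled
    hemoglobins rather than scaling it independently.
    """

    pct_day90: Mapping[str, Mapping[str, float]]
    day_ref: float = 90.0

    def pct(self, group: str, param: str, day: float) -> float:
        if day < 0:
            raise ValueError("day must be non-negative")
        anchor = self.pct_day90[group].get(param, 0.0)
        return anchor * min(day, self.day_ref) / self.day_ref


DEFAULT_TRAJECTORY = NacTrajectory(
    pct_day90={
        PRE: {"water": -11.9, "ct_o2hb": -20.0, "ct_hhb": -2.5,
              "lipid": 3.8, "st_o2": -6.9},
        POST: {"water": 4.4, "ct_o2hb": -20.1, "ct_hhb": 0.5,
               "lipid": -0.4, "st_o2": -7.4},
    }
)


def sample_baseline(
    params: GroupParameters, seed, sum_cap: float | None = None
) -> TissueComposition:
    """Draw one baseline composition from independent truncated normals.

    Concentrations are truncated at zero and water/lipid at [0, 100]
    marginally.  With all SDs equal to zero the group means are returned
    exactly, and sample means converge to the configured group means.

    ``sum_cap`` optionally redraws the (water, lipid) pair until their sum
    stays below the cap.  It is off by default: at the published group
    means (~91 % combined) and SDs, joint rejection at 100 % trims the
    upper tail hard enough to bias both means noticeably — with
    independent draws one can have faithful means or a strict sum bound,
    not both, and the generator favors the means its consumers calibrate
    against.
    """
    rng = _rng(seed)

    def draw(param, lo, hi):
        mean, sd = params.means[param], params.sd(param)
        if sd == 0:
            return float(np.clip(mean, lo, hi))
        for _ in range(1000):
            v = rng.normal(mean, sd)
            if lo <= v <= hi:
                return float(v)
        raise RuntimeError("truncated normal rejection failed")  # pragma: no cover

    ct_hhb = draw("ct_hhb", 0.0, np.inf)
    ct_o2hb = draw("ct_o2hb", 0.0, np.inf)
    for _ in range(1000):
        water = draw("water", 0.0, 100.0)
        lipid = draw("lipid", 0.0, 100.0)
        if sum_cap is None or water + lipid <= sum_cap:
            return TissueComposition(ct_hhb, ct_o2hb, water, lipid)
    raise RuntimeError("water+lipid constraint rejection failed")  # pragma: no cover


def apply_trajectory(
    baseline: TissueComposition, traj: NacTrajectory, group: str, day: float
) -> TissueComposition:
    """Scale each chromophore by its group trajectory at the given day."""
    if day < 0:
        raise ValueError("day must be non-negative")
    values = {
        p: getattr(baseline, p) * (1.0 + traj.pct(group, p, day) / 100.0)
        for p in _PARAMS
    }
    return TissueComposition(**values)


@dataclass(frozen=True)
class GridSpec:
    """Rectangular measurement grid with 10-mm spacing and an areola set."""

    rows: int
    cols: int
    spacing: float = 10.0
    areola: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one row and column")
        if not self.spacing > 0:
            raise ValueError("grid spacing must be positive")
        areola = frozenset((int(r), int(c)) for r, c in self.areola)
        for r, c in areola:
            if not (0 <= r < self.rows and 0 <= c < self.cols):
                raise ValueError(f"areola position {(r, c)} outside grid")
        object.__setattr__(self, "areola", areola)

    def positions(self):
        return [(r, c) for r in range(self.rows) for c in range(self.cols)]

    def areola_mask(self) -> np.ndarray:
        mask = np.zeros((self.rows, self.cols), dtype=bool)
        for r, c in self.areola:
            mask[r, c] = True
        return mask


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise: multiplicative on amplitudes, additive on phase.

    Defaults reflect instrument-level repeatability: 1 % amplitude noise,
    0.1 degree phase noise, 1 % broadband reflectance noise.
    """

    amplitude_frac: float = 0.01
    phase_sd: float = math.radians(0.1)
    broadband_frac: float = 0.01

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0)


@dataclass
class GridScan:
    """One optical scan: per-position FD measurements and broadband spectra."""

    spec: GridSpec
    geometry: FDGeometry
    fd: dict          # (row, col) -> FDMeasurement
    broadband: dict   # (row, col) -> BroadbandReflectance
    truth: dict | None = None          # (row, col) -> TissueComposition
    scatter_truth: ScatterPowerFit | None = None

    def areola_mask(self) -> np.ndarray:
        return self.spec.areola_mask()


DEFAULT_SCATTER = ScatterPowerFit(amplitude=1.0, power=0.6, lambda0=650.0)


def generate_grid_scan(
    composition_field,
    areola_composition: TissueComposition | None,
    spec: GridSpec,
    geometry: FDGeometry | None = None,
    noise_model: NoiseModel | None = None,
    seed=0,
    *,
    scatter: ScatterPowerFit = DEFAULT_SCATTER,
    table: ExtinctionTable | None = None,
    broadband_wavelengths=None,
) -> GridScan:
    """Forward-model a rectangular grid scan.

    ``composition_field`` is either a single :class:`TissueComposition`
    (homogeneous breast) or a callable ``(row, col) -> TissueComposition``.
    Areolar positions use ``areola_composition`` instead.  Each position is
    run through the frequency-domain model at the laser wavelengths and the
    steady-state model over the broadband grid, then corrupted per
    ``noise_model``.  Deterministic for a fixed seed.
    """
    geometry = geometry or FDGeometry()
    noise_model = noise_model or NoiseModel()
    table = table or ExtinctionTable.default()
    if broadband_wavelengths is None:
        broadband_wavelengths = np.arange(650.0, 1001.0, 1.0)
    broadband_wavelengths = np.asarray(broadband_wavelengths, float)
    rng = _rng(seed)

    if isinstance(composition_field, TissueComposition):
        comp_at = lambda r, c: composition_field  # noqa: E731
    else:
        comp_at = composition_field

    lasers = np.asarray(geometry.laser_wavelengths)
    freqs = np.asarray(geometry.modulation_frequencies)
    musp_lasers = scatter(lasers)
    musp_bb = scatter(broadband_wavelengths)

    clean_cache: dict[bytes, tuple] = {}

    def clean_signals(comp: TissueComposition):
        key = comp.as_array().tobytes()
        if key not in clean_cache:
            mua_l = mua_from_composition(comp, table, lasers)
            amp = np.empty((lasers.size, freqs.size))
            pha = np.empty_like(amp)
            for i in range(lasers.size):
                amp[i], pha[i] = fd_reflectance(
                    mua_l[i], musp_lasers[i], geometry, freqs
                )
            mua_bb = mua_from_composition(comp, table, broadband_wavelengths)
            props = OpticalProperties(broadband_wavelengths, mua_bb, musp_bb)
            bb = steady_state_reflectance(props, geometry).reflectance
            clean_cache[key] = (amp, pha, bb)
        return clean_cache[key]

    fd, broadband, truth = {}, {}, {}
    for r, c in spec.positions():
        if (r, c) in spec.areola and areola_composition is not None:
            comp = areola_composition
        else:
            comp = comp_at(r, c)
        amp, pha, bb = clean_signals(comp)
        amp_noisy = amp * (1.0 + noise_model.amplitude_frac * rng.standard_normal(amp.shape))
        pha_noisy = pha + noise_model.phase_sd * rng.standard_normal(pha.shape)
        bb_noisy = bb * (1.0 + noise_model.broadband_frac * rng.standard_normal(bb.shape))
        fd[(r, c)] = FDMeasurement(
            geometry=geometry,
            wavelengths=lasers,
            frequencies=freqs,
            amplitude=np.clip(amp_noisy, 1e-300, None),
            phase=pha_noisy,
        )
        broadband[(r, c)] = BroadbandReflectance(
            broadband_wavelengths, np.clip(bb_noisy, 1e-300, None)
        )
        truth[(r, c)] = comp
    return GridScan(
        spec=spec, geometry=geometry, fd=fd, broadband=broadband,
        truth=truth, scatter_truth=scatter,
    )


# ---------------------------------------------------------------------------
# MRI phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MriPhantomSpec:
    """Geometry and intensity model of the axial T1-weighted breast phantom.

    The volume is indexed (slice z, row y, column x) with ``spacing`` in mm;
    the y axis runs anterior (0) to posterior.  The breast is the anterior
    half of an ellipsoid resting on the chest plane at row ``chest_row``; a
    thorax band of ``thorax_thickness`` rows lies posterior to it.  The
    fibroglandular compartment is a concentric nested region grown voxel by
    voxel until it holds ``fibro_fraction`` of the breast voxels.  Fat is
    bright and fibroglandular tissue dark, as on T1 without fat
    suppression.  The multiplicative bias field is ``1 + amplitude * g``
    with a smooth ``g`` in [-1, 1] (linear ramp by default), and Gaussian
    noise with SD ``noise_sd`` is added everywhere.
    """

    shape: tuple = (24, 72, 72)
    spacing: tuple = (2.0, 1.0, 1.0)
    chest_row: int = 56
    semi_axes: tuple = (9.0, 40.0, 30.0)
    fibro_fraction: float = 0.20
    fibro_mean: float = 420.0
    fat_mean: float = 1000.0
    skin_mean: float = 500.0
    thorax_mean: float = 700.0
    air_mean: float = 40.0
    noise_sd: float = 50.0
    bias_amplitude: float = 0.20
    bias_kind: str = "linear"
    skin_thickness: int = 2
    thorax_thickness: int = 12

    def __post_init__(self) -> None:
        if not 0.0 <= self.fibro_fraction <= 1.0:
            raise ValueError("fibro_fraction must lie in [0, 1]")
        if min(self.fibro_mean, self.fat_mean, self.skin_mean,
               self.thorax_mean, self.air_mean) <= 0:
            raise ValueError("intensity means must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        if not 0 <= self.chest_row < self.shape[1]:
            raise ValueError("chest_row outside volume")


@dataclass
class MriPhantom:
    """Generated phantom volume plus ground truth."""

    volume: np.ndarray
    breast_mask: np.ndarray
    fibro_mask: np.ndarray
    fat_mask: np.ndarray
    skin_mask: np.ndarray
    thorax_mask: np.ndarray
    bias_field: np.ndarray
    true_percent_density: float
    spec: MriPhantomSpec


def _bias_field(spec: MriPhantomSpec) -> np.ndarray:
    nz, ny, nx = spec.shape
    zz, yy, xx = np.meshgrid(
        np.linspace(-1, 1, nz), np.linspace(-1, 1, ny), np.linspace(-1, 1, nx),
        indexing="ij",
    )
    if spec.bias_kind == "linear":
        g = xx
    elif spec.bias_kind == "smooth":
        g = 0.7 * xx + 0.4 * yy + 0.3 * zz + 0.35 * xx * yy
        g = g / np.max(np.abs(g))
    elif spec.bias_kind == "none":
        g = np.zeros_like(xx)
    else:
        raise ValueError(f"unknown bias_kind {spec.bias_kind!r}")
    return 1.0 + spec.bias_amplitude * g


def generate_mri_phantom(spec: MriPhantomSpec, seed=0) -> MriPhantom:
    """Construct a phantom volume with stored ground truth.

    The fibroglandular mask is the set of N breast voxels closest (in
    ellipsoid-normalized distance) to an interior seed point, with
    ``N = round(fraction * breast voxels)``, so the stored true density is
    exact by construction.  Raises ``ValueError`` when the requested
    fraction cannot fit inside the interior (skin-free) core.
    """
    rng = _rng(seed)
    nz, ny, nx = spec.shape
    az, ay, ax = spec.semi_axes
    cz, cy, cx = (nz - 1) / 2.0, float(spec.chest_row), (nx - 1) / 2.0

    zz, yy, xx = np.indices(spec.shape, dtype=float)
    ell = ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2
    breast = (ell <= 1.0) & (yy <= spec.chest_row)

    thorax = np.zeros(spec.shape, dtype=bool)
    t_end = min(ny, spec.chest_row + 1 + spec.thorax_thickness)
    thorax[:, spec.chest_row + 1: t_end, :] = True

    # skin rim: erode treating the thorax side as interior so only the
    # anterior curved surface sheds a rim
    solid = breast | thorax
    if spec.skin_thickness > 0:
        core = ndimage.binary_erosion(
            solid, iterations=spec.skin_thickness, border_value=1
        )
    else:
        core = solid
    skin = breast & ~core

    n_breast = int(breast.sum())
    n_target = int(round(spec.fibro_fraction * n_breast))
    if spec.fibro_fraction >= 1.0:
        fibro = breast.copy()
    elif n_target == 0:
        fibro = np.zeros(spec.shape, dtype=bool)
    else:
        margin = spec.skin_thickness + 1
        interior = breast & ndimage.binary_erosion(
            solid, iterations=margin, border_value=1
        )
        if n_target > interior.sum():
            raise ValueError(
                f"fibroglandular fraction {spec.fibro_fraction} infeasible: "
                f"needs {n_target} voxels, interior core has {int(interior.sum())}"
            )
        fy = cy - 0.45 * ay
        d = ((zz - cz) / az) ** 2 + ((yy - fy) / ay) ** 2 + ((xx - cx) / ax) ** 2
        d = np.where(interior, d, np.inf)
        idx = np.argpartition(d.ravel(), n_target - 1)[:n_target]
        fibro = np.zeros(spec.shape, dtype=bool)
        fibro.ravel()[idx] = True

    fat = breast & ~fibro & ~skin

    clean = np.full(spec.shape, spec.air_mean)
    clean[thorax] = spec.thorax_mean
    clean[fat] = spec.fat_mean
    clean[skin] = spec.skin_mean
    clean[fibro] = spec.fibro_mean

    bias = _bias_field(spec)
    volume = clean * bias + spec.noise_sd * rng.standard_normal(spec.shape)
    volume = np.clip(volume, 1.0, None)

    true_density = 100.0 * fibro.sum() / n_breast
    return MriPhantom(
        volume=volume, breast_mask=breast, fibro_mask=fibro, fat_mask=fat,
        skin_mask=skin, thorax_mask=thorax, bias_field=bias,
        true_percent_density=float(true_density), spec=spec,
    )


# ---------------------------------------------------------------------------
# longitudinal cohort
# ---------------------------------------------------------------------------

#: published follow-up intervals: (label midpoint, range low, range high) days
DEFAULT_INTERVALS = ((30, 21, 43), (60, 55, 69), (90, 78, 104), (120, 106, 127))


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the simulated longitudinal cohort.

    Defaults reproduce the published design: 17 premenopausal and 11
    postmenopausal subjects, visit days jittered uniformly inside the
    printed interval ranges, per-interval attendance probabilities matching
    the printed per-interval sample sizes, and 3 % multiplicative
    within-subject measurement noise (motivated by the reported < 5 %
    test/retest variation).
    """

    params_pre: GroupParameters = BASELINE_PRE
    params_post: GroupParameters = BASELINE_POST
    trajectory: NacTrajectory = DEFAULT_TRAJECTORY
    intervals: tuple = DEFAULT_INTERVALS
    attendance_pre: tuple = (16 / 17, 10 / 17, 16 / 17, 6 / 17)
    attendance_post: tuple = (1.0, 7 / 11, 9 / 11, 4 / 11)
    noise_sd: float = 0.03
    jitter: bool = True

    def __post_init__(self) -> None:
        if len(self.attendance_pre) != len(self.intervals):
            raise ValueError("attendance_pre length must match intervals")
        if len(self.attendance_post) != len(self.intervals):
            raise ValueError("attendance_post length must match intervals")


def generate_cohort(config: CohortConfig | None = None, seed=0) -> pd.DataFrame:
    """Simulate a subjects × visits table of measured DOSI parameters.

    Each subject gets a baseline composition draw; at each attended visit
    the trajectory-scaled true composition is observed with independent
    multiplicative noise per parameter.  Returns a tidy wide frame with one
    row per subject-visit and columns ``subject, group, day, ct_hhb,
    ct_o2hb, water, lipid, st_o2``.  Baseline rows have ``day == 0``.
    """
    config = config or CohortConfig()
    rng = _rng(seed)
    rows = []
    subject_id = 0
    for params, attendance in (
        (config.params_pre, config.attendance_pre),
        (config.params_post, config.attendance_post),
    ):
        group = params.group
        for _ in range(params.n):
            subject_id += 1
            baseline = sample_baseline(params, rng)
            days = [0.0]
            for (mid, lo, hi), p_attend in zip(config.intervals, attendance):
                if rng.uniform() < p_attend:
                    day = rng.uniform(lo, hi) if config.jitter else float(mid)
                    days.append(day)
            for day in days:
                true = apply_trajectory(baseline, config.trajectory, group, day)
                meas = {
                    p: getattr(true, p)
                    * (1.0 + config.noise_sd * rng.standard_normal())
                    for p in _PARAMS
                }
                thb = meas["ct_hhb"] + meas["ct_o2hb"]
                rows.append(
                    {
                        "subject": f"S{subject_id:03d}",
                        "group": group,
                        "day": day,
                        **meas,
                        "st_o2": 100.0 * meas["ct_o2hb"] / thb if thb > 0 else np.nan,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plain-text IO
# ---------------------------------------------------------------------------

def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort as long CSV: one row per subject-visit-parameter."""
    long = df.melt(
        id_vars=["subject", "group", "day"], var_name="parameter", value_name="value"
    )
    long.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a long cohort CSV back into the wide per-visit layout."""
    long = pd.read_csv(path)
    wide = long.pivot_table(
        index=["subject", "group", "day"], columns="parameter", values="value"
    ).reset_index()
    wide.columns.name = None
    return wide


def write_grid_scan(scan: GridScan, scan_path, broadband_path) -> None:
    """Write the FD scan as TSV and the broadband spectra as CSV.

    The TSV carries the geometry in ``#``-prefixed header lines so a scan
    round-trips through :func:`read_grid_scan`.
    """
    g = scan.geometry
    with open(scan_path, "w") as fh:
        fh.write(f"# sd_separation_mm={g.sd_separation}\n")
        fh.write(f"# n_tissue={g.n_tissue}\n")
        fh.write(f"# spacing_mm={scan.spec.spacing}\n")
        fh.write("row\tcol\tareola\twavelength_nm\tfrequency_mhz\tamplitude\tphase\n")
        for (r, c), meas in sorted(scan.fd.items()):
            areola = int((r, c) in scan.spec.areola)
            for i, wl in enumerate(meas.wavelengths):
                for j, f in enumerate(meas.frequencies):
                    fh.write(
                        f"{r}\t{c}\t{areola}\t{wl:g}\t{f:.6g}"
                        f"\t{meas.amplitude[i, j]:.10e}\t{meas.phase[i, j]:.10e}\n"
                    )
    with open(broadband_path, "w") as fh:
        fh.write("row,col,wavelength_nm,reflectance\n")
        for (r, c), bb in sorted(scan.broadband.items()):
            for wl, refl in zip(bb.wavelengths, bb.reflectance):
                fh.write(f"{r},{c},{wl:g},{refl:.10e}\n")


def read_grid_scan(scan_path, broadband_path) -> GridScan:
    """Reconstruct a :class:`GridScan` from the TSV/CSV pair."""
    header = {}
    with open(scan_path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, val = line[1:].strip().split("=")
            header[key.strip()] = float(val)
    fd_table = pd.read_csv(scan_path, sep="\t", comment="#")
    bb_table = pd.read_csv(broadband_path)

    freqs = np.sort(fd_table["frequency_mhz"].unique())
    lasers = np.sort(fd_table["wavelength_nm"].unique())
    geometry = FDGeometry(
        sd_separation=header.get("sd_separation_mm", 22.0),
        modulation_frequencies=tuple(freqs),
        n_tissue=header.get("n_tissue", 1.4),
        laser_wavelengths=tuple(lasers),
    )
    areola = set()
    fd, broadband = {}, {}
    for (r, c), grp in fd_table.groupby(["row", "col"]):
        if grp["areola"].iloc[0]:
            areola.add((int(r), int(c)))
        piv_a = grp.pivot_table(
            index="wavelength_nm", columns="frequency_mhz", values="amplitude"
        )
        piv_p = grp.pivot_table(
            index="wavelength_nm", columns="frequency_mhz", values="phase"
        )
        fd[(int(r), int(c))] = FDMeasurement(
            geometry=geometry,
            wavelengths=piv_a.index.to_numpy(float),
            frequencies=piv_a.columns.to_numpy(float),
            amplitude=piv_a.to_numpy(float),
            phase=piv_p.to_numpy(float),
        )
    for (r, c), grp in bb_table.groupby(["row", "col"]):
        grp = grp.sort_values("wavelength_nm")
        broadband[(int(r), int(c))] = BroadbandReflectance(
            grp["wavelength_nm"].to_numpy(float), grp["reflectance"].to_numpy(float)
        )
    rows = int(fd_table["row"].max()) + 1
    cols = int(fd_table["col"].max()) + 1
    spec = GridSpec(
        rows=rows, cols=cols,
        spacing=header.get("spacing_mm", 10.0), areola=frozenset(areola),
    )
    return GridScan(spec=spec, geometry=geometry, fd=fd, broadband=broadband)


def save_phantom(phantom: MriPhantom, directory) -> None:
    """Write the phantom volume and ground-truth masks as NIfTI files."""
    import os

    import nibabel as nib

    os.makedirs(directory, exist_ok=True)
    dz, dy, dx = phantom.spec.spacing
    affine = np.diag([dz, dy, dx, 1.0])
    nib.save(
        nib.Nifti1Image(phantom.volume.astype(np.float32), affine),
        os.path.join(directory, "t1_phantom.nii.gz"),
    )
    for name in ("breast_mask", "fibro_mask", "fat_mask", "skin_mask", "thorax_mask"):
        nib.save(
            nib.Nifti1Image(getattr(phantom, name).astype(np.uint8), affine),
            os.path.join(directory, f"{name}.nii.gz"),
        )
    with open(os.path.join(directory, "truth.json"), "w") as fh:
        import json

        json.dump(
            {"true_percent_density": phantom.true_percent_density,
             "spacing_mm": list(phantom.spec.spacing)},
            fh, indent=2,
        )
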