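"""Inversion of optical measurements into tissue composition.

The recovery chain mirrors instrument practice:

1. :func:`fit_fd_properties` — per laser wavelength, fit (μa, μs′) and a
   nuisance gain to the frequency sweep of log-amplitude and phase.
2. :func:`fit_scatter_power` — power-law fit μs′(λ) = A (λ/λ0)^−b across
   the laser wavelengths.
3. :func:`recover_broadband_mua` — scale the (gain-ambiguous) broadband
   reflectance to the frequency-domain anchors, then invert the
   steady-state model wavelength by wavelength for the full μa spectrum.
4. :func:`unmix_chromophores` — non-negative least squares of the μa
   spectrum onto the chromophore basis (ctHHb, ctO2Hb, water, lipid).
5. :func:`derived_indices` — total hemoglobin, oxygen saturation, and the
   tissue optical index TOI = ctHHb × water / lipid.

Grid-level helpers interpolate 2-D maps, average a scan excluding the
areola, bin measurement days into follow-up intervals, and compute percent
change from baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.interpolate import RegularGridInterpolator

from .synthetic_cohort import GridScan
from .tissue_optics import (
    BroadbandReflectance,
    ExtinctionTable,
    FDGeometry,
    FDMeasurement,
    OpticalProperties,
    ScatterPowerFit,
    TissueComposition,
    complex_reflectance,
    fd_reflectance,
    musp_power_law,
)

__all__ = [
    "FDFitResult", "DerivedIndices", "ChromophoreMap", "PositionRecovery",
    "SubjectAverage", "ConvergenceError",
    "fit_fd_properties", "fit_scatter_power", "recover_broadband_mua",
    "unmix_chromophores", "derived_indices", "interpolate_map", "export_map",
    "subject_average", "assign_interval", "percent_change",
    "recover_position", "recover_scan",
]

#: interval bin edges (days): midpoints between the published follow-up
#: interval ranges 21-43, 55-69, 78-104, 106-127
INTERVAL_EDGES = (15.0, 45.0, 75.0, 105.0, 135.0)
INTERVAL_LABELS = (30, 60, 90, 120)


class ConvergenceError(RuntimeError):
    """Nonlinear fit failed to converge; carries the residual trace."""

    def __init__(self, message, residual_trace=None):
        super().__init__(message)
        self.residual_trace = residual_trace


@dataclass
class FDFitResult:
    """Per-wavelength frequency-domain fit."""

    mua: float
    musp: float
    log_gain: float
    residual: float
    n_frequencies: int


def _fd_model_logamp_phase(mua, musp, geometry: FDGeometry, freqs):
    amp, phase = fd_reflectance(mua, musp, geometry, freqs)
    return np.log(amp), phase


def fit_fd_properties(
    meas: FDMeasurement,
    wavelength: float,
    *,
    phase_weight: float = 1.0,
    max_nfev: int = 200,
) -> FDFitResult:
    """Fit (μa, μs′) at one laser wavelength from the frequency sweep.

    Joint least squares on log-amplitude and phase with a free additive
    log-gain (the instrument's amplitude scale is arbitrary per
    wavelength).  The gain is profiled out analytically; (μa, μs′) are
    optimized in log space starting from the best point of a coarse grid
    search.  Raises ``ValueError`` with fewer than two frequencies and
    :class:`ConvergenceError` if the optimizer fails.
    """
    freqs, amp, phase = meas.at_wavelength(wavelength)
    if freqs.size < 2:
        raise ValueError("need at least two modulation frequencies")
    log_amp = np.log(amp)
    geometry = meas.geometry

    def residuals(p):
        mua, musp = np.exp(p)
        model_la, model_ph = _fd_model_logamp_phase(mua, musp, geometry, freqs)
        gain = np.mean(log_amp - model_la)
        return np.concatenate(
            [log_amp - model_la - gain, phase_weight * (phase - model_ph)]
        )

    # coarse log-spaced grid over the physiological range
    mua_grid = np.geomspace(5e-4, 0.1, 10)
    musp_grid = np.geomspace(0.2, 3.0, 10)
    best, best_cost = None, np.inf
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        for mua0 in mua_grid:
            for musp0 in musp_grid:
                r = residuals(np.log([mua0, musp0]))
                cost = float(r @ r)
                if cost < best_cost:
                    best, best_cost = (mua0, musp0), cost
        sol = optimize.least_squares(
            residuals,
            np.log(best),
            method="lm",
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
            max_nfev=max_nfev,
        )
    if not sol.success and sol.cost > 1e-6:
        raise ConvergenceError(
            f"frequency-domain fit did not converge at {wavelength} nm",
            residual_trace=sol.fun,
        )
    mua, musp = np.exp(sol.x)
    model_la, _ = _fd_model_logamp_phase(mua, musp, geometry, freqs)
    gain = float(np.mean(log_amp - model_la))
    return FDFitResult(
        mua=float(mua), musp=float(musp), log_gain=gain,
        residual=float(np.sqrt(2.0 * sol.cost)), n_frequencies=int(freqs.size),
    )


def fit_scatter_power(wavelengths, musp, lambda0: float = 650.0) -> ScatterPowerFit:
    """Least-squares power-law fit of μs′ versus wavelength (log–log)."""
    wl = np.atleast_1d(np.asarray(wavelengths, float))
    mu = np.atleast_1d(np.asarray(musp, float))
    if wl.size != mu.size or wl.size < 2:
        raise ValueError("need at least two (wavelength, musp) pairs")
    if np.any(mu <= 0):
        raise ValueError("musp values must be positive")
    x = np.log(wl / lambda0)
    design = np.stack([np.ones_like(x), -x], axis=1)
    (log_a, b), *_ = np.linalg.lstsq(design, np.log(mu), rcond=None)
    return ScatterPowerFit(amplitude=float(np.exp(log_a)), power=float(b), lambda0=lambda0)


def recover_broadband_mua(
    bb: BroadbandReflectance,
    scatter: ScatterPowerFit,
    fd_anchors,
    geometry: FDGeometry | None = None,
    *,
    mua_bracket=(1e-7, 2.0),
) -> OpticalProperties:
    """Recover the full absorption spectrum from broadband reflectance.

    The unknown broadband gain is estimated by least squares over the
    frequency-domain anchors ``[(wavelength, mua), ...]`` (geometric mean
    of measured/model reflectance ratios, i.e. least squares in log
    space).  Each wavelength's μa is then found by 1-D root finding on the
    steady-state model with μs′(λ) from the scatter power law.  Invariant
    to any global positive rescaling of the input reflectance.
    """
    geometry = geometry or FDGeometry()
    anchors = [(float(w), float(m)) for w, m in fd_anchors]
    if len(anchors) < 2:
        raise ValueError("need at least two frequency-domain anchors")
    wl_bb = bb.wavelengths
    refl = bb.reflectance

    def model_cw(mua, musp):
        return float(
            np.real(
                complex_reflectance(mua, musp, geometry.sd_separation, 0.0,
                                    geometry.n_tissue)
            )
        )

    log_ratios = []
    for wl_a, mua_a in anchors:
        idx = np.argmin(np.abs(wl_bb - wl_a))
        if abs(wl_bb[idx] - wl_a) > 2.0:
            continue
        musp_a = float(musp_power_law(scatter, wl_a)[0])
        log_ratios.append(np.log(refl[idx]) - np.log(model_cw(mua_a, musp_a)))
    if len(log_ratios) < 2:
        raise ValueError("fewer than two usable anchors inside the broadband grid")
    log_gain = float(np.mean(log_ratios))

    musp_bb = musp_power_law(scatter, wl_bb)
    mua_out = np.empty_like(wl_bb)
    lo, hi = mua_bracket
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        for i, (wl, r_meas, musp) in enumerate(zip(wl_bb, refl, musp_bb)):
            target = np.log(r_meas) - log_gain

            def f(log_mua):
                return np.log(model_cw(np.exp(log_mua), musp)) - target

            f_lo, f_hi = f(np.log(lo)), f(np.log(hi))
            if f_lo < 0:          # reflectance larger than the lowest-mua model
                mua_out[i] = lo
                continue
            if f_hi > 0:
                mua_out[i] = hi
                continue
            mua_out[i] = np.exp(
                optimize.brentq(f, np.log(lo), np.log(hi), xtol=1e-13)
            )
    return OpticalProperties(wl_bb, mua_out, musp_bb)


def unmix_chromophores(
    wavelengths, mua, table: ExtinctionTable | None = None
) -> tuple[TissueComposition, float]:
    """Non-negative least squares of a μa spectrum onto the four bases.

    Returns the composition (ctHHb, ctO2Hb in µM; water, lipid in %) and
    the residual 2-norm.  Negative excursions in the input spectrum are
    tolerated; the output is non-negative by construction.  Raises
    ``ValueError`` for fewer than four wavelengths or a singular design
    (for example duplicated wavelengths only).
    """
    table = table or ExtinctionTable.default()
    wl = np.atleast_1d(np.asarray(wavelengths, float))
    spectrum = np.atleast_1d(np.asarray(mua, float))
    if wl.size != spectrum.size:
        raise ValueError("wavelength and mua grids differ")
    if np.unique(wl).size < 4:
        raise ValueError("need at least four distinct wavelengths to unmix")
    design = table.basis(wl)
    if np.linalg.matrix_rank(design) < 4:
        raise ValueError("singular chromophore design matrix")
    coefs, residual = optimize.nnls(design, spectrum)
    return TissueComposition.from_array(coefs), float(residual)


@dataclass(frozen=True)
class DerivedIndices:
    """Total hemoglobin (µM), oxygen saturation (%), tissue optical index."""

    ct_thb: float
    st_o2: float
    toi: float


def derived_indices(comp: TissueComposition) -> DerivedIndices:
    """ctTHb = ctHHb + ctO2Hb; stO2 = 100·ctO2Hb/ctTHb; TOI = ctHHb·water/lipid.

    Raises ``ValueError`` when stO2 (ctTHb = 0) or TOI (lipid = 0) is
    undefined.
    """
    ct_thb = comp.ct_hhb + comp.ct_o2hb
    if ct_thb <= 0:
        raise ValueError("stO2 undefined: total hemoglobin is zero")
    if comp.lipid <= 0:
        raise ValueError("TOI undefined: lipid is zero")
    return DerivedIndices(
        ct_thb=ct_thb,
        st_o2=100.0 * comp.ct_o2hb / ct_thb,
        toi=comp.ct_hhb * comp.water / comp.lipid,
    )


@dataclass
class ChromophoreMap:
    """Bilinear 2-D map of one parameter over the measurement grid."""

    values: np.ndarray         # upsampled map
    x_mm: np.ndarray
    y_mm: np.ndarray
    source: np.ndarray         # node values
    spacing: float
    method: str = "bilinear"


def interpolate_map(grid_values, spacing: float = 10.0, upsample: int = 10) -> ChromophoreMap:
    """Bilinear interpolation of node values onto a finer grid.

    Node-exact, no extrapolation beyond the grid hull.  Requires a full
    rectangular grid of at least 2 × 2 nodes.
    """
    values = np.asarray(grid_values, dtype=float)
    if values.ndim != 2:
        raise ValueError("grid values must be a 2-D rectangular array")
    rows, cols = values.shape
    if rows < 2 or cols < 2:
        raise ValueError("grid must be at least 2x2")
    y = np.arange(rows) * spacing
    x = np.arange(cols) * spacing
    interp = RegularGridInterpolator((y, x), values, method="linear",
                                     bounds_error=True)
    y_fine = np.linspace(0, y[-1], (rows - 1) * upsample + 1)
    x_fine = np.linspace(0, x[-1], (cols - 1) * upsample + 1)
    yy, xx = np.meshgrid(y_fine, x_fine, indexing="ij")
    fine = interp(np.stack([yy.ravel(), xx.ravel()], axis=1)).reshape(yy.shape)
    return ChromophoreMap(values=fine, x_mm=x_fine, y_mm=y_fine,
                          source=values, spacing=spacing)


@dataclass
class PositionRecovery:
    """Full recovery at one grid position."""

    composition: TissueComposition
    properties: OpticalProperties
    scatter: ScatterPowerFit
    indices: DerivedIndices
    unmix_residual: float


@dataclass
class SubjectAverage:
    """Scan-level summary over non-areolar positions.

    Whether subject-level stO2 and TOI should be ratios of averaged
    concentrations or averages of per-position ratios is ambiguous in
    field practice, so both are reported: ``indices_of_means`` applies the
    index formulas to the averaged composition, ``mean_of_indices``
    averages the per-position indices.
    """

    composition: TissueComposition
    scatter: ScatterPowerFit
    indices_of_means: DerivedIndices
    mean_of_indices: DerivedIndices
    n_positions: int
    n_excluded: int


def subject_average(results: dict, areola_mask=None) -> SubjectAverage:
    """Unweighted mean of per-position recoveries excluding the areola.

    ``results`` maps (row, col) -> :class:`PositionRecovery`;
    ``areola_mask`` is a 2-D boolean array (or None for no exclusion).
    """
    kept = []
    excluded = 0
    for (r, c), res in sorted(results.items()):
        if areola_mask is not None and areola_mask[r, c]:
            excluded += 1
            continue
        kept.append(res)
    if not kept:
        raise ValueError("all positions are areolar; nothing to average")

    comp_mean = TissueComposition.from_array(
        np.mean([res.composition.as_array() for res in kept], axis=0)
    )
    amp = float(np.mean([res.scatter.amplitude for res in kept]))
    pow_ = float(np.mean([res.scatter.power for res in kept]))
    lambda0 = kept[0].scatter.lambda0
    per_position = [res.indices for res in kept]
    mean_of = DerivedIndices(
        ct_thb=float(np.mean([d.ct_thb for d in per_position])),
        st_o2=float(np.mean([d.st_o2 for d in per_position])),
        toi=float(np.mean([d.toi for d in per_position])),
    )
    return SubjectAverage(
        composition=comp_mean,
        scatter=ScatterPowerFit(amp, pow_, lambda0),
        indices_of_means=derived_indices(comp_mean),
        mean_of_indices=mean_of,
        n_positions=len(kept),
        n_excluded=excluded,
    )


def export_map(cmap: ChromophoreMap, npz_path=None, png_path=None, *,
               title: str = "", cmap_name: str = "viridis") -> None:
    """Write an interpolated map as NPZ (arrays) and/or PNG (rendered).

    The PNG uses physical millimeter axes so areola outlines and grid
    spacing read directly off the figure.
    """
    if npz_path is not None:
        np.savez(
            npz_path, values=cmap.values, x_mm=cmap.x_mm, y_mm=cmap.y_mm,
            source=cmap.source, spacing=np.array([cmap.spacing]),
        )
    if png_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(
            cmap.values, origin="upper", cmap=cmap_name,
            extent=[cmap.x_mm[0], cmap.x_mm[-1], cmap.y_mm[-1], cmap.y_mm[0]],
        )
        ax.set_xlabel("x (mm)")
        ax.set_ylabel("y (mm)")
        if title:
            ax.set_title(title)
        fig.colorbar(im, ax=ax)
        fig.tight_layout()
        fig.savefig(png_path, dpi=120)
        plt.close(fig)


def assign_interval(day: float):
    """Bin a measurement day into baseline or a follow-up interval label.

    Days 0–14 are baseline; edges at 15/45/75/105/135 map to labels
    30/60/90/120 (each printed interval range falls inside its bin); days
    beyond 135 raise ``ValueError``.
    """
    if day < 0:
        raise ValueError("day must be non-negative")
    if day < INTERVAL_EDGES[0]:
        return "baseline"
    for label, hi in zip(INTERVAL_LABELS, INTERVAL_EDGES[1:]):
        if day < hi:
            return label
    if day == INTERVAL_EDGES[-1]:
        return INTERVAL_LABELS[-1]
    raise ValueError(f"day {day} beyond the last follow-up interval")


def percent_change(value: float, baseline: float) -> float:
    """100 × (value − baseline) / baseline."""
    if baseline == 0:
        raise ValueError("baseline must be nonzero")
    return 100.0 * (value - baseline) / baseline


def recover_position(
    fd: FDMeasurement,
    bb: BroadbandReflectance,
    table: ExtinctionTable | None = None,
) -> PositionRecovery:
    """Run the full per-position chain: FD fits → scatter law → broadband
    absorption → chromophore unmixing → derived indices."""
    table = table or ExtinctionTable.default()
    fits = [fit_fd_properties(fd, wl) for wl in fd.wavelengths]
    scatter = fit_scatter_power(fd.wavelengths, [f.musp for f in fits])
    anchors = [(wl, f.mua) for wl, f in zip(fd.wavelengths, fits)]
    props = recover_broadband_mua(bb, scatter, anchors, fd.geometry)
    comp, resid = unmix_chromophores(props.wavelengths, props.mua, table)
    return PositionRecovery(
        composition=comp, properties=props, scatter=scatter,
        indices=derived_indices(comp), unmix_residual=resid,
    )


def recover_scan(
    scan: GridScan, table: ExtinctionTable | None = None
) -> tuple[dict, SubjectAverage]:
    """Recover every position of a grid scan and its areola-excluded average."""
    results = {
        pos: recover_position(scan.fd[pos], scan.broadband[pos], table)
        for pos in scan.fd
    }
    return results, subject_average(results, scan.areola_mask())
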