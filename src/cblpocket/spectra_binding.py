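"""UV-vis spectral comparison and MST binding-curve fitting.

Cobalamin absorbance spectra are diagnostic of the β-axial ligand: the γ
band (near 350–360 nm) collapses and the α/β band (500–560 nm) red-shifts
when hydroxocobalamin is converted to the glutathionyl form. Spectra
recorded with different path lengths and extinction coefficients are made
comparable by area normalization — dividing by the trapezoidal integral of
|A(λ)| over a stated window — after which band positions and heights can be
compared directly.

Microscale thermophoresis quantifies binding through Fnorm, the hot/cold
fluorescence ratio of a thermophoresis trace, in per-mil. Because the
labelled-protein concentration P can exceed the dissociation constant, the
1:1 isotherm is fitted in its probe-depletion (quadratic) form

    bound(L) = ((P + L + Kd) − sqrt((P + L + Kd)² − 4 P L)) / (2 P),

and a fitted Kd at or below P is flagged as a lower limit only — the assay
cannot resolve tighter binding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "Spectrum",
    "ThermophoresisTrace",
    "BindingCurve",
    "area_normalize",
    "band_metrics",
    "compare_spectra",
    "stability_series",
    "fnorm",
    "fit_kd",
    "NoBindingError",
    "NormalizationError",
]

GAMMA_WINDOW = (340.0, 370.0)
ALPHABETA_WINDOW = (490.0, 580.0)
GRID_STEP = 1.0  # nm, common interpolation grid for comparisons


class NormalizationError(ValueError):
    """Spectrum has (near-)zero integrated area over the window."""


class NoBindingError(RuntimeError):
    """Titration amplitude indistinguishable from noise."""


@dataclass
class Spectrum:
    """Absorbance spectrum: strictly increasing wavelengths (nm) vs AU."""

    wavelength: np.ndarray
    absorbance: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelength.ndim != 1 or self.wavelength.shape != self.absorbance.shape:
            raise ValueError("wavelength and absorbance must be equal-length 1-D arrays")
        if not np.all(np.diff(self.wavelength) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")

    @classmethod
    def from_csv(cls, path: str | Path, label: str | None = None) -> "Spectrum":
        """Read a two-column CSV (wavelength_nm, absorbance)."""
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected two columns (wavelength, absorbance)")
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(),
                   label=label if label is not None else Path(path).stem)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"wavelength_nm": self.wavelength,
                      "absorbance": self.absorbance}).to_csv(path, index=False)

    def on_grid(self, grid: np.ndarray) -> "Spectrum":
        """Linear interpolation onto a common wavelength grid."""
        lo, hi = self.wavelength[0], self.wavelength[-1]
        if grid[0] < lo - 1e-9 or grid[-1] > hi + 1e-9:
            raise ValueError("grid extends beyond the spectrum's support")
        return Spectrum(grid, np.interp(grid, self.wavelength, self.absorbance), self.label)


@dataclass
class ThermophoresisTrace:
    """One MST capillary: fluorescence counts vs time at one ligand concentration."""

    time: np.ndarray
    fluorescence: np.ndarray
    concentration: float  # molar

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if self.time.shape != self.fluorescence.shape:
            raise ValueError("time and fluorescence must have equal length")
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")


@dataclass
class BindingCurve:
    """Serial-dilution ΔFnorm data with the fitted 1:1 depletion isotherm."""

    concentrations: np.ndarray          # molar, ascending
    delta_fnorm: np.ndarray             # per-mil
    fitted_kd: float                    # molar
    kd_is_lower_limit: bool
    amplitude: float                    # per-mil
    baseline: float                     # per-mil
    probe_conc: float                   # molar
    residual_sd: float = 0.0

    def model(self, conc: np.ndarray) -> np.ndarray:
        frac = _bound_fraction(np.asarray(conc, dtype=float), self.probe_conc, self.fitted_kd)
        return self.baseline + self.amplitude * frac

    def to_dict(self) -> dict:
        return {
            "kd_M": self.fitted_kd,
            "kd_is_lower_limit": self.kd_is_lower_limit,
            "amplitude_permil": self.amplitude,
            "baseline_permil": self.baseline,
            "probe_M": self.probe_conc,
            "residual_sd_permil": self.residual_sd,
            "n_points": int(len(self.concentrations)),
        }


# ---------------------------------------------------------------------------
# spectra

def area_normalize(s: Spectrum, window: tuple[float, float] | None = None) -> Spectrum:
    """Scale a spectrum so the trapezoidal integral of |A| over ``window``
    (default: full support) equals 1."""
    lo, hi = window if window is not None else (s.wavelength[0], s.wavelength[-1])
    if lo < s.wavelength[0] - 1e-9 or hi > s.wavelength[-1] + 1e-9 or hi <= lo:
        raise ValueError(f"window ({lo}, {hi}) outside spectrum support")
    mask = (s.wavelength >= lo) & (s.wavelength <= hi)
    area = float(np.trapezoid(np.abs(s.absorbance[mask]), s.wavelength[mask]))
    if area <= 1e-12:
        raise NormalizationError(f"spectrum {s.label!r} has zero area over ({lo}, {hi})")
    return Spectrum(s.wavelength, s.absorbance / area, s.label)


def band_metrics(
    s: Spectrum,
    gamma_window: tuple[float, float] = GAMMA_WINDOW,
    alphabeta_window: tuple[float, float] = ALPHABETA_WINDOW,
    normalize: bool = True,
) -> dict:
    """Peak position and height of the γ and α/β bands (on the
    area-normalized spectrum when ``normalize`` is set)."""
    sn = area_normalize(s) if normalize else s
    out = {}
    for name, (lo, hi) in (("gamma", gamma_window), ("alphabeta", alphabeta_window)):
        if lo < sn.wavelength[0] or hi > sn.wavelength[-1]:
            raise ValueError(f"{name} window ({lo}, {hi}) outside spectrum support")
        mask = (sn.wavelength >= lo) & (sn.wavelength <= hi)
        w = sn.wavelength[mask]
        a = sn.absorbance[mask]
        if np.ptp(a) < 1e-12:
            out[name] = {"position_nm": float((lo + hi) / 2.0), "height": float(a[0]),
                         "flat": True}
        else:
            k = int(np.argmax(a))
            out[name] = {"position_nm": float(w[k]), "height": float(a[k]), "flat": False}
    return out


def compare_spectra(
    reference: Spectrum,
    other: Spectrum,
    gamma_window: tuple[float, float] = GAMMA_WINDOW,
    alphabeta_window: tuple[float, float] = ALPHABETA_WINDOW,
) -> dict:
    """Band shifts and γ-collapse ratio of ``other`` relative to ``reference``.

    Both spectra are area-normalized on the overlap of their supports (common
    1 nm grid) first, so the comparison is scale-invariant.
    """
    lo = max(reference.wavelength[0], other.wavelength[0])
    hi = min(reference.wavelength[-1], other.wavelength[-1])
    grid = np.arange(lo, hi + GRID_STEP / 2, GRID_STEP)
    ref = area_normalize(reference.on_grid(grid))
    oth = area_normalize(other.on_grid(grid))
    mref = band_metrics(ref, gamma_window, alphabeta_window, normalize=False)
    moth = band_metrics(oth, gamma_window, alphabeta_window, normalize=False)
    return {
        "gamma_shift_nm": moth["gamma"]["position_nm"] - mref["gamma"]["position_nm"],
        "alphabeta_shift_nm": moth["alphabeta"]["position_nm"] - mref["alphabeta"]["position_nm"],
        "gamma_collapse_ratio": moth["gamma"]["height"] / mref["gamma"]["height"],
        "reference": mref,
        "other": moth,
    }


def stability_series(
    reference: Spectrum,
    series: list[tuple[float, Spectrum]],
) -> dict:
    """Spectral drift of a time series against a reference spectrum.

    Per time point the drift is the L2 distance between area-normalized
    spectra on a common 1 nm grid; the Kendall tau of drift against time
    summarises the trend (near +1: steady decay; near 0: stable).
    """
    if len(series) < 2:
        raise ValueError("stability analysis needs at least 2 time points")
    lo = max([reference.wavelength[0]] + [s.wavelength[0] for _, s in series])
    hi = min([reference.wavelength[-1]] + [s.wavelength[-1] for _, s in series])
    grid = np.arange(lo, hi + GRID_STEP / 2, GRID_STEP)
    ref = area_normalize(reference.on_grid(grid))
    times, drifts = [], []
    for t, s in sorted(series, key=lambda ts: ts[0]):
        sn = area_normalize(s.on_grid(grid))
        times.append(float(t))
        drifts.append(float(np.linalg.norm(sn.absorbance - ref.absorbance)))
    if np.ptp(drifts) < 1e-15:
        tau = 0.0
    else:
        tau = float(stats.kendalltau(times, drifts).statistic)
    return {"times": times, "drifts": drifts, "kendall_tau": tau}


# ---------------------------------------------------------------------------
# MST

def fnorm(
    trace: ThermophoresisTrace,
    cold_window: tuple[float, float],
    hot_window: tuple[float, float],
) -> float:
    """Fnorm in per-mil: 1000 × mean(F, hot window) / mean(F, cold window)."""
    t = trace.time
    for name, (lo, hi) in (("cold", cold_window), ("hot", hot_window)):
        if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9 or hi <= lo:
            raise ValueError(f"{name} window ({lo}, {hi}) outside trace support")
    if min(hot_window) < max(cold_window) and min(cold_window) < max(hot_window):
        raise ValueError("hot and cold windows must not overlap")
    cold = trace.fluorescence[(t >= cold_window[0]) & (t <= cold_window[1])]
    hot = trace.fluorescence[(t >= hot_window[0]) & (t <= hot_window[1])]
    if cold.size == 0 or hot.size == 0:
        raise ValueError("empty hot or cold window")
    cold_mean = float(cold.mean())
    if cold_mean <= 0:
        raise ValueError("non-positive cold-window fluorescence")
    return 1000.0 * float(hot.mean()) / cold_mean


def _bound_fraction(ligand: np.ndarray, probe: float, kd: float) -> np.ndarray:
    """1:1 probe-depletion (quadratic) isotherm: fraction of probe bound."""
    s = probe + ligand + kd
    disc = np.maximum(s * s - 4.0 * probe * ligand, 0.0)
    return (s - np.sqrt(disc)) / (2.0 * probe)


def fit_kd(
    concentrations: np.ndarray,
    delta_fnorm: np.ndarray,
    probe_conc: float,
    n_starts: int = 5,
) -> BindingCurve:
    """Fit the 1:1 depletion isotherm to a ΔFnorm dilution series.

    Requires ≥ 6 concentrations spanning ≥ 3 orders of magnitude. The fit is
    nonlinear least squares over (baseline, amplitude, log Kd) with
    ``n_starts`` log-spaced Kd initialisations across the concentration
    range; raises :class:`NoBindingError` when the fitted amplitude is
    smaller than 3× the residual standard deviation.
    """
    conc = np.asarray(concentrations, dtype=float)
    y = np.asarray(delta_fnorm, dtype=float)
    if conc.ndim != 1 or conc.shape != y.shape:
        raise ValueError("concentrations and delta_fnorm must be equal-length 1-D arrays")
    if not np.all(np.diff(conc) > 0):
        raise ValueError("concentrations must be strictly increasing")
    if conc.size < 6:
        raise ValueError("need at least 6 concentrations")
    pos = conc[conc > 0]
    if pos.size == 0 or pos.max() / pos.min() < 1e3:
        raise ValueError("concentrations must span at least 3 orders of magnitude")
    if probe_conc <= 0:
        raise ValueError("probe concentration must be positive")

    def residuals(params: np.ndarray) -> np.ndarray:
        baseline, amplitude, log_kd = params
        return baseline + amplitude * _bound_fraction(conc, probe_conc, 10.0**log_kd) - y

    span = y[-1] - y[0]
    best = None
    for log_kd0 in np.linspace(np.log10(pos.min()), np.log10(pos.max()), n_starts):
        x0 = np.array([y[0], span if span != 0 else 1.0, log_kd0])
        sol = optimize.least_squares(residuals, x0, method="lm", max_nfev=5000)
        if best is None or sol.cost < best.cost - 1e-15:
            best = sol
    baseline, amplitude, log_kd = best.x
    kd = float(10.0**log_kd)
    res = residuals(best.x)
    dof = max(conc.size - 3, 1)
    residual_sd = float(np.sqrt(np.sum(res**2) / dof))
    if abs(amplitude) < 3.0 * residual_sd:
        raise NoBindingError(
            f"amplitude {amplitude:.3g} ‰ indistinguishable from noise "
            f"(residual SD {residual_sd:.3g} ‰)"
        )
    return BindingCurve(
        concentrations=conc,
        delta_fnorm=y,
        fitted_kd=kd,
        kd_is_lower_limit=bool(kd <= probe_conc),
        amplitude=float(amplitude),
        baseline=float(baseline),
        probe_conc=float(probe_conc),
        residual_sd=residual_sd,
    )


def fit_kd_from_traces(
    traces: list[ThermophoresisTrace],
    probe_conc: float,
    cold_window: tuple[float, float],
    hot_window: tuple[float, float],
) -> BindingCurve:
    """Convenience: Fnorm each trace, sort by concentration, fit the isotherm."""
    pairs = sorted(
        ((tr.concentration, fnorm(tr, cold_window, hot_window)) for tr in traces),
        key=lambda p: p[0],
    )
    conc = np.array([c for c, _ in pairs])
    f = np.array([v for _, v in pairs])
    return fit_kd(conc, f, probe_conc)
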