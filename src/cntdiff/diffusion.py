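"""Diffusion-coefficient estimation from surface trajectories.

The estimator stack is the standard Einstein-relation protocol:

1.  time-origin-averaged mean squared displacement, MSD(τ), per surface
    component (∥ axial, ⊥ circumferential, or their 2D sum);
2.  least-squares line through MSD(τ) on a lag window inside the diffusive
    regime (default 4–10 ps), with D = slope / (2·dim);
3.  replicate spread (standard deviation over independent trajectories) as
    the uncertainty;
4.  finite-size extrapolation D(L) = D∞ − k/L against inverse axial box
    length, motivated by hydrodynamic self-interaction corrections under
    periodic boundary conditions;
5.  a Stokes–Einstein-style ordinary least-squares regression of D on
    N_water^(−1/3), the hydration-shell proxy for the effective
    hydrodynamic radius.

MSD input series are in Å and ps; diffusion coefficients are reported in
1e-5 cm²/s (see :mod:`cntdiff.units`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .geometry import UnwrappedPath
from .units import diffusion_to_reported

DEFAULT_FIT_WINDOW = (4.0, 10.0)

_COMPONENTS = ("par", "perp", "total2d")


class FitFailureError(RuntimeError):
    """A regression could not be performed (degenerate input)."""


@dataclass
class MSDCurve:
    """Mean squared displacement vs lag time.

    ``msd`` is the mean over time origins and replicates;
    ``per_replicate`` holds one row per input trajectory.
    """

    lags: np.ndarray
    msd: np.ndarray
    per_replicate: np.ndarray
    component: str

    def __post_init__(self):
        self.lags = np.asarray(self.lags, float)
        self.msd = np.asarray(self.msd, float)
        self.per_replicate = np.atleast_2d(np.asarray(self.per_replicate, float))

    @property
    def n_replicates(self) -> int:
        return self.per_replicate.shape[0]


@dataclass
class ComponentFit:
    """Einstein-relation fit of one MSD component."""

    D: float            # 1e-5 cm²/s, mean over replicates
    error: float        # std over replicates (0 for a single trajectory)
    per_replicate: np.ndarray
    dimensionality: int
    fit_window: tuple[float, float]


@dataclass
class DiffusionResult:
    """Fitted D⊥, D∥ and the overall 2D coefficient with uncertainties.

    The overall 2D value is the mean of the two 1D coefficients; its error
    propagates the two component errors in quadrature.
    """

    D_perp: float
    D_par: float
    D_2d: float
    err_perp: float
    err_par: float
    err_2d: float
    fit_window: tuple[float, float] = DEFAULT_FIT_WINDOW


@dataclass
class ExtrapolationResult:
    """Infinite-system diffusion coefficient from a 1/L regression."""

    D_inf: float
    slope: float
    lengths: np.ndarray = field(default_factory=lambda: np.array([]))
    D_inf_err: float = 0.0


def _msd_fft_1d(x: np.ndarray, n_lags: int) -> np.ndarray:
    """Time-origin-averaged 1D MSD via FFT autocorrelation, O(N log N).

    msd[m] = (1/(N−m)) Σ_k (x[k+m] − x[k])², for m = 0 … n_lags−1.
    """
    x = np.asarray(x, float)
    n = len(x)
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, n=nfft)
    acf = np.fft.irfft(f * np.conj(f), n=nfft)[:n]
    sq = x * x
    ssum = sq.sum()
    m = np.arange(n_lags)
    # Q[m] = Σ_{k<N−m} (x[k]² + x[k+m]²)
    head = np.concatenate([[0.0], np.cumsum(sq[:-1])])[:n_lags]
    tail = np.concatenate([[0.0], np.cumsum(sq[::-1][:-1])])[:n_lags]
    q = 2.0 * ssum - head - tail
    return (q - 2.0 * acf[:n_lags]) / (n - m)


def msd_brute_force(x: np.ndarray, n_lags: int | None = None) -> np.ndarray:
    """Direct double-loop MSD; the reference oracle for :func:`compute_msd`."""
    x = np.asarray(x, float)
    n = len(x)
    if n_lags is None:
        n_lags = n
    out = np.zeros(n_lags)
    for m in range(1, n_lags):
        diff = x[m:] - x[:-m]
        out[m] = np.mean(diff * diff)
    return out


def _component_series(path: UnwrappedPath, component: str) -> list[np.ndarray]:
    if component == "par":
        return [path.s_par]
    if component == "perp":
        return [path.s_perp]
    if component == "total2d":
        return [path.s_par, path.s_perp]
    raise ValueError(f"component must be one of {_COMPONENTS}, got {component!r}")


def compute_msd(paths, component: str = "total2d",
                max_lag: float | None = None) -> MSDCurve:
    """Time-origin-averaged MSD of one or more replicate paths.

    Parameters
    ----------
    paths:
        An :class:`~cntdiff.geometry.UnwrappedPath` or a sequence of them
        (replicates must share frame spacing and length).
    component:
        ``'par'``, ``'perp'``, or ``'total2d'`` (sum of the two 1D MSDs).
    max_lag:
        Largest lag in ps; defaults to half the trajectory duration.

    All time origins (stride 1) enter the average.
    """
    if isinstance(paths, UnwrappedPath):
        paths = [paths]
    if not paths:
        raise ValueError("no paths given")
    times = paths[0].times
    dts = np.diff(times)
    if dts.size == 0:
        raise ValueError("paths must contain at least two frames")
    dt = dts[0]
    if not np.allclose(dts, dt, rtol=1e-6, atol=1e-9):
        raise ValueError("frame spacing must be uniform")
    duration = times[-1] - times[0]
    if max_lag is None:
        max_lag = duration / 2.0
    if max_lag > duration / 2.0 + 1e-9:
        raise ValueError(f"max_lag {max_lag} exceeds half the duration {duration / 2}")
    n_lags = int(round(max_lag / dt)) + 1
    rows = []
    for p in paths:
        if len(p) != len(times):
            raise ValueError("replicates must share trajectory length")
        row = np.zeros(n_lags)
        for series in _component_series(p, component):
            row += _msd_fft_1d(series, n_lags)
        rows.append(row)
    per_rep = np.array(rows)
    lags = np.arange(n_lags) * dt
    return MSDCurve(lags, per_rep.mean(axis=0), per_rep, component)


def fit_component(msd: MSDCurve, dimensionality: int,
                  window: tuple[float, float] = DEFAULT_FIT_WINDOW) -> ComponentFit:
    """Einstein-relation fit, D = slope / (2·dim), on one MSD component.

    Each replicate curve is fitted separately; the reported D is the mean
    of per-replicate values and the error their standard deviation.
    """
    lo, hi = window
    mask = (msd.lags >= lo - 1e-9) & (msd.lags <= hi + 1e-9)
    if mask.sum() < 2:
        raise ValueError(
            f"fit window {window} ps selects fewer than two lags "
            f"(available 0–{msd.lags[-1]:.3g} ps)")
    t = msd.lags[mask]
    ds = []
    for row in msd.per_replicate:
        slope = np.polyfit(t, row[mask], 1)[0]
        ds.append(diffusion_to_reported(slope / (2.0 * dimensionality)))
    ds = np.array(ds)
    err = float(ds.std(ddof=1)) if len(ds) > 1 else 0.0
    return ComponentFit(float(ds.mean()), err, ds, dimensionality, window)


def fit_diffusion(msd_par: MSDCurve, msd_perp: MSDCurve,
                  window: tuple[float, float] = DEFAULT_FIT_WINDOW) -> DiffusionResult:
    """Fit both 1D components and combine into the overall 2D coefficient.

    The overall 2D D is the mean of the axial and circumferential 1D
    coefficients (equivalently, the 2D Einstein relation MSD_2d = 4·D·t
    applied to the summed MSD).
    """
    fpar = fit_component(msd_par, 1, window)
    fperp = fit_component(msd_perp, 1, window)
    d2d = 0.5 * (fpar.D + fperp.D)
    err2d = 0.5 * float(np.hypot(fpar.error, fperp.error))
    return DiffusionResult(D_perp=fperp.D, D_par=fpar.D, D_2d=d2d,
                           err_perp=fperp.error, err_par=fpar.error,
                           err_2d=err2d, fit_window=window)


def extrapolate_Dinf(lengths, D, errors=None) -> ExtrapolationResult:
    """Extrapolate D to the infinite system: weighted fit of D against 1/L.

    ``D_inf`` is the intercept at 1/L = 0.  With per-point errors the fit
    is weighted by 1/σ; at least three distinct lengths are required.
    """
    lengths = np.asarray(lengths, float)
    D = np.asarray(D, float)
    if len(np.unique(lengths)) < 3:
        raise ValueError("finite-size extrapolation requires >= 3 distinct lengths")
    x = 1.0 / lengths
    if errors is not None:
        w = 1.0 / np.asarray(errors, float)
        coeffs, cov = np.polyfit(x, D, 1, w=w, cov="unscaled")
        err = float(np.sqrt(cov[1, 1]))
    else:
        coeffs = np.polyfit(x, D, 1)
        err = 0.0
    slope, intercept = coeffs
    return ExtrapolationResult(D_inf=float(intercept), slope=float(slope),
                               lengths=lengths, D_inf_err=err)


def stokes_fit(D, N_water):
    """OLS regression of D on N_water^(−1/3) (Stokes–Einstein proxy).

    Returns (slope, intercept, R²).  Under the Stokes–Einstein picture the
    hydrodynamic radius grows as the cube root of the hydration count, so
    fewer first-shell waters should mean faster diffusion (positive slope).
    """
    D = np.asarray(D, float)
    N = np.asarray(N_water, float)
    if len(D) != len(N):
        raise ValueError("D and N_water must have equal length")
    if np.any(N <= 0):
        raise ValueError("N_water must be positive")
    x = N ** (-1.0 / 3.0)
    if np.ptp(x) < 1e-12:
        raise FitFailureError("degenerate predictor: all N_water equal")
    res = stats.linregress(x, D)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)
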