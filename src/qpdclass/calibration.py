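"""Passive trap-stiffness calibration: equipartition and power-spectrum methods.

Two textbook estimators of the transverse trap stiffness from a recorded
position signal:

* **Equipartition** — at thermal equilibrium each degree of freedom holds
  kB T / 2 of potential energy, so ``k = kB T / var(x)``.
* **Power spectrum** — the one-sided PSD of an overdamped trapped bead is a
  Lorentzian, ``Sxx(f) = kB T / (pi^2 gamma (f0^2 + f^2))``; fitting it
  yields the corner frequency f0, and ``k = 2 pi f0 gamma``.

Both serve here as the parameter-recovery check on the simulator: stiffness
programmed into the Langevin integrator must come back out of either
estimator.  Applied to raw detector voltages instead of metres they return
stiffness only up to the squared responsivity, since no volt-to-metre
conversion is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import welch

from .trap_sim import BOLTZMANN_CONSTANT, InvalidParameterError

__all__ = [
    "PSDEstimate",
    "LorentzianFit",
    "StiffnessEstimates",
    "equipartition_stiffness",
    "lorentzian_psd",
    "estimate_psd",
    "fit_lorentzian",
    "calibrate_axis",
    "DegenerateInputError",
    "FitFailureError",
]


class DegenerateInputError(ValueError):
    """The input carries no usable fluctuation signal (e.g. zero variance)."""


class FitFailureError(RuntimeError):
    """The Lorentzian fit did not converge to a corner inside the fit band."""

    def __init__(self, message: str, residuals: np.ndarray | None = None):
        super().__init__(message)
        self.residuals = residuals


@dataclass(frozen=True)
class PSDEstimate:
    """One-sided, block-averaged power spectral density (DC bin excluded).

    ``power`` is in signal-units^2/Hz, normalised so that
    ``sum(power) * df`` approximates the variance of the mean-removed input.
    """

    frequencies: np.ndarray
    power: np.ndarray
    n_blocks: int

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        p = np.asarray(self.power, dtype=float)
        if f.shape != p.shape or f.ndim != 1:
            raise InvalidParameterError("frequencies and power must be equal-length 1-D")
        if f.size and (f[0] <= 0 or np.any(np.diff(f) <= 0)):
            raise InvalidParameterError("frequencies must be strictly increasing and > 0")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "power", p)

    @property
    def df(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])

    def integral(self) -> float:
        """Total power = integral of the density over the one-sided band."""
        return float(np.sum(self.power) * self.df)


@dataclass(frozen=True)
class LorentzianFit:
    """Fitted Lorentzian: corner frequency f0 (Hz), amplitude scale
    (the fitted kB T / (pi^2 gamma) numerator), sum of squared log-residuals,
    and the stiffness ``2 pi f0 gamma`` implied by the supplied drag."""

    corner_frequency: float
    amplitude: float
    residual: float
    stiffness: float


@dataclass(frozen=True)
class StiffnessEstimates:
    """The two passive estimates for one axis, N/m."""

    equipartition: float
    power_spectrum: float
    axis: str = "x"


def equipartition_stiffness(
    positions: np.ndarray, temperature: float, kB: float = BOLTZMANN_CONSTANT
) -> float:
    """Stiffness from the equipartition theorem, ``k = kB T / var(x)``.

    The equilibrium position is estimated by the sample mean; variance is
    taken about it.
    """
    x = np.asarray(positions, dtype=float)
    if x.size < 2:
        raise InvalidParameterError("need at least 2 samples")
    if np.all(x == x[0]):
        raise DegenerateInputError("position signal is constant; no fluctuations")
    var = float(np.var(x, ddof=1))
    if var <= 0:
        raise DegenerateInputError("position variance is zero; no fluctuations")
    return kB * temperature / var


def lorentzian_psd(
    frequency: np.ndarray | float,
    f0: float,
    drag: float,
    temperature: float,
    kB: float = BOLTZMANN_CONSTANT,
) -> np.ndarray | float:
    """Closed-form one-sided PSD of an overdamped trapped bead, m^2/Hz:
    ``Sxx(f) = kB T / (pi^2 gamma (f0^2 + f^2))``."""
    if drag <= 0:
        raise InvalidParameterError("drag must be > 0")
    if f0 < 0:
        raise InvalidParameterError("f0 must be >= 0")
    f = np.asarray(frequency, dtype=float)
    if f0 == 0 and np.any(f == 0):
        raise InvalidParameterError("Sxx diverges at f = f0 = 0")
    out = kB * temperature / (np.pi**2 * drag * (f0**2 + f**2))
    return out if out.ndim else float(out)


def estimate_psd(
    positions: np.ndarray, sampling_rate: float, n_blocks: int = 8
) -> PSDEstimate:
    """Block-averaged (Bartlett) periodogram of a position signal.

    The record is cut into ``n_blocks`` equal non-overlapping rectangular
    blocks whose periodograms are averaged; any remainder is discarded.
    The DC bin is dropped.  With ``n_blocks = 1`` this is the plain
    periodogram of the mean-removed signal.
    """
    x = np.asarray(positions, dtype=float)
    if n_blocks < 1:
        raise InvalidParameterError("n_blocks must be >= 1")
    nperseg = x.size // n_blocks
    if nperseg < 2:
        raise InvalidParameterError(
            f"{x.size} samples leave fewer than 2 per block with {n_blocks} blocks"
        )
    freqs, power = welch(
        x,
        fs=sampling_rate,
        window="boxcar",
        nperseg=nperseg,
        noverlap=0,
        detrend="constant",
        return_onesided=True,
        scaling="density",
    )
    return PSDEstimate(frequencies=freqs[1:], power=power[1:], n_blocks=n_blocks)


def _fit_band_mask(psd: PSDEstimate, fit_band: tuple[float, float]) -> np.ndarray:
    lo, hi = fit_band
    if not lo < hi:
        raise InvalidParameterError("fit_band must satisfy lo < hi")
    return (psd.frequencies >= lo) & (psd.frequencies <= hi)


def fit_lorentzian(
    psd: PSDEstimate,
    drag: float,
    temperature: float,
    fit_band: tuple[float, float] = (1.0, 1000.0),
    kB: float = BOLTZMANN_CONSTANT,
) -> LorentzianFit:
    """Least-squares Lorentzian fit of a PSD in log-power space.

    Periodogram noise is multiplicative, so residuals are taken on
    ``log(power)`` with uniform weights.  Free parameters are the corner
    frequency f0 and the amplitude A of ``S(f) = A / (f0^2 + f^2)``; the
    initial f0 guess is the frequency where power first falls to half the
    low-frequency plateau.  Raises :class:`FitFailureError` if the optimiser
    fails or the fitted corner lands outside the fit band (as for a
    cornerless, white spectrum).
    """
    if drag <= 0:
        raise InvalidParameterError("drag must be > 0")
    mask = _fit_band_mask(psd, fit_band)
    f = psd.frequencies[mask]
    p = psd.power[mask]
    if f.size < 10:
        raise InvalidParameterError(
            f"only {f.size} frequency bins inside fit band {fit_band}; need >= 10"
        )
    if np.any(p <= 0):
        keep = p > 0
        f, p = f[keep], p[keep]
        if f.size < 10:
            raise DegenerateInputError("fit band contains too few positive-power bins")

    plateau = float(np.mean(p[: max(3, f.size // 50)]))
    below = np.nonzero(p <= 0.5 * plateau)[0]
    f0_guess = float(f[below[0]]) if below.size else float(f[f.size // 2])
    a_guess = plateau * f0_guess**2
    log_p = np.log(p)

    def resid(u: np.ndarray) -> np.ndarray:
        log_f0, log_a = u
        return log_a - np.log(np.exp(2 * log_f0) + f**2) - log_p

    sol = least_squares(resid, x0=[np.log(f0_guess), np.log(a_guess)], method="lm")
    if not sol.success:
        raise FitFailureError("Lorentzian fit did not converge", sol.fun)
    f0 = float(np.exp(sol.x[0]))
    amplitude = float(np.exp(sol.x[1]))
    residual = float(np.sum(sol.fun**2))
    if not fit_band[0] <= f0 <= fit_band[1]:
        raise FitFailureError(
            f"fitted corner {f0:.3g} Hz lies outside the fit band {fit_band}; "
            "the spectrum shows no resolvable corner",
            sol.fun,
        )
    return LorentzianFit(
        corner_frequency=f0,
        amplitude=amplitude,
        residual=residual,
        stiffness=2.0 * np.pi * f0 * drag,
    )


def calibrate_axis(
    positions: np.ndarray,
    sampling_rate: float,
    drag: float,
    temperature: float,
    n_blocks: int = 8,
    fit_band: tuple[float, float] | None = None,
    axis: str = "x",
) -> StiffnessEstimates:
    """Run both passive estimators on one axis and report both stiffnesses.

    Default fit band is [1 Hz, sampling_rate / 10]: above slow drift, and
    far enough below Nyquist that the aliased spectral tail (which lies
    above the Lorentzian and would bias f0 upward) is negligible.
    """
    if fit_band is None:
        fit_band = (1.0, sampling_rate / 10.0)
    k_eq = equipartition_stiffness(positions, temperature)
    psd = estimate_psd(positions, sampling_rate, n_blocks=n_blocks)
    fit = fit_lorentzian(psd, drag, temperature, fit_band=fit_band)
    return StiffnessEstimates(
        equipartition=k_eq, power_spectrum=fit.stiffness, axis=axis
    )
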