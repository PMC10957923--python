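"""Forward model of the Randles equivalent circuit.

An impedimetric biosensor read out by electrochemical impedance spectroscopy
(EIS) is modelled as the electrolyte resistance ``Rs`` in series with the
parallel combination of (a) a constant phase element (CPE) standing in for the
non-ideal double-layer capacitance of an inhomogeneous electrode surface and
(b) the faradaic branch: the charge-transfer resistance ``Rct`` in series with
a Warburg element describing mass transport of the redox probe:

    Z(omega) = Rs + [ Z_CPE(omega)^-1 + (Rct + Z_W(omega))^-1 ]^-1

On a Nyquist plot (Re Z vs -Im Z) this traces a semicircle of diameter ``Rct``
at high frequency followed by a diffusion tail at low frequency.  ``Rct`` is
the analyte-proportional signal: target binding hinders diffusion of the
ferro/ferricyanide couple to the electrode and grows the semicircle.

Conventions: frequencies are in Hz (omega = 2*pi*f), spectra are stored
high-to-low frequency matching instrument sweep order, and impedance is stored
as measured, i.e. Im(Z) <= 0 in the capacitive region.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Any, Mapping

import numpy as np

__all__ = [
    "WarburgVariant",
    "RandlesParameters",
    "SpectrumMeta",
    "ImpedanceSpectrum",
    "cpe_impedance",
    "warburg_impedance",
    "randles_impedance",
    "default_frequency_grid",
    "FREQ_MAX_HZ",
    "FREQ_MIN_HZ",
    "DC_POTENTIAL_V",
    "AC_AMPLITUDE_V",
]

# Measurement protocol constants: 0.2 V DC bias, 10 mV AC perturbation,
# sweep from 100 kHz down to 0.1 Hz.
FREQ_MAX_HZ = 1e5
FREQ_MIN_HZ = 0.1
DC_POTENTIAL_V = 0.2
AC_AMPLITUDE_V = 0.010


class WarburgVariant(str, enum.Enum):
    """Which diffusion element closes the faradaic branch.

    ``open_bounded`` is the finite-length "open" (reflective) Warburg,
    Z = w_r * coth(s)/s with s = (i*omega*w_tau)**w_phi, which blocks at DC.
    ``semi_infinite`` is the classical Warburg with a constant -45 deg phase.
    ``none`` drops the element entirely (pure RC semicircle).
    """

    OPEN_BOUNDED = "open_bounded"
    SEMI_INFINITE = "semi_infinite"
    NONE = "none"


@dataclass(frozen=True)
class RandlesParameters:
    """Scalar parameters of the Randles circuit.

    Parameters
    ----------
    rs : float
        Electrolyte (solution) resistance, ohm. ``rs >= 0``.
    rct : float
        Charge-transfer resistance, ohm. ``rct > 0``. The assay signal.
    q : float
        CPE coefficient, S*s^n. ``q > 0``. Equals the double-layer
        capacitance when ``n == 1``.
    n : float
        CPE exponent, dimensionless, ``0 < n <= 1``.
    w_r : float
        Warburg magnitude: ohm for the bounded variant, ohm*s^-1/2 for the
        semi-infinite variant. ``w_r >= 0``.
    w_tau : float
        Warburg time constant, s (bounded variant only). ``w_tau > 0``.
    w_phi : float
        Warburg exponent, ``0 < w_phi <= 0.5``; 0.5 is the ideal diffusive
        value and the default.
    warburg_variant : WarburgVariant
        Diffusion element selector.
    """

    rs: float
    rct: float
    q: float
    n: float
    w_r: float = 0.0
    w_tau: float = 1.0
    w_phi: float = 0.5
    warburg_variant: WarburgVariant = WarburgVariant.OPEN_BOUNDED

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "warburg_variant", WarburgVariant(self.warburg_variant)
        )
        if not self.rs >= 0:
            raise ValueError(f"rs must be >= 0, got {self.rs}")
        if not self.rct > 0:
            raise ValueError(f"rct must be > 0, got {self.rct}")
        if not self.q > 0:
            raise ValueError(f"q must be > 0, got {self.q}")
        if not 0 < self.n <= 1:
            raise ValueError(f"n must be in (0, 1], got {self.n}")
        if not self.w_r >= 0:
            raise ValueError(f"w_r must be >= 0, got {self.w_r}")
        if self.warburg_variant is WarburgVariant.OPEN_BOUNDED and not self.w_tau > 0:
            raise ValueError(f"w_tau must be > 0 for the bounded Warburg, got {self.w_tau}")
        if not 0 < self.w_phi <= 0.5:
            raise ValueError(f"w_phi must be in (0, 0.5], got {self.w_phi}")

    def replace(self, **changes: Any) -> "RandlesParameters":
        return replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return {
            "rs": self.rs,
            "rct": self.rct,
            "q": self.q,
            "n": self.n,
            "w_r": self.w_r,
            "w_tau": self.w_tau,
            "w_phi": self.w_phi,
            "warburg_variant": self.warburg_variant.value,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RandlesParameters":
        return cls(**dict(d))


@dataclass(frozen=True)
class SpectrumMeta:
    """Acquisition metadata carried alongside a spectrum."""

    dc_potential_v: float = DC_POTENTIAL_V
    ac_amplitude_v: float = AC_AMPLITUDE_V
    electrolyte: str = "1 mM Fe(CN)6 3-/4- in 0.1 M KCl"
    label: str = ""


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """An EIS measurement: frequencies (Hz, descending) and complex Z (ohm).

    Frequencies must be positive and distinct; they are stored high-to-low,
    the sweep order of the instrument. The constructor re-sorts if needed.
    """

    frequency: np.ndarray
    z: np.ndarray
    meta: SpectrumMeta = field(default_factory=SpectrumMeta)

    def __post_init__(self) -> None:
        f = np.atleast_1d(np.asarray(self.frequency, dtype=float))
        z = np.atleast_1d(np.asarray(self.z, dtype=complex))
        if f.shape != z.shape:
            raise ValueError(
                f"frequency and z lengths differ: {f.shape} vs {z.shape}"
            )
        if f.size < 1:
            raise ValueError("spectrum needs at least one point")
        if np.any(f <= 0) or not np.all(np.isfinite(f)):
            raise ValueError("all frequencies must be positive and finite")
        uniq, counts = np.unique(f, return_counts=True)
        if np.any(counts > 1):
            raise ValueError(f"duplicate frequencies: {uniq[counts > 1].tolist()}")
        order = np.argsort(f)[::-1]
        f, z = f[order], z[order]
        f.setflags(write=False)
        z.setflags(write=False)
        object.__setattr__(self, "frequency", f)
        object.__setattr__(self, "z", z)

    def __len__(self) -> int:
        return self.frequency.size

    @property
    def omega(self) -> np.ndarray:
        return 2 * np.pi * self.frequency

    def plot_nyquist(self, ax=None, **kwargs):
        """Nyquist plot: -Im(Z) against Re(Z), both in ohm."""
        from .plotting import plot_nyquist

        return plot_nyquist(self, ax=ax, **kwargs)


def cpe_impedance(q: float, n: float, freq) -> np.ndarray | complex:
    """Impedance of a constant phase element, Z = 1 / (q * (i*2*pi*f)**n).

    For ``n == 1`` this is an ideal capacitor of capacitance ``q``; smaller
    exponents model the depressed semicircles of rough electrode surfaces.
    The phase is -n*90 deg at every frequency, so Re >= 0 and Im <= 0.
    """
    freq = np.asarray(freq, dtype=float)
    if not q > 0:
        raise ValueError(f"q must be > 0, got {q}")
    if not 0 < n <= 1:
        raise ValueError(f"n must be in (0, 1], got {n}")
    if np.any(freq <= 0):
        raise ValueError("freq must be > 0")
    z = 1.0 / (q * (2j * np.pi * freq) ** n)
    return z[()] if z.ndim == 0 else z


def _coth(s: np.ndarray) -> np.ndarray:
    # tanh is overflow-safe for large |Re(s)|; s never approaches the
    # imaginary axis here because arg(s) = w_phi*90 deg <= 45 deg.
    return 1.0 / np.tanh(s)


def warburg_impedance(w_r: float, w_tau: float, w_phi: float, variant, freq):
    """Impedance of the diffusion element.

    open_bounded:   Z = w_r * coth(s) / s,  s = (i*2*pi*f*w_tau)**w_phi
    semi_infinite:  Z = w_r * (2*pi*f)**-0.5 * (1 - i)
    none:           Z = 0

    The bounded form tends to w_r/s at high frequency (phase -w_phi*90 deg)
    and to the blocking limit w_r*(1/s**2 + 1/3) as s -> 0.
    """
    variant = WarburgVariant(variant)
    freq = np.asarray(freq, dtype=float)
    if np.any(freq <= 0):
        raise ValueError("freq must be > 0")
    if variant is WarburgVariant.NONE:
        z = np.zeros_like(freq, dtype=complex)
        return z[()] if z.ndim == 0 else z
    if not w_r >= 0:
        raise ValueError(f"w_r must be >= 0, got {w_r}")
    if variant is WarburgVariant.SEMI_INFINITE:
        z = w_r * (2 * np.pi * freq) ** -0.5 * (1 - 1j)
        return z[()] if z.ndim == 0 else z
    if not w_tau > 0:
        raise ValueError(f"w_tau must be > 0, got {w_tau}")
    if not 0 < w_phi <= 0.5:
        raise ValueError(f"w_phi must be in (0, 0.5], got {w_phi}")
    s = (2j * np.pi * freq * w_tau) ** w_phi
    small = np.abs(s) < 1e-4
    z = np.empty(np.shape(s), dtype=complex)
    s_arr = np.atleast_1d(s)
    z_arr = np.atleast_1d(z)
    small_arr = np.atleast_1d(small)
    # series coth(s)/s = 1/s^2 + 1/3 - s^2/45 + ... avoids 0/0 at tiny |s|
    ss = s_arr[small_arr]
    z_arr[small_arr] = w_r * (1.0 / ss**2 + 1.0 / 3.0 - ss**2 / 45.0)
    sb = s_arr[~small_arr]
    z_arr[~small_arr] = w_r * _coth(sb) / sb
    z = z_arr.reshape(np.shape(s))
    return z[()] if z.ndim == 0 else z


def randles_impedance(params: RandlesParameters, frequencies) -> ImpedanceSpectrum:
    """Evaluate the full Randles circuit on a frequency grid.

    Z = rs + 1 / ( 1/Z_CPE + 1/(rct + Z_W) ), per frequency. Deterministic;
    returns an :class:`ImpedanceSpectrum` sorted high-to-low frequency.
    """
    freq = np.atleast_1d(np.asarray(frequencies, dtype=float))
    if freq.size < 1 or np.any(freq <= 0):
        raise ValueError("need at least one positive frequency")
    z_cpe = cpe_impedance(params.q, params.n, freq)
    z_w = warburg_impedance(
        params.w_r, params.w_tau, params.w_phi, params.warburg_variant, freq
    )
    z = params.rs + 1.0 / (1.0 / z_cpe + 1.0 / (params.rct + z_w))
    return ImpedanceSpectrum(frequency=freq, z=np.atleast_1d(z))


def default_frequency_grid(points_per_decade: int = 10) -> np.ndarray:
    """Log-spaced descending grid over the standard sweep, 100 kHz to 0.1 Hz.

    Six decades; ``points_per_decade`` points in each plus the final
    endpoint, so 10 points/decade gives 61 frequencies.
    """
    ppd = int(points_per_decade)
    if ppd < 1:
        raise ValueError("points_per_decade must be >= 1")
    n_dec = int(round(np.log10(FREQ_MAX_HZ / FREQ_MIN_HZ)))
    grid = np.logspace(np.log10(FREQ_MAX_HZ), np.log10(FREQ_MIN_HZ), n_dec * ppd + 1)
    grid[0] = FREQ_MAX_HZ
    grid[-1] = FREQ_MIN_HZ
    return grid
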