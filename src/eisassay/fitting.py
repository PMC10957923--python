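"""Complex nonlinear least-squares (CNLS) estimation of Randles parameters.

The fitter minimises the jointly weighted sum of squared real and imaginary
residuals

    chi2(theta) = sum_k w_k * [ (ReZ_k - ReZhat_k)^2 + (ImZ_k - ImZhat_k)^2 ]

with modulus weighting w_k = 1/|Z_k|^2 by default, which equalises the
influence of points across the decades of |Z| a sweep spans. The
charge-transfer resistance Rct extracted from the optimum is the assay
signal; all downstream calibration statistics consume it.

Scale parameters (rct, q, w_tau) are optimised in log10 space, which makes
the problem well conditioned across their many-decade bounds; standard
errors are mapped back to natural units by the delta method and scaled by
the reduced chi-square (asymptotic, Jacobian-based).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import least_squares

from .circuit import (
    ImpedanceSpectrum,
    RandlesParameters,
    WarburgVariant,
    randles_impedance,
)

__all__ = [
    "FitOptions",
    "CircuitFitResult",
    "RandlesModel",
    "DegenerateSpectrumError",
    "NotConvergedError",
    "initial_guess",
    "fit_randles",
    "extract_rct",
]

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "rs": (0.0, 1e5),
    "rct": (1.0, 1e8),
    "q": (1e-12, 1e-1),
    "n": (0.5, 1.0),
    "w_r": (0.0, 1e8),
    "w_tau": (1e-4, 1e4),
    "w_phi": (0.01, 0.5),
}

# parameters optimised as log10(value); all strictly positive with wide ranges
_LOG_PARAMS = frozenset({"rct", "q", "w_tau"})


class DegenerateSpectrumError(ValueError):
    """Spectrum has no usable semicircle (flat/monotone -Im, or too few points)."""


class NotConvergedError(RuntimeError):
    """Raised when a converged fit is required but the fit did not converge."""


@dataclass(frozen=True)
class FitOptions:
    """Tuning knobs for the CNLS fit.

    weighting: 'modulus' (1/|Z|^2, default), 'unit', or 'proportional'
    (element-wise 1/value^2 on real and imaginary parts separately).
    ``fix`` names parameters frozen at their initial values. ``multistart``
    > 1 adds seeded log-uniform x[1/3, 3] jitters around the start and keeps
    the best chi2.
    """

    weighting: str = "modulus"
    bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    tol: float = 1e-10
    max_iter: int = 1000
    multistart: int = 1
    seed: int = 0
    fix: frozenset[str] = frozenset()
    fit_w_phi: bool = False

    def __post_init__(self) -> None:
        if self.weighting not in ("modulus", "unit", "proportional"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        for name, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {name} must be finite with lo < hi")
        object.__setattr__(self, "fix", frozenset(self.fix))


@dataclass(frozen=True)
class CircuitFitResult:
    """Outcome of a Randles-circuit fit.

    ``params`` are the point estimates, ``stderr`` the per-parameter
    asymptotic standard errors (same units; NaN for fixed parameters),
    ``chi2`` the weighted residual sum of squares and ``dof`` the residual
    degrees of freedom 2N - n_free.
    """

    params: RandlesParameters
    stderr: dict[str, float]
    chi2: float
    dof: int
    weighting: str
    converged: bool
    n_iter: int
    init: RandlesParameters
    message: str = ""

    @property
    def rct(self) -> float:
        return self.params.rct

    @property
    def rct_stderr(self) -> float:
        return self.stderr.get("rct", float("nan"))

    @property
    def reduced_chi2(self) -> float:
        return self.chi2 / self.dof

    def summary(self) -> str:
        lines = [
            "Randles circuit fit (CNLS)",
            f"  variant    : {self.params.warburg_variant.value}",
            f"  weighting  : {self.weighting}",
            f"  converged  : {self.converged}  ({self.message})",
            f"  chi2 / dof : {self.chi2:.6g} / {self.dof}",
            "  %-6s %14s %14s" % ("param", "estimate", "std err"),
        ]
        for name in ("rs", "rct", "q", "n", "w_r", "w_tau", "w_phi"):
            se = self.stderr.get(name, float("nan"))
            lines.append(
                "  %-6s %14.6g %14.6g" % (name, getattr(self.params, name), se)
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "stderr": dict(self.stderr),
            "chi2": self.chi2,
            "dof": self.dof,
            "weighting": self.weighting,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "init": self.init.to_dict(),
            "message": self.message,
        }


def initial_guess(spectrum: ImpedanceSpectrum) -> RandlesParameters:
    """Geometric starting point read off the Nyquist curve.

    rs from the high-frequency real intercept; rct from the semicircle apex
    (at the apex Re(Z) - rs = rct/2 for an ideal semicircle); q from the
    apex frequency via omega_peak = 1/(rct*q); Warburg magnitude from the
    residual low-frequency real extent.
    """
    f = spectrum.frequency
    z = spectrum.z
    if len(spectrum) < 6 or f[0] / f[-1] < 100:
        raise DegenerateSpectrumError(
            "need >= 6 points spanning >= 2 decades for an initial guess"
        )
    neg_im = -z.imag
    # light smoothing so measurement noise cannot fake a semicircle apex
    if len(f) >= 9:
        kernel = np.ones(3) / 3
        smooth = np.convolve(neg_im, kernel, mode="same")
        smooth[0], smooth[-1] = neg_im[0], neg_im[-1]
    else:
        smooth = neg_im
    interior = np.arange(1, len(f) - 1)
    peaks = interior[
        (smooth[interior] > smooth[interior - 1])
        & (smooth[interior] >= smooth[interior + 1])
    ]
    # a real apex is on the scale of the semicircle diameter = real-axis
    # span; tiny high-frequency noise blips are not semicircle apexes (the
    # -Im scale itself is no yardstick: the blocking Warburg tail can dwarf
    # the semicircle at low frequency)
    peaks = peaks[smooth[peaks] > 0.05 * np.ptp(z.real)]
    if peaks.size == 0:
        raise DegenerateSpectrumError(
            "-Im(Z) has no interior maximum; no semicircle to anchor the guess"
        )
    k = peaks[0]  # highest-frequency peak = charge-transfer semicircle apex
    rs = max(z.real[0], 0.0)
    rct = max(2.0 * (z.real[k] - rs), DEFAULT_BOUNDS["rct"][0])
    f_peak = f[k]
    q = 1.0 / (2 * np.pi * f_peak * rct)
    w_r = max(z.real[-1] - rs - rct, 1.0)
    w_tau = 1.0 / (2 * np.pi * f[-1])
    return RandlesParameters(
        rs=rs, rct=rct, q=q, n=0.9, w_r=w_r, w_tau=w_tau, w_phi=0.5,
        warburg_variant=WarburgVariant.OPEN_BOUNDED,
    )


def _free_names(variant: WarburgVariant, options: FitOptions) -> list[str]:
    names = ["rs", "rct", "q", "n"]
    if variant is WarburgVariant.SEMI_INFINITE:
        names.append("w_r")
    elif variant is WarburgVariant.OPEN_BOUNDED:
        names += ["w_r", "w_tau"]
        if options.fit_w_phi:
            names.append("w_phi")
    return [n for n in names if n not in options.fix]


def _to_internal(name: str, value: float) -> float:
    return math.log10(value) if name in _LOG_PARAMS else value


def _from_internal(name: str, u: float) -> float:
    return 10.0**u if name in _LOG_PARAMS else u


class RandlesModel:
    """Model object binding a spectrum to the Randles circuit for fitting.

    Parameters
    ----------
    spectrum : ImpedanceSpectrum
        The measured (or simulated) spectrum.
    variant : WarburgVariant or str
        Circuit variant to fit; default the bounded "open" Warburg.
    options : FitOptions, optional

    ``fit()`` returns a :class:`CircuitFitResult`. Non-convergence is
    reported in the result (``converged=False``), never silently.
    """

    def __init__(
        self,
        spectrum: ImpedanceSpectrum,
        variant: WarburgVariant | str = WarburgVariant.OPEN_BOUNDED,
        options: FitOptions | None = None,
    ) -> None:
        self.spectrum = spectrum
        self.variant = WarburgVariant(variant)
        self.options = options or FitOptions()
        self._weights = self._make_weights()

    def _make_weights(self) -> tuple[np.ndarray, np.ndarray]:
        z = self.spectrum.z
        w = self.options.weighting
        if w == "modulus":
            wr = wi = 1.0 / np.maximum(np.abs(z), 1e-300) ** 2
        elif w == "unit":
            wr = wi = np.ones(len(self.spectrum))
        else:  # proportional: element-wise 1/value^2
            wr = 1.0 / np.maximum(np.abs(z.real), 1e-300) ** 2
            wi = 1.0 / np.maximum(np.abs(z.imag), 1e-300) ** 2
        return np.sqrt(wr), np.sqrt(wi)

    def _params_from_vector(
        self, u: np.ndarray, names: list[str], base: RandlesParameters
    ) -> RandlesParameters:
        changes = {nm: _from_internal(nm, ui) for nm, ui in zip(names, u)}
        return base.replace(**changes)

    def _residuals(
        self, u: np.ndarray, names: list[str], base: RandlesParameters
    ) -> np.ndarray:
        p = self._params_from_vector(u, names, base)
        zhat = randles_impedance(p, self.spectrum.frequency).z
        dz = self.spectrum.z - zhat
        swr, swi = self._weights
        return np.concatenate([swr * dz.real, swi * dz.imag])

    def fit(self, init: RandlesParameters | None = None) -> CircuitFitResult:
        opts = self.options
        if init is None:
            init = initial_guess(self.spectrum)
        init = init.replace(warburg_variant=self.variant)
        names = _free_names(self.variant, opts)
        if not names:
            raise ValueError("no free parameters to fit")
        n_res = 2 * len(self.spectrum)
        dof = n_res - len(names)
        if dof <= 0:
            raise DegenerateSpectrumError(
                f"{len(self.spectrum)} points cannot constrain {len(names)} parameters"
            )

        lo = np.array([_to_internal(nm, max(opts.bounds[nm][0], 1e-300)) for nm in names])
        hi = np.array([_to_internal(nm, opts.bounds[nm][1]) for nm in names])

        def clip(u: np.ndarray) -> np.ndarray:
            return np.clip(u, lo, hi)

        u0 = clip(np.array([_to_internal(nm, getattr(init, nm)) for nm in names]))
        starts = [u0]
        if opts.multistart > 1:
            rng = np.random.default_rng(opts.seed)
            for _ in range(opts.multistart - 1):
                jitter = 3.0 ** rng.uniform(-1, 1, size=len(names))
                u = np.array(
                    [
                        _to_internal(nm, _from_internal(nm, ui) * jf)
                        for nm, ui, jf in zip(names, u0, jitter)
                    ]
                )
                starts.append(clip(u))

        best = None
        for u_start in starts:
            sol = least_squares(
                self._residuals,
                u_start,
                args=(names, init),
                bounds=(lo, hi),
                method="trf",
                xtol=opts.tol,
                ftol=opts.tol,
                gtol=opts.tol,
                max_nfev=opts.max_iter * max(len(names), 1),
                x_scale="jac",
            )
            if best is None or sol.cost < best.cost:
                best = sol

        chi2 = 2.0 * best.cost
        params = self._params_from_vector(best.x, names, init)
        converged = bool(best.status > 0) and np.isfinite(chi2)
        stderr = self._stderr(best, names, params, chi2, dof)
        return CircuitFitResult(
            params=params,
            stderr=stderr,
            chi2=float(chi2),
            dof=int(dof),
            weighting=opts.weighting,
            converged=converged,
            n_iter=int(best.nfev),
            init=init,
            message=str(best.message),
        )

    @staticmethod
    def _stderr(
        sol, names: list[str], params: RandlesParameters, chi2: float, dof: int
    ) -> dict[str, float]:
        J = sol.jac
        try:
            cov = np.linalg.pinv(J.T @ J) * max(chi2, 0.0) / dof
            se_u = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        except np.linalg.LinAlgError:
            se_u = np.full(len(names), np.nan)
        out: dict[str, float] = {}
        for nm, se in zip(names, se_u):
            if nm in _LOG_PARAMS:  # delta method: d(10^u) = 10^u ln10 du
                out[nm] = float(getattr(params, nm) * math.log(10) * se)
            else:
                out[nm] = float(se)
        return out


def fit_randles(
    spectrum: ImpedanceSpectrum,
    options: FitOptions | None = None,
    init: RandlesParameters | None = None,
    variant: WarburgVariant | str | None = None,
) -> CircuitFitResult:
    """Fit the Randles circuit to a spectrum; see :class:`RandlesModel`.

    ``variant`` defaults to the initial guess's variant (the bounded Warburg
    when the guess is automatic).
    """
    if variant is None:
        variant = (
            init.warburg_variant if init is not None else WarburgVariant.OPEN_BOUNDED
        )
    return RandlesModel(spectrum, variant=variant, options=options).fit(init=init)


def extract_rct(fit: CircuitFitResult) -> tuple[float, float]:
    """Return (rct, stderr) from a converged fit; refuse otherwise.

    Rct is the only circuit parameter proportional to analyte concentration,
    so it is the quantity carried into calibration.
    """
    if not fit.converged:
        raise NotConvergedError(
            f"cannot extract Rct from a non-converged fit: {fit.message}"
        )
    return fit.params.rct, fit.rct_stderr
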