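"""Seeded synthetic data emulating a paper-strip impedimetric assay.

Generates every input the analysis pipeline consumes — Nyquist spectra,
semi-log and Langmuir dose-response series, blank replicates, repeatability
sets, selectivity panels — with the statistical structure the assay
statistics assume:

* spectrum-level noise: proportional complex Gaussian, Z*(1+eps) with the
  real and imaginary components of eps i.i.d. N(0, sigma^2/2) (default
  sigma = 0.01, instrument-like);
* electrode-level variability: log-normal multiplicative scatter on Rct,
  exp(N(0, sigma_e^2)) (default sigma_e = 0.10, matching the ~10-11%
  inter-electrode RSD of hand-made screen-printed strips).

Every draw is a pure function of (config, seed): one global seed is split
into per-operation substreams keyed by (seed, operation name, index), so
results do not depend on call order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np

from .circuit import (
    ImpedanceSpectrum,
    RandlesParameters,
    SpectrumMeta,
    default_frequency_grid,
    randles_impedance,
)
from .assay import DoseResponseSeries

__all__ = [
    "ScenarioConfig",
    "substream",
    "simulate_spectrum",
    "simulate_dose_response",
    "simulate_panel",
    "INTEGRIN_SEMILOG",
    "SEV_SEMILOG",
    "INTEGRIN_LANGMUIR",
    "DEFAULT_BASE_PARAMS",
]

# Printed calibration lines of the assay: Rct [ohm] = slope*log10(c) + intercept.
INTEGRIN_SEMILOG = {"model": "semilog", "slope": 10944.0, "intercept": 3940.0}
SEV_SEMILOG = {"model": "semilog", "slope": 5860.0, "intercept": 11400.0}
# Apparent binding constant of the surface-bound probe, ng/mL.
INTEGRIN_LANGMUIR = {
    "model": "langmuir",
    "k_app": 5.3,
    "delta_rct_max": 45000.0,
    "baseline_rct": 3000.0,
}

# Blank-electrode circuit of a nano-engineered strip in ferro/ferricyanide:
# small solution resistance, kilo-ohm-scale Rct, depressed double layer,
# bounded diffusion tail.
DEFAULT_BASE_PARAMS = RandlesParameters(
    rs=200.0, rct=2000.0, q=5e-6, n=0.9, w_r=2000.0, w_tau=10.0
)


def substream(seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Deterministic RNG substream keyed by (seed, operation name, index)."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key, int(index)]))


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of one simulated assay campaign.

    ``response`` selects the dose-response law and carries its parameters:
    {"model": "semilog", "slope", "intercept"} or {"model": "langmuir",
    "k_app", "delta_rct_max", "baseline_rct"}. ``noise_sigma`` is the
    spectrum-level proportional sigma, ``sigma_e`` the electrode-level Rct
    sigma. ``blank_rct`` defaults to half the response at the lowest
    concentration for the semi-log law (whose line does not extend to zero
    analyte) and to the baseline for the Langmuir law.
    """

    analyte: str = "avb6 integrin"
    unit: str = "ng/mL"
    base_params: RandlesParameters = DEFAULT_BASE_PARAMS
    response: Mapping[str, Any] = field(
        default_factory=lambda: dict(INTEGRIN_SEMILOG)
    )
    concentrations: tuple[float, ...] = (1.0, 2.0, 4.0, 5.0, 10.0, 20.0)
    replicates: int = 3
    n_blanks: int = 3
    noise_sigma: float = 0.01
    sigma_e: float = 0.10
    blank_rct: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0 or self.sigma_e < 0:
            raise ValueError("noise sigmas must be >= 0")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be > 0")
        if self.replicates < 1 or self.n_blanks < 0:
            raise ValueError("replicates must be >= 1 and n_blanks >= 0")
        object.__setattr__(self, "response", dict(self.response))
        object.__setattr__(
            self, "concentrations", tuple(float(c) for c in self.concentrations)
        )

    def true_rct(self, concentration: float) -> float:
        """Noise-free Rct at a concentration under the response law."""
        r = self.response
        if r["model"] == "semilog":
            return r["slope"] * np.log10(concentration) + r["intercept"]
        if r["model"] == "langmuir":
            return r["baseline_rct"] + r["delta_rct_max"] * concentration / (
                r["k_app"] + concentration
            )
        raise ValueError(f"unknown response model {r['model']!r}")

    def true_blank_rct(self) -> float:
        if self.blank_rct is not None:
            return float(self.blank_rct)
        r = self.response
        if r["model"] == "langmuir":
            return float(r["baseline_rct"])
        # the semi-log line is undefined at c = 0; anchor blanks at half the
        # response at the lowest calibrated concentration
        return 0.5 * self.true_rct(min(self.concentrations))

    def to_dict(self) -> dict[str, Any]:
        return {
            "analyte": self.analyte,
            "unit": self.unit,
            "base_params": self.base_params.to_dict(),
            "response": dict(self.response),
            "concentrations": list(self.concentrations),
            "replicates": self.replicates,
            "n_blanks": self.n_blanks,
            "noise_sigma": self.noise_sigma,
            "sigma_e": self.sigma_e,
            "blank_rct": self.blank_rct,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ScenarioConfig":
        d = dict(d)
        if isinstance(d.get("base_params"), Mapping):
            d["base_params"] = RandlesParameters.from_dict(d["base_params"])
        if "concentrations" in d:
            d["concentrations"] = tuple(d["concentrations"])
        return cls(**d)


def simulate_spectrum(
    params: RandlesParameters,
    grid: np.ndarray | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    label: str = "",
) -> ImpedanceSpectrum:
    """Randles spectrum with proportional complex Gaussian noise.

    Z_k = Z_model(f_k) * (1 + eps_k), eps_k = (a + i*b)/sqrt(2) * sigma with
    a, b ~ N(0,1). noise_sigma = 0 returns exactly the forward model.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if grid is None:
        grid = default_frequency_grid(10)
    spec = randles_impedance(params, grid)
    z = spec.z
    if noise_sigma > 0:
        rng = substream(seed, "spectrum")
        eps = (
            rng.normal(0.0, noise_sigma / np.sqrt(2), z.size)
            + 1j * rng.normal(0.0, noise_sigma / np.sqrt(2), z.size)
        )
        z = z * (1 + eps)
    return ImpedanceSpectrum(
        frequency=spec.frequency, z=z, meta=SpectrumMeta(label=label)
    )


def simulate_dose_response(
    config: ScenarioConfig,
    full_spectra: bool = False,
    grid: np.ndarray | None = None,
) -> tuple[DoseResponseSeries, dict]:
    """Simulate a dose-response campaign.

    For each concentration level and electrode replicate the true Rct from
    the response law is multiplied by a log-normal electrode effect
    exp(N(0, sigma_e^2)); blanks are drawn identically around the blank Rct.
    With ``full_spectra=True`` each electrode additionally yields a whole
    noisy spectrum with its Rct substituted into the base circuit, keyed
    ``(concentration, replicate)`` (blanks under concentration 0.0).

    Returns ``(series, truth)``; ``truth`` holds the generating Rct values
    and, when requested, the spectra.
    """
    if grid is None:
        grid = default_frequency_grid(10)
    points = []
    truth: dict[str, Any] = {
        "config": config.to_dict(),
        "true_rct": {},
        "sampled_rct": {},
        "spectra": {} if full_spectra else None,
    }

    def draw_level(conc_key: float, true_rct: float, n: int, idx: int) -> np.ndarray:
        rng = substream(config.seed, "electrode_effect", idx)
        if config.sigma_e > 0:
            effects = np.exp(rng.normal(0.0, config.sigma_e, n))
        else:
            effects = np.ones(n)
        rcts = true_rct * effects
        if full_spectra:
            for rep, rct in enumerate(rcts):
                p = config.base_params.replace(rct=float(rct))
                truth["spectra"][(conc_key, rep)] = simulate_spectrum(
                    p,
                    grid,
                    config.noise_sigma,
                    seed=int(substream(config.seed, "spectrum_seed", idx * 1000 + rep)
                             .integers(0, 2**31 - 1)),
                    label=f"c={conc_key:g} {config.unit} rep={rep}",
                )
        return rcts

    blank_true = config.true_blank_rct()
    blanks = draw_level(0.0, blank_true, config.n_blanks, 0) if config.n_blanks else np.array([])
    truth["true_rct"][0.0] = blank_true
    truth["sampled_rct"][0.0] = blanks.tolist()
    for i, c in enumerate(config.concentrations, start=1):
        t = config.true_rct(c)
        reps = draw_level(c, t, config.replicates, i)
        truth["true_rct"][c] = t
        truth["sampled_rct"][c] = reps.tolist()
        points.append((c, reps))
    series = DoseResponseSeries(
        analyte=config.analyte,
        unit=config.unit,
        points=tuple(points),
        blanks=blanks,
    )
    return series, truth


def simulate_panel(
    effects: Mapping[str, float],
    blank_mean: float = 2000.0,
    blank_rsd: float = 0.05,
    replicates: int = 5,
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Selectivity/condition panel: per-label replicate Rct draws.

    Each label's replicates are drawn at blank_mean * (1 + effect) with
    multiplicative log-normal noise of relative width ``blank_rsd``; a blank
    replicate set is drawn at effect 0. Returns (groups, blanks), ready for
    :func:`eisassay.assay.compare_conditions`.
    """
    if replicates < 2:
        raise ValueError("need >= 2 replicates per group")
    if not blank_mean > 0:
        raise ValueError("blank_mean must be > 0")
    sigma = float(blank_rsd)
    groups: dict[str, np.ndarray] = {}
    for i, (label, effect) in enumerate(effects.items()):
        rng = substream(seed, f"panel:{label}", i)
        level = blank_mean * (1.0 + float(effect))
        if level <= 0:
            raise ValueError(f"effect {effect} for {label!r} gives non-positive Rct")
        groups[label] = level * np.exp(rng.normal(0.0, sigma, replicates))
    rng = substream(seed, "panel:blank")
    blanks = blank_mean * np.exp(rng.normal(0.0, sigma, replicates))
    return groups, blanks
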