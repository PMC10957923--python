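import numpy as np
import pytest

from eisassay import RandlesParameters, WarburgVariant, default_frequency_grid


@pytest.fixture
def grid61():
    return default_frequency_grid(10)


@pytest.fixture
def textbook_params():
    """A well-conditioned circuit: visible semicircle plus diffusion tail."""
    return RandlesParameters(
        rs=200.0, rct=10_000.0, q=5e-6, n=0.9, w_r=2_000.0, w_tau=10.0
    )


@pytest.fixture
def rc_params():
    """Ideal-capacitor, no-Warburg circuit: exact Nyquist semicircle."""
    return RandlesParameters(
        rs=200.0, rct=10_000.0, q=5e-6, n=1.0, warburg_variant=WarburgVariant.NONE
    )


def draw_params(rng: np.random.Generator, variant=None) -> RandlesParameters:
    """Random parameter draw producing assay-like spectra: a clear
    semicircle followed by a visible diffusion tail.

    The draw keeps every parameter identifiable from a 100 kHz-0.1 Hz
    sweep: the semicircle apex frequency 1/(2*pi*rct*q) sits well above
    the bounded-Warburg transition 1/(2*pi*w_tau) (so the two features do
    not merge), w_tau stays below ~1.4 s (transition inside the sweep;
    beyond it only w_r/sqrt(w_tau) is identifiable), and the tail magnitude
    w_r is 10-100% of rct (a tail too small to see is a tail too small to
    fit). These are the shapes the instrument produces; spectra outside
    them are degenerate for circuit fitting by construction.
    """
    if variant is None:
        variant = rng.choice(["none", "semi_infinite", "open_bounded"])
    rct = 10.0 ** rng.uniform(3, 5)
    f_apex = 10.0 ** rng.uniform(1.7, 3.7)  # 50 Hz - 5 kHz
    q = 1.0 / (2 * np.pi * f_apex * rct)
    w_tau_lo = max(1e-2, 30 / (2 * np.pi * f_apex))
    return RandlesParameters(
        rs=10.0 ** rng.uniform(1, 3),
        rct=rct,
        q=q,
        n=rng.uniform(0.75, 1.0),
        w_r=rct * 10.0 ** rng.uniform(-1, 0),
        w_tau=10.0 ** rng.uniform(np.log10(w_tau_lo), np.log10(1.4)),
        warburg_variant=variant,
    )
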