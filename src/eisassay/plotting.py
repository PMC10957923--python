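"""Basic Nyquist plotting for impedance spectra."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt


def plot_nyquist(spectrum, ax=None, **kwargs):
    """Plot -Im(Z) vs Re(Z) (both ohm), the conventional Nyquist view.

    The semicircle diameter is the charge-transfer resistance; the
    low-frequency tail reflects diffusion.
    """
    if ax is None:
        _, ax = plt.subplots()
    kwargs.setdefault("marker", "o")
    kwargs.setdefault("ms", 3)
    kwargs.setdefault("lw", 1)
    label = kwargs.pop("label", spectrum.meta.label or None)
    ax.plot(spectrum.z.real, -spectrum.z.imag, label=label, **kwargs)
    ax.set_xlabel(r"Re(Z) / $\Omega$")
    ax.set_ylabel(r"$-$Im(Z) / $\Omega$")
    ax.set_aspect("equal", adjustable="datalim")
    if label:
        ax.legend()
    return ax
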