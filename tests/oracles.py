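"""Independent reference implementations used only to check the package.

Deliberately written on a different code path from eisassay: scalar cmath
arithmetic in polar form, exp-based coth, and explicit admittance summation,
so agreement with the vectorized numpy implementation is meaningful.
"""

import cmath
import math


def cpe_polar(q: float, n: float, freq: float) -> complex:
    """CPE impedance by direct polar-form arithmetic: |Z| = 1/(q w^n), arg = -n*pi/2."""
    w = 2 * math.pi * freq
    mag = 1.0 / (q * w**n)
    ang = -n * math.pi / 2
    return cmath.rect(mag, ang)


def coth_exp(s: complex) -> complex:
    """coth via its exponential definition (no tanh shortcut).

    Uses the exp(-2s) form, which cannot overflow for Re(s) > 0 — always the
    case here since arg(s) = w_phi*90 deg <= 45 deg.
    """
    e2 = cmath.exp(-2 * s)
    return (1 + e2) / (1 - e2)


def coth_series_over_s(s: complex) -> complex:
    """Laurent series of coth(s)/s around 0, for the small-|s| cross-check."""
    return 1 / s**2 + 1 / 3 - s**2 / 45 + 2 * s**4 / 945


def warburg_open(w_r: float, w_tau: float, w_phi: float, freq: float) -> complex:
    s = (2j * math.pi * freq * w_tau) ** w_phi
    return w_r * coth_exp(s) / s


def warburg_semiinf(w_r: float, freq: float) -> complex:
    return w_r * (2 * math.pi * freq) ** -0.5 * (1 - 1j)


def randles_branch_admittance(p, freq: float) -> complex:
    """Independent composition: sum the CPE and faradaic branch admittances."""
    variant = getattr(p.warburg_variant, "value", p.warburg_variant)
    if variant == "open_bounded":
        zw = warburg_open(p.w_r, p.w_tau, p.w_phi, freq)
    elif variant == "semi_infinite":
        zw = warburg_semiinf(p.w_r, freq)
    else:
        zw = 0.0
    w = 2 * math.pi * freq
    y_cpe = p.q * cmath.rect(w**p.n, p.n * math.pi / 2)
    y_faradaic = 1.0 / (p.rct + zw)
    return p.rs + 1.0 / (y_cpe + y_faradaic)


def rc_semicircle(rs: float, rct: float, c: float, freq: float) -> complex:
    """Closed-form ideal-capacitor Randles impedance (n=1, no Warburg)."""
    w = 2 * math.pi * freq
    return rs + rct / (1 + 1j * w * rct * c)
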