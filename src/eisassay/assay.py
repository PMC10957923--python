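"""Assay figures of merit computed from per-electrode Rct values.

Covers the downstream statistics of an impedimetric dose-response assay:

* semi-log calibration  Rct = slope * log10(c) + intercept  over a stated
  linear range, with R^2;
* limits of detection and quantification (two standard conventions: the
  blank-mean + 3*SD signal threshold inverted through the calibration, and
  3.3*sigma_blank/slope applied in the log10-concentration domain);
* Langmuir binding isotherm  Rct(c) = baseline + dRmax * c / (K + c), whose
  half-saturation concentration K is the apparent binding constant of the
  surface-immobilised probe;
* repeatability (inter-electrode relative standard deviation);
* selectivity/condition panels flagged against the 3-SD blank threshold.

Sample statistics use the n-1 denominator throughout (replicate sets are
small, typically 3-8 electrodes). Blanks are never log-transformed; they
enter only through LOD and panel thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import linregress

__all__ = [
    "DoseResponseSeries",
    "CalibrationModel",
    "LodResult",
    "BindingFit",
    "SemilogModel",
    "LangmuirModel",
    "fit_semilog",
    "invert_calibration",
    "lod_blank_plus_3sd",
    "lod_sigma33_over_slope",
    "fit_langmuir",
    "repeatability_rsd",
    "compare_conditions",
    "CalibrationRangeWarning",
]


class CalibrationRangeWarning(UserWarning):
    """Emitted when a calibration is inverted outside its validity range."""


@dataclass(frozen=True)
class DoseResponseSeries:
    """Concentrations mapped to replicate Rct values, blanks held apart.

    ``points`` is a sequence of (concentration, replicate Rct array) pairs;
    concentrations are strictly positive (zero-analyte blanks live in
    ``blanks`` and are never log-transformed). ``unit`` is the concentration
    unit, e.g. "ng/mL" for a purified protein or "S-EVs/mL" for vesicles.
    """

    analyte: str
    unit: str
    points: tuple[tuple[float, np.ndarray], ...]
    blanks: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        pts = []
        for c, reps in self.points:
            c = float(c)
            reps = np.atleast_1d(np.asarray(reps, dtype=float))
            if c <= 0:
                raise ValueError(f"concentration must be > 0, got {c}")
            if np.any(reps <= 0):
                raise ValueError(f"Rct values must be > 0 (at c={c})")
            reps.setflags(write=False)
            pts.append((c, reps))
        pts.sort(key=lambda p: p[0])
        object.__setattr__(self, "points", tuple(pts))
        blanks = np.atleast_1d(np.asarray(self.blanks, dtype=float))
        if blanks.size and np.any(blanks <= 0):
            raise ValueError("blank Rct values must be > 0")
        blanks.setflags(write=False)
        object.__setattr__(self, "blanks", blanks)

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for c, _ in self.points])

    def flatten(self) -> tuple[np.ndarray, np.ndarray]:
        """All replicate points as parallel (concentration, rct) arrays."""
        cs, ys = [], []
        for c, reps in self.points:
            cs.extend([c] * reps.size)
            ys.extend(reps.tolist())
        return np.array(cs), np.array(ys)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: concentration, unit, rct_ohm, electrode_id.

        Blanks are encoded as concentration 0, matching the CSV dialect.
        """
        rows = []
        for i, b in enumerate(self.blanks):
            rows.append((0.0, self.unit, b, i))
        for c, reps in self.points:
            for i, y in enumerate(reps):
                rows.append((c, self.unit, y, i))
        return pd.DataFrame(
            rows, columns=["concentration", "unit", "rct_ohm", "electrode_id"]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, analyte: str = "") -> "DoseResponseSeries":
        required = {"concentration", "rct_ohm"}
        if not required.issubset(df.columns):
            raise ValueError(f"dose-response table needs columns {sorted(required)}")
        unit = str(df["unit"].iloc[0]) if "unit" in df.columns and len(df) else ""
        blanks = df.loc[df["concentration"] == 0, "rct_ohm"].to_numpy(float)
        pos = df[df["concentration"] > 0]
        points = [
            (float(c), g["rct_ohm"].to_numpy(float))
            for c, g in pos.groupby("concentration")
        ]
        return cls(analyte=analyte, unit=unit, points=tuple(points), blanks=blanks)


@dataclass(frozen=True)
class CalibrationModel:
    """Semi-log calibration line Rct = slope * log10(c) + intercept.

    slope is in ohm per decade of concentration; ``range`` is the validity
    window (min, max concentration) the fit was performed on.
    """

    slope: float
    intercept: float
    r_squared: float
    range: tuple[float, float]
    unit: str
    log_base: int = 10
    n_points: int = 0

    def __post_init__(self) -> None:
        if not self.range[0] < self.range[1]:
            raise ValueError("calibration range must have min < max")

    def predict(self, concentration) -> np.ndarray | float:
        c = np.asarray(concentration, dtype=float)
        if np.any(c <= 0):
            raise ValueError("concentration must be > 0")
        y = self.slope * np.log10(c) + self.intercept
        return y[()] if y.ndim == 0 else y

    def invert(self, rct: float) -> float:
        return invert_calibration(self, rct)

    def summary(self) -> str:
        lo, hi = self.range
        return (
            f"Semi-log calibration ({self.unit}): "
            f"Rct = {self.slope:.6g} * log10(c) + {self.intercept:.6g}  "
            f"(R^2 = {self.r_squared:.4f}, range {lo:g}-{hi:g} {self.unit}, "
            f"{self.n_points} points)"
        )

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "range": list(self.range),
            "unit": self.unit,
            "log_base": self.log_base,
            "n_points": self.n_points,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CalibrationModel":
        d = dict(d)
        d["range"] = tuple(d["range"])
        return cls(**d)


@dataclass(frozen=True)
class LodResult:
    """Limit of detection and quantification with the blank statistics used.

    ``loq`` is stored as exactly 3 * ``lod``; ``method`` records which
    convention produced it. ``note`` documents caveats of the method.
    """

    lod: float
    loq: float
    method: str
    blank_mean: float
    blank_sd: float
    n_blanks: int
    unit: str = ""
    note: str = ""

    def __post_init__(self) -> None:
        if not self.lod > 0:
            raise ValueError("lod must be > 0")

    def to_dict(self) -> dict:
        return {
            "lod": self.lod,
            "loq": self.loq,
            "method": self.method,
            "blank_mean": self.blank_mean,
            "blank_sd": self.blank_sd,
            "n_blanks": self.n_blanks,
            "unit": self.unit,
            "note": self.note,
        }


@dataclass(frozen=True)
class BindingFit:
    """Langmuir isotherm fit: Rct(c) = baseline + delta_rct_max*c/(k_app + c).

    ``k_app`` is the apparent (surface-density dependent) binding constant:
    the concentration at half of the maximal Rct increase. ``spans_saturation``
    is False when the data do not reach above k_app, in which case k_app is
    an extrapolation.
    """

    k_app: float
    delta_rct_max: float
    baseline_rct: float
    stderr: dict[str, float]
    unit: str = ""
    converged: bool = True
    spans_saturation: bool = True

    def __post_init__(self) -> None:
        if not self.k_app > 0:
            raise ValueError("k_app must be > 0")
        if not self.delta_rct_max > 0:
            raise ValueError("delta_rct_max must be > 0")

    def predict(self, concentration) -> np.ndarray | float:
        c = np.asarray(concentration, dtype=float)
        y = self.baseline_rct + self.delta_rct_max * c / (self.k_app + c)
        return y[()] if y.ndim == 0 else y

    def summary(self) -> str:
        se = self.stderr
        return (
            f"Langmuir binding fit: K_app = {self.k_app:.4g} +/- "
            f"{se.get('k_app', float('nan')):.2g} {self.unit}, "
            f"dRct_max = {self.delta_rct_max:.4g} +/- "
            f"{se.get('delta_rct_max', float('nan')):.2g} ohm, "
            f"baseline = {self.baseline_rct:.4g} ohm"
        )

    def to_dict(self) -> dict:
        return {
            "k_app": self.k_app,
            "delta_rct_max": self.delta_rct_max,
            "baseline_rct": self.baseline_rct,
            "stderr": dict(self.stderr),
            "unit": self.unit,
            "converged": self.converged,
            "spans_saturation": self.spans_saturation,
        }


class SemilogModel:
    """Ordinary least squares of Rct on log10(concentration).

    All replicates enter as individual points (no pre-averaging), which
    keeps replicate scatter in R^2. ``window`` restricts the fit to a
    concentration sub-range (inclusive).
    """

    def __init__(
        self,
        series: DoseResponseSeries,
        window: tuple[float, float] | None = None,
    ) -> None:
        self.series = series
        self.window = window

    def fit(self) -> CalibrationModel:
        c, y = self.series.flatten()
        if self.window is not None:
            lo, hi = self.window
            keep = (c >= lo) & (c <= hi)
            c, y = c[keep], y[keep]
        if np.unique(c).size < 2:
            raise ValueError(
                "need >= 2 distinct concentrations in range for a calibration"
            )
        x = np.log10(c)
        if np.unique(c).size == 2 and c.size == 2:
            # exact interpolation through two points; linregress handles it
            pass
        res = linregress(x, y)
        yhat = res.slope * x + res.intercept
        ss_res = float(np.sum((y - yhat) ** 2))
        ss_tot = float(np.sum((y - np.mean(y)) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        return CalibrationModel(
            slope=float(res.slope),
            intercept=float(res.intercept),
            r_squared=float(min(max(r2, 0.0), 1.0)),
            range=(float(c.min()), float(c.max())),
            unit=self.series.unit,
            n_points=int(c.size),
        )


def fit_semilog(
    series: DoseResponseSeries,
    window: tuple[float, float] | None = None,
) -> CalibrationModel:
    """Fit the semi-log calibration line; see :class:`SemilogModel`."""
    return SemilogModel(series, window=window).fit()


def invert_calibration(model: CalibrationModel, rct: float) -> float:
    """Concentration whose predicted Rct equals ``rct``: 10**((rct-b)/m).

    Warns (:class:`CalibrationRangeWarning`) when the result falls outside
    the calibration's validity range.
    """
    if model.slope == 0:
        raise ZeroDivisionError("calibration slope is zero; cannot invert")
    c = 10.0 ** ((rct - model.intercept) / model.slope)
    if not model.range[0] <= c <= model.range[1]:
        warnings.warn(
            f"inverted concentration {c:g} {model.unit} lies outside the "
            f"calibration range {model.range[0]:g}-{model.range[1]:g}",
            CalibrationRangeWarning,
            stacklevel=2,
        )
    return float(c)


def lod_blank_plus_3sd(blanks, model: CalibrationModel, unit: str | None = None) -> LodResult:
    """LOD as the concentration whose Rct equals blank mean + 3*SD.

    The signal threshold mean(blanks) + 3*sd(blanks) (sample SD, n-1) is
    inverted through the calibration; LOQ = 3*LOD.
    """
    blanks = np.atleast_1d(np.asarray(blanks, dtype=float))
    if blanks.size < 3:
        raise ValueError(f"need >= 3 blank replicates, got {blanks.size}")
    if not model.slope > 0:
        raise ValueError("calibration slope must be > 0 for a detection limit")
    mean = float(np.mean(blanks))
    sd = float(np.std(blanks, ddof=1))
    threshold = mean + 3.0 * sd
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", CalibrationRangeWarning)
        lod = invert_calibration(model, threshold)
    return LodResult(
        lod=lod,
        loq=3.0 * lod,
        method="blank_plus_3sd",
        blank_mean=mean,
        blank_sd=sd,
        n_blanks=int(blanks.size),
        unit=unit if unit is not None else model.unit,
    )


_SIGMA33_NOTE = (
    "3.3*sigma/slope on a semi-log calibration yields an increment in "
    "log10-concentration units; the LOD is anchored at the lower edge of "
    "the linear range: LOD = c_min * 10**(3.3*sd/slope)."
)


def lod_sigma33_over_slope(
    blank_sd: float,
    model: CalibrationModel,
    anchor: float | None = None,
    n_blanks: int = 0,
    blank_mean: float = float("nan"),
) -> LodResult:
    """LOD by the 3.3*sigma/slope convention, applied in the log domain.

    With an ohm-per-decade slope the quotient 3.3*blank_sd/slope is a
    log10-concentration increment, so the limit is expressed relative to the
    low anchor of the linear range (``anchor``, default ``model.range[0]``):
    LOD = anchor * 10**(3.3*sd/slope). LOQ = 3*LOD.
    """
    if not blank_sd > 0:
        raise ValueError("blank_sd must be > 0")
    if not model.slope > 0:
        raise ValueError("calibration slope must be > 0")
    if anchor is None:
        anchor = model.range[0]
    if not anchor > 0:
        raise ValueError("anchor concentration must be > 0")
    delta_x = 3.3 * blank_sd / model.slope
    lod = float(anchor * 10.0**delta_x)
    return LodResult(
        lod=lod,
        loq=3.0 * lod,
        method="sigma33_over_slope",
        blank_mean=float(blank_mean),
        blank_sd=float(blank_sd),
        n_blanks=int(n_blanks),
        unit=model.unit,
        note=_SIGMA33_NOTE,
    )


class LangmuirModel:
    """Nonlinear least squares for the Langmuir dose-response isotherm.

    Rct(c) = baseline + delta_rct_max * c / (k_app + c). Blanks, when
    present, enter as c = 0 points and pin the baseline. k_app is fitted in
    log10 space for conditioning.
    """

    def __init__(self, series: DoseResponseSeries) -> None:
        if len(series.points) < 4:
            raise ValueError(
                "need >= 4 distinct concentrations for a Langmuir fit, got "
                f"{len(series.points)}"
            )
        self.series = series

    def _data(self) -> tuple[np.ndarray, np.ndarray]:
        c, y = self.series.flatten()
        if self.series.blanks.size:
            c = np.concatenate([np.zeros(self.series.blanks.size), c])
            y = np.concatenate([self.series.blanks, y])
        return c, y

    def fit(self) -> BindingFit:
        c, y = self._data()
        means = {cc: reps.mean() for cc, reps in self.series.points}
        y_lo, y_hi = min(means.values()), max(means.values())
        baseline0 = self.series.blanks.mean() if self.series.blanks.size else y_lo
        dmax0 = max(y_hi - baseline0, 1e-6 * max(abs(y_hi), 1.0))
        # initial K: concentration whose mean response is nearest half-saturation
        half = baseline0 + dmax0 / 2
        k0 = min(means, key=lambda cc: abs(means[cc] - half))

        def resid(theta: np.ndarray) -> np.ndarray:
            logk, dmax, base = theta
            return base + dmax * c / (10.0**logk + c) - y

        cs = self.series.concentrations
        sol = least_squares(
            resid,
            x0=np.array([np.log10(k0), dmax0, baseline0]),
            bounds=(
                [np.log10(cs.min()) - 6, 0.0, 0.0],
                [np.log10(cs.max()) + 6, np.inf, np.inf],
            ),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
        logk, dmax, base = sol.x
        k = 10.0**logk
        dof = max(c.size - 3, 1)
        chi2 = 2.0 * sol.cost
        try:
            cov = np.linalg.pinv(sol.jac.T @ sol.jac) * chi2 / dof
            se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
        except np.linalg.LinAlgError:
            se = np.full(3, np.nan)
        stderr = {
            "k_app": float(k * np.log(10) * se[0]),
            "delta_rct_max": float(se[1]),
            "baseline_rct": float(se[2]),
        }
        spans = bool(cs.max() > k)
        if not spans:
            warnings.warn(
                f"dose-response does not span saturation (max c {cs.max():g} "
                f"< fitted k_app {k:g}); k_app is an extrapolation",
                UserWarning,
                stacklevel=2,
            )
        return BindingFit(
            k_app=float(k),
            delta_rct_max=float(dmax),
            baseline_rct=float(base),
            stderr=stderr,
            unit=self.series.unit,
            converged=bool(sol.status > 0),
            spans_saturation=spans,
        )


def fit_langmuir(series: DoseResponseSeries) -> BindingFit:
    """Fit the Langmuir isotherm; see :class:`LangmuirModel`."""
    return LangmuirModel(series).fit()


def repeatability_rsd(values) -> tuple[float, float, float]:
    """Sample mean, sample SD (n-1) and RSD% of replicate Rct values.

    The inter-electrode RSD quantifies fabrication repeatability; the exact
    quotient 100*sd/mean is reported without rounding.
    """
    v = np.atleast_1d(np.asarray(values, dtype=float))
    if v.size < 2:
        raise ValueError(f"need >= 2 replicates, got {v.size}")
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1))
    return mean, sd, 100.0 * sd / mean


def compare_conditions(
    groups: Mapping[str, Iterable[float]],
    blank: Iterable[float],
) -> pd.DataFrame:
    """Per-condition summary with detection flags against the blank.

    For each labelled group of replicate Rct values: mean, sample SD,
    fold-over-blank (group mean / blank mean), and ``detected`` =
    group mean > blank mean + 3 * blank SD — the same 3-SD rule used for
    the LOD. Rows ordered by descending mean. Blank statistics are stored
    in ``DataFrame.attrs``.
    """
    blank = np.atleast_1d(np.asarray(blank, dtype=float))
    if blank.size < 2:
        raise ValueError("need >= 2 blank replicates")
    b_mean = float(np.mean(blank))
    b_sd = float(np.std(blank, ddof=1))
    threshold = b_mean + 3.0 * b_sd
    rows = []
    for label, vals in groups.items():
        v = np.atleast_1d(np.asarray(list(vals), dtype=float))
        if v.size < 2:
            raise ValueError(f"group {label!r} needs >= 2 replicates")
        m = float(np.mean(v))
        rows.append(
            {
                "label": label,
                "n": int(v.size),
                "mean": m,
                "sd": float(np.std(v, ddof=1)),
                "fold_over_blank": m / b_mean,
                "detected": bool(m > threshold),
            }
        )
    df = pd.DataFrame(rows).sort_values("mean", ascending=False).reset_index(drop=True)
    df.attrs.update(blank_mean=b_mean, blank_sd=b_sd, threshold=threshold)
    return df
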