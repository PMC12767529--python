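"""Quantitative metrics for the validation growth assays.

Small, exactly specified calculations: caliper tumour volume, xenograft
luminescence growth ratio, live-cell confluence over baseline, clonogenic
potential from crystal-violet optical density, and growth-rate (GR)
dose-response metrics with the GR50 read off a fitted 3-parameter sigmoid.

The GR framework (Hafner et al., Nat Methods 2016) rescales an endpoint
cell measure by the untreated growth over the same interval:

    GR(c) = 2 ** ( log2(x_c / x0) / log2(x_ctrl / x0) ) - 1

so GR = 1 means growth equal to the untreated control, GR = 0 complete
cytostasis, and GR < 0 net cell loss.  GR50 is the concentration at which
the fitted curve crosses GR = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, InsufficientDataError, ParameterError


def tumor_volume(width: float, length: float) -> float:
    """Caliper tumour volume: ``width**2 * length / 2`` (length units cubed)."""
    if width < 0 or length < 0:
        raise ParameterError("width and length must be >= 0")
    return width**2 * length / 2.0


def growth_ratio(radiance, baseline: float) -> tuple[np.ndarray, float]:
    """Luminescence trend and final growth ratio relative to baseline.

    Returns ``(trend, ratio_percent)`` where ``trend[t] = radiance[t] /
    baseline`` and ``ratio_percent = 100 * (radiance[-1] - baseline) /
    baseline`` (the final increase over baseline, as a percentage).
    """
    radiance = np.asarray(radiance, float)
    if radiance.size == 0:
        raise ParameterError("radiance series is empty")
    if baseline <= 0:
        raise ParameterError("baseline radiance must be > 0")
    trend = radiance / baseline
    ratio = 100.0 * (radiance[-1] - baseline) / baseline
    return trend, float(ratio)


def confluence_over_baseline(confluence) -> np.ndarray:
    """Confluence series as percentage of the first timepoint."""
    confluence = np.asarray(confluence, float)
    if confluence.size == 0:
        raise ParameterError("confluence series is empty")
    if confluence[0] <= 0:
        raise ParameterError("baseline (first) confluence must be > 0")
    return 100.0 * confluence / confluence[0]


def clonogenic_potential(od_treated: float, od_control: float) -> float:
    """Colony-stain OD of a treatment normalized to its control."""
    if od_control <= 0:
        raise ParameterError("control OD must be > 0")
    return od_treated / od_control


def gr_value(x_c: float, x0: float, x_ctrl: float) -> float:
    """Growth rate metric GR for one treated endpoint measure.

    ``x0`` is the baseline (time-0) measure, ``x_ctrl`` the untreated
    endpoint and ``x_c`` the treated endpoint.  Requires a growing control
    (``x_ctrl > x0``).
    """
    if x0 <= 0 or x_c <= 0:
        raise ParameterError("cell measures must be > 0")
    if x_ctrl <= x0:
        raise ParameterError("control did not grow (x_ctrl <= x0); GR undefined")
    return float(2.0 ** (np.log2(x_c / x0) / np.log2(x_ctrl / x0)) - 1.0)


@dataclass
class DoseResponseSeries:
    """One GR dose-response experiment: shared x0/x_ctrl, one x_c per dose."""

    concentrations: np.ndarray
    x0: float
    x_ctrl: float
    x_c: np.ndarray

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, float)
        self.x_c = np.asarray(self.x_c, float)
        if self.x0 <= 0:
            raise ParameterError("x0 must be > 0")
        if self.x_ctrl <= self.x0:
            raise ParameterError("control did not grow (x_ctrl <= x0)")
        if np.any(self.concentrations <= 0):
            raise ParameterError("concentrations must be > 0")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ParameterError("concentrations must be strictly increasing")
        if len(self.x_c) != len(self.concentrations):
            raise ParameterError("x_c and concentrations must align")

    def gr(self) -> np.ndarray:
        return np.array([gr_value(x, self.x0, self.x_ctrl) for x in self.x_c])


@dataclass
class GR50Fit:
    """Fitted GR sigmoid and the GR50 it implies."""

    gr50: float | None  # None == "not reached"
    gec50: float
    hill: float
    gr_inf: float
    residual_norm: float

    @property
    def reached(self) -> bool:
        return self.gr50 is not None


def sigmoid_gr(c, gec50: float, hill: float, gr_inf: float):
    """3-parameter GR dose-response curve."""
    c = np.asarray(c, float)
    return gr_inf + (1.0 - gr_inf) / (1.0 + (c / gec50) ** hill)


def gr50(series: DoseResponseSeries, seed: int = 0) -> GR50Fit:
    """Fit the GR sigmoid and invert it at GR = 0.5.

    Least-squares fit in log-concentration parameterization with three
    deterministic multi-starts (GEC50 initialized at the low, middle and
    high end of the tested range).  GR50 is the analytic solution of
    ``sigmoid_gr(c) = 0.5``; "not reached" (``gr50 = None``) when the
    fitted plateau never crosses 0.5 or the crossing falls outside the
    tested range widened 10-fold on either side.
    """
    if len(series.concentrations) < 4:
        raise InsufficientDataError("GR50 fit needs >= 4 concentrations")
    conc = series.concentrations
    grs = series.gr()
    logc = np.log10(conc)

    def resid(theta):
        log_gec50, log_h, gr_inf = theta
        return sigmoid_gr(conc, 10.0**log_gec50, np.exp(log_h), gr_inf) - grs

    best = None
    for start_logc in (logc[0], logc[len(logc) // 2], logc[-1]):
        theta0 = np.array([start_logc, 0.0, float(np.clip(grs.min(), -1.0, 0.9))])
        try:
            sol = least_squares(
                resid,
                theta0,
                bounds=([logc[0] - 3, np.log(0.1), -1.0],
                        [logc[-1] + 3, np.log(10.0), 1.0]),
                method="trf",
            )
        except Exception:  # pragma: no cover - scipy failure path
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitError("GR sigmoid fit did not converge from any start")

    log_gec50, log_h, gr_inf = best.x
    gec50 = 10.0**log_gec50
    hill = float(np.exp(log_h))
    gr50_val = None
    if gr_inf < 0.5:
        c_half = gec50 * (0.5 / (0.5 - gr_inf)) ** (1.0 / hill)
        if conc[0] / 10.0 <= c_half <= conc[-1] * 10.0:
            gr50_val = float(c_half)
    return GR50Fit(
        gr50=gr50_val,
        gec50=float(gec50),
        hill=hill,
        gr_inf=float(gr_inf),
        residual_norm=float(np.sqrt(2.0 * best.cost)),
    )
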