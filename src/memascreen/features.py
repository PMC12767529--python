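"""Per-cell feature processing: EdU auto-gating and spot summarization.

The screen's proliferation readout is the proportion of EdU-positive cells
per spot.  EdU log-intensity is bimodal (S-phase cells incorporate the
analogue, others show background), so the gate is found per scope group —
per array by default, since illumination varies array to array — by a
two-component Gaussian mixture on log intensity with the threshold at the
equal-posterior point, falling back to Otsu's method when the mixture fit
degenerates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .design import ExperimentDesign, SpotAddress
from .errors import (
    InsufficientDataError,
    ParameterError,
    ReconciliationError,
)

GATING_SCOPES = {"array": ["array"], "plate": ["plate"], "global": []}

SPOT_KEY = ["plate", "well", "array", "row", "col"]


@dataclass
class GateResult:
    """An EdU gate: per-scope-group thresholds plus per-cell labels.

    ``thresholds`` maps scope-group key (array id, plate id, or ``"all"``)
    to the log-intensity cutoff; ``labels`` is a boolean array aligned with
    the cell table passed to :func:`gate_edu` (label == log intensity >=
    threshold of the cell's group).
    """

    scope: str
    method: str
    thresholds: dict[str, float]
    labels: np.ndarray
    diagnostics: dict = field(default_factory=dict)


def _gmm_threshold(logx: np.ndarray, random_state: int = 0):
    """Equal-posterior cut between two Gaussian components on log intensity.

    Returns (threshold, diagnostics) or None when the fit is degenerate
    (components collapsed or one nearly empty).
    """
    q25, q75 = np.quantile(logx, [0.25, 0.75])
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        means_init=[[q25], [q75]],
        random_state=random_state,
        max_iter=200,
    ).fit(logx.reshape(-1, 1))
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    w = gm.weights_.ravel()
    order = np.argsort(means)
    m0, m1 = means[order]
    s0, s1 = sds[order]
    w0, w1 = w[order]
    if (m1 - m0) < 0.5 * max(s0, s1) or min(w0, w1) < 0.02:
        return None
    # w0 N(x|m0,s0) = w1 N(x|m1,s1)  ->  quadratic in x
    a = 1.0 / s1**2 - 1.0 / s0**2
    b = 2.0 * (m0 / s0**2 - m1 / s1**2)
    c = m1**2 / s1**2 - m0**2 / s0**2 + 2.0 * np.log((w0 * s1) / (w1 * s0))
    if abs(a) < 1e-12:
        thr = -c / b if abs(b) > 1e-12 else 0.5 * (m0 + m1)
    else:
        disc = b**2 - 4 * a * c
        if disc < 0:
            thr = 0.5 * (m0 + m1)
        else:
            roots = (-b + np.array([-1.0, 1.0]) * np.sqrt(disc)) / (2 * a)
            inside = roots[(roots > m0) & (roots < m1)]
            thr = float(inside[0]) if inside.size else 0.5 * (m0 + m1)
    diag = {"means": (float(m0), float(m1)), "sds": (float(s0), float(s1)),
            "weights": (float(w0), float(w1))}
    return float(thr), diag


def _otsu_threshold(logx: np.ndarray) -> float:
    from skimage.filters import threshold_otsu

    return float(threshold_otsu(logx))


def gate_edu(
    cells: pd.DataFrame,
    scope: str = "array",
    method: str = "gmm",
    random_state: int = 0,
) -> GateResult:
    """Auto-gate EdU intensity to label each cell EdU-positive or -negative.

    ``scope`` is one of ``"array"`` (default — lighting varies by array),
    ``"plate"`` or ``"global"``; a separate threshold is fit per scope
    group on the natural-log intensities.  ``method`` is ``"gmm"``
    (mixture, Otsu fallback) or ``"otsu"``.

    A group whose intensities are all identical is labeled all-negative
    with a warning; a group with fewer than 2 cells is an error.
    """
    if scope not in GATING_SCOPES:
        raise ParameterError(f"unknown gating scope {scope!r}")
    if method not in ("gmm", "otsu"):
        raise ParameterError(f"unknown gating method {method!r}")
    x = cells["edu_intensity"].to_numpy(float)
    if np.any(~(x > 0)):
        raise ParameterError("EdU intensities must be strictly positive")
    logx = np.log(x)

    keys = GATING_SCOPES[scope]
    if keys:
        group_ids = cells[keys[0]].to_numpy()
    else:
        group_ids = np.repeat("all", len(cells))

    labels = np.zeros(len(cells), dtype=bool)
    thresholds: dict[str, float] = {}
    diagnostics: dict[str, dict] = {}
    for gid in pd.unique(group_ids):
        m = group_ids == gid
        lg = logx[m]
        if lg.size < 2:
            raise InsufficientDataError(
                f"gating group {gid!r} has {lg.size} cells (need >= 2)"
            )
        if np.ptp(lg) == 0.0:
            warnings.warn(
                f"gating group {gid!r}: all EdU intensities identical; "
                "labeling all cells negative",
                stacklevel=2,
            )
            thresholds[str(gid)] = float("inf")
            continue
        fit = _gmm_threshold(lg, random_state) if method == "gmm" else None
        if fit is not None:
            thr, diag = fit
            diagnostics[str(gid)] = diag
            used = "gmm"
        else:
            thr = _otsu_threshold(lg)
            used = "otsu" if method == "gmm" else "otsu"
        diagnostics.setdefault(str(gid), {})["method"] = used
        thresholds[str(gid)] = thr
        labels[m] = lg >= thr
    return GateResult(scope, method, thresholds, labels, diagnostics)


def summarize_spots(
    cells: pd.DataFrame,
    gate: GateResult,
    design: ExperimentDesign,
) -> pd.DataFrame:
    """Collapse cells to one record per assigned spot.

    cell_count is the number of segmented nuclei at the address (zero-cell
    spots are retained so replicate accounting stays auditable);
    edu_prop is the EdU-positive fraction (missing when the spot is empty);
    per-signal medians are the plain sample medians over the spot's cells.
    Cells at addresses absent from the design raise
    :class:`ReconciliationError`.
    """
    frame = design.to_frame()
    if len(gate.labels) != len(cells):
        raise ParameterError("gate labels are not aligned with the cell table")

    cells = cells.copy()
    cells["_edu_pos"] = gate.labels

    cell_addrs = cells[SPOT_KEY].drop_duplicates()
    probe = cell_addrs.merge(frame[SPOT_KEY], on=SPOT_KEY, how="left", indicator=True)
    orphans = sorted(
        map(tuple, probe.loc[probe["_merge"] == "left_only", SPOT_KEY].itertuples(index=False))
    )
    if orphans:
        shown = ", ".join(
            SpotAddress(p, w, a, r, c).__repr__() for p, w, a, r, c in orphans[:5]
        )
        raise ReconciliationError(
            f"{len(orphans)} cell spot address(es) not in design: {shown}"
            + (" ..." if len(orphans) > 5 else ""),
            addresses=orphans,
        )

    signal_cols = [
        c for c in cells.columns
        if c.endswith("_intensity") or c in getattr(cells, "attrs", {}).get("extra_signals", [])
    ]
    grouped = cells.groupby(SPOT_KEY, sort=False)
    agg = grouped.agg(
        cell_count=("_edu_pos", "size"),
        edu_pos=("_edu_pos", "sum"),
        **{
            f"{c.removesuffix('_intensity')}_median": (c, "median")
            for c in signal_cols
        },
    ).reset_index()

    spots = frame.merge(agg, on=SPOT_KEY, how="left")
    spots["cell_count"] = spots["cell_count"].fillna(0).astype(int)
    with np.errstate(invalid="ignore"):
        spots["edu_prop"] = np.where(
            spots["cell_count"] > 0,
            spots["edu_pos"] / spots["cell_count"].replace(0, np.nan),
            np.nan,
        )
    spots["edu_pos"] = spots["edu_pos"].fillna(0).astype(int)
    return spots
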