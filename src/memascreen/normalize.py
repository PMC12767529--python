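"""Normalization of spot-level signals: RUV then bivariate LOESS.

Array-to-array (batch) variation is removed by a remove-unwanted-variation
(RUV) step whose negative controls are the residuals left after subtracting
each spot value's replicate-group median — the replicate structure of the
screen means those residuals carry the unwanted variation but none of the
microenvironment signal.  Signals are arranged in matrices with arrays as
rows and spot positions as columns; the top singular vectors of the
residual matrix give per-array unwanted factors that are regressed out of
the full matrix.  Within-array spatial artifacts (edge and gradient
effects of printing, staining and imaging) are then removed by a bivariate
LOESS fit on the spot's array row and column, subtracting the fitted
surface while adding back the array grand median so cross-array levels set
by RUV are preserved.

All normalization happens on transformed scales: log(count + 1) for cell
counts, the empirical logit for EdU proportions, natural log for intensity
medians.  Counts and EdU labels themselves are never altered; normalized
values live in ``*_norm`` columns beside the raw ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError, DegenerateDataError

ARRAY_KEY = "array"
POS_KEY = ["row", "col"]


@dataclass
class SignalMatrix:
    """One signal as an arrays x spot-positions matrix.

    ``values[i, j]`` is the signal at spot position ``j`` of array ``i``
    (NaN where masked/missing).  ``replicate_groups`` maps a group key (the
    MEP label) to the list of ``(row_index, col_index)`` entries carrying
    that MEP; because different arrays receive different ligands, a
    replicate group may span both rows and columns of the matrix.
    """

    values: np.ndarray
    array_ids: list[str]
    positions: pd.DataFrame  # one row per column: row, col, ecm at that position
    replicate_groups: dict[str, list[tuple[int, int]]]

    @property
    def mask(self) -> np.ndarray:
        return np.isnan(self.values)


@dataclass
class RUVFit:
    """Diagnostics of one RUV step: the estimated unwanted factors."""

    k: int
    unwanted_factors: np.ndarray  # arrays x k (column-centered scores)
    loadings: np.ndarray  # k x spots (regression coefficients removed)
    singular_values: np.ndarray = field(default_factory=lambda: np.array([]))


def build_signal_matrix(
    spots: pd.DataFrame, signal: str
) -> SignalMatrix:
    """Pivot a spot table (one plate or experiment) into arrays x positions.

    Spot positions are identified by (row, col) of the shared print layout;
    every array is assumed to carry the same layout, which is how the
    arrays are physically printed.
    """
    if signal not in spots.columns:
        raise ParameterError(f"signal column {signal!r} not in spot table")
    arrays = sorted(spots[ARRAY_KEY].unique())
    pos = (
        spots[POS_KEY + ["ecm"]]
        .drop_duplicates(POS_KEY)
        .sort_values(POS_KEY)
        .reset_index(drop=True)
    )
    pos_index = {(r, c): j for j, (r, c) in enumerate(zip(pos["row"], pos["col"]))}
    arr_index = {a: i for i, a in enumerate(arrays)}

    values = np.full((len(arrays), len(pos)), np.nan)
    groups: dict[str, list[tuple[int, int]]] = {}
    for a, r, c, ecm, lig, v in zip(
        spots[ARRAY_KEY], spots["row"], spots["col"],
        spots["ecm"], spots["ligand"], spots[signal],
    ):
        i, j = arr_index[a], pos_index[(r, c)]
        values[i, j] = v
        groups.setdefault(f"{ecm}:{lig}", []).append((i, j))
    return SignalMatrix(values, arrays, pos, groups)


def build_residual_controls(matrix: SignalMatrix) -> np.ndarray:
    """Residuals from replicate medians: the RUV negative controls.

    Each entry's residual is its value minus the median of its replicate
    group (the other spots carrying the same MEP), computed over unmasked
    entries.  Groups of size 1 yield residual 0 and a warning — they carry
    no information about unwanted variation.
    """
    if not matrix.replicate_groups:
        raise DegenerateDataError("signal matrix has no replicate groups")
    resid = np.full_like(matrix.values, np.nan)
    singletons = []
    for key, entries in matrix.replicate_groups.items():
        idx = tuple(np.array(entries).T)
        vals = matrix.values[idx]
        ok = ~np.isnan(vals)
        if ok.sum() == 0:
            continue
        if ok.sum() == 1:
            singletons.append(key)
            resid[idx] = np.where(ok, 0.0, np.nan)
            continue
        med = np.median(vals[ok])
        resid[idx] = vals - med
    if singletons:
        warnings.warn(
            f"{len(singletons)} replicate group(s) of size 1 contribute zero "
            f"residuals (e.g. {singletons[0]!r})",
            stacklevel=2,
        )
    return resid


def ruv_normalize(
    matrix: SignalMatrix, k: int = 1
) -> tuple[SignalMatrix, RUVFit]:
    """Remove ``k`` unwanted array-level factors estimated from residual controls.

    The residual-control matrix is decomposed by SVD; the top-``k`` left
    singular vectors are the per-array scores of unwanted variation.  The
    scores are column-centered and their least-squares projection is
    removed from every column of the full matrix (masked entries excluded
    and left masked).  ``k = 0`` is the identity.
    """
    n_arrays, n_spots = matrix.values.shape
    if n_arrays < 2:
        raise ParameterError("RUV needs at least 2 arrays")
    if k < 0 or k > min(n_arrays - 1, n_spots):
        raise ParameterError(
            f"k={k} outside [0, min(n_arrays - 1, n_spots)] = "
            f"[0, {min(n_arrays - 1, n_spots)}]"
        )
    if k == 0:
        return matrix, RUVFit(0, np.zeros((n_arrays, 0)), np.zeros((0, n_spots)))

    resid = build_residual_controls(matrix)
    r0 = np.nan_to_num(resid, nan=0.0)
    u, s, _ = np.linalg.svd(r0, full_matrices=False)
    alpha = u[:, :k] * s[:k]  # array scores, scaled by singular values
    alpha = alpha - alpha.mean(axis=0, keepdims=True)
    if not np.any(alpha):
        # constant matrix: controls are all zero, nothing to remove
        return matrix, RUVFit(k, alpha, np.zeros((k, n_spots)), s[:k])

    values = matrix.values.copy()
    loadings = np.zeros((k, n_spots))
    mask = matrix.mask
    if not mask.any():
        beta, *_ = np.linalg.lstsq(alpha, values, rcond=None)
        values = values - alpha @ beta
        loadings = beta
    else:
        for j in range(n_spots):
            obs = ~mask[:, j]
            if obs.sum() <= k:
                warnings.warn(f"column {j} mostly masked; skipped", stacklevel=2)
                continue
            a = alpha[obs]
            b, *_ = np.linalg.lstsq(a, values[obs, j], rcond=None)
            values[obs, j] -= a @ b
            loadings[:, j] = b
    out = SignalMatrix(values, matrix.array_ids, matrix.positions, matrix.replicate_groups)
    return out, RUVFit(k, alpha, loadings, s[:k])


def loess2d(
    x: np.ndarray, y: np.ndarray, z: np.ndarray, span: float = 0.5
) -> np.ndarray:
    """Bivariate local-linear (LOESS) fit of z on (x, y) with tricube weights.

    For each point, the ``ceil(span * n)`` nearest neighbours (Euclidean
    distance in the (x, y) plane) are weighted by the tricube kernel and a
    weighted plane is fit; the returned array is the fitted value at each
    point.
    """
    if not (0.0 < span <= 1.0):
        raise ParameterError(f"span must be in (0, 1], got {span}")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    n = len(z)
    q = max(3, int(np.ceil(span * n)))
    fitted = np.empty(n)
    pts = np.column_stack([x, y])
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    for i in range(n):
        d = np.sqrt(d2[i])
        dq = np.partition(d, q - 1)[q - 1]
        if dq == 0:
            dq = d.max() if d.max() > 0 else 1.0
        w = np.clip(1.0 - (d / dq) ** 3, 0.0, None) ** 3
        sel = w > 0
        if sel.sum() < 3:
            sel = d <= np.partition(d, min(3, n) - 1)[min(3, n) - 1]
            w = np.where(sel, 1.0, 0.0)
        X = np.column_stack([np.ones(sel.sum()), x[sel] - x[i], y[sel] - y[i]])
        W = w[sel]
        XtW = X.T * W
        try:
            coef = np.linalg.solve(XtW @ X, XtW @ z[sel])
        except np.linalg.LinAlgError:
            coef = np.linalg.lstsq(np.sqrt(W)[:, None] * X,
                                   np.sqrt(W) * z[sel], rcond=None)[0]
        fitted[i] = coef[0]
    return fitted


def loess_normalize(
    array_spots: pd.DataFrame,
    signal: str,
    span: float = 0.5,
    min_spots: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Remove the smooth spatial surface of one signal on one array.

    Fits ``signal ~ loess(row, col)`` and returns
    ``(corrected, fitted_surface)`` where
    ``corrected = value - surface + grand_median`` so the array's overall
    level (set by RUV) is preserved.  Arrays with fewer than ``min_spots``
    finite values are returned unchanged with a warning.
    """
    if not (0.0 < span <= 1.0):
        raise ParameterError(f"span must be in (0, 1], got {span}")
    z = array_spots[signal].to_numpy(float)
    finite = np.isfinite(z)
    if finite.sum() < min_spots:
        warnings.warn(
            f"array has {int(finite.sum())} usable spots (< {min_spots}); "
            f"LOESS skipped for {signal!r}",
            stacklevel=2,
        )
        return z.copy(), np.zeros_like(z)
    r = array_spots["row"].to_numpy(float)[finite]
    c = array_spots["col"].to_numpy(float)[finite]
    fitted = loess2d(r, c, z[finite], span=span)
    surface = np.zeros_like(z)
    surface[finite] = fitted
    corrected = z.copy()
    corrected[finite] = z[finite] - fitted + np.median(z[finite])
    return corrected, surface


# -- signal transforms ------------------------------------------------------


def transform_signal(spots: pd.DataFrame, signal: str) -> np.ndarray:
    """Map a raw spot column onto the additive scale used for normalization."""
    if signal == "cell_count":
        return np.log1p(spots["cell_count"].to_numpy(float))
    if signal == "edu_prop":
        # empirical logit with 0.5 pseudocounts, defined even at 0 and 1
        k = spots["edu_pos"].to_numpy(float)
        n = spots["cell_count"].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.log((k + 0.5) / (n - k + 0.5))
        out[n == 0] = np.nan
        return out
    vals = spots[signal].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(vals > 0, np.log(vals), np.nan)


DEFAULT_SIGNALS = ("cell_count", "edu_prop", "dapi_median", "edu_median")


def normalize_pipeline(
    spots: pd.DataFrame,
    signals: tuple[str, ...] = DEFAULT_SIGNALS,
    k: int = 1,
    span: float = 0.5,
    min_spots: int = 20,
    matrix_scope: str = "plate",
) -> tuple[pd.DataFrame, dict]:
    """Full normalization: transform -> residual controls -> RUV -> LOESS.

    Each signal is handled independently; matrices are built per
    ``matrix_scope`` (``"plate"`` or ``"experiment"``).  Adds one
    ``<signal>_norm`` column per signal (on the transformed scale) and
    returns per-signal variance-decomposition diagnostics before and after
    normalization.
    """
    if matrix_scope not in ("plate", "experiment"):
        raise ParameterError(f"unknown matrix scope {matrix_scope!r}")
    spots = spots.copy()
    if spots.empty:
        return spots, {}
    diagnostics: dict[str, dict] = {}

    for signal in signals:
        missing = signal not in spots.columns and signal not in ("cell_count", "edu_prop")
        if missing:
            raise ParameterError(f"signal column {signal!r} not in spot table")
        spots[f"_t_{signal}"] = transform_signal(spots, signal)

    scopes = (
        [(p, g) for p, g in spots.groupby("plate", sort=True)]
        if matrix_scope == "plate"
        else [("experiment", spots)]
    )

    norm_parts = []
    for scope_name, part in scopes:
        part = part.copy()
        for signal in signals:
            tcol = f"_t_{signal}"
            sm = build_signal_matrix(part.rename(columns={tcol: "_v"}), "_v")
            try:
                sm_n, fit = ruv_normalize(sm, k=k)
            except DegenerateDataError:
                sm_n, fit = sm, RUVFit(0, np.zeros((len(sm.array_ids), 0)),
                                       np.zeros((0, sm.values.shape[1])))
            # map matrix entries back to spot rows
            pos_index = {
                (r, c): j
                for j, (r, c) in enumerate(zip(sm.positions["row"], sm.positions["col"]))
            }
            arr_index = {a: i for i, a in enumerate(sm.array_ids)}
            ii = part[ARRAY_KEY].map(arr_index).to_numpy()
            jj = [pos_index[(r, c)] for r, c in zip(part["row"], part["col"])]
            ruved = sm_n.values[ii, jj]
            part[f"_r_{signal}"] = ruved

            corrected = np.empty(len(part))
            surf = np.empty(len(part))
            for _, idx in part.groupby(ARRAY_KEY, sort=False).indices.items():
                sub = part.iloc[idx]
                cvals, svals = loess_normalize(
                    sub.rename(columns={f"_r_{signal}": "_v"}), "_v",
                    span=span, min_spots=min_spots,
                )
                corrected[idx] = cvals
                surf[idx] = svals
            part[f"{signal}_norm"] = corrected

            diag = diagnostics.setdefault(signal, {"scopes": {}})
            diag["scopes"][str(scope_name)] = {
                "ruv_k": fit.k,
                "singular_values": fit.singular_values.tolist(),
                "variance_before": _variance_components(sm),
                "variance_after": _variance_components(
                    SignalMatrix(sm_n.values, sm.array_ids, sm.positions,
                                 sm.replicate_groups)
                ),
            }
        norm_parts.append(part)

    out = pd.concat(norm_parts).sort_index()
    out = out.drop(columns=[c for c in out.columns if c.startswith(("_t_", "_r_"))])
    return out, diagnostics


def _variance_components(matrix: SignalMatrix) -> dict:
    """Crude decomposition: between-array, and residual replicate variance."""
    resid = build_residual_controls(matrix)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        arr_means = np.nanmean(resid, axis=1)
        between = float(np.nanvar(arr_means))
        within = float(np.nanvar(resid))
    return {"between_array": between, "replicate_residual": within}


def replicate_residuals(matrix: SignalMatrix) -> np.ndarray:
    """Public alias for the residual-control construction (diagnostics)."""
    return build_residual_controls(matrix)
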