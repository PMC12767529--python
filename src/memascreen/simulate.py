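"""Synthetic MEMA screens with known ground truth.

The generator emulates the statistical structure of a real screen without
any imaging: spot-level cell counts are overdispersed (negative binomial)
around a product of baseline, ECM effect, ligand effect, array batch factor
and a smooth spatial surface over the print grid; per-cell EdU
log-intensities are a two-component log-normal mixture whose positive-class
prevalence follows a logit model with per-ligand shifts.  Everything the
downstream pipeline is asked to recover (true EdU labels, true spot means,
array factors, surface values) is returned in a ground-truth record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .design import ExperimentDesign
from .errors import GenerationError, ParameterError


@dataclass(frozen=True)
class SurfaceSpec:
    """Smooth within-array spatial artifact, additive on the log-count scale.

    kinds:
      ``none``    -- flat surface (0 everywhere);
      ``planar``  -- a*row + b*col gradient, params (a, b);
      ``bump``    -- centered Gaussian bump, params (amplitude, width) with
                     width in grid units;
      ``poly``    -- low-order polynomial a*r + b*c + c2*r*c + d*r^2 + e*c^2,
                     params (a, b, c2, d, e);
    with row/col centered to the array midpoint so the surface has no
    built-in offset.
    """

    kind: str = "planar"
    params: tuple = (0.04, -0.03)

    def evaluate(self, row: np.ndarray, col: np.ndarray, geometry: tuple[int, int]) -> np.ndarray:
        nr, nc = geometry
        r = np.asarray(row, float) - (nr - 1) / 2.0
        c = np.asarray(col, float) - (nc - 1) / 2.0
        if self.kind == "none":
            return np.zeros_like(r)
        if self.kind == "planar":
            a, b = self.params
            with np.errstate(invalid="ignore"):
                return a * r + b * c
        if self.kind == "bump":
            amp, width = self.params
            return amp * np.exp(-(r**2 + c**2) / (2.0 * width**2))
        if self.kind == "poly":
            a, b, c2, d, e = self.params
            return a * r + b * c + c2 * r * c + d * r**2 + e * c**2
        raise ParameterError(f"unknown surface kind {self.kind!r}")


@dataclass
class EffectSpec:
    """Ground-truth parameters for one simulated screen.

    Multiplicative effects act on the expected spot cell count; EdU shifts
    are additive on the logit of the per-cell EdU-positive probability.
    Arrays not listed in ``array_factors`` get factors drawn log-normally
    with ``array_factor_log_sd`` (the drawn values are recorded in the
    ground truth).  ``count_dispersion`` is the negative-binomial size
    parameter: var = mu + mu^2 / dispersion.
    """

    baseline_cells_per_spot: float = 40.0
    ecm_effects: Mapping[str, float] = field(default_factory=dict)
    ligand_effects: Mapping[str, float] = field(default_factory=dict)
    edu_base_rate: float = 0.30
    ligand_edu_shift: Mapping[str, float] = field(default_factory=dict)
    array_factors: Mapping[str, float] | None = None
    array_factor_log_sd: float = 0.15
    spatial_surface: SurfaceSpec = field(default_factory=SurfaceSpec)
    count_dispersion: float = 5.0
    edu_mixture: tuple[float, float, float] = (5.0, 7.0, 0.5)
    dapi_log_mean: float = 6.0
    dapi_log_sd: float = 0.4
    seed: int = 0
    overlap_warn_bound: float = 0.26  # ~5% irreducible misclassification

    def __post_init__(self):
        if self.baseline_cells_per_spot <= 0:
            raise ParameterError("baseline_cells_per_spot must be > 0")
        if not (0.0 < self.edu_base_rate < 1.0):
            raise ParameterError("edu_base_rate must be in (0, 1)")
        if self.count_dispersion <= 0:
            raise ParameterError("count_dispersion must be > 0")
        for name, f in {**dict(self.ecm_effects), **dict(self.ligand_effects)}.items():
            if f <= 0:
                raise ParameterError(f"effect for {name!r} must be > 0")
        mu_n, mu_p, sd = self.edu_mixture
        if mu_p <= mu_n:
            raise ParameterError("EdU positive log-mean must exceed negative log-mean")
        if sd <= 0:
            raise ParameterError("EdU mixture log-sd must be > 0")
        # Bhattacharyya coefficient of the equal-variance components: a high
        # overlap makes the planted labels unrecoverable by any gate.
        bc = float(np.exp(-((mu_p - mu_n) ** 2) / (8.0 * sd**2)))
        if bc > self.overlap_warn_bound:
            warnings.warn(
                f"EdU mixture components overlap (Bhattacharyya {bc:.3f} > "
                f"{self.overlap_warn_bound}); gating may be unreliable",
                stacklevel=2,
            )


@dataclass
class GroundTruth:
    """What the generator planted; sufficient to score any pipeline output."""

    spots: pd.DataFrame  # per-spot: address, mep, mu, array_factor, surface, count
    cell_labels: np.ndarray  # EdU-positive indicator per cell row
    array_factors: dict[str, float]
    spec: EffectSpec
    seed: int


CELL_COLUMNS = [
    "plate", "well", "array", "row", "col",
    "ecm", "ecm_conc", "ligand", "ligand_conc", "is_control",
    "cell_id", "dapi_intensity", "edu_intensity",
]


def simulate_experiment(
    design: ExperimentDesign, spec: EffectSpec
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw one synthetic screen: a per-cell table plus its ground truth.

    For each assigned spot the expected count is
    ``mu = baseline * ecm_effect * ligand_effect * array_factor *
    exp(surface(row, col))`` and the realized count is negative binomial
    with that mean and ``count_dispersion``.  Cells then receive an EdU
    label (Bernoulli with ligand-shifted logit prevalence), an EdU
    intensity from the matching log-normal component, and a DAPI intensity.
    Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    frame = design.to_frame()
    if frame.empty:
        raise GenerationError("design has no assigned spots")

    ecm_f = frame["ecm"].map(lambda e: spec.ecm_effects.get(e, 1.0)).to_numpy(float)
    lig_f = frame["ligand"].map(lambda l: spec.ligand_effects.get(l, 1.0)).to_numpy(float)

    arrays = sorted(frame["array"].unique())
    if spec.array_factors is not None:
        factors = {a: float(spec.array_factors.get(a, 1.0)) for a in arrays}
    else:
        draws = np.exp(rng.normal(0.0, spec.array_factor_log_sd, size=len(arrays)))
        factors = dict(zip(arrays, draws))
    arr_f = frame["array"].map(factors).to_numpy(float)

    surface = spec.spatial_surface.evaluate(
        frame["row"].to_numpy(), frame["col"].to_numpy(), design.array_geometry
    )
    mu = spec.baseline_cells_per_spot * ecm_f * lig_f * arr_f * np.exp(surface)
    if not np.all(np.isfinite(mu)):
        bad = frame.iloc[int(np.argmax(~np.isfinite(mu)))]
        raise GenerationError(
            f"non-finite expected count at spot "
            f"{bad['array']} r{bad['row']} c{bad['col']}"
        )

    size = spec.count_dispersion
    counts = rng.negative_binomial(size, size / (size + mu))

    # per-cell draws, vectorized over the whole screen
    spot_idx = np.repeat(np.arange(len(frame)), counts)
    n_cells = int(counts.sum())
    shift = (
        frame["ligand"].map(lambda l: spec.ligand_edu_shift.get(l, 0.0)).to_numpy(float)
    )
    p_pos = expit(logit(spec.edu_base_rate) + shift)[spot_idx]
    labels = rng.random(n_cells) < p_pos
    mu_n, mu_p, sd = spec.edu_mixture
    edu = np.exp(rng.normal(np.where(labels, mu_p, mu_n), sd))
    dapi = np.exp(rng.normal(spec.dapi_log_mean, spec.dapi_log_sd, size=n_cells))

    cells = frame.iloc[spot_idx].reset_index(drop=True)
    cells["cell_id"] = [f"c{i}" for i in range(n_cells)]
    cells["dapi_intensity"] = dapi
    cells["edu_intensity"] = edu
    cells = cells[CELL_COLUMNS]

    truth_spots = frame.copy()
    truth_spots["mu"] = mu
    truth_spots["array_factor"] = arr_f
    truth_spots["surface"] = surface
    truth_spots["count"] = counts
    truth_spots["p_edu"] = expit(logit(spec.edu_base_rate) + shift)
    truth = GroundTruth(
        spots=truth_spots,
        cell_labels=labels,
        array_factors=factors,
        spec=spec,
        seed=spec.seed,
    )
    return cells, truth


def make_null_experiment(
    design: ExperimentDesign,
    spec: EffectSpec | None = None,
    seed: int | None = None,
    artifacts: bool = True,
) -> tuple[pd.DataFrame, GroundTruth]:
    """A screen with no ligand effects: the null for false-positive testing.

    All ligand count effects are 1 and all EdU shifts 0; array and spatial
    artifacts are retained unless ``artifacts`` is False.  ECM effects are
    kept (they are shared by control and treated spots and are not part of
    the ligand null hypothesis).
    """
    spec = spec if spec is not None else EffectSpec()
    updates: dict = {"ligand_effects": {}, "ligand_edu_shift": {}}
    if seed is not None:
        updates["seed"] = seed
    if not artifacts:
        updates["array_factors"] = {}
        updates["array_factor_log_sd"] = 0.0
        updates["spatial_surface"] = SurfaceSpec("none", ())
    return simulate_experiment(design, replace(spec, **updates))
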