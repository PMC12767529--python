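"""Experiment design model for MEMA (microenvironment microarray) screens.

A MEMA screen prints spots of ECM (extracellular matrix) proteins on the
floor of multiwell plates; cells adhere to the spots and a soluble ligand is
added to each well.  One ECM x ligand combination is a MEP (microenvironment
perturbation), the experimental unit of the screen.  PBS (vehicle) plays the
role of the control ligand: the PBS spots of each ECM are the comparison
baseline for hit calling.

The design model is deliberately free-form: a spot assignment maps an
addressed spot (plate, well, array, row, col) to a MEP, so both the
one-ligand-per-well layout used on the physical platform and more general
layouts can be represented.  Arrays are treated as identifiers nested within
wells (one array per well on the 8-well plates used here, but nothing relies
on that).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .errors import DesignError

#: Conventional name of the vehicle-control "ligand".
CONTROL_LIGAND = "PBS"


@dataclass(frozen=True)
class LigandSpec:
    """A soluble ligand added to a well, e.g. one SASP factor.

    ``is_control`` marks the vehicle (PBS) condition used as the Dunnett
    baseline.  ``concentration`` carries an arbitrary unit tag so designs
    with mixed units stay auditable.
    """

    name: str
    concentration: float = 0.0
    unit: str = "ng/ml"
    is_control: bool = False

    def __post_init__(self):
        if not self.name:
            raise DesignError("ligand name must be nonempty")
        if self.concentration < 0:
            raise DesignError(f"ligand {self.name!r}: concentration must be >= 0")


@dataclass(frozen=True)
class ECMSpec:
    """An ECM protein printed as spot substrate, at a given print concentration."""

    name: str
    print_concentration: float = 0.0

    def __post_init__(self):
        if not self.name:
            raise DesignError("ECM name must be nonempty")
        if self.print_concentration < 0:
            raise DesignError(f"ECM {self.name!r}: print concentration must be >= 0")


@dataclass(frozen=True)
class MEP:
    """One microenvironment perturbation: an ECM x ligand pair.

    Identity is the (ECM name, ligand name, ligand concentration) triple,
    carried by the frozen component specs; print-concentration variants of
    the same ECM protein are distinct ``ECMSpec`` entries and hence distinct
    MEPs unless the caller collapses them.
    """

    ecm: ECMSpec
    ligand: LigandSpec

    @property
    def is_control(self) -> bool:
        return self.ligand.is_control

    @property
    def label(self) -> str:
        return f"{self.ecm.name}:{self.ligand.name}"


@dataclass(frozen=True, order=True)
class SpotAddress:
    """Physical address of a printed spot: plate / well / array / row / col.

    Rows and columns are 0-based indices into the array's print geometry.
    """

    plate: str
    well: str
    array: str
    row: int
    col: int

    def __post_init__(self):
        if self.row < 0 or self.col < 0:
            raise DesignError(f"spot {self} has negative row/col")


@dataclass
class DesignReport:
    """Result of :func:`validate_design`: non-fatal findings and tallies."""

    replicate_counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.warnings


@dataclass
class ExperimentDesign:
    """A full screen design: ligand/ECM panels plus the spot layout.

    ``array_geometry`` is the (n_rows, n_cols) print grid shared by all
    arrays; addresses outside it are rejected.  Failed/unprinted positions
    are simply absent from ``spot_assignments``.
    """

    ligands: list[LigandSpec]
    ecms: list[ECMSpec]
    array_geometry: tuple[int, int]
    spot_assignments: dict[SpotAddress, MEP]
    replicates_per_mep: int = 15

    def __post_init__(self):
        _check_unique([l.name for l in self.ligands], "ligand")
        _check_unique([e.name for e in self.ecms], "ECM")
        nr, nc = self.array_geometry
        valid = set(self.meps())
        for addr, mep in self.spot_assignments.items():
            if addr.row >= nr or addr.col >= nc:
                raise DesignError(
                    f"spot {addr} outside array geometry {self.array_geometry}"
                )
            if mep not in valid:
                raise DesignError(f"spot {addr} assigned unknown MEP {mep.label}")

    # -- enumeration ---------------------------------------------------

    def meps(self) -> list[MEP]:
        """Full ECM x ligand product, ECM-major order."""
        return enumerate_meps(self.ligands, self.ecms)

    def control_ligands(self) -> list[LigandSpec]:
        return [l for l in self.ligands if l.is_control]

    def arrays(self) -> list[str]:
        return sorted({a.array for a in self.spot_assignments})

    # -- tabular form --------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """One row per assigned spot; the on-disk design CSV dialect."""
        rows = []
        for addr in sorted(self.spot_assignments):
            mep = self.spot_assignments[addr]
            rows.append(
                {
                    "plate": addr.plate,
                    "well": addr.well,
                    "array": addr.array,
                    "row": addr.row,
                    "col": addr.col,
                    "ecm": mep.ecm.name,
                    "ecm_conc": mep.ecm.print_concentration,
                    "ligand": mep.ligand.name,
                    "ligand_conc": mep.ligand.concentration,
                    "is_control": mep.ligand.is_control,
                }
            )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, replicates_per_mep: int | None = None
    ) -> "ExperimentDesign":
        ligands: dict[str, LigandSpec] = {}
        ecms: dict[str, ECMSpec] = {}
        assignments: dict[SpotAddress, MEP] = {}
        for rec in frame.to_dict("records"):
            lig = ligands.setdefault(
                str(rec["ligand"]),
                LigandSpec(
                    str(rec["ligand"]),
                    float(rec.get("ligand_conc", 0.0)),
                    is_control=bool(rec.get("is_control", False)),
                ),
            )
            ecm = ecms.setdefault(
                str(rec["ecm"]),
                ECMSpec(str(rec["ecm"]), float(rec.get("ecm_conc", 0.0))),
            )
            addr = SpotAddress(
                str(rec["plate"]),
                str(rec["well"]),
                str(rec["array"]),
                int(rec["row"]),
                int(rec["col"]),
            )
            if addr in assignments:
                raise DesignError(f"duplicate spot address {addr}")
            assignments[addr] = MEP(ecm, lig)
        nr = max((a.row for a in assignments), default=-1) + 1
        nc = max((a.col for a in assignments), default=-1) + 1
        if replicates_per_mep is None:
            counts = pd.Series([m.label for m in assignments.values()]).value_counts()
            replicates_per_mep = int(counts.median()) if len(counts) else 0
        return cls(
            ligands=list(ligands.values()),
            ecms=list(ecms.values()),
            array_geometry=(nr, nc),
            spot_assignments=assignments,
            replicates_per_mep=replicates_per_mep,
        )


def _check_unique(names: Iterable[str], what: str) -> None:
    seen = set()
    for n in names:
        if n in seen:
            raise DesignError(f"duplicate {what} name {n!r}")
        seen.add(n)
    if not seen:
        raise DesignError(f"{what} list must be nonempty")


def enumerate_meps(
    ligands: list[LigandSpec], ecms: list[ECMSpec]
) -> list[MEP]:
    """Cartesian product of the ECM and ligand panels, ECM-major order.

    The screen interrogates every combination, so 63 ligands crossed with
    25 ECM proteins yield 1,575 distinct MEPs.
    """
    _check_unique([l.name for l in ligands], "ligand")
    _check_unique([e.name for e in ecms], "ECM")
    return [MEP(e, l) for e, l in itertools.product(ecms, ligands)]


def validate_design(
    design: ExperimentDesign, min_replicates: int = 3
) -> DesignReport:
    """Audit a design: replicate tallies, missing controls, sparse MEPs.

    Raises :class:`DesignError` on fatal defects (no PBS control spots at
    all, or a well used for testing without any control spots).  Non-fatal
    findings (MEPs below ``min_replicates`` assigned spots, enumerated MEPs
    with no spots) are returned as warnings.
    """
    report = DesignReport()
    if not any(l.is_control for l in design.ligands):
        raise DesignError("design has no control (PBS) ligand")
    assigned = list(design.spot_assignments.values())
    if not any(m.is_control for m in assigned):
        raise DesignError("design has no control (PBS) spots")

    counts: dict[str, int] = {}
    for mep in assigned:
        counts[mep.label] = counts.get(mep.label, 0) + 1
    report.replicate_counts = counts
    for mep in design.meps():
        n = counts.get(mep.label, 0)
        if n == 0:
            report.warnings.append(f"MEP {mep.label} has no assigned spots")
        elif n < min_replicates and not mep.is_control:
            report.warnings.append(
                f"MEP {mep.label} has {n} replicate spots (< {min_replicates})"
            )
    return report


def build_screen_design(
    ligands: list[LigandSpec],
    ecms: list[ECMSpec],
    arrays_per_ligand: int = 3,
    spots_per_ecm: int = 5,
    control_spots_per_ecm: int = 2,
    wells_per_plate: int = 8,
    layout_seed: int = 0,
) -> ExperimentDesign:
    """Build the canonical screen layout used by the simulator and tests.

    Each treatment ligand is dosed into ``arrays_per_ligand`` wells (one
    array per well); every array carries the identical print layout:
    ``spots_per_ecm`` spots of each ECM receiving the well's ligand plus
    ``control_spots_per_ecm`` PBS control slots per ECM, so PBS controls
    sit in every well used for testing.  Each treatment MEP therefore has
    ``arrays_per_ligand * spots_per_ecm`` replicate spots split across
    arrays, while the PBS control MEPs span all arrays.  Both features
    matter statistically: within-array controls keep ligand contrasts free
    of array confounding, and control replicates spanning arrays let the
    replicate-median residuals carry the array-level unwanted variation
    that RUV estimates.  The print layout (which ECM / control slot sits at
    which row/col) is a seeded shuffle shared by all arrays, as a printing
    robot would produce.
    """
    import numpy as np

    if arrays_per_ligand < 1 or spots_per_ecm < 1 or control_spots_per_ecm < 1:
        raise DesignError(
            "arrays_per_ligand, spots_per_ecm and control_spots_per_ecm must be >= 1"
        )
    treatments = [l for l in ligands if not l.is_control]
    controls = [l for l in ligands if l.is_control]
    if not treatments:
        raise DesignError("need at least one treatment ligand")
    if len(controls) != 1:
        raise DesignError("need exactly one control (PBS) ligand in the panel")
    pbs = controls[0]

    # shared print layout: each slot is (ecm, is_control_slot)
    slots = [(e, False) for e in ecms for _ in range(spots_per_ecm)]
    slots += [(e, True) for e in ecms for _ in range(control_spots_per_ecm)]
    rng = np.random.default_rng(layout_seed)
    rng.shuffle(slots)
    n_spots = len(slots)
    nc = int(math.ceil(math.sqrt(n_spots)))
    nr = int(math.ceil(n_spots / nc))

    assignments: dict[SpotAddress, MEP] = {}
    well_idx = 0
    for lig in treatments:
        for _ in range(arrays_per_ligand):
            plate = f"P{well_idx // wells_per_plate + 1:02d}"
            well = f"{plate}-W{well_idx % wells_per_plate + 1}"
            array = f"{well}-A1"
            well_idx += 1
            for k, (ecm, is_ctrl) in enumerate(slots):
                addr = SpotAddress(plate, well, array, k // nc, k % nc)
                assignments[addr] = MEP(ecm, pbs if is_ctrl else lig)
    return ExperimentDesign(
        ligands=treatments + [pbs],
        ecms=list(ecms),
        array_geometry=(nr, nc),
        spot_assignments=assignments,
        replicates_per_mep=arrays_per_ligand * spots_per_ecm,
    )


def default_ligand_panel(n_treatment: int, concentration: float = 100.0) -> list[LigandSpec]:
    """``n_treatment`` generically named ligands plus the PBS control."""
    panel = [LigandSpec(f"L{i + 1:02d}", concentration) for i in range(n_treatment)]
    panel.append(LigandSpec(CONTROL_LIGAND, 0.0, is_control=True))
    return panel


def default_ecm_panel(n_ecm: int, print_concentration: float = 200.0) -> list[ECMSpec]:
    return [ECMSpec(f"ECM{i + 1:02d}", print_concentration) for i in range(n_ecm)]
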