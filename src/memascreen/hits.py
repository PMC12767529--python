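"""MEP-level summarization and ligand hit calling against PBS controls.

After normalization, the replicate spots of each MEP are median-summarized
for reporting, while the hit test runs on the normalized spot values
themselves so it keeps replicate-level degrees of freedom.  Each treatment
ligand is compared with the PBS control spots by Dunnett's many-to-one
test, either within each ECM stratum (each ECM family tested against its
own PBS spots) or pooled across ECMs after centering out the per-ECM
median, which keeps the whole screen a single comparison family.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .design import CONTROL_LIGAND
from .dunnett import dunnett_test
from .errors import ConfigurationError, ParameterError

ENDPOINT_COLUMNS = {
    "cell_count": "cell_count_norm",
    "edu_proportion": "edu_prop_norm",
}


def summarize_meps(spots: pd.DataFrame) -> pd.DataFrame:
    """Median-summarize the replicate spots of each MEP.

    Returns one row per (ecm, ligand): replicate count, median cell count,
    median EdU-positive proportion (over spots with a defined proportion),
    and medians of any normalized signals present.  MEPs whose spots are
    all empty get missing endpoint medians and a warning.
    """
    value_cols = ["cell_count", "edu_prop"] + [
        c for c in spots.columns if c.endswith("_norm")
    ]
    rows = []
    for (ecm, lig), grp in spots.groupby(["ecm", "ligand"], sort=True):
        rec = {
            "ecm": ecm,
            "ligand": lig,
            "is_control": bool(grp["is_control"].iloc[0]),
            "n_spots": len(grp),
        }
        for c in value_cols:
            vals = grp[c].to_numpy(float)
            vals = vals[np.isfinite(vals)]
            rec[f"median_{c}"] = float(np.median(vals)) if vals.size else np.nan
        if grp["cell_count"].sum() == 0:
            warnings.warn(
                f"MEP {ecm}:{lig} has no cells in any spot; endpoint medians missing",
                stacklevel=2,
            )
        rows.append(rec)
    out = pd.DataFrame(rows)
    return out.rename(
        columns={"median_cell_count": "median_cell_count",
                 "median_edu_prop": "median_edu_proportion"}
    )


def call_hits(
    spots: pd.DataFrame,
    endpoint: str = "cell_count",
    alpha: float = 0.05,
    stratify: str = "ecm",
    alternative: str = "two-sided",
    control: str | None = None,
    unit: str = "spot",
) -> pd.DataFrame:
    """Dunnett comparison of every ligand against the PBS control spots.

    ``endpoint`` is ``"cell_count"`` or ``"edu_proportion"``; the test runs
    on the corresponding normalized column (``*_norm``), which must be
    present.  ``stratify="ecm"`` tests each ECM family separately;
    ``stratify="pooled"`` centers values by ECM median and runs one family
    over the whole screen.  Hits are rows with adjusted p < alpha,
    direction "up"/"down" by the sign of the estimate; output is sorted by
    adjusted p, then |estimate| (descending), then ligand name.

    ``unit`` selects the observational unit: ``"spot"`` uses every
    normalized spot value (replicate-level degrees of freedom, valid when
    array-level variation has been fully removed), while ``"array"``
    median-summarizes to one value per ligand per array first.  Arrays are
    the independently perturbed physical unit, so the array-level test
    keeps family-wise error honest even when residual array variation
    survives normalization; it is the unit used for screen-level error
    calibration.
    """
    if endpoint not in ENDPOINT_COLUMNS:
        raise ConfigurationError(
            f"unknown endpoint {endpoint!r}; expected one of {sorted(ENDPOINT_COLUMNS)}"
        )
    col = ENDPOINT_COLUMNS[endpoint]
    if col not in spots.columns:
        raise ConfigurationError(
            f"endpoint column {col!r} absent — run normalization first"
        )
    if not (0.0 <= alpha < 1.0):
        raise ParameterError(f"alpha must be in [0, 1), got {alpha}")
    if stratify not in ("ecm", "pooled"):
        raise ParameterError(f"unknown stratification {stratify!r}")
    if unit not in ("spot", "array"):
        raise ParameterError(f"unknown test unit {unit!r}")
    if control is None:
        controls = spots.loc[spots["is_control"], "ligand"].unique()
        if len(controls) == 0:
            raise ConfigurationError("spot table has no control (PBS) spots")
        control = CONTROL_LIGAND if CONTROL_LIGAND in controls else str(controls[0])

    rows = []
    if stratify == "ecm":
        strata = list(spots.groupby("ecm", sort=True))
    else:
        pooled = spots.copy()
        med = pooled.groupby("ecm")[col].transform("median")
        pooled[col] = pooled[col] - med
        strata = [("all", pooled)]

    for stratum, part in strata:
        usable = part[np.isfinite(part[col].to_numpy(float))]
        if unit == "array":
            usable = (
                usable.groupby(["ligand", "array"], as_index=False)[col]
                .median()
            )
        res = dunnett_test(
            usable[col].to_numpy(float),
            usable["ligand"].to_numpy(),
            control=control,
            alternative=alternative,
        )
        for c in res.comparisons:
            rows.append(
                {
                    "ligand": c.group,
                    "ecm_stratum": str(stratum),
                    "endpoint": endpoint,
                    "estimate": c.estimate,
                    "t": c.t,
                    "adj_p": c.p_adjusted,
                    "direction": "up" if c.estimate > 0 else "down",
                    "hit": c.p_adjusted < alpha,
                    "n": c.n,
                }
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["_absest"] = out["estimate"].abs()
    out = (
        out.sort_values(["adj_p", "_absest", "ligand"], ascending=[True, False, True])
        .drop(columns="_absest")
        .reset_index(drop=True)
    )
    return out


def report_tables(mep_summaries: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Report bundle: count heatmap matrix and ranked EdU tables.

    Returns ``{"count_matrix": ECM x ligand median cell counts,
    "edu_by_ligand": ligand-ranked median EdU proportion,
    "edu_by_ecm": ECM-ranked median EdU proportion}``; ranked tables are
    sorted non-decreasing by the endpoint with deterministic name
    tie-breaks, so they are stable under input row shuffles.
    """
    if mep_summaries.empty:
        empty = pd.DataFrame()
        return {"count_matrix": empty, "edu_by_ligand": empty, "edu_by_ecm": empty}
    count_matrix = mep_summaries.pivot_table(
        index="ecm", columns="ligand", values="median_cell_count", aggfunc="median"
    ).sort_index(axis=0).sort_index(axis=1)

    def ranked(by: str) -> pd.DataFrame:
        t = (
            mep_summaries.groupby(by, sort=True)["median_edu_proportion"]
            .median()
            .reset_index()
            .rename(columns={"median_edu_proportion": "median_edu_proportion"})
        )
        return t.sort_values(
            ["median_edu_proportion", by], kind="mergesort"
        ).reset_index(drop=True)

    return {
        "count_matrix": count_matrix,
        "edu_by_ligand": ranked("ligand"),
        "edu_by_ecm": ranked("ecm"),
    }


def render_report(tables: dict[str, pd.DataFrame], out_dir) -> list[str]:
    """Write the report bundle as CSVs plus heatmap/bar figures (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        path = out_dir / f"{name}.csv"
        table.to_csv(path, index=(name == "count_matrix"))
        written.append(str(path))

    cm = tables["count_matrix"]
    if not cm.empty:
        fig, ax = plt.subplots(
            figsize=(max(4, 0.25 * cm.shape[1]), max(3, 0.25 * cm.shape[0]))
        )
        im = ax.imshow(cm.to_numpy(float), aspect="auto", cmap="viridis")
        ax.set_xticks(range(cm.shape[1]), cm.columns, rotation=90, fontsize=5)
        ax.set_yticks(range(cm.shape[0]), cm.index, fontsize=6)
        ax.set_xlabel("ligand")
        ax.set_ylabel("ECM")
        fig.colorbar(im, ax=ax, label="median cells per spot")
        fig.tight_layout()
        p = out_dir / "count_matrix.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        written.append(str(p))

    for name, key in (("edu_by_ligand", "ligand"), ("edu_by_ecm", "ecm")):
        t = tables[name]
        if t.empty:
            continue
        fig, ax = plt.subplots(figsize=(max(4, 0.18 * len(t)), 3))
        ax.bar(t[key], t["median_edu_proportion"], color="#4878a8")
        ax.tick_params(axis="x", rotation=90, labelsize=5)
        ax.set_ylabel("median EdU+ proportion")
        fig.tight_layout()
        p = out_dir / f"{name}.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        written.append(str(p))
    return written
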