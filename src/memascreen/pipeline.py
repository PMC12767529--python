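"""One-call orchestration of the screen analysis chain.

``analyze_screen`` runs gate -> spot summarization -> RUV/LOESS
normalization -> MEP summaries -> Dunnett hit calling on an in-memory cell
table, returning every intermediate; it is the programmatic equivalent of
chaining the CLI stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .config import PipelineConfig
from .design import ExperimentDesign
from .features import GateResult, gate_edu, summarize_spots
from .hits import call_hits, summarize_meps
from .normalize import normalize_pipeline


@dataclass
class ScreenResult:
    spots: pd.DataFrame
    normalized: pd.DataFrame
    gate: GateResult
    mep_summaries: pd.DataFrame
    hits: dict[str, pd.DataFrame] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)


def analyze_screen(
    cells: pd.DataFrame,
    design: ExperimentDesign,
    config: PipelineConfig | None = None,
    endpoints: tuple[str, ...] = ("cell_count",),
    summarize: bool = True,
) -> ScreenResult:
    cfg = config or PipelineConfig()
    gate = gate_edu(cells, scope=cfg.gating_scope, method=cfg.gating_method)
    spots = summarize_spots(cells, gate, design)
    normalized, diagnostics = normalize_pipeline(
        spots,
        signals=cfg.signals,
        k=cfg.ruv_k,
        span=cfg.loess_span,
        min_spots=cfg.loess_min_spots,
        matrix_scope=cfg.matrix_scope,
    )
    summaries = summarize_meps(normalized) if summarize else pd.DataFrame()
    hits = {
        ep: call_hits(
            normalized,
            endpoint=ep,
            alpha=cfg.alpha,
            stratify=cfg.stratify,
            alternative=cfg.alternative,
            unit=cfg.test_unit,
        )
        for ep in endpoints
    }
    return ScreenResult(spots, normalized, gate, summaries, hits, diagnostics)
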