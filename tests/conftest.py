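import numpy as np
import pytest

import memascreen as ms


@pytest.fixture(scope="session")
def small_design():
    """4 treatment ligands x 3 ECMs, 2 arrays/ligand — the smallest useful screen."""
    return ms.build_screen_design(
        ms.default_ligand_panel(4),
        ms.default_ecm_panel(3),
        arrays_per_ligand=2,
        spots_per_ecm=5,
        control_spots_per_ecm=2,
    )


@pytest.fixture(scope="session")
def screen_design():
    """The desk-scale screen: 8 treatment ligands x 4 ECMs, 15 replicates/MEP."""
    return ms.build_screen_design(ms.default_ligand_panel(8), ms.default_ecm_panel(4))


@pytest.fixture(scope="session")
def lean_config():
    """Fast single-signal pipeline configuration used by whole-screen tests."""
    return ms.PipelineConfig(
        gating_scope="global",
        signals=("cell_count",),
        stratify="pooled",
        test_unit="array",
    )


@pytest.fixture(scope="session")
def null_screen(screen_design):
    cells, truth = ms.make_null_experiment(screen_design, seed=1)
    return cells, truth


def spearman(x, y):
    from scipy.stats import spearmanr

    return spearmanr(np.asarray(x), np.asarray(y)).statistic
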