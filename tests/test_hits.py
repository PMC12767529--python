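import numpy as np
import pandas as pd
import pytest

import memascreen as ms
from memascreen.errors import ConfigurationError
from memascreen.hits import call_hits, report_tables, summarize_meps


def _spot_frame(records):
    return pd.DataFrame(
        records,
        columns=["plate", "well", "array", "row", "col", "ecm", "ligand",
                 "is_control", "cell_count", "edu_pos", "edu_prop"],
    )


class TestSummarizeMeps:
    def test_constant_replicates_median(self):
        rows = [
            ("P1", "W1", "A1", 0, i, "E", "L", False, 40, 10, 0.25)
            for i in range(15)
        ]
        out = summarize_meps(_spot_frame(rows))
        assert out.loc[0, "median_cell_count"] == 40
        assert out.loc[0, "n_spots"] == 15

    def test_even_sample_median_interpolates(self):
        props = [0.1, 0.2, 0.3, 0.4]
        rows = [
            ("P1", "W1", "A1", 0, i, "E", "L", False, 10, int(10 * p), p)
            for i, p in enumerate(props)
        ]
        out = summarize_meps(_spot_frame(rows))
        assert out.loc[0, "median_edu_proportion"] == pytest.approx(0.25)

    def test_all_empty_spots_warn_missing_endpoint(self):
        rows = [
            ("P1", "W1", "A1", 0, i, "E", "L", False, 0, 0, np.nan)
            for i in range(3)
        ]
        with pytest.warns(UserWarning, match="no cells"):
            out = summarize_meps(_spot_frame(rows))
        assert np.isnan(out.loc[0, "median_edu_proportion"])


class TestCallHits:
    def test_planted_up_ligands_are_top_hits(self, lean_config):
        """Exactly 3 planted 2-fold-up ligands in an 8-ligand screen: the
        planted three are the top-3 comparisons and are called up-hits."""
        design = ms.build_screen_design(
            ms.default_ligand_panel(8), ms.default_ecm_panel(4)
        )
        planted = {"L02": 2.0, "L05": 2.0, "L07": 2.0}
        spec = ms.EffectSpec(ligand_effects=planted, seed=13)
        cells, _ = ms.simulate_experiment(design, spec)
        result = ms.analyze_screen(cells, design, lean_config, summarize=False)
        hits = result.hits["cell_count"]
        top3 = hits.head(3)
        assert set(top3["ligand"]) == set(planted)
        assert (top3["direction"] == "up").all()
        assert top3["hit"].all()

    def test_alpha_zero_empty_hit_list(self, lean_config, null_screen, screen_design):
        cells, _ = null_screen
        result = ms.analyze_screen(cells, screen_design, lean_config, summarize=False)
        table = result.hits["cell_count"]
        zero = call_hits(result.normalized, alpha=0.0, stratify="pooled", unit="array")
        assert not zero["hit"].any()
        assert len(zero) == len(table)

    def test_missing_endpoint_column_raises(self, null_screen, screen_design):
        cells, _ = null_screen
        gate = ms.gate_edu(cells, scope="global")
        spots = ms.summarize_spots(cells, gate, screen_design)
        with pytest.raises(ConfigurationError, match="normaliz"):
            call_hits(spots, endpoint="cell_count")

    def test_stratified_mode_one_family_per_ecm(self, lean_config, screen_design):
        cells, _ = ms.make_null_experiment(screen_design, seed=21)
        cfg = ms.PipelineConfig(
            gating_scope="global", signals=("cell_count",),
            stratify="ecm", test_unit="array",
        )
        result = ms.analyze_screen(cells, screen_design, cfg, summarize=False)
        hits = result.hits["cell_count"]
        assert set(hits["ecm_stratum"]) == {e.name for e in screen_design.ecms}
        n_treat = sum(not l.is_control for l in screen_design.ligands)
        assert len(hits) == n_treat * len(screen_design.ecms)

    def test_recall_monotone_in_effect_size(self):
        """Hit recall of planted up-ligands does not decrease as the
        planted fold-change grows (1.5x, 2x, 4x)."""
        design = ms.build_screen_design(
            ms.default_ligand_panel(8), ms.default_ecm_panel(4)
        )
        cfg = ms.PipelineConfig(
            gating_scope="global", signals=("cell_count",),
            stratify="pooled", test_unit="array",
        )
        planted_names = ["L01", "L04", "L08"]
        recalls = []
        for fold in (1.5, 2.0, 4.0):
            spec = ms.EffectSpec(
                ligand_effects={n: fold for n in planted_names}, seed=17
            )
            cells, _ = ms.simulate_experiment(design, spec)
            result = ms.analyze_screen(cells, design, cfg, summarize=False)
            hits = result.hits["cell_count"]
            called = set(hits.loc[hits["hit"] & (hits["direction"] == "up"), "ligand"])
            recalls.append(len(called & set(planted_names)) / len(planted_names))
        assert recalls == sorted(recalls)
        assert recalls[-1] == 1.0


class TestReportTables:
    @staticmethod
    def _summaries(n_ecm, n_lig):
        rng = np.random.default_rng(0)
        recs = []
        for e in range(n_ecm):
            for l in range(n_lig):
                recs.append(
                    {
                        "ecm": f"E{e:02d}",
                        "ligand": f"L{l:02d}",
                        "is_control": False,
                        "n_spots": 15,
                        "median_cell_count": float(rng.integers(10, 100)),
                        "median_edu_proportion": float(rng.random()),
                    }
                )
        return pd.DataFrame(recs)

    def test_full_design_heatmap_shape(self):
        tables = report_tables(self._summaries(25, 63))
        assert tables["count_matrix"].shape == (25, 63)

    def test_single_mep_matrix(self):
        tables = report_tables(self._summaries(1, 1))
        assert tables["count_matrix"].shape == (1, 1)

    def test_ranked_tables_sorted_and_shuffle_stable(self):
        summaries = self._summaries(4, 9)
        tables = report_tables(summaries)
        ranked = tables["edu_by_ligand"]["median_edu_proportion"].to_numpy()
        assert (np.diff(ranked) >= 0).all()
        shuffled = summaries.sample(frac=1.0, random_state=5).reset_index(drop=True)
        tables2 = report_tables(shuffled)
        pd.testing.assert_frame_equal(tables["edu_by_ligand"], tables2["edu_by_ligand"])
        pd.testing.assert_frame_equal(tables["count_matrix"], tables2["count_matrix"])

    def test_empty_input_empty_tables(self):
        tables = report_tables(pd.DataFrame())
        assert all(t.empty for t in tables.values())

    def test_render_writes_csv_and_png(self, tmp_path):
        tables = report_tables(self._summaries(3, 5))
        from memascreen.hits import render_report

        written = render_report(tables, tmp_path)
        assert (tmp_path / "count_matrix.csv").exists()
        assert (tmp_path / "count_matrix.png").exists()
        assert any(str(p).endswith("edu_by_ligand.png") for p in written)
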