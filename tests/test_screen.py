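"""Plate normalization, replicate aggregation, hit calling, artifacts, Z'."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fretscreen as fs


def well_row(well_id, role, mean_peak, compound_id="", valid=True, n_cells=170,
             baseline_donor=700.0, baseline_acceptor=735.0, replicate=1):
    return {
        "well_id": well_id,
        "role": role,
        "compound_id": compound_id,
        "replicate": replicate,
        "mean_peak_responsive": mean_peak,
        "responsive_fraction": 0.9,
        "n_cells": n_cells,
        "valid": valid,
        "baseline_donor_mean": baseline_donor,
        "baseline_acceptor_mean": baseline_acceptor,
    }


@pytest.fixture
def demo_wells():
    rows = [well_row(f"A{i+1:02d}", "DMSO", 1.0 + 0.01 * (i - 1)) for i in range(3)]
    rows += [
        well_row("B01", "compound", 0.5, "C1"),
        well_row("B02", "compound", 0.6, "C1"),
        well_row("B03", "compound", 1.0, "C2"),
        well_row("B04", "compound", 0.95, "C2", valid=False),
    ]
    return pd.DataFrame(rows)


class TestNormalizeToDmso:
    def test_divides_by_dmso_mean(self, demo_wells):
        out = fs.normalize_to_dmso(demo_wells)
        dmso_mean = demo_wells.loc[demo_wells.role == "DMSO", "mean_peak_responsive"].mean()
        assert out.loc[out.well_id == "B01", "normalized_response"].iloc[0] == pytest.approx(0.5 / dmso_mean)

    def test_dmso_self_normalization_averages_to_one(self, demo_wells):
        out = fs.normalize_to_dmso(demo_wells)
        assert out.loc[out.role == "DMSO", "normalized_response"].mean() == pytest.approx(1.0)

    def test_no_dmso_rejected(self):
        df = pd.DataFrame([well_row("A01", "compound", 0.5, "C1")])
        with pytest.raises(ValueError, match="DMSO"):
            fs.normalize_to_dmso(df)

    def test_invalid_wells_get_nan(self, demo_wells):
        out = fs.normalize_to_dmso(demo_wells)
        assert np.isnan(out.loc[out.well_id == "B04", "normalized_response"].iloc[0])

    def test_scale_invariance(self, demo_wells):
        out1 = fs.normalize_to_dmso(demo_wells)
        scaled = demo_wells.copy()
        scaled["mean_peak_responsive"] *= 7.3
        out2 = fs.normalize_to_dmso(scaled)
        assert np.allclose(
            out1["normalized_response"], out2["normalized_response"], equal_nan=True
        )


class TestAggregateReplicates:
    def test_identical_replicates(self):
        df = pd.DataFrame(
            [well_row(f"B{i:02d}", "compound", 0.8, "C1", replicate=i) for i in range(1, 5)]
        )
        df["normalized_response"] = 0.8
        agg = fs.aggregate_replicates(df)
        row = agg.iloc[0]
        assert row.normalized_response_mean == pytest.approx(0.8)
        assert row.normalized_response_sd == 0.0

    def test_two_point_sample_sd(self):
        df = pd.DataFrame(
            [well_row("B01", "compound", 0.7, "C1"), well_row("B02", "compound", 0.9, "C1")]
        )
        df["normalized_response"] = df["mean_peak_responsive"]
        agg = fs.aggregate_replicates(df)
        assert agg.iloc[0].normalized_response_mean == pytest.approx(0.8)
        assert agg.iloc[0].normalized_response_sd == pytest.approx(np.sqrt(0.02), rel=1e-9)

    def test_invalid_replicates_excluded_and_counted(self, demo_wells):
        out = fs.normalize_to_dmso(demo_wells)
        agg = fs.aggregate_replicates(out)
        c2 = agg[agg.compound_id == "C2"].iloc[0]
        assert c2.n_replicates == 2 and c2.n_valid == 1
        assert c2.normalized_response_mean == pytest.approx(1.0)

    def test_all_invalid_flags_unmeasured(self):
        df = pd.DataFrame([well_row("B01", "compound", 0.5, "C1", valid=False)])
        df["normalized_response"] = np.nan
        agg = fs.aggregate_replicates(df)
        assert bool(agg.iloc[0].unmeasured)


class TestCallHits:
    def _table(self, means, **flags):
        df = pd.DataFrame(
            {
                "compound_id": [f"C{i}" for i in range(len(means))],
                "normalized_response_mean": means,
            }
        )
        for k, v in flags.items():
            df[k] = v
        return df

    def test_strict_cutoff_boundary(self):
        out = fs.call_hits(self._table([0.89, 0.90, 0.91]))
        assert out.hit.tolist() == [True, False, False]

    def test_artifact_precedence(self):
        out = fs.call_hits(
            self._table([0.85, 0.85], autofluorescent=[False, True], toxic=[False, False])
        )
        assert out.hit.tolist() == [True, False]

    def test_float_noise_at_boundary_rounds_to_cutoff(self):
        out = fs.call_hits(self._table([0.9 - 1e-12, 0.9 + 1e-12]))
        assert out.hit.tolist() == [False, False]


class TestFlagArtifacts:
    def _wells(self):
        rows = [well_row(f"A{i:02d}", "DMSO", 1.0,
                         baseline_donor=700 + i, baseline_acceptor=735 + i,
                         n_cells=170) for i in range(1, 5)]
        rows.append(well_row("B01", "compound", 0.9, "C1", n_cells=20))        # toxic
        rows.append(well_row("B02", "compound", 0.9, "C2",
                             baseline_donor=1400.0))                            # autofluor
        rows.append(well_row("B03", "compound", 0.9, "C3"))                     # clean
        return pd.DataFrame(rows)

    def test_toxic_flag_from_cell_count(self):
        out = fs.flag_artifacts(self._wells())
        assert bool(out.loc[out.well_id == "B01", "toxic"].iloc[0])
        assert not bool(out.loc[out.well_id == "B03", "toxic"].iloc[0])

    def test_autofluorescent_flag_from_baseline(self):
        out = fs.flag_artifacts(self._wells())
        assert bool(out.loc[out.well_id == "B02", "autofluorescent"].iloc[0])
        assert not bool(out.loc[out.well_id == "B03", "autofluorescent"].iloc[0])

    def test_baseline_equal_to_dmso_unflagged(self):
        out = fs.flag_artifacts(self._wells())
        dmso_flags = out.loc[out.role == "DMSO", ["autofluorescent", "toxic"]]
        assert not dmso_flags.any().any()


class TestZprime:
    def test_zero_sds_give_one(self):
        qc = fs.zprime([0.3, 0.3], [1.0, 1.0])
        assert qc.zprime_canonical == 1.0
        assert qc.zprime_as_printed == 1.0

    def test_hand_computed_variants(self):
        # sigma values chosen to make the arithmetic checkable by hand
        rng = np.random.default_rng(0)

        # construct samples with exact mean/sd via affine adjustment
        def sample(mu, sd, n):
            x = rng.normal(size=n)
            x = (x - x.mean()) / x.std(ddof=1)
            return mu + sd * x

        tp = sample(0.3, 0.02, 16)
        dmso = sample(1.0, 0.03, 16)
        qc = fs.zprime(tp, dmso)
        assert qc.zprime_canonical == pytest.approx(1 - 0.15 / 0.7, abs=1e-9)
        assert qc.zprime_as_printed == pytest.approx(1 - 0.09 / 0.7, abs=1e-9)

    def test_equal_means_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            fs.zprime([1.0, 1.1], [1.1, 1.0])

    def test_needs_two_wells_per_group(self):
        with pytest.raises(ValueError):
            fs.zprime([0.3], [1.0, 1.1])

    @settings(derandomize=True, deadline=None, max_examples=30)
    @given(
        sd_tp=st.floats(min_value=0.001, max_value=0.2),
        bump=st.floats(min_value=0.001, max_value=0.2),
    )
    def test_canonical_at_most_one_and_decreases_with_spread(self, sd_tp, bump):
        rng = np.random.default_rng(5)
        base = rng.normal(size=16)
        base = (base - base.mean()) / base.std(ddof=1)
        tp = 0.3 + sd_tp * base
        tp_wider = 0.3 + (sd_tp + bump) * base
        dmso = 1.0 + 0.03 * base
        z1 = fs.zprime(tp, dmso).zprime_canonical
        z2 = fs.zprime(tp_wider, dmso).zprime_canonical
        assert z1 <= 1.0
        assert z2 < z1


class TestPlantedArtifacts:
    def test_generator_planted_artifacts_are_flagged_and_block_hits(self):
        """A compound rendered with donor-channel autofluorescence and one
        rendered with cell kill are flagged and excluded from the hit list
        even when their normalized response is below the cutoff."""
        import dataclasses

        base = fs.SimParams(responder_fraction=1.0).noiseless()
        params = dataclasses.replace(
            base,
            n_cells=25,
            field_shape=(192, 192),
            compound_suppression={"AF": 0.5, "TOX": 0.5, "OK": 0.5},
            autofluorescent_compounds=frozenset({"AF"}),
            toxic_compounds=frozenset({"TOX"}),
        )
        layout = fs.make_layout(
            ["AF", "TOX", "OK"], n_replicates=2, n_dmso=3, n_tp=2,
            n_cpa=0, n_tmb8=0, n_untreated=0,
        )
        plate = fs.simulate_plate(layout, params, seed=3)
        results = []
        for well in layout:
            sim = plate.wells[well.well_id]
            seg = fs.segment_field(sim.stack)
            res, _ = fs.analyze_well(sim.stack, seg, min_responsive_cells=3)
            results.append(res)
        table = fs.build_screen_table(fs.well_results_frame(results, layout))
        by_id = table.set_index("compound_id")
        assert bool(by_id.loc["AF", "autofluorescent"])
        assert bool(by_id.loc["TOX", "toxic"])
        assert not bool(by_id.loc["OK", "autofluorescent"])
        assert not bool(by_id.loc["OK", "toxic"])
        assert set(table.loc[table.hit, "compound_id"]) == {"OK"}


class TestResponsiveFractionReport:
    def test_genotype_contrast_table(self):
        rows = []
        for i in range(5):
            rows.append({**well_row(f"A{i:02d}", "DMSO", 1.3), "condition": "FAD",
                         "responsive_fraction": 0.96})
            rows.append({**well_row(f"B{i:02d}", "DMSO", 0.45), "condition": "WT",
                         "responsive_fraction": 0.29})
        report = fs.responsive_fraction_report(pd.DataFrame(rows))
        fad = report[report.condition == "FAD"].iloc[0]
        wt = report[report.condition == "WT"].iloc[0]
        assert fad.responsive_fraction_mean > 0.95
        assert wt.responsive_fraction_mean == pytest.approx(0.29)

    def test_single_well_single_condition(self):
        df = pd.DataFrame([{**well_row("A01", "DMSO", 1.0), "condition": "WT"}])
        report = fs.responsive_fraction_report(df)
        assert len(report) == 1 and report.iloc[0].n_wells == 1
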