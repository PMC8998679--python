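"""Hotspot screening, contribution ranking, comparison, and heat maps."""

import pytest

from nanossbd import (DataTier, ImpactResult, NanoForm, ReleaseModel,
                      ValidationError, build_heatmap, compare_systems,
                      find_process_hotspots, make_case_fixture,
                      run_framework, screen_nanoform)
from nanossbd.fixtures import CaseParams


def control_form():
    """A benign control: large, spherical, soluble, fully characterized."""
    return NanoForm("control", "ZnO-like", particle_size_nm=100.0,
                    surface_area_m2_g=10.0, aspect_ratio=1.0,
                    solubility_class="soluble", persistence="non_persistent",
                    reactivity="low", agglomeration="non_agglomerating")


class TestScreenNanoform:
    def test_small_size_flag_with_action_text(self, case_fixture):
        form = case_fixture.original.nanoforms["cu2o_p25"]
        report = screen_nanoform(form)
        size_flags = [f for f in report.flags if f.parameter == "size"]
        assert len(size_flags) == 1
        assert size_flags[0].triggering_value == 20.0
        assert size_flags[0].action == (
            "Alter design to avoid NMs below this threshold")

    def test_benign_control_raises_no_flags(self):
        report = screen_nanoform(control_form())
        assert report.flags == []

    def test_harn_flag(self):
        form = NanoForm("fibre", "CNT-like", particle_size_nm=100.0,
                        surface_area_m2_g=10.0, aspect_ratio=6.0,
                        solubility_class="soluble",
                        persistence="non_persistent", reactivity="low",
                        agglomeration="non_agglomerating")
        report = screen_nanoform(form)
        assert [f.parameter for f in report.flags] == ["shape"]

    def test_fibrous_non_soluble_combination(self):
        form = NanoForm("fibre", "CNT-like", particle_size_nm=100.0,
                        surface_area_m2_g=10.0, aspect_ratio=6.0,
                        solubility_class="non_soluble",
                        persistence="non_persistent", reactivity="low",
                        agglomeration="non_agglomerating")
        params = {f.parameter for f in screen_nanoform(form).flags}
        assert params == {"shape", "solubility"}

    def test_unknown_attribute_gives_information_gap(self):
        form = NanoForm("partial", "TiO2", particle_size_nm=100.0,
                        surface_area_m2_g=10.0, aspect_ratio=1.0,
                        solubility_class="soluble",
                        persistence="unknown", reactivity="low",
                        agglomeration="non_agglomerating")
        report = screen_nanoform(form)
        assert [f.flag_type for f in report.flags] == ["information_gap"]
        assert "needs characterization" in report.flags[0].action

    def test_unstable_coating_flagged_only_for_coated_forms(self):
        coated = NanoForm("c", "TiO2", coating="Cu2O", particle_size_nm=100.0,
                          surface_area_m2_g=10.0, aspect_ratio=1.0,
                          solubility_class="soluble",
                          coating_stability="unstable",
                          persistence="non_persistent", reactivity="low",
                          agglomeration="non_agglomerating")
        assert [f.parameter for f in screen_nanoform(coated).flags] == (
            ["coating_stability"])
        # the same stability value on an uncoated form is not applicable
        uncoated = NanoForm("u", "TiO2", particle_size_nm=100.0,
                            surface_area_m2_g=10.0, aspect_ratio=1.0,
                            solubility_class="soluble",
                            coating_stability="unstable",
                            persistence="non_persistent", reactivity="low",
                            agglomeration="non_agglomerating")
        assert screen_nanoform(uncoated).flags == []

    def test_high_release_rate_flag(self):
        release = ReleaseModel("nm_manufacture", "control",
                               {"air": 0.004, "sewer": 0.025})
        report = screen_nanoform(control_form(), release)
        assert [f.parameter for f in report.flags] == ["release_rate"]
        quiet = ReleaseModel("use", "control", {"air": 0.001})
        assert screen_nanoform(control_form(), quiet).flags == []

    def test_shrinking_size_only_adds_the_size_flag(self):
        big = screen_nanoform(control_form())
        small = screen_nanoform(NanoForm(
            "small", "ZnO-like", particle_size_nm=20.0,
            surface_area_m2_g=10.0, aspect_ratio=1.0,
            solubility_class="soluble", persistence="non_persistent",
            reactivity="low", agglomeration="non_agglomerating"))
        big_params = {f.parameter for f in big.flags}
        small_params = {f.parameter for f in small.flags}
        assert small_params - big_params == {"size"}
        assert big_params <= small_params


def results_with_contributions(contribs, indicator="HTP", basis="nano"):
    total = sum(contribs.values())
    return [ImpactResult(indicator, basis, total, "cases·d", dict(contribs))]


class TestProcessHotspots:
    def test_dominant_process_flagged(self):
        report = find_process_hotspots(
            results_with_contributions({"P1": 0.9, "P2": 0.1}))
        assert report.dominant["HTP/nano"] == "P1"
        ranked = report.process_hotspots["HTP/nano"]
        assert ranked[0] == ("P1", 0.9, pytest.approx(0.9))

    def test_uniform_contributions_no_dominance(self):
        report = find_process_hotspots(
            results_with_contributions({f"P{i}": 0.25 for i in range(4)}))
        assert report.dominant["HTP/nano"] is None

    def test_single_process_trivially_dominant(self):
        report = find_process_hotspots(
            results_with_contributions({"only": 1.0}))
        assert report.dominant["HTP/nano"] == "only"

    def test_ranking_stable_under_input_permutation(self):
        a = find_process_hotspots(results_with_contributions(
            {"B": 0.2, "A": 0.2, "C": 0.6}))
        b = find_process_hotspots(results_with_contributions(
            {"C": 0.6, "A": 0.2, "B": 0.2}))
        assert a.process_hotspots == b.process_hotspots
        # ties broken by process id
        assert [p for p, _, _ in a.process_hotspots["HTP/nano"]] == (
            ["C", "A", "B"])


def impact(indicator, total, unit, basis="bulk"):
    return ImpactResult(indicator, basis, total, unit, {"total": total})


class TestCompareSystems:
    def test_trade_off_detected(self):
        reference = [impact("GWP", 18.17, "kg CO2-eq"),
                     impact("FEP", 15.08, "PAF·m3·d", "nano")]
        original = [impact("GWP", 9.28, "kg CO2-eq"),
                    impact("FEP", 16.26, "PAF·m3·d", "nano")]
        report = compare_systems(reference, original)
        assert report.row("GWP").verdict == "better"
        assert report.row("FEP").verdict == "worse"
        assert report.trade_off_flag
        assert report.overall == "mixed"

    def test_identical_results_no_trade_off(self):
        results = [impact("GWP", 1.0, "kg CO2-eq")]
        report = compare_systems(results, results)
        assert report.rows[0].verdict == "equal"
        assert not report.trade_off_flag
        assert report.overall == "equal"

    def test_dominating_original_overall_better(self):
        reference = [impact("GWP", 2.0, "kg CO2-eq"),
                     impact("CED", 10.0, "MJ"),
                     impact("HTP", 1.0, "cases·d"),
                     impact("FEP", 5.0, "PAF·m3·d")]
        original = [impact("GWP", 1.0, "kg CO2-eq"),
                    impact("CED", 5.0, "MJ"),
                    impact("HTP", 0.5, "cases·d"),
                    impact("FEP", 2.0, "PAF·m3·d")]
        report = compare_systems(reference, original)
        assert not report.trade_off_flag
        assert report.overall == "better"

    def test_antisymmetry_under_swap(self):
        reference = [impact("GWP", 18.17, "kg CO2-eq"),
                     impact("FEP", 15.08, "PAF·m3·d")]
        original = [impact("GWP", 9.28, "kg CO2-eq"),
                    impact("FEP", 16.26, "PAF·m3·d")]
        fwd = compare_systems(reference, original)
        rev = compare_systems(original, reference)
        flip = {"better": "worse", "worse": "better", "equal": "equal"}
        for r_fwd, r_rev in zip(fwd.rows, rev.rows):
            assert r_rev.verdict == flip[r_fwd.verdict]
        assert fwd.trade_off_flag == rev.trade_off_flag

    def test_zero_reference_relative_delta_undefined(self):
        report = compare_systems([impact("GWP", 0.0, "kg CO2-eq")],
                                 [impact("GWP", 1.0, "kg CO2-eq")])
        assert report.rows[0].relative_delta is None

    def test_unit_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="unit mismatch"):
            compare_systems([impact("GWP", 1.0, "kg CO2-eq")],
                            [impact("GWP", 1.0, "t CO2-eq")])


class TestHeatmaps:
    def test_case_fixture_cells(self, case_fixture):
        result = run_framework(case_fixture.original.profile)
        lci, cf = build_heatmap(result.plan,
                                [case_fixture.reference.system,
                                 case_fixture.original.system],
                                case_fixture.original.registry)
        assert cf.cells.loc["cu2o_p25", "FEP"] == DataTier.read_across
        assert cf.cells.loc["cu2o_p25", "HTP"] == DataTier.literature
        assert cf.cells.loc["p25_tio2", "FEP"] == DataTier.literature
        assert (lci.cells.loc["nano_coating"] ==
                DataTier.measured_lab).all()

    def test_cell_count_is_rows_times_columns(self, case_fixture):
        result = run_framework(case_fixture.original.profile)
        lci, cf = build_heatmap(result.plan,
                                [case_fixture.reference.system,
                                 case_fixture.original.system],
                                case_fixture.original.registry)
        assert lci.n_cells == len(lci.cells.index) * len(lci.cells.columns)
        assert cf.n_cells == len(cf.cells.index) * len(cf.cells.columns)
        n_processes = len(set(case_fixture.reference.system.processes)
                          | set(case_fixture.original.system.processes))
        assert lci.n_cells == n_processes * 4
        assert cf.n_cells == 2 * 2

    def test_all_measured_profile_uniform_lowest_uncertainty(self):
        from test_framework_engine import full_industrial_profile
        from nanossbd import Exchange, Flow, Process, ProductSystem
        from nanossbd import CharacterizationRegistry, CharFactorSet
        system = ProductSystem(
            [Flow("p", "p", "product")],
            [Process("proc", "proc", "p", (Exchange("p", 1.0, "output"),),
                     data_tier="measured_industrial")],
            {"p": 1.0})
        registry = CharacterizationRegistry(
            [CharFactorSet("nf", "freshwater", ind, cf=1.0,
                           source_tier=DataTier.measured_industrial)
             for ind in ("FEP", "HTP")])
        plan = run_framework(full_industrial_profile()).plan
        lci, cf = build_heatmap(plan, [system], registry)
        assert (lci.cells == DataTier.measured_industrial).all().all()
        assert (cf.cells == DataTier.measured_industrial).all().all()

    def test_one_defaulted_xf_adds_one_precautionary_cell(self):
        # identical registries except one drops the exposure factor: the CF
        # resolves through the precautionary default and exactly one heat-map
        # cell changes tier
        from nanossbd import (CharacterizationRegistry, CharFactorSet,
                              Exchange, Flow, Process, ProductSystem)
        system = ProductSystem(
            [Flow("p", "p", "product")],
            [Process("proc", "proc", "p", (Exchange("p", 1.0, "output"),),
                     data_tier="measured_lab")],
            {"p": 1.0})
        plan = {"cf:nf": DataTier.literature}

        def reg(with_xf):
            return CharacterizationRegistry([
                CharFactorSet("nf", "freshwater", "FEP", ff_days=2.0,
                              xf=0.5 if with_xf else None, ef=10.0,
                              source_tier=DataTier.literature),
                CharFactorSet("nf", "freshwater", "HTP", cf=1.0,
                              source_tier=DataTier.literature)])

        _, cf_with = build_heatmap(plan, [system], reg(True))
        _, cf_without = build_heatmap(plan, [system], reg(False))
        diff = (cf_with.cells != cf_without.cells).to_numpy().sum()
        assert diff == 1
        assert cf_without.cells.loc["nf", "FEP"] == (
            DataTier.default_precautionary)

    def test_uncovered_cf_source_listed(self, case_fixture):
        plan = {"cf:mystery_form": None}
        with pytest.raises(ValidationError, match="mystery_form"):
            build_heatmap(plan, [case_fixture.reference.system],
                          case_fixture.original.registry)
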