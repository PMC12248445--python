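"""Annotation, class-percentage profiles, aggregation and group comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lipidmsi as lm
from lipidmsi.lipid_db import LipidClass
from lipidmsi import msi_io
from lipidmsi import profiles_stats as ps
from lipidmsi import synthetic_data as sd


# -- annotation --------------------------------------------------------------


def _matrix_with_mz(mzs):
    vals = np.ones((1, len(mzs)))
    return msi_io.FeatureMatrix(np.asarray(mzs, dtype=float), vals, [(0, 0)], (16, 16))


def test_annotation_ppm_worked_examples(panel):
    matrix = _matrix_with_mz([885.5512, 885.6600])
    ann = ps.annotate_features(matrix, panel)
    good, bad = ann.matches
    assert good.accepted and good.species_name == "PI 38:4"
    assert good.ppm_error == pytest.approx(
        (885.5512 - 885.5499) / 885.5499 * 1e6, abs=0.2)
    assert not bad.accepted


def test_annotation_rejects_beyond_nine_ppm(panel):
    pi384 = next(e.mz for e in panel if e.species.name == "PI 38:4")
    matrix = _matrix_with_mz([pi384 * (1 + 11.4e-6)])
    ann = ps.annotate_features(matrix, panel)
    assert not ann.matches[0].accepted
    matrix = _matrix_with_mz([pi384 * (1 + 8.5e-6)])
    assert ps.annotate_features(matrix, panel).matches[0].accepted


def test_plasmalogen_isobar_recorded_in_ledger(panel):
    pep386 = next(e.mz for e in panel if e.species.name == "PE P 38:6")
    ann = ps.annotate_features(_matrix_with_mz([pep386]), panel)
    assert ann.matches[0].species_name == "PE P 38:6"
    assert ann.isobar_ledger == [(0, "PE P 38:6", "PE O 38:7")]


def test_default_simulation_annotations_within_nine_ppm(control_matrix,
                                                        control_annotations):
    accepted = control_annotations.accepted
    assert accepted
    assert max(abs(m.ppm_error) for m in accepted) < 9.0


# -- class percentages -------------------------------------------------------


def test_class_percentages_single_species_is_100(panel):
    pe384 = next(e.mz for e in panel if e.species.name == "PE 38:4")
    matrix = _matrix_with_mz([pe384])
    ann = ps.annotate_features(matrix, panel)
    prof = ps.class_percentages(matrix, ann, [0])
    assert prof.pct(LipidClass.PE, "38:4") == 100.0


def test_class_percentages_simple_arithmetic(panel):
    pe384 = next(e.mz for e in panel if e.species.name == "PE 38:4")
    pe361 = next(e.mz for e in panel if e.species.name == "PE 36:1")
    matrix = msi_io.FeatureMatrix(np.sort([pe384, pe361]),
                                  np.array([[70.0, 30.0]]), [(0, 0)], (16, 16))
    ann = ps.annotate_features(matrix, panel)
    prof = ps.class_percentages(matrix, ann, [0])
    assert prof.pct(LipidClass.PE, "36:1") == pytest.approx(70.0)
    assert prof.pct(LipidClass.PE, "38:4") == pytest.approx(30.0)


def test_class_percentages_scale_invariance(control_matrix, control_annotations,
                                            tissue_labels_for):
    subset = tissue_labels_for == 1
    a = ps.class_percentages(control_matrix, control_annotations, subset)
    scaled = msi_io.FeatureMatrix(
        control_matrix.mz_axis, control_matrix.dense_values() * 5.0,
        list(control_matrix.pixel_index), control_matrix.grid_shape)
    b = ps.class_percentages(scaled, control_annotations, subset)
    for cls in a.percentages:
        for key, v in a.percentages[cls].items():
            assert b.percentages[cls][key] == pytest.approx(v)


def test_class_percentages_sum_to_100(control_matrix, control_annotations,
                                      tissue_labels_for):
    prof = ps.class_percentages(control_matrix, control_annotations,
                                tissue_labels_for == 2)
    for cls, spp in prof.percentages.items():
        assert sum(spp.values()) == pytest.approx(100.0, abs=1e-6)


def test_empty_subset_rejected(control_matrix, control_annotations):
    with pytest.raises(ValueError):
        ps.class_percentages(control_matrix, control_annotations, [])


def test_zero_noise_tumor_epithelium_exact(panel):
    """Full chain on noiseless data returns the generator profile exactly."""
    grid = np.ones((16, 16), dtype=int)
    phantom = lm.make_phantom(16, 16, "from_mask", grid)
    epi = lm.default_group_profiles("tumor")["epithelium"]
    cube, _ = lm.simulate_section(
        phantom, {r: epi for r in sd.REGION_LABELS.values()},
        sd.AcquisitionParams.zero_noise(), seed=0)
    from lipidmsi import preprocess as pp

    matrix = pp.run_preprocessing(cube, threshold_fraction=0.0)
    ann = ps.annotate_features(matrix, panel)
    prof = ps.class_percentages(matrix, ann, np.arange(matrix.n_pixels))
    for cls, spp in epi.percentages.items():
        for key, v in spp.items():
            assert prof.pct(cls, key) == pytest.approx(v, abs=1e-9)


def test_intensity_weighted_equals_per_pixel_mean_on_zero_noise(panel):
    """Summing intensities over pixels equals averaging per-pixel percentages
    when there is no pixel-to-pixel variation."""
    grid = np.ones((16, 16), dtype=int)
    phantom = lm.make_phantom(16, 16, "from_mask", grid)
    epi = lm.default_group_profiles("control")["epithelium"]
    cube, _ = lm.simulate_section(
        phantom, {r: epi for r in sd.REGION_LABELS.values()},
        sd.AcquisitionParams.zero_noise(), seed=0)
    from lipidmsi import preprocess as pp

    matrix = pp.run_preprocessing(cube, threshold_fraction=0.0)
    ann = ps.annotate_features(matrix, panel)
    pooled = ps.class_percentages(matrix, ann, np.arange(matrix.n_pixels))
    per_pixel = [ps.class_percentages(matrix, ann, [i]) for i in range(3)]
    for cls, spp in pooled.percentages.items():
        for key, v in spp.items():
            assert np.mean([p.pct(cls, key) for p in per_pixel]) == pytest.approx(v)


# -- aggregation and percent change ------------------------------------------


def _profile(label, pct):
    return ps.ClassProfile(label, {LipidClass.PI: pct}, n_pixels=10)


def test_aggregate_mean_and_sem():
    profiles = [_profile(f"s{i}", {"38:4": v}) for i, v in enumerate((10.0, 20.0, 30.0))]
    agg = ps.aggregate_group(profiles)
    mean, sem = agg[(LipidClass.PI, "38:4")]
    assert mean == pytest.approx(20.0)
    assert sem == pytest.approx(10.0 / np.sqrt(3))


def test_aggregate_single_section_sem_missing():
    agg = ps.aggregate_group([_profile("s0", {"38:4": 41.5})])
    mean, sem = agg[(LipidClass.PI, "38:4")]
    assert mean == 41.5 and sem is None


def test_aggregate_identical_sections_sem_zero():
    agg = ps.aggregate_group([_profile(f"s{i}", {"38:4": 7.0}) for i in range(4)])
    assert agg[(LipidClass.PI, "38:4")][1] == 0.0


def test_percent_change_worked_examples():
    assert ps.percent_change(70.7, 58.5) == -17.3
    assert ps.percent_change(18.8, 16.1) == -14.4
    assert ps.percent_change(5.0, 5.0) == 0.0
    with pytest.raises(ValueError):
        ps.percent_change(0.0, 5.0)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(a=st.floats(1.0, 99.0), b=st.floats(1.0, 99.0))
def test_percent_change_reciprocal_property(a, b):
    dab = (b - a) / a * 100.0
    dba = (a - b) / b * 100.0
    assert (1 + dab / 100.0) * (1 + dba / 100.0) == pytest.approx(1.0)
    # rounded public form stays within rounding error of the identity
    assert abs(ps.percent_change(a, b) - dab) <= 0.05 + 1e-9


# -- group comparisons -------------------------------------------------------


def test_identical_groups_t_zero_p_one():
    ga = [_profile(f"a{i}", {"38:4": v}) for i, v in enumerate((1.0, 2.0, 3.0))]
    gb = [_profile(f"b{i}", {"38:4": v}) for i, v in enumerate((1.0, 2.0, 3.0))]
    (comp,) = ps.compare_groups(ga, gb)
    assert comp.t_statistic == pytest.approx(0.0)
    assert comp.p_value == pytest.approx(1.0)
    assert comp.stars == "ns"


def test_degenerate_equal_groups():
    ga = [_profile(f"a{i}", {"38:4": 10.0}) for i in range(3)]
    gb = [_profile(f"b{i}", {"38:4": 10.0}) for i in range(3)]
    (comp,) = ps.compare_groups(ga, gb)
    assert comp.t_statistic == 0.0 and comp.p_value == 1.0


def test_strongly_separated_groups_three_stars():
    rng = np.random.default_rng(0)
    ga = [_profile(f"a{i}", {"38:4": 10.0 + rng.normal(0, 0.01)}) for i in range(4)]
    gb = [_profile(f"b{i}", {"38:4": 20.0 + rng.normal(0, 0.01)}) for i in range(4)]
    (comp,) = ps.compare_groups(ga, gb)
    assert comp.p_value <= 0.001
    assert comp.stars == "***"
    assert comp.percent_change == pytest.approx(100.0, abs=1.0)


def test_stars_thresholds():
    assert ps.stars_for(0.04) == "*"
    assert ps.stars_for(0.009) == "**"
    assert ps.stars_for(0.0009) == "***"
    assert ps.stars_for(0.2) == "ns"


def test_welch_and_fdr_options():
    rng = np.random.default_rng(1)
    ga = [_profile(f"a{i}", {"38:4": 10 + rng.normal(0, 1), "36:2": 5 + rng.normal(0, 1)})
          for i in range(5)]
    gb = [_profile(f"b{i}", {"38:4": 14 + rng.normal(0, 3), "36:2": 5 + rng.normal(0, 1)})
          for i in range(5)]
    pooled = ps.compare_groups(ga, gb)
    welch = ps.compare_groups(ga, gb, welch=True)
    assert pooled[0].p_value != welch[0].p_value
    with_fdr = ps.compare_groups(ga, gb, fdr=True)
    assert all(c.p_adjusted is not None and c.p_adjusted >= c.p_value - 1e-12
               for c in with_fdr)


def test_tumor_vs_non_tumor_sections_flag_aa_species():
    """Across many cohort draws at default between-subject dispersion, the
    arachidonic-acid carriers come out significant and increased."""
    hits_pi = hits_pe = 0
    n_seeds = 20
    for seed in range(n_seeds):
        rng = np.random.default_rng(1000 + seed)
        ga, gb = [], []
        for i in range(5):
            nt = lm.draw_section_profiles(
                lm.default_group_profiles("non_tumor"), 0.06, rng)["epithelium"]
            tu = lm.draw_section_profiles(
                lm.default_group_profiles("tumor"), 0.06, rng)["epithelium"]
            ga.append(ps.ClassProfile(f"nt{i}", nt.percentages, 100))
            gb.append(ps.ClassProfile(f"t{i}", tu.percentages, 100))
        comps = {c.species: c for c in ps.compare_groups(ga, gb, "non_tumor", "tumor")}
        pi, pe = comps["PI 38:4"], comps["PE 38:4"]
        hits_pi += pi.p_value <= 0.05 and pi.percent_change > 0
        hits_pe += pe.p_value <= 0.05 and pe.percent_change > 0
    assert hits_pi >= 0.9 * n_seeds
    assert hits_pe >= 0.9 * n_seeds


def test_comparisons_tsv_export(tmp_path):
    ga = [_profile(f"a{i}", {"38:4": v}) for i, v in enumerate((10.0, 12.0, 11.0))]
    gb = [_profile(f"b{i}", {"38:4": v}) for i, v in enumerate((20.0, 22.0, 21.0))]
    comps = ps.compare_groups(ga, gb, "A", "B")
    path = tmp_path / "cmp.tsv"
    ps.comparisons_to_tsv(comps, path)
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    assert df.loc[0, "species"] == "PI 38:4"
    assert df.loc[0, "stars"] == "***"
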