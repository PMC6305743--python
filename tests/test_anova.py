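"""Variance components: one-way random ANOVA, eta_o, ICC, design effect,
and the balanced two-way patient x treatment partition."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cfdeff import (
    ArgumentError,
    AssayRecord,
    DegenerateDataError,
    GroupedSample,
    design_effect,
    effective_group_size,
    estimate_icc_pipeline,
    icc_from_anova,
    one_way_random_anova,
    two_way_mixed_anova,
)


def naive_anova(groups):
    """Independent double-loop sums-of-squares oracle."""
    all_vals = [v for g in groups for v in g]
    grand = sum(all_vals) / len(all_vals)
    ss_b = 0.0
    ss_w = 0.0
    for g in groups:
        mean_g = sum(g) / len(g)
        ss_b += len(g) * (mean_g - grand) ** 2
        for v in g:
            ss_w += (v - mean_g) ** 2
    k, n = len(groups), len(all_vals)
    ms_w = ss_w / (n - k)
    f = (ss_b / (k - 1)) / ms_w if ms_w > 0 else float("inf")
    return ss_b, ss_w, f


def test_one_way_hand_example():
    res = one_way_random_anova(GroupedSample({"a": [1, 2, 3], "b": [4, 5, 6]}))
    assert res.ms_between == pytest.approx(13.5)
    assert res.ms_within == pytest.approx(1.0)
    assert res.f == pytest.approx(13.5)
    assert res.ss_total == pytest.approx(res.ss_between + res.ss_within)


def test_one_way_identical_groups():
    res = one_way_random_anova(GroupedSample({"a": [1, 2, 3], "b": [1, 2, 3]}))
    assert res.ss_between == pytest.approx(0.0)
    assert res.f == pytest.approx(0.0)


def test_one_way_constant_data_flagged_degenerate():
    res = one_way_random_anova(GroupedSample({"a": [2.0], "b": [2.0], "c": [2.0, 2.0]}))
    assert res.ss_total == 0.0
    assert res.ms_within == 0.0
    assert res.degenerate


def test_one_way_preconditions():
    with pytest.raises(ArgumentError):
        one_way_random_anova(GroupedSample({"a": [1.0, 2.0]}))
    with pytest.raises(DegenerateDataError, match="singleton"):
        one_way_random_anova(GroupedSample({"a": [1.0], "b": [2.0]}))


def test_singleton_groups_allowed_alongside_larger():
    sample = GroupedSample({"a": [1.0], "b": [2.0, 4.0], "c": [3.0]})
    res = one_way_random_anova(sample)
    assert res.df_within == 1
    assert math.isfinite(res.f)


@given(
    st.lists(
        st.lists(st.floats(-10, 10), min_size=1, max_size=12),
        min_size=2,
        max_size=10,
    ).filter(lambda gs: sum(len(g) for g in gs) > len(gs))
)
def test_one_way_matches_double_loop_oracle(groups):
    sample = GroupedSample({f"g{i}": g for i, g in enumerate(groups)})
    res = one_way_random_anova(sample)
    ss_b, ss_w, f = naive_anova(groups)
    assert res.ss_between == pytest.approx(ss_b, rel=1e-9, abs=1e-9)
    assert res.ss_within == pytest.approx(ss_w, rel=1e-9, abs=1e-9)
    if res.ms_within > 1e-12:
        assert res.f == pytest.approx(f, rel=1e-9)


def test_eta_o_examples():
    assert effective_group_size([3, 3, 3]) == pytest.approx(3.0)
    assert effective_group_size([2, 4]) == pytest.approx(2.6667, abs=5e-5)
    with pytest.raises(ArgumentError):
        effective_group_size([5])
    with pytest.raises(ArgumentError):
        effective_group_size([3, 0])


@given(n=st.integers(1, 20), k=st.integers(2, 20))
def test_eta_o_balanced_identity(n, k):
    assert effective_group_size([n] * k) == pytest.approx(n, rel=1e-12)


def _anova_from_ms(ms_b, ms_w, df_b=4, df_w=20):
    from cfdeff.anova import AnovaOneWay

    return AnovaOneWay(
        ss_between=ms_b * df_b,
        ss_within=ms_w * df_w,
        df_between=df_b,
        df_within=df_w,
        f=ms_b / ms_w if ms_w > 0 else math.inf,
        p=0.5,
    )


def test_icc_equal_mean_squares_gives_zero():
    icc = icc_from_anova(_anova_from_ms(2.0, 2.0), eta_o=7.0)
    assert icc.rho == pytest.approx(0.0)
    assert icc.design_effect == pytest.approx(1.0)


def test_icc_perfect_consistency():
    icc = icc_from_anova(_anova_from_ms(3.0, 0.0), eta_o=5.0)
    assert icc.rho == pytest.approx(1.0)
    assert icc.design_effect == pytest.approx(5.0)


def test_icc_substitution_example():
    icc = icc_from_anova(_anova_from_ms(3.0, 1.0), eta_o=5.0)
    assert icc.rho == pytest.approx(2.0 / 7.0)


def test_icc_negative_truncation_policy():
    anova = _anova_from_ms(0.5, 1.0)
    trunc = icc_from_anova(anova, eta_o=4.0, truncate=True)
    raw = icc_from_anova(anova, eta_o=4.0, truncate=False)
    assert trunc.rho < 0
    assert trunc.rho_truncated == 0.0
    assert trunc.design_effect == pytest.approx(1.0)
    assert raw.design_effect < 1.0
    assert raw.design_effect == pytest.approx(design_effect(raw.rho, 4.0))


def test_icc_degenerate_and_precondition_errors():
    with pytest.raises(DegenerateDataError):
        icc_from_anova(_anova_from_ms(0.0, 0.0), eta_o=3.0)
    with pytest.raises(ArgumentError):
        icc_from_anova(_anova_from_ms(3.0, 1.0), eta_o=1.0)


def test_design_effect_reference_values():
    assert design_effect(0.377, 5.86) == pytest.approx(2.83, abs=5e-3)
    assert design_effect(0.2816, 4.34) == pytest.approx(1.94, abs=5e-3)
    assert design_effect(0.0, 9.0) == 1.0


@given(
    rho=st.floats(0.0, 1.0),
    eta=st.floats(1.0, 20.0),
)
def test_design_effect_range(rho, eta):
    deff = design_effect(rho, eta)
    assert 1.0 - 1e-12 <= deff <= eta + 1e-12


@given(
    rho1=st.floats(0.0, 0.99),
    drho=st.floats(0.001, 0.5),
    eta=st.floats(1.5, 20.0),
)
def test_design_effect_monotone_in_rho(rho1, drho, eta):
    assert design_effect(min(rho1 + drho, 1.0), eta) > design_effect(rho1, eta)


@given(
    rho=st.floats(0.01, 1.0),
    eta1=st.floats(1.0, 19.0),
    deta=st.floats(0.1, 5.0),
)
def test_design_effect_monotone_in_eta(rho, eta1, deta):
    assert design_effect(rho, eta1 + deta) > design_effect(rho, eta1)


def test_pipeline_rejects_mixed_treatments(grouped_sim_records):
    with pytest.raises(ArgumentError, match="multiple treatments"):
        GroupedSample.from_records(grouped_sim_records)


def test_pipeline_null_clustering_near_zero():
    from cfdeff import SimulationConfig, simulate_grouped_assay

    rhos = []
    for seed in range(200):
        cfg = SimulationConfig(group_sd=0.0, within_sd=1.0, seed=seed)
        records = simulate_grouped_assay(cfg)
        rhos.append(estimate_icc_pipeline(records, "corrector").icc.rho)
    assert abs(float(np.mean(rhos))) <= 0.05


def test_pipeline_report_structure(grouped_sim_records):
    report = estimate_icc_pipeline(grouped_sim_records, "corrector")
    assert report.k == 23
    assert report.n_total == sum(report.group_sizes)
    d = report.to_dict()
    assert d["icc"]["design_effect"] == pytest.approx(
        design_effect(d["icc"]["rho_truncated"], d["icc"]["eta_o"])
    )


def test_two_way_worked_example(two_by_two_records):
    part = two_way_mixed_anova(two_by_two_records)
    assert part.percent_treatment == pytest.approx(81.82, abs=5e-3)
    assert part.percent_patient == pytest.approx(9.09, abs=5e-3)
    assert part.percent_interaction == pytest.approx(9.09, abs=5e-3)
    assert part.percent_residual == pytest.approx(0.0)
    total = (
        part.percent_treatment
        + part.percent_patient
        + part.percent_interaction
        + part.percent_residual
    )
    assert total == pytest.approx(100.0, abs=1e-6)


def test_two_way_all_equal_is_degenerate():
    records = [
        AssayRecord(p, "a", t, f"r{i}", 2.0)
        for p in ("P1", "P2")
        for t in ("vehicle", "corrector")
        for i in range(2)
    ]
    part = two_way_mixed_anova(records)
    assert part.degenerate
    assert part.percent_treatment == 0.0


def test_two_way_additive_no_noise_has_zero_interaction():
    # y = patient effect + treatment effect exactly -> interaction SS = 0
    patient_fx = {"P1": 0.0, "P2": 1.0, "P3": -0.5}
    treat_fx = {"vehicle": 0.0, "corrector": 3.0}
    records = []
    for p, pe in patient_fx.items():
        for t, te in treat_fx.items():
            for i in range(2):
                records.append(AssayRecord(p, "a", t, f"r{i}", 1.0 + pe + te))
    part = two_way_mixed_anova(records)
    assert part.percent_interaction == pytest.approx(0.0, abs=1e-9)


def test_two_way_unbalanced_is_error(two_by_two_records):
    with pytest.raises(ArgumentError, match="unbalanced"):
        two_way_mixed_anova(two_by_two_records[:-1])
    missing_cell = [r for r in two_by_two_records if not (
        r.patient_id == "P2" and r.treatment == "corrector")]
    with pytest.raises(ArgumentError, match="unbalanced"):
        two_way_mixed_anova(missing_cell)
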