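"""Reference averaging, the two exclusion gates, delta-Ct arithmetic, and
the variance filter."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ctcpredict.datatypes import (
    ExpressionMatrix,
    PipelineError,
    ROLE_EPITHELIAL,
    ROLE_REFERENCE,
    ROLE_TARGET,
)
from ctcpredict import SimulationConfig, generate_cohort
from ctcpredict.qc import (
    apply_qc,
    delta_ct_normalize,
    epithelial_quality_gate,
    mean_reference_ct,
    reference_detected_count,
    reference_quality_gate,
    variance_filter,
)
from conftest import make_ct

ROLES3 = {"HMBS": ROLE_REFERENCE, "HPRT1": ROLE_REFERENCE, "GUSB": ROLE_REFERENCE}


def ref_only(values):
    genes = ["HMBS", "HPRT1", "GUSB"]
    return make_ct(
        {g: [v] for g, v in zip(genes, values)} | {"T1": [30.0]},
        ROLES3 | {"T1": ROLE_TARGET},
    )


@pytest.mark.parametrize(
    "refs, expected_mean, expected_detected",
    [
        ((20.0, 22.0, 24.0), 22.0, 3),
        ((26.0, 26.0, 26.0), 26.0, 3),
        ((20.0, np.nan, 24.0), 22.0, 2),
    ],
)
def test_mean_reference_ct(refs, expected_mean, expected_detected):
    ct = ref_only(refs)
    assert mean_reference_ct(ct, "P1") == pytest.approx(expected_mean)
    assert reference_detected_count(ct)["P1"] == expected_detected


def test_no_detected_reference_is_unevaluable_and_fails_gate():
    ct = ref_only((np.nan, np.nan, np.nan))
    assert math.isnan(mean_reference_ct(ct, "P1"))
    assert not reference_quality_gate(ct)["P1"]


@pytest.mark.parametrize(
    "mean_ct, passes", [(25.9, True), (26.0, True), (26.1, False)]
)
def test_reference_gate_threshold(mean_ct, passes):
    ct = ref_only((mean_ct,) * 3)
    assert reference_quality_gate(ct, cutoff=26.0)["P1"] == passes


@given(st.floats(min_value=15, max_value=35), st.floats(min_value=0, max_value=10))
def test_reference_gate_monotone_in_cutoff(mean_ct, drop):
    """Lowering the cutoff never converts a fail into a pass."""
    ct = ref_only((mean_ct,) * 3)
    high = reference_quality_gate(ct, cutoff=26.0)["P1"]
    low = reference_quality_gate(ct, cutoff=26.0 - drop)["P1"]
    assert not (low and not high)


def test_epithelial_gate(tiny_ct):
    # P1: both epithelial genes detected near the reference mean -> pass;
    # P2/P3: all epithelial undetected -> fail
    gate = epithelial_quality_gate(tiny_ct, min_detected=1, min_delta_ct=-15.0)
    assert bool(gate["P1"]) and not gate["P2"] and not gate["P3"]
    # a stricter expression threshold can fail the detected sample too
    strict = epithelial_quality_gate(tiny_ct, min_detected=1, min_delta_ct=0.0)
    assert not strict["P1"]


def test_gate_accounting_is_disjoint_and_ordered(tiny_ct):
    retained, report = apply_qc(tiny_ct, reference_cutoff=26.0)
    ref_ex = set(report.excluded_reference)
    epi_ex = set(report.excluded_epithelial)
    kept = set(report.retained)
    assert ref_ex | epi_ex | kept == set(tiny_ct.samples)
    assert not (ref_ex & epi_ex) and not (ref_ex & kept) and not (epi_ex & kept)
    # P3 (ref mean 27) fails the reference gate and must NOT be re-counted
    # by the epithelial gate
    assert "P3" in ref_ex and "P3" not in epi_ex
    assert retained.samples == report.retained


def test_cohort_tuned_to_study_accounting():
    """78 samples built so 5 fail the reference gate and 28 the epithelial
    gate leave 45 for analysis."""
    cohort = generate_cohort(SimulationConfig(n_samples=78, seed=2))
    ct = cohort.ct.ct.copy()
    refs = cohort.ct.reference_genes
    epis = cohort.ct.epithelial_genes
    samples = list(ct.columns)
    ct.loc[refs, samples[:5]] = 28.0  # late reference amplification
    ct.loc[refs, samples[5:]] = 22.0
    ct.loc[epis, samples[5:33]] = np.nan  # no epithelial signal
    ct.loc[epis, samples[33:]] = 30.0
    from ctcpredict.datatypes import CtMatrix

    _, report = apply_qc(CtMatrix(ct, cohort.ct.gene_roles))
    assert report.counts == {
        "n_initial": 78,
        "n_excluded_reference_gate": 5,
        "n_after_reference_gate": 73,
        "n_excluded_epithelial_gate": 28,
        "n_retained": 45,
    }


def test_delta_ct_definition(tiny_ct):
    expr = delta_ct_normalize(tiny_ct)
    # P1: ref mean 22; T1 Ct 25 -> delta -3; T2 Ct 22 -> delta 0
    assert expr.delta_ct.loc["T1", "P1"] == pytest.approx(-3.0)
    assert expr.delta_ct.loc["T2", "P1"] == pytest.approx(0.0)
    # undetected target imputed at 40 cycles
    assert expr.delta_ct.loc["T3", "P1"] == pytest.approx(22.0 - 40.0)
    # reference genes dropped from the output
    assert set(expr.genes) == {"EPI1", "EPI2", "T1", "T2", "T3"}


def test_full_panel_drops_references_96_to_93():
    cohort = generate_cohort(SimulationConfig(seed=1))
    retained, _ = apply_qc(cohort.ct)
    expr = delta_ct_normalize(retained)
    assert expr.n_genes == 93


def test_delta_ct_empty_sample_set_halts(tiny_ct):
    empty = tiny_ct.subset_samples([])
    with pytest.raises(PipelineError):
        delta_ct_normalize(empty)


@given(st.floats(min_value=-5, max_value=5))
def test_shift_equivariance(c):
    """Adding a constant to every Ct of a sample leaves its delta-Ct fixed."""
    ct = make_ct(
        {"HMBS": [20.0], "HPRT1": [22.0], "GUSB": [24.0], "T1": [28.0], "T2": [31.0]},
        ROLES3 | {"T1": ROLE_TARGET, "T2": ROLE_TARGET},
    )
    shifted = make_ct(
        {
            "HMBS": [20.0 + c], "HPRT1": [22.0 + c], "GUSB": [24.0 + c],
            "T1": [28.0 + c], "T2": [31.0 + c],
        },
        ROLES3 | {"T1": ROLE_TARGET, "T2": ROLE_TARGET},
    )
    a = delta_ct_normalize(ct).delta_ct
    b = delta_ct_normalize(shifted).delta_ct
    pd.testing.assert_frame_equal(a, b, atol=1e-9, rtol=0)


def test_one_cycle_more_ct_means_one_unit_less_expression():
    base = make_ct(
        {"HMBS": [20.0], "HPRT1": [22.0], "GUSB": [24.0], "T1": [28.0]},
        ROLES3 | {"T1": ROLE_TARGET},
    )
    plus = make_ct(
        {"HMBS": [20.0], "HPRT1": [22.0], "GUSB": [24.0], "T1": [29.0]},
        ROLES3 | {"T1": ROLE_TARGET},
    )
    d0 = delta_ct_normalize(base).delta_ct.loc["T1", "P1"]
    d1 = delta_ct_normalize(plus).delta_ct.loc["T1", "P1"]
    assert d1 == pytest.approx(d0 - 1.0)


# ---------------------------------------------------------------------------
# variance filter


def _expr(values: np.ndarray) -> ExpressionMatrix:
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[f"G{i}" for i in range(values.shape[0])],
            columns=[f"P{j}" for j in range(values.shape[1])],
        )
    )


def test_variance_filter_cardinality_93_to_70():
    rng = np.random.default_rng(0)
    expr = _expr(rng.normal(size=(93, 10)))
    assert variance_filter(expr, keep_fraction=0.75).n_genes == 70


def test_variance_filter_identity_at_fraction_one():
    rng = np.random.default_rng(1)
    expr = _expr(rng.normal(size=(12, 5)))
    out = variance_filter(expr, keep_fraction=1.0)
    pd.testing.assert_frame_equal(out.delta_ct, expr.delta_ct)


def test_variance_filter_keeps_top_variance_genes():
    # variances 0, 1, 4, 9 by construction
    vals = np.array([[1.0, 1, 1], [0, 1, 2], [0, 2, 4], [0, 3, 6]])
    expr = _expr(vals)
    out = variance_filter(expr, keep_fraction=0.5)
    assert out.genes == ["G2", "G3"]


def test_variance_filter_matches_brute_force_oracle():
    rng = np.random.default_rng(3)
    expr = _expr(rng.normal(size=(20, 8)))
    k = math.ceil(0.75 * 20)
    var = expr.delta_ct.var(axis=1, ddof=1)
    oracle = set(var.sort_values(ascending=False).index[:k])
    out = variance_filter(expr, keep_fraction=0.75)
    assert set(out.genes) == oracle
    assert set(out.genes) <= set(expr.genes)


def test_variance_filter_constant_matrix_ties_break_by_panel_order():
    expr = _expr(np.ones((8, 4)))
    out = variance_filter(expr, keep_fraction=0.5)
    assert out.genes == ["G0", "G1", "G2", "G3"]
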