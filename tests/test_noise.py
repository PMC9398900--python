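"""Levene/BH oracles, variance scan invariances, and panel-rule semantics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from proteonoise import (
    ConfigurationError,
    InsufficientDataError,
    NoisePanelSelector,
    SimulationConfig,
    TransitionSpec,
    ValidationError,
    bh_step_up,
    default_transitions,
    levene_mean,
    select_noise_panel,
    simulate_study,
    variance_scan,
)

from conftest import normalize_to_matrix


# ---------------------------------------------------------------------------
# levene_mean
# ---------------------------------------------------------------------------

def test_levene_identical_groups_is_null():
    g = [1.0, 2.0, 3.0, 4.0]
    w, p = levene_mean([g, list(g)])
    assert w == 0.0
    assert p == 1.0


def test_levene_equals_anova_on_absolute_deviations():
    groups = [[0.0, 0.0, 0.0, 0.0], [-3.0, -1.0, 1.0, 3.0]]
    z = [np.abs(np.asarray(g) - np.mean(g)) for g in groups]
    f_expected, p_expected = stats.f_oneway(*z)
    w, p = levene_mean(groups)
    assert w == pytest.approx(f_expected, rel=1e-12)
    assert p == pytest.approx(p_expected, rel=1e-12)


@pytest.mark.parametrize("k", [2, 3])
def test_levene_matches_scipy_on_random_instances(k, rng):
    for _ in range(50):
        groups = [rng.uniform(0, 10, rng.integers(2, 11)) for _ in range(k)]
        w, p = levene_mean(groups)
        w_ref, p_ref = stats.levene(*groups, center="mean")
        assert w == pytest.approx(w_ref, rel=1e-10)
        assert p == pytest.approx(p_ref, rel=1e-10)


def test_levene_power_on_threefold_sd_ratio(rng):
    """k=2, n=50/group, 3x SD ratio: p < 0.01 in >= 99% of replicates."""
    hits = sum(
        levene_mean([rng.normal(0, 1, 50), rng.normal(0, 3, 50)])[1] < 0.01
        for _ in range(400)
    )
    assert hits / 400 >= 0.99


def test_levene_degenerate_inputs():
    # all absolute deviations zero in both groups, distinct means
    w, p = levene_mean([[5.0, 5.0, 5.0], [9.0, 9.0]])
    assert (w, p) == (0.0, 1.0)
    # zero within-group deviation spread, different deviation means
    w, p = levene_mean([[5.0, 5.0, 5.0], [0.0, 10.0]])
    assert np.isinf(w) and p == 0.0
    with pytest.raises(InsufficientDataError):
        levene_mean([[1.0], [2.0, 3.0]])
    with pytest.raises(InsufficientDataError):
        levene_mean([[1.0, 2.0]])


# ---------------------------------------------------------------------------
# bh_step_up
# ---------------------------------------------------------------------------

def _bh_brute_force(p, q):
    """Evaluate the step-up inequality at every rank independently."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    kmax = 0
    for rank in range(1, m + 1):
        if p[order[rank - 1]] <= rank * q / m:
            kmax = rank
    flags = np.zeros(m, bool)
    flags[order[:kmax]] = True
    return flags


def test_bh_worked_example():
    flags = bh_step_up([0.01, 0.02, 0.03, 0.5], q=0.10)
    assert flags.tolist() == [True, True, True, False]


def test_bh_all_ones_rejects_nothing():
    assert not bh_step_up([1.0] * 10, q=0.10).any()


def test_bh_single_p():
    assert bh_step_up([0.05], q=0.10).tolist() == [True]
    assert bh_step_up([0.15], q=0.10).tolist() == [False]


def test_bh_empty_and_invalid():
    assert bh_step_up([], q=0.1).size == 0
    with pytest.raises(ValidationError):
        bh_step_up([0.5, 1.5])
    with pytest.raises(ValidationError):
        bh_step_up([0.5], q=-0.1)


@given(st.lists(st.floats(0, 1), min_size=1, max_size=50), st.integers(0, 10**6))
def test_bh_matches_brute_force_and_statsmodels(p, salt):
    from statsmodels.stats.multitest import multipletests

    q = 0.05 + (salt % 3) * 0.05
    flags = bh_step_up(p, q=q)
    assert flags.tolist() == _bh_brute_force(p, q).tolist()
    sm_flags = multipletests(p, alpha=q, method="fdr_bh")[0]
    assert flags.tolist() == sm_flags.tolist()


@given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
def test_bh_monotone_in_q(p):
    r1 = bh_step_up(p, q=0.05)
    r2 = bh_step_up(p, q=0.10)
    assert np.all(r2 | ~r1)  # rejections at q=0.05 are a subset of q=0.10


# ---------------------------------------------------------------------------
# variance_scan
# ---------------------------------------------------------------------------

def test_scan_duplicate_groups_are_flat(small_cohorts):
    matrix, _ = small_cohorts
    young = matrix.subset(matrix.sample_mask(cohort="young"))
    dup = young.values.copy()
    dup.columns = [f"{c}__dup" for c in dup.columns]
    meta_dup = young.meta.copy()
    meta_dup.index = dup.columns
    meta_dup["cohort"] = "old"
    from proteonoise import AbundanceMatrix

    combined = AbundanceMatrix(
        values=pd.concat([young.values, dup], axis=1),
        meta=pd.concat([young.meta, meta_dup]),
    )
    table = variance_scan(combined)
    assert (table["direction"] == "flat").all()
    assert not table["bh_reject"].any()
    assert (table["p_value"] == 1.0).all()


def test_scan_is_invariant_to_per_analyte_shift(small_study):
    matrix, _ = small_study
    table = variance_scan(matrix)
    shifted = matrix.values.copy()
    shifted.iloc[0] += 1234.5
    from proteonoise import AbundanceMatrix

    table2 = variance_scan(AbundanceMatrix(values=shifted, meta=matrix.meta))
    for col in ("sd_a", "sd_b", "levene_w", "p_value"):
        assert np.allclose(table[col], table2[col], equal_nan=True)
    assert (table["bh_reject"] == table2["bh_reject"]).all()


def test_scan_recovers_planted_inflation():
    cfg = SimulationConfig(
        n_analytes=40,
        noise_set=("P001", "P002", "P003", "P004"),
        level_shift_set=(),
        n_per_cohort={"young": 30, "old": 30},
        seed=8,
    )
    samples, truth = simulate_study(cfg)
    matrix = normalize_to_matrix(samples)
    table = variance_scan(matrix)
    y2o = table[table["transition"] == "young_to_old"].set_index("analyte_id")
    planted = list(truth.planted_noise_set)
    assert (y2o.loc[planted, "direction"] == "up").all()
    assert (y2o.loc[planted, "p_value"] < 0.05).all()
    assert y2o.loc[planted, "bh_reject"].all()


def test_default_transitions_cover_available_cohorts(small_study):
    matrix, _ = small_study
    names = {t.name for t in default_transitions(matrix.meta)}
    assert names == {
        "young_to_old",
        "pre_to_post_tpe",
        "old_to_disease",
        "young_to_middle",
    }


def test_transition_validation(small_study):
    matrix, _ = small_study
    with pytest.raises(ValidationError, match="overlap"):
        TransitionSpec("bad", {"cohort": "young"}, {"cohort": ("young", "old")}).masks(
            matrix.meta
        )
    with pytest.raises(InsufficientDataError):
        TransitionSpec(
            "tiny", {"cohort": "young"}, {"subject_id": "old_001"}
        ).masks(matrix.meta)


def test_brown_forsythe_variant_matches_scipy(small_cohorts):
    matrix, _ = small_cohorts
    sub = matrix.subset(matrix.sample_mask(cohort=("young", "old")))
    table = variance_scan(sub, center="median")
    y = sub.values.to_numpy()[:, sub.sample_mask(cohort="young")]
    o = sub.values.to_numpy()[:, sub.sample_mask(cohort="old")]
    w_ref, p_ref = stats.levene(y[3], o[3], center="median")
    row = table[table["transition"] == "young_to_old"].iloc[3]
    assert row["levene_w"] == pytest.approx(w_ref)
    assert row["p_value"] == pytest.approx(p_ref)


# ---------------------------------------------------------------------------
# select_noise_panel
# ---------------------------------------------------------------------------

def _fixture_table():
    """Eight analytes with hand-constructed flags covering every rule."""
    rows = []

    def add(analyte, transition, sd_a, sd_b, p, bh):
        rows.append(
            {
                "analyte_id": analyte,
                "transition": transition,
                "sd_a": sd_a,
                "sd_b": sd_b,
                "sd_fold": sd_b / sd_a,
                "direction": "up" if sd_b > sd_a else ("down" if sd_b < sd_a else "flat"),
                "levene_w": 1.0,
                "p_value": p,
                "bh_reject": bh,
            }
        )

    # a1: rule A only (BH up with age, down with TPE, small TPE fold)
    add("a1", "young_to_old", 1, 3, 0.001, True)
    add("a1", "pre_to_post_tpe", 3, 2, 0.2, False)
    add("a1", "old_to_disease", 3, 3, 0.9, False)
    # a2: rules A and C (BH up with age, >= 5-fold TPE contraction)
    add("a2", "young_to_old", 1, 4, 0.001, True)
    add("a2", "pre_to_post_tpe", 5, 0.5, 0.01, False)
    add("a2", "old_to_disease", 4, 4, 0.9, False)
    # a3: rule B only (raw-significant up with age and with disease, TPE up)
    add("a3", "young_to_old", 1, 2, 0.02, False)
    add("a3", "pre_to_post_tpe", 2, 3, 0.5, False)
    add("a3", "old_to_disease", 2, 6, 0.01, False)
    # a4: rules B, C and D
    add("a4", "young_to_old", 1, 3, 0.01, True)
    add("a4", "pre_to_post_tpe", 6, 1, 0.001, True)
    add("a4", "old_to_disease", 3, 7, 0.02, False)
    # a5: significant DOWN with age -> never selected
    add("a5", "young_to_old", 3, 1, 0.001, True)
    add("a5", "pre_to_post_tpe", 1, 0.1, 0.01, False)
    add("a5", "old_to_disease", 1, 5, 0.01, False)
    # a6: up with age but not significant anywhere
    add("a6", "young_to_old", 1, 1.5, 0.4, False)
    add("a6", "pre_to_post_tpe", 1.5, 0.2, 0.3, False)
    add("a6", "old_to_disease", 1.5, 2, 0.6, False)
    # a7: raw-significant up with age, TPE down but < 5-fold, no disease
    add("a7", "young_to_old", 1, 2.5, 0.03, False)
    add("a7", "pre_to_post_tpe", 2.5, 1.0, 0.2, False)
    add("a7", "old_to_disease", 2.5, 2.4, 0.8, False)
    # a8: null everywhere
    add("a8", "young_to_old", 1, 1, 1.0, False)
    add("a8", "pre_to_post_tpe", 1, 1, 1.0, False)
    add("a8", "old_to_disease", 1, 1, 1.0, False)
    return pd.DataFrame(rows)


def test_panel_rules_match_row_by_row_predicates():
    panel = select_noise_panel(_fixture_table())
    assert set(panel.analytes) == {"a1", "a2", "a3", "a4"}
    assert panel.provenance["a1"] == ("A",)
    assert panel.provenance["a2"] == ("A", "C")
    assert panel.provenance["a3"] == ("B",)
    assert panel.provenance["a4"] == ("A", "B", "C", "D")


def test_panel_external_addition_and_errors():
    table = _fixture_table()
    panel = select_noise_panel(table, external_additions=("a8",))
    assert "a8" in panel.analytes
    assert panel.provenance["a8"] == ("external",)
    with pytest.raises(ConfigurationError, match="TLR4"):
        select_noise_panel(table, external_additions=("TLR4",))
    with pytest.raises(ConfigurationError, match="pre_to_post_tpe"):
        select_noise_panel(table[table["transition"] == "young_to_old"])


def test_panel_empty_when_nothing_significant():
    table = _fixture_table()
    null = table.assign(p_value=1.0, bh_reject=False, direction="flat")
    assert select_noise_panel(null).analytes == ()


def test_panel_selection_commutes_with_reordering():
    table = _fixture_table()
    shuffled = table.sample(frac=1.0, random_state=0).reset_index(drop=True)
    a = select_noise_panel(table)
    b = select_noise_panel(shuffled)
    assert set(a.analytes) == set(b.analytes)
    assert {k: set(v) for k, v in a.provenance.items()} == {
        k: set(v) for k, v in b.provenance.items()
    }


def test_panel_structure_nine_planted_plus_external():
    """Nine planted noise reporters plus one externally nominated analyte
    give a ten-member panel with the external member tagged as such."""
    ids = tuple(f"P{i:03d}" for i in range(1, 120)) + ("TLR4",)
    cfg = SimulationConfig(
        n_analytes=120,
        analyte_ids=ids,
        noise_set=ids[:9],
        level_shift_set=(),
        n_per_cohort={"young": 30, "old": 30, "disease": 30, "tpe": 30},
        seed=4,
    )
    samples, truth = simulate_study(cfg)
    matrix = normalize_to_matrix(samples)
    table = variance_scan(matrix)
    panel = select_noise_panel(table, external_additions=("TLR4",))
    assert set(truth.planted_noise_set) <= set(panel.analytes)
    assert panel.provenance["TLR4"] == ("external",)
    assert panel.external_additions == ("TLR4",)


def test_noise_panel_selector_estimator(small_study):
    matrix, truth = small_study
    sel = NoisePanelSelector()
    X = matrix.values.T
    sel.fit(X, matrix.meta)
    assert sel.variance_table_.shape[0] == 4 * len(matrix.analyte_ids)
    assert set(sel.panel_.analytes) == set(
        np.array(matrix.analyte_ids)[sel.get_support()]
    )
    assert sel.transform(X).shape[1] == len(sel.panel_.analytes)
    # sklearn parameter plumbing
    assert sel.get_params()["q"] == 0.10
    sel.set_params(sd_fold_min=3.0)
    assert sel.sd_fold_min == 3.0
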