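"""Inference stage: matching, imputation, FDR, contrasts, comparisons, power."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gazesal.stats import (
    ModelSpec,
    compare_models,
    fdr_adjust,
    fit_lmm,
    impute_covariates,
    marginal_contrasts,
    match_groups,
    power_simulation,
)
from gazesal.synth import simulate_records


# ---------------------------------------------------------------------------
# matching


def _cohort(n=10, shift=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for g, d in (("ASD", shift), ("TD", 0.0)):
        for i in range(n):
            rows.append(
                {
                    "participant": f"{g.lower()}{i}",
                    "group": g,
                    "age": rng.uniform(6, 30) + d,
                    "perceptual_iq": rng.normal(100, 15),
                    "accuracy_z": rng.normal(0, 1),
                }
            )
    return pd.DataFrame(rows).set_index("participant")


def test_identical_groups_all_matched():
    c = _cohort(n=6, seed=1)
    c.loc[c["group"] == "TD", ["age", "perceptual_iq", "accuracy_z"]] = (
        c.loc[c["group"] == "ASD", ["age", "perceptual_iq", "accuracy_z"]].to_numpy()
    )
    matched = match_groups(c, match_vars=("age", "perceptual_iq", "accuracy_z"))
    assert len(matched) == len(c)
    assert matched.groupby("pair_id").size().eq(2).all()


def test_case_far_on_one_variable_unmatched():
    c = _cohort(n=5, seed=2)
    # push one case > 1 SD away from every control on age
    c.loc[c.index[0], "age"] = c["age"].max() + 3 * c["age"].std()
    matched = match_groups(c, match_vars=("age", "perceptual_iq", "accuracy_z"))
    assert c.index[0] not in matched.index


def test_greedy_matching_agrees_with_bruteforce_pair_ranking():
    """Every accepted pair must be the closest available pair at the time it
    was accepted (exhaustive re-simulation, n <= 20)."""
    c = _cohort(n=8, seed=3)
    vars_ = ("age", "perceptual_iq", "accuracy_z")
    matched = match_groups(c, match_vars=vars_, caliper_sd=10.0)
    z = c[list(vars_)].apply(lambda s: (s - s.mean()) / s.std(ddof=1))
    dist = {}
    for a in c.index[c["group"] == "ASD"]:
        for b in c.index[c["group"] == "TD"]:
            dist[(a, b)] = float(np.sqrt(((z.loc[a] - z.loc[b]) ** 2).sum()))
    order = sorted(dist, key=dist.get)
    used_a, used_b, expect = set(), set(), []
    for a, b in order:
        if a not in used_a and b not in used_b:
            used_a.add(a)
            used_b.add(b)
            expect.append((a, b))
    got = [
        tuple(matched[matched["pair_id"] == k].index)
        for k in sorted(matched["pair_id"].unique())
    ]
    got = [(a, b) if a.startswith("asd") else (b, a) for a, b in got]
    assert set(got) == set(expect)


def test_disjoint_groups_warn_and_return_empty():
    c = _cohort(n=3, seed=4)
    c.loc[c["group"] == "ASD", "age"] = 1000.0
    with pytest.warns(UserWarning, match="no feasible"):
        matched = match_groups(c, match_vars=("age",))
    assert len(matched) == 0


# ---------------------------------------------------------------------------
# imputation


def _cov_table(seed=0, n=30, missing=3):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "group": np.repeat(["ASD", "TD"], n // 2),
            "age": rng.uniform(6, 30, n),
            "perceptual_iq": rng.normal(100, 15, n),
            "srs_score": np.where(
                np.repeat(["ASD", "TD"], n // 2) == "ASD",
                rng.normal(95, 20, n),
                rng.normal(30, 15, n),
            ),
        }
    )
    df.loc[df.index[:missing], "srs_score"] = np.nan
    return df


def test_no_missing_is_identity():
    df = _cov_table(missing=0)
    out = impute_covariates(df, columns=("srs_score",))
    assert out["srs_score"].equals(df["srs_score"])
    assert not out["srs_score_imputed"].any()


def test_imputed_value_is_a_group_donor_value():
    df = _cov_table(missing=2)
    out = impute_covariates(df, columns=("srs_score",))
    assert out["srs_score"].notna().all()
    for i in df.index[:2]:
        g = df.loc[i, "group"]
        donors = df.loc[(df["group"] == g) & df["srs_score"].notna(), "srs_score"]
        assert out.loc[i, "srs_score"] in set(donors)  # PMM: observed values only
        assert out.loc[i, "srs_score_imputed"]


def test_entirely_missing_covariate_rejected():
    df = _cov_table()
    df["srs_score"] = np.nan
    with pytest.raises(ValueError, match="entirely missing"):
        impute_covariates(df, columns=("srs_score",))


# ---------------------------------------------------------------------------
# FDR


def test_bh_hand_computation():
    out = fdr_adjust([0.01, 0.02, 0.04])
    assert np.allclose(out, [0.03, 0.03, 0.04])


def test_bh_equal_ps_unchanged():
    assert np.allclose(fdr_adjust([0.03, 0.03, 0.03]), 0.03)


@settings(deadline=None, derandomize=True)
@given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=10))
def test_bh_adjusted_never_below_raw(ps):
    adj = fdr_adjust(ps)
    assert np.all(adj >= np.asarray(ps) - 1e-12)


def test_empty_input_empty_output():
    assert fdr_adjust([]).size == 0


# ---------------------------------------------------------------------------
# marginal contrasts


def test_zero_interaction_gives_equal_simple_effects():
    """Without an interaction term the group effect is identical at both
    category levels; with one, the simple effects differ exactly by the
    estimated interaction (algebraic identity of the linear predictor)."""
    rec = simulate_records(n_per_group=10, n_scenes=8, beta_group=0.3, seed=5)
    no_int = fit_lmm(
        ModelSpec(outcome="pupil_response", interactions=(), poly_time=False), rec
    )
    mc0 = marginal_contrasts(no_int, term="group", by="category")
    assert mc0.loc["human", "delta"] == pytest.approx(
        mc0.loc["non-human", "delta"], abs=1e-9
    )
    with_int = fit_lmm(ModelSpec(outcome="pupil_response", poly_time=False), rec)
    mc1 = marginal_contrasts(with_int, term="group", by="category")
    diff = mc1.loc["human", "delta"] - mc1.loc["non-human", "delta"]
    assert diff == pytest.approx(
        with_int.effects.loc["group:category", "beta"], abs=1e-9
    )


def test_two_cell_difference_equals_dummy_coefficient():
    """In a two-group model the marginal group contrast equals the group
    coefficient times the coding span (identity)."""
    rec = simulate_records(n_per_group=8, n_scenes=6, beta_group=0.4, seed=6)
    res = fit_lmm(ModelSpec(outcome="pupil_response", interactions=(), poly_time=False), rec)
    mc = marginal_contrasts(res, term="group", by="category")
    assert mc.loc["human", "delta"] == pytest.approx(res.effects.loc["group", "beta"])


def test_planted_interaction_recovered_in_simple_effect_difference():
    rec = simulate_records(
        n_per_group=40, n_scenes=20, beta_interaction=0.3, seed=7
    )
    res = fit_lmm(ModelSpec(outcome="pupil_response", poly_time=False), rec)
    mc = marginal_contrasts(res, term="group", by="category")
    diff = mc.loc["human", "delta"] - mc.loc["non-human", "delta"]
    # simple-effect difference recovers the planted interaction coefficient
    assert diff == pytest.approx(0.3, abs=0.1)
    assert (mc["ci_low"] < mc["delta"]).all() and (mc["delta"] < mc["ci_high"]).all()


# ---------------------------------------------------------------------------
# model comparison


def test_identical_specs_chi2_zero():
    rec = simulate_records(n_per_group=6, n_scenes=4, seed=8)
    spec = ModelSpec(outcome="pupil_response", poly_time=False)
    out = compare_models(spec, spec, rec)
    assert out["chi2"] == pytest.approx(0.0, abs=1e-6)
    assert out["df"] == 0


def test_planted_moderator_improves_fit():
    rng = np.random.default_rng(9)
    rec = simulate_records(n_per_group=15, n_scenes=10, seed=9)
    rec["pr1"] = rng.normal(0, 1, len(rec))
    rec["pupil_response"] = rec["pupil_response"] + 0.5 * rec["pr1"]
    null = ModelSpec(outcome="pupil_response", interactions=(), poly_time=False)
    full = ModelSpec(
        outcome="pupil_response", interactions=(), covariates=("pr1",), poly_time=False
    )
    out = compare_models(null, full, rec)
    assert out["chi2"] > 3.84  # beyond the 1-df 5% critical value
    assert out["p"] < 0.05


def test_non_nested_specs_rejected():
    rec = simulate_records(n_per_group=6, n_scenes=4, seed=10)
    a = ModelSpec(outcome="pupil_response", fixed=("group",), interactions=(), poly_time=False)
    b = ModelSpec(outcome="pupil_response", fixed=("category",), interactions=(), poly_time=False)
    with pytest.raises(ValueError, match="not nested"):
        compare_models(a, b, rec)


# ---------------------------------------------------------------------------
# power simulation


def test_zero_iterations_rejected():
    rec = simulate_records(n_per_group=6, n_scenes=4, seed=11)
    res = fit_lmm(ModelSpec(outcome="pupil_response", poly_time=False), rec)
    with pytest.raises(ValueError):
        power_simulation(res, "group", iterations=0)


def test_power_larger_for_large_effect_than_null():
    rec = simulate_records(n_per_group=10, n_scenes=10, seed=12)
    res = fit_lmm(ModelSpec(outcome="pupil_response", poly_time=False), rec)
    null = power_simulation(res, "group:category", effect_size=0.0, iterations=40, seed=1)
    big = power_simulation(res, "group:category", effect_size=0.6, iterations=40, seed=1)
    assert big.power > null.power
    assert big.power > 0.9
    assert 0.0 <= null.ci_low <= null.power <= null.ci_high <= 1.0


def test_ci_width_shrinks_with_iterations():
    rec = simulate_records(n_per_group=8, n_scenes=6, seed=13)
    res = fit_lmm(ModelSpec(outcome="pupil_response", poly_time=False), rec)
    small = power_simulation(res, "group", effect_size=0.3, iterations=20, seed=2)
    # binomial CI width at the same point estimate scales as 1/sqrt(n):
    # compare widths from the same simulation stream
    large = power_simulation(res, "group", effect_size=0.3, iterations=80, seed=2)
    assert (large.ci_high - large.ci_low) < (small.ci_high - small.ci_low)


# ---------------------------------------------------------------------------
# face-gaze aggregation and directional recovery


def test_face_gaze_proportion_counting_oracle():
    from gazesal.stats import aggregate_face_gaze

    rec = pd.DataFrame(
        {
            "participant": ["p0"] * 10,
            "group": ["TD"] * 10,
            "scene": ["s0"] * 10,
            "category": ["human"] * 10,
            "t_scene_ms": np.linspace(100, 900, 10),
            "aoi_face": [1.0] * 3 + [0.0] * 7,
        }
    )
    agg = aggregate_face_gaze(rec, bin_ms=1000.0)
    assert len(agg) == 1
    assert agg.loc[0, "face_prop"] == pytest.approx(0.30)
    assert agg.loc[0, "n_fixations"] == 10
    assert agg.loc[0, "group"] == "TD"


def test_planted_effect_directions_recovered_across_cohorts():
    """Cohorts planted with the hypothesized directions -- ASD pupil response
    higher in non-human and lower in human scenes (negative group x category
    coefficient under +0.5 = ASD/human coding), ASD face gaze lower -- yield
    the correct fitted signs in >= 9 of 10 cohorts."""
    pupil_spec = ModelSpec(outcome="pupil_response", poly_time=False)
    face_spec = ModelSpec(outcome="aoi_face", fixed=("group",), interactions=(), poly_time=False)
    hits = 0
    for seed in range(10):
        pup = simulate_records(n_per_group=40, n_scenes=20, beta_interaction=-0.3, seed=seed)
        face = simulate_records(
            n_per_group=40, n_scenes=20, beta_group=-0.3, seed=500 + seed,
            outcome="aoi_face",
        )
        face["category"] = "human"
        sign1 = fit_lmm(pupil_spec, pup).effects.loc["group:category", "beta"] < 0
        sign2 = fit_lmm(face_spec, face).effects.loc["group", "beta"] < 0
        hits += bool(sign1 and sign2)
    assert hits >= 9


def test_moderator_attenuates_group_effect_when_it_carries_it():
    """When the group effect on the outcome is routed through a moderator,
    adding the moderator as a predictor attenuates the group coefficient."""
    rng = np.random.default_rng(21)
    rec = simulate_records(n_per_group=30, n_scenes=12, seed=22)
    gcode = np.where(rec["group"] == "ASD", 0.5, -0.5)
    moderator = gcode * 0.8 + rng.normal(0, 0.5, len(rec))
    rec["pr1"] = moderator
    rec["pupil_response"] = rec["pupil_response"] + 0.6 * moderator
    without = fit_lmm(
        ModelSpec(outcome="pupil_response", interactions=(), poly_time=False), rec
    )
    with_mod = fit_lmm(
        ModelSpec(
            outcome="pupil_response", interactions=(), covariates=("pr1",),
            poly_time=False,
        ),
        rec,
    )
    assert abs(with_mod.effects.loc["group", "beta"]) < abs(
        without.effects.loc["group", "beta"]
    )
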