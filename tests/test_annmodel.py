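import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eggprint.annmodel import (
    AnnConfig,
    ModelError,
    compare_probe_sets,
    compute_sensitivities,
    genotype_variance,
    nested_subset_run,
    train_ensemble,
)
from eggprint.dataio import ExpressionMatrix, GenotypeMatrix
from tests.conftest import planted_probe_ids


def _linear_fixture(n_probes=10, n_samples=16, noise=0.0, seed=3):
    """Target is an exact (or noisy) linear map of probes that share a
    latent factor — the co-expressed regime the ensembles are built for."""
    rng = np.random.default_rng(seed)
    f = rng.normal(0, 1, n_samples)
    loadings = rng.uniform(0.8, 1.2, n_probes)
    X = np.outer(loadings, f) + 0.1 * rng.normal(0, 1, (n_probes, n_samples))
    w = rng.uniform(0.5, 1.5, n_probes)
    y = w @ X + noise * rng.normal(0, 1, n_samples)
    y = 50 + 10 * (y - y.mean()) / y.std()
    expr = ExpressionMatrix(
        [f"p{i:02d}" for i in range(n_probes)],
        [f"s{i:02d}" for i in range(n_samples)],
        X, scale_flag="normalized",
    )
    return expr, y


def test_noiseless_linear_target_is_learned():
    """A linear map is representable by the network; OLS confirms the
    target is exactly linear in the inputs, and the ensemble's holdout
    performance approaches it."""
    expr, y = _linear_fixture()
    coef, res_ss, *_ = np.linalg.lstsq(
        np.column_stack([expr.values.T, np.ones(16)]), y, rcond=None
    )
    assert res_ss.size == 0 or res_ss[0] < 1e-18  # OLS oracle: perfectly linear
    res = train_ensemble(expr, y, AnnConfig(seed=5, l2_penalty=0.01))
    assert res.mean_cv_r2 >= 0.95


def test_permuted_target_sits_at_the_null_floor():
    """Shuffling the target severs the signal; with squared-correlation
    R^2 and 4-sample holdouts the null expectation is ~1/3, far below a
    real fit."""
    expr, y = _linear_fixture()
    rng = np.random.default_rng(8)
    res_true = train_ensemble(expr, y, AnnConfig(seed=5, l2_penalty=0.01))
    res_null = train_ensemble(expr, rng.permutation(y), AnnConfig(seed=5, l2_penalty=0.01))
    assert res_null.mean_cv_r2 < 0.55
    assert res_true.mean_cv_r2 - res_null.mean_cv_r2 > 0.4


def test_default_split_is_12_train_4_holdout():
    expr, y = _linear_fixture()
    res = train_ensemble(expr, y, AnnConfig(seed=5))
    for m in res.models:
        assert len(m.train_idx) == 12
        assert len(m.test_idx) == 4
    assert res.all_samples_held_out


def test_ensemble_is_bit_deterministic():
    expr, y = _linear_fixture()
    a = train_ensemble(expr, y, AnnConfig(seed=5))
    b = train_ensemble(expr, y, AnnConfig(seed=5))
    assert np.array_equal(a.train_r2, b.train_r2)
    assert np.array_equal(a.cv_r2, b.cv_r2)
    assert a.oof_predictions == b.oof_predictions


def test_leaky_standardization_changes_cv():
    """Standardizing with global statistics leaks holdout information;
    the contract requires training-split statistics, and the two must
    measurably differ."""
    expr, y = _linear_fixture(noise=1.0)
    clean = train_ensemble(expr, y, AnnConfig(seed=5))
    leaky = train_ensemble(expr, y, AnnConfig(seed=5, standardize="global"))
    assert not np.allclose(clean.cv_r2, leaky.cv_r2)


def test_constant_target_rejected():
    expr, _ = _linear_fixture()
    with pytest.raises(ModelError, match="constant target"):
        train_ensemble(expr, np.full(16, 50.0), AnnConfig(seed=1))


def test_tiny_holdout_rejected():
    expr, y = _linear_fixture(n_samples=8)
    with pytest.raises(ModelError, match="holdout"):
        train_ensemble(expr, y[:8], AnnConfig(seed=1, train_fraction=0.95))


def test_sensitivity_of_linear_map_tracks_coefficients():
    """For y = 2*z1 + z2 the fitted model's sensitivity share ratio is ~2."""
    rng = np.random.default_rng(4)
    Z = rng.normal(0, 1, (2, 16))
    Z = (Z - Z.mean(axis=1, keepdims=True)) / Z.std(axis=1, keepdims=True)
    y = 50 + 5 * (2 * Z[0] + Z[1])
    expr = ExpressionMatrix(["z1", "z2"], [f"s{i}" for i in range(16)], Z,
                            scale_flag="normalized")
    res = train_ensemble(expr, y, AnnConfig(seed=9, l2_penalty=1e-3))
    sens = compute_sensitivities(res)
    tab = sens.table.set_index("probe_id")
    ratio = tab.loc["z1", "share"] / tab.loc["z2", "share"]
    assert ratio == pytest.approx(2.0, rel=0.10)


def test_sensitivity_shares_normalized_and_ranked(small_study, small_normalized,
                                                  small_screen):
    norm, _ = small_normalized
    sub = norm.subset_probes(small_screen.selected[:60])
    y = small_study.phenotype.target("pct_4h_viable").reindex(sub.sample_ids)
    res = train_ensemble(sub, y.to_numpy(dtype=float), AnnConfig(seed=2, n_models=5))
    sens = compute_sensitivities(res)
    assert sens.table["share"].sum() == pytest.approx(1.0)
    assert (sens.table["share"] >= 0).all()
    assert sorted(sens.table["rank"]) == list(range(1, 61))


def test_nested_single_stage_equals_plain_ensemble(small_study, small_normalized,
                                                   small_screen):
    norm, _ = small_normalized
    cfg = AnnConfig(seed=21, n_models=4)
    runs = nested_subset_run(norm, small_study.phenotype, small_screen,
                             sizes=[30], config=cfg)
    y = small_study.phenotype.target("pct_4h_viable").reindex(norm.sample_ids)
    direct = train_ensemble(norm.subset_probes(small_screen.selected[:30]),
                            y.to_numpy(dtype=float), cfg, stage=0)
    assert np.array_equal(runs[30][0].cv_r2, direct.cv_r2)


def test_nested_cascade_recovers_planted_probes(small_study, small_normalized,
                                                small_screen):
    """With 40 planted genes, the sensitivity-selected smaller stage keeps
    mostly planted probes."""
    norm, _ = small_normalized
    runs = nested_subset_run(norm, small_study.phenotype, small_screen,
                             sizes=[60, 20], config=AnnConfig(seed=17, n_models=10))
    planted = planted_probe_ids(small_study)
    kept = runs[60][1].top(20)
    assert len(planted & set(kept)) >= 14  # >= 70% of the refined set


def test_nested_sizes_validation(small_study, small_normalized, small_screen):
    norm, _ = small_normalized
    with pytest.raises(ModelError, match="descending"):
        nested_subset_run(norm, small_study.phenotype, small_screen,
                          sizes=[10, 20], config=AnnConfig(seed=1))
    with pytest.raises(ModelError, match="exceeds"):
        nested_subset_run(norm, small_study.phenotype, small_screen,
                          sizes=[10**6], config=AnnConfig(seed=1))


# ---------------------------------------------------------------------------
# ANOVA + Duncan


def _fake_result(r2_values):
    from eggprint.annmodel import EnsembleResult

    r2 = np.asarray(r2_values, dtype=float)
    return EnsembleResult(
        feature_ids=[], sample_ids=[], target_name="t",
        train_r2=r2, cv_r2=r2, models=[], X=np.zeros((1, 1)), y=np.zeros(1),
    )


def test_anova_matches_hand_computation():
    """Textbook 3-group example: groups (5,6,7), (6,7,8), (10,11,12) have
    SSB=42 (df 2), SSW=6 (df 6), F=21; Duncan separates the third group."""
    groups = {3: [5, 6, 7], 2: [6, 7, 8], 1: [10, 11, 12]}
    # feed raw values through the transform's inverse so the comparison
    # operates on exactly these numbers after arcsin-sqrt
    results = {k: _fake_result(np.sin(np.array(v) / 13.0) ** 2) for k, v in groups.items()}
    comp = compare_probe_sets(results, which="cv")
    means = {k: np.mean(v) / 13.0 for k, v in groups.items()}
    grand = np.mean([x / 13.0 for v in groups.values() for x in v])
    ssb = sum(3 * (m - grand) ** 2 for m in means.values())
    ssw = sum(((np.array(v) / 13.0 - means[k]) ** 2).sum() for k, v in groups.items())
    f_hand = (ssb / 2) / (ssw / 6)
    assert comp.anova_f == pytest.approx(f_hand, abs=1e-10)
    assert comp.anova_f == pytest.approx(21.0, abs=1e-9)
    assert comp.anova_p == pytest.approx(stats.f.sf(21.0, 2, 6), abs=1e-12)
    # group 1 holds the values (10,11,12): separated from the other two
    assert comp.letters[1] != comp.letters[2]
    assert comp.letters[2] == comp.letters[3]


def test_identical_groups_share_one_letter():
    results = {k: _fake_result([0.5, 0.5, 0.5]) for k in (1, 2, 3)}
    comp = compare_probe_sets(results)
    assert np.isnan(comp.anova_f)
    assert set(comp.letters.values()) == {"a"}


def test_arcsin_sqrt_transform_closed_form():
    res = {1: _fake_result([0.902] * 3), 2: _fake_result([0.5] * 3)}
    comp = compare_probe_sets(res)
    assert comp.group_means[1] == pytest.approx(np.arcsin(np.sqrt(0.902)), abs=1e-12)


def test_r2_outside_unit_interval_rejected():
    res = {1: _fake_result([0.5, 0.6]), 2: _fake_result([1.0, 1.1])}
    res[2].cv_r2 = np.array([1.0, 1.1])
    with pytest.raises(ModelError, match="outside"):
        compare_probe_sets(res)


# ---------------------------------------------------------------------------
# genotype


def test_null_genotype_explains_nothing(small_study):
    share = genotype_variance(small_study.genotype, small_study.phenotype,
                              AnnConfig(seed=3, l2_penalty=0.01, n_models=10))
    assert share <= 0.05


def test_planted_genotype_positive_control(small_study):
    y = small_study.phenotype.target("pct_4h_viable").to_numpy(dtype=float)
    n = len(y)
    rng = np.random.default_rng(5)
    dos = np.zeros((n, 4), dtype=int)
    dos[:, 0] = (y > 50) * 2  # allele dosage tracking the quality group
    dos[:, 1] = 2 - dos[:, 0]
    b = rng.integers(0, 2, n)
    dos[:, 2] = b * 2
    dos[:, 3] = 2 - dos[:, 2]
    geno = GenotypeMatrix(small_study.phenotype.sample_ids,
                          ["L01:A1", "L01:A2", "L02:A1", "L02:A2"], dos)
    share = genotype_variance(geno, small_study.phenotype,
                              AnnConfig(seed=3, l2_penalty=0.01))
    assert share >= 0.5


def test_constant_genotype_reports_zero(small_study):
    n = small_study.expression.n_samples
    geno = GenotypeMatrix(small_study.phenotype.sample_ids, ["L01:A1"],
                          np.full((n, 1), 2, dtype=int))
    assert genotype_variance(geno, small_study.phenotype, AnnConfig(seed=1)) == 0.0


def test_noise_probes_do_not_inflate_cv(small_study, small_normalized):
    """Appending pure-noise probes to an informative set must not raise
    mean CV R^2 by more than 0.05."""
    norm, _ = small_normalized
    planted = sorted(planted_probe_ids(small_study) & set(norm.probe_ids))[:20]
    y = small_study.phenotype.target("pct_4h_viable").reindex(norm.sample_ids)
    yv = y.to_numpy(dtype=float)
    base = train_ensemble(norm.subset_probes(planted), yv, AnnConfig(seed=31, n_models=10))
    noise_ids = [p for p in norm.probe_ids[-200:] if p not in planted]
    padded = train_ensemble(norm.subset_probes(planted + noise_ids), yv,
                            AnnConfig(seed=31, n_models=10))
    assert padded.mean_cv_r2 <= base.mean_cv_r2 + 0.05
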