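import itertools

import numpy as np
import pytest

from eggprint.annmodel import AnnConfig
from eggprint.dataio import ExpressionMatrix
from eggprint.fingerprint import (
    FingerprintError,
    ModulePartition,
    ResidualMatrix,
    clustergram,
    mmc_cluster,
    reverse_residualize,
    weighted_modularity,
)


def _expr(values, scale="normalized", prefix="g"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        [f"{prefix}{i:03d}" for i in range(values.shape[0])],
        [f"s{i:02d}" for i in range(values.shape[1])],
        values, scale_flag=scale,
    )


# ---------------------------------------------------------------------------
# reverse residualization


def test_residual_plus_fitted_is_observed_exactly():
    rng = np.random.default_rng(0)
    expr = _expr(rng.normal(8, 1, (12, 16)))
    y = rng.uniform(0, 100, 16)
    res = reverse_residualize(expr, y, AnnConfig(seed=1))
    assert np.array_equal(res.residuals + res.fitted, expr.values)


def test_phenotype_driven_gene_is_cleaned():
    """A gene built as 0.5*z(phenotype) + noise keeps almost no phenotype
    correlation in its residuals; a polynomial regression oracle confirms
    the relation is capturable."""
    rng = np.random.default_rng(3)
    y = np.concatenate([rng.uniform(55, 90, 8), rng.uniform(2, 28, 8)])
    z = (y - y.mean()) / y.std()
    genes = np.stack([0.5 * z + 0.1 * rng.normal(0, 1, 16) for _ in range(6)])
    expr = _expr(genes + 8.0)
    # oracle: a cubic polynomial fit removes the dependence entirely
    for row in genes:
        resid_poly = row - np.polyval(np.polyfit(z, row, 3), z)
        assert abs(np.corrcoef(resid_poly, y)[0, 1]) < 0.15
    res = reverse_residualize(expr, y)
    for i in range(expr.n_probes):
        assert abs(np.corrcoef(res.residuals[i], y)[0, 1]) < 0.15


def test_independent_gene_residuals_are_centered_observations():
    rng = np.random.default_rng(4)
    y = rng.uniform(0, 100, 16)
    genes = rng.normal(9, 0.5, (8, 16))  # no phenotype dependence
    expr = _expr(genes)
    res = reverse_residualize(expr, y, AnnConfig(seed=3))
    centered = genes - genes.mean(axis=1, keepdims=True)
    for i in range(8):
        rms = np.sqrt(np.mean((res.residuals[i] - centered[i]) ** 2))
        assert rms < 0.1 * genes[i].std()


def test_constant_phenotype_centers_data_without_error():
    rng = np.random.default_rng(5)
    genes = rng.normal(0, 1, (4, 10))
    expr = _expr(genes)
    res = reverse_residualize(expr, np.full(10, 42.0), AnnConfig(seed=1))
    assert np.allclose(res.fitted, genes.mean(axis=1, keepdims=True))
    assert np.allclose(res.residuals, genes - genes.mean(axis=1, keepdims=True))


# ---------------------------------------------------------------------------
# weighted modularity + MMC


def _all_partitions(n):
    """Every set partition of range(n) as a label array."""
    if n == 0:
        yield np.zeros(0, dtype=int)
        return
    for labels in itertools.product(*[range(i + 1) for i in range(n)]):
        # restricted growth strings enumerate partitions uniquely
        ok = True
        seen_max = -1
        for lab in labels:
            if lab > seen_max + 1:
                ok = False
                break
            seen_max = max(seen_max, lab)
        if ok:
            yield np.array(labels, dtype=int)


def test_partition_enumeration_is_bell_number():
    assert sum(1 for _ in _all_partitions(4)) == 15  # Bell(4)


def test_mmc_matches_brute_force_on_toy_weights():
    """4-gene weight matrix: the returned Q equals the maximum over all 15
    partitions enumerated exhaustively."""
    W = np.array(
        [
            [0.0, 0.9, 0.2, 0.1],
            [0.9, 0.0, 0.15, 0.2],
            [0.2, 0.15, 0.0, 0.8],
            [0.1, 0.2, 0.8, 0.0],
        ]
    )
    best_q = max(weighted_modularity(W, labels) for labels in _all_partitions(4))
    resid = ResidualMatrix(
        gene_ids=[f"g{i}" for i in range(4)],
        sample_ids=[f"s{i}" for i in range(6)],
        residuals=np.zeros((4, 6)) + np.eye(4, 6),  # placeholder, bypassed
        fitted=np.zeros((4, 6)),
    )
    part = mmc_cluster(resid, sharpness_grid=[1], weights=W)
    assert part.modularity == pytest.approx(best_q, abs=1e-12)


def test_three_perfect_blocks_recovered_exactly():
    from sklearn.metrics import adjusted_rand_score

    rng = np.random.default_rng(6)
    base = rng.normal(0, 1, (3, 20))
    genes = np.repeat(base, 10, axis=0) + 1e-6 * rng.normal(0, 1, (30, 20))
    truth = np.repeat([0, 1, 2], 10)
    resid = ResidualMatrix([f"g{i:02d}" for i in range(30)],
                           [f"s{i:02d}" for i in range(20)],
                           genes, np.zeros_like(genes))
    part = mmc_cluster(resid)
    labels = part.labels(resid.gene_ids)
    assert adjusted_rand_score(truth, labels) == 1.0


def test_uncorrelated_genes_flagged_low_confidence():
    rng = np.random.default_rng(7)
    genes = rng.normal(0, 1, (12, 400))  # large n: true r ~ 0
    resid = ResidualMatrix([f"g{i:02d}" for i in range(12)],
                           [f"s{i:03d}" for i in range(400)],
                           genes, np.zeros_like(genes))
    part = mmc_cluster(resid, sharpness_grid=[1, 2, 4])
    assert part.low_confidence


def test_mmc_q_invariant_to_gene_order():
    rng = np.random.default_rng(8)
    base = rng.normal(0, 1, (2, 24))
    genes = np.repeat(base, 6, axis=0) + 0.3 * rng.normal(0, 1, (12, 24))
    ids = [f"g{i:02d}" for i in range(12)]
    resid = ResidualMatrix(ids, [f"s{i}" for i in range(24)], genes,
                           np.zeros_like(genes))
    part = mmc_cluster(resid, sharpness_grid=[1, 3, 5])
    perm = rng.permutation(12)
    resid_p = ResidualMatrix([ids[i] for i in perm], resid.sample_ids,
                             genes[perm], np.zeros_like(genes))
    part_p = mmc_cluster(resid_p, sharpness_grid=[1, 3, 5])
    assert part_p.modularity == pytest.approx(part.modularity, abs=1e-12)
    # same grouping, module names aside
    for a, b in itertools.combinations(ids, 2):
        assert (part.module_of[a] == part.module_of[b]) == (
            part_p.module_of[a] == part_p.module_of[b]
        )


def test_sharpening_never_splits_true_block_before_crossing():
    """On a two-block planted matrix, every sharpness keeps each true block
    intact or splits it only after between-block merges are gone."""
    rng = np.random.default_rng(9)
    base = rng.normal(0, 1, (2, 30))
    genes = np.repeat(base, 8, axis=0) + 0.2 * rng.normal(0, 1, (16, 30))
    truth = np.repeat([0, 1], 8)
    resid = ResidualMatrix([f"g{i:02d}" for i in range(16)],
                           [f"s{i:02d}" for i in range(30)],
                           genes, np.zeros_like(genes))
    for s in (1, 2, 4, 8, 16):
        part = mmc_cluster(resid, sharpness_grid=[s])
        labels = part.labels(resid.gene_ids)
        # no module mixes the two blocks
        for mod in set(labels):
            members = truth[labels == mod]
            assert len(set(members)) == 1


def test_zero_variance_gene_is_named_in_error():
    genes = np.ones((3, 8))
    genes[0] = np.linspace(0, 1, 8)
    genes[1] = np.linspace(1, 0, 8)
    resid = ResidualMatrix(["ok1", "ok2", "flat"], [f"s{i}" for i in range(8)],
                           genes, np.zeros_like(genes))
    with pytest.raises(FingerprintError, match="flat"):
        mmc_cluster(resid)


# ---------------------------------------------------------------------------
# clustergram


def test_identical_profiles_merge_at_height_zero():
    rng = np.random.default_rng(10)
    row = rng.normal(0, 1, 6)
    genes = np.stack([row, row, rng.normal(0, 1, 6), rng.normal(0, 1, 6)])
    cg = clustergram(_expr(genes + 5))
    assert cg.gene_linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
    assert set(cg.gene_linkage[0, :2].astype(int)) == {0, 1}


def test_linkage_heights_match_brute_force_average_linkage():
    """4-gene fixture: every merge height equals the hand-computed average
    of pairwise correlation distances between the merged groups."""
    rng = np.random.default_rng(11)
    genes = rng.normal(0, 1, (4, 10))
    cg = clustergram(_expr(genes + 7))
    X = genes - genes.mean(axis=1, keepdims=True)
    d = 1 - np.corrcoef(X)

    clusters = {i: [i] for i in range(4)}
    next_id = 4
    for row in cg.gene_linkage:
        a, b, height, size = int(row[0]), int(row[1]), row[2], int(row[3])
        ga, gb = clusters[a], clusters[b]
        hand = np.mean([d[i, j] for i in ga for j in gb])
        assert height == pytest.approx(hand, abs=1e-12)
        assert size == len(ga) + len(gb)
        clusters[next_id] = ga + gb
        next_id += 1


def test_displayed_matrix_rows_are_centered(small_study, small_normalized):
    norm, _ = small_normalized
    sub = norm.subset_probes(norm.probe_ids[:25])
    cg = clustergram(sub)
    assert np.allclose(cg.matrix.to_numpy().mean(axis=1), 0.0, atol=1e-12)
    assert set(cg.matrix.index) == set(sub.probe_ids)


def test_clustergram_writes_image(tmp_path):
    rng = np.random.default_rng(12)
    path = tmp_path / "heat.png"
    clustergram(_expr(rng.normal(0, 1, (6, 8))), image_path=str(path))
    assert path.stat().st_size > 0
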