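"""Mixing model, density change, Mann-Whitney/BH, correlation, clustering,
inverse fraction estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import editomix as em
from editomix.composition import pool_non_neuron, simulate_site_counts
from conftest import CONTROL_MIXTURE


def _levels(rows, cells=("neuron", "astrocyte")):
    return pd.DataFrame(rows, columns=list(cells), index=[f"s{i}" for i in range(len(rows))])


# --------------------------------------------------------------------- mixing


def test_mixing_examples():
    lv = _levels([[0.70, 0.03]])
    tissue = em.mix_editomes(lv, {"neuron": 0.5, "astrocyte": 0.5})
    assert tissue.levels.iloc[0] == pytest.approx(0.365)
    pure = em.mix_editomes(lv, {"neuron": 1.0})
    assert pure.levels.iloc[0] == pytest.approx(0.70)


def test_copa_like_site_rises_with_neuron_loss():
    """COPA-type rates (neuron 3.1%, astro 18.35%): f_n 0.5 -> 0.4 raises
    the mixed level from 10.725% to 12.25%."""
    lv = _levels([[0.031, 0.1835]])
    at_half = em.mix_editomes(lv, {"neuron": 0.5, "astrocyte": 0.5}).levels.iloc[0]
    at_forty = em.mix_editomes(lv, {"neuron": 0.4, "astrocyte": 0.6}).levels.iloc[0]
    assert at_half == pytest.approx(0.10725)
    assert at_forty == pytest.approx(0.1225)


def test_mixing_with_expression_weights():
    lv = _levels([[0.8, 0.2]])
    lv.index = ["s0"]
    expr = pd.DataFrame({"neuron": [3.0], "astrocyte": [1.0]}, index=["G1"])
    gmap = pd.Series({"s0": "G1"})
    tissue = em.mix_editomes(lv, {"neuron": 0.5, "astrocyte": 0.5}, expr, gmap)
    assert tissue.levels.iloc[0] == pytest.approx((0.5 * 3 * 0.8 + 0.5 * 1 * 0.2) / (0.5 * 3 + 0.5))


def test_mixing_errors():
    lv = _levels([[0.5, 0.1]])
    with pytest.raises(ValueError, match="sum"):
        em.mix_editomes(lv, {"neuron": 0.6, "astrocyte": 0.6})
    with pytest.raises(ValueError, match="no editome"):
        em.mix_editomes(lv, {"neuron": 0.5, "ghost": 0.5})


@settings(max_examples=40, deadline=None)
@given(
    st.lists(st.floats(0, 1), min_size=2, max_size=5),
    st.lists(st.floats(0.01, 1), min_size=2, max_size=5),
)
def test_mixed_level_stays_in_convex_hull(levels, fracs):
    k = min(len(levels), len(fracs))
    levels, fracs = levels[:k], np.array(fracs[:k])
    fracs = fracs / fracs.sum()
    cells = [f"c{i}" for i in range(k)]
    lv = pd.DataFrame([levels], columns=cells, index=["s0"])
    mixture = dict(zip(cells, fracs))
    mixture[cells[-1]] += 1.0 - sum(mixture.values())  # exact simplex closure
    tissue = em.mix_editomes(lv, mixture)
    assert min(levels) - 1e-12 <= tissue.levels.iloc[0] <= max(levels) + 1e-12


def test_density_change_redistribution():
    assert em.simulate_density_change({"neuron": 0.5, "astrocyte": 0.5}, -0.2) == pytest.approx(
        {"neuron": 0.4, "astrocyte": 0.6}
    )
    base = {"neuron": 0.5, "astrocyte": 0.3, "microglia": 0.2}
    out = em.simulate_density_change(base, -0.2)
    assert out == pytest.approx({"neuron": 0.4, "astrocyte": 0.36, "microglia": 0.24})
    assert em.simulate_density_change(base, 0.0) == pytest.approx(base)
    with pytest.raises(ValueError, match="outside"):
        em.simulate_density_change({"neuron": 0.9, "astrocyte": 0.1}, 0.5)


def test_sign_law_on_presets(world):
    """Reducing neuronal density lowers neuron-high sites and raises
    astrocyte-high (COPA/COG3) sites on both presets."""
    for profile, mixture in (
        ("table2", {"neuron": 0.5, "astrocyte": 0.5}),
        ("paperlike", CONTROL_MIXTURE),
    ):
        truth = em.make_cell_editomes(world["catalog"], profile, seed=3)
        injured = em.simulate_density_change(mixture, -0.2)
        before = em.mix_editomes(truth.levels, mixture).levels
        after = em.mix_editomes(truth.levels, injured).levels
        delta = after - before
        astro_high = truth.sites["gene"].isin(["COPA_IV", "COG3_IV"])
        neuron_high = truth.levels.idxmax(axis=1) == "neuron"
        assert (delta[astro_high.to_numpy()] > 0).all()
        assert (delta[(neuron_high & ~astro_high).to_numpy()] < 0).all()


# ----------------------------------------------------------------- statistics


def test_mann_whitney_exact_canonical_example():
    """Fully separated 3v3 groups: 2 of 20 splits are as extreme, p = 0.1."""
    assert em.mann_whitney_exact([1, 2, 3], [4, 5, 6])[1] == pytest.approx(0.1)


def test_mann_whitney_identical_groups_p_one():
    assert em.mann_whitney([2.0, 2.0, 2.0], [2.0, 2.0, 2.0]) == 1.0


@pytest.mark.parametrize("nx,ny", [(2, 3), (3, 3), (4, 4), (5, 6), (6, 6)])
def test_mann_whitney_exact_matches_scipy_on_tie_free_data(nx, ny):
    rng = np.random.default_rng(nx * 10 + ny)
    for _ in range(5):
        pooled = rng.permutation(np.arange(nx + ny, dtype=float))
        x, y = pooled[:nx], pooled[nx:]
        ours = em.mann_whitney_exact(x, y)[1]
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert ours == pytest.approx(ref)


def test_mann_whitney_exact_matches_permutation_test_with_ties():
    rng = np.random.default_rng(9)
    x = rng.integers(0, 3, size=5).astype(float)
    y = rng.integers(0, 3, size=5).astype(float)

    def statistic(a, b):
        return stats.mannwhitneyu(a, b, alternative="two-sided").statistic

    ref = stats.permutation_test(
        (x, y), statistic, permutation_type="independent", alternative="two-sided",
        n_resamples=np.inf,
    ).pvalue
    assert em.mann_whitney_exact(x, y)[1] == pytest.approx(ref)


def test_benjamini_hochberg_step_up():
    q = em.benjamini_hochberg([0.01, 0.02, 0.5])
    assert q == pytest.approx([0.03, 0.03, 0.5])


@settings(max_examples=30, deadline=None)
@given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=20))
def test_bh_q_monotone_and_bounded_below_by_p(pvals):
    p = np.array(pvals)
    q = em.benjamini_hochberg(p)
    assert (q >= p - 1e-12).all()
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


def test_differential_editing_table():
    a = pd.DataFrame([[0.5, 0.52, 0.48, 0.51]], index=["s0"])
    b = pd.DataFrame([[0.3, 0.32, 0.28, 0.31]], index=["s0"])
    out = em.differential_editing(a, b)
    row = out.loc["s0"]
    assert row["delta"] == pytest.approx(-20.0, abs=0.5)
    assert row["direction"] == "down"
    assert row["q"] >= row["p"]

    skip = em.differential_editing(a.iloc[:, :1], b)
    assert skip.loc["s0", "skipped"] and "replicates" in skip.loc["s0", "reason"]


def test_differential_identical_groups():
    a = pd.DataFrame([[0.4, 0.4, 0.4]], index=["s0"])
    out = em.differential_editing(a, a.copy())
    assert out.loc["s0", "p"] == 1.0 and out.loc["s0", "delta"] == 0.0


# ---------------------------------------------------------------- correlation


def test_correlation_perfect_proportionality():
    d = pd.Series([0.1, 0.2, 0.3, 0.4], index=list("abcd"))
    res = em.editome_correlation(d, d * 0, d * 0.5, d * 0)
    assert res.r == pytest.approx(1.0) and res.r2 == pytest.approx(1.0)


def test_correlation_orthogonal_construction():
    rng = np.random.default_rng(2)
    x = pd.Series(rng.normal(size=30))
    raw = pd.Series(rng.normal(size=30))
    y = raw - (raw @ x) / (x @ x) * x  # Gram-Schmidt: orthogonal to x
    y = y - y.mean() + (y.mean() - y.mean())
    # re-orthogonalize after centering to make Pearson r exactly 0
    xc = x - x.mean()
    y = y - (y @ xc) / (xc @ xc) * xc
    res = em.editome_correlation(x, x * 0, y, y * 0)
    assert res.r == pytest.approx(0.0, abs=1e-10)


def test_correlation_includes_repeat_point_and_errors():
    d = pd.Series([0.1, 0.2, 0.3], index=list("abc"))
    res = em.editome_correlation(d, d * 0, d * 0.5, d * 0, repeat_deltas=(0.01, 0.005))
    assert len(res.pairs) == 4 and "repeat_index" in set(res.pairs["point"])
    with pytest.raises(ValueError, match="variance"):
        em.editome_correlation(d * 0 + 0.5, d * 0, d, d * 0)


# ----------------------------------------------------------------- clustering


def test_identical_samples_merge_first_and_anticorrelated_max_distance():
    rng = np.random.default_rng(4)
    base = rng.random(10)
    mat = pd.DataFrame(
        {"a": base, "b": base, "c": 1 - base, "d": rng.random(10)},
        index=[f"s{i}" for i in range(10)],
    )
    tree = em.cluster_editomes(mat)
    assert tree.distances.loc["a", "b"] == pytest.approx(0.0)
    assert tree.distances.loc["a", "c"] == pytest.approx(2.0)
    assert tree.linkage[0, 2] == pytest.approx(0.0)  # first merge at distance 0
    assert {tree.labels[int(tree.linkage[0, 0])], tree.labels[int(tree.linkage[0, 1])]} == {"a", "b"}


def test_two_group_cut_separates_neurons(world):
    """Replicate editomes of 7 cell types: the 2-cut isolates neuron-like
    samples (neurons + the close OPC lineage on one side at worst)."""
    truth = world["truth"]
    rng = np.random.default_rng(8)
    cols = {}
    for ct in truth.levels.columns:
        for rep in range(2):
            noise = rng.normal(0, 0.01, size=len(truth.levels))
            cols[f"{ct}_{rep}"] = np.clip(truth.levels[ct] + noise, 0, 1)
    mat = pd.DataFrame(cols, index=truth.levels.index)
    tree = em.cluster_editomes(mat)
    g_neuron = {tree.two_groups[f"neuron_{r}"] for r in range(2)}
    assert len(g_neuron) == 1
    far_types = ("astrocyte", "microglia", "endothelial", "mo", "nfo")
    g_far = {tree.two_groups[f"{ct}_{r}"] for ct in far_types for r in range(2)}
    assert g_neuron.isdisjoint(g_far)


def test_cluster_newick_is_parseable(world):
    truth = world["truth"]
    mat = truth.levels.rename(columns=str)
    tree = em.cluster_editomes(mat)
    import dendropy

    parsed = dendropy.Tree.get(data=tree.newick(), schema="newick")
    assert {t.label for t in parsed.taxon_namespace} == set(mat.columns)


def test_cluster_drops_sparse_samples():
    rng = np.random.default_rng(6)
    mat = pd.DataFrame(rng.random((10, 4)), columns=list("abcd"))
    mat.loc[2:, "d"] = np.nan  # only 2 usable sites
    tree = em.cluster_editomes(mat)
    assert tree.dropped == ["d"] and "d" not in tree.labels


# -------------------------------------------------------------- inverse model


def test_fraction_change_exact_on_noise_free_mixtures(world):
    truth = world["truth"]
    injured = em.simulate_density_change(CONTROL_MIXTURE, -0.2)
    pre = em.mix_editomes(truth.levels, CONTROL_MIXTURE).levels
    post = em.mix_editomes(truth.levels, injured).levels
    est = em.estimate_fraction_change(pre, post, truth.levels)
    assert not est.ill_conditioned
    assert est.neuron_delta == pytest.approx(-0.20, abs=1e-6)
    assert est.fractions_pre["neuron"] == pytest.approx(0.5, abs=1e-6)


def test_fraction_change_collinear_editomes_flagged(world):
    truth = world["truth"]
    lv = truth.levels[["neuron"]].copy()
    lv["clone"] = lv["neuron"]
    pre = em.mix_editomes(truth.levels, CONTROL_MIXTURE).levels
    est = em.estimate_fraction_change(pre, pre, lv)
    assert est.ill_conditioned and np.isnan(est.neuron_delta)


def test_fraction_change_recovery_under_binomial_noise(world):
    truth = world["truth"]
    injured = em.simulate_density_change(CONTROL_MIXTURE, -0.2)
    basis = pool_non_neuron(truth.levels, CONTROL_MIXTURE)
    rng = np.random.default_rng(12)
    pre = simulate_site_counts(truth.levels, CONTROL_MIXTURE, 1e4, rng)
    post = simulate_site_counts(truth.levels, injured, 1e4, rng)
    est = em.estimate_fraction_change(pre, post, basis)
    assert est.neuron_delta == pytest.approx(-0.20, abs=0.03)
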