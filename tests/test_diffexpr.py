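import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import polysomely as pl
from polysomely.diffexpr import DiffExprError, _exact_pvalue


def make_two_group(arr, reps, cell="A", pool="T"):
    """Counts + design for a single (N vs H) two-group layout in one pool."""
    arr = np.asarray(arr, dtype=np.int64)
    n_samples = 2 * reps
    assert arr.shape[1] == n_samples
    sids = [f"{cell}_N_{pool}_{r}" for r in range(1, reps + 1)] + [
        f"{cell}_H_{pool}_{r}" for r in range(1, reps + 1)
    ]
    counts = pl.CountMatrix(
        pd.DataFrame(arr, index=pd.Index([f"g{i}" for i in range(arr.shape[0])],
                                         name="gene_id"), columns=sids)
    )
    rows = [
        {"sample_id": s, "cell_line": cell,
         "treatment": s.split("_")[1], "pool": pool, "replicate": int(s.split("_")[3])}
        for s in sids
    ]
    design = pl.SampleDesign(pd.DataFrame(rows))
    return counts, design


def unit_factors(counts):
    lib = counts.library_sizes()
    return pl.NormFactors(tuple(map(str, counts.sample_ids)), np.ones(len(lib)), lib)


def binom_oracle(s1, s2, n1, n2):
    """Exact conditional binomial two-sided p at the Poisson limit, by full
    enumeration of the support."""
    total = s1 + s2
    if total == 0:
        return 1.0
    pr = n1 / (n1 + n2)
    pmf = stats.binom.pmf(np.arange(total + 1), total, pr)
    return float(min(1.0, pmf[pmf <= pmf[s1] + 1e-12].sum()))


def bh_oracle(p):
    """Literal step-up definition with explicit loops."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    for rank_pos, i in enumerate(order, start=1):
        adj[i] = min(
            min(m * p[j] / (list(order).index(j) + 1) for j in order[rank_pos - 1:]),
            1.0,
        )
    return adj


class TestBhAdjust:
    def test_worked_four_vector(self):
        got = pl.bh_adjust([0.005, 0.01, 0.03, 0.04])
        assert np.allclose(got, [0.02, 0.02, 0.04, 0.04])

    def test_all_ones_fixed_point(self):
        assert np.allclose(pl.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_single_value_identity(self):
        assert pl.bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_matches_statsmodels_and_oracle_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(99)
        for _ in range(200):
            n = int(rng.integers(1, 120))
            p = rng.uniform(0, 1, size=n)
            got = pl.bh_adjust(p)
            _, sm, _, _ = multipletests(p, method="fdr_bh")
            assert np.allclose(got, sm, atol=1e-12)
        p = rng.uniform(size=12)
        assert np.allclose(pl.bh_adjust(p), bh_oracle(list(p)), atol=1e-12)

    def test_monotone_on_sorted_input(self):
        rng = np.random.default_rng(1)
        p = np.sort(rng.uniform(size=50))
        adj = pl.bh_adjust(p)
        assert (np.diff(adj) >= -1e-15).all()

    def test_invalid_inputs_rejected(self):
        with pytest.raises(DiffExprError):
            pl.bh_adjust([0.5, 1.5])
        with pytest.raises(DiffExprError):
            pl.bh_adjust([0.5, np.nan])


class TestFilterLowExpression:
    def test_all_zero_gene_removed(self):
        arr = np.array([[100, 90, 110], [0, 0, 0], [40, 50, 60]])
        cm = pl.CountMatrix(pd.DataFrame(
            arr, index=pd.Index(["g0", "gz", "g2"], name="gene_id"),
            columns=["a", "b", "c"]))
        kept = pl.filter_low_expression(cm, min_cpm=0.001, min_samples=1)
        assert "gz" not in kept.gene_ids
        assert list(kept.gene_ids) == ["g0", "g2"]

    def test_zero_threshold_is_identity(self, toy_counts):
        assert pl.filter_low_expression(toy_counts, min_cpm=0) == toy_counts

    def test_matches_direct_enumeration(self):
        arr = np.array([[100, 0, 0], [5, 5, 5], [0, 0, 1], [50, 60, 70], [1, 0, 0]])
        cm = pl.CountMatrix(pd.DataFrame(
            arr, index=pd.Index([f"g{i}" for i in range(5)], name="gene_id"),
            columns=["a", "b", "c"]))
        lib = arr.sum(axis=0)
        cpm = arr / lib * 1e6
        min_cpm, min_samples = 10.0, 2
        want = [f"g{i}" for i in range(5) if (cpm[i] >= min_cpm).sum() >= min_samples]
        kept = pl.filter_low_expression(cm, min_cpm=min_cpm, min_samples=min_samples)
        assert list(kept.gene_ids) == want

    def test_min_samples_exceeding_total_rejected(self, toy_counts):
        with pytest.raises(DiffExprError, match="min_samples"):
            pl.filter_low_expression(toy_counts, min_samples=10)


class TestEstimateDispersions:
    def test_zero_within_group_variance_gives_zero_mom(self):
        arr = np.array([[50, 50, 80, 80], [10, 10, 10, 10]])
        counts, design = make_two_group(arr, reps=2)
        d = pl.estimate_dispersions(counts, design, unit_factors(counts))
        assert d.common == 0.0
        assert np.allclose(d.per_gene, 0.0)

    def test_poisson_counts_give_small_dispersion(self):
        rng = np.random.default_rng(8)
        means = np.exp(rng.normal(5.5, 1, size=2000))
        arr = rng.poisson(np.tile(means[:, None], (1, 8)))
        counts, design = make_two_group(arr, reps=4)
        d = pl.estimate_dispersions(counts, design, unit_factors(counts))
        assert np.median(d.per_gene) <= 0.02

    @pytest.mark.parametrize("phi", [0.05, 0.1, 0.3])
    def test_nb_common_dispersion_recovery(self, phi):
        rng = np.random.default_rng(int(phi * 1000))
        means = np.exp(rng.normal(6, 1, size=2000))
        lam = rng.gamma(1 / phi, phi * np.tile(means[:, None], (1, 16)))
        arr = rng.poisson(lam)
        counts, design = make_two_group(arr, reps=8)
        d = pl.estimate_dispersions(counts, design, unit_factors(counts))
        assert phi * 0.7 <= d.common <= phi * 1.3

    def test_no_replication_rejected(self):
        arr = np.array([[5, 9], [3, 2]])
        counts, design = make_two_group(arr, reps=1)
        with pytest.raises(DiffExprError, match="replicate"):
            pl.estimate_dispersions(counts, design, unit_factors(counts))


def fixed_dispersions(counts, phi):
    gids = tuple(map(str, counts.gene_ids))
    return pl.DispersionEstimates(gids, float(phi), np.full(len(gids), float(phi)), 0.0)


class TestExactTest:
    def test_poisson_limit_matches_binomial_enumeration(self):
        """phi -> 0 with equal libraries: the conditional NB test collapses
        to the exact conditional binomial test."""
        for n1, n2 in [(3, 3), (2, 4)]:
            for total in range(0, 61):
                for s1 in range(total + 1):
                    got = _exact_pvalue(s1, total - s1, n1, n2, 0.0)
                    want = binom_oracle(s1, total - s1, n1, n2)
                    assert abs(got - want) < 1e-6, (n1, n2, s1, total)

    def test_test_contrast_poisson_limit_through_full_path(self):
        rng = np.random.default_rng(17)
        arr = rng.poisson(100, size=(40, 6))
        # equalize library sizes exactly with a balancing gene
        pad = arr.sum(axis=0).max() - arr.sum(axis=0)
        arr = np.vstack([arr, pad])
        counts, design = make_two_group(arr, reps=3)
        res = pl.test_contrast(counts, design, unit_factors(counts),
                               fixed_dispersions(counts, 0.0), "A", "T", "H")
        tab = res.table.set_index("gene_id")
        treat = [s for s in counts.sample_ids if "_H_" in s]
        ctrl = [s for s in counts.sample_ids if "_N_" in s]
        for g in counts.gene_ids:
            s1 = int(counts.values.loc[g, treat].sum())
            s2 = int(counts.values.loc[g, ctrl].sum())
            assert abs(tab.loc[g, "pvalue"] - binom_oracle(s1, s2, 3, 3)) < 1e-6

    def test_null_pvalues_approximately_uniform(self):
        rng = np.random.default_rng(30)
        phi = 0.1
        means = np.full(2000, 300.0)
        lam = rng.gamma(1 / phi, phi * np.tile(means[:, None], (1, 6)))
        arr = rng.poisson(lam)
        counts, design = make_two_group(arr, reps=3)
        disp = pl.estimate_dispersions(counts, design, unit_factors(counts))
        res = pl.test_contrast(counts, design, unit_factors(counts), disp, "A", "T", "H")
        frac = (res.table["pvalue"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_planted_fold_change_recovered(self):
        rng = np.random.default_rng(31)
        phi, mean, fc = 0.05, 500.0, 4.0
        n_planted, n_null, reps = 300, 2700, 4
        lam_c = rng.gamma(1 / phi, phi * np.full((n_planted, reps), mean))
        lam_t = rng.gamma(1 / phi, phi * np.full((n_planted, reps), mean * fc))
        planted = np.hstack([rng.poisson(lam_c), rng.poisson(lam_t)])
        lam_bg = rng.gamma(1 / phi, phi * np.full((n_null, 2 * reps), mean))
        arr = np.vstack([planted, rng.poisson(lam_bg)])
        counts, design = make_two_group(arr, reps=reps)
        factors = pl.tmm_factors(counts)  # corrects the composition shift
        disp = fixed_dispersions(counts, phi)
        res = pl.test_contrast(counts, design, factors, disp, "A", "T", "H")
        planted_fc = res.table["log2FC"].to_numpy()[:n_planted]
        assert abs(np.median(planted_fc) - 2.0) < 0.15

    def test_log2fc_antisymmetry(self):
        rng = np.random.default_rng(40)
        arr = rng.poisson(80, size=(30, 6))
        counts, design = make_two_group(arr, reps=3)
        disp = fixed_dispersions(counts, 0.1)
        fwd = pl.test_contrast(counts, design, unit_factors(counts), disp,
                               "A", "T", "H", control="N")
        rev = pl.test_contrast(counts, design, unit_factors(counts), disp,
                               "A", "T", "N", control="H")
        assert np.allclose(fwd.table["log2FC"], -rev.table["log2FC"], atol=1e-12)

    def test_replicate_relabeling_invariance(self):
        rng = np.random.default_rng(41)
        arr = rng.poisson(60, size=(20, 6))
        counts, design = make_two_group(arr, reps=3)
        disp = fixed_dispersions(counts, 0.1)
        a = pl.test_contrast(counts, design, unit_factors(counts), disp, "A", "T", "H")
        # swap replicate labels 1 and 3 within the treatment group
        tab = design.table.copy()
        mask = tab["treatment"] == "H"
        tab.loc[mask, "replicate"] = tab.loc[mask, "replicate"].map({1: 3, 2: 2, 3: 1})
        b = pl.test_contrast(counts, pl.SampleDesign(tab), unit_factors(counts),
                             disp, "A", "T", "H")
        assert np.allclose(a.table["pvalue"], b.table["pvalue"], atol=1e-12)

    def test_empty_group_rejected(self, toy_counts):
        arr = np.array([[5, 6, 7, 8]])
        counts, design = make_two_group(arr, reps=2)
        with pytest.raises(DiffExprError, match="empty group"):
            pl.test_contrast(counts, design, unit_factors(counts),
                             fixed_dispersions(counts, 0.0), "A", "T", "X")

    def test_gene_universe_mismatch_rejected(self):
        arr = np.array([[5, 6, 7, 8], [1, 2, 3, 4]])
        counts, design = make_two_group(arr, reps=2)
        bad = pl.DispersionEstimates(("other",), 0.0, np.zeros(1), 0.0)
        with pytest.raises(DiffExprError, match="universe"):
            pl.test_contrast(counts, design, unit_factors(counts), bad, "A", "T", "H")


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
def test_bh_property_matches_statsmodels(pvals):
    from statsmodels.stats.multitest import multipletests

    got = pl.bh_adjust(pvals)
    _, sm, _, _ = multipletests(pvals, method="fdr_bh")
    assert np.allclose(got, sm, atol=1e-12)
    assert ((got >= 0) & (got <= 1)).all()
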