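import subprocess
import textwrap

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata

from dgecompare.diffexp import (
    bh_fdr,
    degs_vs_depth,
    equalize_lib_sizes,
    estimate_dispersion,
    nb_exact_test,
    run_de,
    tmm_factors,
)
from dgecompare.simulate import SimulationConfig, simulate_paired_experiment
from .conftest import make_matrix


def _reference_tmm_factor(y_k, y_r, trim_m=0.3, trim_a=0.05):
    """Independent straight-line TMM for one sample vs a reference."""
    nk, nr = y_k.sum(), y_r.sum()
    ok = (y_k > 0) & (y_r > 0)
    yk, yr = y_k[ok], y_r[ok]
    m = np.log2((yk / nk) / (yr / nr))
    a = 0.5 * np.log2((yk / nk) * (yr / nr))
    w = (nk - yk) / (nk * yk) + (nr - yr) / (nr * yr)
    n = m.size
    rm, ra = rankdata(m), rankdata(a)
    keep = (
        (rm >= np.floor(n * trim_m) + 1)
        & (rm <= n + 1 - np.floor(n * trim_m))
        & (ra >= np.floor(n * trim_a) + 1)
        & (ra <= n + 1 - np.floor(n * trim_a))
    )
    return 2 ** (np.sum(m[keep] / w[keep]) / np.sum(1 / w[keep]))


class TestTMM:
    def test_identical_samples_give_unit_factors(self):
        y = np.tile(np.arange(1, 51)[:, None], (1, 3))
        assert np.allclose(tmm_factors(y), 1.0)

    def test_pure_depth_change_gives_unit_factors(self):
        rng = np.random.default_rng(0)
        col = rng.poisson(100, 200) + 1
        y = np.column_stack([col, col * 3])
        assert np.allclose(tmm_factors(y), 1.0)

    def test_spiked_sample_matches_independent_oracle(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(200, 20) + 10
        spiked = base.copy()
        spiked[0] *= 10
        y = np.column_stack([base, spiked])
        factors = tmm_factors(y, reference=0)
        ref = _reference_tmm_factor(spiked.astype(float), base.astype(float))
        # factors are geomean-normalized; the ratio is scale-free
        assert factors[1] / factors[0] == pytest.approx(ref, abs=1e-6)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            tmm_factors(np.array([[1, 0], [2, 0]]))

    def test_agrees_with_edger_calcnormfactors(self, tmp_path):
        rng = np.random.default_rng(7)
        mu = rng.lognormal(4, 1.5, 300)
        y = rng.poisson(mu[:, None] * rng.uniform(0.5, 2.0, 4)[None, :])
        y[y == 0] += 1
        np.savetxt(tmp_path / "y.tsv", y, fmt="%d", delimiter="\t")
        script = textwrap.dedent("""
            suppressMessages(library(edgeR))
            y <- as.matrix(read.delim("y.tsv", header=FALSE))
            f <- calcNormFactors(y, method="TMM")
            cat(f, sep="\\n")
        """)
        (tmp_path / "tmm.R").write_text(script)
        out = subprocess.run(
            ["Rscript", "tmm.R"], cwd=tmp_path, capture_output=True, text=True, check=True
        )
        edger = np.array([float(v) for v in out.stdout.split()])
        ours = tmm_factors(y)
        assert np.allclose(ours, edger, rtol=0.02)


class TestDispersion:
    def test_poisson_data_estimates_near_zero(self):
        rng = np.random.default_rng(2)
        mu = rng.lognormal(4, 1, 5000)
        y = rng.poisson(mu[:, None], size=(5000, 12))
        est = estimate_dispersion(y, np.array(["a"] * 8 + ["b"] * 4), tagwise=False)
        assert est.common_dispersion < 0.01

    def test_nb_dispersion_recovered_within_20_percent(self):
        rng = np.random.default_rng(3)
        phi, r = 0.1, 10.0
        estimates = []
        for _ in range(5):
            mu = rng.lognormal(4, 1.5, 3000)
            y = rng.negative_binomial(r, r / (r + mu[:, None]), size=(3000, 12))
            est = estimate_dispersion(y, np.array(["a"] * 8 + ["b"] * 4), tagwise=False)
            estimates.append(est.common_dispersion)
        assert abs(np.median(estimates) - phi) / phi < 0.2

    def test_tagwise_shrinks_toward_common(self):
        rng = np.random.default_rng(4)
        r = 10.0
        mu = rng.lognormal(4, 1, 1000)
        y = rng.negative_binomial(r, r / (r + mu[:, None]), size=(1000, 8))
        est = estimate_dispersion(y, np.array(["a"] * 4 + ["b"] * 4), tagwise=True)
        # raw per-gene ML estimates (prior weight 0) spread much wider
        raw = estimate_dispersion(y, np.array(["a"] * 4 + ["b"] * 4),
                                  tagwise=True, prior_n=0.0)
        assert est.tagwise.std() < raw.tagwise.std()

    def test_no_replication_rejected(self):
        with pytest.raises(ValueError, match="single sample"):
            estimate_dispersion(np.ones((10, 2), dtype=int), np.array(["a", "b"]))


class TestExactTest:
    def test_poisson_limit_reduces_to_binomial(self):
        # phi=0, equal libs, totals 3 vs 7 -> 2 P(X<=3 | n=10, 1/2) = 0.34375
        p = nb_exact_test(np.array([[3]]), np.array([[7]]), 0.0)
        assert p[0] == pytest.approx(0.34375, abs=1e-10)

    def test_identical_totals_give_p_one(self):
        p = nb_exact_test(np.array([[5, 5]]), np.array([[6, 4]]), 0.2)
        assert p[0] == 1.0

    def test_symmetric_under_group_swap(self):
        rng = np.random.default_rng(5)
        a = rng.poisson(30, (50, 3))
        b = rng.poisson(30, (50, 4))
        assert np.allclose(nb_exact_test(a, b, 0.15), nb_exact_test(b, a, 0.15))

    def test_null_p_values_near_uniform(self):
        rng = np.random.default_rng(6)
        r = 10.0  # phi = 0.1
        mu = rng.lognormal(4, 1, 4000)
        pm = r / (r + mu[:, None])
        a = rng.negative_binomial(r, pm, size=(4000, 4))
        b = rng.negative_binomial(r, pm, size=(4000, 4))
        p = nb_exact_test(a, b, 0.1)
        # CDF within a tolerance band of uniform (discreteness makes it conservative)
        for q in (0.05, 0.25, 0.5):
            assert (p <= q).mean() <= q + 0.03

    def test_agrees_with_edger_exact_test(self, tmp_path):
        rng = np.random.default_rng(8)
        r = 5.0  # phi = 0.2
        mu = rng.lognormal(3, 1, 200)
        pm = r / (r + mu[:, None])
        a = rng.negative_binomial(r, pm, size=(200, 4))
        b = rng.negative_binomial(r, pm, size=(200, 3))
        np.savetxt(tmp_path / "a.tsv", a, fmt="%d", delimiter="\t")
        np.savetxt(tmp_path / "b.tsv", b, fmt="%d", delimiter="\t")
        script = textwrap.dedent("""
            suppressMessages(library(edgeR))
            a <- as.matrix(read.delim("a.tsv", header=FALSE))
            b <- as.matrix(read.delim("b.tsv", header=FALSE))
            p <- edgeR:::exactTestDoubleTail(a, b, dispersion=0.2)
            cat(p, sep="\\n")
        """)
        (tmp_path / "et.R").write_text(script)
        out = subprocess.run(
            ["Rscript", "et.R"], cwd=tmp_path, capture_output=True, text=True, check=True
        )
        edger = np.array([float(v) for v in out.stdout.split()])
        ours = nb_exact_test(a, b, 0.2)
        # edgeR interpolates a continuous pmf; agreement is close but not exact
        assert np.corrcoef(np.log(ours), np.log(edger))[0, 1] > 0.999
        assert np.median(np.abs(ours - edger)) < 0.01


class TestBH:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.03], [0.03]),
            ([0.01, 0.02, 0.03, 0.5], [0.04, 0.04, 0.04, 0.5]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ],
    )
    def test_hand_computed_step_up(self, p, expected):
        assert np.allclose(bh_fdr(np.array(p)), expected)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=40))
    def test_matches_brute_force_step_up(self, p):
        p = np.array(p)
        m = p.size
        order = np.argsort(p)
        brute = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            brute[i] = running
        assert np.allclose(bh_fdr(p), brute)


@pytest.fixture(scope="module")
def de_experiment():
    cfg = SimulationConfig(
        n_genes=3000, n_control=6, n_treated=4, library_size_mean=8e5,
        dispersion=0.1, n_de_genes=400, de_log2fc_mean=2.0, de_log2fc_sd=0.3,
        detection_dropout=0.0, seed=31,
    )
    conv, _, _, truth = simulate_paired_experiment(cfg)
    return conv, truth


class TestRunDE:
    def test_null_contrast_finds_almost_nothing(self):
        cfg = SimulationConfig(
            n_genes=3000, n_control=6, n_treated=4, library_size_mean=8e5,
            dispersion=0.1, n_de_genes=0, detection_dropout=0.0, seed=32,
        )
        conv, _, _, _ = simulate_paired_experiment(cfg)
        res = run_de(conv, ("TRT", "CTRL"))
        assert res.n_deg_at_cutoff <= 5

    def test_positive_contrast_finds_true_effects(self, de_experiment):
        conv, truth = de_experiment
        res = run_de(conv, ("TRT", "CTRL"))
        true_de = set(np.asarray(truth.gene_ids)[truth.is_de])
        deg = set(res.deg_genes)
        assert len(deg) > 200
        recovery = len(deg & true_de) / len(true_de)
        false_frac = len(deg - true_de) / len(deg)
        assert recovery > 0.5
        assert false_frac < 0.2  # FDP near the nominal 0.1

    def test_log2fc_sign_matches_truth(self, de_experiment):
        conv, truth = de_experiment
        res = run_de(conv, ("TRT", "CTRL"))
        t = res.table.set_index("gene_id")
        strong = np.asarray(truth.gene_ids)[truth.is_de & (np.abs(truth.true_log2fc) > 1)]
        strong = [g for g in strong if g in t.index and t.loc[g, "fdr"] < 0.1]
        truth_lfc = dict(zip(truth.gene_ids, truth.true_log2fc))
        agree = np.mean([np.sign(t.loc[g, "log2fc"]) == np.sign(truth_lfc[g]) for g in strong])
        assert agree > 0.95

    def test_permuted_labels_collapse_deg_count(self, de_experiment):
        conv, _ = de_experiment
        rng = np.random.default_rng(0)
        # permute treatments across samples, balanced within the permutation
        perm = rng.permutation([s.treatment for s in conv.samples])
        shuffled = make_matrix(conv.counts, treatments=list(perm))
        res_perm = run_de(shuffled, ("TRT", "CTRL"))
        res_true = run_de(conv, ("TRT", "CTRL"))
        assert res_perm.n_deg_at_cutoff < 0.1 * res_true.n_deg_at_cutoff

    def test_fdr_cutoff_one_declares_everything(self, de_experiment):
        conv, _ = de_experiment
        res = run_de(conv, ("TRT", "CTRL"), fdr_cutoff=1.0000001)
        assert res.n_deg_at_cutoff == len(res.table)

    def test_empty_group_rejected(self, de_experiment):
        conv, _ = de_experiment
        with pytest.raises(ValueError, match="empty group"):
            run_de(conv, ("MISSING", "CTRL"))


class TestDegsVsDepth:
    def test_zero_depth_zero_degs_and_monotone_trend(self):
        cfg = SimulationConfig(
            n_genes=1500, n_control=4, n_treated=4, library_size_mean=4e5,
            dispersion=0.1, n_de_genes=300, de_log2fc_mean=2.0, de_log2fc_sd=0.0,
            detection_dropout=0.0, seed=33,
        )
        conv, _, _, _ = simulate_paired_experiment(cfg)
        full = int(conv.column_sums().min())
        grid = np.array([0, full // 50, full // 5, full])
        table = degs_vs_depth(conv, ("TRT", "CTRL"), grid, seed=1)
        assert table.loc[0, "mean_degs"] == 0
        degs = table["mean_degs"].to_numpy()
        assert degs[-1] > degs[1]
        # overall increasing trend across the grid
        assert np.all(np.diff(degs) >= -0.05 * degs.max())
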