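import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from omicsnet.io_formats import MultiOmicsDataset, OmicsLayer
from omicsnet.synthetic_data import SimConfig, generate_dataset
from omicsnet.vif_regression import (VIFConfig, adjusted_r2,
                                     count_candidates, fit_all, fit_gene)

from conftest import make_dataset


class TestAdjustedR2:
    @pytest.mark.parametrize("r2,n,p,expected", [
        (1.0, 50, 5, 1.0),
        (0.0, 100, 0, 0.0),
        (0.5, 10, 2, 1 - 0.5 * 9 / 7),
    ])
    def test_known_values(self, r2, n, p, expected):
        assert adjusted_r2(r2, n, p) == pytest.approx(expected, abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            adjusted_r2(0.5, 5, 4)

    @given(r2a=st.floats(0, 1), r2b=st.floats(0, 1),
           n=st.integers(10, 500), p=st.integers(1, 8))
    @settings(max_examples=200, derandomize=True)
    def test_monotone_in_r2_and_never_above_r2(self, r2a, r2b, n, p):
        lo, hi = sorted((r2a, r2b))
        assert adjusted_r2(lo, n, p) <= adjusted_r2(hi, n, p) + 1e-12
        assert adjusted_r2(r2a, n, p) <= r2a + 1e-12


class TestCountCandidates:
    def test_paper_scale_sum(self):
        def layer(tag, k):
            fill = 0.5 if tag == "methylation" else 0.0
            return OmicsLayer(tag, pd.DataFrame(
                np.full((k, 2), fill),
                index=[f"{tag}{i}" for i in range(k)], columns=["A", "B"]))

        ds = MultiOmicsDataset(layer("mrna", 1), layer("mirna", 437),
                               layer("methylation", 18498),
                               layer("cnv", 24174), ["A", "B"])
        assert count_candidates(ds) == 43109

    def test_small_sum(self):
        ds, _ = generate_dataset(SimConfig(n_genes=5, n_mirna=50, n_meth=200,
                                           n_cnv=200, n_samples=20))
        assert count_candidates(ds) == 450


class TestFitGene:
    def test_perfect_predictor_recovered_with_adj_r2_one(self, rng):
        x = rng.normal(size=60)
        ds = make_dataset(mrna={"T": 2.5 * x + 1.0},
                          mirna={"m0": x, "m1": rng.normal(size=60)})
        res = fit_gene(ds, "T", VIFConfig(seed=0))
        assert res.selected_nodes() == ["mirna:m0"]
        assert res.adj_r2 == pytest.approx(1.0)
        assert res.selected[0][1] == pytest.approx(2.5)
        assert res.intercept == pytest.approx(1.0)

    def test_missing_gene_raises_key_error(self, rng):
        ds = make_dataset(mrna={"T": rng.normal(size=20)})
        with pytest.raises(KeyError):
            fit_gene(ds, "NOPE")

    def test_too_few_samples_flagged_unusable(self, rng):
        ds = make_dataset(mrna={"T": rng.normal(size=5)},
                          mirna={"m": rng.normal(size=5)})
        res = fit_gene(ds, "T")
        assert not res.usable and res.n_used == 5

    def test_constant_target_gives_empty_model(self, rng):
        ds = make_dataset(mrna={"T": np.full(30, 4.0)},
                          mirna={"m": rng.normal(size=30)})
        res = fit_gene(ds, "T")
        assert res.selected == [] and res.adj_r2 == 0.0 and res.usable

    def test_missing_values_drop_samples_for_that_model_only(self, rng):
        y = rng.normal(size=40)
        y[3] = np.nan
        ds = make_dataset(mrna={"T": y, "U": rng.normal(size=40)},
                          mirna={"m": rng.normal(size=40)})
        assert fit_gene(ds, "T").n_used == 39
        assert fit_gene(ds, "U").n_used == 40

    def test_every_streamed_candidate_costs_one_test(self, rng):
        """Zero-variance candidates are skipped; all others each spend
        exactly one hypothesis test on a pure-noise target."""
        ds = make_dataset(
            mrna={"T": rng.normal(size=80)},
            mirna={f"m{i}": rng.normal(size=80) for i in range(12)},
            cnv={"flat": np.zeros(80)})
        res = fit_gene(ds, "T", VIFConfig(seed=1))
        assert res.n_candidates == 14  # 12 miRNA + flat cnv + meth pad
        assert res.n_tests == 12       # two constant columns skipped

    def test_true_regulators_selected_in_strong_signal(self):
        """Three planted regulators out of 650 candidates are all found and
        agree with the exhaustive best size-3 subset over a reduced pool."""
        cfg = SimConfig(seed=104, n_samples=200, k_min=3, k_max=3,
                        target_r2=0.7, frac_regulated=0.1)
        ds, truth = generate_dataset(cfg)
        gene = truth.regulated_genes()[0]
        res = fit_gene(ds, gene, VIFConfig(seed=4))
        tset = truth.edges_of(gene)
        assert tset <= set(res.selected_nodes())

        # brute-force oracle: best subset of size 3 over 20 candidates
        # (the 3 true regulators plus 17 decoys)
        from omicsnet.vif_regression import candidate_design
        import itertools
        nodes, X = candidate_design(ds)
        decoys = [n for n in nodes if n not in tset][:17]
        pool = sorted(tset) + decoys
        y = ds.mrna.values.loc[gene].to_numpy()
        best, best_a = None, -np.inf
        for S in itertools.combinations(range(len(pool)), 3):
            D = np.column_stack([np.ones(len(y))]
                                + [ds.node_values(pool[j]) for j in S])
            b, *_ = np.linalg.lstsq(D, y, rcond=None)
            r = y - D @ b
            r2 = 1 - (r @ r) / ((y - y.mean()) ** 2).sum()
            a = adjusted_r2(max(0.0, min(1.0, r2)), len(y), 3)
            if a > best_a:
                best, best_a = {pool[j] for j in S}, a
        assert best == tset


class TestFitAll:
    def test_result_count_and_subset_order(self):
        ds, _ = generate_dataset(SimConfig(seed=1, n_genes=12, n_mirna=5,
                                           n_meth=12, n_cnv=12, n_samples=60))
        assert len(fit_all(ds)) == 12
        subset = ["G0005", "G0002", "G0009"]
        res = fit_all(ds, gene_subset=subset)
        assert [r.target_gene for r in res] == subset

    def test_worker_count_does_not_change_selection(self):
        ds, _ = generate_dataset(SimConfig(seed=5, n_genes=10, n_mirna=10,
                                           n_meth=30, n_cnv=30, n_samples=80))
        a = fit_all(ds, VIFConfig(seed=5), n_jobs=1)
        b = fit_all(ds, VIFConfig(seed=5), n_jobs=2)
        assert [r.selected for r in a] == [r.selected for r in b]
        assert [r.adj_r2 for r in a] == [r.adj_r2 for r in b]

    def test_per_gene_failure_is_flagged_not_raised(self, rng):
        ds = make_dataset(mrna={"T": rng.normal(size=30)},
                          mirna={"m": rng.normal(size=30)})
        res = fit_all(ds, gene_subset=["T", "GHOST"])
        assert res[0].usable
        assert not res[1].usable and "KeyError" in res[1].message
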