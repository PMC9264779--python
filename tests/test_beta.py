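import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import fishdiv as fd

COMPONENTS = fd.beta.COMPONENTS


valid_counts = st.tuples(
    st.integers(0, 60), st.integers(0, 60), st.integers(0, 60)
).filter(lambda t: t[0] + t[1] >= 1 and t[0] + t[2] >= 1)


class TestPairCounts:
    def test_identical_sites(self):
        assert fd.pair_counts([1] * 5, [1] * 5) == (5, 0, 0)

    def test_disjoint_sites(self):
        assert fd.pair_counts([1, 1, 0, 0, 0], [0, 0, 1, 1, 1]) == (0, 2, 3)

    def test_partial_overlap(self):
        # sites {1,2,3} and {2,3,4,5,6}
        u = [1, 1, 1, 0, 0, 0]
        v = [0, 1, 1, 1, 1, 1]
        assert fd.pair_counts(u, v) == (2, 1, 3)

    def test_empty_site_rejected(self):
        with pytest.raises(fd.ValidationError):
            fd.pair_counts([0, 0], [1, 0])


class TestDecomposePair:
    def test_hand_computed_case(self):
        out = fd.decompose_pair(fd.PairCounts(2, 1, 3))
        assert out["beta_sor"] == pytest.approx(0.5)
        assert out["beta_sim"] == pytest.approx(1 / 3)
        assert out["beta_sne"] == pytest.approx(1 / 6)
        assert out["beta_jac"] == pytest.approx(2 / 3)
        assert out["beta_jtu"] == pytest.approx(0.5)
        assert out["beta_jne"] == pytest.approx(1 / 6)

    def test_identical_assemblages_all_zero(self):
        out = fd.decompose_pair(fd.PairCounts(5, 0, 0))
        assert all(v == 0.0 for v in out.values())

    def test_perfect_nesting_has_zero_turnover(self):
        out = fd.decompose_pair(fd.PairCounts(4, 0, 3))
        assert out["beta_sim"] == 0.0 and out["beta_jtu"] == 0.0
        assert out["beta_sor"] == pytest.approx(3 / 11)

    @given(valid_counts)
    def test_additivity_and_ordering(self, abc):
        """Turnover + nestedness reconstructs the total in both families."""
        out = fd.decompose_pair(fd.PairCounts(*abc))
        assert abs(out["beta_sor"] - out["beta_sim"] - out["beta_sne"]) < 1e-12
        assert abs(out["beta_jac"] - out["beta_jtu"] - out["beta_jne"]) < 1e-12
        assert out["beta_sim"] <= out["beta_sor"] + 1e-12
        assert out["beta_sor"] <= out["beta_jac"] + 1e-12
        assert all(-1e-12 <= v <= 1 + 1e-12 for v in out.values())


class TestPairwiseMatrices:
    def test_two_site_matrix_matches_single_pair(self):
        frame = pd.DataFrame({"x": [1, 1, 1, 0, 0, 0], "y": [0, 1, 1, 1, 1, 1]},
                             index=pd.Index([f"s{i}" for i in range(6)],
                                            name="species_id"))
        mats = fd.pairwise_matrices(fd.OccurrenceMatrix(frame))
        single = fd.decompose_pair(fd.PairCounts(2, 1, 3))
        for comp in COMPONENTS:
            assert mats[comp].loc["x", "y"] == pytest.approx(single[comp])
            assert mats[comp].loc["y", "x"] == pytest.approx(single[comp])
            assert mats[comp].loc["x", "x"] == 0.0

    def test_nested_chain_zero_turnover_everywhere(self, nested_chain):
        mats = fd.pairwise_matrices(nested_chain)
        assert np.allclose(mats["beta_sim"].to_numpy(), 0.0)
        assert np.allclose(mats["beta_jtu"].to_numpy(), 0.0)

    def test_site_relabeling_equivariance(self, guangxi_data):
        _, mx = guangxi_data
        mats = fd.pairwise_matrices(mx)
        perm = list(reversed(mx.sites))
        mx2 = fd.OccurrenceMatrix(mx.frame[perm], mx.checklist)
        mats2 = fd.pairwise_matrices(mx2)
        for comp in COMPONENTS:
            pd.testing.assert_frame_equal(
                mats[comp].loc[perm, perm], mats2[comp])


class TestSiteSummary:
    def test_equidistant_sites(self):
        frame = pd.DataFrame({"a": [1, 1, 0, 0], "b": [0, 1, 1, 0],
                              "c": [0, 0, 1, 1], "d": [1, 0, 0, 1]},
                             index=pd.Index([f"s{i}" for i in range(4)],
                                            name="species_id"))
        mats = fd.pairwise_matrices(fd.OccurrenceMatrix(frame))
        summ = fd.site_summary(mats)
        # grand mean of per-site means equals grand pairwise mean
        iu = np.triu_indices(4, 1)
        grand = mats["beta_sor"].to_numpy()[iu].mean()
        assert summ["beta_sor_mean"].mean() == pytest.approx(grand)

    def test_depauperate_nested_site_has_max_total_dissimilarity(self):
        # one tiny site nested inside three nearly identical rich sites
        frame = pd.DataFrame({
            "rich1": [1] * 10,
            "rich2": [1] * 9 + [0],
            "rich3": [0] + [1] * 9,
            "poor": [1, 1] + [0] * 8,
        }, index=pd.Index([f"s{i}" for i in range(10)], name="species_id"))
        mats = fd.pairwise_matrices(fd.OccurrenceMatrix(frame))
        summ = fd.site_summary(mats)
        assert summ["beta_sor_mean"].idxmax() == "poor"


class TestMultiSite:
    def test_two_site_reduction(self):
        x = np.array([[1, 1, 1, 0, 0, 0], [0, 1, 1, 1, 1, 1]], dtype=bool)
        ms = fd.multi_site(x)
        pairwise = fd.decompose_pair(fd.PairCounts(2, 1, 3))
        for comp in COMPONENTS:
            assert getattr(ms, comp) == pytest.approx(pairwise[comp])

    def test_nested_chain_turnover_zero(self, nested_chain):
        assert fd.multi_site(nested_chain).beta_sim == 0.0

    def test_additivity_on_preset(self, guangxi_data):
        _, mx = guangxi_data
        ms = fd.multi_site(mx)
        assert ms.beta_sor == pytest.approx(ms.beta_sim + ms.beta_sne, abs=1e-12)
        assert ms.beta_jac == pytest.approx(ms.beta_jtu + ms.beta_jne, abs=1e-12)

    def test_vegan_multisite_oracle(self, tmp_path):
        """Cross-check the Sorensen-family multi-site split against vegan."""
        if shutil.which("Rscript") is None:
            pytest.xfail("Rscript not on PATH")
        rng = np.random.default_rng(21)
        x = (rng.random((5, 14)) < 0.45).astype(int)
        x[:, 0] = 1  # no empty site
        np.savetxt(tmp_path / "comm.csv", x, fmt="%d", delimiter=",")
        script = textwrap.dedent("""
            suppressMessages(library(vegan))
            x <- as.matrix(read.csv("comm.csv", header=FALSE))
            v <- nestedbetasor(x)
            cat(sprintf("%.12f %.12f %.12f", v[1], v[2], v[3]))
        """)
        (tmp_path / "oracle.R").write_text(script)
        out = subprocess.run(["Rscript", "oracle.R"], cwd=tmp_path,
                             capture_output=True, text=True, check=True)
        turn, nest, total = map(float, out.stdout.split())
        ms = fd.multi_site(x.astype(bool))
        assert ms.beta_sim == pytest.approx(turn, abs=1e-10)
        assert ms.beta_sne == pytest.approx(nest, abs=1e-10)
        assert ms.beta_sor == pytest.approx(total, abs=1e-10)

    def test_vegan_pairwise_oracle(self, tmp_path):
        """Pairwise beta_sor/beta_sim match vegan::betadiver w and sim."""
        if shutil.which("Rscript") is None:
            pytest.xfail("Rscript not on PATH")
        rng = np.random.default_rng(22)
        x = (rng.random((4, 12)) < 0.5).astype(int)
        x[:, 0] = 1
        np.savetxt(tmp_path / "comm.csv", x, fmt="%d", delimiter=",")
        script = textwrap.dedent("""
            suppressMessages(library(vegan))
            x <- as.matrix(read.csv("comm.csv", header=FALSE))
            w <- as.matrix(betadiver(x, "w"))
            s <- as.matrix(betadiver(x, "sim"))
            write.csv(w, "w.csv"); write.csv(s, "s.csv")
        """)
        (tmp_path / "oracle.R").write_text(script)
        subprocess.run(["Rscript", "oracle.R"], cwd=tmp_path,
                       capture_output=True, text=True, check=True)
        frame = pd.DataFrame(x.T, columns=list("abcd"),
                             index=pd.Index([f"s{i}" for i in range(12)],
                                            name="species_id"))
        mats = fd.pairwise_matrices(fd.OccurrenceMatrix(frame))
        w = pd.read_csv(tmp_path / "w.csv", index_col=0).to_numpy()
        s = pd.read_csv(tmp_path / "s.csv", index_col=0).to_numpy()
        assert np.allclose(mats["beta_sor"].to_numpy(), w, atol=1e-10)
        assert np.allclose(mats["beta_sim"].to_numpy(), s, atol=1e-10)


class TestResampling:
    def test_full_subset_sd_zero(self, guangxi_data):
        _, mx = guangxi_data
        out = fd.resample_multi_site(mx, subset_size=mx.n_sites, seed=1)
        assert (out["sd"] == 0.0).all()

    def test_same_seed_identical(self, guangxi_data):
        _, mx = guangxi_data
        a = fd.resample_multi_site(mx, n_resamples=30, seed=5)
        b = fd.resample_multi_site(mx, n_resamples=30, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_nested_fixture_resampled_turnover_zero(self, nested_chain):
        out = fd.resample_multi_site(nested_chain, n_resamples=20,
                                     subset_size=2, seed=3)
        assert out.loc["beta_sim", "mean"] == 0.0
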