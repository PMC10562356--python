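"""Redundancy-index attribution and empirical risk summaries."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

import forcarb_uq as f
from forcarb_uq.attribution import encode_features
from forcarb_uq.engine import EnsembleResult

YEARS = [2015, 2035, 2050]


def make_ensemble(harvest, nbe_by_sim, features_extra=None, rcp="RCP4.5",
                  gcm=None, n_regions=1, seed=0):
    """Minimal hand-built ensemble for attribution tests."""
    rng = np.random.default_rng(seed)
    n_sim = len(nbe_by_sim)
    nbe = np.tile(np.asarray(nbe_by_sim, dtype=float),
                  (n_regions, len(YEARS), 1))
    regions = [f"{i + 1:02d}" for i in range(n_regions)]
    data = xr.Dataset(
        {"nbe": (("region", "year", "sim"), nbe),
         "vol0": (("region", "sim"), rng.normal(120, 5, (n_regions, n_sim))),
         "age0": (("region", "sim"), rng.normal(60, 3, (n_regions, n_sim)))},
        coords={"region": regions, "year": YEARS, "sim": np.arange(n_sim)})
    feats = pd.DataFrame({
        "RCP": rcp, "Harv": harvest,
        "GCM": gcm if gcm is not None else rng.choice(list(f.GCMS), n_sim),
        "vol0": data.vol0.isel(region=0).to_numpy(),
        "age0": data.age0.isel(region=0).to_numpy(),
    }, index=pd.RangeIndex(n_sim, name="sim"))
    if features_extra:
        for k, v in features_extra.items():
            feats[k] = v
    return EnsembleResult(data=data, features=feats,
                          region_areas_km2=np.full(n_regions, 10.0),
                          rcp=rcp, harvest=harvest)


class TestRedundancyIndex:
    def test_perfect_redundancy(self):
        x = np.random.default_rng(0).normal(size=200)
        assert f.redundancy_index(x, x) == pytest.approx(1.0, abs=1e-9)

    def test_independent_feature_vanishes(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=10_000), rng.normal(size=10_000)
        assert f.redundancy_index(x, y) <= 0.02

    def test_known_correlation_gives_r_squared(self):
        rng = np.random.default_rng(2)
        n, r = 10_000, 0.6
        x = rng.normal(size=n)
        y = r * x + np.sqrt(1 - r ** 2) * rng.normal(size=n)
        assert f.redundancy_index(x, y) == pytest.approx(0.36, abs=0.03)

    def test_duplicated_column_identical_index(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=500)
        y = 0.5 * x + rng.normal(size=500)
        assert f.redundancy_index(x, y) == f.redundancy_index(x.copy(), y)

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=800)
        y = 0.4 * x + rng.normal(size=800)
        base = f.redundancy_index(x, y)
        assert f.redundancy_index(3.0 * x - 7.0, y) == pytest.approx(base, rel=1e-9)
        assert f.redundancy_index(x, -0.5 * y + 2.0) == pytest.approx(base, rel=1e-9)

    def test_multicolumn_block_equals_regression_r2(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(2000, 3))
        y = X @ np.array([0.5, -0.3, 0.1]) + rng.normal(size=2000)
        # independent oracle: OLS coefficient of determination
        Xc = np.column_stack([np.ones(2000), X])
        resid = y - Xc @ np.linalg.lstsq(Xc, y, rcond=None)[0]
        r2 = 1.0 - resid.var() / y.var()
        assert f.redundancy_index(X, y) == pytest.approx(r2, abs=1e-9)

    def test_canonical_correlations_match_sklearn(self):
        from sklearn.cross_decomposition import CCA
        rng = np.random.default_rng(6)
        X = rng.normal(size=(500, 3))
        Y = np.column_stack([X @ [0.6, 0.1, 0.0] + 0.5 * rng.normal(size=500),
                             rng.normal(size=500)])
        ours = f.redundancy_index(X, Y)
        # oracle: explicit Stewart-Love sum from sklearn's canonical variates
        cca = CCA(n_components=2, scale=True).fit(X, Y)
        U, V = cca.transform(X, Y)
        rd = 0.0
        for k in range(2):
            rho = np.corrcoef(U[:, k], V[:, k])[0, 1]
            loadings = [np.corrcoef(Y[:, j], V[:, k])[0, 1] for j in range(2)]
            rd += rho ** 2 * np.mean(np.square(loadings))
        assert ours == pytest.approx(rd, abs=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="3 rows"):
            f.redundancy_index(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="variance"):
            f.redundancy_index(np.arange(10.0), np.ones(10))


class TestEncodeFeatures:
    def test_one_hot_arity(self):
        ens = [make_ensemble(h, np.random.default_rng(i).normal(size=100), seed=i)
               for i, h in enumerate(["LowHarv", "BaseHarv", "MaxHarv"])]
        fm, y = encode_features(ens, 2035, "nbe")
        assert fm.n_rows == 300 and y.size == 300
        harv_cols = [c for c in fm.matrix.columns if c.startswith("Harv=")]
        assert len(harv_cols) == 2  # k-1 indicators for 3 levels

    def test_constant_columns_flagged_and_dropped(self):
        ens = make_ensemble("BaseHarv", np.random.default_rng(0).normal(size=50),
                            gcm="GFDL")
        fm, _ = encode_features(ens, 2035, "nbe")
        assert not any(c.startswith(("Harv=", "RCP=", "GCM=")) for c in fm.matrix.columns)

    def test_rows_align_with_feature_values(self):
        ens = [make_ensemble("BaseHarv", np.arange(30.0), seed=1),
               make_ensemble("MaxHarv", 100 + np.arange(30.0), seed=2)]
        fm, y = encode_features(ens, 2035, "nbe")
        ind = fm.matrix["Harv=MaxHarv"].to_numpy()
        # output rows from the MaxHarv ensemble carry the indicator
        np.testing.assert_array_equal(ind == 1.0, y >= 100.0)

    def test_noharv_excluded_by_default(self):
        ens = [make_ensemble("NoHarv", np.zeros(10) + np.arange(10), seed=1),
               make_ensemble("BaseHarv", np.arange(10.0), seed=2),
               make_ensemble("MaxHarv", 1 + np.arange(10.0), seed=3)]
        fm, y = encode_features(ens, 2035, "nbe")
        assert fm.n_rows == 20
        fm2, y2 = encode_features(ens, 2035, "nbe", include_noharv=True)
        assert fm2.n_rows == 30

    def test_unknown_variable_rejected(self):
        ens = make_ensemble("BaseHarv", np.arange(10.0))
        with pytest.raises(ValueError, match="variable"):
            encode_features(ens, 2035, "nope")
        with pytest.raises(ValueError, match="year"):
            encode_features(ens, 1999, "nbe")


class TestAttributeSources:
    def test_harvest_dominates_constructed_ensemble(self):
        """Ensemble built so only the harvest scenario moves the output."""
        rng = np.random.default_rng(7)
        ens = []
        for offset, h in [(0.0, "LowHarv"), (5.0, "BaseHarv"), (10.0, "MaxHarv")]:
            nbe = offset + 0.1 * rng.normal(size=80)
            ens.append(make_ensemble(
                h, nbe, features_extra={"pCrob_resp_frac": rng.normal(size=80)},
                seed=int(offset)))
        rd = f.attribute_sources(ens, years=[2035], outputs=["nbe"], regions=[None])
        assert rd.top_feature(2035, "nbe") == "Harv"
        table = rd.table
        assert ((table["rd_ind"] >= 0) & (table["rd_ind"] <= 1)).all()

    def test_all_features_constant_yields_empty_table(self):
        ens = make_ensemble("BaseHarv", np.random.default_rng(0).normal(size=20),
                            gcm="GFDL")
        ens.features["vol0"] = 1.0
        ens.features["age0"] = 1.0
        ens.data["vol0"][:] = 1.0
        ens.data["age0"][:] = 1.0
        rd = f.attribute_sources(ens, years=[2035], outputs=["nbe"], regions=[None])
        assert rd.table.empty


class TestEcdf:
    def test_examples(self):
        assert f.ecdf_probability([1, 2, 3, 4], 2.5) == 0.5
        assert f.ecdf_probability([1, 2, 3, 4], 0.0) == 0.0
        assert f.ecdf_probability([1, 2, 3, 4], 4.0) == 1.0

    def test_normal_median(self):
        x = np.random.default_rng(0).normal(size=100_000)
        assert f.ecdf_probability(x, 0.0) == pytest.approx(0.5, abs=0.01)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            f.ecdf_probability([], 0.0)


class TestInterquantileRange:
    def test_constant_samples(self):
        assert f.interquantile_range(np.ones(100)) == 0.0

    def test_normal_closed_form(self):
        x = np.random.default_rng(1).standard_normal(1_000_000)
        assert f.interquantile_range(x, 0.95) == pytest.approx(3.92, abs=0.02)

    def test_uniform_closed_form(self):
        x = np.random.default_rng(2).random(1_000_000)
        assert f.interquantile_range(x, 0.95) == pytest.approx(0.95, abs=0.01)

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            f.interquantile_range([1.0, 2.0], 1.5)
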