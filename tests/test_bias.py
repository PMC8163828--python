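"""Bias factors against brute-force oracles, and the random-forest bias model."""

import numpy as np
import pandas as pd
import pytest

from fragsig.coverage import FragmentLengthDistribution
from fragsig.io_formats import SignalTrack
from fragsig.liquorice import (
    bin_regions,
    compute_bias_features,
    correct_coverage,
    coverage_weight_vector,
    endpoint_weight_vectors,
    gc_bias_factor,
    kmer_bias_factors,
    kmer_classes,
    mappability_bias_factors,
    train_bias_model,
)
from fragsig.liquorice.bias import FACTOR_COLUMNS
from fragsig.synthetic_data import make_fld


@pytest.fixture(scope="module")
def cwv():
    return coverage_weight_vector(make_fld(167, 28.0), 100, n_draws=200, seed=5)


class TestGCFactor:
    def test_extremes_and_n(self, cwv):
        n = len(cwv)
        assert gc_bias_factor("G" * n, cwv) == pytest.approx(1.0)
        assert gc_bias_factor("A" * n, cwv) == pytest.approx(0.0)
        assert gc_bias_factor("N" * n, cwv) == pytest.approx(0.461)

    def test_matches_weighted_mean_oracle(self, cwv, rng):
        n = len(cwv)
        seq = "".join(rng.choice(list("ACGT"), n))
        expected = sum(
            w for b, w in zip(seq, cwv.weights) if b in "GC"
        ) / cwv.total
        # oracle: positionwise 0/1 weights averaged under the vector
        oracle = np.dot([1.0 if b in "GC" else 0.0 for b in seq], cwv.weights) / cwv.total
        assert gc_bias_factor(seq, cwv) == pytest.approx(oracle)
        assert oracle == pytest.approx(expected)

    def test_short_window_is_error(self, cwv):
        with pytest.raises(ValueError):
            gc_bias_factor("ACGT", cwv)


class TestKmerFactors:
    def test_class_counts(self):
        assert len(kmer_classes(2)[0]) == 10
        assert len(kmer_classes(3)[0]) == 32
        assert len(FACTOR_COLUMNS) == 46

    def test_poly_a_concentrates_on_aa_tt(self, cwv):
        f = kmer_bias_factors("A" * len(cwv), cwv, 2)
        assert f["AA/TT"] == pytest.approx(1.0, abs=1e-3)  # final-position edge
        assert sum(v for k, v in f.items() if k != "AA/TT") < 1e-3

    def test_factors_sum_to_about_one(self, cwv, rng):
        seq = "".join(rng.choice(list("ACGT"), len(cwv)))
        for k in (2, 3):
            assert sum(kmer_bias_factors(seq, cwv, k).values()) == pytest.approx(1.0, abs=1e-3)

    def test_alternating_ac_split(self, cwv):
        seq = ("AC" * (len(cwv) // 2 + 1))[: len(cwv)]
        f = kmer_bias_factors(seq, cwv, 2)
        # positions alternate between starting AC and CA
        assert f["AC/GT"] == pytest.approx(0.5, abs=0.01)
        assert f["CA/TG"] == pytest.approx(0.5, abs=0.01)
        assert f["AC/GT"] + f["CA/TG"] == pytest.approx(1.0, abs=1e-3)

    def test_brute_force_occupancy_oracle(self, cwv, rng):
        seq = "".join(rng.choice(list("ACGT"), len(cwv)))
        got = kmer_bias_factors(seq, cwv, 3)
        names, _ = kmer_classes(3)
        comp = str.maketrans("ACGT", "TGCA")
        oracle = dict.fromkeys(names, 0.0)
        for i in range(len(seq) - 2):
            kmer = seq[i : i + 3]
            rc = kmer.translate(comp)[::-1]
            key = min(kmer, rc)
            name = key if kmer == rc else f"{key}/{key.translate(comp)[::-1]}"
            oracle[name] += cwv.weights[i]
        for name in names:
            assert got[name] == pytest.approx(oracle[name] / cwv.total, abs=1e-12)


@pytest.fixture(scope="module")
def ewv():
    return endpoint_weight_vectors(make_fld(167, 28.0), 100, n_draws=200, seed=5)


@pytest.fixture(scope="module")
def feature_rows():
    rng = np.random.default_rng(7)
    n = 400
    df = pd.DataFrame(rng.uniform(0, 1, size=(n, len(FACTOR_COLUMNS))),
                      columns=list(FACTOR_COLUMNS))
    df["region_id"] = np.repeat(np.arange(n // 80), 80)[:n]
    df["is_core"] = False
    df.loc[::20, "is_core"] = True
    return df


class TestMappabilityFactors:
    def test_constant_tracks(self, ewv):
        fw, rv = ewv
        n = len(fw) + 75
        assert mappability_bias_factors(np.ones(n), fw, rv) == pytest.approx((1, 1, 1))
        assert mappability_bias_factors(np.zeros(n), fw, rv) == pytest.approx((0, 0, 0))

    def test_step_track_matches_weighted_mean_oracle(self, ewv, rng):
        fw, rv = ewv
        n = len(fw)
        window = (rng.random(n + 75) < 0.5).astype(float)
        f, r, mx = mappability_bias_factors(window, fw, rv)
        m_fwd, m_rev = window[75:], window[:n]
        assert f == pytest.approx(np.dot(m_fwd, fw.weights) / fw.total)
        assert r == pytest.approx(np.dot(m_rev, rv.weights) / rv.total)
        mean_w = (fw.weights + rv.weights) / 2
        assert mx == pytest.approx(
            np.dot(np.maximum(m_fwd, m_rev), mean_w) / mean_w.sum()
        )


class TestBiasModel:
    def test_constant_response_predicts_constant(self, feature_rows):
        df = feature_rows.copy()
        df["coverage"] = 1.0
        model = train_bias_model(df, seed=0)
        np.testing.assert_allclose(model.predict(df), 1.0)
        np.testing.assert_allclose(correct_coverage(df, model), 0.0, atol=1e-12)

    def test_deterministic_gc_signal_is_recovered(self, feature_rows):
        df = feature_rows.copy()
        df["coverage"] = 2.0 * df["gc"]
        model = train_bias_model(df, seed=0)
        assert model.oob_r2 > 0.9

    def test_core_rows_never_trained_on(self, feature_rows):
        df = feature_rows.copy()
        df["coverage"] = 1.0
        model = train_bias_model(df, seed=0)
        assert model.n_training_rows == int((~df["is_core"]).sum())

    def test_too_few_rows_is_error(self, feature_rows):
        df = feature_rows.head(50).copy()
        df["coverage"] = 1.0
        with pytest.raises(ValueError, match="non-core"):
            train_bias_model(df)

    def test_same_seed_same_predictions(self, feature_rows, rng):
        df = feature_rows.copy()
        df["coverage"] = rng.normal(1, 0.1, len(df))
        a = train_bias_model(df, seed=11).predict(df)
        b = train_bias_model(df, seed=11).predict(df)
        np.testing.assert_array_equal(a, b)


class TestFeatureTable:
    def test_all_factors_in_unit_interval(self, tiny_genome):
        cfg = tiny_genome.config
        binned = bin_regions(
            tiny_genome.regions, {cfg.chrom: len(tiny_genome.sequence)}
        )[:2]
        fld = make_fld(167, 28.0)
        feats = compute_bias_features(
            {cfg.chrom: tiny_genome.sequence}, tiny_genome.mappability, binned, fld,
            seed=1,
        )
        vals = feats[list(FACTOR_COLUMNS)].to_numpy()
        assert np.all(vals >= 0) and np.all(vals <= 1 + 1e-9)
        assert len(feats) == 2 * 85
        # expanding shared reverse-complement classes, occupancies sum to ~1
        di = feats[[c for c in feats.columns if c.startswith("di_")]].sum(axis=1)
        tri = feats[[c for c in feats.columns if c.startswith("tri_")]].sum(axis=1)
        assert np.allclose(di, 1.0, atol=5e-3)
        assert np.allclose(tri, 1.0, atol=5e-3)
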