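"""Connectome features: Fisher z, QC filter, network means, segregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fcmega.cohort import NETWORKS, NetworkAtlas, ParcelTimeSeries, SubjectRecord, default_atlas
from fcmega.features import (ConnectivityMatrix, compute_fc, edge_vector,
                             filter_subjects, fisher_z, matrix_from_edges,
                             network_segregation, within_network_mean)


def _record(sid="s", fd=0.2, age=30.0):
    return SubjectRecord(subject_id=sid, site_id="site00", group="HC",
                         age=age, sex="F", mean_fd=fd)


def _random_fc(rng, p):
    m = rng.normal(scale=0.4, size=(p, p))
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, np.nan)
    ids = tuple(f"p{i}" for i in range(p))
    return ConnectivityMatrix(m, ids)


class TestFilterSubjects:
    def test_threshold_is_inclusive_and_age_bounds_apply(self):
        fds = [0.2, 0.56, 0.55, 0.9, 0.1]
        recs = [_record(f"s{i}", fd=fd) for i, fd in enumerate(fds)]
        kept, excluded = filter_subjects(recs)
        assert [r.subject_id for r in kept] == ["s0", "s2", "s4"]
        assert {e.reason for e in excluded} == {"high_motion"}

    @pytest.mark.parametrize("age,kept", [(17.0, False), (18.0, True),
                                          (65.0, True), (65.5, False)])
    def test_age_window(self, age, kept):
        k, e = filter_subjects([_record(age=age)])
        assert bool(k) is kept
        if not kept:
            assert e[0].reason == "age_range"

    def test_missing_covariate_recorded_not_dropped(self):
        rec = _record()
        object.__setattr__(rec, "mean_fd", float("nan"))
        kept, excluded = filter_subjects([rec])
        assert not kept
        assert excluded[0].reason == "missing_covariate"


class TestFisherZ:
    def test_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5493061443340549, abs=1e-12)
        # clipping keeps perfect correlation finite
        assert np.isfinite(fisher_z(1.0))
        assert fisher_z(1.0) == pytest.approx(np.arctanh(1 - 1e-7))

    def test_odd_function(self, rng):
        r = rng.uniform(-1, 1, size=50)
        np.testing.assert_allclose(fisher_z(r), -fisher_z(-r), atol=1e-14)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fisher_z(1.0001)


class TestComputeFc:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2, 3, 4])
        ts = ParcelTimeSeries("s", np.column_stack([x, x, x[::-1]]), ("a", "b", "c"))
        fc = compute_fc(ts)
        assert fc.values[0, 1] == pytest.approx(np.arctanh(1 - 1e-7))
        assert fc.values[0, 2] == pytest.approx(-np.arctanh(1 - 1e-7))
        assert np.isnan(fc.values).sum() == 3  # diagonal undefined
        off = ~np.eye(3, dtype=bool)
        np.testing.assert_allclose(fc.values[off], fc.values.T[off])

    def test_white_noise_scale(self, rng):
        # independent columns: z approximately N(0, 1/(T-3))
        t_len = 400
        ts = ParcelTimeSeries("s", rng.standard_normal((t_len, 30)),
                              tuple(f"p{i}" for i in range(30)))
        z = edge_vector(compute_fc(ts))
        assert abs(np.mean(z)) < 4 / np.sqrt(t_len - 3) / np.sqrt(len(z) / 10)
        assert np.std(z) == pytest.approx(1 / np.sqrt(t_len - 3), rel=0.15)

    def test_permutation_equivariance(self, rng):
        x = rng.standard_normal((50, 6))
        ids = tuple(f"p{i}" for i in range(6))
        perm = rng.permutation(6)
        fc = compute_fc(ParcelTimeSeries("s", x, ids))
        fc_p = compute_fc(ParcelTimeSeries("s", x[:, perm],
                                           tuple(ids[i] for i in perm)))
        np.testing.assert_allclose(fc_p.values, fc.values[np.ix_(perm, perm)],
                                   atol=1e-12, equal_nan=True)

    def test_affine_invariance(self, rng):
        x = rng.standard_normal((60, 5))
        ids = tuple(f"p{i}" for i in range(5))
        y = x.copy()
        y[:, 2] = 3.5 * y[:, 2] + 11.0  # positive rescale + shift
        a = compute_fc(ParcelTimeSeries("s", x, ids)).values
        b = compute_fc(ParcelTimeSeries("s", y, ids)).values
        np.testing.assert_allclose(a, b, atol=1e-10, equal_nan=True)

    def test_zero_variance_column_names_parcel(self):
        x = np.ones((10, 3))
        x[:, 0] = np.arange(10)
        x[:, 2] = np.arange(10) ** 2
        with pytest.raises(ValueError, match="pB"):
            compute_fc(ParcelTimeSeries("s", x, ("pA", "pB", "pC")))


def _brute_within_mean(fc, atlas, network):
    ids = fc.parcel_ids
    total, n = 0.0, 0
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if atlas.network_of(ids[i]) == network and atlas.network_of(ids[j]) == network:
                total += fc.values[i, j]
                n += 1
    return total / n


def _brute_segregation(fc, atlas, network, between_policy="positive"):
    ids = fc.parcel_ids
    within, between = [], []
    for i in range(len(ids)):
        for j in range(len(ids)):
            if i == j:
                continue
            ni, nj = atlas.network_of(ids[i]), atlas.network_of(ids[j])
            if ni == network and nj == network and i < j:
                within.append(fc.values[i, j])
            elif ni == network and nj != network:
                between.append(fc.values[i, j])
    wpos = [v for v in within if v > 0]
    if not wpos:
        return float("nan")
    zn = sum(wpos) / len(wpos)
    if between_policy == "positive":
        bpos = [v for v in between if v > 0]
        za = sum(bpos) / len(bpos) if bpos else 0.0
    else:
        za = sum(between) / len(between)
    return (zn - za) / zn


@pytest.fixture(scope="module")
def random_atlas_fc():
    rng = np.random.default_rng(99)
    cases = []
    for _ in range(30):
        p = int(rng.integers(14, 30))
        labels = list(NETWORKS) * 2 + [str(rng.choice(NETWORKS)) for _ in range(p - 14)]
        rng.shuffle(labels)
        ids = tuple(f"p{i}" for i in range(p))
        atlas = NetworkAtlas(ids, tuple(labels[:p]))
        m = rng.normal(scale=0.4, size=(p, p))
        m = 0.5 * (m + m.T)
        np.fill_diagonal(m, np.nan)
        cases.append((ConnectivityMatrix(m, ids), atlas))
    return cases


class TestNetworkSummaries:
    def test_within_mean_small_examples(self):
        atlas = NetworkAtlas(tuple(f"p{i}" for i in range(14)),
                             tuple(n for n in NETWORKS for _ in range(2)))
        m = np.full((14, 14), 0.05)
        m[0, 1] = m[1, 0] = 0.3  # the VN pair
        np.fill_diagonal(m, np.nan)
        fc = ConnectivityMatrix(m, atlas.parcel_ids)
        assert within_network_mean(fc, atlas, "VN") == pytest.approx(0.3)

    def test_within_mean_matches_bruteforce(self, random_atlas_fc):
        for fc, atlas in random_atlas_fc:
            for net in NETWORKS:
                assert within_network_mean(fc, atlas, net) == pytest.approx(
                    _brute_within_mean(fc, atlas, net), abs=1e-12)

    def test_segregation_matches_bruteforce(self, random_atlas_fc):
        for fc, atlas in random_atlas_fc:
            for net in NETWORKS:
                for policy in ("positive", "signed"):
                    got = network_segregation(fc, atlas, net, policy)
                    want = _brute_segregation(fc, atlas, net, policy)
                    if np.isnan(want):
                        assert np.isnan(got)
                    else:
                        assert got == pytest.approx(want, abs=1e-12)

    def test_segregation_formula_arithmetic(self):
        # Z̄n = 0.5, Z̄a = 0.25 -> s = 0.5; all-negative between -> s = 1
        atlas = NetworkAtlas(tuple(f"p{i}" for i in range(14)),
                             tuple(n for n in NETWORKS for _ in range(2)))
        m = np.full((14, 14), 0.25)
        m[0, 1] = m[1, 0] = 0.5
        np.fill_diagonal(m, np.nan)
        fc = ConnectivityMatrix(m, atlas.parcel_ids)
        assert network_segregation(fc, atlas, "VN") == pytest.approx(0.5)
        m2 = np.full((14, 14), -0.2)
        m2[0, 1] = m2[1, 0] = 0.5
        np.fill_diagonal(m2, np.nan)
        fc2 = ConnectivityMatrix(m2, atlas.parcel_ids)
        assert network_segregation(fc2, atlas, "VN") == pytest.approx(1.0)
        # Z̄n == Z̄a -> 0
        m3 = np.full((14, 14), 0.4)
        np.fill_diagonal(m3, np.nan)
        fc3 = ConnectivityMatrix(m3, atlas.parcel_ids)
        assert network_segregation(fc3, atlas, "VN") == pytest.approx(0.0)

    def test_segregation_invariances(self, rng):
        atlas = default_atlas(21)
        m = rng.normal(scale=0.4, size=(21, 21))
        m = 0.5 * (m + m.T)
        np.fill_diagonal(m, np.nan)
        fc = ConnectivityMatrix(m, atlas.parcel_ids)
        s = {n: network_segregation(fc, atlas, n) for n in NETWORKS}
        # uniform positive rescaling of z leaves segregation unchanged
        fc_scaled = ConnectivityMatrix(m * 3.7, atlas.parcel_ids)
        for n in NETWORKS:
            assert network_segregation(fc_scaled, atlas, n) == pytest.approx(
                s[n], abs=1e-12, nan_ok=True)
        # relabeling parcels inside a network leaves it unchanged
        idx = atlas.indices("SMN")
        perm = np.arange(21)
        perm[idx] = idx[::-1]
        fc_perm = ConnectivityMatrix(m[np.ix_(perm, perm)], atlas.parcel_ids)
        for n in NETWORKS:
            assert network_segregation(fc_perm, atlas, n) == pytest.approx(
                s[n], abs=1e-12, nan_ok=True)

    def test_no_positive_within_edge_is_missing(self):
        atlas = NetworkAtlas(tuple(f"p{i}" for i in range(14)),
                             tuple(n for n in NETWORKS for _ in range(2)))
        m = np.full((14, 14), 0.3)
        m[0, 1] = m[1, 0] = -0.4
        np.fill_diagonal(m, np.nan)
        fc = ConnectivityMatrix(m, atlas.parcel_ids)
        assert np.isnan(network_segregation(fc, atlas, "VN"))


class TestSubjectFeatures:
    def test_agrees_with_single_matrix_operations(self, rng):
        from fcmega.features import subject_features

        atlas = default_atlas(21)
        series = [ParcelTimeSeries(f"s{i}", rng.standard_normal((60, 21)),
                                   atlas.parcel_ids) for i in range(3)]
        for policy in ("positive", "signed"):
            feats, edges = subject_features(series, atlas, between_policy=policy,
                                            include_edges=True)
            for i, ts in enumerate(series):
                fc = compute_fc(ts)
                for net in NETWORKS:
                    assert feats.loc[i, f"fc_{net}"] == pytest.approx(
                        within_network_mean(fc, atlas, net), abs=1e-12)
                    assert feats.loc[i, f"seg_{net}"] == pytest.approx(
                        network_segregation(fc, atlas, net, policy),
                        abs=1e-12, nan_ok=True)
                np.testing.assert_array_equal(edges[i], edge_vector(fc))


class TestEdgeVector:
    @pytest.mark.parametrize("p,expected", [(3, 3), (42, 861), (400, 79800)])
    def test_length(self, rng, p, expected):
        fc = _random_fc(rng, p)
        assert edge_vector(fc).shape == (expected,)

    @given(st.integers(min_value=2, max_value=25), st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_roundtrip_bijection(self, p, seed):
        fc = _random_fc(np.random.default_rng(seed), p)
        back = matrix_from_edges(edge_vector(fc), fc.parcel_ids)
        np.testing.assert_allclose(back.values, fc.values, equal_nan=True)
        np.testing.assert_array_equal(edge_vector(back), edge_vector(fc))
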