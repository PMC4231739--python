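"""Single-pass circular statistics and the T-linear association measure."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tetradna import circstats as cs


def pairwise_rho_t(theta_deg, phi_deg):
    """O(n²) double-loop oracle for Fisher's T-linear association."""
    t = np.radians(theta_deg)
    p = np.radians(phi_deg)
    dt = t[:, None] - t[None, :]
    dp = p[:, None] - p[None, :]
    iu = np.triu_indices(len(t), 1)
    num = np.sum(np.sin(dt[iu]) * np.sin(dp[iu]))
    den = np.sqrt(np.sum(np.sin(dt[iu]) ** 2) * np.sum(np.sin(dp[iu]) ** 2))
    return num / den


class TestLinToAngle:
    def test_anchor_points(self):
        assert cs.lin_to_angle(0.0) == 0.0
        assert cs.lin_to_angle(5.0) == pytest.approx(45.0)
        assert cs.lin_to_angle(-5.0) == pytest.approx(-45.0)

    def test_configurable_scale_and_bounds(self, rng):
        x = rng.normal(0, 50, 1000)
        a = cs.lin_to_angle(x, scale=2.0)
        assert np.all(np.abs(a) < 90.0)
        assert cs.lin_to_angle(2.0, scale=2.0) == pytest.approx(45.0)


class TestCircMoments:
    def test_wraparound_mean(self):
        assert cs.circ_moments([359.0, 1.0]).mean == pytest.approx(0.0, abs=1e-9)

    def test_constant_series(self):
        m = cs.circ_moments([77.0] * 10)
        assert m.sd == pytest.approx(0.0, abs=1e-6)
        assert m.range == pytest.approx(0.0)

    def test_narrow_data_matches_arithmetic_mean(self, rng):
        x = rng.normal(200.0, 8.0, 20000)
        m = cs.circ_moments(x % 360.0)
        assert (m.mean % 360.0) == pytest.approx(np.mean(x) % 360.0, abs=0.01)

    def test_min_mean_max_ordering(self, rng):
        x = rng.normal(350.0, 10.0, 5000) % 360.0
        m = cs.circ_moments(x)
        mean = m.mean if m.mean >= m.minimum else m.mean + 360.0
        assert m.minimum <= mean <= m.maximum
        assert m.range <= 360.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cs.circ_moments([])


class TestFisherT:
    def test_perfect_association(self, rng):
        t = rng.uniform(0, 360, 500)
        assert cs.fisher_T(t, t) == pytest.approx(1.0)
        assert cs.fisher_T(t, -t) == pytest.approx(-1.0)

    def test_single_pass_equals_pairwise_oracle(self, rng):
        t = rng.uniform(0, 360, 200)
        p = rng.uniform(0, 360, 200)
        assert cs.fisher_T(t, p) == pytest.approx(pairwise_rho_t(t, p), abs=1e-10)

    def test_narrow_range_close_to_pearson(self, rng):
        t = rng.normal(30, 5, 20000)
        p = 0.6 * t + rng.normal(0, 4, 20000)
        assert abs(cs.fisher_T(t, p) - cs.pearson(t, p)) < 0.02

    @given(st.floats(-720, 720), st.floats(-720, 720))
    def test_rotation_invariance(self, c1, c2):
        rng = np.random.default_rng(5)
        t = rng.uniform(0, 360, 100)
        p = rng.uniform(0, 360, 100)
        base = cs.fisher_T(t, p)
        assert cs.fisher_T(t + c1, p + c2) == pytest.approx(base, abs=1e-9)

    def test_symmetry(self, rng):
        t = rng.uniform(0, 360, 300)
        p = rng.uniform(0, 360, 300)
        assert cs.fisher_T(t, p) == pytest.approx(cs.fisher_T(p, t), abs=1e-12)

    def test_degenerate_denominator_flagged(self):
        t = np.array([0.0, 180.0] * 10)  # antipodal-degenerate
        p = np.arange(20.0)
        assert cs.fisher_T(t, p) is None

    def test_linear_member_mapped_through_atan(self, rng):
        x = rng.normal(0, 1.0, 1000)  # Å
        t = rng.uniform(0, 360, 1000)
        direct = cs.fisher_T(cs.lin_to_angle(x), t)
        assert cs.fisher_T(x, t, theta_circular=False) == pytest.approx(direct)


class TestAccumulators:
    def test_merge_associativity_exact(self, rng):
        t = rng.uniform(0, 360, 999)
        p = rng.uniform(0, 360, 999)
        whole = cs.PairedCircAccumulator().add(t, p)
        chunks = [
            cs.PairedCircAccumulator().add(t[i : i + 100], p[i : i + 100])
            for i in range(0, 999, 100)
        ]
        merged = chunks[0]
        for c in chunks[1:]:
            merged = merged.merge(c)
        # commutativity of a merge is exact (float addition commutes) ...
        ab = chunks[0].merge(chunks[1])
        ba = chunks[1].merge(chunks[0])
        for f in cs.PairedCircAccumulator._FIELDS:
            assert getattr(ab, f) == getattr(ba, f)
        # ... and regrouping agrees to round-off
        left = chunks[0].merge(chunks[1]).merge(chunks[2])
        right = chunks[0].merge(chunks[1].merge(chunks[2]))
        for f in cs.PairedCircAccumulator._FIELDS:
            assert getattr(left, f) == pytest.approx(getattr(right, f), rel=1e-12, abs=1e-12)
        assert merged.n == whole.n
        assert merged.rho_t == pytest.approx(whole.rho_t, abs=1e-12)

    def test_streaming_equals_whole(self, rng):
        x = rng.uniform(0, 360, 1000)
        whole = cs.CircAccumulator().add(x)
        stream = cs.CircAccumulator()
        for chunk in np.array_split(x, 7):
            stream.add(chunk)
        assert stream.mean == pytest.approx(whole.mean)
        assert stream.sd == pytest.approx(whole.sd)


class TestCorrMatrix:
    def test_diagonal_and_independence(self, rng):
        n = 100_000
        series = {
            "twist": rng.normal(33, 5, n),
            "shift": rng.normal(0, 0.4, n),
            "zeta": rng.uniform(0, 360, n),
        }
        flags = {"twist": True, "shift": False, "zeta": True}
        names, mat, mask = cs.corr_matrix(series, flags)
        assert np.allclose(np.diag(mat), 1.0)
        off = mat[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 0.05)
        assert not mask[~np.eye(3, dtype=bool)].any()

    def test_coupled_pair_masked_positive(self, rng):
        n = 50_000
        zeta = rng.normal(265, 15, n)
        twist = 33 + 0.25 * (zeta - 265) + rng.normal(0, 2.8, n)
        names, mat, mask = cs.corr_matrix(
            {"zeta": zeta, "twist": twist}, {"zeta": True, "twist": True}
        )
        r = mat[0, 1]
        assert r > 0.4
        assert mask[0, 1] == 1


class TestHistogram:
    def test_uniform_circular_near_flat(self, rng):
        edges, counts, density = cs.histogram(rng.uniform(0, 360, 200_000), 2.0, circular=True)
        assert counts.sum() == 200_000
        assert np.ptp(density) < 0.5 * density.mean()

    def test_density_integrates_to_one(self, rng):
        edges, counts, density = cs.histogram(rng.normal(0, 1, 10_000), 0.1)
        assert np.sum(density * np.diff(edges)) == pytest.approx(1.0)

    def test_mixture_two_maxima(self, rng):
        x = np.concatenate([rng.normal(20, 3, 50_000), rng.normal(40, 3, 50_000)])
        edges, counts, density = cs.histogram(x, 2.0)
        centers = 0.5 * (edges[:-1] + edges[1:])
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(density, prominence=0.1 * density.max())
        assert len(peaks) == 2
        assert centers[peaks] == pytest.approx([20, 40], abs=2.5)

    def test_bad_width(self):
        with pytest.raises(ValueError):
            cs.histogram([1.0], 0.0)
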