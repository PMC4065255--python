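"""Sweep-transformed SFS, CLR scan, r^2 and omega."""

import numpy as np
import pytest

from popsweep import coalescent as co
from popsweep import sweep as sw
from popsweep.sweep import (
    BackgroundSFS,
    SnpMatrix,
    background_sfs,
    clr_scan,
    omega_at,
    omega_scan,
    r_squared,
    sweep_transformed_sfs,
)

from oracles import omega_enum, r2_direct, sweep_transform_enum


def _uniform_bg(n):
    probs = np.zeros(n + 1)
    probs[1:n] = 1.0 / (n - 1)
    return BackgroundSFS(n, probs)


def _neutral_bg(n):
    probs = np.zeros(n + 1)
    probs[1:n] = 1.0 / np.arange(1, n)
    probs /= probs.sum()
    return BackgroundSFS(n, probs)


class TestSweepTransformedSfs:
    def test_full_escape_recovers_background(self):
        bg = _neutral_bg(10)
        out = sweep_transformed_sfs(bg, 1.0)
        np.testing.assert_allclose(out, bg.probs, atol=1e-12)

    def test_complete_hitchhiking_polymorphism_vanishes(self):
        bg = _uniform_bg(8)
        # unnormalized polymorphic mass tends to 0; the conditional
        # spectrum concentrates on singleton / (n-1) classes
        out = sweep_transformed_sfs(bg, 1e-9)
        assert out[1] + out[7] == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("pe", [0.1, 0.5, 0.9])
    def test_matches_enumeration_at_n4(self, pe):
        bg = _uniform_bg(4)
        ours = sweep_transformed_sfs(bg, pe)
        enum = sweep_transform_enum(bg.probs, 4, pe)
        np.testing.assert_allclose(ours, enum, atol=1e-10)

    @pytest.mark.parametrize("pe", [0.0, 0.2, 0.7, 1.0])
    def test_sums_to_one(self, pe):
        bg = _neutral_bg(12)
        out = sweep_transformed_sfs(bg, pe)
        assert out.sum() == pytest.approx(1.0)


def _snps_from_counts(rng, n, counts, positions):
    cols = []
    for c in counts:
        col = np.zeros(n, dtype=np.uint8)
        col[rng.choice(n, size=c, replace=False)] = 1
        cols.append(col)
    return SnpMatrix(np.asarray(positions, dtype=float),
                     np.column_stack(cols), np.ones(len(counts), dtype=bool))


def _sweep_data(rng, n=20, S=200, L=17_000.0, x_star=8_500.0, alpha=5e-4):
    """SNP counts drawn directly from the sweep-transformed model."""
    bg = _neutral_bg(n)
    C = sw._transform_matrix(bg)
    positions = np.sort(rng.uniform(0, L, size=S))
    counts = []
    for p in positions:
        pe = 1.0 - np.exp(-alpha * abs(p - x_star))
        probs = sweep_transformed_sfs(bg, pe, _C=C)
        counts.append(int(rng.choice(n + 1, p=probs)))
    return _snps_from_counts(rng, n, counts, positions)


class TestClrScan:
    def test_localizes_planted_sweep(self):
        """argmax within 2 kb of the true sweep site in >= 80% of replicates."""
        rng = np.random.default_rng(1)
        hits = 0
        n_rep = 30
        for _ in range(n_rep):
            snps = _sweep_data(rng)
            track = clr_scan(snps)
            if abs(track.argmax_position - 8_500.0) <= 2_000.0:
                hits += 1
        assert hits / n_rep >= 0.8

    def test_neutral_alpha_only_grid_gives_zero(self):
        rng = np.random.default_rng(2)
        reps = co.simulate_neutral(co.SimConfig(n=12, theta=30.0, L=10_000.0,
                                                replicates=1, seed=3))
        snps = SnpMatrix.from_haplotypes(reps[0])
        track = clr_scan(snps, alpha_grid=np.array([np.inf]))
        assert np.allclose(track.track["stat"], 0.0, atol=1e-9)

    def test_clr_nonnegative_everywhere(self):
        rng = np.random.default_rng(4)
        snps = _sweep_data(rng, S=100)
        track = clr_scan(snps)
        assert (track.track["stat"] >= -1e-9).all()

    def test_too_few_snps_error(self):
        snps = _snps_from_counts(np.random.default_rng(0), 10, [3], [100.0])
        with pytest.raises(ValueError, match="2 SNPs"):
            clr_scan(snps)


class TestRSquared:
    def test_identical_columns(self):
        col = np.array([0, 0, 1, 1, 0, 1])
        assert r_squared(col, col) == pytest.approx(1.0)

    def test_complementary_columns(self):
        col = np.array([0, 0, 1, 1, 0, 1])
        assert r_squared(col, 1 - col) == pytest.approx(1.0)

    def test_monomorphic_undefined(self):
        with pytest.raises(ValueError, match="monomorphic"):
            r_squared(np.zeros(6), np.array([0, 1, 0, 1, 0, 1]))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_counting_on_toy_instances(self, seed):
        rng = np.random.default_rng(seed)
        while True:
            a = rng.integers(0, 2, size=8)
            b = rng.integers(0, 2, size=8)
            if 0 < a.sum() < 8 and 0 < b.sum() < 8:
                break
        assert r_squared(a, b) == pytest.approx(r2_direct(a, b), abs=1e-12)

    def test_allele_relabeling_invariance(self, rng):
        while True:
            a = rng.integers(0, 2, size=10)
            b = rng.integers(0, 2, size=10)
            if 0 < a.sum() < 10 and 0 < b.sum() < 10:
                break
        assert r_squared(a, b) == pytest.approx(r_squared(1 - a, b), abs=1e-12)


def _block_snps(n=12):
    """Two internally perfect LD blocks with zero cross-block correlation."""
    rng = np.random.default_rng(8)
    left_hap = np.array([0] * 6 + [1] * 6, dtype=np.uint8)
    right_hap = np.array([0, 1] * 6, dtype=np.uint8)
    cols = [left_hap] * 3 + [right_hap] * 3
    positions = [100.0, 300.0, 1100.0, 2100.0, 2900.0, 3100.0]
    return SnpMatrix(np.array(positions), np.column_stack(cols),
                     np.ones(6, dtype=bool))


class TestOmega:
    def test_perfect_blocks_give_infinite_omega(self):
        snps = _block_snps()
        om, el, r = omega_at(1600.0, snps, minwin=1000, maxwin=2000)
        assert np.isinf(om)

    def test_all_equal_r2_gives_one(self):
        # identical columns everywhere: every pairwise r^2 = 1
        col = np.array([0, 0, 1, 1, 1, 0], dtype=np.uint8)
        positions = np.array([0.0, 400.0, 800.0, 1200.0, 1600.0, 2000.0])
        snps = SnpMatrix(positions, np.column_stack([col] * 6),
                         np.ones(6, dtype=bool))
        om, _, _ = omega_at(1000.0, snps, minwin=500, maxwin=1000)
        assert om == pytest.approx(1.0)

    def test_insufficient_flanking_snps_is_nan(self):
        snps = _block_snps()
        om, _, _ = omega_at(150.0, snps, minwin=1000, maxwin=2000)
        assert np.isnan(om)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_split_enumeration(self, seed):
        rng = np.random.default_rng(seed + 10)
        n, S = 10, 12
        while True:
            mat = rng.integers(0, 2, size=(n, S)).astype(np.uint8)
            counts = mat.sum(axis=0)
            if np.all((counts > 0) & (counts < n)):
                break
        positions = np.sort(rng.uniform(0, 4000, size=S))
        positions += np.arange(S) * 1e-6
        snps = SnpMatrix(positions, mat, np.ones(S, dtype=bool))
        center = 2000.0
        ours, _, _ = omega_at(center, snps, minwin=800, maxwin=1800)
        enum = omega_enum(positions, mat.astype(float), center, 800, 1800)
        if np.isnan(enum):
            assert np.isnan(ours)
        else:
            assert ours == pytest.approx(enum, rel=1e-9)


class TestOmegaScan:
    def test_grid_spans_snp_range(self):
        snps = _block_snps()
        track = omega_scan(snps, grid=50, minwin=500, maxwin=1500)
        pos = track.track["position"].to_numpy()
        assert pos[0] == snps.positions[0]
        assert pos[-1] == snps.positions[-1]
        assert len(pos) == 50

    def test_maximized_at_block_boundary(self):
        # the decoupled zone runs from the last left-block SNP (1100)
        # to the first right-block SNP (2100)
        snps = _block_snps()
        track = omega_scan(snps, grid=61, minwin=500, maxwin=2000)
        assert 1100.0 <= track.argmax_position <= 2100.0
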