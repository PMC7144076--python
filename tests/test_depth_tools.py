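"""Tests for the simulator, subsampler and depth sweep."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rxsex import (
    Call,
    ChromosomeRecord,
    IdxstatsTable,
    Karyotype,
    Role,
    SimSpec,
    compute_rx,
    depth_sweep,
    elephant_like_karyotype,
    join_counts,
    simulate_idxstats,
    subsample_idxstats,
)
from rxsex.errors import ConfigurationError, ValidationError
from rxsex.karyo_io import IdxstatsRow

REL = 1e-9


@pytest.fixture(scope="module")
def karyo():
    return elephant_like_karyotype()


# ---------------------------------------------------------------------------
# simulate_idxstats
# ---------------------------------------------------------------------------

class TestSimulate:
    def test_noise_free_homogametic_gives_unit_ratio(self, karyo):
        spec = SimSpec(
            karyotype=karyo,
            true_sex=Call.HOMOGAMETIC,
            total_reads=100_000,
            mode="noise_free",
        )
        res = compute_rx(join_counts(simulate_idxstats(spec), karyo))
        assert res.rx == pytest.approx(1.0, rel=REL)
        assert res.se == pytest.approx(0.0, abs=1e-12)
        assert res.call_label == "female"

    def test_noise_free_heterogametic_gives_half_ratio(self, karyo):
        spec = SimSpec(
            karyotype=karyo,
            true_sex=Call.HETEROGAMETIC,
            total_reads=100_000,
            mode="noise_free",
        )
        res = compute_rx(join_counts(simulate_idxstats(spec), karyo))
        assert res.rx == pytest.approx(0.5, rel=REL)
        assert res.call_label == "male"

    def test_multinomial_heterogametic_near_half(self, karyo):
        # bound frozen after 200-seed brute-force replication:
        # observed range [0.4903, 0.5087] at this depth
        spec = SimSpec(
            karyotype=karyo,
            true_sex=Call.HETEROGAMETIC,
            total_reads=10**6,
            mode="multinomial",
            seed=42,
        )
        res = compute_rx(join_counts(simulate_idxstats(spec), karyo))
        assert 0.48 <= res.rx <= 0.52

    def test_multinomial_total_is_exact(self, karyo):
        spec = SimSpec(
            karyotype=karyo, true_sex=Call.HOMOGAMETIC, total_reads=12_345, seed=1
        )
        assert simulate_idxstats(spec).total_mapped == 12_345

    def test_deterministic_under_seed(self, karyo):
        spec = SimSpec(
            karyotype=karyo, true_sex=Call.HOMOGAMETIC, total_reads=10_000, seed=9
        )
        assert simulate_idxstats(spec).rows == simulate_idxstats(spec).rows

    def test_bias_shifts_expected_counts(self, karyo):
        spec = SimSpec(
            karyotype=karyo,
            true_sex=Call.HOMOGAMETIC,
            total_reads=100_000,
            mode="noise_free",
            bias={"chr1": 2.0},
        )
        plain = SimSpec(
            karyotype=karyo,
            true_sex=Call.HOMOGAMETIC,
            total_reads=100_000,
            mode="noise_free",
        )
        biased_c1 = simulate_idxstats(spec).mapped_by_name()["chr1"]
        plain_c1 = simulate_idxstats(plain).mapped_by_name()["chr1"]
        assert biased_c1 > plain_c1

    def test_bias_validation(self, karyo):
        with pytest.raises(ConfigurationError, match="bias"):
            SimSpec(
                karyotype=karyo,
                true_sex=Call.HOMOGAMETIC,
                total_reads=100,
                bias={"nope": 1.0},
            )

    def test_invalid_spec_rejected(self, karyo):
        with pytest.raises(ConfigurationError):
            SimSpec(karyotype=karyo, true_sex=Call.HOMOGAMETIC, total_reads=0)
        with pytest.raises(ConfigurationError):
            SimSpec(
                karyotype=karyo,
                true_sex=Call.UNASSIGNED,
                total_reads=100,
            )

    def test_excluded_and_limited_get_zero_reads(self):
        k = Karyotype(
            chromosomes=(
                ChromosomeRecord("chr1", 1000, Role.AUTOSOME),
                ChromosomeRecord("chr2", 800, Role.AUTOSOME),
                ChromosomeRecord("chr3", 600, Role.AUTOSOME),
                ChromosomeRecord("chrX", 500, Role.SHARED_SEX),
                ChromosomeRecord("chrY", 200, Role.LIMITED_SEX),
                ChromosomeRecord("chrM", 16, Role.EXCLUDED),
            )
        )
        homo = simulate_idxstats(
            SimSpec(karyotype=k, true_sex=Call.HOMOGAMETIC, total_reads=10_000, seed=3)
        ).mapped_by_name()
        assert homo["chrY"] == 0 and homo["chrM"] == 0
        hetero = simulate_idxstats(
            SimSpec(
                karyotype=k, true_sex=Call.HETEROGAMETIC, total_reads=10_000, seed=3
            )
        ).mapped_by_name()
        assert hetero["chrM"] == 0
        assert hetero["chrY"] > 0  # one Y copy draws reads


def test_parameter_recovery_and_zero_misclassification(karyo):
    """Mean rx converges to 1.0 / 0.5 at 1e5 reads; no wrong calls."""
    for true_sex, expected in [(Call.HOMOGAMETIC, 1.0), (Call.HETEROGAMETIC, 0.5)]:
        rxs = []
        for seed in range(40):
            spec = SimSpec(
                karyotype=karyo, true_sex=true_sex, total_reads=10**5, seed=seed
            )
            res = compute_rx(join_counts(simulate_idxstats(spec), karyo))
            rxs.append(res.rx)
            assert res.call is true_sex
        assert np.mean(rxs) == pytest.approx(expected, abs=0.005)


def test_zw_mirror_symmetry():
    """A ZW homogametic-style single-Z female matches an XY male distribution.

    With identical chromosome geometry and seeds, a ZW female (one Z) and an
    XY male (one X) are the same multinomial draw, so the rx values must be
    bitwise equal and only the labels differ.
    """
    xy = elephant_like_karyotype(system="XY")
    zw = elephant_like_karyotype(system="ZW")
    for seed in range(10):
        res_xy = compute_rx(
            join_counts(
                simulate_idxstats(
                    SimSpec(
                        karyotype=xy,
                        true_sex=Call.HETEROGAMETIC,
                        total_reads=50_000,
                        seed=seed,
                    )
                ),
                xy,
            )
        )
        res_zw = compute_rx(
            join_counts(
                simulate_idxstats(
                    SimSpec(
                        karyotype=zw,
                        true_sex=Call.HETEROGAMETIC,
                        total_reads=50_000,
                        seed=seed,
                    )
                ),
                zw,
            )
        )
        assert res_zw.rx == res_xy.rx
        assert res_xy.call_label == "male"
        assert res_zw.call_label == "female"


# ---------------------------------------------------------------------------
# subsample_idxstats
# ---------------------------------------------------------------------------

class TestSubsample:
    def test_exact_total(self, karyo):
        table = simulate_idxstats(
            SimSpec(karyotype=karyo, true_sex=Call.HOMOGAMETIC, total_reads=10**6, seed=0)
        )
        sub = subsample_idxstats(table, 10_000, seed=1)
        assert sub.total_mapped == 10_000

    def test_identity_at_full_depth(self, karyo):
        table = simulate_idxstats(
            SimSpec(karyotype=karyo, true_sex=Call.HOMOGAMETIC, total_reads=5_000, seed=0)
        )
        sub = subsample_idxstats(table, int(table.total_mapped), seed=1)
        assert sub.rows == table.rows

    def test_seed_reproducibility(self, karyo):
        table = simulate_idxstats(
            SimSpec(karyotype=karyo, true_sex=Call.HETEROGAMETIC, total_reads=10**5, seed=0)
        )
        a = subsample_idxstats(table, 1_000, seed=7)
        b = subsample_idxstats(table, 1_000, seed=7)
        c = subsample_idxstats(table, 1_000, seed=8)
        assert a.rows == b.rows
        assert a.rows != c.rows

    def test_target_exceeding_total_is_error(self, karyo):
        table = simulate_idxstats(
            SimSpec(karyotype=karyo, true_sex=Call.HOMOGAMETIC, total_reads=100, seed=0)
        )
        with pytest.raises(ValidationError, match="exceeds"):
            subsample_idxstats(table, 101)

    def test_marginal_expectation_preserved(self):
        """E[m_c'] = target * m_c / total — checked by averaging many draws."""
        rows = [
            IdxstatsRow("chr1", 1000, 6000, 0),
            IdxstatsRow("chr2", 800, 3000, 0),
            IdxstatsRow("chrX", 500, 1000, 0),
        ]
        table = IdxstatsTable(rows=rows)
        target = 1000
        sums = np.zeros(3)
        n_draws = 400
        for seed in range(n_draws):
            sub = subsample_idxstats(table, target, seed=seed)
            sums += [r.mapped for r in sub.rows]
        observed = sums / n_draws
        expected = np.array([6000, 3000, 1000]) / 10000 * target
        # hypergeometric sd per draw is < 16 reads; 400 draws shrink it ~20x
        assert observed == pytest.approx(expected, abs=3.0)

    def test_rejects_fractional_counts(self, karyo):
        table = simulate_idxstats(
            SimSpec(
                karyotype=karyo,
                true_sex=Call.HOMOGAMETIC,
                total_reads=999,
                mode="noise_free",
            )
        )
        with pytest.raises(ValidationError, match="integer"):
            subsample_idxstats(table, 100)

    @given(
        target=st.integers(1, 10_000),
        seed=st.integers(0, 2**32 - 1),
    )
    @settings(max_examples=30, deadline=None)
    def test_total_exactness_property(self, target, seed):
        rows = [
            IdxstatsRow("chr1", 1000, 5000, 0),
            IdxstatsRow("chr2", 800, 3000, 0),
            IdxstatsRow("chrX", 500, 2000, 0),
        ]
        sub = subsample_idxstats(IdxstatsTable(rows=rows), target, seed=seed)
        assert sub.total_mapped == target
        assert all(r.mapped >= 0 for r in sub.rows)


# ---------------------------------------------------------------------------
# depth_sweep
# ---------------------------------------------------------------------------

class TestDepthSweep:
    def test_ci_width_increases_as_depth_decreases(self, karyo):
        spec = SimSpec(
            karyotype=karyo, true_sex=Call.HETEROGAMETIC, total_reads=10**5
        )
        result = depth_sweep(spec, [100_000, 10_000, 1_000], replicates=25, seed=3)
        summary = result.summary().sort_values("target_depth", ascending=False)
        widths = summary["mean_ci_width"].to_numpy()
        assert np.all(np.diff(widths) > 0)

    def test_sqrt_depth_scaling_of_ci_width(self, karyo):
        """log-log slope of CI width vs depth is ~ -0.5 over a 100x range."""
        spec = SimSpec(
            karyotype=karyo, true_sex=Call.HOMOGAMETIC, total_reads=10**5
        )
        result = depth_sweep(
            spec, [100_000, 31_623, 10_000, 3_162, 1_000], replicates=20, seed=11
        )
        summary = result.summary()
        slope = np.polyfit(
            np.log(summary["target_depth"]), np.log(summary["mean_ci_width"]), 1
        )[0]
        assert slope == pytest.approx(-0.5, abs=0.1)

    def test_single_depth_identity_on_real_table(self, karyo):
        table = simulate_idxstats(
            SimSpec(karyotype=karyo, true_sex=Call.HETEROGAMETIC, total_reads=50_000, seed=5)
        )
        result = depth_sweep(
            table, [int(table.total_mapped)], replicates=1, seed=0, karyotype=karyo
        )
        direct = compute_rx(join_counts(table, karyo))
        row = result.rows.iloc[0]
        assert row["rx"] == direct.rx
        assert row["ci_low"] == direct.ci_low

    def test_zero_replicates_is_error(self, karyo):
        spec = SimSpec(karyotype=karyo, true_sex=Call.HOMOGAMETIC, total_reads=1000)
        with pytest.raises(ValidationError, match="replicates"):
            depth_sweep(spec, [100], replicates=0)

    def test_depth_above_table_total_is_error(self, karyo):
        table = simulate_idxstats(
            SimSpec(karyotype=karyo, true_sex=Call.HOMOGAMETIC, total_reads=1000, seed=0)
        )
        with pytest.raises(ValidationError, match="exceed"):
            depth_sweep(table, [2000], replicates=1, karyotype=karyo)

    def test_sweep_reproducible_under_seed(self, karyo):
        spec = SimSpec(karyotype=karyo, true_sex=Call.HETEROGAMETIC, total_reads=10**4)
        a = depth_sweep(spec, [10_000, 1_000], replicates=5, seed=21)
        b = depth_sweep(spec, [10_000, 1_000], replicates=5, seed=21)
        assert a.rows.equals(b.rows)
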