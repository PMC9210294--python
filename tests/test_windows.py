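"""Window aggregation arithmetic, peak calling, composition tracks."""

import numpy as np
import pandas as pd
import pytest

from bsascan import (
    NullModel,
    WindowConfig,
    build_windows,
    call_peaks,
    heterozygosity_track,
    mean_snp_count_per_window,
)
from bsascan.errors import ContractViolation
from bsascan.sliding_windows import MAIZE_PRESET


def snp_frame(positions, ssnp=None, chrom="Chr1", **extra):
    df = pd.DataFrame({"chrom": chrom, "pos": np.asarray(positions, dtype=int)})
    df["is_ssnp"] = np.zeros(len(df), bool) if ssnp is None else np.asarray(ssnp, bool)
    df["ad_ref1"] = 10
    df["ad_alt1"] = 10
    df["ad_ref2"] = 10
    df["ad_alt2"] = 10
    for k, v in extra.items():
        df[k] = v
    return df


class TestBuildWindows:
    def test_peak_window_ratio_arithmetic(self, rng):
        # one full window holding 1139 SNPs of which 675 are significant
        pos = np.sort(rng.choice(np.arange(1, 2_000_000), 1139, replace=False))
        flags = np.zeros(1139, bool)
        flags[:675] = True
        wins = build_windows(snp_frame(pos, rng.permutation(flags)), WindowConfig())
        first = wins.iloc[0]
        assert first["total_snps"] == 1139 and first["ssnps"] == 675
        assert round(first["ratio"], 4) == 0.5926

    def test_zero_ssnps_zero_ratio(self):
        wins = build_windows(snp_frame([10, 20, 30]), WindowConfig())
        assert (wins["ratio"] == 0).all()

    def test_interior_snp_in_window_size_over_step_windows(self):
        cfg = WindowConfig(window_size=100, step=10)
        pos = np.arange(1, 1002)  # dense chromosome
        wins = build_windows(snp_frame(pos), cfg)
        target = 555  # interior SNP
        covering = ((wins["start"] <= target) & (wins["end"] > target) & (wins["total_snps"] > 0)).sum()
        assert covering == cfg.window_size // cfg.step

    def test_half_open_boundaries(self):
        cfg = WindowConfig(window_size=100, step=100)
        wins = build_windows(snp_frame([1, 100, 101]), cfg)
        assert wins.iloc[0]["total_snps"] == 2  # pos 1 and 100 in [1, 101)
        assert wins.iloc[1]["total_snps"] == 1  # pos 101 in [101, 201)

    def test_ratio_equals_mean_of_indicators(self, rng):
        pos = np.sort(rng.choice(np.arange(1, 5_000_000), 400, replace=False))
        flags = rng.random(400) < 0.3
        df = snp_frame(pos, flags)
        wins = build_windows(df, WindowConfig())
        for _, w in wins.head(20).iterrows():
            mask = (df["pos"] >= w["start"]) & (df["pos"] < w["end"])
            if mask.sum():
                assert w["ratio"] == pytest.approx(df.loc[mask, "is_ssnp"].mean())

    def test_step_partition_conserves_snp_count(self, rng):
        cfg = WindowConfig(window_size=200_000, step=50_000)
        pos = np.sort(rng.choice(np.arange(1, 2_000_000), 300, replace=False))
        wins = build_windows(snp_frame(pos), cfg)
        # non-overlapping partition at stride window_size covers every SNP once
        stride = wins[(wins["start"] - 1) % cfg.window_size == 0]
        assert stride["total_snps"].sum() == 300

    def test_unsorted_input_rejected(self):
        df = snp_frame([100, 50, 200])
        with pytest.raises(ContractViolation):
            build_windows(df, WindowConfig())

    def test_maize_preset_window_size(self):
        assert MAIZE_PRESET.window_size == 5_000_000 and MAIZE_PRESET.step == 10_000


class TestMeanSnpCount:
    def test_arithmetic_mean(self):
        wins = pd.DataFrame({"total_snps": [4, 6, 8]})
        assert mean_snp_count_per_window(wins) == 6.0

    def test_single_window_identity_and_permutation(self, rng):
        counts = rng.integers(0, 50, 30)
        a = pd.DataFrame({"total_snps": counts})
        b = pd.DataFrame({"total_snps": rng.permutation(counts)})
        assert mean_snp_count_per_window(a) == mean_snp_count_per_window(b)
        assert mean_snp_count_per_window(a.iloc[:1]) == counts[0]

    def test_no_windows_rejected(self):
        with pytest.raises(ContractViolation):
            mean_snp_count_per_window(pd.DataFrame({"total_snps": []}))


class TestCallPeaks:
    def windows(self, ratios, chrom="Chr1"):
        n = len(ratios)
        return pd.DataFrame(
            {
                "chrom": chrom,
                "start": 1 + 10_000 * np.arange(n),
                "end": 1 + 10_000 * np.arange(n) + 2_000_000,
                "total_snps": 100,
                "ssnps": (np.asarray(ratios) * 100).astype(int),
                "ratio": ratios,
            }
        )

    def test_all_below_threshold_no_peaks(self):
        assert call_peaks(self.windows([0.01, 0.02, 0.0]), "ratio", genome_threshold=0.1) == []

    def test_single_run_peaks_at_maximum(self):
        wins = self.windows([0.0, 0.2, 0.5, 0.3, 0.0])
        (peak,) = call_peaks(wins, "ratio", genome_threshold=0.1)
        assert peak.value == 0.5 and peak.position == wins.iloc[2]["start"]
        assert not peak.verified  # no stats/model supplied -> unverified candidate

    def test_two_runs_verification_split(self, rng):
        # run A barely above a tiny genome threshold but far below its own
        # window null threshold; run B saturated -> verified
        n = 400
        d = np.full(n, 20)
        a1 = rng.binomial(d, 0.5)
        a2 = rng.binomial(d, 0.5)
        stats = pd.DataFrame(
            {
                "chrom": "Chr1",
                "pos": np.concatenate(
                    [
                        np.sort(rng.choice(np.arange(1, 2_000_000), 200, replace=False)),
                        np.sort(rng.choice(np.arange(8_000_001, 10_000_000), 200, replace=False)),
                    ]
                ),
                "ad_ref1": d - a1,
                "ad_alt1": a1,
                "ad_ref2": d - a2,
                "ad_alt2": a2,
            }
        )
        wins = self.windows([0.02] + [0.0] * 798 + [0.9], chrom="Chr1")
        wins.loc[799, "start"] = 8_000_001
        wins.loc[799, "end"] = 10_000_001
        peaks = call_peaks(
            wins,
            "ratio",
            genome_threshold=0.01,
            stats=stats,
            model=NullModel(replicates=400, seed=3),
        )
        assert len(peaks) == 2
        verified = {p.value: p.verified for p in peaks}
        assert verified[0.9] is True and verified[0.02] is False

    def test_g_and_delta_af_window_thresholds(self):
        wins = self.windows([0.0] * 5)
        wins["mean_g"] = [1.0, 9.0, 2.0, 1.0, 1.0]
        wins["mean_g_thr"] = 5.0
        (gp,) = call_peaks(wins, "g")
        assert gp.value == 9.0 and gp.verified

        wins["mean_delta_af"] = [0.1, -0.8, 0.2, 0.75, 0.0]
        wins["mean_delta_af_lo"] = -0.6
        wins["mean_delta_af_hi"] = 0.6
        peaks = call_peaks(wins, "delta_af")
        # both a valley and a peak outside the band are reported
        assert sorted(round(p.value, 2) for p in peaks) == [-0.8, 0.75]

    def test_runs_do_not_cross_chromosomes(self):
        a = self.windows([0.5, 0.5], chrom="Chr1")
        b = self.windows([0.5, 0.5], chrom="Chr2")
        wins = pd.concat([a, b], ignore_index=True)
        peaks = call_peaks(wins, "ratio", genome_threshold=0.1)
        assert [p.chrom for p in peaks] == ["Chr1", "Chr2"]


class TestHeterozygosityTrack:
    def test_fractions_and_conservation(self, rng):
        n = 100
        origin = np.array(["htSNP"] * 60 + ["shared"] * 30 + ["bsSNP"] * 10)
        df = pd.DataFrame(
            {
                "chrom": "Chr1",
                "pos": np.sort(rng.choice(np.arange(1, 1_000_000), n, replace=False)),
                "origin": rng.permutation(origin),
                "is_ssnp": False,
            }
        )
        track = heterozygosity_track(df, WindowConfig(window_size=1_000_000, step=1_000_000))
        row = track.iloc[0]
        assert row["heterozygosity"] == pytest.approx(0.60)
        assert row["bs_snps"] == 10
        total_fraction = row["heterozygosity"] + row["bs_fraction"] + row["shared_fraction"]
        assert total_fraction == pytest.approx(1.0)

    def test_no_htsnps_gives_zero_track(self, rng):
        df = pd.DataFrame(
            {
                "chrom": "Chr1",
                "pos": np.arange(1, 50) * 1000,
                "origin": "shared",
                "is_ssnp": False,
            }
        )
        track = heterozygosity_track(df, WindowConfig())
        assert (track["heterozygosity"].fillna(0) == 0).all()
        assert (track["ht_ssnp_ratio"].fillna(0) == 0).all()
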