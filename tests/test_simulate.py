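"""Synthetic-data generator: dilution math, determinism, moment recovery."""

import numpy as np
import pytest

from urivar.errors import UrivarError
from urivar.io import write_counts
from urivar.simulate import (
    HET,
    HOM,
    DilutionSpec,
    SimConfig,
    SimulatedAssay,
    expected_vaf,
    get_assay,
    inject_cnv,
    inject_loh,
    simulate_dilution,
    simulate_null,
    simulate_pon,
    simulate_serial_urine,
    simulate_tumor_urine_pair,
)


class TestExpectedVaf:
    @pytest.mark.parametrize(
        "genotype, ratio, expected",
        [
            (HOM, "1:10", 0.10),
            (HET, "1:10", 0.05),
            (HOM, "1:50", 0.02),
            (HET, "1:50", 0.01),
            (HET, "1:1", 0.50),  # undiluted heterozygote
            (HOM, "1:100", 0.01),
            (HET, "1:100", 0.005),
        ],
    )
    def test_dilution_table(self, genotype, ratio, expected):
        assert expected_vaf(genotype, ratio) == pytest.approx(expected)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(UrivarError):
            expected_vaf(HET, "1:0")
        with pytest.raises(UrivarError):
            expected_vaf(HET, "2:10")
        with pytest.raises(UrivarError):
            expected_vaf("diploid", "1:10")

    def test_unsupported_dilution_spec(self):
        with pytest.raises(UrivarError, match="supported"):
            DilutionSpec(ratio="1:7")


class TestDeterminism:
    def test_identical_seeds_identical_counts(self, small_sim, tmp_path):
        a = simulate_null(small_sim, seed=5)
        b = simulate_null(small_sim, seed=5)
        assert a == b
        pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_counts(a, pa)
        write_counts(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_different_seeds_differ(self, small_sim):
        assert simulate_null(small_sim, seed=5) != simulate_null(
            small_sim, seed=6
        )

    def test_assay_state_reproducible(self, small_sim):
        a = SimulatedAssay(small_sim)
        b = SimulatedAssay(small_sim)
        np.testing.assert_array_equal(a.ref_idx, b.ref_idx)
        np.testing.assert_allclose(a.err, b.err)
        np.testing.assert_allclose(a.capture, b.capture)
        np.testing.assert_array_equal(a.snp_rows, b.snp_rows)


class TestPonSimulation:
    def test_cohort_size(self, small_sim):
        assert len(simulate_pon(small_sim, n=16, seed=1)) == 16
        with pytest.raises(UrivarError):
            simulate_pon(small_sim, n=1)

    def test_zero_error_rate_gives_clean_reference(self, small_sim):
        assay = SimulatedAssay(small_sim)
        assay.err[:] = 0.0
        rng = np.random.default_rng(4)
        s = assay.synthesize("clean", rng)  # no genotypes, no spikes
        totals = s.allele_totals
        nonref = totals.sum(axis=1) - totals[np.arange(s.n_sites), s.ref_idx]
        assert np.all(nonref == 0)

    def test_observed_error_matches_drawn_rates(self, small_sim):
        # law of large numbers: mean non-ref fraction over the cohort
        # approaches the mean per-site error rate
        assay = get_assay(small_sim)
        samples = simulate_pon(small_sim, n=16, seed=2)
        fracs = []
        for s in samples:
            totals = s.allele_totals
            depth = s.depth
            keep = np.ones(s.n_sites, dtype=bool)
            keep[assay.snp_rows] = False  # genotypes are not errors
            keep &= depth > 0
            nonref = (
                totals.sum(axis=1)
                - totals[np.arange(s.n_sites), s.ref_idx]
            )
            fracs.append(nonref[keep] / depth[keep])
        observed = float(np.mean(np.concatenate(fracs)))
        expected = float(np.mean(assay.err[keep]))
        n_obs = sum(len(f) for f in fracs)
        se = np.sqrt(expected / (small_sim.depth_mean * n_obs)) + 3e-5
        assert abs(observed - expected) < 3 * se


class TestDilutionSimulation:
    def test_replicates_share_truth_but_not_counts(self, small_sim):
        sims = simulate_dilution(
            small_sim, DilutionSpec(ratio="1:10", n_het=15, n_hom=15), seed=8
        )
        assert len(sims) == 3
        truths = [t for _s, t in sims]
        assert truths[0].keys() == truths[1].keys() == truths[2].keys()
        assert sims[0][0] != sims[1][0]

    def test_truth_vaf_recovered_unbiasedly(self, small_sim):
        # observed VAF at truth sites matches the generative mean
        # (expected_vaf + site error) within 3 binomial SEs, per level
        assay = get_assay(small_sim)
        idx = {
            (assay.chrom[i], int(assay.pos[i])): i
            for i in range(assay.n_sites)
        }
        for ratio in ("1:10", "1:50"):
            sims = simulate_dilution(
                small_sim,
                DilutionSpec(ratio=ratio, n_het=60, n_hom=60),
                seed=21,
            )
            by_level: dict[float, list[float]] = {}
            ns: dict[float, list[float]] = {}
            for s, truth in sims:
                totals = s.allele_totals
                depth = s.depth
                for t in truth:
                    i = idx[(t.chrom, t.pos)]
                    if depth[i] == 0:
                        continue
                    bi = "ACGT".index(t.alt)
                    gen_mean = min(t.expected_vaf + assay.err[i], 1.0)
                    by_level.setdefault(t.expected_vaf, []).append(
                        totals[i, bi] / depth[i] - gen_mean
                    )
                    ns.setdefault(t.expected_vaf, []).append(depth[i])
            for level, diffs in by_level.items():
                mean_diff = float(np.mean(diffs))
                se = float(
                    np.sqrt(level / np.mean(ns[level]) / len(diffs))
                )
                assert abs(mean_diff) < 3 * se, (ratio, level)

    def test_no_spikes_gives_empty_truth(self, small_sim):
        sims = simulate_dilution(
            small_sim, DilutionSpec(ratio="1:10", n_het=0, n_hom=0), seed=8
        )
        assert all(len(t) == 0 for _s, t in sims)

    def test_default_benchmark_shape(self, small_sim):
        spec = DilutionSpec(ratio="1:50", n_het=30, n_hom=30)
        sims = simulate_dilution(small_sim, spec, seed=8)
        levels = sims[0][1].by_level()
        assert set(levels) == {0.01, 0.02}
        assert all(len(v) == 30 for v in levels.values())


class TestInjections:
    def test_cnv_scales_target_depth(self, small_sim):
        base = simulate_null(small_sim, seed=41)
        assay = get_assay(small_sim)
        rows = assay.rows_of_gene("GENE03")
        mut = inject_cnv(base, "GENE03", 2.0, small_sim, seed=1)
        ratio = mut.depth[rows].mean() / base.depth[rows].mean()
        assert ratio == pytest.approx(2.0, rel=0.05)
        other = np.setdiff1d(np.arange(base.n_sites), rows)
        np.testing.assert_array_equal(
            mut.counts[other], base.counts[other]
        )

    def test_cnv_unknown_target_rejected(self, small_sim):
        base = simulate_null(small_sim, seed=41)
        with pytest.raises(UrivarError, match="unknown"):
            inject_cnv(base, "NOPE", 2.0, small_sim, seed=1)

    def test_loh_shifts_het_vafs(self, small_sim):
        assay = get_assay(small_sim)
        base = simulate_null(small_sim, seed=42)
        region = "GENE01"
        rows = set(assay.rows_of_gene(region).tolist())
        mut = inject_loh(base, region, 0.6, small_sim, seed=2)
        totals_b, totals_m = base.allele_totals, mut.allele_totals
        shifted = []
        for j, r in enumerate(assay.snp_rows):
            if int(r) not in rows or base.depth[r] == 0:
                continue
            alt = assay.snp_alt_idx[j]
            v_b = totals_b[r, alt] / base.depth[r]
            if 0.1 <= v_b <= 0.9:
                shifted.append(totals_m[r, alt] / mut.depth[r])
        if shifted:  # the individual carries het SNPs in the region
            assert np.mean(shifted) == pytest.approx(0.8, abs=0.06)

    def test_zero_fraction_keeps_balance(self, small_sim):
        base = simulate_null(small_sim, seed=43)
        mut = inject_loh(base, "GENE01", 0.0, small_sim, seed=3)
        np.testing.assert_array_equal(mut.depth, base.depth)


class TestTumorUrinePair:
    def test_expected_urine_vaf_is_shedding_scaled(self, small_sim):
        _t, _u, truth = simulate_tumor_urine_pair(
            small_sim, n_clonal=5, clonal_vaf_tumor=0.4, shedding=0.1,
            n_urine_exclusive=0, seed=9,
        )
        assert all(
            t.expected_vaf == pytest.approx(0.04)
            for t in truth.clonal_urine
        )
        assert len(truth.urine_exclusive) == 0

    def test_full_shedding_matches_tumor_vafs(self, small_sim):
        tumor, urine, truth = simulate_tumor_urine_pair(
            small_sim, n_clonal=8, clonal_vaf_tumor=0.3, shedding=1.0,
            n_urine_exclusive=0, seed=10,
        )
        idx = {
            (tumor.chrom[i], int(tumor.pos[i])): i
            for i in range(tumor.n_sites)
        }
        ratios = []
        for t in truth.clonal_tumor:
            i = idx[(t.chrom, t.pos)]
            bi = "ACGT".index(t.alt)
            tv = tumor.allele_totals[i, bi] / tumor.depth[i]
            uv = urine.allele_totals[i, bi] / urine.depth[i]
            ratios.append(uv / tv)
        assert np.median(ratios) == pytest.approx(1.0, abs=0.15)

    def test_urine_exclusive_vafs_low(self, small_sim):
        _t, _u, truth = simulate_tumor_urine_pair(
            small_sim, n_clonal=2, n_urine_exclusive=12, seed=11,
        )
        vafs = [t.expected_vaf for t in truth.urine_exclusive]
        assert all(0.002 <= v <= 0.01 for v in vafs)

    def test_invalid_shedding_rejected(self, small_sim):
        with pytest.raises(UrivarError):
            simulate_tumor_urine_pair(small_sim, shedding=0.0)


class TestCoverageKnob:
    def test_relative_coverage_spread_monotone_in_sigma(self):
        # the capture-nonuniformity knob must map onto relative-coverage
        # spread so panel comparisons can be reproduced qualitatively
        spreads = []
        for sigma in (0.05, 0.15, 0.4):
            cfg = SimConfig(
                n_targets=30, target_len=200, capture_sigma=sigma, seed=3
            )
            assay = get_assay(cfg)
            s = simulate_null(cfg, seed=1)
            depth = s.depth.astype(float)
            tmean = np.array([
                depth[assay.target_idx == t].mean() for t in range(30)
            ])
            rel = tmean / np.median(tmean)
            spreads.append(rel.std())
        assert spreads[0] < spreads[1] < spreads[2]


class TestSerialUrine:
    def test_zero_shedding_timepoints_lack_signal(self, small_sim):
        tumor, serial, truth = simulate_serial_urine(
            small_sim, sheddings=[0.5, 0.0], times=[0.0, 10.0], seed=12
        )
        idx = {
            (tumor.chrom[i], int(tumor.pos[i])): i
            for i in range(tumor.n_sites)
        }
        _t0, with_signal = serial[0]
        _t1, without = serial[1]
        for t in truth:
            i = idx[(t.chrom, t.pos)]
            bi = "ACGT".index(t.alt)
            v_on = with_signal.allele_totals[i, bi] / max(
                with_signal.depth[i], 1
            )
            v_off = without.allele_totals[i, bi] / max(without.depth[i], 1)
            assert v_off < 0.05
            assert v_on > 0.1
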