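"""CNV calling by coverage t-test and copy-neutral LOH detection."""

import numpy as np
import pytest
from scipy import stats

from urivar.cnv_loh import call_cnv, call_loh, normalized_coverage
from urivar.errors import UrivarError
from urivar.simulate import (
    inject_cnv,
    inject_loh,
    simulate_null,
)
from urivar.types import GenomicInterval, SampleCounts, TargetPanel


def _uniform_sample(panel, depth_per_target, sample_id="s"):
    chrom, pos, tgt = panel.site_grid()
    n = len(pos)
    counts = np.zeros((n, 4, 2), dtype=np.int64)
    for i in range(n):
        d = int(depth_per_target[tgt[i]])
        counts[i, 0, 0] = d // 2
        counts[i, 0, 1] = d - d // 2
    quals = np.zeros((n, 4))
    quals[:, 0] = 37.0
    return SampleCounts(
        sample_id, chrom, pos, np.zeros(n, dtype=np.int64), counts, quals
    )


@pytest.fixture()
def flat_panel():
    return TargetPanel(
        [GenomicInterval("chr1", i * 100, i * 100 + 50, f"G{i}")
         for i in range(9)]
    )


class TestNormalizedCoverage:
    def test_uniform_depth_gives_ones(self, flat_panel):
        s = _uniform_sample(flat_panel, [500] * 9)
        np.testing.assert_allclose(
            normalized_coverage(s, flat_panel), np.ones(9)
        )

    def test_doubled_target_stands_out(self, flat_panel):
        depths = [500] * 9
        depths[4] = 1000
        rel = normalized_coverage(
            _uniform_sample(flat_panel, depths), flat_panel
        )
        assert rel[4] == pytest.approx(2.0)
        assert np.allclose(np.delete(rel, 4), 1.0)

    def test_scale_invariance(self, flat_panel):
        depths = np.array([300, 400, 500, 600, 700, 800, 900, 1000, 1100])
        a = normalized_coverage(
            _uniform_sample(flat_panel, depths), flat_panel
        )
        b = normalized_coverage(
            _uniform_sample(flat_panel, depths * 7), flat_panel
        )
        np.testing.assert_allclose(a, b)

    def test_zero_median_depth_rejected(self, flat_panel):
        with pytest.raises(UrivarError, match="median"):
            normalized_coverage(
                _uniform_sample(flat_panel, [0] * 9), flat_panel
            )


class TestCallCnv:
    def test_prediction_interval_t_statistic(self, small_reference):
        # mean_pon 1.0, sd 0.05, n = 16, x = 1.5:
        # log2fc = log2(1.5) ~ 0.585 and t = 0.5 / (0.05 sqrt(17/16)) ~ 9.70
        # at n = 16 the reference arithmetic gives t ~ 9.70
        assert 0.5 / (0.05 * np.sqrt(1 + 1 / 16)) == pytest.approx(
            9.70, abs=0.02
        )
        _assay, _normals, pon = small_reference
        n = pon.n_normals
        t_expected = 0.5 / (0.05 * np.sqrt(1 + 1 / n))
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, n)
        relcov = 1.0 + 0.05 * (base - base.mean()) / base.std(ddof=1)
        pon.target_relcov[0] = relcov  # exact mean 1.0, sd 0.05
        sample = _uniform_sample(
            pon.panel,
            [1500] + [1000] * (len(pon.panel) - 1),
        )
        # make target 0 the only non-median target
        call = {c.gene: c for c in call_cnv(sample, pon)}[
            pon.panel.genes[0]
        ]
        assert call.log2fc == pytest.approx(np.log2(1.5), abs=1e-6)
        assert call.t_stat == pytest.approx(t_expected, rel=1e-6)
        p_expected = 2 * stats.t.sf(t_expected, df=n - 1)
        assert call.p_value == pytest.approx(p_expected, rel=1e-9)

    def test_sample_at_pon_mean_is_neutral(self, small_reference):
        _assay, _normals, pon = small_reference
        # a synthetic sample whose relative coverage equals the PON mean
        sample = _uniform_sample(
            pon.panel,
            np.round(1000 * pon.target_relcov.mean(axis=1)),
        )
        calls = call_cnv(sample, pon)
        assert all(c.direction == "neutral" for c in calls)
        assert all(abs(c.log2fc) < 0.1 for c in calls)

    def test_injected_gain_detected(self, small_sim, small_reference):
        assay, _normals, pon = small_reference
        target = assay.panel.genes[3]
        base = simulate_null(small_sim, seed=61)
        mut = inject_cnv(base, target, 2.0, small_sim, seed=62)
        call = {c.gene: c for c in call_cnv(mut, pon)}[target]
        assert call.direction == "gain"
        assert call.log2fc == pytest.approx(1.0, abs=0.25)

    def test_null_false_call_rate_controlled(self, small_sim, small_reference):
        _assay, _normals, pon = small_reference
        flagged = total = 0
        for seed in range(70, 76):
            calls = call_cnv(simulate_null(small_sim, seed=seed), pon)
            flagged += sum(c.direction != "neutral" for c in calls)
            total += len(calls)
        # BH at q<0.05 plus the effect-size floor keeps null calls rare
        assert flagged / total <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / total)


class TestCallLoh:
    def test_balanced_hets_give_no_events(self, small_reference):
        assay, _normals, pon = small_reference
        # construct a sample whose SNP sites sit exactly at VAF 0.5
        chrom, pos, _tgt = assay.panel.site_grid()
        n = len(pos)
        counts = np.zeros((n, 4, 2), dtype=np.int64)
        counts[:, 0, 0] = 500
        counts[:, 0, 1] = 500
        for j, r in enumerate(assay.snp_rows):
            alt = assay.snp_alt_idx[j]
            counts[r, 0, 0] = counts[r, 0, 1] = 250
            counts[r, alt, 0] = counts[r, alt, 1] = 250
        quals = np.full((n, 4), 37.0)
        sample = SampleCounts(
            "hets", chrom, pos, assay.ref_idx.copy(), counts, quals
        )
        events, burden = call_loh(sample, assay.snp_sites, pon)
        assert burden == 0
        assert all(e.mean_dev == pytest.approx(0.0) for e in events)

    def test_homozygous_sites_do_not_contribute(self, small_reference):
        assay, _normals, pon = small_reference
        chrom, pos, _tgt = assay.panel.site_grid()
        n = len(pos)
        counts = np.zeros((n, 4, 2), dtype=np.int64)
        counts[:, 0, 0] = counts[:, 0, 1] = 500
        for j, r in enumerate(assay.snp_rows):
            alt = assay.snp_alt_idx[j]
            counts[r, 0, 0] = counts[r, 0, 1] = 0
            counts[r, alt, 0] = counts[r, alt, 1] = 500  # VAF 1.00
        quals = np.full((n, 4), 37.0)
        sample = SampleCounts(
            "homs", chrom, pos, assay.ref_idx.copy(), counts, quals
        )
        events, burden = call_loh(sample, assay.snp_sites, pon)
        # VAF 1.00 matches the expected homozygous state: no het sites,
        # hence no regions and no events
        assert events == [] and burden == 0

    def test_injected_loh_called(self, small_sim, small_reference):
        assay, _normals, pon = small_reference
        for seed in (81, 82, 83):
            base = simulate_null(small_sim, seed=seed)
            events0, _ = call_loh(base, assay.snp_sites, pon)
            region = next(
                (e.region for e in events0 if e.n_het_sites >= 5), None
            )
            if region is None:
                continue
            mut = inject_loh(base, region, 0.6, small_sim, seed=seed + 100)
            events, burden = call_loh(mut, assay.snp_sites, pon)
            ev = {e.region: e for e in events}[region]
            assert ev.mean_dev == pytest.approx(0.30, abs=0.05)
            assert ev.called and burden >= 1
            return
        pytest.skip("no region with enough het SNPs in these draws")

    def test_null_burden_near_zero(self, small_sim, small_reference):
        assay, _normals, pon = small_reference
        burdens = [
            call_loh(simulate_null(small_sim, seed=s), assay.snp_sites,
                     pon)[1]
            for s in range(90, 96)
        ]
        assert sum(burdens) <= 1


class TestGroupContrast:
    def test_mann_whitney_separates_burden_groups(
        self, small_sim, small_reference
    ):
        # two cohorts of 30: one null, one with LOH injected into two
        # regions; the rank test must reject at alpha = 0.05
        assay, _normals, pon = small_reference
        genes = assay.panel.genes
        null_b, loh_b = [], []
        for i in range(30):
            s = simulate_null(small_sim, seed=200 + i)
            null_b.append(call_loh(s, assay.snp_sites, pon)[1])
            s2 = simulate_null(small_sim, seed=300 + i)
            for g in (genes[0], genes[4]):
                s2 = inject_loh(s2, g, 0.8, small_sim, seed=400 + i)
            loh_b.append(call_loh(s2, assay.snp_sites, pon)[1])
        res = stats.mannwhitneyu(loh_b, null_b, alternative="greater")
        assert res.pvalue < 0.05
        assert np.mean(loh_b) > np.mean(null_b)
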