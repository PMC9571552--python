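"""Ensemble SNV caller: filters, thresholds, scoring, classification."""

import numpy as np
import pytest
from scipy import stats

from urivar.caller import (
    CallerConfig,
    calibrate,
    classify_germline,
    empirical_call,
    ensemble_call,
    feature_matrix,
    fit_forest,
    hard_filters,
    score_anomaly,
    somatic_calls,
)
from urivar.errors import CalibrationError
from urivar.io import write_vcf
from urivar.simulate import DilutionSpec, simulate_dilution, simulate_null
from urivar.types import CandidateVariant


def _cand(vaf_n=10, depth=1000, qual=35.0, fwd=None):
    fwd = vaf_n // 2 if fwd is None else fwd
    return CandidateVariant(
        chrom="chr1", pos=101, ref="A", alt="G",
        alt_depth=vaf_n, depth=depth, mean_alt_qual=qual,
        fwd_alt=fwd, rev_alt=vaf_n - fwd,
    )


class TestHardFilters:
    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            # phred floor of 30: a 2% variant at Q29 fails on quality alone
            (dict(vaf_n=20, depth=1000, qual=29.0), ["min_phred"]),
            # VAF floor of 0.15%: 0.10% fails even at high quality
            (dict(vaf_n=1, depth=1000, qual=35.0), ["min_vaf", "min_alt"]),
            # a clean 1% variant passes everything
            (dict(vaf_n=10, depth=1000, qual=35.0), []),
            (dict(vaf_n=5, depth=80, qual=35.0), ["min_depth"]),
            (dict(vaf_n=2, depth=1000, qual=35.0), ["min_alt"]),
        ],
    )
    def test_filter_reasons(self, kwargs, expected):
        assert hard_filters(_cand(**kwargs), CallerConfig()) == expected


class TestEmpiricalCall:
    def test_spike_over_quiet_site_emitted(self, small_trained):
        assay, _normals, pon, _model, cc, _calib, _training = small_trained
        sims = simulate_dilution(
            assay.cfg, DilutionSpec(ratio="1:10", n_het=20, n_hom=0), seed=31
        )
        sample, truth = sims[0]
        got = {c.key for c in empirical_call(sample, pon, cc)}
        # 5% spikes over a quiet PON overwhelmingly pass
        assert len(truth.keys() & got) >= 18

    def test_subthreshold_candidate_suppressed(self, small_trained):
        assay, _normals, pon, _model, cc, _calib, _training = small_trained
        sample = simulate_null(assay.cfg, seed=77)
        # force a noisy site threshold above an injected weak signal
        chrom, pos = sample.chrom[5], int(sample.pos[5])
        row = pon.site_row(chrom, pos)
        bi = int(np.argmax(np.arange(4) != pon.ref_idx[row]))
        pon.mean_err[row, bi] = 0.004
        pon.sd_err[row, bi] = 0.001
        pon.max_err[row, bi] = 0.006
        d = int(sample.depth[5])
        sample.counts[5, bi, 0] = int(0.005 * d) // 2
        sample.counts[5, bi, 1] = int(0.005 * d) - int(0.005 * d) // 2
        sample.quals[5, bi] = 37.0
        got = empirical_call(sample, pon, cc)
        key = (chrom, pos, "ACGT"[bi])
        assert key not in {c.key for c in got}  # 0.005 < threshold 0.008


class TestGermlineClassification:
    SNPS = frozenset({("chr1", 101)})

    def test_balanced_het_at_snp_is_germline(self):
        c = _cand(vaf_n=500, depth=1000, qual=37.0)
        assert classify_germline(c, self.SNPS, CallerConfig()) == "germline"

    def test_low_vaf_anywhere_is_somatic(self):
        c = _cand(vaf_n=10, depth=1000)
        assert classify_germline(c, self.SNPS, CallerConfig()) == "somatic"
        assert classify_germline(c, frozenset(), CallerConfig()) == "somatic"

    def test_modest_imbalance_still_germline(self):
        # 240/500 = 0.48: the exact binomial test does not reject at 0.01
        c = _cand(vaf_n=240, depth=500)
        p = stats.binomtest(240, 500, 0.5).pvalue
        assert p > 0.01  # oracle: scipy's exact two-sided test
        assert classify_germline(c, self.SNPS, CallerConfig()) == "germline"

    def test_high_vaf_off_snp_is_ambiguous(self):
        c = _cand(vaf_n=400, depth=1000)
        assert classify_germline(c, frozenset(), CallerConfig()) == "ambiguous"

    def test_homozygous_at_snp_is_germline(self):
        c = _cand(vaf_n=996, depth=1000)
        assert classify_germline(c, self.SNPS, CallerConfig()) == "germline"


class TestEnsembleCall:
    def test_uncalibrated_model_refused(self, small_reference):
        assay, normals, pon = small_reference
        cc = CallerConfig(psi=64)
        X = feature_matrix(
            empirical_call(normals[0], pon, cc) or
            [_cand()], pon, cc,
        )
        model = fit_forest(np.vstack([X] * 70), psi=64, seed=1)
        sample = simulate_null(assay.cfg, seed=3)
        with pytest.raises(CalibrationError, match="calibrate"):
            ensemble_call(sample, pon, model, cc, assay.snp_sites)

    def test_truth_variants_called_somatic(self, small_trained):
        assay, _n, pon, model, cc, _calib, _training = small_trained
        sims = simulate_dilution(
            assay.cfg, DilutionSpec(ratio="1:10", n_het=20, n_hom=0), seed=31
        )
        sample, truth = sims[0]
        calls = ensemble_call(sample, pon, model, cc, assay.snp_sites)
        som = {c.key for c in somatic_calls(calls)}
        assert len(truth.keys() & som) >= 17
        assert all(c.passed for c in calls)

    def test_raising_cutoff_shrinks_call_set(self, small_trained):
        assay, _n, pon, model, cc, calib, _training = small_trained
        sample = simulate_null(assay.cfg, seed=55)
        baseline = model.cutoff
        sizes = []
        for cutoff in (0.0, baseline, min(1.0, baseline + 0.1)):
            model.cutoff = cutoff
            sizes.append(len(ensemble_call(sample, pon, model, cc)))
        model.cutoff = baseline
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_deterministic_vcf_output(self, small_trained, tmp_path):
        assay, _n, pon, model, cc, _calib, _training = small_trained
        sims = simulate_dilution(
            assay.cfg, DilutionSpec(ratio="1:10", n_het=10, n_hom=5), seed=13
        )
        sample, _truth = sims[0]
        paths = []
        for i in (1, 2):
            calls = ensemble_call(sample, pon, model, cc, assay.snp_sites)
            p = tmp_path / f"run{i}.vcf"
            write_vcf(calls, sample.sample_id, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()


class TestScoreAnomaly:
    def test_scalar_interface(self, small_trained):
        _a, _n, _pon, model, _cc, _calib, _training = small_trained
        x = np.zeros(model.n_features)
        s = score_anomaly(model, x)
        assert 0 < s <= 1


class TestCalibrate:
    def test_unachievable_target_reports_best(self, small_trained):
        assay, _n, pon, model, cc, _calib, training = small_trained
        with pytest.raises(CalibrationError, match="best achievable"):
            calibrate(
                model, training, pon, cc, snp_sites=assay.snp_sites,
                target_sensitivity=0.99999,
            )

    def test_zero_cutoff_limit_equals_empirical_sensitivity(
        self, small_trained
    ):
        # at cutoff 0 the forest is disabled: ensemble sensitivity equals
        # the empirical component's
        assay, _n, pon, model, cc, _calib, training = small_trained
        n_truth = emp_tp = 0
        for sample, truth in training:
            keys = truth.keys()
            n_truth += len(keys)
            got = {c.key for c in empirical_call(sample, pon, cc)}
            emp_tp += len(keys & got)
        baseline = model.cutoff
        model.cutoff = 0.0
        ens_tp = 0
        for sample, truth in training:
            calls = ensemble_call(sample, pon, model, cc, assay.snp_sites)
            ens_tp += len(truth.keys() & {c.key for c in calls})
        model.cutoff = baseline
        assert ens_tp == emp_tp

    def test_calibrated_sensitivity_meets_target(self, small_trained):
        _a, _n, _pon, _model, _cc, calib, _training = small_trained
        assert calib.sensitivity >= 0.5
        assert 0 <= calib.ppv <= 1


class TestMonotoneShrinkage:
    def test_call_count_weakly_decreases_in_each_knob(self, small_trained):
        assay, _n, pon, model, cc, _calib, _training = small_trained
        sims = simulate_dilution(
            assay.cfg, DilutionSpec(ratio="1:50", n_het=20, n_hom=20), seed=99
        )
        sample, _ = sims[0]

        def count(**kw):
            from dataclasses import replace

            return len(
                ensemble_call(sample, pon, model, replace(cc, **kw),
                              assay.snp_sites)
            )

        base = count()
        assert count(k=cc.k + 2) <= base
        assert count(floor=0.005) <= base
        assert count(min_phred=36.0) <= base
        assert count(min_alt=cc.min_alt + 3) <= base
        assert count(min_depth=400) <= base
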