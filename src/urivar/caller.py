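"""Ensemble somatic SNV calling for urine-derived DNA.

The caller combines two complementary components and requires both to
accept a candidate (a conjunction — the precision-preserving choice when
the goal is high positive predictive value at low VAF):

1. an *empirical* component: hard quality/depth/VAF filters plus a
   location-specific VAF threshold derived from the panel-of-normals noise
   at that site (see :mod:`urivar.noise`); and
2. an *anomaly* component: an isolation forest trained on presumed-negative
   above-floor observations from the panel of normals and from training
   dilutions, so that genuine low-VAF somatic signal stands out from the
   site-noise cloud. The forest's score cutoff is calibrated on spike-in
   training simulations to a target sensitivity, maximizing precision
   subject to that target.

Passing calls are finally classified somatic / germline / ambiguous from
the common-SNP site list and an exact binomial test of allelic balance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import CalibrationError, PanelMismatchError
from .forest import IsolationForest
from .noise import DEFAULT_DELTA, DEFAULT_FLOOR, DEFAULT_K, PanelOfNormals, SD_EPS
from .types import (
    AMBIGUOUS,
    BASES,
    CandidateVariant,
    GERMLINE,
    SOMATIC,
    SampleCounts,
    VariantCall,
)

#: Order of the columns produced by :func:`feature_matrix`. VAF-like and
#: count-like quantities are log-scaled and the PON z-score is asinh-scaled:
#: isolation trees split uniformly within a feature's range, so heavy-tailed
#: features must be represented on the scale where their structure lives.
FEATURE_NAMES: tuple[str, ...] = (
    "log10_vaf",
    "log10_depth",
    "asinh_pon_z",
    "log10_pon_mean_err",
    "mean_alt_qual",
    "strand_balance",
    "log2_alt_depth",
    "log2_excess",
)


@dataclass(frozen=True)
class CallerConfig:
    """Tunable knobs of the ensemble caller (all VAFs as fractions)."""

    min_phred: float = 30.0       # minimum mean alt base quality
    min_vaf: float = 0.0015       # assay VAF floor (0.15%)
    min_depth: int = 100          # minimum total depth at the site
    min_alt: int = 3              # minimum alt-supporting reads
    k: float = DEFAULT_K          # sd multiplier of the site threshold
    delta: float = DEFAULT_DELTA  # inflation of the PON max error VAF
    floor: float = DEFAULT_FLOOR  # threshold floor (equals min_vaf)
    germline_vaf_max: float = 0.35
    germline_alpha: float = 0.01
    hom_p: float = 0.995          # expected allele fraction of a hom call
    n_trees: int = 100
    psi: int = 256
    target_train_sensitivity: float = 0.91

    def validate(self) -> None:
        if self.min_phred < 0 or not 0 <= self.min_vaf <= 1:
            raise ValueError("min_phred/min_vaf out of range")
        if self.min_depth < 1 or self.min_alt < 1:
            raise ValueError("min_depth and min_alt must be >= 1")
        if self.k <= 0 or self.delta < 0 or not 0 <= self.floor <= 1:
            raise ValueError("threshold parameters out of range")
        if not 0 < self.germline_vaf_max < 1:
            raise ValueError("germline_vaf_max must be in (0, 1)")
        if not 0 < self.germline_alpha < 1:
            raise ValueError("germline_alpha must be in (0, 1)")
        if not 0 < self.target_train_sensitivity <= 1:
            raise ValueError("target_train_sensitivity must be in (0, 1]")


# ---------------------------------------------------------------------------
# hard filters
# ---------------------------------------------------------------------------

def hard_filters(c: CandidateVariant, config: CallerConfig) -> list[str]:
    """Names of the hard filters the candidate fails (empty = pass)."""
    failed = []
    if c.mean_alt_qual < config.min_phred:
        failed.append("min_phred")
    if c.vaf < config.min_vaf:
        failed.append("min_vaf")
    if c.depth < config.min_depth:
        failed.append("min_depth")
    if c.alt_depth < config.min_alt:
        failed.append("min_alt")
    return failed


# ---------------------------------------------------------------------------
# vectorized candidate extraction
# ---------------------------------------------------------------------------

def _candidate_arrays(sample: SampleCounts):
    totals = sample.allele_totals
    depth = totals.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(depth[:, None] > 0, totals / depth[:, None], 0.0)
    return totals, depth, vaf


def _empirical_mask(sample, thresholds, config):
    totals, depth, vaf = _candidate_arrays(sample)
    S = sample.n_sites
    alt_mask = np.ones((S, 4), dtype=bool)
    alt_mask[np.arange(S), sample.ref_idx] = False
    mask = (
        alt_mask
        & (vaf >= config.min_vaf)
        & (vaf >= thresholds)
        & (sample.quals >= config.min_phred)
        & (totals >= config.min_alt)
        & (depth[:, None] >= config.min_depth)
    )
    return mask, totals, depth, vaf


def _mask_to_candidates(sample, mask, totals, depth) -> list[CandidateVariant]:
    rows, alts = np.nonzero(mask)
    cands = []
    for i, bi in zip(rows, alts):
        cands.append(
            CandidateVariant(
                chrom=sample.chrom[i],
                pos=int(sample.pos[i]),
                ref=BASES[sample.ref_idx[i]],
                alt=BASES[bi],
                alt_depth=int(totals[i, bi]),
                depth=int(depth[i]),
                mean_alt_qual=float(sample.quals[i, bi]),
                fwd_alt=int(sample.counts[i, bi, 0]),
                rev_alt=int(sample.counts[i, bi, 1]),
            )
        )
    cands.sort(key=lambda c: (c.chrom, c.pos, c.alt))
    return cands


def empirical_call(
    sample: SampleCounts,
    pon: PanelOfNormals,
    config: CallerConfig = CallerConfig(),
) -> list[CandidateVariant]:
    """Candidates passing the hard filters and the site noise thresholds."""
    rows = pon.align(sample)
    if not (rows >= 0).any() and sample.n_sites:
        raise PanelMismatchError(
            f"sample {sample.sample_id!r} shares no sites with the PON panel"
        )
    thresholds = pon.thresholds_for_rows(
        rows, sample.ref_idx, k=config.k, floor=config.floor,
        delta=config.delta,
    )
    mask, totals, depth, _ = _empirical_mask(sample, thresholds, config)
    return _mask_to_candidates(sample, mask, totals, depth)


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def feature_matrix(
    cands: list[CandidateVariant],
    pon: PanelOfNormals,
    config: CallerConfig = CallerConfig(),
) -> np.ndarray:
    """Feature vectors (one row per candidate) for anomaly scoring.

    Features (see :data:`FEATURE_NAMES`): the VAF (log10); log10 depth;
    the PON z-score of the VAF against the site's error distribution
    (asinh-compressed); the PON mean error VAF (log10); the mean alt base
    quality; strand balance (min/max of the per-strand alt support); the
    alt read count (log2); and the log2 margin of the VAF over the site's
    calling threshold.
    """
    n = len(cands)
    X = np.zeros((n, len(FEATURE_NAMES)))
    for i, c in enumerate(cands):
        row = pon.site_row(c.chrom, c.pos)
        bi = BASES.index(c.alt)
        if row is not None and pon.n_obs[row, bi] >= 2:
            mean = float(pon.mean_err[row, bi])
            sd = float(pon.sd_err[row, bi])
            if np.isnan(mean):
                mean = pon.global_mean_err
            if np.isnan(sd):
                sd = pon.global_sd_err
        else:
            mean, sd = pon.global_mean_err, pon.global_sd_err
        thr = pon.site_threshold(
            c.chrom, c.pos, c.alt, k=config.k, floor=config.floor,
            delta=config.delta,
        )
        vaf = c.vaf
        X[i] = (
            np.log10(max(vaf, 1e-6)),
            np.log10(max(c.depth, 1)),
            np.arcsinh((vaf - mean) / max(sd, SD_EPS)),
            np.log10(max(mean, 1e-6)),
            c.mean_alt_qual,
            min(c.fwd_alt, c.rev_alt) / max(1, c.alt_depth),
            np.log2(1 + c.alt_depth),
            np.log2(max(vaf, 1e-6) / max(thr, 1e-6)),
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature encountered")
    return X


def feature_vector(
    c: CandidateVariant,
    pon: PanelOfNormals,
    config: CallerConfig = CallerConfig(),
) -> np.ndarray:
    return feature_matrix([c], pon, config)[0]


def _above_floor_candidates(sample, pon, config) -> list[CandidateVariant]:
    """All (site, alt) observations with VAF at or above the assay floor."""
    totals, depth, vaf = _candidate_arrays(sample)
    S = sample.n_sites
    alt_mask = np.ones((S, 4), dtype=bool)
    alt_mask[np.arange(S), sample.ref_idx] = False
    mask = alt_mask & (vaf >= config.min_vaf) & (totals >= 1)
    return _mask_to_candidates(sample, mask, totals, depth)


def build_training_features(
    pon_samples: list[SampleCounts],
    pon: PanelOfNormals,
    config: CallerConfig = CallerConfig(),
    dilutions=None,
) -> np.ndarray:
    """Presumed-negative training matrix for the isolation forest.

    Rows are feature vectors of every above-floor (site, alt) observation
    in the panel-of-normals samples, plus the non-truth observations from
    the training dilutions (their truth sites are excluded — the forest
    models background noise only).
    """
    blocks = []
    for s in pon_samples:
        cands = _above_floor_candidates(s, pon, config)
        if cands:
            blocks.append(feature_matrix(cands, pon, config))
    for sample, truth in dilutions or []:
        keys = truth.keys()
        cands = [
            c for c in _above_floor_candidates(sample, pon, config)
            if c.key not in keys
        ]
        if cands:
            blocks.append(feature_matrix(cands, pon, config))
    if not blocks:
        raise ValueError("no above-floor training observations")
    return np.vstack(blocks)


def fit_forest(
    training: np.ndarray,
    n_trees: int = 100,
    psi: int = 256,
    seed: int = 0,
) -> IsolationForest:
    """Fit the anomaly forest on a training feature matrix."""
    return IsolationForest(n_trees=n_trees, psi=psi, seed=seed).fit(training)


def score_anomaly(model: IsolationForest, x: np.ndarray) -> float:
    """Anomaly score of one feature vector (higher = more somatic-like)."""
    return model.score_one(np.asarray(x, dtype=float))


# ---------------------------------------------------------------------------
# germline classification
# ---------------------------------------------------------------------------

def classify_germline(
    variant: CandidateVariant,
    snp_sites,
    config: CallerConfig = CallerConfig(),
) -> str:
    """Classify a passing call as germline, somatic, or ambiguous.

    At a common-SNP site the call is germline when an exact two-sided
    binomial test of the alt count is consistent with heterozygous (p=0.5)
    or homozygous (p=hom_p) allelic balance at level ``germline_alpha``.
    Otherwise low-VAF calls (< germline_vaf_max) are somatic; the remainder
    is ambiguous.
    """
    if snp_sites and (variant.chrom, variant.pos) in snp_sites:
        p_het = stats.binomtest(
            variant.alt_depth, variant.depth, 0.5
        ).pvalue
        p_hom = stats.binomtest(
            variant.alt_depth, variant.depth, config.hom_p
        ).pvalue
        if max(p_het, p_hom) >= config.germline_alpha:
            return GERMLINE
    if variant.vaf < config.germline_vaf_max:
        return SOMATIC
    return AMBIGUOUS


# ---------------------------------------------------------------------------
# ensemble calling and calibration
# ---------------------------------------------------------------------------

def ensemble_call(
    sample: SampleCounts,
    pon: PanelOfNormals,
    model: IsolationForest,
    config: CallerConfig = CallerConfig(),
    snp_sites=frozenset(),
) -> list[VariantCall]:
    """PASS calls: empirical candidates whose anomaly score clears the cutoff."""
    cutoff = model.require_calibrated()
    cands = empirical_call(sample, pon, config)
    if not cands:
        return []
    X = feature_matrix(cands, pon, config)
    scores = model.score(X)
    calls = []
    for c, s in zip(cands, scores):
        if s < cutoff:
            continue
        thr = pon.site_threshold(
            c.chrom, c.pos, c.alt, k=config.k, floor=config.floor,
            delta=config.delta,
        )
        calls.append(
            VariantCall(
                variant=c,
                site_threshold=thr,
                anomaly_score=float(s),
                filters_failed=(),
                classification=classify_germline(c, snp_sites, config),
            )
        )
    calls.sort(key=lambda v: (v.chrom, v.pos, v.alt))
    return calls


def somatic_calls(calls: list[VariantCall]) -> list[VariantCall]:
    """The subset of PASS calls classified somatic."""
    return [c for c in calls if c.passed and c.classification == SOMATIC]


def non_germline_calls(calls: list[VariantCall]) -> list[VariantCall]:
    """PASS calls that are not germline (somatic plus ambiguous).

    High-VAF clonal tumor mutations land in the ambiguous class (a
    tumor-only caller cannot separate a 40% somatic clone from a private
    germline variant by allele fraction alone), so concordance and
    longitudinal tracking operate on this set.
    """
    return [c for c in calls if c.passed and c.classification != GERMLINE]


@dataclass
class CalibrationResult:
    cutoff: float
    sensitivity: float
    ppv: float
    n_truth: int
    n_candidates: int


def calibrate(
    model: IsolationForest,
    training_sims,
    pon: PanelOfNormals,
    config: CallerConfig = CallerConfig(),
    snp_sites=frozenset(),
    target_sensitivity: float | None = None,
) -> CalibrationResult:
    """Choose the forest's anomaly cutoff from truth-bearing training sims.

    Grid-searches the cutoff over the observed score range and selects,
    among cutoffs whose training sensitivity meets the target, the one
    maximizing PPV (largest cutoff on ties). Raises
    :class:`~urivar.errors.CalibrationError`, reporting the best achievable
    operating point, when no cutoff reaches the target sensitivity.
    """
    if target_sensitivity is None:
        target_sensitivity = config.target_train_sensitivity
    truth_scores: list[float] = []
    fp_scores: list[float] = []
    n_truth = 0
    for sample, truth in training_sims:
        keys = truth.keys()
        n_truth += len(truth)
        cands = empirical_call(sample, pon, config)
        if not cands:
            continue
        X = feature_matrix(cands, pon, config)
        scores = model.score(X)
        seen = {}
        for c, s in zip(cands, scores):
            if c.key in keys:
                seen[c.key] = max(seen.get(c.key, -np.inf), float(s))
            elif classify_germline(c, snp_sites, config) == SOMATIC:
                fp_scores.append(float(s))
        truth_scores.extend(seen.values())
    if n_truth == 0:
        raise CalibrationError("training simulations carry no truth variants")

    ts = np.array(truth_scores)
    fs = np.array(fp_scores)
    grid = np.unique(np.concatenate([[0.0], ts, fs]))
    tp = (ts[:, None] >= grid[None, :]).sum(axis=0)
    fp = (
        (fs[:, None] >= grid[None, :]).sum(axis=0)
        if len(fs)
        else np.zeros(len(grid), dtype=int)
    )
    sens = tp / n_truth
    with np.errstate(invalid="ignore", divide="ignore"):
        ppv = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), np.nan)
    feasible = sens >= target_sensitivity
    if not feasible.any():
        best = int(np.argmax(sens))
        raise CalibrationError(
            f"no cutoff reaches training sensitivity "
            f"{target_sensitivity:.3f}; best achievable is "
            f"sensitivity={sens[best]:.3f} at PPV={ppv[best]:.3f} "
            f"(cutoff={grid[best]:.4f})"
        )
    ppv_f = np.where(feasible, ppv, -np.inf)
    best_ppv = np.nanmax(ppv_f)
    ties = np.flatnonzero(ppv_f >= best_ppv - 1e-12)
    idx = int(ties[np.argmax(grid[ties])])
    model.cutoff = float(grid[idx])
    return CalibrationResult(
        cutoff=float(grid[idx]),
        sensitivity=float(sens[idx]),
        ppv=float(ppv[idx]),
        n_truth=n_truth,
        n_candidates=int(len(ts) + len(fs)),
    )
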