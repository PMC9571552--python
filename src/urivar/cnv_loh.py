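"""Copy-number and copy-neutral LOH calling against the panel of normals.

CNV: per-target normalized coverage (target mean depth over the sample's
median target depth) is compared to the PON's normalized-coverage
distribution with a prediction-interval t-statistic for a single new
observation,

    t = (x - mean_pon) / (sd_pon * sqrt(1 + 1/n)),   df = n - 1,

two-sided p-values are Benjamini-Hochberg corrected across targets, and a
gain/loss requires both q < q_max and |log2 fold change| above an
effect-size floor.

Copy-neutral LOH: at common germline-SNP positions, heterozygous sites
(sample VAF within the het window) should sit near VAF 0.5; LOH shifts the
retained allele to 0.5 + t/2 at tumor fraction t. Each region's mean
|VAF - 0.5| over het sites is standardized against the PON baseline and
called when the z-statistic and het-site count clear their minima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import PanelMismatchError, UrivarError
from .noise import PanelOfNormals
from .types import SampleCounts, TargetPanel

GAIN = "gain"
LOSS = "loss"
NEUTRAL = "neutral"


@dataclass
class CNVCall:
    gene: str
    sample_rel_cov: float
    log2fc: float
    t_stat: float
    p_value: float
    q_value: float
    direction: str


@dataclass
class LOHEvent:
    region: str
    n_het_sites: int
    mean_dev: float
    z_stat: float
    called: bool


def normalized_coverage(sample: SampleCounts, panel: TargetPanel) -> np.ndarray:
    """Per-target relative coverage: target mean depth / median target depth."""
    chrom, pos, tgt = panel.site_grid()
    index = {(c, int(p)): i for i, (c, p) in enumerate(zip(chrom, pos))}
    rows = np.fromiter(
        (index.get((c, int(p)), -1)
         for c, p in zip(sample.chrom, sample.pos)),
        dtype=np.int64,
        count=sample.n_sites,
    )
    seen = rows >= 0
    if not seen.any():
        raise PanelMismatchError(
            f"sample {sample.sample_id!r} shares no sites with the panel"
        )
    depth = sample.depth
    n_targets = len(panel)
    tsum = np.bincount(tgt[rows[seen]], weights=depth[seen],
                       minlength=n_targets)
    tcnt = np.bincount(tgt[rows[seen]], minlength=n_targets)
    with np.errstate(invalid="ignore", divide="ignore"):
        tmean = np.where(tcnt > 0, tsum / tcnt, np.nan)
    med = np.nanmedian(tmean)
    if not med > 0:
        raise UrivarError(
            f"sample {sample.sample_id!r} has zero median target depth"
        )
    return tmean / med


def call_cnv(
    sample: SampleCounts,
    pon: PanelOfNormals,
    q_max: float = 0.05,
    min_abs_log2fc: float = 0.3,
) -> list[CNVCall]:
    """Per-target CNV calls versus the PON coverage distribution."""
    x = normalized_coverage(sample, pon.panel)
    n = pon.n_normals
    mean = pon.target_relcov.mean(axis=1)
    sd = pon.target_relcov.std(axis=1, ddof=1)
    genes = pon.panel.genes

    usable = np.isfinite(x) & (sd > 0) & (mean > 0)
    if not usable.all():
        import warnings

        for t in np.flatnonzero(~usable):
            warnings.warn(
                f"target {genes[t]!r} skipped (zero PON coverage spread "
                f"or no sample coverage)",
                stacklevel=2,
            )
    t_stat = np.full(len(genes), np.nan)
    t_stat[usable] = (x[usable] - mean[usable]) / (
        sd[usable] * np.sqrt(1.0 + 1.0 / n)
    )
    p = np.full(len(genes), np.nan)
    p[usable] = 2.0 * stats.t.sf(np.abs(t_stat[usable]), df=n - 1)
    q = np.full(len(genes), np.nan)
    if usable.any():
        q[usable] = multipletests(p[usable], method="fdr_bh")[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        log2fc = np.log2(x / mean)

    calls = []
    for t in np.flatnonzero(usable):
        direction = NEUTRAL
        if q[t] < q_max and abs(log2fc[t]) > min_abs_log2fc:
            direction = GAIN if log2fc[t] > 0 else LOSS
        calls.append(
            CNVCall(
                gene=genes[t],
                sample_rel_cov=float(x[t]),
                log2fc=float(log2fc[t]),
                t_stat=float(t_stat[t]),
                p_value=float(p[t]),
                q_value=float(q[t]),
                direction=direction,
            )
        )
    return calls


def call_loh(
    sample: SampleCounts,
    snp_sites,
    pon: PanelOfNormals,
    z_min: float = 3.0,
    min_het: int = 5,
    het_window: tuple[float, float] = (0.10, 0.90),
) -> tuple[list[LOHEvent], int]:
    """Copy-neutral LOH events per region and the sample's LOH burden.

    Heterozygous sites are SNP positions whose sample VAF falls in
    ``het_window``; homozygous sites (VAF near 0 or 1) match their
    expected allelic state and contribute nothing. Returns the per-region
    events (regions with no het sites are excluded) and the number of
    called regions.
    """
    chrom, pos, tgt = pon.panel.site_grid()
    genes = pon.panel.genes
    rows = pon.align(sample)
    totals = sample.allele_totals
    depth = sample.depth

    snp = set((c, int(p)) for c, p in snp_sites)
    by_region: dict[str, list[float]] = {}
    for i in range(sample.n_sites):
        key = (sample.chrom[i], int(sample.pos[i]))
        if key not in snp or depth[i] == 0 or rows[i] < 0:
            continue
        ref = sample.ref_idx[i]
        nonref = totals[i].astype(float)
        nonref[ref] = -1.0
        vaf = nonref.max() / depth[i]
        if not het_window[0] <= vaf <= het_window[1]:
            continue
        region = genes[tgt[rows[i]]]
        by_region.setdefault(region, []).append(abs(vaf - 0.5))

    events = []
    burden = 0
    for region in sorted(by_region):
        devs = by_region[region]
        mean_dev = float(np.mean(devs))
        baseline = pon.loh_baselines.get(region)
        if baseline is None:
            z = np.nan
        else:
            z = (mean_dev - baseline.mean_dev) / baseline.sd_dev
        called = bool(
            len(devs) >= min_het and np.isfinite(z) and z >= z_min
        )
        burden += called
        events.append(
            LOHEvent(
                region=region,
                n_het_sites=len(devs),
                mean_dev=mean_dev,
                z_stat=float(z),
                called=called,
            )
        )
    return events, burden
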