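"""Panel-of-normals (PON) noise and coverage model.

The PON summarizes, per panel site and per alternate base, the background
error VAF observed across a cohort of normal urine samples. Those summaries
drive location-specific calling thresholds: sites that are systematically
noisy demand more alt signal before a variant is considered. The PON also
stores per-target normalized-coverage vectors (for CNV calling) and, when a
germline-SNP site list is supplied, per-region heterozygous-VAF deviation
baselines (for copy-neutral LOH calling).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import PanelMismatchError, UrivarError
from .types import BASES, SampleCounts, TargetPanel

PON_FORMAT_VERSION = "1"

#: numerical floor for sd terms when standardizing
SD_EPS = 1e-6

#: default threshold-rule parameters
DEFAULT_K = 4.0
DEFAULT_FLOOR = 0.0015
DEFAULT_DELTA = 0.1


def beta_method_of_moments(mean, var):
    """Method-of-moments Beta(a, b) fit from a mean and variance.

    Returns ``(a, b)`` arrays; entries are NaN when the moments are outside
    the feasible range (``0 < mean < 1`` and ``0 < var < mean (1 - mean)``).
    """
    mean = np.asarray(mean, dtype=float)
    var = np.asarray(var, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        feasible = (mean > 0) & (mean < 1) & (var > 0) & (var < mean * (1 - mean))
        common = np.where(feasible, mean * (1 - mean) / var - 1.0, np.nan)
        a = mean * common
        b = (1.0 - mean) * common
    return a, b


@dataclass
class AltNoiseStats:
    """Error-VAF summary for a single (site, alt) pair."""

    n_samples: int
    mean_err_vaf: float
    sd_err_vaf: float
    max_err_vaf: float
    beta_alpha: float
    beta_beta: float


@dataclass
class SiteNoiseProfile:
    """Per-alt noise statistics at one panel site."""

    chrom: str
    pos: int
    ref: str
    alts: dict[str, AltNoiseStats]


@dataclass
class LohBaseline:
    """Heterozygous-VAF deviation baseline for one panel region (gene)."""

    region: str
    mean_dev: float
    sd_dev: float
    n_samples: int


class PanelOfNormals:
    """Site-level noise statistics plus coverage baselines from n normals.

    Array attributes are aligned to ``panel.site_grid()``; the second axis
    indexes the four bases A, C, G, T (the reference base's column is NaN).
    """

    def __init__(
        self,
        panel: TargetPanel,
        n_normals: int,
        ref_idx: np.ndarray,
        n_obs: np.ndarray,
        mean_err: np.ndarray,
        sd_err: np.ndarray,
        max_err: np.ndarray,
        target_relcov: np.ndarray,
        global_mean_err: float,
        global_sd_err: float,
        global_max_err: float,
        snp_mask: np.ndarray | None = None,
        loh_baselines: dict[str, LohBaseline] | None = None,
    ) -> None:
        if n_normals < 2:
            raise UrivarError("a panel of normals needs n_normals >= 2")
        self.panel = panel
        self.n_normals = int(n_normals)
        self.chrom, self.pos, self.target_idx = panel.site_grid()
        self.ref_idx = ref_idx
        self.n_obs = n_obs
        self.mean_err = mean_err
        self.sd_err = sd_err
        self.max_err = max_err
        self.target_relcov = target_relcov  # (n_targets, n_normals)
        self.global_mean_err = float(global_mean_err)
        self.global_sd_err = float(global_sd_err)
        self.global_max_err = float(global_max_err)
        self.snp_mask = (
            snp_mask if snp_mask is not None
            else np.zeros(len(self.pos), dtype=bool)
        )
        self.loh_baselines = loh_baselines or {}
        self._index: dict[tuple[str, int], int] | None = None

    # -- lookups ------------------------------------------------------------

    def _build_index(self) -> dict[tuple[str, int], int]:
        if self._index is None:
            self._index = {
                (c, int(p)): i
                for i, (c, p) in enumerate(zip(self.chrom, self.pos))
            }
        return self._index

    def site_row(self, chrom: str, pos: int) -> int | None:
        return self._build_index().get((chrom, pos))

    def align(self, sample: SampleCounts) -> np.ndarray:
        """Grid row of each sample site (-1 where the site is unseen)."""
        idx = self._build_index()
        rows = np.fromiter(
            (idx.get((c, int(p)), -1) for c, p in zip(sample.chrom, sample.pos)),
            dtype=np.int64,
            count=sample.n_sites,
        )
        return rows

    def profile(self, chrom: str, pos: int) -> SiteNoiseProfile | None:
        i = self.site_row(chrom, pos)
        if i is None:
            return None
        ref = BASES[self.ref_idx[i]]
        alts = {}
        for bi, b in enumerate(BASES):
            if b == ref:
                continue
            alts[b] = AltNoiseStats(
                n_samples=int(self.n_obs[i, bi]),
                mean_err_vaf=float(self.mean_err[i, bi]),
                sd_err_vaf=float(self.sd_err[i, bi]),
                max_err_vaf=float(self.max_err[i, bi]),
                beta_alpha=float(self.beta_a[i, bi]),
                beta_beta=float(self.beta_b[i, bi]),
            )
        return SiteNoiseProfile(chrom=chrom, pos=pos, ref=ref, alts=alts)

    @property
    def beta_a(self) -> np.ndarray:
        if not hasattr(self, "_beta_a"):
            with np.errstate(invalid="ignore"):
                var = self.sd_err**2
            self._beta_a, self._beta_b = beta_method_of_moments(
                self.mean_err, var
            )
        return self._beta_a

    @property
    def beta_b(self) -> np.ndarray:
        self.beta_a  # noqa: B018 - triggers the lazy fit
        return self._beta_b

    # -- thresholds ---------------------------------------------------------

    def _global_threshold(self, k: float, floor: float, delta: float) -> float:
        return max(
            floor,
            self.global_mean_err + k * self.global_sd_err,
            (1.0 + delta) * self.global_max_err,
        )

    def thresholds(
        self,
        k: float = DEFAULT_K,
        floor: float = DEFAULT_FLOOR,
        delta: float = DEFAULT_DELTA,
        min_obs: int = 2,
    ) -> np.ndarray:
        """Per-(site, alt) VAF thresholds over the whole grid, shape (S, 4).

        The rule is ``max(floor, mean + k*sd, (1+delta)*max)`` computed from
        the PON error-VAF summaries; site/alt pairs observed in fewer than
        ``min_obs`` normals fall back to the panel-global statistic. The
        reference base's column holds +inf (a ref allele is never a
        variant).
        """
        with np.errstate(invalid="ignore"):
            thr = np.maximum(
                floor,
                np.maximum(
                    self.mean_err + k * self.sd_err,
                    (1.0 + delta) * self.max_err,
                ),
            )
        fallback = self._global_threshold(k, floor, delta)
        thr = np.where(self.n_obs >= min_obs, thr, fallback)
        thr[np.isnan(thr)] = fallback
        rows = np.arange(len(self.pos))
        thr[rows, self.ref_idx] = np.inf
        return thr

    def site_threshold(
        self,
        chrom: str,
        pos: int,
        alt: str,
        k: float = DEFAULT_K,
        floor: float = DEFAULT_FLOOR,
        delta: float = DEFAULT_DELTA,
        min_obs: int = 2,
    ) -> float:
        """Location-specific VAF threshold for one candidate substitution."""
        i = self.site_row(chrom, pos)
        fallback = self._global_threshold(k, floor, delta)
        if i is None:
            return fallback
        bi = {b: j for j, b in enumerate(BASES)}[alt]
        if bi == self.ref_idx[i]:
            raise ValueError(f"{alt} is the reference base at {chrom}:{pos}")
        if self.n_obs[i, bi] < min_obs:
            return fallback
        return float(
            max(
                floor,
                self.mean_err[i, bi] + k * self.sd_err[i, bi],
                (1.0 + delta) * self.max_err[i, bi],
            )
        )

    def stats_for_rows(self, rows: np.ndarray, min_obs: int = 2):
        """(mean, sd) error VAF aligned to ``rows``; fallback where unseen."""
        S = len(rows)
        mean = np.full((S, 4), self.global_mean_err)
        sd = np.full((S, 4), self.global_sd_err)
        seen = rows >= 0
        r = rows[seen]
        m = self.mean_err[r].copy()
        s = self.sd_err[r].copy()
        ok = self.n_obs[r] >= min_obs
        m[~ok] = self.global_mean_err
        s[~ok] = self.global_sd_err
        m[np.isnan(m)] = self.global_mean_err
        s[np.isnan(s)] = self.global_sd_err
        mean[seen] = m
        sd[seen] = s
        return mean, sd

    def thresholds_for_rows(
        self,
        rows: np.ndarray,
        ref_idx: np.ndarray,
        k: float = DEFAULT_K,
        floor: float = DEFAULT_FLOOR,
        delta: float = DEFAULT_DELTA,
        min_obs: int = 2,
    ) -> np.ndarray:
        """Thresholds aligned to sample rows (-1 rows use the fallback)."""
        full = self.thresholds(k=k, floor=floor, delta=delta, min_obs=min_obs)
        fallback = self._global_threshold(k, floor, delta)
        S = len(rows)
        out = np.full((S, 4), fallback)
        seen = rows >= 0
        out[seen] = full[rows[seen]]
        sr = np.arange(S)
        out[sr, ref_idx] = np.inf
        return out

    # -- serialization ------------------------------------------------------

    def to_json(self, path) -> None:
        def listify(a):
            return np.where(np.isnan(a), None, a.astype(object)).tolist()

        payload = {
            "format_version": PON_FORMAT_VERSION,
            "n_normals": self.n_normals,
            "panel": [
                [iv.chrom, iv.start, iv.end, iv.gene] for iv in self.panel
            ],
            "ref_idx": self.ref_idx.tolist(),
            "n_obs": self.n_obs.tolist(),
            "mean_err": listify(self.mean_err),
            "sd_err": listify(self.sd_err),
            "max_err": listify(self.max_err),
            "target_relcov": self.target_relcov.tolist(),
            "global_mean_err": self.global_mean_err,
            "global_sd_err": self.global_sd_err,
            "global_max_err": self.global_max_err,
            "snp_mask": self.snp_mask.astype(int).tolist(),
            "loh_baselines": {
                r: [b.mean_dev, b.sd_dev, b.n_samples]
                for r, b in sorted(self.loh_baselines.items())
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, separators=(",", ":"))

    @classmethod
    def from_json(cls, path) -> "PanelOfNormals":
        from .types import GenomicInterval

        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format_version") != PON_FORMAT_VERSION:
            raise UrivarError(
                f"unsupported PON format version: "
                f"{payload.get('format_version')!r}"
            )

        def arr(x):
            return np.array(
                [[np.nan if v is None else v for v in row] for row in x],
                dtype=float,
            )

        panel = TargetPanel(
            GenomicInterval(c, s, e, g) for c, s, e, g in payload["panel"]
        )
        loh = {
            r: LohBaseline(r, m, s, int(n))
            for r, (m, s, n) in payload["loh_baselines"].items()
        }
        return cls(
            panel=panel,
            n_normals=payload["n_normals"],
            ref_idx=np.array(payload["ref_idx"], dtype=np.int64),
            n_obs=np.array(payload["n_obs"], dtype=np.int64),
            mean_err=arr(payload["mean_err"]),
            sd_err=arr(payload["sd_err"]),
            max_err=arr(payload["max_err"]),
            target_relcov=np.array(payload["target_relcov"], dtype=float),
            global_mean_err=payload["global_mean_err"],
            global_sd_err=payload["global_sd_err"],
            global_max_err=payload["global_max_err"],
            snp_mask=np.array(payload["snp_mask"], dtype=bool),
            loh_baselines=loh,
        )


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def _align_sample(
    sample: SampleCounts,
    grid_index: dict[tuple[str, int], int],
    n_grid: int,
) -> np.ndarray:
    rows = np.fromiter(
        (
            grid_index.get((c, int(p)), -1)
            for c, p in zip(sample.chrom, sample.pos)
        ),
        dtype=np.int64,
        count=sample.n_sites,
    )
    covered = int((rows >= 0).sum())
    if covered < 0.5 * n_grid:
        raise PanelMismatchError(
            f"sample {sample.sample_id!r} covers only {covered}/{n_grid} "
            f"panel sites (>50% required)"
        )
    return rows


def build_pon(
    samples: list[SampleCounts],
    panel: TargetPanel,
    snp_sites=None,
    min_het_sites: int = 3,
    het_window: tuple[float, float] = (0.10, 0.90),
) -> PanelOfNormals:
    """Build a :class:`PanelOfNormals` from normal-sample counts tables.

    Per site and alternate base, the error VAF ``alt_depth / depth`` is
    collected across samples (zero-depth sites are treated as missing) and
    summarized as mean, sample sd, and max. Per-target normalized coverage
    (target mean depth over the sample median target depth) is collected per
    normal. When ``snp_sites`` is given, common-SNP sites are excluded from
    the panel-global fallback statistics and per-region heterozygous-VAF
    deviation baselines are recorded for LOH calling.
    """
    if len(samples) < 2:
        raise UrivarError(f"build_pon needs >=2 samples, got {len(samples)}")
    chrom, pos, tgt = panel.site_grid()
    S = len(pos)
    grid_index = {(c, int(p)): i for i, (c, p) in enumerate(zip(chrom, pos))}
    n = len(samples)

    ref_idx = np.full(S, -1, dtype=np.int64)
    n_obs = np.zeros((S, 4), dtype=np.int64)
    sum_v = np.zeros((S, 4))
    sum_v2 = np.zeros((S, 4))
    max_v = np.zeros((S, 4))
    n_targets = len(panel)
    relcov = np.zeros((n_targets, n))

    snp_rows = np.zeros(S, dtype=bool)
    if snp_sites:
        for key in snp_sites:
            i = grid_index.get((key[0], int(key[1])))
            if i is not None:
                snp_rows[i] = True

    # per-(region, sample) heterozygous deviation for LOH baselines
    genes = panel.genes
    dev_by_region: dict[str, list[float]] = {g: [] for g in set(genes)}

    for si, sample in enumerate(samples):
        rows = _align_sample(sample, grid_index, S)
        seen = rows >= 0
        r = rows[seen]
        # reference consistency
        new = ref_idx[r] == -1
        ref_idx[r[new]] = sample.ref_idx[seen][new]
        if np.any(ref_idx[r] != sample.ref_idx[seen]):
            raise PanelMismatchError(
                f"sample {sample.sample_id!r} disagrees with the PON on "
                f"reference bases"
            )
        depth = sample.depth
        totals = sample.allele_totals
        with np.errstate(invalid="ignore", divide="ignore"):
            vaf = totals / depth[:, None]
        has_depth = depth > 0
        use = seen & has_depth
        ru = rows[use]
        v = vaf[use]
        n_obs[ru] += 1
        sum_v[ru] += v
        sum_v2[ru] += v * v
        np.maximum.at(max_v, ru, v)

        # normalized coverage per target
        tsum = np.bincount(tgt[r], weights=depth[seen], minlength=n_targets)
        tcnt = np.bincount(tgt[r], minlength=n_targets)
        with np.errstate(invalid="ignore", divide="ignore"):
            tmean = tsum / tcnt
        med = np.nanmedian(tmean)
        if not med > 0:
            raise UrivarError(
                f"sample {sample.sample_id!r} has zero median target depth"
            )
        relcov[:, si] = tmean / med

        # LOH deviation baseline contributions
        if snp_sites:
            svaf = np.zeros(S)
            sdep = np.zeros(S, dtype=bool)
            # alt allele at a SNP site = the highest non-ref allele
            tot_grid = np.zeros((S, 4))
            tot_grid[ru] = v
            sdep[ru] = True
            alt_v = tot_grid.copy()
            alt_v[np.arange(S), np.maximum(ref_idx, 0)] = -1.0
            svaf = alt_v.max(axis=1)
            het = (
                snp_rows
                & sdep
                & (svaf >= het_window[0])
                & (svaf <= het_window[1])
            )
            for g in dev_by_region:
                mask = het & np.isin(tgt, [
                    t for t, gg in enumerate(genes) if gg == g
                ])
                if mask.sum() >= min_het_sites:
                    dev_by_region[g].append(
                        float(np.mean(np.abs(svaf[mask] - 0.5)))
                    )

    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sum_v / n_obs
        var = (sum_v2 - n_obs * mean**2) / np.maximum(n_obs - 1, 1)
        var = np.clip(var, 0.0, None)
        sd = np.sqrt(var)
    mean[n_obs == 0] = np.nan
    sd[n_obs < 2] = np.nan
    max_v[n_obs == 0] = np.nan
    rows_all = np.arange(S)
    valid_ref = ref_idx >= 0
    mean[rows_all[valid_ref], ref_idx[valid_ref]] = np.nan
    sd[rows_all[valid_ref], ref_idx[valid_ref]] = np.nan
    max_v[rows_all[valid_ref], ref_idx[valid_ref]] = np.nan
    n_obs[rows_all[valid_ref], ref_idx[valid_ref]] = 0

    # panel-global fallback statistics over non-SNP alt observations
    alt_mask = (n_obs > 0) & ~snp_rows[:, None]
    if alt_mask.any():
        tot_n = n_obs[alt_mask].sum()
        g_mean = float(sum_v[alt_mask].sum() / tot_n)
        g_var = float(sum_v2[alt_mask].sum() / tot_n - g_mean**2)
        g_sd = float(np.sqrt(max(g_var, 0.0)))
        g_max = float(np.nanquantile(max_v[alt_mask], 0.99))
    else:
        g_mean = g_sd = g_max = 0.0

    loh = {}
    for g, devs in dev_by_region.items():
        if len(devs) >= 2:
            arr = np.array(devs)
            loh[g] = LohBaseline(
                region=g,
                mean_dev=float(arr.mean()),
                sd_dev=float(max(arr.std(ddof=1), 2e-3)),
                n_samples=len(devs),
            )

    return PanelOfNormals(
        panel=panel,
        n_normals=n,
        ref_idx=np.maximum(ref_idx, 0),
        n_obs=n_obs,
        mean_err=mean,
        sd_err=sd,
        max_err=max_v,
        target_relcov=relcov,
        global_mean_err=g_mean,
        global_sd_err=g_sd,
        global_max_err=g_max,
        snp_mask=snp_rows,
        loh_baselines=loh,
    )
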