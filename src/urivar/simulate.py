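"""Synthetic targeted-sequencing data for benchmarking the callers.

The generator emulates the validation design used to qualify urine-based
somatic calling: a pool of normal samples for noise modeling, spike-in
dilutions of one reference genotype into another (``1:d`` mixing at spike
fraction ``1/d``, so a heterozygous germline variant appears at expected
VAF ``0.5/d``), null samples for false-positive accounting, injected
copy-number and copy-neutral-LOH events, and matched tumor/urine pairs
with low-VAF urine-exclusive mutations.

Noise structure:

* a per-site error rate ``e_i ~ Beta(a, b)`` (default mean 1e-3), fixed
  per assay so a panel of normals can learn it;
* error reads spread over the three non-reference bases with weights
  0.5 / 0.3 / 0.2 (transition favored over the two transversions);
* per-site depth ``~ NegBin(mean, dispersion)`` modulated by a per-target
  capture factor ``~ LogNormal(0, capture_sigma)`` shared across samples
  (probe affinity) plus a smaller per-sample, per-target factor
  (library-to-library capture variation);
* common germline SNP positions with population minor-allele frequencies,
  genotyped per simulated individual under Hardy-Weinberg proportions.

Everything is deterministic given the config seed plus the per-call seed.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, replace

import numpy as np

from .errors import UrivarError
from .types import BASES, SampleCounts, TargetPanel, TRANSITION, GenomicInterval

SUPPORTED_DILUTIONS = (1, 10, 50, 100)

HET = "het"
HOM = "hom"

_GENOTYPE_VAF = {HET: 0.5, HOM: 1.0}


def parse_ratio(ratio: str) -> int:
    """Parse a dilution label '1:d' into the integer d."""
    try:
        one, d = ratio.split(":")
        one_i, d_i = int(one), int(d)
    except ValueError as exc:
        raise UrivarError(f"malformed dilution ratio {ratio!r}") from exc
    if one_i != 1 or d_i < 1:
        raise UrivarError(f"dilution ratio must be '1:d' with d >= 1, got {ratio!r}")
    return d_i


def expected_vaf(genotype: str, ratio: str) -> float:
    """Expected VAF of a spiked germline variant under a '1:d' dilution.

    The spike fraction is ``1/d``; a heterozygous variant (germline VAF
    0.5) therefore appears at ``0.5/d`` and a homozygous variant at
    ``1/d``. For example (het, '1:10') -> 0.05 and (hom, '1:50') -> 0.02.
    """
    if genotype not in _GENOTYPE_VAF:
        raise UrivarError(f"genotype must be 'het' or 'hom', got {genotype!r}")
    d = parse_ratio(ratio)
    return _GENOTYPE_VAF[genotype] / d


@dataclass(frozen=True)
class TruthVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    expected_vaf: float
    genotype: str  # 'het' or 'hom' origin in the spike sample

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.alt)


class TruthSet:
    """Spiked variants with their expected VAFs, keyed by (chrom, pos, alt)."""

    def __init__(self, entries) -> None:
        self.entries: tuple[TruthVariant, ...] = tuple(
            sorted(entries, key=lambda t: (t.chrom, t.pos, t.alt))
        )

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def keys(self) -> frozenset[tuple[str, int, str]]:
        return frozenset(t.key for t in self.entries)

    def by_level(self) -> dict[float, tuple[TruthVariant, ...]]:
        levels: dict[float, list[TruthVariant]] = {}
        for t in self.entries:
            levels.setdefault(t.expected_vaf, []).append(t)
        return {lv: tuple(ts) for lv, ts in sorted(levels.items())}


@dataclass(frozen=True)
class DilutionSpec:
    """One spike-in mixture: ratio, genotype composition, replicate count."""

    ratio: str = "1:10"
    n_het: int = 180
    n_hom: int = 180
    replicates: int = 3

    def __post_init__(self) -> None:
        d = parse_ratio(self.ratio)
        if d not in SUPPORTED_DILUTIONS:
            raise UrivarError(
                f"supported dilutions are 1:d for d in {SUPPORTED_DILUTIONS}"
            )
        if self.n_het < 0 or self.n_hom < 0 or self.replicates < 1:
            raise UrivarError("negative spike counts or no replicates")

    @property
    def fraction(self) -> float:
        return 1.0 / parse_ratio(self.ratio)


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic assay; defaults are the benchmark conditions."""

    # panel geometry: n_targets * target_len bases (default 50 kb)
    n_targets: int = 50
    target_len: int = 1000
    n_chroms: int = 5
    # per-site error-rate distribution (mean a/(a+b) = 1e-3)
    err_beta_a: float = 1.0
    err_beta_b: float = 999.0
    # depth model
    depth_mean: float = 1000.0
    depth_dispersion: float = 20.0
    capture_sigma: float = 0.15
    sample_capture_sigma: float = 0.05
    # common germline SNPs
    snps_per_target: int = 16
    snp_maf_low: float = 0.2
    snp_maf_high: float = 0.5
    # per-read phred quality of genuine vs erroneous base calls
    qual_real_mean: float = 37.0
    qual_real_sd: float = 1.5
    qual_err_mean: float = 33.0
    qual_err_sd: float = 3.0
    # error spread over the three non-ref bases (transition first)
    alt_weights: tuple[float, float, float] = (0.5, 0.3, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_targets < 1 or self.target_len < 1:
            raise UrivarError("panel must have >=1 target of >=1 base")
        if not (self.err_beta_a > 0 and self.err_beta_b > 0):
            raise UrivarError("error Beta parameters must be positive")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise UrivarError("depth mean and dispersion must be positive")
        if abs(sum(self.alt_weights) - 1.0) > 1e-9:
            raise UrivarError("alt_weights must sum to 1")
        if not 0 <= self.snp_maf_low <= self.snp_maf_high <= 0.5:
            raise UrivarError("SNP MAF range must satisfy 0<=low<=high<=0.5")


class SimulatedAssay:
    """Fixed, seed-derived assay state shared by every simulated sample.

    Holds the panel, per-site reference bases and error rates, per-target
    capture factors, and the common-SNP map. Two calls with the same config
    produce identical assays.
    """

    def __init__(self, cfg: SimConfig) -> None:
        self.cfg = cfg
        rng = np.random.default_rng([cfg.seed, 0xA55A])
        intervals = []
        per_chrom: dict[int, int] = {}
        for t in range(cfg.n_targets):
            c = t % cfg.n_chroms
            j = per_chrom.get(c, 0)
            per_chrom[c] = j + 1
            start = 100_000 + j * (cfg.target_len + 10_000)
            intervals.append(
                GenomicInterval(
                    chrom=f"chr{c + 1}",
                    start=start,
                    end=start + cfg.target_len,
                    gene=f"GENE{t + 1:02d}",
                )
            )
        self.panel = TargetPanel(intervals)
        self.chrom, self.pos, self.target_idx = self.panel.site_grid()
        S = len(self.pos)
        self.n_sites = S
        self.ref_idx = rng.integers(0, 4, size=S)
        self.err = rng.beta(cfg.err_beta_a, cfg.err_beta_b, size=S)
        self.capture = np.exp(
            rng.normal(0.0, cfg.capture_sigma, size=len(self.panel))
        )
        # error weight per (site, base): transition 0.5, transversions 0.3/0.2
        self.err_weights = np.zeros((S, 4))
        for ri, ref in enumerate(BASES):
            rows = self.ref_idx == ri
            ti = BASES.index(TRANSITION[ref])
            tv = [i for i in range(4) if i != ri and i != ti]
            self.err_weights[rows, ti] = cfg.alt_weights[0]
            self.err_weights[rows, tv[0]] = cfg.alt_weights[1]
            self.err_weights[rows, tv[1]] = cfg.alt_weights[2]

        # common germline SNP sites: snps_per_target uniformly within each
        # target, each with a population MAF and a fixed alt base
        snp_rows = []
        for t in range(len(self.panel)):
            rows = np.flatnonzero(self.target_idx == t)
            take = min(cfg.snps_per_target, len(rows))
            snp_rows.append(rng.choice(rows, size=take, replace=False))
        self.snp_rows = np.sort(np.concatenate(snp_rows))
        nsnp = len(self.snp_rows)
        self.snp_maf = rng.uniform(cfg.snp_maf_low, cfg.snp_maf_high, size=nsnp)
        # SNP alt base: a random non-ref base per site
        offs = rng.integers(1, 4, size=nsnp)
        self.snp_alt_idx = (self.ref_idx[self.snp_rows] + offs) % 4

    @property
    def snp_sites(self) -> frozenset[tuple[str, int]]:
        return frozenset(
            (self.chrom[i], int(self.pos[i])) for i in self.snp_rows
        )

    def rows_of_gene(self, gene: str) -> np.ndarray:
        genes = self.panel.genes
        if gene not in genes:
            raise UrivarError(f"unknown target/region {gene!r}")
        t = genes.index(gene)
        return np.flatnonzero(self.target_idx == t)

    # -- sample synthesis ---------------------------------------------------

    def draw_genotypes(self, rng) -> np.ndarray:
        """Germline dosage (0, 0.5, 1) at each SNP site for one individual."""
        q = self.snp_maf
        u = rng.random(len(q))
        hom_alt = q**2
        het = 2 * q * (1 - q)
        g = np.zeros(len(q))
        g[u < hom_alt] = 1.0
        g[(u >= hom_alt) & (u < hom_alt + het)] = 0.5
        return g

    def synthesize(
        self,
        sample_id: str,
        rng,
        spikes: dict[int, tuple[int, float]] | None = None,
        genotypes: np.ndarray | None = None,
        depth_scale: np.ndarray | None = None,
        collection_time: float | None = None,
    ) -> SampleCounts:
        """Draw one sample; ``spikes`` maps grid row -> (alt_idx, p_alt)."""
        cfg = self.cfg
        S = self.n_sites
        jitter = np.exp(
            rng.normal(0.0, cfg.sample_capture_sigma, size=len(self.panel))
        )
        mean = cfg.depth_mean * (self.capture * jitter)[self.target_idx]
        if depth_scale is not None:
            mean = mean * depth_scale
        k = cfg.depth_dispersion
        depth = rng.negative_binomial(k, k / (k + mean))

        counts = rng.binomial(
            depth[:, None], self.err_weights * self.err[:, None]
        )
        # genuinely present non-reference alleles (germline SNPs, spikes)
        real_alt = np.zeros((S, 4), dtype=bool)

        if genotypes is not None:
            g = genotypes
            carrier = g > 0
            rows = self.snp_rows[carrier]
            alt = self.snp_alt_idx[carrier]
            p = np.where(g[carrier] >= 1.0, 1.0 - self.err[rows], 0.5)
            counts[rows, alt] = rng.binomial(depth[rows], p)
            real_alt[rows, alt] = True

        if spikes:
            for row in sorted(spikes):
                alt, p_alt = spikes[row]
                p = float(np.clip(p_alt + self.err[row], 0.0, 1.0))
                counts[row, alt] = rng.binomial(depth[row], p)
                real_alt[row, alt] = True

        # reference reads take the remaining depth; on the rare overshoot
        # trim error counts (smallest weights first)
        counts[np.arange(S), self.ref_idx] = 0
        nonref = counts.sum(axis=1)
        over = np.flatnonzero(nonref > depth)
        for i in over:
            deficit = int(nonref[i] - depth[i])
            order = np.argsort(self.err_weights[i])
            for b in order:
                if deficit <= 0:
                    break
                if b == self.ref_idx[i] or real_alt[i, b]:
                    continue
                take = min(deficit, int(counts[i, b]))
                counts[i, b] -= take
                deficit -= take
            if deficit > 0:  # trim real alleles as a last resort
                for b in order:
                    if deficit <= 0:
                        break
                    take = min(deficit, int(counts[i, b]))
                    counts[i, b] -= take
                    deficit -= take
        counts[np.arange(S), self.ref_idx] = depth - counts.sum(axis=1)

        fwd = rng.binomial(counts, 0.5)
        strand = np.stack([fwd, counts - fwd], axis=2)

        real = real_alt.copy()
        real[np.arange(S), self.ref_idx] = True
        qmean = np.where(real, cfg.qual_real_mean, cfg.qual_err_mean)
        qsd = np.where(real, cfg.qual_real_sd, cfg.qual_err_sd)
        with np.errstate(invalid="ignore", divide="ignore"):
            quals = rng.normal(qmean, qsd / np.sqrt(np.maximum(counts, 1)))
        quals = np.clip(quals, 2.0, 45.0)
        quals[counts == 0] = 0.0

        return SampleCounts(
            sample_id=sample_id,
            chrom=self.chrom,
            pos=self.pos,
            ref_idx=self.ref_idx,
            counts=strand,
            quals=quals,
            collection_time=collection_time,
        )


@functools.lru_cache(maxsize=8)
def get_assay(cfg: SimConfig) -> SimulatedAssay:
    """Assay state for a config (cached; identical across calls)."""
    return SimulatedAssay(cfg)


# ---------------------------------------------------------------------------
# public simulation operations
# ---------------------------------------------------------------------------

def simulate_pon(cfg: SimConfig, n: int = 16, seed: int = 0):
    """Simulate ``n`` normal urine samples over the assay panel."""
    if n < 2:
        raise UrivarError("a panel of normals needs n >= 2")
    assay = get_assay(cfg)
    samples = []
    for i in range(n):
        rng = np.random.default_rng([cfg.seed, seed, 1, i])
        genotypes = assay.draw_genotypes(rng)
        samples.append(
            assay.synthesize(f"normal{i + 1:02d}", rng, genotypes=genotypes)
        )
    return samples


def simulate_null(cfg: SimConfig, seed: int = 0, sample_id: str = "null"):
    """One sample drawn from the same error model as the PON."""
    assay = get_assay(cfg)
    rng = np.random.default_rng([cfg.seed, seed, 2])
    genotypes = assay.draw_genotypes(rng)
    return assay.synthesize(sample_id, rng, genotypes=genotypes)


def _draw_spike_sites(assay: SimulatedAssay, n: int, rng) -> np.ndarray:
    """Distinct non-SNP grid rows for spike-in placement."""
    candidates = np.setdiff1d(
        np.arange(assay.n_sites), assay.snp_rows, assume_unique=False
    )
    if n > len(candidates):
        raise UrivarError(
            f"cannot place {n} spike variants on {len(candidates)} "
            f"non-SNP panel sites"
        )
    return np.sort(rng.choice(candidates, size=n, replace=False))


def simulate_dilution(cfg: SimConfig, spec: DilutionSpec, seed: int = 0):
    """Replicate spike-in dilution samples with their shared truth set.

    Returns a list of ``(SampleCounts, TruthSet)`` of length
    ``spec.replicates``. The spiked genotype set is drawn once (the same
    physical mixture is sequenced repeatedly); read counts differ between
    replicates.
    """
    assay = get_assay(cfg)
    site_rng = np.random.default_rng([cfg.seed, seed, 3, parse_ratio(spec.ratio)])
    rows = _draw_spike_sites(assay, spec.n_het + spec.n_hom, site_rng)
    genos = [HET] * spec.n_het + [HOM] * spec.n_hom
    site_rng.shuffle(genos)
    entries = []
    spikes: dict[int, tuple[int, float]] = {}
    for row, geno in zip(rows, genos):
        alt = int(
            (assay.ref_idx[row] + site_rng.integers(1, 4)) % 4
        )
        evaf = expected_vaf(geno, spec.ratio)
        spikes[int(row)] = (alt, evaf)
        entries.append(
            TruthVariant(
                chrom=assay.chrom[row],
                pos=int(assay.pos[row]),
                ref=BASES[assay.ref_idx[row]],
                alt=BASES[alt],
                expected_vaf=evaf,
                genotype=geno,
            )
        )
    truth = TruthSet(entries)
    out = []
    for rep in range(spec.replicates):
        rng = np.random.default_rng(
            [cfg.seed, seed, 4, parse_ratio(spec.ratio), rep]
        )
        genotypes = assay.draw_genotypes(rng)  # background individual
        sample = assay.synthesize(
            f"dilution_{spec.ratio.replace(':', 'to')}_r{rep + 1}",
            rng,
            spikes=spikes if spec.fraction > 0 else None,
            genotypes=genotypes,
        )
        out.append((sample, truth))
    return out


def inject_cnv(
    sample: SampleCounts,
    target: str,
    ratio: float,
    cfg: SimConfig,
    seed: int = 0,
) -> SampleCounts:
    """Re-draw one target's depths with the mean scaled by ``ratio``."""
    if ratio <= 0:
        raise UrivarError("copy ratio must be > 0")
    assay = get_assay(cfg)
    rows = assay.rows_of_gene(target)
    rng = np.random.default_rng([cfg.seed, seed, 5])
    counts = sample.counts.copy()
    quals = sample.quals.copy()
    k = cfg.depth_dispersion
    depth = sample.depth
    for i in rows:
        d_old = int(depth[i])
        mean = ratio * max(d_old, 1)
        d_new = int(rng.negative_binomial(k, k / (k + mean)))
        flat = counts[i].reshape(-1).astype(float)
        if d_old > 0 and d_new >= 0:
            p = flat / flat.sum()
            counts[i] = rng.multinomial(d_new, p).reshape(4, 2)
        elif d_new > 0:
            counts[i, sample.ref_idx[i], 0] = d_new  # was empty; all ref fwd
    return SampleCounts(
        sample_id=sample.sample_id,
        chrom=sample.chrom,
        pos=sample.pos,
        ref_idx=sample.ref_idx,
        counts=counts,
        quals=quals,
        collection_time=sample.collection_time,
    )


def inject_loh(
    sample: SampleCounts,
    region: str,
    tumor_fraction: float,
    cfg: SimConfig,
    seed: int = 0,
) -> SampleCounts:
    """Shift heterozygous-SNP VAFs in ``region`` from 0.5 to 0.5 + t/2.

    Models copy-neutral loss of heterozygosity at tumor fraction ``t``: the
    retained allele's expected fraction rises to ``0.5 + t/2`` while total
    depth is unchanged.
    """
    if not 0 <= tumor_fraction <= 1:
        raise UrivarError("tumor_fraction must be in [0, 1]")
    assay = get_assay(cfg)
    region_rows = set(assay.rows_of_gene(region).tolist())
    rng = np.random.default_rng([cfg.seed, seed, 6])
    counts = sample.counts.copy()
    depth = sample.depth
    totals = sample.allele_totals
    p_ret = 0.5 + tumor_fraction / 2.0
    for j, row in enumerate(assay.snp_rows):
        if int(row) not in region_rows:
            continue
        alt = int(assay.snp_alt_idx[j])
        ref = int(sample.ref_idx[row])
        d = int(depth[row])
        if d == 0:
            continue
        vaf = totals[row, alt] / d
        if not 0.10 <= vaf <= 0.90:
            continue  # not heterozygous in this individual
        other = int(totals[row].sum() - totals[row, alt] - totals[row, ref])
        nbi = d - other
        a = int(rng.binomial(nbi, p_ret))
        r = nbi - a
        fa = int(rng.binomial(a, 0.5))
        fr = int(rng.binomial(r, 0.5))
        counts[row, alt] = (fa, a - fa)
        counts[row, ref] = (fr, r - fr)
    return SampleCounts(
        sample_id=sample.sample_id,
        chrom=sample.chrom,
        pos=sample.pos,
        ref_idx=sample.ref_idx,
        counts=counts,
        quals=sample.quals.copy(),
        collection_time=sample.collection_time,
    )


@dataclass(frozen=True)
class PairTruth:
    """Truth annotations for a simulated tumor/urine pair."""

    clonal_tumor: TruthSet  # expected VAFs in the tumor
    clonal_urine: TruthSet  # the same mutations at shedding-scaled VAFs
    urine_exclusive: TruthSet
    shedding: float


def simulate_tumor_urine_pair(
    cfg: SimConfig,
    n_clonal: int = 8,
    clonal_vaf_tumor: float = 0.4,
    shedding: float = 0.5,
    n_urine_exclusive: int = 10,
    seed: int = 0,
    urine_exclusive_vaf: tuple[float, float] = (0.002, 0.01),
    collection_time: float | None = None,
):
    """Matched tumor and urine samples sharing a clonal mutation set.

    Clonal mutations appear in the tumor at ``clonal_vaf_tumor`` and in the
    urine at ``shedding * clonal_vaf_tumor``; urine-exclusive mutations
    appear only in the urine at low VAFs (default U(0.002, 0.01)).
    """
    if not 0 < shedding <= 1:
        raise UrivarError("shedding must be in (0, 1]")
    if n_clonal < 0 or n_urine_exclusive < 0:
        raise UrivarError("mutation counts must be non-negative")
    assay = get_assay(cfg)
    rng_sites = np.random.default_rng([cfg.seed, seed, 7])
    rows = _draw_spike_sites(assay, n_clonal + n_urine_exclusive, rng_sites)
    clonal_rows = rows[:n_clonal]
    excl_rows = rows[n_clonal:]
    excl_vafs = rng_sites.uniform(*urine_exclusive_vaf, size=len(excl_rows))

    def entry(row, evaf):
        alt = int((assay.ref_idx[row] + rng_sites.integers(1, 4)) % 4)
        return alt, TruthVariant(
            chrom=assay.chrom[row],
            pos=int(assay.pos[row]),
            ref=BASES[assay.ref_idx[row]],
            alt=BASES[alt],
            expected_vaf=evaf,
            genotype=HET,
        )

    clonal_alt, clonal_tumor, clonal_urine = [], [], []
    for row in clonal_rows:
        alt, t = entry(row, clonal_vaf_tumor)
        clonal_alt.append(alt)
        clonal_tumor.append(t)
        clonal_urine.append(replace(t, expected_vaf=shedding * clonal_vaf_tumor))
    excl_entries, excl_alt = [], []
    for row, evaf in zip(excl_rows, excl_vafs):
        alt, t = entry(row, float(evaf))
        excl_alt.append(alt)
        excl_entries.append(t)

    genotypes_rng = np.random.default_rng([cfg.seed, seed, 8])
    genotypes = get_assay(cfg).draw_genotypes(genotypes_rng)

    tumor_spikes = {
        int(r): (a, clonal_vaf_tumor) for r, a in zip(clonal_rows, clonal_alt)
    }
    urine_spikes = {
        int(r): (a, shedding * clonal_vaf_tumor)
        for r, a in zip(clonal_rows, clonal_alt)
    }
    urine_spikes.update(
        {int(r): (a, float(v))
         for r, a, v in zip(excl_rows, excl_alt, excl_vafs)}
    )
    tumor = assay.synthesize(
        "tumor", np.random.default_rng([cfg.seed, seed, 9]),
        spikes=tumor_spikes, genotypes=genotypes,
    )
    urine = assay.synthesize(
        "urine", np.random.default_rng([cfg.seed, seed, 10]),
        spikes=urine_spikes, genotypes=genotypes,
        collection_time=collection_time,
    )
    truth = PairTruth(
        clonal_tumor=TruthSet(clonal_tumor),
        clonal_urine=TruthSet(clonal_urine),
        urine_exclusive=TruthSet(excl_entries),
        shedding=shedding,
    )
    return tumor, urine, truth


def simulate_serial_urine(
    cfg: SimConfig,
    sheddings: list[float],
    times: list[float],
    n_clonal: int = 5,
    clonal_vaf_tumor: float = 0.4,
    seed: int = 0,
):
    """Serial urine collections with a shedding fraction per timepoint.

    A shedding of 0 at a timepoint means the tumor sheds nothing (the
    clonal mutations are absent). Returns
    ``(tumor, [(time, urine), ...], clonal_truth)``.
    """
    if len(sheddings) != len(times):
        raise UrivarError("sheddings and times must have equal length")
    assay = get_assay(cfg)
    rng_sites = np.random.default_rng([cfg.seed, seed, 11])
    rows = _draw_spike_sites(assay, n_clonal, rng_sites)
    alts = [
        int((assay.ref_idx[r] + rng_sites.integers(1, 4)) % 4) for r in rows
    ]
    truth = TruthSet(
        TruthVariant(
            chrom=assay.chrom[r],
            pos=int(assay.pos[r]),
            ref=BASES[assay.ref_idx[r]],
            alt=BASES[a],
            expected_vaf=clonal_vaf_tumor,
            genotype=HET,
        )
        for r, a in zip(rows, alts)
    )
    genotypes = assay.draw_genotypes(np.random.default_rng([cfg.seed, seed, 12]))
    tumor = assay.synthesize(
        "tumor",
        np.random.default_rng([cfg.seed, seed, 13]),
        spikes={int(r): (a, clonal_vaf_tumor) for r, a in zip(rows, alts)},
        genotypes=genotypes,
    )
    serial = []
    for i, (shed, t) in enumerate(zip(sheddings, times)):
        spikes = (
            {int(r): (a, shed * clonal_vaf_tumor) for r, a in zip(rows, alts)}
            if shed > 0
            else None
        )
        urine = assay.synthesize(
            f"urine_t{i}",
            np.random.default_rng([cfg.seed, seed, 14, i]),
            spikes=spikes,
            genotypes=genotypes,
            collection_time=t,
        )
        serial.append((t, urine))
    return tumor, serial, truth
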