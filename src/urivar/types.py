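"""Core domain types for targeted-panel sequencing of urine-derived DNA.

Coordinate conventions follow the file formats they mirror: BED intervals
are 0-based half-open, while per-site counts and VCF records are 1-based.
A 1-based position ``p`` belongs to the interval ``[start, end)`` iff
``start < p <= end``.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .errors import PanelFormatError

#: Canonical base ordering used for all per-allele arrays.
BASES: tuple[str, ...] = ("A", "C", "G", "T")
BASE_INDEX: dict[str, int] = {b: i for i, b in enumerate(BASES)}

#: Purine<->purine / pyrimidine<->pyrimidine partner of each base.
TRANSITION: dict[str, str] = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` with a gene label."""

    chrom: str
    start: int
    end: int
    gene: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if not self.start < self.end:
            raise ValueError(
                f"start must be < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        """True if the 1-based position ``pos`` falls inside the interval."""
        return self.start < pos <= self.end


class TargetPanel:
    """An ordered, non-overlapping set of capture targets.

    Intervals are sorted by ``(chrom, start)`` at construction; overlapping
    intervals on the same chromosome are rejected.
    """

    def __init__(self, intervals) -> None:
        ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start))
        for prev, cur in zip(ivs, ivs[1:]):
            if prev.chrom == cur.chrom and cur.start < prev.end:
                raise PanelFormatError(
                    f"overlapping intervals on {cur.chrom}: "
                    f"[{prev.start}, {prev.end}) and [{cur.start}, {cur.end})"
                )
        self._intervals: tuple[GenomicInterval, ...] = tuple(ivs)
        self._starts: dict[str, list[int]] = {}
        self._by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in self._intervals:
            self._starts.setdefault(iv.chrom, []).append(iv.start)
            self._by_chrom.setdefault(iv.chrom, []).append(iv)
        self._grid: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None

    @property
    def intervals(self) -> tuple[GenomicInterval, ...]:
        return self._intervals

    @property
    def total_bases(self) -> int:
        return sum(len(iv) for iv in self._intervals)

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TargetPanel):
            return NotImplemented
        return self._intervals == other._intervals

    def __hash__(self) -> int:
        return hash(self._intervals)

    def target_index(self, chrom: str, pos: int) -> int | None:
        """Index of the interval containing 1-based ``pos``, or None."""
        starts = self._starts.get(chrom)
        if not starts:
            return None
        i = bisect.bisect_left(starts, pos) - 1
        if i < 0:
            return None
        iv = self._by_chrom[chrom][i]
        if iv.contains(pos):
            return self._offset(chrom, i)
        return None

    def _offset(self, chrom: str, local_i: int) -> int:
        # intervals are stored sorted by (chrom, start); compute the global
        # index of the local_i-th interval of `chrom`
        n = 0
        for c in sorted(self._by_chrom):
            if c == chrom:
                return n + local_i
            n += len(self._by_chrom[c])
        raise KeyError(chrom)

    def contains(self, chrom: str, pos: int) -> bool:
        return self.target_index(chrom, pos) is not None

    def site_grid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Arrays ``(chrom, pos, target_idx)`` enumerating every panel base.

        Positions are 1-based; the grid is ordered by ``(chrom, start)`` and
        has length ``total_bases``.
        """
        if self._grid is None:
            chroms, poss, tidx = [], [], []
            for t, iv in enumerate(self._intervals):
                n = len(iv)
                chroms.append(np.full(n, iv.chrom, dtype=object))
                poss.append(np.arange(iv.start + 1, iv.end + 1, dtype=np.int64))
                tidx.append(np.full(n, t, dtype=np.int64))
            if chroms:
                self._grid = (
                    np.concatenate(chroms),
                    np.concatenate(poss),
                    np.concatenate(tidx),
                )
            else:
                self._grid = (
                    np.empty(0, dtype=object),
                    np.empty(0, dtype=np.int64),
                    np.empty(0, dtype=np.int64),
                )
        return self._grid

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(iv.gene for iv in self._intervals)


@dataclass
class SiteCounts:
    """Per-strand allele counts and mean base qualities at one site."""

    chrom: str
    pos: int
    ref: str
    fwd_counts: np.ndarray  # (4,) counts per base, forward strand
    rev_counts: np.ndarray  # (4,) counts per base, reverse strand
    mean_qual: np.ndarray  # (4,) mean phred per allele (0 where no reads)

    @property
    def depth(self) -> int:
        return int(self.fwd_counts.sum() + self.rev_counts.sum())

    def allele_depth(self, base: str) -> int:
        i = BASE_INDEX[base]
        return int(self.fwd_counts[i] + self.rev_counts[i])

    def vaf(self, base: str) -> float:
        d = self.depth
        return self.allele_depth(base) / d if d else 0.0


class SampleCounts:
    """Per-site allele counts for one sample over a target panel.

    The heavy data live in numpy arrays ordered site-by-site:

    ``counts``
        int64 array of shape ``(n_sites, 4, 2)`` — reads per base
        (A, C, G, T) per strand (forward, reverse).
    ``quals``
        float64 array of shape ``(n_sites, 4)`` — mean phred base quality
        per allele, 0 where the allele has no reads.
    """

    def __init__(
        self,
        sample_id: str,
        chrom: np.ndarray,
        pos: np.ndarray,
        ref_idx: np.ndarray,
        counts: np.ndarray,
        quals: np.ndarray,
        collection_time: float | None = None,
    ) -> None:
        n = len(pos)
        if not (len(chrom) == len(ref_idx) == n and counts.shape == (n, 4, 2)
                and quals.shape == (n, 4)):
            raise ValueError("inconsistent array shapes for SampleCounts")
        if np.any(counts < 0):
            raise ValueError("negative allele counts")
        if np.any(quals < 0):
            raise ValueError("negative mean qualities")
        self.sample_id = sample_id
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ref_idx = np.asarray(ref_idx, dtype=np.int64)
        self.counts = np.asarray(counts, dtype=np.int64)
        self.quals = np.asarray(quals, dtype=np.float64)
        self.collection_time = collection_time
        self._index: dict[tuple[str, int], int] | None = None

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def depth(self) -> np.ndarray:
        """Total read depth per site, shape ``(n_sites,)``."""
        return self.counts.sum(axis=(1, 2))

    @property
    def allele_totals(self) -> np.ndarray:
        """Strand-pooled counts per allele, shape ``(n_sites, 4)``."""
        return self.counts.sum(axis=2)

    def _build_index(self) -> dict[tuple[str, int], int]:
        if self._index is None:
            self._index = {
                (c, int(p)): i
                for i, (c, p) in enumerate(zip(self.chrom, self.pos))
            }
        return self._index

    def site(self, chrom: str, pos: int) -> SiteCounts:
        i = self._build_index()[(chrom, pos)]
        return SiteCounts(
            chrom=chrom,
            pos=pos,
            ref=BASES[self.ref_idx[i]],
            fwd_counts=self.counts[i, :, 0].copy(),
            rev_counts=self.counts[i, :, 1].copy(),
            mean_qual=self.quals[i].copy(),
        )

    def same_grid(self, other: "SampleCounts") -> bool:
        return (
            self.n_sites == other.n_sites
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.chrom, other.chrom)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleCounts):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.collection_time == other.collection_time
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref_idx, other.ref_idx)
            and np.array_equal(self.counts, other.counts)
            and np.array_equal(self.quals, other.quals)
        )


@dataclass(frozen=True)
class CandidateVariant:
    """A single-nucleotide substitution candidate at one site."""

    chrom: str
    pos: int
    ref: str
    alt: str
    alt_depth: int
    depth: int
    mean_alt_qual: float
    fwd_alt: int
    rev_alt: int

    def __post_init__(self) -> None:
        if self.alt == self.ref:
            raise ValueError("alt must differ from ref")
        if not 0 <= self.alt_depth <= self.depth:
            raise ValueError("alt_depth must be within [0, depth]")

    @property
    def vaf(self) -> float:
        return self.alt_depth / self.depth if self.depth else 0.0

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.alt)


# classification labels for VariantCall
SOMATIC = "somatic"
GERMLINE = "germline"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class VariantCall:
    """A candidate variant annotated by the ensemble caller."""

    variant: CandidateVariant
    site_threshold: float
    anomaly_score: float
    filters_failed: tuple[str, ...] = ()
    classification: str = SOMATIC

    @property
    def passed(self) -> bool:
        return not self.filters_failed

    # convenience pass-throughs
    @property
    def chrom(self) -> str:
        return self.variant.chrom

    @property
    def pos(self) -> int:
        return self.variant.pos

    @property
    def ref(self) -> str:
        return self.variant.ref

    @property
    def alt(self) -> str:
        return self.variant.alt

    @property
    def vaf(self) -> float:
        return self.variant.vaf

    @property
    def key(self) -> tuple[str, int, str]:
        return self.variant.key
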