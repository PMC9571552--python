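"""Readers and writers for the standard file formats urivar consumes.

Supported formats:

* BED (target panel) — 0-based half-open intervals, optional 4th gene column.
* TSV counts table — one row per panel site with per-strand, per-base read
  counts and per-allele mean phred qualities (header documented in
  :data:`COUNTS_COLUMNS`).
* VCF 4.2 — variant calls (via pysam), truth sets, and germline-SNP site
  lists.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .errors import CountsFormatError, PanelFormatError, VcfFormatError
from .types import (
    BASE_INDEX,
    BASES,
    CandidateVariant,
    GenomicInterval,
    SampleCounts,
    TargetPanel,
    VariantCall,
)

#: Required column order of the counts table.
COUNTS_COLUMNS: tuple[str, ...] = (
    "chrom",
    "pos",
    "ref",
    "A_fwd", "A_rev", "C_fwd", "C_rev", "G_fwd", "G_rev", "T_fwd", "T_rev",
    "qual_A", "qual_C", "qual_G", "qual_T",
)

_FILTER_DESCRIPTIONS = {
    "min_phred": "Mean alt base quality below the phred floor",
    "min_vaf": "VAF below the assay floor",
    "min_depth": "Total depth below the minimum",
    "min_alt": "Alt read support below the minimum",
    "site_threshold": "VAF below the location-specific noise threshold",
    "anomaly": "Isolation-forest anomaly score below the calibrated cutoff",
}


# ---------------------------------------------------------------------------
# BED panels
# ---------------------------------------------------------------------------

def read_panel(path: str | Path) -> TargetPanel:
    """Parse a BED file into a :class:`TargetPanel`.

    BED semantics: 0-based half-open coordinates; a 4th column, when
    present, is taken as the gene label. Raises
    :class:`~urivar.errors.PanelFormatError` with the offending line number
    on malformed input or overlapping intervals.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise PanelFormatError(
                    f"{path}: line {lineno}: expected >=3 tab-separated "
                    f"columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise PanelFormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            gene = fields[3] if len(fields) > 3 else ""
            try:
                intervals.append(GenomicInterval(fields[0], start, end, gene))
            except ValueError as exc:
                raise PanelFormatError(
                    f"{path}: line {lineno}: {exc}"
                ) from exc
    return TargetPanel(intervals)


def write_panel(panel: TargetPanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in panel:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.gene}\n")


# ---------------------------------------------------------------------------
# Counts tables
# ---------------------------------------------------------------------------

def read_counts(
    path: str | Path,
    panel: TargetPanel,
    sample_id: str | None = None,
    collection_time: float | None = None,
) -> SampleCounts:
    """Read a TSV counts table and validate it against ``panel``.

    Every row must lie inside a panel interval; if a ``depth`` column is
    present it is checked against the recomputed sum of the eight
    strand/base counts.
    """
    if sample_id is None:
        sample_id = Path(path).stem
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str})
    missing = [c for c in COUNTS_COLUMNS if c not in df.columns]
    if missing:
        raise CountsFormatError(f"{path}: missing columns: {missing}")
    if df.empty:
        warnings.warn(f"{path}: counts table has no data rows", stacklevel=2)
        return SampleCounts(
            sample_id,
            np.empty(0, dtype=object),
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.int64),
            np.zeros((0, 4, 2), dtype=np.int64),
            np.zeros((0, 4)),
            collection_time=collection_time,
        )

    bad_ref = ~df["ref"].isin(BASES)
    if bad_ref.any():
        row = df[bad_ref].iloc[0]
        raise CountsFormatError(
            f"{path}: invalid ref base {row['ref']!r} at "
            f"{row['chrom']}:{row['pos']}"
        )
    for chrom, pos in zip(df["chrom"], df["pos"]):
        if not panel.contains(chrom, int(pos)):
            raise CountsFormatError(
                f"{path}: site {chrom}:{pos} lies outside the target panel"
            )

    count_cols = [f"{b}_{s}" for b in BASES for s in ("fwd", "rev")]
    counts = df[count_cols].to_numpy(dtype=np.int64).reshape(-1, 4, 2)
    if "depth" in df.columns:
        recomputed = counts.sum(axis=(1, 2))
        stated = df["depth"].to_numpy(dtype=np.int64)
        bad = recomputed != stated
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise CountsFormatError(
                f"{path}: depth mismatch at {df['chrom'].iloc[i]}:"
                f"{df['pos'].iloc[i]}: stated {stated[i]}, "
                f"recomputed {recomputed[i]}"
            )
    quals = df[[f"qual_{b}" for b in BASES]].to_numpy(dtype=np.float64)

    # order rows deterministically by (chrom, pos)
    order = np.lexsort((df["pos"].to_numpy(), df["chrom"].to_numpy()))
    return SampleCounts(
        sample_id,
        df["chrom"].to_numpy(dtype=object)[order],
        df["pos"].to_numpy(dtype=np.int64)[order],
        np.array([BASE_INDEX[b] for b in df["ref"]], dtype=np.int64)[order],
        counts[order],
        quals[order],
        collection_time=collection_time,
    )


def write_counts(sample: SampleCounts, path: str | Path) -> None:
    data = {
        "chrom": sample.chrom,
        "pos": sample.pos,
        "ref": [BASES[i] for i in sample.ref_idx],
    }
    for bi, b in enumerate(BASES):
        data[f"{b}_fwd"] = sample.counts[:, bi, 0]
        data[f"{b}_rev"] = sample.counts[:, bi, 1]
    for bi, b in enumerate(BASES):
        data[f"qual_{b}"] = np.round(sample.quals[:, bi], 4)
    data["depth"] = sample.depth
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF calls
# ---------------------------------------------------------------------------

def _call_header(calls, sample_id: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line("##source=urivar")
    header.add_line(f"##urivar_sample={sample_id}")
    contigs = sorted({c.chrom for c in calls})
    maxpos: dict[str, int] = {}
    for c in calls:
        maxpos[c.chrom] = max(maxpos.get(c.chrom, 0), c.pos)
    for contig in contigs:
        header.contigs.add(contig, length=maxpos[contig] + 1000)
    header.info.add("VAF", 1, "Float", "Variant allele frequency")
    header.info.add("ATHR", 1, "Float", "Location-specific VAF threshold")
    header.info.add("ASCORE", 1, "Float", "Isolation-forest anomaly score")
    header.info.add("CLS", 1, "String",
                    "Classification: somatic, germline or ambiguous")
    header.info.add("ALTD", 1, "Integer", "Alt-supporting read depth")
    header.info.add("DP", 1, "Integer", "Total read depth")
    header.info.add("ALTDF", 1, "Integer",
                    "Alt depth on the forward strand")
    header.info.add("ALTDR", 1, "Integer",
                    "Alt depth on the reverse strand")
    header.info.add("AQ", 1, "Float", "Mean phred quality of alt reads")
    names = set(_FILTER_DESCRIPTIONS)
    for c in calls:
        names.update(c.filters_failed)
    for name in sorted(names):
        if name != "PASS":
            header.filters.add(
                name, None, None,
                _FILTER_DESCRIPTIONS.get(name, "Failed filter"),
            )
    return header


def write_vcf(calls, sample_id: str, path: str | Path) -> None:
    """Write calls as VCF 4.2; round-trips through :func:`read_vcf`."""
    calls = sorted(calls, key=lambda c: (c.chrom, c.pos, c.alt))
    header = _call_header(calls, sample_id)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for c in calls:
            rec = vcf.new_record(
                contig=c.chrom,
                start=c.pos - 1,
                stop=c.pos,
                alleles=(c.ref, c.alt),
            )
            rec.info["VAF"] = c.vaf
            rec.info["ATHR"] = c.site_threshold
            rec.info["ASCORE"] = c.anomaly_score
            rec.info["CLS"] = c.classification
            rec.info["ALTD"] = c.variant.alt_depth
            rec.info["DP"] = c.variant.depth
            rec.info["ALTDF"] = c.variant.fwd_alt
            rec.info["ALTDR"] = c.variant.rev_alt
            rec.info["AQ"] = c.variant.mean_alt_qual
            if c.filters_failed:
                for name in c.filters_failed:
                    rec.filter.add(name)
            else:
                rec.filter.add("PASS")
            vcf.write(rec)


def read_vcf(path: str | Path) -> list[VariantCall]:
    calls = []
    try:
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                info = rec.info
                variant = CandidateVariant(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    alt_depth=int(info["ALTD"]),
                    depth=int(info["DP"]),
                    mean_alt_qual=float(info["AQ"]),
                    fwd_alt=int(info["ALTDF"]),
                    rev_alt=int(info["ALTDR"]),
                )
                filters = tuple(f for f in rec.filter.keys() if f != "PASS")
                calls.append(
                    VariantCall(
                        variant=variant,
                        site_threshold=float(info["ATHR"]),
                        anomaly_score=float(info["ASCORE"]),
                        filters_failed=filters,
                        classification=str(info["CLS"]),
                    )
                )
    except (OSError, ValueError, KeyError) as exc:
        raise VcfFormatError(f"{path}: {exc}") from exc
    return calls


# ---------------------------------------------------------------------------
# Truth sets and SNP site lists
# ---------------------------------------------------------------------------

def write_truth_vcf(truth, path: str | Path) -> None:
    """Serialize a simulator truth set (spiked variants with expected VAF)."""
    header = pysam.VariantHeader()
    header.add_line("##source=urivar-simulate")
    entries = sorted(truth, key=lambda t: (t.chrom, t.pos, t.alt))
    maxpos: dict[str, int] = {}
    for t in entries:
        maxpos[t.chrom] = max(maxpos.get(t.chrom, 0), t.pos)
    for contig in sorted(maxpos):
        header.contigs.add(contig, length=maxpos[contig] + 1000)
    header.info.add("EVAF", 1, "Float", "Expected variant allele frequency")
    header.info.add("ORIGIN", 1, "String",
                    "Genotype of the spiked-in variant: het or hom")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for t in entries:
            rec = vcf.new_record(
                contig=t.chrom, start=t.pos - 1, stop=t.pos,
                alleles=(t.ref, t.alt),
            )
            rec.info["EVAF"] = t.expected_vaf
            rec.info["ORIGIN"] = t.genotype
            vcf.write(rec)


def read_truth_vcf(path: str | Path):
    from .simulate import TruthSet, TruthVariant

    entries = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            entries.append(
                TruthVariant(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    expected_vaf=float(rec.info["EVAF"]),
                    genotype=str(rec.info["ORIGIN"]),
                )
            )
    return TruthSet(entries)


def read_snp_sites(path: str | Path) -> frozenset[tuple[str, int]]:
    """Read common-germline-SNP sites from a VCF or two-column TSV."""
    p = str(path)
    if p.endswith((".vcf", ".vcf.gz", ".bcf")):
        sites = set()
        with pysam.VariantFile(p) as vcf:
            for rec in vcf:
                sites.add((rec.chrom, rec.pos))
        return frozenset(sites)
    df = pd.read_csv(p, sep="\t", dtype={"chrom": str})
    if "chrom" not in df.columns or "pos" not in df.columns:
        raise CountsFormatError(
            f"{path}: SNP site TSV needs 'chrom' and 'pos' columns"
        )
    return frozenset(
        (c, int(q)) for c, q in zip(df["chrom"], df["pos"])
    )


def write_snp_sites(sites, path: str | Path) -> None:
    rows = sorted(sites)
    with open(path, "w") as fh:
        fh.write("chrom\tpos\n")
        for chrom, pos in rows:
            fh.write(f"{chrom}\t{pos}\n")
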