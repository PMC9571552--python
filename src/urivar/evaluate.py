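"""Benchmark scoring: confusion counts, concordance, dilution metrics.

True negatives use per-possible-substitution accounting: each panel base
has three possible alternate alleles, so ``TN = 3 * panel_bases - |truth|
- FP``. On a targeted panel the TN universe vastly outnumbers calls, which
is why PPV, not specificity, is the informative precision metric.
Mutation identity is ``(chrom, pos, alt)`` throughout; VAF plays no role
in matching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UrivarError
from .types import TargetPanel


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int


def confusion(calls, truth, panel: TargetPanel) -> ConfusionCounts:
    """Confusion counts for a call set against a truth set.

    ``calls`` may be :class:`~urivar.types.VariantCall` objects or
    ``(chrom, pos, alt)`` keys; ``truth`` is a
    :class:`~urivar.simulate.TruthSet` or an iterable of keys.
    """
    call_keys = {getattr(c, "key", c) for c in calls}
    truth_keys = (
        truth.keys() if hasattr(truth, "keys") and callable(truth.keys)
        else {getattr(t, "key", t) for t in truth}
    )
    for chrom, pos, _alt in truth_keys:
        if not panel.contains(chrom, pos):
            raise UrivarError(f"truth site {chrom}:{pos} is off-panel")
    tp = len(call_keys & truth_keys)
    fp = len(call_keys - truth_keys)
    fn = len(truth_keys - call_keys)
    tn = 3 * panel.total_bases - len(truth_keys) - fp
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Sensitivity, specificity and PPV; None where the denominator is 0."""
    def frac(num, den):
        return num / den if den > 0 else None

    return {
        "sensitivity": frac(c.tp, c.tp + c.fn),
        "specificity": frac(c.tn, c.tn + c.fp),
        "ppv": frac(c.tp, c.tp + c.fp),
    }


@dataclass
class ConcordanceResult:
    tumor_in_urine: float | None
    urine_in_tumor: float | None
    shared: list
    tumor_exclusive: list
    urine_exclusive: list


def _vaf_of(c) -> float:
    return getattr(c, "vaf", getattr(c, "expected_vaf", 0.0))


def concordance(
    tumor_calls,
    urine_calls,
    tumor_subclonal_cutoff: float = 0.10,
) -> ConcordanceResult:
    """Tumor<->urine mutation overlap fractions.

    ``tumor_in_urine`` is computed over tumor mutations at or above the
    sub-clonal VAF cutoff (default 10%) — tumor mutations below it are too
    uncertain to demand in the urine; ``urine_in_tumor`` is computed over
    all urine calls against the unfiltered tumor set.
    """
    tumor = {getattr(c, "key", c): c for c in tumor_calls}
    urine = {getattr(c, "key", c): c for c in urine_calls}
    clonal = {
        k: c for k, c in tumor.items()
        if _vaf_of(c) >= tumor_subclonal_cutoff
    }
    tiu = (
        sum(k in urine for k in clonal) / len(clonal) if clonal else None
    )
    uit = (
        sum(k in tumor for k in urine) / len(urine) if urine else None
    )
    shared = sorted(set(tumor) & set(urine))
    return ConcordanceResult(
        tumor_in_urine=tiu,
        urine_in_tumor=uit,
        shared=[(k, _vaf_of(tumor[k]), _vaf_of(urine[k])) for k in shared],
        tumor_exclusive=[
            (k, _vaf_of(tumor[k])) for k in sorted(set(tumor) - set(urine))
        ],
        urine_exclusive=[
            (k, _vaf_of(urine[k])) for k in sorted(set(urine) - set(tumor))
        ],
    )


def urine_exclusive_summary(
    result: ConcordanceResult, vaf_cut: float = 0.01
) -> dict:
    """Fraction of urine-exclusive events below ``vaf_cut``, plus quantiles."""
    vafs = np.array([v for _k, v in result.urine_exclusive])
    if len(vafs) == 0:
        return {
            "count": 0,
            "fraction_below_cut": None,
            "vaf_quantiles": None,
        }
    return {
        "count": int(len(vafs)),
        "fraction_below_cut": float((vafs < vaf_cut).mean()),
        "vaf_quantiles": {
            "q25": float(np.quantile(vafs, 0.25)),
            "median": float(np.quantile(vafs, 0.5)),
            "q75": float(np.quantile(vafs, 0.75)),
        },
    }


def benchmark(sims, caller, panel: TargetPanel) -> pd.DataFrame:
    """Score a caller over truth-bearing simulated samples.

    ``sims`` is an iterable of ``(SampleCounts, TruthSet)``; ``caller``
    maps a sample to a list of calls. Returns a tidy frame with one row
    per (sample, expected-VAF level) carrying tp/fn/sensitivity for the
    level and the per-sample fp/ppv/specificity (identical across that
    sample's level rows). Row order is deterministic.
    """
    rows = []
    for sample, truth in sims:
        if truth is None:
            raise UrivarError(f"sample {sample.sample_id!r} carries no truth")
        calls = caller(sample)
        call_keys = {getattr(c, "key", c) for c in calls}
        conf = confusion(call_keys, truth, panel)
        sample_metrics = metrics(conf)
        for level, variants in sorted(truth.by_level().items()):
            keys = {t.key for t in variants}
            tp = len(call_keys & keys)
            rows.append(
                {
                    "sample": sample.sample_id,
                    "expected_vaf": level,
                    "n_truth": len(keys),
                    "tp": tp,
                    "fn": len(keys) - tp,
                    "sensitivity": tp / len(keys) if keys else np.nan,
                    "fp": conf.fp,
                    "tn": conf.tn,
                    "ppv_sample": sample_metrics["ppv"],
                    "specificity": sample_metrics["specificity"],
                }
            )
    return pd.DataFrame(rows)


def pooled_level_metrics(bench: pd.DataFrame) -> pd.DataFrame:
    """Pool a benchmark frame across replicates, per expected-VAF level.

    Sensitivity pools tp/(tp+fn) within a level; PPV pools each sample's
    full call set (all its levels) over the samples containing the level —
    the per-sample precision of the mixtures in which those variants were
    sought.
    """
    out = []
    for level, g in bench.groupby("expected_vaf"):
        tp = int(g["tp"].sum())
        fn = int(g["fn"].sum())
        per_sample = bench[bench["sample"].isin(g["sample"])]
        tp_all = int(per_sample["tp"].sum())
        fp_all = int(per_sample.drop_duplicates("sample")["fp"].sum())
        out.append(
            {
                "expected_vaf": level,
                "n_truth": int(g["n_truth"].sum()),
                "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
                "ppv": tp_all / (tp_all + fp_all)
                if tp_all + fp_all
                else np.nan,
                "min_specificity": float(g["specificity"].min()),
            }
        )
    return pd.DataFrame(out).sort_values("expected_vaf", ignore_index=True)
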