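"""Longitudinal residual-disease tracking across serial urine collections.

Given the mutation set that defines a patient's primary tumor (from tumor
sequencing or the first positive urine), serial urine call sets are joined
by mutation identity into a mutation x timepoint VAF matrix. A timepoint
is flagged *residual* when at least one primary mutation is detected at or
above the assay floor; the flag sequence is then summarized into a
clinical course: cleared, residual-then-cleared, persistent, or recurrent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UrivarError

CLEARED = "cleared"
RESIDUAL_THEN_CLEARED = "residual_then_cleared"
PERSISTENT = "persistent"
RECURRENT = "recurrent"

PRIMARY = "primary"
SECONDARY = "secondary"


@dataclass
class LongitudinalProfile:
    """Mutation x timepoint VAF matrix with residual-disease flags."""

    mutations: list[tuple[str, int, str]]  # ordered (chrom, pos, alt)
    labels: list[str]  # 'primary' or 'secondary' per mutation
    baseline_vafs: dict[tuple[str, int, str], float]
    times: list[float]
    matrix: np.ndarray  # (n_mutations, n_timepoints), 0 where absent
    residual: list[bool]  # per timepoint
    floor: float

    def trend(self, key: tuple[str, int, str]) -> np.ndarray:
        """VAF trajectory of one mutation across timepoints."""
        return self.matrix[self.mutations.index(key)]


def _key_vaf(call) -> tuple[tuple[str, int, str], float]:
    key = getattr(call, "key", None)
    if key is None:
        key, vaf = call  # (key, vaf) tuples are accepted too
        return tuple(key), float(vaf)
    return key, call.vaf


def build_profile(
    primary_calls,
    serial_calls,
    floor: float = 0.0015,
) -> LongitudinalProfile:
    """Join primary-tumor mutations with serial urine call sets.

    ``serial_calls`` is a list of ``(time, calls)`` with strictly
    increasing times. Mutations appearing in serial samples but absent
    from the primary set are labeled secondary; they never drive the
    residual flag.
    """
    times = [t for t, _ in serial_calls]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise UrivarError("collection times must be strictly increasing")

    primary = {}
    for c in primary_calls:
        key, vaf = _key_vaf(c)
        primary[key] = max(vaf, primary.get(key, 0.0))

    order: list[tuple[str, int, str]] = sorted(primary)
    labels = [PRIMARY] * len(order)
    seen = set(order)
    per_time = []
    for _t, calls in serial_calls:
        m = {}
        for c in calls:
            key, vaf = _key_vaf(c)
            m[key] = max(vaf, m.get(key, 0.0))
        per_time.append(m)
        for key in sorted(m):
            if key not in seen:
                seen.add(key)
                order.append(key)
                labels.append(SECONDARY)

    matrix = np.zeros((len(order), len(times)))
    for j, m in enumerate(per_time):
        for i, key in enumerate(order):
            matrix[i, j] = m.get(key, 0.0)

    primary_rows = [i for i, lab in enumerate(labels) if lab == PRIMARY]
    residual = [
        bool(len(primary_rows) and (matrix[primary_rows, j] >= floor).any())
        for j in range(len(times))
    ]
    return LongitudinalProfile(
        mutations=order,
        labels=labels,
        baseline_vafs=primary,
        times=list(times),
        matrix=matrix,
        residual=residual,
        floor=floor,
    )


def classify_course(profile: LongitudinalProfile) -> str:
    """Summarize the residual-flag sequence into a clinical course.

    * ``cleared`` — no timepoint is residual.
    * ``recurrent`` — a residual timepoint follows a negative one (the
      disease signal went away, or was absent, and came back).
    * ``residual_then_cleared`` — residual disease ends with at least two
      consecutive negative collections.
    * ``persistent`` — residual at the final timepoint with no negative
      gap, or residual followed by a single trailing negative (one
      negative collection is insufficient evidence of clearance).
    """
    flags = profile.residual
    if len(flags) < 2:
        raise UrivarError("classify_course needs >= 2 timepoints")
    if not any(flags):
        return CLEARED
    # a negative timepoint followed (not necessarily adjacently) by residual
    seen_negative = False
    for f in flags:
        if not f:
            seen_negative = True
        elif seen_negative:
            return RECURRENT
    if flags[-1]:
        return PERSISTENT
    trailing = 0
    for f in reversed(flags):
        if f:
            break
        trailing += 1
    return RESIDUAL_THEN_CLEARED if trailing >= 2 else PERSISTENT
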