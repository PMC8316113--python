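"""Small-RNA analytics.

A 21-nt length mode in reads mapping to both strands of a viral RNA is the
signature of an siRNA (RNA-interference) response.  This module reports the
length histogram/mode of a trimmed small-RNA library and correlates siRNA
coverage with footprint coverage per position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ambiribo.readquant import AlignmentSet

LENGTH_SUPPORT = (18, 35)


@dataclass
class LengthHistogram:
    """Counts per integer read length with the modal length (ties broken
    toward the smaller length and flagged)."""

    counts: dict[int, int]
    modal_length: int
    tie: bool = False

    @property
    def n_reads(self) -> int:
        return sum(self.counts.values())


def sirna_length_mode(reads: AlignmentSet | list[int]) -> LengthHistogram:
    """Length histogram and mode of a small-RNA library (post-trimming)."""
    lengths = (
        [r.length for r in reads.reads]
        if isinstance(reads, AlignmentSet)
        else list(reads)
    )
    if not lengths:
        raise ValueError("empty read set: length mode undefined")
    values, counts = np.unique(np.asarray(lengths), return_counts=True)
    top = counts.max()
    modes = values[counts == top]
    return LengthHistogram(
        counts=dict(zip(values.tolist(), counts.tolist())),
        modal_length=int(modes.min()),
        tie=len(modes) > 1,
    )


@dataclass
class CorrelationResult:
    r: float
    pvalue: float
    defined: bool = True


def coverage_correlation(
    profile_a: np.ndarray, profile_b: np.ndarray
) -> CorrelationResult:
    """Pearson correlation of two per-position coverage profiles.

    Used to test whether siRNA hotspots coincide with footprint plateaus;
    invariant to affine rescaling of either profile.  Zero-variance input
    is flagged undefined rather than raising.
    """
    a = np.asarray(profile_a, float)
    b = np.asarray(profile_b, float)
    if len(a) != len(b):
        raise ValueError("profiles must have equal length")
    if np.std(a) == 0 or np.std(b) == 0:
        return CorrelationResult(math.nan, math.nan, defined=False)
    r, p = stats.pearsonr(a, b)
    return CorrelationResult(float(r), float(p))
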