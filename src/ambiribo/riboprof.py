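"""Ribosome-footprint statistics.

Coverage mapping conventions (center vs 5'-end), per-million normalization,
UMI-based duplicate collapse, footprint length distributions, Welch
power-spectral-density periodicity, and plateau-concentration metrics.

The two mapping conventions follow ribosome-profiling practice: *center*
mapping distributes one read's unit count evenly across all positions the
read covers (useful for coverage shape when the exact ribosome site is
uncertain, as after MNase digestion); *fiveprime* mapping assigns the whole
count to the 5'-end position (used for periodicity analysis, where the 3-nt
translation step appears as a spectral peak at ~0.33 cycles/nt).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import signal, stats

from ambiribo.readquant import AlignmentSet, Read

DEFAULT_LENGTH_RANGE = (27, 39)
WELCH_PARAMS = dict(
    window="hann", nperseg=500, noverlap=250, scaling="density", average="median"
)


@dataclass
class CoverageProfile:
    """Per-position footprint density under a named mapping convention."""

    reference: str
    strand: str
    mapping: Literal["center", "fiveprime"]
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("coverage values must be non-negative")


@dataclass
class PsdResult:
    frequencies: np.ndarray
    power: np.ndarray
    peak_frequency: float
    flat: bool = False  # no power off zero frequency (e.g. constant input)


@dataclass
class UmiCollapseReport:
    n_input: int
    n_kept: int

    @property
    def depletion(self) -> float:
        return 1.0 - self.n_kept / self.n_input if self.n_input else 0.0


def umi_collapse(
    footprints: AlignmentSet,
) -> tuple[AlignmentSet, UmiCollapseReport]:
    """Collapse PCR duplicates on 100% identity of (footprint, UMI).

    Footprint identity is its mapped (start, length, strand); one
    representative is kept per identical (footprint, UMI) pair.  Heavily
    concentrated libraries deplete strongly here because true positional
    diversity can be below the 4^5 = 1024 diversity of a random 5-nt UMI.
    """
    seen = set()
    kept: list[Read] = []
    for r in footprints.reads:
        if r.umi is None:
            raise ValueError("read without UMI; cannot collapse")
        key = (r.start, r.length, r.strand, r.umi)
        if key not in seen:
            seen.add(key)
            kept.append(r)
    report = UmiCollapseReport(len(footprints), len(kept))
    return AlignmentSet(footprints.reference, footprints.ref_length, kept), report


def footprint_coverage(
    footprints: AlignmentSet,
    mapping: Literal["center", "fiveprime"] = "center",
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
    normalize: bool = False,
    strand: str = "+",
) -> CoverageProfile:
    """Build a coverage profile from footprints on one strand.

    Reads with lengths outside ``length_range`` are excluded.  Center
    mapping adds 1/L to each of the L covered positions, so the
    unnormalized vector sums exactly to the number of mapped reads.
    Normalization multiplies by 1e6 / total mapped reads (reads per
    million).
    """
    lo, hi = length_range
    values = np.zeros(footprints.ref_length)
    n_mapped = 0
    for r in footprints.reads:
        if r.strand != strand or not (lo <= r.length <= hi):
            continue
        n_mapped += 1
        if mapping == "center":
            values[r.start : r.start + r.length] += 1.0 / r.length
        elif mapping == "fiveprime":
            pos = r.start if strand == "+" else r.start + r.length - 1
            values[pos] += 1.0
        else:
            raise ValueError(f"unknown mapping {mapping!r}")
    if normalize and n_mapped:
        values *= 1e6 / n_mapped
    return CoverageProfile(
        footprints.reference, strand, mapping, values, normalized=normalize
    )


def footprint_to_total_ratio(
    fp_profile: CoverageProfile,
    rna_profile: CoverageProfile,
    cds: tuple[int, int],
) -> float:
    """Mean within-CDS footprint density over mean within-CDS total-RNA
    density (both per-million normalized, positive strand).  Low values
    flag RNAs that are abundant but sparsely footprinted."""
    if not (fp_profile.normalized and rna_profile.normalized):
        raise ValueError("both profiles must be normalized")
    if fp_profile.reference != rna_profile.reference:
        raise ValueError("profiles refer to different references")
    s, e = cds
    fp = float(np.mean(fp_profile.values[s:e]))
    rna = float(np.mean(rna_profile.values[s:e]))
    if rna == 0:
        return math.nan
    return fp / rna


@dataclass
class LengthDistribution:
    counts: dict[int, int]
    mode: int
    n: int


def length_distribution(
    footprints: AlignmentSet | Sequence[int], min_n: int = 1
) -> LengthDistribution:
    """Histogram of footprint lengths and the modal length (ties broken
    toward the smaller length)."""
    if isinstance(footprints, AlignmentSet):
        lengths = [r.length for r in footprints.reads]
    else:
        lengths = list(footprints)
    if len(lengths) < min_n:
        raise ValueError(f"need >= {min_n} footprints, got {len(lengths)}")
    values, counts = np.unique(np.asarray(lengths), return_counts=True)
    mode = int(values[np.argmax(counts)])
    return LengthDistribution(
        dict(zip(values.tolist(), counts.tolist())), mode, len(lengths)
    )


@dataclass
class LengthComparison:
    statistic: float
    pvalue: float
    significant: bool
    indeterminate: bool = False


def compare_length_distributions(
    a: AlignmentSet | Sequence[int],
    b: AlignmentSet | Sequence[int],
    min_n: int = 50,
    alpha: float = 0.05,
) -> LengthComparison:
    """Two-sample Kolmogorov-Smirnov test on integer footprint lengths."""

    def lengths(x):
        return (
            [r.length for r in x.reads] if isinstance(x, AlignmentSet) else list(x)
        )

    la, lb = lengths(a), lengths(b)
    if len(la) < min_n or len(lb) < min_n:
        return LengthComparison(math.nan, math.nan, False, indeterminate=True)
    res = stats.ks_2samp(la, lb)
    return LengthComparison(float(res.statistic), float(res.pvalue), res.pvalue < alpha)


def welch_periodicity(
    profile: CoverageProfile,
    cds: tuple[int, int],
    pad: int = 25,
    nperseg: int = WELCH_PARAMS["nperseg"],
    noverlap: int = WELCH_PARAMS["noverlap"],
) -> PsdResult:
    """Welch power spectral density of a 5'-end footprint profile.

    The CDS region is taken with ``pad`` nt of flanking padding, scaled to
    unit sum within the reference (so libraries are comparable), and the
    PSD is estimated with a Hann window, 500-nt segments, 250-nt overlap,
    density scaling and median averaging.  Actively translating ribosomes
    put the dominant peak at ~0.33 cycles/nt (3-nt period); the peak
    frequency is the argmax over strictly positive frequencies.
    """
    if profile.mapping != "fiveprime":
        raise ValueError("periodicity analysis expects a fiveprime profile")
    s, e = cds
    lo = max(0, s - pad)
    hi = min(len(profile.values), e + pad)
    region = profile.values[lo:hi].astype(float)
    if len(region) < nperseg:
        raise ValueError(
            f"padded CDS length {len(region)} < nperseg={nperseg}; "
            f"use nperseg <= {len(region)}"
        )
    total = region.sum()
    if total > 0:
        region = region / total
    freqs, power = signal.welch(
        region,
        window=WELCH_PARAMS["window"],
        nperseg=nperseg,
        noverlap=noverlap,
        scaling=WELCH_PARAMS["scaling"],
        average=WELCH_PARAMS["average"],
    )
    positive = freqs > 0
    pos_max = float(np.max(power[positive], initial=0.0))
    # the input is scaled to unit sum, so genuine off-zero power is many
    # orders of magnitude above machine noise; below this it is leakage
    flat = pos_max < 1e-20
    peak = float(freqs[positive][np.argmax(power[positive])]) if not flat else 0.0
    return PsdResult(freqs, power, peak, flat=flat)


@dataclass
class PlateauResult:
    gini: float
    mass90_fraction: float
    defined: bool = True


def plateau_concentration(
    profile: CoverageProfile | np.ndarray, cds: tuple[int, int] | None = None
) -> PlateauResult:
    """Concentration statistics of a coverage profile.

    Returns the Gini coefficient of per-position density (0 = uniform,
    (n-1)/n = a single occupied position) and the smallest fraction of
    positions holding 90% of the total density.  Both are reproducible
    surrogates for the step-like "plateau" footprint pattern on viral
    RNAs, which concentrates density at few discrete positions.
    """
    v = profile.values if isinstance(profile, CoverageProfile) else np.asarray(profile, float)
    if cds is not None:
        v = v[cds[0] : cds[1]]
    total = v.sum()
    if total <= 0:
        return PlateauResult(math.nan, math.nan, defined=False)
    x = np.sort(v)
    n = len(x)
    # Gini via the sorted-rank identity
    gini = float((2 * np.arange(1, n + 1) - n - 1) @ x / (n * total))
    desc = np.sort(v)[::-1]
    csum = np.cumsum(desc)
    k = int(np.searchsorted(csum, 0.9 * total) + 1)
    return PlateauResult(gini, k / n)


def profile_to_bedgraph(profile: CoverageProfile, path: str | Path) -> None:
    """Write a profile as bedGraph-like TSV (ref, start, end, value, strand)."""
    with open(path, "w") as fh:
        for i, v in enumerate(profile.values):
            if v:
                fh.write(
                    f"{profile.reference}\t{i}\t{i + 1}\t{v:.6g}\t{profile.strand}\n"
                )
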