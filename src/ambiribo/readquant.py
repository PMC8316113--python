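"""Read-level (mNGS) estimators.

Strand ratio, length-normalized copy ratio, per-position coverage,
3' (subgenomic-like) enrichment, and classification of SNV patterns as
host-biallelic versus viral-quasispecies.

Alignments are held in a light columnar container (`AlignmentSet`) that can
be built from a SAM file (primary alignments only, via pysam) or from the
package's tab-delimited alignment tables.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

DEFAULT_MIN_READS = 100  # segments with fewer mapped reads are discarded
DEFAULT_BIALLELIC_BAND = (0.40, 0.60)
DEFAULT_SUBGENOMIC_THRESHOLD = 5.0


@dataclass(frozen=True)
class Read:
    """One aligned read: 0-based start, length in nt, strand, optional UMI
    and optional list of (position, alt_base) variants it carries."""

    start: int
    length: int
    strand: str
    umi: str | None = None
    variants: tuple[tuple[int, str], ...] = ()


@dataclass
class AlignmentSet:
    """Stranded read alignments against one reference."""

    reference: str
    ref_length: int
    reads: list[Read] = field(default_factory=list)

    def __post_init__(self) -> None:
        for r in self.reads:
            if r.strand not in "+-":
                raise ValueError(f"bad strand {r.strand!r}")
            if r.start < 0 or r.start + r.length > self.ref_length:
                raise ValueError(
                    f"read [{r.start},{r.start + r.length}) outside reference "
                    f"of length {self.ref_length}"
                )

    def __len__(self) -> int:
        return len(self.reads)

    def starts(self) -> np.ndarray:
        return np.fromiter((r.start for r in self.reads), dtype=np.int64)

    def lengths(self) -> np.ndarray:
        return np.fromiter((r.length for r in self.reads), dtype=np.int64)

    def strands(self) -> np.ndarray:
        return np.array([r.strand for r in self.reads])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start": self.starts(),
                "length": self.lengths(),
                "strand": self.strands(),
                "umi": [r.umi for r in self.reads],
            }
        )

    def to_table(self, path: str | Path) -> None:
        df = self.to_frame()
        df["variants"] = [
            ";".join(f"{p}:{b}" for p, b in r.variants) for r in self.reads
        ]
        df.insert(0, "reference", self.reference)
        df.insert(1, "ref_length", self.ref_length)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_table(cls, path: str | Path) -> "AlignmentSet":
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        reads = []
        for row in df.itertuples(index=False):
            variants = tuple(
                (int(p), b)
                for p, b in (
                    v.split(":") for v in str(row.variants).split(";") if v
                )
            )
            umi = row.umi if row.umi else None
            reads.append(Read(int(row.start), int(row.length), row.strand, umi, variants))
        ref = df["reference"].iloc[0] if len(df) else "ref"
        ref_len = int(df["ref_length"].iloc[0]) if len(df) else 0
        return cls(ref, ref_len, reads)

    @classmethod
    def from_sam(cls, path: str | Path, reference: str | None = None) -> "AlignmentSet":
        """Import primary alignments for one reference from a SAM/BAM file."""
        import pysam

        with pysam.AlignmentFile(str(path), check_sq=False) as f:
            if reference is None:
                reference = f.references[0]
            ref_len = f.get_reference_length(reference)
            reads = []
            for a in f.fetch(until_eof=True):
                if a.is_unmapped or a.is_secondary or a.is_supplementary:
                    continue
                if a.reference_name != reference:
                    continue
                umi = a.get_tag("RX") if a.has_tag("RX") else None
                reads.append(
                    Read(
                        start=a.reference_start,
                        length=a.reference_length or a.query_length,
                        strand="-" if a.is_reverse else "+",
                        umi=umi,
                    )
                )
        return cls(reference, ref_len, reads)


class BelowMinReads(Exception):
    """Raised when a segment has too few reads to estimate a ratio
    (mirrors the reanalysis filter discarding segments with <100 mapped
    read pairs)."""


def strand_ratio(alns: AlignmentSet, min_reads: int = DEFAULT_MIN_READS) -> float:
    """Positive:negative strand read ratio; inf when no negative reads."""
    if len(alns) < min_reads:
        raise BelowMinReads(
            f"{len(alns)} reads < min_reads={min_reads}; segment filtered"
        )
    strands = alns.strands()
    plus = int(np.sum(strands == "+"))
    minus = len(strands) - plus
    if minus == 0:
        return math.inf
    return plus / minus


def length_normalized_copy_ratio(
    alns_a: AlignmentSet,
    len_a: int,
    alns_b: AlignmentSet,
    len_b: int,
) -> float:
    """(reads_a/len_a) / (reads_b/len_b): copy-number ratio of segment a to
    segment b under uniform sampling, independent of segment length."""
    if len_a <= 0 or len_b <= 0:
        raise ValueError("segment lengths must be positive")
    if len(alns_b) == 0:
        return math.inf
    return (len(alns_a) / len_a) / (len(alns_b) / len_b)


def coverage_profile(alns: AlignmentSet) -> dict[str, np.ndarray]:
    """Per-position read-overlap counts, split by strand.

    Each read contributes 1 to every position it covers, so the per-strand
    vector sums to the total aligned bases on that strand.
    """
    out = {}
    for strand in "+-":
        diff = np.zeros(alns.ref_length + 1)
        for r in alns.reads:
            if r.strand == strand:
                diff[r.start] += 1
                diff[r.start + r.length] -= 1
        out[strand] = np.cumsum(diff[:-1])
    return out


@dataclass
class EnrichmentResult:
    ratio: float
    subgenomic_like: bool
    defined: bool = True


def detect_three_prime_enrichment(
    profile: np.ndarray,
    cds: tuple[int, int],
    tail_len: int,
    threshold: float = DEFAULT_SUBGENOMIC_THRESHOLD,
) -> EnrichmentResult:
    """Mean coverage of the 3' tail relative to the CDS body.

    A large excess (default >5x) is the hallmark of subgenomic-RNA
    production, as seen for flavivirus 3' UTRs in mNGS coverage.
    """
    s, e = cds
    if tail_len <= 0 or e + tail_len > len(profile):
        raise ValueError("tail interval empty or outside the profile")
    body = float(np.mean(profile[s:e]))
    tail = float(np.mean(profile[e : e + tail_len]))
    if body == 0:
        return EnrichmentResult(math.nan, False, defined=False)
    ratio = tail / body
    return EnrichmentResult(ratio, ratio > threshold)


# --- SNV calling and pattern classification --------------------------------


@dataclass
class SnvRecord:
    """One variant site: allele counts, non-reference frequencies, and a
    haplotype-consistency (phasing) verdict.  ``phase_informative`` is
    False when no read spans this site together with another variant, in
    which case ``phased`` carries no evidence either way."""

    position: int
    counts: dict[str, int]
    frequencies: dict[str, float]
    phased: bool
    phase_informative: bool = True

    @property
    def coverage(self) -> int:
        return sum(self.counts.values())

    @property
    def n_alleles(self) -> int:
        return sum(1 for n in self.counts.values() if n > 0)


def call_snvs(
    alns: AlignmentSet,
    reference: str,
    min_coverage: int = 20,
    phasing_consistency: float = 0.90,
) -> list[SnvRecord]:
    """Tabulate variant sites from per-read variant lists.

    Phasing is operationalized from reads spanning >=2 variant sites: a
    site is called phased when >=``phasing_consistency`` of spanning reads
    carry one of two complementary allele combinations (as expected for two
    haplotypes of a diploid host), and unphased otherwise.
    """
    per_site: dict[int, Counter] = defaultdict(Counter)
    site_cov: Counter = Counter()
    for r in alns.reads:
        for pos, alt in r.variants:
            per_site[pos][alt] += 1
    cov = coverage_profile(alns)
    total_cov = cov["+"] + cov["-"]

    records = []
    positions = sorted(per_site)
    pairs_seen: dict[tuple[int, int], Counter] = defaultdict(Counter)
    for r in alns.reads:
        span = [p for p in positions if r.start <= p < r.start + r.length]
        muts = dict(r.variants)
        for i in range(len(span)):
            for j in range(i + 1, len(span)):
                a = muts.get(span[i], ".")
                b = muts.get(span[j], ".")
                pairs_seen[(span[i], span[j])][(a, b)] += 1

    phased_pairs: dict[tuple[int, int], bool] = {}
    for key, combos in pairs_seen.items():
        total = sum(combos.values())
        # two complementary haplotype combinations: both-reference, or the
        # major alternate allele at both sites
        major = tuple(
            per_site[pos].most_common(1)[0][0] if per_site[pos] else "."
            for pos in key
        )
        consistent = combos.get((".", "."), 0) + combos.get(major, 0)
        phased_pairs[key] = total > 0 and consistent / total >= phasing_consistency

    for pos in positions:
        coverage = int(total_cov[pos])
        if coverage < min_coverage:
            continue
        alt_counts = dict(per_site[pos])
        ref_base = reference[pos]
        counts = {ref_base: coverage - sum(alt_counts.values()), **alt_counts}
        freqs = {b: n / coverage for b, n in alt_counts.items()}
        verdicts = [ok for key, ok in phased_pairs.items() if pos in key]
        records.append(
            SnvRecord(
                pos,
                counts,
                freqs,
                phased=bool(verdicts) and all(verdicts),
                phase_informative=bool(verdicts),
            )
        )
    return records


Verdict = Literal["host_biallelic", "quasispecies", "indeterminate"]


@dataclass
class SnvClassification:
    verdict: Verdict
    n_sites: int
    freq_range: tuple[float, float] | None
    max_alleles: int
    all_phased: bool


def classify_snv_pattern(
    snvs: Sequence[SnvRecord],
    biallelic_band: tuple[float, float] = DEFAULT_BIALLELIC_BAND,
) -> SnvClassification:
    """Classify an SNV set as host-like or quasispecies-like.

    Host (diploid) variation shows ~50% biallelic frequencies that phase
    into two haplotypes; a replicating viral quasispecies shows many
    low-frequency unphased variants, sometimes >2 alleles per site.
    """
    if not snvs:
        return SnvClassification("indeterminate", 0, None, 0, False)
    freqs = [f for rec in snvs for f in rec.frequencies.values()]
    lo, hi = biallelic_band
    max_alleles = max(rec.n_alleles for rec in snvs)
    informative = [rec for rec in snvs if rec.phase_informative]
    all_phased = all(rec.phased for rec in informative)
    any_unphased = any(not rec.phased for rec in informative)
    in_band = all(lo <= f <= hi for f in freqs)
    any_below = any(f < lo for f in freqs)
    frange = (min(freqs), max(freqs))
    if in_band and max_alleles <= 2 and informative and all_phased:
        verdict: Verdict = "host_biallelic"
    elif any_below or max_alleles > 2 or any_unphased:
        verdict = "quasispecies"
    else:
        verdict = "indeterminate"
    return SnvClassification(verdict, len(snvs), frange, max_alleles, all_phased)
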