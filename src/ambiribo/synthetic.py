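"""Seeded synthetic-data generators.

Every downstream estimator in this package is tested as parameter recovery
against data produced here.  The generators emulate the statistical
structure of a persistently narnavirus-infected mosquito cell line:

* ambigrammatic genomes with 5'-GGGG / CCCC-3' termini and a 21-nt 3'
  hairpin, forward frame free of stops and of the three reverse-stop
  generators (TTA/CTA/TCA);
* stranded mNGS reads at configurable strand ratios (~70:1 for an
  RdRp-like 3.2-kb segment, ~145:1 for a Robin-like 0.8-kb segment) and a
  length-normalized copy ratio (~3.8 Robin:RdRp);
* host-like biallelic phased SNVs (~0.5 frequency, two haplotypes) versus
  viral quasispecies SNVs (low, spread frequencies, >=1 tri-allelic site,
  no linkage);
* ribosome footprints that are either host-like (33-nt length mode, 5'
  ends phase-locked to codons) or viral plateau-like (27-37 nt uniform
  lengths, 5' ends concentrated at stall-queue positions spaced 30-40 nt);
* small RNAs with a 21-nt length mode from both strands (siRNA response).

All generators are deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np

from ambiribo.ambigram import (
    Segment,
    STOP_CODONS,
    reverse_stop_codons,
    revcomp,
    _all_codons,
)
from ambiribo.readquant import AlignmentSet, Read

UMI_LENGTH = 5
_BASES = np.array(list("ACGT"))

# codons legal anywhere in the dual-coding overlap: no forward stop, no
# reverse-stop generator
ALLOWED_CODONS = sorted(
    set(_all_codons()) - set(STOP_CODONS) - set(reverse_stop_codons())
)

# default footprint length distributions
HOST_FOOTPRINT_LENGTHS = {31: 0.05, 32: 0.20, 33: 0.50, 34: 0.15, 35: 0.10}
VIRAL_FOOTPRINT_LENGTHS = {L: 1.0 / 11 for L in range(27, 38)}

# siRNA length distribution, mode 21 nt
SIRNA_LENGTHS = {19: 0.05, 20: 0.15, 21: 0.40, 22: 0.20, 23: 0.10, 24: 0.06, 25: 0.04}


@dataclass
class SimConfig:
    """Simulation parameters; defaults are the study conditions.

    strand_ratio maps segment roles to +:- fold excess; copy_ratio is the
    small:large (Robin:RdRp) length-normalized copy-number ratio.
    """

    seed: int = 0
    rdrp_length: int = 3200
    robin_length: int = 800
    copy_ratio: float = 3.8
    strand_ratio: dict[str, float] = field(
        default_factory=lambda: {"rdrp": 70.0, "robin": 145.0}
    )
    read_length: int = 100
    host_af_range: tuple[float, float] = (0.45, 0.50)
    viral_af_range: tuple[float, float] = (0.02, 0.32)
    viral_max_alleles: int = 3
    host_fp_lengths: dict[int, float] = field(
        default_factory=lambda: dict(HOST_FOOTPRINT_LENGTHS)
    )
    viral_fp_lengths: dict[int, float] = field(
        default_factory=lambda: dict(VIRAL_FOOTPRINT_LENGTHS)
    )
    n_stall_sites: tuple[int, int] = (4, 6)
    queue_spacing: tuple[int, int] = (30, 40)
    queue_depth: int = 8
    periodic: bool = True
    sirna_lengths: dict[int, float] = field(
        default_factory=lambda: dict(SIRNA_LENGTHS)
    )
    mnase_jitter: int = 0  # max +/- nt of A/T-preferring end jitter

    def __post_init__(self) -> None:
        if self.rdrp_length <= 0 or self.robin_length <= 0:
            raise ValueError("segment lengths must be positive")
        if self.copy_ratio <= 0 or any(v <= 0 for v in self.strand_ratio.values()):
            raise ValueError("ratios must be positive")
        for dist in (self.host_fp_lengths, self.viral_fp_lengths, self.sirna_lengths):
            if any(not (18 <= L <= 50) for L in dist):
                raise ValueError("length supports must lie within [18, 50]")

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(seed, stream: str) -> np.random.Generator:
    """Named substream derived from a root seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _stream_key(stream)]))

def _stream_key(stream: str) -> int:
    return int.from_bytes(stream.encode()[:8].ljust(8, b"\0"), "big") % (2**31)


def make_ambigram_genome(length_nt: int, seed: int = 0, seg_id: str = "segment") -> Segment:
    """Generate an ambigrammatic segment of the requested length.

    Layout: 5'-GGGG, then a dual-coding region built codon-by-codon from
    the 58 codons that are neither forward stops nor reverse-stop
    generators (first codon ATG; last codon CAT so the reverse strand
    reads ATG; codon 14 is CAA, a donor admitting a forward-stop design),
    then a 21-nt inverted-repeat (hairpin-capable) tail ending CCCC-3'.
    """
    if length_nt < 300:
        raise ValueError("length must be >= 300 nt")
    head = "GGGG"
    stem = "GGGGAGCT"
    tail = stem + "AATAA"[:21 - 2 * len(stem)] + revcomp(stem)  # 21 nt, ends CCCC
    body_len = length_nt - len(head) - len(tail)
    n_codons = body_len // 3
    pad = body_len - 3 * n_codons  # spacer between body and tail
    if n_codons < 90:
        raise ValueError(f"length {length_nt} infeasible for an ambigram body")
    rng = _rng(seed, f"genome:{seg_id}")
    codons = list(rng.choice(ALLOWED_CODONS, size=n_codons))
    codons[0] = "ATG"
    codons[14] = "CAA"   # forward-stop donor: CAA->TAA is reverse-synonymous
    codons[-1] = "CAT"   # reverse-strand ATG
    body = "".join(codons)
    seq = head + body + "A" * pad + tail

    fwd_start = len(head)
    fwd_end = fwd_start + 3 * n_codons
    L = len(seq)
    # -0 frame on the reverse complement: codons antiparallel to forward's
    rev_frame = (L - fwd_end) % 3
    rev_start = L - fwd_end
    rev_end = L - fwd_start
    return Segment(
        id=seg_id,
        sequence=seq,
        fwd_orf=(fwd_start, fwd_end, 0),
        rev_orf=(rev_start, rev_end, rev_frame),
        terminal5=head,
        terminal3="CCCC",
    )


def simulate_stranded_reads(
    segments: dict[str, Segment],
    cfg: SimConfig,
    n_reads: int = 50_000,
    copy_numbers: dict[str, float] | None = None,
) -> dict[str, AlignmentSet]:
    """Simulate a stranded mNGS library over one or more segments.

    Expected read count per segment is proportional to copy_number x
    length; read starts are uniform over the template; each read's strand
    is drawn from the segment's configured +:- ratio.
    """
    if copy_numbers is None:
        # two-segment default: robin copies / rdrp copies = copy_ratio
        copy_numbers = {}
        for name in segments:
            if "robin" in name:
                copy_numbers[name] = cfg.copy_ratio
            else:
                copy_numbers[name] = 1.0
    weights = np.array(
        [copy_numbers[name] * len(segments[name]) for name in segments], float
    )
    weights /= weights.sum()
    rng = _rng(cfg.seed, "mNGS")
    counts = rng.multinomial(n_reads, weights)
    out = {}
    for (name, seg), n_seg in zip(segments.items(), counts):
        L = len(seg)
        rlen = min(cfg.read_length, L)
        ratio = cfg.strand_ratio.get(name, 1.0)
        p_plus = ratio / (ratio + 1.0)
        starts = rng.integers(0, L - rlen + 1, size=n_seg)
        plus = rng.random(n_seg) < p_plus
        reads = [
            Read(int(s), rlen, "+" if p else "-")
            for s, p in zip(starts, plus)
        ]
        out[name] = AlignmentSet(seg.id, L, reads)
    return out


def inject_snvs(
    alns: AlignmentSet,
    reference: str,
    mode: Literal["host_biallelic", "viral_quasispecies"],
    cfg: SimConfig,
    n_sites: int = 5,
) -> AlignmentSet:
    """Overlay SNVs on an alignment set.

    host_biallelic: two haplotypes; each read belongs wholly to one, with
    the minor-haplotype fraction drawn once from cfg.host_af_range, so all
    site frequencies are ~equal and phased.

    viral_quasispecies: per-site frequencies drawn independently from
    cfg.viral_af_range; each read draws each variant independently (no
    linkage); the first site carries two alternate alleles (tri-allelic).
    """
    if n_sites == 0:
        return alns
    L = alns.ref_length
    if n_sites > L:
        raise ValueError("more sites requested than template positions")
    rng = _rng(cfg.seed, f"snv:{mode}:{alns.reference}")
    # sites are placed in close pairs (within half a read length) so that
    # individual reads span adjacent sites and phasing is testable, as it
    # is for real short-read data
    gap_hi = max(10, cfg.read_length // 2)
    positions: list[int] = []
    while len(positions) < n_sites:
        anchor = int(rng.integers(0, L - gap_hi))
        positions.append(anchor)
        if len(positions) < n_sites:
            positions.append(anchor + int(rng.integers(5, gap_hi)))
    positions = np.sort(np.unique(positions[:n_sites]))

    def alt_base(pos: int, exclude: set[str]) -> str:
        choices = [b for b in "ACGT" if b != reference[pos] and b not in exclude]
        return str(rng.choice(choices))

    new_reads = []
    if mode == "host_biallelic":
        q = rng.uniform(*cfg.host_af_range)
        alts = {int(p): alt_base(int(p), set()) for p in positions}
        for r in alns.reads:
            hap_b = rng.random() < q
            variants = tuple(
                (p, alts[p])
                for p in alts
                if hap_b and r.start <= p < r.start + r.length
            )
            new_reads.append(Read(r.start, r.length, r.strand, r.umi, variants))
    elif mode == "viral_quasispecies":
        freqs = {int(p): rng.uniform(*cfg.viral_af_range) for p in positions}
        site_alts: dict[int, list[str]] = {}
        for i, p in enumerate(positions):
            p = int(p)
            first = alt_base(p, set())
            site_alts[p] = [first]
            if i == 0 and cfg.viral_max_alleles > 2:
                site_alts[p].append(alt_base(p, {first}))
        for r in alns.reads:
            variants = []
            for p, alist in site_alts.items():
                if r.start <= p < r.start + r.length and rng.random() < freqs[p]:
                    variants.append((p, alist[int(rng.integers(len(alist)))]))
            new_reads.append(Read(r.start, r.length, r.strand, r.umi, tuple(variants)))
    else:
        raise ValueError(f"unknown SNV mode {mode!r}")
    return AlignmentSet(alns.reference, L, new_reads)


def _draw_lengths(rng: np.random.Generator, dist: dict[int, float], n: int) -> np.ndarray:
    lengths = np.array(sorted(dist))
    probs = np.array([dist[L] for L in lengths], float)
    probs /= probs.sum()
    return rng.choice(lengths, size=n, p=probs)


def _random_umis(rng: np.random.Generator, n: int) -> list[str]:
    idx = rng.integers(0, 4, size=(n, UMI_LENGTH))
    return ["".join(row) for row in _BASES[idx]]


def stall_queue_positions(
    segment: Segment, cfg: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Discrete 5'-end positions implied by ribosome queueing: per stall
    site, a run of positions spaced by 30-40 nt upstream."""
    s, e, _ = segment.fwd_orf
    n_stalls = int(rng.integers(cfg.n_stall_sites[0], cfg.n_stall_sites[1] + 1))
    stalls = rng.integers(s + cfg.queue_depth * cfg.queue_spacing[1], e, size=n_stalls)
    positions = []
    for stall in stalls:
        pos = int(stall)
        for _ in range(cfg.queue_depth):
            positions.append(pos)
            pos -= int(rng.integers(cfg.queue_spacing[0], cfg.queue_spacing[1] + 1))
            if pos < s:
                break
    return np.array(sorted(set(positions)))


def simulate_footprints(
    segment: Segment,
    profile_kind: Literal["host", "viral_plateau"],
    cfg: SimConfig,
    n_footprints: int = 10_000,
) -> AlignmentSet:
    """Simulate ribosome footprints with UMIs on one segment.

    host: 5' ends phase-locked to codon boundaries (3-nt periodicity),
    lengths peaked at 33 nt.  viral_plateau: 5' ends concentrated at
    stall-queue positions, lengths ~uniform on 27-37 nt, no phase lock.
    """
    rng = _rng(cfg.seed, f"footprints:{profile_kind}:{segment.id}")
    s, e, _ = segment.fwd_orf
    L = len(segment)
    if profile_kind == "host":
        lengths = _draw_lengths(rng, cfg.host_fp_lengths, n_footprints)
        max_len = int(lengths.max())
        codon_starts = np.arange(s, e - max_len, 3)
        if cfg.periodic:
            starts = rng.choice(codon_starts, size=n_footprints)
        else:
            starts = rng.integers(s, e - max_len, size=n_footprints)
    elif profile_kind == "viral_plateau":
        lengths = _draw_lengths(rng, cfg.viral_fp_lengths, n_footprints)
        max_len = int(lengths.max())
        sites = stall_queue_positions(segment, cfg, rng)
        sites = sites[(sites >= s) & (sites < e - max_len)]
        starts = rng.choice(sites, size=n_footprints)
    else:
        raise ValueError(f"unknown profile kind {profile_kind!r}")

    if cfg.mnase_jitter:
        jitter = rng.integers(-cfg.mnase_jitter, cfg.mnase_jitter + 1, size=n_footprints)
        starts = np.clip(starts + jitter, 0, L - 1)
        lengths = np.clip(lengths - jitter, 18, 50)
    starts = np.minimum(starts, L - lengths)
    umis = _random_umis(rng, n_footprints)
    reads = [
        Read(int(st), int(ln), "+", umi)
        for st, ln, umi in zip(starts, lengths, umis)
    ]
    return AlignmentSet(segment.id, L, reads)


def simulate_small_rnas(
    segment: Segment, cfg: SimConfig, n_reads: int = 10_000
) -> AlignmentSet:
    """Simulate an siRNA-like small-RNA library: both strands, length mode
    at the configured value (default 21 nt)."""
    rng = _rng(cfg.seed, f"sirna:{segment.id}")
    if n_reads == 0:
        return AlignmentSet(segment.id, len(segment), [])
    L = len(segment)
    lengths = _draw_lengths(rng, cfg.sirna_lengths, n_reads)
    starts = rng.integers(0, L - int(lengths.max()) + 1, size=n_reads)
    plus = rng.random(n_reads) < 0.5
    reads = [
        Read(int(s), int(ln), "+" if p else "-")
        for s, ln, p in zip(starts, lengths, plus)
    ]
    return AlignmentSet(segment.id, L, reads)
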