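"""Genome-level analytics of ambigrammatic organization.

An ambigrammatic segment carries a forward ORF and a reverse ORF read in the
"-0" frame: the reverse codons are exactly antiparallel to the forward
codons, so reverse codon k is the reverse complement of forward codon k.  A
reverse-frame stop therefore corresponds to one of three forward-frame
codons (TTA, CTA, TCA, whose reverse complements are TAA, TAG, TGA), and an
ambigrammatic genome is one that avoids both the forward stops and these
three reverse-stop generators over nearly its whole length.

Coordinates are 0-based half-open on the forward sequence throughout;
reverse-strand features are reported by their projection onto forward
coordinates.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Seq import Seq
from Bio.Data.CodonTable import standard_dna_table

STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # {TAA, TAG, TGA}

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_alphabet(seq: str) -> str:
    """Uppercase and convert RNA (U) to the internal DNA alphabet (T)."""
    return seq.upper().replace("U", "T")


def translate(seq: str) -> str:
    """Translate a DNA string codon-by-codon; stops are '*', partials dropped."""
    n = len(seq) - len(seq) % 3
    return str(Seq(seq[:n]).translate())


def reverse_stop_codons() -> frozenset[str]:
    """Forward-strand codons whose reverse complements are stop codons.

    These are the codons an ambigrammatic genome must avoid in its forward
    reading frame to keep the antiparallel (-0) reverse frame stop-free:
    TTA, CTA and TCA (UUA, CUA, UCA on the RNA).
    """
    return frozenset(
        c for c in _all_codons() if revcomp(c) in STOP_CODONS
    )


def _all_codons() -> Iterable[str]:
    for a in _BASES:
        for b in _BASES:
            for c in _BASES:
                yield a + b + c


@dataclass(frozen=True)
class OrfRecord:
    """One ORF (or flagged stop-free stretch) found by the scanner.

    ``start``/``end`` are 0-based half-open on the *forward* sequence, for
    both strands.  ``frame`` is the frame offset on the strand's own 5'->3'
    reading (0, 1 or 2).  ``has_start`` distinguishes true ATG-initiated
    ORFs from maximal stop-free stretches reported for completeness.
    """

    strand: str
    frame: int
    start: int
    end: int
    has_start: bool

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Segment:
    """An ambigrammatic viral reference sequence.

    fwd_orf / rev_orf are (start, end, frame) with 0-based half-open
    intervals; rev_orf coordinates are on the reverse complement, with the
    constraint that its frame is the -0 frame (codons exactly antiparallel
    to the forward ORF codons).
    """

    id: str
    sequence: str
    fwd_orf: tuple[int, int, int] | None = None
    rev_orf: tuple[int, int, int] | None = None
    terminal5: str = ""
    terminal3: str = ""

    def __post_init__(self) -> None:
        self.sequence = normalize_alphabet(self.sequence)
        L = len(self.sequence)
        for orf in (self.fwd_orf, self.rev_orf):
            if orf is not None:
                s, e, _ = orf
                if not (0 <= s <= e <= L):
                    raise ValueError(f"ORF interval {orf} outside [0, {L}]")
        if self.fwd_orf is not None:
            s, e, _ = self.fwd_orf
            if (e - s) % 3:
                raise ValueError("forward ORF length must be divisible by 3")
        if self.fwd_orf is not None and self.rev_orf is not None:
            if self.rev_orf[2] != self.minus_zero_frame():
                raise ValueError(
                    "rev_orf frame is not the -0 frame of the forward ORF"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def minus_zero_frame(self) -> int:
        """Frame offset on the reverse complement whose codon boundaries
        coincide (antiparallel) with the forward ORF's codons."""
        if self.fwd_orf is None:
            raise ValueError("forward ORF not set")
        L = len(self.sequence)
        return (L - self.fwd_orf[1]) % 3

    def rev_orf_projection(self) -> tuple[int, int]:
        """rev_orf interval projected onto forward coordinates."""
        if self.rev_orf is None:
            raise ValueError("reverse ORF not set")
        s, e, _ = self.rev_orf
        L = len(self.sequence)
        return (L - e, L - s)

    def fwd_cds(self) -> str:
        s, e, _ = self.fwd_orf
        return self.sequence[s:e]

    def rev_cds(self) -> str:
        s, e, _ = self.rev_orf
        return revcomp(self.sequence)[s:e]


def scan_orfs_both_strands(
    seq: str, min_len: int = 60
) -> list[OrfRecord]:
    """Find all maximal ORFs in all six frames of ``seq``.

    For each frame on each strand, maximal stop-free codon stretches are
    located; within each stretch the ORF runs from the first ATG to the end
    of the stretch (a stop codon or the sequence end).  Stretches of at
    least ``min_len`` nt without an ATG are reported too, flagged with
    ``has_start=False``, since start annotation on reverse ORFs of
    ambigrammatic genomes is often schematic.

    Coordinates are reported on the forward sequence for both strands.
    """
    seq = normalize_alphabet(seq)
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    records: list[OrfRecord] = []
    L = len(seq)
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            for st, en, has_start in _scan_frame(s, frame, min_len):
                if strand == "+":
                    records.append(OrfRecord("+", frame, st, en, has_start))
                else:
                    records.append(
                        OrfRecord("-", frame, L - en, L - st, has_start)
                    )
    records.sort(key=lambda r: (r.strand, r.frame, r.start))
    return records


def _scan_frame(
    s: str, frame: int, min_len: int
) -> Iterable[tuple[int, int, bool]]:
    """Yield (start, end, has_start) ORFs in one frame of one strand."""
    n_codons = (len(s) - frame) // 3
    stretch_start = None  # codon index where current stop-free stretch began
    first_atg = None
    for k in range(n_codons + 1):
        codon = s[frame + 3 * k : frame + 3 * k + 3] if k < n_codons else None
        if codon is None or codon in STOP_CODONS:
            if stretch_start is not None:
                end = frame + 3 * k
                if first_atg is not None:
                    st = frame + 3 * first_atg
                    if end - st >= min_len:
                        yield st, end, True
                st = frame + 3 * stretch_start
                if first_atg != stretch_start and end - st >= min_len:
                    yield st, end, False
            stretch_start = None
            first_atg = None
        else:
            if stretch_start is None:
                stretch_start = k
            if first_atg is None and codon == "ATG":
                first_atg = k


def ambigram_overlap_fraction(seg: Segment) -> float:
    """Fraction of the segment covered by both the forward ORF and the
    forward-coordinate projection of the reverse (-0 frame) ORF."""
    if seg.fwd_orf is None or seg.rev_orf is None:
        raise ValueError(
            "both ORFs must be annotated: input is not ambigrammatic"
        )
    fs, fe, _ = seg.fwd_orf
    rs, re_ = seg.rev_orf_projection()
    inter = max(0, min(fe, re_) - max(fs, rs))
    return inter / len(seg.sequence)


def codon_avoidance_stats(seg: Segment) -> dict[str, int]:
    """Counts of the three reverse-stop-generating codons (TTA, CTA, TCA)
    in the forward ORF frame.  An ambigrammatic genome scores 0 for all
    three across the dual-coding region."""
    if seg.fwd_orf is None:
        raise ValueError("forward ORF not set")
    cds = seg.fwd_cds()
    counts = Counter(cds[i : i + 3] for i in range(0, len(cds) - 2, 3))
    return {c: counts.get(c, 0) for c in sorted(reverse_stop_codons())}


# --- mutation design -------------------------------------------------------

_MODES = ("stop_reverse", "nonsyn_reverse", "stop_forward", "gdd_knockout")


@dataclass
class MutationPlan:
    """Single-base substitutions with forward/reverse-frame consequences.

    ``sites`` holds (position, ref_base, alt_base) on the forward sequence;
    every substitution is synonymous in the protected frame (forward for
    stop_reverse / nonsyn_reverse, reverse for stop_forward).
    """

    mode: str
    sites: list[tuple[int, str, str]] = field(default_factory=list)
    n_codons: int = 0

    def apply(self, sequence: str) -> str:
        out = list(normalize_alphabet(sequence))
        for pos, ref, alt in self.sites:
            if out[pos] != ref:
                raise ValueError(
                    f"reference mismatch at {pos}: {out[pos]} != {ref}"
                )
            out[pos] = alt
        return "".join(out)


def _synonymous(codon_a: str, codon_b: str) -> bool:
    return translate(codon_a) == translate(codon_b)


def _stop_reverse_candidates(cds: str) -> list[tuple[int, int, str, str]]:
    """Codon positions in a forward CDS where a single forward-synonymous
    substitution creates a reverse (-0) stop AND the same position admits a
    forward-synonymous non-stop alternative (so a matched nonsynonymous-
    reverse control can be designed at identical nucleotide positions).

    Returns (codon_index, offset_in_codon, stop_alt_base, ns_alt_base).
    """
    out = []
    rev_stop_gen = reverse_stop_codons()
    for k in range(len(cds) // 3):
        codon = cds[3 * k : 3 * k + 3]
        if codon in STOP_CODONS or codon in rev_stop_gen:
            continue
        for off in range(3):
            stop_alt = None
            ns_alt = None
            for b in _BASES:
                if b == codon[off]:
                    continue
                mut = codon[:off] + b + codon[off + 1 :]
                if not _synonymous(codon, mut):
                    continue
                if mut in rev_stop_gen:
                    stop_alt = b
                elif _differs_rev(codon, mut):
                    ns_alt = b
            if stop_alt is not None and ns_alt is not None:
                out.append((k, off, stop_alt, ns_alt))
                break
    return out


def _differs_rev(codon: str, mut: str) -> bool:
    """True if the substitution changes the reverse (-0 frame) amino acid."""
    return translate(revcomp(codon)) != translate(revcomp(mut))


def _stop_forward_candidates(cds: str) -> list[tuple[int, int, str]]:
    """Codon positions where a single reverse-synonymous substitution turns
    the forward codon into a stop.  Returns (codon_index, offset, alt)."""
    out = []
    for k in range(len(cds) // 3):
        codon = cds[3 * k : 3 * k + 3]
        if codon in STOP_CODONS:
            continue
        for off in range(3):
            for b in _BASES:
                if b == codon[off]:
                    continue
                mut = codon[:off] + b + codon[off + 1 :]
                if mut in STOP_CODONS and _synonymous(
                    revcomp(codon), revcomp(mut)
                ):
                    out.append((k, off, b))
                    break
            else:
                continue
            break
    return out


def design_opposing_mutations(
    seg: Segment,
    mode: str,
    n_codons: int,
    region: tuple[int, int] | None = None,
) -> MutationPlan:
    """Design single-base mutants that disrupt one reading frame while
    remaining synonymous in the opposing frame.

    Modes
    -----
    stop_reverse (stR)
        Forward-synonymous substitutions creating stops in the reverse -0
        frame; candidate donors are the Leu/Ser codons one base away from
        TTA/CTA/TCA.
    nonsyn_reverse (ns)
        Forward-synonymous substitutions at the SAME nucleotide positions
        as the stop_reverse plan, changing the reverse amino acid without
        creating a stop (matched control for stR).
    stop_forward (stF)
        Reverse-synonymous substitutions creating forward stops, starting
        14 codons downstream of the forward start.

    Site selection is deterministic: 5'-most eligible codons first within
    ``region`` (forward coordinates; defaults to the whole forward ORF).
    Every plan is verified by translating both frames before and after.
    """
    if mode not in _MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {_MODES}")
    if mode == "gdd_knockout":
        raise NotImplementedError(
            "gdd_knockout requires an RdRp motif annotation; use "
            "stop_reverse/nonsyn_reverse/stop_forward for opposing-frame "
            "designs"
        )
    if seg.fwd_orf is None or seg.rev_orf is None:
        raise ValueError("segment must carry both ORF annotations")
    fs, fe, _ = seg.fwd_orf
    cds = seg.fwd_cds()
    rs, re_ = seg.rev_orf_projection()
    overlap = (max(fs, rs), min(fe, re_))
    lo, hi = region if region is not None else overlap
    if lo < overlap[0] or hi > overlap[1]:
        raise ValueError("region must lie within the dual-coding overlap")

    if mode in ("stop_reverse", "nonsyn_reverse"):
        cands = _stop_reverse_candidates(cds)
        alt_idx = 2 if mode == "stop_reverse" else 3
    else:  # stop_forward: begin 14 codons into the forward ORF
        cands = [
            (k, off, alt)
            for (k, off, alt) in _stop_forward_candidates(cds)
            if k >= 14
        ]
        alt_idx = 2

    sites: list[tuple[int, str, str]] = []
    codons_used: list[int] = []
    for cand in cands:
        k, off = cand[0], cand[1]
        pos = fs + 3 * k + off
        if not (lo <= pos < hi):
            continue
        sites.append((pos, seg.sequence[pos], cand[alt_idx]))
        codons_used.append(k)
        if len(sites) == n_codons:
            break
    if len(sites) < n_codons:
        raise ValueError(
            f"only {len(sites)} eligible codon(s) in region for mode "
            f"{mode!r}; requested {n_codons}"
        )

    plan = MutationPlan(mode=mode, sites=sites, n_codons=len(set(codons_used)))
    _verify_plan(seg, plan)
    return plan


def _verify_plan(seg: Segment, plan: MutationPlan) -> None:
    """Internal oracle: translate both frames before/after and check the
    mode's contract."""
    mutant = plan.apply(seg.sequence)
    fs, fe, _ = seg.fwd_orf
    rs, re_, _ = seg.rev_orf
    fwd_before = translate(seg.sequence[fs:fe])
    fwd_after = translate(mutant[fs:fe])
    rev_before = translate(revcomp(seg.sequence)[rs:re_])
    rev_after = translate(revcomp(mutant)[rs:re_])
    if plan.mode in ("stop_reverse", "nonsyn_reverse"):
        if fwd_after != fwd_before:
            raise AssertionError("forward protein changed in a fwd-synonymous plan")
        new_stops = rev_after.count("*") - rev_before.count("*")
        if plan.mode == "stop_reverse" and new_stops != plan.n_codons:
            raise AssertionError(
                f"expected {plan.n_codons} new reverse stops, got {new_stops}"
            )
        if plan.mode == "nonsyn_reverse":
            if new_stops != 0:
                raise AssertionError("nonsyn_reverse plan created a reverse stop")
            changed = sum(a != b for a, b in zip(rev_before, rev_after))
            if changed != plan.n_codons:
                raise AssertionError("nonsyn_reverse changed wrong residue count")
    elif plan.mode == "stop_forward":
        if rev_after != rev_before:
            raise AssertionError("reverse protein changed in a rev-synonymous plan")
        if fwd_after.count("*") - fwd_before.count("*") != plan.n_codons:
            raise AssertionError("stop_forward introduced wrong stop count")


# --- ends libraries --------------------------------------------------------

HANDLE = "TGCATA"


@dataclass
class EndsReport:
    """Consensus terminal sequence from a dephased ends library."""

    consensus5: str | None
    consensus3: str | None
    kmer5_freqs: dict[str, float]
    kmer3_freqs: dict[str, float]
    n_reads: int
    n_dropped: int
    ambiguous5: bool = False
    ambiguous3: bool = False


def characterize_ends(
    reads: Sequence[str],
    handle: str = HANDLE,
    k: int = 8,
    max_lead: int = 11,
    tie_ratio: float = 2.0,
) -> EndsReport:
    """Locate and trim the dephasing handle, then report terminal consensus.

    Ends-library reads carry 0-5 random leading bases, the ligation handle
    (TGCATA), then the insert beginning at the true RNA terminus.  The
    terminal ``k``-mer distribution is tabulated from trimmed inserts; a
    consensus is only declared when the top k-mer is at least ``tie_ratio``
    times more frequent than the runner-up (e.g. 5'-GGGG vs 5'-GGG starts
    at similar frequencies yield an ambiguous call, not a forced one).
    Reads without the handle are dropped and counted.
    """
    inserts = []
    dropped = 0
    for r in reads:
        r = normalize_alphabet(r)
        idx = r.find(handle, 0, max_lead)
        if idx < 0:
            dropped += 1
            continue
        inserts.append(r[idx + len(handle) :])
    c5 = Counter(ins[:k] for ins in inserts if len(ins) >= k)
    c3 = Counter(ins[-k:] for ins in inserts if len(ins) >= k)

    def summarize(c: Counter) -> tuple[str | None, dict[str, float], bool]:
        total = sum(c.values())
        if not total:
            return None, {}, False
        freqs = {s: n / total for s, n in c.most_common()}
        top = c.most_common(2)
        if len(top) > 1 and top[0][1] < tie_ratio * top[1][1]:
            return None, freqs, True
        return top[0][0], freqs, False

    cons5, f5, amb5 = summarize(c5)
    cons3, f3, amb3 = summarize(c3)
    return EndsReport(
        consensus5=cons5,
        consensus3=cons3,
        kmer5_freqs=f5,
        kmer3_freqs=f3,
        n_reads=len(inserts),
        n_dropped=dropped,
        ambiguous5=amb5,
        ambiguous3=amb3,
    )
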