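"""FASTA/FASTQ import/export for segments, reads and footprints.

Footprint FASTQ carries the UMI in the header as ``@name UMI:XXXXX``;
mutation plans are tab-delimited with before/after amino acids in both
frames.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ambiribo.ambigram import MutationPlan, Segment, revcomp, translate
from ambiribo.readquant import AlignmentSet, Read


def write_segments(segments: Iterable[Segment], path: str | Path) -> None:
    records = []
    for seg in segments:
        desc = []
        if seg.fwd_orf:
            desc.append(f"fwd_orf={seg.fwd_orf[0]}-{seg.fwd_orf[1]}/{seg.fwd_orf[2]}")
        if seg.rev_orf:
            desc.append(f"rev_orf={seg.rev_orf[0]}-{seg.rev_orf[1]}/{seg.rev_orf[2]}")
        records.append(
            SeqRecord(Seq(seg.sequence), id=seg.id, description=" ".join(desc))
        )
    SeqIO.write(records, str(path), "fasta")


def read_segments(path: str | Path) -> list[Segment]:
    segments = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fwd = rev = None
        for token in rec.description.split():
            if token.startswith(("fwd_orf=", "rev_orf=")):
                span, frame = token.split("=")[1].split("/")
                lo, hi = span.split("-")
                orf = (int(lo), int(hi), int(frame))
                if token.startswith("fwd"):
                    fwd = orf
                else:
                    rev = orf
        segments.append(Segment(rec.id, str(rec.seq), fwd, rev))
    return segments


def write_footprints_fastq(
    alns: AlignmentSet, reference_seq: str, path: str | Path
) -> None:
    """Write footprints as FASTQ with the UMI in the header."""
    with open(path, "w") as fh:
        for i, r in enumerate(alns.reads):
            seq = reference_seq[r.start : r.start + r.length]
            if r.strand == "-":
                seq = revcomp(seq)
            umi = f" UMI:{r.umi}" if r.umi else ""
            fh.write(f"@fp{i} ref={alns.reference} start={r.start} strand={r.strand}{umi}\n")
            fh.write(f"{seq}\n+\n{'I' * len(seq)}\n")


def read_footprints_fastq(path: str | Path, reference_seq: str, reference: str = "ref") -> AlignmentSet:
    """Load footprints written by :func:`write_footprints_fastq` (the
    header's truth coordinates are trusted; no alignment is performed)."""
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        fields = dict(
            kv.split(":", 1) if ":" in kv else kv.split("=", 1)
            for kv in rec.description.split()[1:]
        )
        reads.append(
            Read(
                start=int(fields["start"]),
                length=len(rec.seq),
                strand=fields.get("strand", "+"),
                umi=fields.get("UMI"),
            )
        )
    return AlignmentSet(reference, len(reference_seq), reads)


def write_mutation_plan(
    plan: MutationPlan, seg: Segment, path: str | Path
) -> None:
    """Tab-delimited plan: position, ref, alt, fwd/rev amino acids
    before/after (1-based positions for human readability)."""
    mutant = plan.apply(seg.sequence)
    fs, fe, _ = seg.fwd_orf
    L = len(seg.sequence)
    with open(path, "w") as fh:
        fh.write(
            "position_1based\tref\talt\tfwd_aa_before\tfwd_aa_after\t"
            "rev_aa_before\trev_aa_after\n"
        )
        for pos, ref, alt in plan.sites:
            k = (pos - fs) // 3
            fwd_before = translate(seg.sequence[fs + 3 * k : fs + 3 * k + 3])
            fwd_after = translate(mutant[fs + 3 * k : fs + 3 * k + 3])
            rev_codon_before = revcomp(seg.sequence[fs + 3 * k : fs + 3 * k + 3])
            rev_codon_after = revcomp(mutant[fs + 3 * k : fs + 3 * k + 3])
            fh.write(
                f"{pos + 1}\t{ref}\t{alt}\t{fwd_before}\t{fwd_after}\t"
                f"{translate(rev_codon_before)}\t{translate(rev_codon_after)}\n"
            )
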