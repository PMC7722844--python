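"""Minimal deterministic single-end seed-and-extend mapper plus SAM I/O.

The mapper performs ungapped alignment only: candidate placements are found
through an exact k-mer seed table over both strands of the reference set, each
candidate is scored by Hamming distance, and a read is reported mapped only if
its unique best placement has a mismatch fraction at or below the configured
maximum.  Ties are conservatively reported unmapped.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import pysam

from ._seq import revcomp

DEFAULT_K = 15
DEFAULT_MAX_MISMATCH_FRACTION = 0.06


@dataclass
class AlignmentRecord:
    """One single-end alignment (or unmapped read) with optional mate fields.

    Coordinates are 0-based; ``strand`` is '+' or '-'; unmapped records carry
    no coordinate.
    """

    query_id: str
    sequence: str
    mapped: bool
    reference: Optional[str] = None
    position: Optional[int] = None
    strand: str = "+"
    mismatches: Optional[int] = None
    paired: bool = False
    is_read1: bool = True
    mate_mapped: bool = False
    mate_reference: Optional[str] = None
    mate_position: Optional[int] = None
    mate_strand: str = "+"

    def __post_init__(self):
        if self.mapped:
            if self.reference is None or self.position is None or self.position < 0:
                raise ValueError("mapped record needs a valid reference and position >= 0")
        else:
            if self.reference is not None or self.position is not None:
                raise ValueError("unmapped record must not carry a coordinate")


class MapperIndex:
    """Exact k-mer location table over a reference set, both strands.

    For every reference position ``i`` the forward k-mer is stored under
    ``(ref, i, '+')`` and its reverse complement under ``(ref, i, '-')``,
    so occurrence lookups see both strands.
    """

    def __init__(self, references: Mapping[str, str], k: int = DEFAULT_K):
        if k < 11:
            raise ValueError("k must be >= 11")
        if not references:
            raise ValueError("empty reference set")
        for name, seq in references.items():
            if len(seq) < k:
                raise ValueError(f"reference {name!r} shorter than k={k}")
        self.k = k
        self.references = {name: seq.upper() for name, seq in references.items()}
        self.lengths = {name: len(seq) for name, seq in self.references.items()}
        table: dict = {}
        for name, seq in self.references.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i:i + k]
                rc = revcomp(kmer)
                table.setdefault(kmer, []).append((name, i, "+"))
                if rc != kmer:  # self-complementary k-mers occupy one entry
                    table.setdefault(rc, []).append((name, i, "-"))
        self.table = table

    def occurrences(self, kmer: str):
        return self.table.get(kmer.upper(), [])

    def n_entries(self) -> int:
        return sum(len(v) for v in self.table.values())


def build_index(references: Mapping[str, str], k: int = DEFAULT_K) -> MapperIndex:
    return MapperIndex(references, k=k)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def map_read(
    read_id: str,
    sequence: str,
    index: MapperIndex,
    max_mismatch_fraction: float = DEFAULT_MAX_MISMATCH_FRACTION,
    seed_step: int = 5,
) -> AlignmentRecord:
    """Map one read; unmapped on seed failure, threshold failure, or a tie.

    Any placement whose Hamming distance d satisfies d <= floor((L-k)/k-ish
    clean-segment bound is guaranteed to be seeded; in particular every
    placement with at most two mismatches of a 100-mer at k=15 is found.
    """
    seq = sequence.upper()
    L = len(seq)
    k = index.k
    if L < k:
        raise ValueError("read shorter than k")

    candidates = set()
    offsets = list(range(0, L - k + 1, seed_step))
    if offsets[-1] != L - k:
        offsets.append(L - k)
    for off in offsets:
        for ref, pos, strand in index.occurrences(seq[off:off + k]):
            if strand == "+":
                start = pos - off
            else:
                # the k-mer matches the reverse strand at forward position
                # pos; align revcomp(read) starting at pos - (L - k - off)
                start = pos - (L - k - off)
            if 0 <= start and start + L <= index.lengths[ref]:
                candidates.add((ref, start, strand))

    if not candidates:
        return AlignmentRecord(read_id, sequence, mapped=False)

    rc = revcomp(seq)
    scored = []
    for ref, start, strand in candidates:
        window = index.references[ref][start:start + L]
        query = seq if strand == "+" else rc
        scored.append((_hamming(query, window), ref, start, strand))
    scored.sort()
    best = scored[0]
    if best[0] > max_mismatch_fraction * L:
        return AlignmentRecord(read_id, sequence, mapped=False)
    if len(scored) > 1 and scored[1][0] == best[0]:
        return AlignmentRecord(read_id, sequence, mapped=False)  # ambiguous
    mm, ref, start, strand = best
    return AlignmentRecord(
        read_id, sequence, mapped=True,
        reference=ref, position=start, strand=strand, mismatches=mm,
    )


def map_pairs(
    pairs1: Sequence[tuple],
    pairs2: Sequence[tuple],
    index: MapperIndex,
    max_mismatch_fraction: float = DEFAULT_MAX_MISMATCH_FRACTION,
) -> list:
    """Map FR read pairs given as parallel (id, sequence) lists.

    Returns a list of (mate1, mate2) AlignmentRecord tuples with mutually
    consistent mate fields.
    """
    if len(pairs1) != len(pairs2):
        raise ValueError("mate count mismatch")
    out = []
    for (id1, seq1), (id2, seq2) in zip(pairs1, pairs2):
        if _pair_stem(id1) != _pair_stem(id2):
            raise ValueError(f"mate identifier mismatch: {id1!r} vs {id2!r}")
        stem = _pair_stem(id1)
        r1 = map_read(stem, seq1, index, max_mismatch_fraction)
        r2 = map_read(stem, seq2, index, max_mismatch_fraction)
        r1 = replace(
            r1, paired=True, is_read1=True, mate_mapped=r2.mapped,
            mate_reference=r2.reference, mate_position=r2.position, mate_strand=r2.strand,
        )
        r2 = replace(
            r2, paired=True, is_read1=False, mate_mapped=r1.mapped,
            mate_reference=r1.reference, mate_position=r1.position, mate_strand=r1.strand,
        )
        out.append((r1, r2))
    return out


def _pair_stem(read_id: str) -> str:
    return read_id[:-2] if read_id.endswith(("/1", "/2")) else read_id


# ---------------------------------------------------------------------------
# SAM round trip
# ---------------------------------------------------------------------------


def write_sam(records: Sequence[AlignmentRecord], references: Mapping[str, int], path):
    """Write records as SAM honoring flags 0x1/0x4/0x8/0x10/0x20/0x40/0x80."""
    names = sorted(references)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": int(references[n])} for n in names],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for rec in records:
            a = pysam.AlignedSegment(sam.header)
            a.query_name = rec.query_id
            a.query_sequence = rec.sequence
            a.query_qualities = pysam.qualitystring_to_array("I" * len(rec.sequence))
            a.is_paired = rec.paired
            if rec.paired:
                a.is_read1 = rec.is_read1
                a.is_read2 = not rec.is_read1
            a.is_unmapped = not rec.mapped
            if rec.mapped:
                a.reference_id = names.index(rec.reference)
                a.reference_start = rec.position
                a.is_reverse = rec.strand == "-"
                a.cigarstring = f"{len(rec.sequence)}M"
                if rec.mismatches is not None:
                    a.set_tag("NM", int(rec.mismatches))
            if rec.paired:
                a.mate_is_unmapped = not rec.mate_mapped
                if rec.mate_mapped:
                    a.next_reference_id = names.index(rec.mate_reference)
                    a.next_reference_start = rec.mate_position
                    a.mate_is_reverse = rec.mate_strand == "-"
            sam.write(a)


def read_sam(path) -> list:
    """Read a SAM file back into AlignmentRecord objects (lossless for the
    fields write_sam emits)."""
    out = []
    with pysam.AlignmentFile(str(path), "r") as sam:
        for a in sam:
            mapped = not a.is_unmapped
            mate_mapped = a.is_paired and not a.mate_is_unmapped
            out.append(
                AlignmentRecord(
                    query_id=a.query_name,
                    sequence=a.query_sequence or "",
                    mapped=mapped,
                    reference=a.reference_name if mapped else None,
                    position=a.reference_start if mapped else None,
                    strand="-" if (mapped and a.is_reverse) else "+",
                    mismatches=a.get_tag("NM") if (mapped and a.has_tag("NM")) else None,
                    paired=a.is_paired,
                    is_read1=(a.is_read1 or not a.is_paired),
                    mate_mapped=mate_mapped,
                    mate_reference=sam.get_reference_name(a.next_reference_id)
                    if mate_mapped and a.next_reference_id >= 0 else None,
                    mate_position=a.next_reference_start if mate_mapped else None,
                    mate_strand="-" if (mate_mapped and a.mate_is_reverse) else "+",
                )
            )
    return out
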