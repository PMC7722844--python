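"""Half-mapped-read transposon mobility survey.

Read pairs are aligned against a transposon reference set; pairs with exactly
one mapped mate are kept, the unmapped mate (the anchor) is re-mapped to the
genome, anchor pileups pooled over strains are merged into loci, per-strain
distinct-read counts are thresholded into a presence matrix, and loci with a
large max/min count ratio are flagged as differential.  All three thresholds
default to 10 reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .read_mapping import AlignmentRecord, MapperIndex, map_read


@dataclass(frozen=True)
class SurveyConfig:
    min_locus_reads: int = 10      # pooled distinct reads to call a locus
    presence_threshold: int = 10   # per-strain distinct reads to score presence
    differential_ratio: float = 10.0
    merge_distance: int = 200      # bp gap merged between anchor intervals

    def __post_init__(self):
        if min(self.min_locus_reads, self.presence_threshold) <= 0 or self.differential_ratio <= 0:
            raise ValueError("all thresholds must be positive")
        if self.merge_distance < 0:
            raise ValueError("merge_distance must be >= 0")


@dataclass(frozen=True)
class HalfMappedPair:
    """A pair with exactly one TE-mapped mate; the other mate is the anchor."""

    te_name: str
    anchor_id: str
    anchor_seq: str
    strain: str


@dataclass(frozen=True)
class AnchoredRead:
    te_name: str
    strain: str
    read_id: str
    alignment: AlignmentRecord


@dataclass
class TELocus:
    chrom: str
    start: int
    end: int
    counts: dict          # strain -> distinct anchor-read count
    te_names: frozenset

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("locus must have start < end")

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def pooled_count(self) -> int:
        return sum(self.counts.values())


@dataclass
class PresenceMatrix:
    counts: pd.DataFrame    # loci x strains distinct-read counts
    presence: pd.DataFrame  # boolean, counts >= presence_threshold
    te_of_locus: pd.Series  # locus id -> comma-joined TE names


# ---------------------------------------------------------------------------
# stage 1: classify half-mapped pairs
# ---------------------------------------------------------------------------


def classify_half_mapped(
    pair_alignments: Iterable[tuple],
    strain: str,
) -> list:
    """Keep pairs with exactly one TE-mapped mate; the unmapped mate anchors.

    ``pair_alignments`` yields (mate1, mate2) AlignmentRecord tuples from
    mapping against the TE reference set.
    """
    out = []
    for r1, r2 in pair_alignments:
        if r1.query_id != r2.query_id:
            raise ValueError(f"malformed pair: {r1.query_id!r} vs {r2.query_id!r}")
        if r1.mapped == r2.mapped:
            continue  # fully mapped or fully unmapped
        mapped, anchor = (r1, r2) if r1.mapped else (r2, r1)
        out.append(
            HalfMappedPair(
                te_name=mapped.reference,
                anchor_id=anchor.query_id,
                anchor_seq=anchor.sequence,
                strain=strain,
            )
        )
    return out


# ---------------------------------------------------------------------------
# stage 2: anchor the unmapped mates on the genome
# ---------------------------------------------------------------------------


def anchor_map(
    half_mapped: Iterable[HalfMappedPair],
    genome_index: MapperIndex,
    max_mismatch_fraction: float = 0.06,
) -> list:
    """Map each anchor read to the genome; unmapped anchors are retained in
    the output but excluded by locus calling."""
    out = []
    for hm in half_mapped:
        aln = map_read(hm.anchor_id, hm.anchor_seq, genome_index, max_mismatch_fraction)
        out.append(AnchoredRead(hm.te_name, hm.strain, hm.anchor_id, aln))
    return out


# ---------------------------------------------------------------------------
# stage 3: locus calling from pooled anchor coverage
# ---------------------------------------------------------------------------


def call_loci(anchored: Sequence[AnchoredRead], config: SurveyConfig = SurveyConfig()) -> list:
    """Merge anchor intervals pooled over strains into loci.

    Loci are maximal intervals of nonzero anchor coverage after merging gaps
    of at most ``merge_distance`` bp, retained when the pooled distinct-read
    count reaches ``min_locus_reads``.  Duplicate read identifiers collapse
    to one read per strain.
    """
    mapped = [a for a in anchored if a.alignment.mapped]
    intervals = sorted(
        (
            (a.alignment.reference, a.alignment.position,
             a.alignment.position + len(a.alignment.sequence), a)
            for a in mapped
        ),
        key=lambda t: (t[0], t[1], t[2]),
    )
    loci: list = []
    cluster: list = []
    cur_chrom, cur_start, cur_end = None, 0, -1

    def flush():
        if not cluster:
            return
        reads: dict = {}
        tes = set()
        for a in cluster:
            reads.setdefault(a.strain, set()).add(a.read_id)
            tes.add(a.te_name)
        counts = {s: len(ids) for s, ids in reads.items()}
        if sum(counts.values()) >= config.min_locus_reads:
            loci.append(TELocus(cur_chrom, cur_start, cur_end, counts, frozenset(tes)))

    for chrom, start, end, a in intervals:
        if chrom != cur_chrom or start > cur_end + config.merge_distance:
            flush()
            cluster = []
            cur_chrom, cur_start, cur_end = chrom, start, end
        cluster.append(a)
        cur_end = max(cur_end, end)
    flush()
    loci.sort(key=lambda l: (l.chrom, l.start))
    return loci


# ---------------------------------------------------------------------------
# stage 4: presence scoring and differential flags
# ---------------------------------------------------------------------------


def score_presence(
    loci: Sequence[TELocus],
    strains: Sequence[str],
    config: SurveyConfig = SurveyConfig(),
) -> PresenceMatrix:
    """Presence call per locus and strain: count >= presence_threshold."""
    index = [l.locus_id for l in loci]
    counts = pd.DataFrame(
        [[l.counts.get(s, 0) for s in strains] for l in loci],
        index=index, columns=list(strains), dtype=int,
    )
    presence = counts >= config.presence_threshold
    te_of_locus = pd.Series(
        [",".join(sorted(l.te_names)) for l in loci], index=index, name="te"
    )
    return PresenceMatrix(counts=counts, presence=presence, te_of_locus=te_of_locus)


def flag_differential(counts: pd.DataFrame, config: SurveyConfig = SurveyConfig()) -> pd.Series:
    """Boolean flag per locus: max/min count ratio >= differential_ratio.

    A zero minimum counts as an infinite ratio and is flagged whenever the
    maximum reaches the presence threshold.
    """
    mx = counts.max(axis=1).to_numpy(dtype=float)
    mn = counts.min(axis=1).to_numpy(dtype=float)
    zero = mn == 0
    with np.errstate(divide="ignore"):
        ratio = np.where(zero, np.inf, mx / np.where(zero, 1.0, mn))
    flagged = np.where(
        zero, mx >= config.presence_threshold, ratio >= config.differential_ratio
    )
    return pd.Series(flagged, index=counts.index, name="differential")


# ---------------------------------------------------------------------------
# stage 5: per-TE summary table
# ---------------------------------------------------------------------------


def summarize_survey(
    presence: pd.DataFrame,
    te_of_locus: pd.Series,
    roster: Sequence[str],
) -> pd.DataFrame:
    """Per-TE pattern-class summary.

    Classes: present in all roster strains; present in exactly one strain
    (one column per strain); present in all strains except the first roster
    strain; anything else under ``other``.  Every locus falls in exactly one
    class, so per-TE totals equal the sum of the class counts.
    """
    roster = list(roster)
    if list(presence.columns) != roster:
        presence = presence[roster]
    triple = roster[1:]
    triple_label = "+".join(triple) if len(roster) >= 3 else None

    columns = ["total", "all_strains"] + [f"{s}_only" for s in roster]
    if triple_label:
        columns.append(triple_label)
    columns.append("other")

    summary: dict = {}
    for locus, row in presence.iterrows():
        present = [s for s in roster if row[s]]
        if not present:
            raise ValueError(f"locus {locus} present in zero strains")
        te = te_of_locus.loc[locus]
        cls = "other"
        if len(present) == len(roster):
            cls = "all_strains"
        elif len(present) == 1:
            cls = f"{present[0]}_only"
        elif triple_label and present == triple:
            cls = triple_label
        rec = summary.setdefault(te, {c: 0 for c in columns})
        rec[cls] += 1
        rec["total"] += 1

    frame = pd.DataFrame.from_dict(summary, orient="index", columns=columns).astype(int)
    frame.index.name = "te"
    return frame.sort_index()
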