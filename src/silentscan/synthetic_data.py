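"""Seeded generators for every input the pipeline consumes.

Each generator returns both the simulated data and a ground-truth record so
that downstream stages can be tested for recovery without any external file.
All randomness flows through :func:`numpy.random.default_rng` with an explicit
seed; identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import BASES, revcomp

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: allele-origin codes shared with :mod:`silentscan.mapping_screen`
ALLELE_MUTANT = "mutant"
ALLELE_POLYMORPHIC = "polymorphic"
ALLELE_MISSING = "missing"


# ---------------------------------------------------------------------------
# configuration / truth types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TruthInsertion:
    """A planted transposon insertion on the backbone genome.

    ``position`` is the 0-based backbone coordinate immediately before which
    the element is inserted; ``strain_set`` lists the carrier strains.
    """

    te_name: str
    strain_set: frozenset
    chrom: str
    position: int
    te_length: int

    def __post_init__(self):
        if not self.strain_set:
            raise ValueError("strain_set must be non-empty")
        if self.te_length <= 0:
            raise ValueError("te_length must be positive")
        if self.position < 0:
            raise ValueError("position must be non-negative")


@dataclass(frozen=True)
class ReadSimConfig:
    read_length: int = 100
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    coverage: float = 30.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")
        if self.insert_mean < 2 * self.read_length:
            raise ValueError("insert_mean must be >= 2 * read_length")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not (0 <= self.error_rate < 0.1):
            raise ValueError("error_rate must be in [0, 0.1)")


@dataclass(frozen=True)
class CountSimConfig:
    n_genes: int = 2000
    n_replicates: int = 4
    baseline_mean: float = 100.0
    baseline_log2_sd: float = 1.0
    dispersion: float = 0.05
    planted_de: tuple = ()  # (gene index, log2 fold-change) pairs
    seed: int = 0

    def __post_init__(self):
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        idx = [i for i, _ in self.planted_de]
        if len(set(idx)) != len(idx):
            raise ValueError("planted gene indices must be unique")
        if any(i < 0 or i >= self.n_genes for i in idx):
            raise ValueError("planted gene index out of range")


@dataclass(frozen=True)
class PairedRead:
    """One simulated fragment with its truth origin (0-based half-open)."""

    name: str
    seq1: str
    seq2: str
    chrom: str
    fragment_start: int
    fragment_end: int


# ---------------------------------------------------------------------------
# genomes and insertions
# ---------------------------------------------------------------------------


def simulate_genome(length: int, gc_fraction: float = 0.5, seed: int = 0) -> str:
    """Random nucleotide sequence of the requested length and GC content."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0 < gc_fraction < 1):
        raise ValueError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    at = (1 - gc_fraction) / 2
    gc = gc_fraction / 2
    draw = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=[at, gc, gc, at])
    return draw.tobytes().decode("ascii")


def plant_te_insertions(
    backbone: Mapping[str, str],
    te_library: Mapping[str, str],
    design: Sequence[TruthInsertion],
):
    """Realize a multi-strain insertion design on a shared backbone.

    Returns ``(strain_genomes, design)`` where ``strain_genomes`` maps each
    strain named in the design to ``{chrom: sequence}``.  Per strain, the
    genome length equals the backbone length plus the summed lengths of the
    elements that strain carries.
    """
    seen = set()
    for ins in design:
        if ins.chrom not in backbone:
            raise ValueError(f"unknown chromosome {ins.chrom!r}")
        if ins.te_name not in te_library:
            raise ValueError(f"unknown TE {ins.te_name!r}")
        if ins.position > len(backbone[ins.chrom]):
            raise ValueError(f"insertion position {ins.position} beyond {ins.chrom}")
        if len(te_library[ins.te_name]) != ins.te_length:
            raise ValueError(f"te_length mismatch for {ins.te_name!r}")
        key = (ins.chrom, ins.position)
        if key in seen:
            raise ValueError(f"overlapping insertions at {key}")
        seen.add(key)

    strains = sorted({s for ins in design for s in ins.strain_set})
    genomes = {}
    for strain in strains:
        genome = {}
        for chrom, seq in backbone.items():
            mine = sorted(
                (i for i in design if i.chrom == chrom and strain in i.strain_set),
                key=lambda i: i.position,
            )
            parts, prev = [], 0
            for ins in mine:
                parts.append(seq[prev:ins.position])
                parts.append(te_library[ins.te_name])
                prev = ins.position
            parts.append(seq[prev:])
            genome[chrom] = "".join(parts)
        genomes[strain] = genome
    return genomes, list(design)


def lift_position(chrom: str, position: int, strain: str, design: Sequence[TruthInsertion]) -> int:
    """Backbone coordinate -> coordinate in the strain genome built by
    :func:`plant_te_insertions` (shifted by upstream carried insertions)."""
    shift = sum(
        i.te_length
        for i in design
        if i.chrom == chrom and strain in i.strain_set and i.position < position
    )
    return position + shift


# ---------------------------------------------------------------------------
# paired-end reads
# ---------------------------------------------------------------------------


def simulate_paired_reads(
    strain_genome: Mapping[str, str],
    config: ReadSimConfig,
    name_prefix: str = "read",
) -> list:
    """Simulate FR paired-end reads from a genome.

    Fragment lengths are normal(insert_mean, insert_sd) truncated at
    2x read_length; mate 2 is the reverse complement of the fragment's far
    end; substitution errors only; the pair count is
    round(coverage * genome_length / (2 * read_length)).
    """
    chroms = sorted(strain_genome)
    lengths = np.array([len(strain_genome[c]) for c in chroms], dtype=float)
    min_len = config.insert_mean + 4 * config.insert_sd
    if any(l < min_len for l in lengths):
        raise ValueError("genome shorter than insert_mean + 4*insert_sd")

    rng = np.random.default_rng(config.seed)
    rl = config.read_length
    total = lengths.sum()
    n_pairs = int(round(config.coverage * total / (2 * rl)))

    chrom_idx = rng.choice(len(chroms), size=n_pairs, p=lengths / total)
    frag = rng.normal(config.insert_mean, config.insert_sd, size=n_pairs)
    frag = np.maximum(np.rint(frag).astype(int), 2 * rl)
    frag = np.minimum(frag, lengths[chrom_idx].astype(int))
    starts = np.floor(rng.random(n_pairs) * (lengths[chrom_idx] - frag + 1)).astype(int)

    n_err1 = rng.binomial(rl, config.error_rate, size=n_pairs)
    n_err2 = rng.binomial(rl, config.error_rate, size=n_pairs)

    pairs = []
    for i in range(n_pairs):
        chrom = chroms[chrom_idx[i]]
        seq = strain_genome[chrom]
        s, e = starts[i], starts[i] + frag[i]
        r1 = seq[s:s + rl]
        r2 = revcomp(seq[e - rl:e])
        if n_err1[i]:
            r1 = _mutate(r1, n_err1[i], rng)
        if n_err2[i]:
            r2 = _mutate(r2, n_err2[i], rng)
        pairs.append(PairedRead(f"{name_prefix}:{i}", r1, r2, chrom, int(s), int(e)))
    return pairs


def _mutate(read: str, n_errors: int, rng) -> str:
    out = list(read)
    for pos in rng.choice(len(read), size=n_errors, replace=False):
        alternatives = [b for b in BASES if b != out[pos]]
        out[pos] = alternatives[rng.integers(3)]
    return "".join(out)


def write_fastq_pair(pairs: Sequence[PairedRead], path1, path2, quality_char: str = "I"):
    """Write the two mate streams as FASTQ (constant qualities)."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            q1 = quality_char * len(p.seq1)
            q2 = quality_char * len(p.seq2)
            f1.write(f"@{p.name}/1\n{p.seq1}\n+\n{q1}\n")
            f2.write(f"@{p.name}/2\n{p.seq2}\n+\n{q2}\n")


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------


def simulate_counts(config: CountSimConfig):
    """Negative-binomial count matrix with planted fold-changes.

    Returns ``(counts, truth)``: a genes x samples DataFrame (columns
    ``A1..An, B1..Bn``) and a truth table of planted DE genes with their
    log2 fold-changes (group B relative to group A).
    """
    rng = np.random.default_rng(config.seed)
    base = config.baseline_mean * np.exp2(
        rng.normal(0.0, config.baseline_log2_sd, size=config.n_genes)
    )
    lfc = np.zeros(config.n_genes)
    for idx, fc in config.planted_de:
        lfc[idx] = fc
    mu_a = base
    mu_b = base * np.exp2(lfc)

    r = 1.0 / config.dispersion
    n = config.n_replicates

    def draw(mu):
        p = r / (r + mu)
        return rng.negative_binomial(r, p[:, None], size=(config.n_genes, n))

    counts = np.hstack([draw(mu_a), draw(mu_b)])
    columns = [f"A{i + 1}" for i in range(n)] + [f"B{i + 1}" for i in range(n)]
    genes = [f"gene{i}" for i in range(config.n_genes)]
    frame = pd.DataFrame(counts, index=genes, columns=columns)
    truth = pd.DataFrame(
        {
            "gene": [genes[i] for i, _ in config.planted_de],
            "log2fc": [fc for _, fc in config.planted_de],
        }
    )
    truth["direction"] = np.where(truth["log2fc"] > 0, "up", "down") if len(truth) else ""
    return frame, truth


# ---------------------------------------------------------------------------
# segregant genotypes
# ---------------------------------------------------------------------------


def simulate_genotypes(
    n_segregants: int,
    rf_truth: Mapping[str, float],
    seed: int = 0,
    missing_rate: float = 0.0,
):
    """Marker genotypes for a phenotype-selected mapping population.

    Every segregant carries the causal allele; each marker allele comes from
    the mutant parent with probability (1 - rf).  Returns ``(table, rf_truth)``
    where the table has one row per segregant and one column per marker plus a
    ``phenotype`` column (all selected, hence all expressing).
    """
    for marker, rf in rf_truth.items():
        if not (0 <= rf <= 0.5):
            raise ValueError(f"rf for {marker!r} outside [0, 0.5]")
    rng = np.random.default_rng(seed)
    data = {}
    for marker in sorted(rf_truth):
        rf = rf_truth[marker]
        alleles = np.where(
            rng.random(n_segregants) < 1 - rf, ALLELE_MUTANT, ALLELE_POLYMORPHIC
        )
        if missing_rate:
            alleles = np.where(rng.random(n_segregants) < missing_rate, ALLELE_MISSING, alleles)
        data[marker] = alleles
    table = pd.DataFrame(data, index=[f"seg{i}" for i in range(n_segregants)])
    table.index.name = "segregant"
    table["phenotype"] = "expressing"
    return table, dict(rf_truth)


# ---------------------------------------------------------------------------
# qPCR Cq tables
# ---------------------------------------------------------------------------


def simulate_cq(
    truth_percent_input: Mapping[tuple, float],
    n_replicates: int = 6,
    seed: int = 0,
    noise_sd: float = 0.0,
    input_fraction: float = 0.10,
    base_cq_input: float = 20.0,
    efficiency: float = 2.0,
):
    """Cq table whose noise-free percent-of-input equals the given truth.

    ``truth_percent_input`` maps (strain, mark, region) to the true percent
    input.  Gaussian noise of ``noise_sd`` cycles is added independently to IP
    and input Cq values.
    """
    rng = np.random.default_rng(seed)
    rows = []
    log_eff = np.log2(efficiency)
    for (strain, mark, region), percent in sorted(truth_percent_input.items()):
        if percent <= 0:
            raise ValueError("true percent input must be positive")
        delta = np.log2(percent / (100.0 * input_fraction)) / log_eff
        for rep in range(1, n_replicates + 1):
            cq_input = base_cq_input + rng.normal(0, noise_sd) if noise_sd else base_cq_input
            cq_ip = cq_input - delta + (rng.normal(0, noise_sd) if noise_sd else 0.0)
            rows.append(
                {
                    "strain": strain,
                    "mark": mark,
                    "region": region,
                    "replicate": rep,
                    "cq_ip": float(cq_ip),
                    "cq_input": float(cq_input),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# annotated variants
# ---------------------------------------------------------------------------


def simulate_variants(
    strains: Sequence[str],
    specs: Sequence[Mapping],
    chrom: str = "chr1",
    seed: int = 0,
):
    """Small annotated variant set with configurable per-strain genotypes.

    Each spec is a mapping with keys ``gene``, ``effect`` and ``carriers``
    (the strains genotyped as carrying the alternate allele); optional keys
    ``missing`` (strains with missing genotype) and ``pos``.  Returns a list
    of :class:`silentscan.variant_triage.VariantRecord`.
    """
    from .variant_triage import GT_ALT, GT_MISSING, GT_REF, VariantRecord

    rng = np.random.default_rng(seed)
    records = []
    next_pos = 100
    for spec in specs:
        pos = int(spec.get("pos", next_pos))
        next_pos = pos + int(rng.integers(50, 500))
        ref = BASES[rng.integers(4)]
        alt = [b for b in BASES if b != ref][rng.integers(3)]
        carriers = set(spec["carriers"])
        missing = set(spec.get("missing", ()))
        unknown = (carriers | missing) - set(strains)
        if unknown:
            raise ValueError(f"unknown strains {unknown}")
        genotypes = {
            s: GT_ALT if s in carriers else (GT_MISSING if s in missing else GT_REF)
            for s in strains
        }
        records.append(
            VariantRecord(
                chrom=spec.get("chrom", chrom),
                pos=pos,
                ref=ref,
                alt=alt,
                genotypes=genotypes,
                effect=spec.get("effect", "missense_variant"),
                gene=spec.get("gene"),
            )
        )
    return records


# ---------------------------------------------------------------------------
# protein alignments evolved on a known tree
# ---------------------------------------------------------------------------


def simulate_protein_alignment(
    n_taxa: int = 6,
    n_sites: int = 500,
    subs_prob: float = 0.15,
    seed: int = 0,
):
    """Gap-free protein alignment evolved along a random binary tree.

    Each edge substitutes every site independently with probability
    ``subs_prob`` (uniform replacement).  Returns ``(names, sequences,
    true_splits)`` where ``true_splits`` holds the internal bipartitions of
    the generating topology, each given as the frozenset side not containing
    the alphabetically first taxon.
    """
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa for informative splits")
    rng = np.random.default_rng(seed)
    names = [f"T{i + 1}" for i in range(n_taxa)]
    all_names = frozenset(names)
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")

    def evolve(seq):
        mask = rng.random(n_sites) < subs_prob
        out = seq.copy()
        out[mask] = rng.choice(aa, size=int(mask.sum()))
        return out

    # random rooted binary topology by sequential random joins
    nodes: list = list(names)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        nodes.append((a, b))
    topology = nodes[0]

    def leafset(node) -> frozenset:
        if isinstance(node, str):
            return frozenset([node])
        return leafset(node[0]) | leafset(node[1])

    leaf_seqs = {}
    splits = set()

    def walk(node, seq):
        if isinstance(node, str):
            leaf_seqs[node] = seq
            return
        ls = leafset(node)
        if 2 <= len(ls) <= n_taxa - 2:
            splits.add(ls if names[0] not in ls else all_names - ls)
        for child in node:
            walk(child, evolve(seq))

    root_seq = rng.choice(aa, size=n_sites)
    for child in topology:
        walk(child, evolve(root_seq))

    seqs = [leaf_seqs[nm].tobytes().decode("ascii") for nm in names]
    return names, seqs, splits
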