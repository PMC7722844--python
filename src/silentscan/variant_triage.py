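"""Multi-strain variant triage and CAPS (restriction gain/loss) marker design.

The triage keeps variants called reference in the progenitor strain but
carrying the alternate allele in at least one mutant strain, then looks for
genes hit by distinct qualifying variants private to each of two mutants.
CAPS design counts restriction-site occurrences on both strands of a sequence
window before and after applying a substitution.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

from ._seq import IUPAC, iupac_match, revcomp_iupac

GT_REF = "hom-ref"
GT_ALT = "carries-alt"
GT_MISSING = "missing"

#: effect annotations (matched case-insensitively as substrings) that count
#: as protein-changing for gene triage
DEFAULT_EFFECT_ALLOWLIST = ("missense", "nonsynonymous", "non-synonymous")


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int                 # 1-based
    ref: str
    alt: str
    genotypes: Mapping[str, str]  # strain -> GT_REF / GT_ALT / GT_MISSING
    effect: str = ""
    gene: Optional[str] = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")

    @property
    def key(self):
        return (self.chrom, self.pos, self.alt)


@dataclass(frozen=True)
class CapsResult:
    enzyme: str
    recognition: str
    sites_reference: int
    sites_mutant: int

    @property
    def verdict(self) -> str:
        if self.sites_mutant > self.sites_reference:
            return "gain"
        if self.sites_mutant < self.sites_reference:
            return "loss"
        return "none"


# ---------------------------------------------------------------------------
# triage
# ---------------------------------------------------------------------------


def select_mutant_specific(
    variants: Iterable[VariantRecord],
    progenitor: str,
    mutants: Sequence[str],
) -> list:
    """Variants reference in the progenitor but alternate in >=1 mutant.

    Records with a missing progenitor genotype are dropped: the rule needs
    positive evidence of the reference state.
    """
    out = []
    for v in variants:
        for strain in (progenitor, *mutants):
            if strain not in v.genotypes:
                raise KeyError(f"unknown strain {strain!r} in variant {v.chrom}:{v.pos}")
        if v.genotypes[progenitor] != GT_REF:
            continue
        if any(v.genotypes[m] == GT_ALT for m in mutants):
            out.append(v)
    return out


def genes_hit_in_both(
    variants: Iterable[VariantRecord],
    mutant_a: str,
    mutant_b: str,
    effect_allowlist: Sequence[str] = DEFAULT_EFFECT_ALLOWLIST,
) -> list:
    """Genes with distinct qualifying variants private to each mutant.

    A variant is private to a mutant when that mutant carries the alternate
    allele and the other mutant does not; two variants are distinct when they
    differ in (chrom, pos, alt).  Returns sorted gene identifiers.
    """
    def passes(v: VariantRecord) -> bool:
        e = v.effect.lower()
        return v.gene is not None and any(tag in e for tag in effect_allowlist)

    private_a: dict = {}
    private_b: dict = {}
    for v in variants:
        if not passes(v):
            continue
        in_a = v.genotypes.get(mutant_a) == GT_ALT
        in_b = v.genotypes.get(mutant_b) == GT_ALT
        if in_a and not in_b:
            private_a.setdefault(v.gene, set()).add(v.key)
        elif in_b and not in_a:
            private_b.setdefault(v.gene, set()).add(v.key)
    # private-to-A and private-to-B variant keys are disjoint by construction,
    # so any gene appearing in both maps carries distinct variants
    return sorted(private_a.keys() & private_b.keys())


def split_multiallelic(
    chrom: str, pos: int, ref: str, alts: Sequence[str],
    genotypes_by_alt: Mapping[str, Mapping[str, str]],
    effect: str = "", gene: Optional[str] = None,
) -> list:
    """Expand one multi-allelic site into biallelic VariantRecords."""
    return [
        VariantRecord(chrom, pos, ref, alt, dict(genotypes_by_alt[alt]), effect, gene)
        for alt in alts
    ]


# ---------------------------------------------------------------------------
# CAPS design
# ---------------------------------------------------------------------------


def count_sites(window: str, recognition: str) -> int:
    """Occurrences of an IUPAC recognition sequence on both strands."""
    window = window.upper()
    n = 0
    m = len(recognition)
    rc = revcomp_iupac(recognition)
    for i in range(len(window) - m + 1):
        sub = window[i:i + m]
        if iupac_match(recognition, sub):
            n += 1
        if rc != recognition and iupac_match(rc, sub):
            n += 1
    return n


def design_caps_marker(
    window: str,
    pos: int,                # 1-based position of the substitution in window
    ref_base: str,
    alt_base: str,
    enzymes: Mapping[str, str],
) -> list:
    """Score restriction-site gain/loss caused by a substitution.

    Returns one :class:`CapsResult` per enzyme, comparing site counts (both
    strands) between the reference window and the mutated window.
    """
    window = window.upper()
    if not (1 <= pos <= len(window)):
        raise ValueError("variant position outside window")
    if window[pos - 1] != ref_base.upper():
        raise ValueError(
            f"window has {window[pos - 1]!r} at position {pos}, expected {ref_base!r}"
        )
    mutant = window[:pos - 1] + alt_base.upper() + window[pos:]
    results = []
    for name in sorted(enzymes):
        site = enzymes[name].upper()
        if any(c not in IUPAC for c in site):
            raise ValueError(f"recognition sequence for {name!r} is not IUPAC")
        results.append(
            CapsResult(name, site, count_sites(window, site), count_sites(mutant, site))
        )
    return results


def load_enzymes(path=None) -> dict:
    """Enzyme name -> recognition sequence from a two-column TSV.

    Without a path, the bundled table is used.
    """
    if path is None:
        source = resources.files("silentscan").joinpath("data/enzymes.tsv")
        text = source.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    enzymes = {}
    for row in csv.reader(text.splitlines(), delimiter="\t"):
        if not row or row[0].startswith("#"):
            continue
        enzymes[row[0]] = row[1].upper()
    return enzymes


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------


def _collapse_gt(gt) -> str:
    """Any genotype containing an alt allele index counts as carries-alt."""
    if gt is None or all(a is None for a in gt):
        return GT_MISSING
    if any(a is not None and a > 0 for a in gt):
        return GT_ALT
    return GT_REF


def read_vcf(path, effect_field: str = "ANN") -> list:
    """Read annotated variants from a VCF with per-sample GT fields.

    Multi-allelic sites are split into biallelic records.  Effect class and
    gene are taken from the SnpEff-style ANN/EFF INFO field when present
    (second and fourth '|' separated items of the matching allele entry).
    """
    import pysam

    records = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            anns = rec.info.get(effect_field, ()) if effect_field in rec.info else ()
            if isinstance(anns, str):
                anns = (anns,)
            for alt_idx, alt in enumerate(rec.alts or (), start=1):
                genotypes = {}
                for s in samples:
                    gt = rec.samples[s].get("GT")
                    if gt is None or all(a is None for a in gt):
                        genotypes[s] = GT_MISSING
                    elif any(a == alt_idx for a in gt if a is not None):
                        genotypes[s] = GT_ALT
                    else:
                        genotypes[s] = GT_REF
                effect, gene = "", None
                for ann in anns:
                    parts = ann.split("|")
                    if parts and parts[0] == alt:
                        effect = parts[1] if len(parts) > 1 else ""
                        gene = parts[3] if len(parts) > 3 and parts[3] else None
                        break
                records.append(
                    VariantRecord(rec.chrom, rec.pos, rec.ref, alt, genotypes, effect, gene)
                )
    return records


def write_vcf(records: Sequence[VariantRecord], path, contig_lengths: Optional[Mapping[str, int]] = None):
    """Write biallelic VariantRecords as an uncompressed annotated VCF."""
    strains = sorted({s for r in records for s in r.genotypes})
    contigs = {}
    for r in records:
        contigs[r.chrom] = max(contigs.get(r.chrom, 0), r.pos + len(r.ref))
    if contig_lengths:
        contigs.update(contig_lengths)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted(contigs):
            fh.write(f"##contig=<ID={chrom},length={contigs[chrom]}>\n")
        fh.write('##INFO=<ID=ANN,Number=.,Type=String,Description="Allele|Annotation|Impact|Gene">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(strains) + "\n")
        gt_code = {GT_REF: "0/0", GT_ALT: "1/1", GT_MISSING: "./."}
        for r in sorted(records, key=lambda v: (v.chrom, v.pos, v.alt)):
            ann = f"ANN={r.alt}|{r.effect}|MODIFIER|{r.gene or ''}"
            gts = "\t".join(gt_code[r.genotypes.get(s, GT_MISSING)] for s in strains)
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t{ann}\tGT\t{gts}\n"
            )
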