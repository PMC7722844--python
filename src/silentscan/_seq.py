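"""Small shared sequence helpers used across modules."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (IUPAC letters beyond ACGTN are not handled)."""
    return seq.translate(_COMPLEMENT)[::-1]


# IUPAC nucleotide degeneracy, used for restriction-site matching.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_IUPAC_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp_iupac(seq: str) -> str:
    """Reverse complement over the full IUPAC nucleotide alphabet."""
    return seq.upper().translate(_IUPAC_COMP)[::-1]


def iupac_match(site: str, window: str) -> bool:
    """True if `window` (plain ACGT) matches the IUPAC pattern `site` exactly."""
    if len(site) != len(window):
        return False
    for s, w in zip(site.upper(), window.upper()):
        allowed = IUPAC.get(s)
        if allowed is None:
            raise ValueError(f"invalid IUPAC code {s!r} in recognition sequence")
        if w not in allowed:
            return False
    return True
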