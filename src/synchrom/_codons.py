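"""Codon-level utilities shared by the recoding rules.

Synonymous recoding is always deterministic: candidate codons are ranked by an
explicit key (see :func:`ranked_synonyms`), so the same input sequence and
policy always yield the same design.
"""

from __future__ import annotations

from functools import lru_cache

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: Standard genetic code, DNA alphabet.
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

#: S. cerevisiae codon usage, occurrences per 1000 codons.  Only the relative
#: ranking within a synonym family matters for recoding decisions.
YEAST_USAGE = {
    "TTT": 26.1, "TTC": 18.4, "TTA": 26.2, "TTG": 27.2,
    "CTT": 12.3, "CTC": 5.4, "CTA": 13.4, "CTG": 10.5,
    "ATT": 30.1, "ATC": 17.2, "ATA": 17.8, "ATG": 20.9,
    "GTT": 22.1, "GTC": 11.8, "GTA": 11.8, "GTG": 10.8,
    "TCT": 23.5, "TCC": 14.2, "TCA": 18.7, "TCG": 8.6,
    "CCT": 13.5, "CCC": 6.8, "CCA": 18.3, "CCG": 5.3,
    "ACT": 20.3, "ACC": 12.7, "ACA": 17.8, "ACG": 8.0,
    "GCT": 21.2, "GCC": 12.6, "GCA": 16.2, "GCG": 6.2,
    "TAT": 18.8, "TAC": 14.8, "TAA": 1.1, "TAG": 0.5,
    "CAT": 13.6, "CAC": 7.8, "CAA": 27.3, "CAG": 12.1,
    "AAT": 35.7, "AAC": 24.8, "AAA": 41.9, "AAG": 30.8,
    "GAT": 37.6, "GAC": 20.2, "GAA": 45.6, "GAG": 19.2,
    "TGT": 8.1, "TGC": 4.8, "TGA": 0.7, "TGG": 10.4,
    "CGT": 6.4, "CGC": 2.6, "CGA": 3.0, "CGG": 1.7,
    "AGT": 14.2, "AGC": 9.8, "AGA": 21.3, "AGG": 9.2,
    "GGT": 23.9, "GGC": 9.8, "GGA": 10.9, "GGG": 6.0,
}

_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in GENETIC_CODE.items():
    _FAMILIES.setdefault(_aa, ())
    _FAMILIES[_aa] = _FAMILIES[_aa] + (_codon,)


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate a DNA CDS (length divisible by 3) with '*' for stops."""
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    return "".join(GENETIC_CODE[cds[i : i + 3]] for i in range(0, len(cds), 3))


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@lru_cache(maxsize=None)
def synonyms(codon: str) -> tuple[str, ...]:
    """All codons encoding the same amino acid (including ``codon`` itself)."""
    return _FAMILIES[GENETIC_CODE[codon]]


@lru_cache(maxsize=None)
def ranked_synonyms(codon: str) -> tuple[str, ...]:
    """Alternative synonymous codons ranked for 'maximal-difference' recoding.

    Order: larger Hamming distance to the original first, then higher yeast
    usage, then alphabetical.  The original codon is excluded.
    """
    alts = [c for c in synonyms(codon) if c != codon]
    alts.sort(key=lambda c: (-hamming(c, codon), -YEAST_USAGE[c], c))
    return tuple(alts)


@lru_cache(maxsize=None)
def minimal_change_synonyms(codon: str) -> tuple[str, ...]:
    """Alternative synonymous codons ranked for minimal disturbance.

    Order: fewer changed bases first, then higher usage, then alphabetical.
    Used when a motif merely has to be destroyed, not maximally recoded.
    """
    alts = [c for c in synonyms(codon) if c != codon]
    alts.sort(key=lambda c: (hamming(c, codon), -YEAST_USAGE[c], c))
    return tuple(alts)


def max_mismatch_recode(codon: str) -> str | None:
    """The preferred maximal-difference synonymous replacement, if any."""
    alts = ranked_synonyms(codon)
    return alts[0] if alts else None
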