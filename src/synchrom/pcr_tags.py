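"""PCR-tag design: recoded amplicon windows distinguishable by allele-specific PCR.

A PCR tag is a short stretch of coding sequence recoded with synonymous
codons so that wild-type and synthetic alleles can be discriminated by PCR.
Tags respect chunk membership (a tag must sit entirely inside one chunk so a
single junction PCR can genotype it), never overlap another tag in the same
gene (the overlapping-tag failure mode that once introduced a missense
change is an explicit regression here), and never change the protein.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from Bio.SeqUtils import MeltingTemp as mt

from ._codons import hamming, max_mismatch_recode, revcomp
from .design_rules import DesignedChromosome, DesignPolicy, Edit, EditPlan
from .genome_model import ChromosomeAnnotation, OrfFeature

logger = logging.getLogger(__name__)

#: Nearest-neighbor Tm conditions: 500 nM primer, 50 mM Na+, 3 mM Mg2+,
#: 0.8 mM dNTPs — typical qPCR mix.
_TM_KWARGS = dict(dnac1=500.0, dnac2=0.0, Na=50.0, Mg=3.0, dNTPs=0.8)


def primer_tm(seq: str) -> float:
    """Nearest-neighbor melting temperature (°C) under qPCR-like conditions."""
    return float(mt.Tm_NN(seq, **_TM_KWARGS))


@dataclass(frozen=True)
class Primer:
    seq: str
    tm: float


@dataclass(frozen=True)
class PcrTagPair:
    gene_id: str
    chunk_id: str
    window: tuple[int, int]  # wild-type coordinates, inside the CDS
    wt_amplicon: str
    syn_amplicon: str
    n_mismatches: int
    wt_primers: tuple[Primer, Primer]
    syn_primers: tuple[Primer, Primer]
    unique_in_wt: bool
    unique_in_syn: bool

    def __post_init__(self) -> None:
        if len(self.wt_amplicon) != len(self.syn_amplicon):
            raise ValueError("amplicons must have equal length")


def _pick_primer(template: str, policy: DesignPolicy, reverse: bool) -> Primer | None:
    """Shortest primer from the template end whose Tm falls in the band."""
    lo, hi = policy.tag_primer_len
    band_lo, band_hi = policy.tag_tm_band
    for length in range(lo, min(hi, len(template)) + 1):
        seq = template[-length:] if reverse else template[:length]
        if reverse:
            seq = revcomp(seq)
        tm = primer_tm(seq)
        if band_lo <= tm <= band_hi:
            return Primer(seq, round(tm, 2))
        if tm > band_hi:
            return None  # further extension only raises Tm
    return None


def _count_both_strands(haystack: str, needle: str) -> int:
    n = 0
    for pat in {needle, revcomp(needle)}:
        start = 0
        while True:
            i = haystack.find(pat, start)
            if i < 0:
                break
            n += 1
            start = i + 1
    return n


def _recode_window(window_seq: str, skip_first_codon: bool) -> str:
    out = []
    for i in range(0, len(window_seq), 3):
        codon = window_seq[i : i + 3]
        if skip_first_codon and i == 0:
            out.append(codon)
            continue
        alt = max_mismatch_recode(codon)
        out.append(alt if alt is not None else codon)
    return "".join(out)


def design_tags(
    designed: DesignedChromosome,
    ann: ChromosomeAnnotation,
    segmentation,
    policy: DesignPolicy,
) -> list[PcrTagPair]:
    """Design candidate PCR tags for every verified/uncharacterized ORF.

    Candidate windows are codon-aligned, tiled left to right along each CDS,
    and accepted when they (a) avoid every previously planned edit, (b) sit
    entirely inside one chunk and one exon, (c) reach the mismatch minimum,
    (d) have primers within the Tm band, (e) do not cross-amplify the
    wild-type chromosome, and (f) do not overlap an already-accepted tag of
    the same gene.
    """
    wt_seq = ann.sequence
    window_codons = (policy.tag_window_bp[1] // 3) or 1
    window_len = window_codons * 3
    if window_len < policy.tag_window_bp[0]:
        window_codons += 1
        window_len = window_codons * 3

    # genomic positions touched by prior edits (incl. insertion points)
    blocked: set[int] = set()
    for e in designed.plan:
        s, en = e.wt_interval
        blocked.update(range(s, en))
        if e.kind == "insert":
            blocked.add(s)

    chunk_intervals = [(c.id, c.interval) for c in segmentation.chunks]
    tags: list[PcrTagPair] = []
    for orf in ann.orfs_by_class("verified", "uncharacterized"):
        n_codons = orf.cds_length() // 3
        if n_codons - 2 < window_codons:  # exclude start and stop codons
            logger.info("%s too short for a tag window", orf.id)
            continue
        accepted: list[tuple[int, int]] = []
        cds = orf.spliced_cds(wt_seq)
        ci = 1  # skip the start codon
        while ci + window_codons <= n_codons - 1:
            tag = _try_window(
                orf, cds, ci, window_codons, window_len, wt_seq, designed,
                blocked, chunk_intervals, policy, accepted,
            )
            if tag is not None:
                tags.append(tag)
                accepted.append(tag.window)
                ci += window_codons
            else:
                ci += 1
    tags.sort(key=lambda t: (t.chunk_id, t.gene_id, t.window))
    return tags


def _try_window(
    orf: OrfFeature,
    cds: str,
    ci: int,
    window_codons: int,
    window_len: int,
    wt_seq: str,
    designed: DesignedChromosome,
    blocked: set[int],
    chunk_intervals: list[tuple[str, tuple[int, int]]],
    policy: DesignPolicy,
    accepted: list[tuple[int, int]],
) -> PcrTagPair | None:
    cds_start = ci * 3
    gpos = [orf.cds_to_genomic(cds_start + k) for k in range(window_len)]
    lo, hi = min(gpos), max(gpos) + 1
    if hi - lo != window_len:
        return None  # window crosses an intron
    if any(p in blocked for p in range(lo, hi)):
        return None
    if any(a0 < hi and lo < a1 for a0, a1 in accepted):
        return None  # overlaps an accepted tag of this gene

    d_lo = designed.liftover.wt_to_designed(lo)
    d_hi = designed.liftover.wt_to_designed(hi - 1)
    if d_lo is None or d_hi is None:
        return None
    chunk_id = next(
        (cid for cid, (cs, ce) in chunk_intervals if cs <= d_lo and d_hi < ce),
        None,
    )
    if chunk_id is None:
        return None  # spans a chunk junction

    wt_window = cds[cds_start : cds_start + window_len]
    syn_window = _recode_window(wt_window, skip_first_codon=False)
    n_mm = hamming(wt_window, syn_window)
    if n_mm < policy.min_tag_mismatches:
        return None

    primers = {}
    for name, template in (("wt", wt_window), ("syn", syn_window)):
        fwd = _pick_primer(template, policy, reverse=False)
        rev = _pick_primer(template, policy, reverse=True)
        if fwd is None or rev is None:
            return None
        primers[name] = (fwd, rev)
    # cross-amplification: synthetic primers must not prime the wild type
    for primer in primers["syn"]:
        if _count_both_strands(wt_seq, primer.seq) > 0:
            return None

    wt_amp = wt_window if orf.strand == "+" else revcomp(wt_window)
    syn_amp = syn_window if orf.strand == "+" else revcomp(syn_window)
    return PcrTagPair(
        gene_id=orf.id,
        chunk_id=chunk_id,
        window=(lo, hi),
        wt_amplicon=wt_amp,
        syn_amplicon=syn_amp,
        n_mismatches=n_mm,
        wt_primers=primers["wt"],
        syn_primers=primers["syn"],
        unique_in_wt=_count_both_strands(wt_seq, wt_amp) == 1,
        unique_in_syn=_count_both_strands(wt_seq, syn_amp) == 0,
    )


def minimize_tags(tags: Sequence[PcrTagPair], policy: DesignPolicy) -> list[PcrTagPair]:
    """Apply the per-(gene, chunk) tag quota.

    Keeps the ``tags_per_gene_per_chunk`` best tags (most mismatches, ties
    broken by leftmost window) for every gene/chunk pair; a quota of 0 means
    unlimited.
    """
    quota = policy.tags_per_gene_per_chunk
    if quota <= 0:
        return list(tags)
    groups: dict[tuple[str, str], list[PcrTagPair]] = {}
    for t in tags:
        groups.setdefault((t.gene_id, t.chunk_id), []).append(t)
    kept: list[PcrTagPair] = []
    for key in sorted(groups):
        group = sorted(groups[key], key=lambda t: (-t.n_mismatches, t.window))
        kept.extend(group[:quota])
    kept.sort(key=lambda t: (t.chunk_id, t.gene_id, t.window))
    return kept


def tags_to_edits(tags: Sequence[PcrTagPair], ann: ChromosomeAnnotation) -> EditPlan:
    """Length-preserving substitution edits realizing the tags (wild-type frame)."""
    edits = []
    for t in tags:
        if t.n_mismatches == 0:
            continue
        lo, hi = t.window
        # amplicons are stored genomic-forward for both strands
        edits.append(
            Edit("substitute", (lo, hi), t.syn_amplicon, "tag_recode", t.gene_id)
        )
    return EditPlan(edits)


def recoded_bp(tags: Sequence[PcrTagPair]) -> int:
    """Total recoded bp: sum of window lengths of tags with >=1 mismatch."""
    return sum(t.window[1] - t.window[0] for t in tags if t.n_mismatches > 0)


def tag_report(tags: Sequence[PcrTagPair]) -> pd.DataFrame:
    """Deterministic tag table ordered by (chunk, gene, window)."""
    rows = []
    for t in sorted(tags, key=lambda t: (t.chunk_id, t.gene_id, t.window)):
        rows.append(
            {
                "chunk_id": t.chunk_id,
                "gene_id": t.gene_id,
                "wt_start": t.window[0],
                "wt_end": t.window[1],
                "n_mismatches": t.n_mismatches,
                "wt_amplicon": t.wt_amplicon,
                "syn_amplicon": t.syn_amplicon,
                "wt_fwd": t.wt_primers[0].seq,
                "wt_fwd_tm": t.wt_primers[0].tm,
                "wt_rev": t.wt_primers[1].seq,
                "wt_rev_tm": t.wt_primers[1].tm,
                "syn_fwd": t.syn_primers[0].seq,
                "syn_fwd_tm": t.syn_primers[0].tm,
                "syn_rev": t.syn_primers[1].seq,
                "syn_rev_tm": t.syn_primers[1].tm,
                "unique_in_wt": t.unique_in_wt,
                "unique_in_syn": t.unique_in_syn,
            }
        )
    columns = [
        "chunk_id", "gene_id", "wt_start", "wt_end", "n_mismatches",
        "wt_amplicon", "syn_amplicon",
        "wt_fwd", "wt_fwd_tm", "wt_rev", "wt_rev_tm",
        "syn_fwd", "syn_fwd_tm", "syn_rev", "syn_rev_tm",
        "unique_in_wt", "unique_in_syn",
    ]
    return pd.DataFrame(rows, columns=columns)


def plate_order_csv(tags: Sequence[PcrTagPair]) -> pd.DataFrame:
    """Primer plate-ordering sheet: one row per oligo, well-ordered."""
    rows = []
    wells = _well_series()
    for t in sorted(tags, key=lambda t: (t.chunk_id, t.gene_id, t.window)):
        for role, primer in (
            ("wt_fwd", t.wt_primers[0]), ("wt_rev", t.wt_primers[1]),
            ("syn_fwd", t.syn_primers[0]), ("syn_rev", t.syn_primers[1]),
        ):
            rows.append(
                {
                    "well": next(wells),
                    "name": f"{t.gene_id}_{t.window[0]}_{role}",
                    "sequence": primer.seq,
                    "tm": primer.tm,
                }
            )
    return pd.DataFrame(rows, columns=["well", "name", "sequence", "tm"])


def _well_series():
    plate = 1
    while True:
        for row in "ABCDEFGH":
            for col in range(1, 13):
                yield f"P{plate}-{row}{col}"
        plate += 1
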