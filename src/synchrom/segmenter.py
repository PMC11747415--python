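"""Chunk/megachunk segmentation for SwAP-In assembly planning.

The designed chromosome is partitioned left to right into synthesis chunks
(6–10 kb, adjacent chunks sharing a 40 bp overlap) grouped into megachunks
of four to five chunks.  Consecutive megachunks share a 450 bp homology
region, and each megachunk's terminal chunk carries an auxotrophic marker,
alternating URA3/LEU2 along the chromosome.  Chunk termini are screened for
two integration hazards: non-unique terminus k-mers (which can misdirect
homologous recombination) and termini landing inside coding sequences of
essential or conditionally essential genes (which the marker insertion would
disrupt).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
import pandas as pd

from ._codons import revcomp
from .design_rules import DesignedChromosome, DesignPolicy
from .genome_model import ChromosomeAnnotation, OrfFeature

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Chunk:
    id: str
    interval: tuple[int, int]  # designed coordinates
    left_kmer: str
    right_kmer: str
    flagged: bool = False  # terminal chunk deviating from the length band


@dataclass(frozen=True)
class Megachunk:
    letter: str
    chunk_ids: tuple[str, ...]
    marker: str
    overlap_450: tuple[int, int] | None  # shared with the NEXT megachunk
    flagged: bool = False  # deviates from the 4-5 chunk band


@dataclass(frozen=True)
class TerminusViolation:
    chunk_id: str
    kind: str  # nonunique_kmer | blacklist_cds | telomere_homology
    detail: str
    offending: str  # gene id or duplicate-locus position


@dataclass
class Segmentation:
    chunks: list[Chunk]
    megachunks: list[Megachunk]
    cuts: list[int] = field(default_factory=list)
    chunk_overlap_bp: int = 40
    megachunk_overlap_bp: int = 450

    def chunk(self, chunk_id: str) -> Chunk:
        for c in self.chunks:
            if c.id == chunk_id:
                return c
        raise KeyError(chunk_id)

    def reassemble(self, designed_sequence: str) -> str:
        """Overlap-trimmed concatenation of chunk sequences."""
        parts = []
        prev_end = 0
        for c in self.chunks:
            s, e = c.interval
            parts.append(designed_sequence[max(s, prev_end):e])
            prev_end = e
        return "".join(parts)

    def to_json(self) -> str:
        data = {
            "chunk_overlap_bp": self.chunk_overlap_bp,
            "megachunk_overlap_bp": self.megachunk_overlap_bp,
            "cuts": self.cuts,
            "chunks": [
                {"id": c.id, "start": c.interval[0], "end": c.interval[1],
                 "flagged": c.flagged}
                for c in self.chunks
            ],
            "megachunks": [
                {"letter": m.letter, "chunks": list(m.chunk_ids),
                 "marker": m.marker,
                 "overlap_450": list(m.overlap_450) if m.overlap_450 else None,
                 "flagged": m.flagged}
                for m in self.megachunks
            ],
        }
        return json.dumps(data, indent=2)


def _megachunk_letters():
    from string import ascii_uppercase

    for ch in ascii_uppercase:
        yield ch
    for ch in ascii_uppercase:
        yield ch * 2


def _group_sizes(n: int, lo: int, hi: int) -> list[int]:
    """Split n chunks into groups of lo..hi (prefer hi); last group may deviate."""
    if n <= hi:
        return [n]
    for n_hi in range(n // hi, -1, -1):
        rest = n - n_hi * hi
        if rest == 0:
            return [hi] * n_hi
        if rest % lo == 0:
            return [hi] * n_hi + [lo] * (rest // lo)
        # allow intermediate sizes between lo and hi
        for size in range(hi - 1, lo - 1, -1):
            if rest % size == 0 and lo <= size <= hi:
                return [hi] * n_hi + [size] * (rest // size)
    sizes = [hi] * (n // hi)
    leftover = n - sum(sizes)
    if leftover:
        sizes.append(leftover)  # flagged later
    return sizes


def _kmer_count(seq: str, kmer: str) -> int:
    n = 0
    for pat in {kmer, revcomp(kmer)}:
        start = 0
        while True:
            i = seq.find(pat, start)
            if i < 0:
                break
            n += 1
            start = i + 1
    return n


def _terminus_ok(
    seq: str,
    boundary: int,
    ann: ChromosomeAnnotation | None,
    policy: DesignPolicy,
) -> bool:
    k = policy.uniqueness_k
    offsets = [0, policy.chunk_overlap_bp, policy.megachunk_overlap_bp]
    for off in offsets:
        s = boundary - off
        for kmer in (seq[max(0, s - k):s], seq[s:s + k]):
            if len(kmer) == k and _kmer_count(seq, kmer) != 1:
                return False
    if ann is not None:
        for off in offsets:
            pos = boundary - off
            for orf in ann.orfs:
                if not orf.contains(pos):
                    continue
                if orf.essential or (
                    orf.conditional_tags & policy.terminus_blacklist_tags
                ):
                    return False
    return True


def segment(
    designed: DesignedChromosome | str,
    ann: ChromosomeAnnotation | None,
    policy: DesignPolicy,
) -> Segmentation:
    """Greedy left-to-right partition into chunks and megachunks.

    Cut positions aim at the middle of the chunk-length band and are locally
    shifted (within ``policy.boundary_shift_bp``) to keep chunk termini
    unique and outside blacklisted coding sequences; where no acceptable
    position exists the nominal cut stands and ``check_termini`` will report
    the violation.  ``ann`` should be the designed-frame annotation.
    """
    seq = designed.sequence if isinstance(designed, DesignedChromosome) else designed
    if ann is None and isinstance(designed, DesignedChromosome):
        ann = designed.features_lifted
    L = len(seq)
    lo, hi = policy.chunk_len_bp
    target = (lo + hi) // 2

    cuts: list[int] = [0]
    pos = 0
    flagged_single = L < lo
    while L - pos > hi:
        nominal = pos + target
        lo_b = max(pos + lo, nominal - policy.boundary_shift_bp)
        hi_b = min(pos + hi, nominal + policy.boundary_shift_bp, L - 1)
        chosen = nominal
        if policy.boundary_shift_bp > 0:
            chosen = None
            for delta in range(0, policy.boundary_shift_bp + 1):
                for cand in (nominal + delta, nominal - delta):
                    if lo_b <= cand <= hi_b and _terminus_ok(seq, cand, ann, policy):
                        chosen = cand
                        break
                if chosen is not None:
                    break
            if chosen is None:
                chosen = nominal
                logger.warning("no acceptable cut near %d; keeping nominal", nominal)
        # avoid a short terminal remainder
        if L - chosen < lo:
            break
        cuts.append(chosen)
        pos = chosen
    cuts.append(L)
    if flagged_single:
        logger.warning("chromosome shorter than min chunk length; single chunk")

    n_chunks = len(cuts) - 1
    glo, ghi = policy.chunks_per_megachunk
    sizes = _group_sizes(n_chunks, glo, ghi)

    chunks: list[Chunk] = []
    megachunks: list[Megachunk] = []
    letters = _megachunk_letters()
    k = policy.uniqueness_k
    ci = 0
    for mi, size in enumerate(sizes):
        letter = next(letters)
        ids = []
        for j in range(size):
            cut_lo, cut_hi = cuts[ci], cuts[ci + 1]
            if ci == 0:
                start = cut_lo
            elif j == 0:  # first chunk of a megachunk: 450 bp homology arm
                start = cut_lo - policy.megachunk_overlap_bp
            else:
                start = cut_lo - policy.chunk_overlap_bp
            start = max(start, 0)
            cid = f"{letter}{j + 1}"
            length = cut_hi - cut_lo
            flag = not (lo <= length <= hi)
            chunks.append(
                Chunk(
                    id=cid,
                    interval=(start, cut_hi),
                    left_kmer=seq[start : start + k],
                    right_kmer=seq[max(0, cut_hi - k) : cut_hi],
                    flagged=flag,
                )
            )
            ids.append(cid)
            ci += 1
        marker = policy.marker_cycle[mi % len(policy.marker_cycle)]
        if mi < len(sizes) - 1:
            boundary = cuts[ci]
            overlap = (boundary - policy.megachunk_overlap_bp, boundary)
        else:
            overlap = None
        megachunks.append(
            Megachunk(
                letter=letter,
                chunk_ids=tuple(ids),
                marker=marker,
                overlap_450=overlap,
                flagged=not (glo <= size <= ghi),
            )
        )
    return Segmentation(
        chunks=chunks,
        megachunks=megachunks,
        cuts=cuts,
        chunk_overlap_bp=policy.chunk_overlap_bp,
        megachunk_overlap_bp=policy.megachunk_overlap_bp,
    )


def check_termini(
    seg: Segmentation,
    designed: DesignedChromosome | str,
    ann: ChromosomeAnnotation,
    policy: DesignPolicy,
    host_genome: str | None = None,
) -> list[TerminusViolation]:
    """Screen every chunk terminus for integration hazards.

    For each terminus k-mer, exact occurrences (both strands) in the designed
    sequence — and optionally a host genome — must equal one; a terminus
    inside an essential or blacklist-tagged CDS is a marker-disruption
    hazard.  A non-unique k-mer whose extra occurrence falls inside a
    telomere feature is reported as telomere homology.
    """
    seq = designed.sequence if isinstance(designed, DesignedChromosome) else designed
    violations: list[TerminusViolation] = []
    k = policy.uniqueness_k
    prev_end: int | None = None
    for chunk in seg.chunks:
        s, e = chunk.interval
        sides = [("right", chunk.right_kmer, e - 1)]
        # when the left terminus region coincides with the previous chunk's
        # right terminus region (the shared 40 bp overlap) it is the same
        # physical junction and is checked once
        if prev_end is None or (s, s + k) != (prev_end - k, prev_end):
            sides.insert(0, ("left", chunk.left_kmer, s))
        prev_end = e
        for side, kmer, pos in sides:
            if len(kmer) < policy.uniqueness_k:
                continue
            count = _kmer_count(seq, kmer)
            if host_genome is not None:
                count += _kmer_count(host_genome, kmer)
            if count != 1:
                extra = _extra_occurrence(seq, kmer, pos)
                kind = "nonunique_kmer"
                if extra is not None and any(
                    t0 <= extra < t1 for t0, t1 in ann.telomeres
                ):
                    kind = "telomere_homology"
                violations.append(
                    TerminusViolation(
                        chunk_id=chunk.id,
                        kind=kind,
                        detail=f"{side} terminus {policy.uniqueness_k}-mer occurs "
                               f"{count} times",
                        offending=str(extra if extra is not None else pos),
                    )
                )
            hit = _blacklist_gene_at(ann, pos, policy)
            if hit is not None:
                violations.append(
                    TerminusViolation(
                        chunk_id=chunk.id,
                        kind="blacklist_cds",
                        detail=f"{side} terminus at {pos} inside CDS of {hit.id}",
                        offending=hit.id,
                    )
                )
    return violations


def _extra_occurrence(seq: str, kmer: str, own_pos: int) -> int | None:
    for pat in {kmer, revcomp(kmer)}:
        start = 0
        while True:
            i = seq.find(pat, start)
            if i < 0:
                break
            if abs(i - own_pos) > len(kmer):
                return i
            start = i + 1
    return None


def _blacklist_gene_at(
    ann: ChromosomeAnnotation, pos: int, policy: DesignPolicy
) -> OrfFeature | None:
    for orf in ann.orfs:
        if orf.contains(pos) and (
            orf.essential or orf.conditional_tags & policy.terminus_blacklist_tags
        ):
            return orf
    return None


def marker_plan(seg: Segmentation, ann: ChromosomeAnnotation) -> pd.DataFrame:
    """Per-megachunk marker placement and any CDS it would disrupt.

    The marker cassette sits at the end of the terminal chunk of each
    megachunk (just inside the junction).  ``ann`` must be the designed-frame
    annotation so coordinates line up with the segmentation.
    """
    rows = []
    for m in seg.megachunks:
        terminal = seg.chunk(m.chunk_ids[-1])
        coord = terminal.interval[1] - 1
        disrupted = next((o for o in ann.orfs if o.contains(coord)), None)
        blacklisted = bool(
            disrupted is not None
            and (disrupted.essential or disrupted.conditional_tags)
        )
        rows.append(
            {
                "megachunk": m.letter,
                "marker": m.marker,
                "terminal_chunk": terminal.id,
                "insertion_coord": coord,
                "disrupted_cds": disrupted.id if disrupted else "",
                "violation": blacklisted,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["megachunk", "marker", "terminal_chunk", "insertion_coord",
                 "disrupted_cds", "violation"],
    )
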