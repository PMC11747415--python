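"""End-to-end design pipeline: rules → segmentation → tags → audit."""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

from .auditor import AuditReport, audit
from .design_rules import (
    DesignedChromosome,
    DesignPolicy,
    apply_edits,
    build_base_plan,
)
from .genome_model import ChromosomeAnnotation
from .pcr_tags import PcrTagPair, design_tags, minimize_tags, tags_to_edits
from .segmenter import Segmentation, segment


@dataclass
class DesignResult:
    wild_type: ChromosomeAnnotation
    policy: DesignPolicy
    designed: DesignedChromosome
    segmentation: Segmentation
    tags: list[PcrTagPair]
    report: AuditReport


def _refresh_chunk_kmers(seg: Segmentation, sequence: str, k: int) -> Segmentation:
    chunks = [
        dc_replace(
            c,
            left_kmer=sequence[c.interval[0] : c.interval[0] + k],
            right_kmer=sequence[max(0, c.interval[1] - k) : c.interval[1]],
        )
        for c in seg.chunks
    ]
    return Segmentation(
        chunks=chunks,
        megachunks=seg.megachunks,
        cuts=seg.cuts,
        chunk_overlap_bp=seg.chunk_overlap_bp,
        megachunk_overlap_bp=seg.megachunk_overlap_bp,
    )


def design_chromosome(ann: ChromosomeAnnotation, policy: DesignPolicy) -> DesignResult:
    """Run the full design on a wild-type annotation.

    Stages: (1) the base rule set (deletions, loxPsym, stop swaps, repeat
    smashing, restriction-site removal) is planned and applied; (2) the
    intermediate chromosome is segmented into chunks/megachunks; (3) PCR
    tags are designed against chunk membership, trimmed to the policy quota,
    and applied as length-preserving substitutions (chunk coordinates stay
    valid); (4) the audit double-derives the headline counts.
    """
    base_plan = build_base_plan(ann, policy)
    intermediate = apply_edits(ann, base_plan)
    seg = segment(intermediate, intermediate.features_lifted, policy)
    candidates = design_tags(intermediate, ann, seg, policy)
    tags = minimize_tags(candidates, policy)
    full_plan = base_plan + tags_to_edits(tags, ann)
    designed = apply_edits(ann, full_plan)
    seg = _refresh_chunk_kmers(seg, designed.sequence, policy.uniqueness_k)
    report = audit(designed, ann, tags, seg, policy)
    return DesignResult(
        wild_type=ann,
        policy=policy,
        designed=designed,
        segmentation=seg,
        tags=tags,
        report=report,
    )
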