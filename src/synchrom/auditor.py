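"""Design verification: headline counts, dual derivation, integrity sweeps.

The audit recomputes every headline count twice — once from the edit plan
and once independently from the sequences (motif scans, per-ORF stop-codon
comparison) — and treats any disagreement between the two derivations as a
violation in its own right.  It also sweeps every real gene for protein
changes and, under the v2 policy, confirms that no loxPsym insertion
intrudes on the exclusion window upstream of a verified start codon.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from ._codons import translate
from .design_rules import DesignedChromosome, DesignPolicy
from .genome_model import ChromosomeAnnotation

COUNT_FIELDS = (
    "loxpsym_sites", "stop_swaps", "tag_windows", "tag_recoded_bp",
    "rs_sites_recoded", "rs_recoded_bp", "repeat_smash_orfs",
    "trna_genes_removed", "trna_bp_removed", "introns_removed",
    "repeat_bp_deleted", "insertions_bp", "deletions_bp", "final_length",
)

MONOTONE_FIELDS = ("loxpsym_sites", "stop_swaps", "tag_windows")


@dataclass(frozen=True)
class Violation:
    rule: str
    feature: str
    coordinate: int
    message: str


@dataclass
class AuditReport:
    chromosome: str
    wild_length: int
    counts: dict[str, int]
    violations: list[Violation] = field(default_factory=list)
    policy_echo: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.violations

    def to_dict(self) -> dict:
        return {
            "chromosome": self.chromosome,
            "wild_length": self.wild_length,
            "counts": dict(self.counts),
            "violations": [
                {"rule": v.rule, "feature": v.feature,
                 "coordinate": v.coordinate, "message": v.message}
                for v in self.violations
            ],
            "policy": self.policy_echo,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def summary(self) -> str:
        lines = [f"Audit of {self.chromosome} (wild type {self.wild_length} bp)"]
        for k in COUNT_FIELDS:
            lines.append(f"  {k:22s} {self.counts.get(k, 0)}")
        if self.violations:
            lines.append(f"  VIOLATIONS ({len(self.violations)}):")
            for v in self.violations:
                lines.append(f"    [{v.rule}] {v.feature}@{v.coordinate}: {v.message}")
        else:
            lines.append("  no violations")
        return "\n".join(lines)


def _count_nonoverlapping(seq: str, motif: str) -> int:
    n = 0
    start = 0
    while True:
        i = seq.find(motif, start)
        if i < 0:
            return n
        n += 1
        start = i + len(motif)


def audit(
    designed: DesignedChromosome,
    ann: ChromosomeAnnotation,
    tags: Sequence | None,
    seg,
    policy: DesignPolicy,
) -> AuditReport:
    """Verify a design and produce the headline count report.

    Absent stages (``tags``/``seg`` = None) are audited as zero.
    """
    plan = designed.plan
    violations: list[Violation] = []

    counts: dict[str, int] = {k: 0 for k in COUNT_FIELDS}
    lox_edits = plan.by_rule("loxpsym")
    counts["loxpsym_sites"] = sum(
        len(e.replacement) // len(policy.loxpsym_motif) for e in lox_edits
    )
    counts["stop_swaps"] = len(plan.by_rule("stop_swap"))
    rs_edits = plan.by_rule("rs_removal")
    rs_sites = {e.feature_id for e in rs_edits}
    counts["rs_sites_recoded"] = len(rs_sites)
    # bp of recognition sites destroyed (site label encodes the motif)
    counts["rs_recoded_bp"] = sum(
        len(fid.split("|")[-1].split("@")[0]) for fid in rs_sites
    )
    counts["repeat_smash_orfs"] = len({e.feature_id for e in plan.by_rule("repeat_smash")})
    trna_edits = plan.by_rule("trna_del")
    counts["trna_genes_removed"] = len(trna_edits)
    counts["trna_bp_removed"] = sum(
        e.wt_interval[1] - e.wt_interval[0] for e in trna_edits
    )
    counts["introns_removed"] = len(plan.by_rule("intron_del"))
    counts["repeat_bp_deleted"] = sum(
        e.wt_interval[1] - e.wt_interval[0] for e in plan.by_rule("repeat_del")
    )
    counts["insertions_bp"] = plan.total_insertion_bp()
    counts["deletions_bp"] = plan.total_deletion_bp()
    counts["final_length"] = len(designed.sequence)

    if tags is not None:
        from .pcr_tags import recoded_bp

        counts["tag_windows"] = len(tags)
        counts["tag_recoded_bp"] = recoded_bp(tags)

    # invariant: length bookkeeping
    expect = len(ann.sequence) + counts["insertions_bp"] - counts["deletions_bp"]
    if expect != counts["final_length"]:
        violations.append(
            Violation("length", designed.features_lifted.name, 0,
                      f"final length {counts['final_length']} != "
                      f"wild {len(ann.sequence)} + ins - del = {expect}")
        )

    # sequence-derived loxPsym count must agree with the plan-derived count
    wt_occ = _count_nonoverlapping(ann.sequence, policy.loxpsym_motif)
    seq_lox = _count_nonoverlapping(designed.sequence, policy.loxpsym_motif)
    if wt_occ == 0 and seq_lox != counts["loxpsym_sites"]:
        violations.append(
            Violation("loxpsym", "motif_scan", 0,
                      f"sequence scan finds {seq_lox} motifs, plan has "
                      f"{counts['loxpsym_sites']}")
        )

    # per-ORF stop comparison, protein integrity, and the designed-frame
    # annotation for window sweeps
    lifted = {o.id: o for o in designed.features_lifted.orfs}
    seq_swaps = 0
    for orf in ann.orfs:
        wt_cds = orf.spliced_cds(ann.sequence)
        l_orf = lifted.get(orf.id)
        if l_orf is None:
            continue  # dropped by deletions; logged at apply time
        syn_cds = l_orf.spliced_cds(designed.sequence)
        if wt_cds[-3:] == "TAG" and syn_cds[-3:] == "TAA":
            seq_swaps += 1
        if orf.classification in ("verified", "uncharacterized"):
            if len(syn_cds) % 3 or translate(syn_cds)[:-1] != translate(wt_cds)[:-1]:
                violations.append(
                    Violation("protein_integrity", orf.id, orf.start,
                              "designed CDS translation differs from wild type")
                )
    if seq_swaps != counts["stop_swaps"]:
        violations.append(
            Violation("stop_swap", "sequence_scan", 0,
                      f"sequence comparison finds {seq_swaps} TAG→TAA swaps, "
                      f"plan has {counts['stop_swaps']}")
        )

    # v2: no loxPsym motif may intersect a verified ORF's upstream window
    if policy.version == "v2":
        motif = policy.loxpsym_motif
        occ = []
        start = 0
        while True:
            i = designed.sequence.find(motif, start)
            if i < 0:
                break
            occ.append(i)
            start = i + 1
        for orf in designed.features_lifted.orfs_by_class("verified"):
            lo, hi = orf.upstream_window(policy.utr_exclusion_bp)
            lo = max(lo, 0)
            for i in occ:
                if i <= hi and i + len(motif) > lo:
                    violations.append(
                        Violation("utr_exclusion", orf.id, i,
                                  "loxPsym motif intrudes on the upstream "
                                  f"{policy.utr_exclusion_bp} bp window")
                    )
                    break

    from dataclasses import asdict

    policy_echo = {k: (sorted(v) if isinstance(v, frozenset) else
                       list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(policy).items()}
    return AuditReport(
        chromosome=ann.name,
        wild_length=len(ann.sequence),
        counts=counts,
        violations=violations,
        policy_echo=policy_echo,
    )


def diff_designs(report_v1: AuditReport, report_v2: AuditReport) -> pd.DataFrame:
    """Per-count delta table between two audits of the same wild type.

    Raises on different wild-type inputs and on any refinement count (loxPsym
    sites, stop swaps, tag windows) that grew from v1 to v2 — the redesign is
    a monotone refinement.
    """
    if (report_v1.chromosome != report_v2.chromosome
            or report_v1.wild_length != report_v2.wild_length):
        raise ValueError("audits are of different wild-type inputs")
    rows = []
    for k in COUNT_FIELDS:
        a, b = report_v1.counts.get(k, 0), report_v2.counts.get(k, 0)
        rows.append({"count": k, "v1": a, "v2": b, "delta": b - a})
        if k in MONOTONE_FIELDS and b > a:
            raise ValueError(
                f"monotonicity violated: {k} rose from {a} (v1) to {b} (v2)"
            )
    return pd.DataFrame(rows, columns=["count", "v1", "v2", "delta"])
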