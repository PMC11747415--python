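"""The refactoring rule set: edit planning and coordinate liftover.

The rules mirror the Sc2.0 chromosome-refactoring conventions:

* a 34-bp symmetric loxPsym site inserted 3 bp downstream of the stop codon
  of every eligible (non-essential) ORF;
* TAG stop codons swapped to TAA by a single third-position substitution;
* tandem repeats inside coding sequence broken by synonymous recoding
  confined to the repeat span;
* restriction-enzyme recognition sites inside coding sequence destroyed by
  minimal synonymous substitutions;
* tRNA genes, introns and LTR/Ty/subtelomeric repeats deleted.

Two policy versions are supported.  ``v1`` reproduces the original design
conventions.  ``v2`` incorporates the debugging lessons: loxPsym sites are
withheld from dubious ORFs and from the fixed exclusion window upstream of
verified start codons, and TAG→TAA swaps are reverted for dubious ORFs whose
stop codon sits inside another gene's CDS.
"""

from __future__ import annotations

import logging
import re
from bisect import bisect_right
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from ._codons import (
    STOP_CODONS,
    minimal_change_synonyms,
    ranked_synonyms,
    revcomp,
)
from .genome_model import ChromosomeAnnotation, OrfFeature, find_dubious_overlaps

logger = logging.getLogger(__name__)

#: Canonical 34-bp symmetric loxPsym site (13-bp arm, 8-bp palindromic
#: spacer, reverse-complement arm); equal to its own reverse complement.
LOXPSYM = "ATAACTTCGTATAATGTACATTATACGAAGTTAT"

RULE_IDS = (
    "loxpsym", "stop_swap", "rs_removal", "repeat_smash",
    "trna_del", "intron_del", "repeat_del", "tag_recode", "terminus_adjust",
)


class DesignError(ValueError):
    """Raised when a plan or policy violates its invariants."""


# ---------------------------------------------------------------------------
# Policy
# ---------------------------------------------------------------------------

@dataclass
class DesignPolicy:
    """Every numeric and boolean rule parameter, for both design versions."""

    version: str = "v2"
    loxpsym_motif: str = LOXPSYM
    loxpsym_offset_bp: int = 3
    utr_exclusion_bp: int = 250
    exclude_dubious_overlap_loxpsym: bool = True
    exclude_all_dubious_loxpsym: bool = True
    revert_dubious_stop_swap: bool = True
    tags_per_gene_per_chunk: int = 1
    tag_window_bp: tuple[int, int] = (28, 33)
    min_tag_mismatches: int = 8
    tag_primer_len: tuple[int, int] = (16, 33)
    tag_tm_band: tuple[float, float] = (58.0, 62.0)
    chunk_len_bp: tuple[int, int] = (6000, 10000)
    chunks_per_megachunk: tuple[int, int] = (4, 5)
    megachunk_overlap_bp: int = 450
    chunk_overlap_bp: int = 40
    boundary_shift_bp: int = 1500
    marker_cycle: tuple[str, ...] = ("URA3", "LEU2")
    terminus_blacklist_tags: frozenset[str] = frozenset(
        {"respiratory", "mito_maintenance", "thermotolerance", "osmotic"}
    )
    uniqueness_k: int = 40
    enzyme_set: tuple[str, ...] = ("GGTACC", "GAATTC")
    remove_intergenic_enzyme_sites: bool = False
    min_tandem_repeat: tuple[int, int] = (3, 3)  # (unit_len, copies)
    trna_flank_bp: int = 100
    random_seed: int = 0

    def __post_init__(self) -> None:
        self.loxpsym_motif = self.loxpsym_motif.upper()
        if revcomp(self.loxpsym_motif) != self.loxpsym_motif:
            raise DesignError("loxpsym_motif must equal its own reverse complement")
        if self.loxpsym_offset_bp < 0 or self.utr_exclusion_bp < 0:
            raise DesignError("offsets and windows must be non-negative")
        if self.chunk_len_bp[0] > self.chunk_len_bp[1]:
            raise DesignError("chunk_len_bp min must be <= max")
        self.marker_cycle = tuple(self.marker_cycle)
        self.enzyme_set = tuple(e.upper() for e in self.enzyme_set)
        self.terminus_blacklist_tags = frozenset(self.terminus_blacklist_tags)

    @classmethod
    def v1(cls, **overrides) -> "DesignPolicy":
        """Original design conventions (no dubious-ORF exceptions)."""
        base = dict(
            version="v1",
            exclude_dubious_overlap_loxpsym=False,
            exclude_all_dubious_loxpsym=False,
            revert_dubious_stop_swap=False,
            utr_exclusion_bp=250,  # still used for overlap reporting
            tags_per_gene_per_chunk=0,  # 0 = unlimited
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def v2(cls, **overrides) -> "DesignPolicy":
        """Refined conventions from the iterated redesign."""
        return cls(version="v2", **overrides)

    # YAML round trip -------------------------------------------------------

    def to_yaml(self, path: str | Path | None = None) -> str:
        data = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, frozenset):
                v = sorted(v)
            elif isinstance(v, tuple):
                v = list(v)
            data[f.name] = v
        text = yaml.safe_dump(data, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path_or_text: str | Path) -> "DesignPolicy":
        p = Path(path_or_text)
        text = p.read_text() if p.exists() else str(path_or_text)
        data = yaml.safe_load(text)
        tuple_fields = {
            "tag_window_bp", "tag_primer_len", "tag_tm_band", "chunk_len_bp",
            "chunks_per_megachunk", "min_tandem_repeat", "marker_cycle",
            "enzyme_set",
        }
        for k in tuple_fields & set(data):
            data[k] = tuple(data[k])
        if "terminus_blacklist_tags" in data:
            data["terminus_blacklist_tags"] = frozenset(data["terminus_blacklist_tags"])
        return cls(**data)


# ---------------------------------------------------------------------------
# Edits and plans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Edit:
    kind: str  # substitute | delete | insert
    wt_interval: tuple[int, int]
    replacement: str
    rule_id: str
    feature_id: str

    def __post_init__(self) -> None:
        s, e = self.wt_interval
        if self.kind == "insert":
            if s != e:
                raise DesignError(f"insert must have start==end, got {self.wt_interval}")
            if not self.replacement:
                raise DesignError("insert needs a replacement string")
        elif self.kind == "delete":
            if s >= e or self.replacement:
                raise DesignError("delete needs a non-empty interval and empty replacement")
        elif self.kind == "substitute":
            if s >= e or not self.replacement:
                raise DesignError("substitute needs interval and replacement")
        else:
            raise DesignError(f"unknown edit kind {self.kind!r}")
        if set(self.replacement) - set("ACGT"):
            raise DesignError(f"replacement must be over ACGT: {self.replacement!r}")
        if self.rule_id not in RULE_IDS:
            raise DesignError(f"unknown rule_id {self.rule_id!r}")

    @property
    def length_delta(self) -> int:
        s, e = self.wt_interval
        return len(self.replacement) - (e - s)


class EditPlan:
    """An ordered, non-overlapping list of edits in wild-type coordinates."""

    def __init__(self, edits: Iterable[Edit] = ()) -> None:
        self.edits: list[Edit] = sorted(edits, key=lambda e: e.wt_interval)
        self._validate()

    def _validate(self) -> None:
        prev: Edit | None = None
        for e in self.edits:
            if prev is not None:
                if e.wt_interval[0] < prev.wt_interval[1]:
                    raise DesignError(
                        f"overlapping edits: {prev} and {e}"
                    )
                if (
                    prev.kind == "insert"
                    and e.kind == "insert"
                    and prev.wt_interval == e.wt_interval
                ):
                    raise DesignError(
                        f"two insertions at the same point: {prev} and {e}"
                    )
            prev = e

    def __len__(self) -> int:
        return len(self.edits)

    def __iter__(self):
        return iter(self.edits)

    def __add__(self, other: "EditPlan") -> "EditPlan":
        return EditPlan(list(self.edits) + list(other.edits))

    def by_rule(self, rule_id: str) -> list[Edit]:
        return [e for e in self.edits if e.rule_id == rule_id]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "kind": e.kind,
                "wt_start": e.wt_interval[0],
                "wt_end": e.wt_interval[1],
                "replacement": e.replacement,
                "rule_id": e.rule_id,
                "feature_id": e.feature_id,
            }
            for e in self.edits
        ]
        return pd.DataFrame(
            rows, columns=["kind", "wt_start", "wt_end", "replacement",
                           "rule_id", "feature_id"]
        )

    def to_vcf_like(self, ann: ChromosomeAnnotation) -> pd.DataFrame:
        """VCF-style records (1-based POS, REF/ALT) against the wild type."""
        rows = []
        for e in self.edits:
            s, en = e.wt_interval
            if e.kind == "substitute":
                pos, ref, alt = s + 1, ann.sequence[s:en], e.replacement
            elif e.kind == "delete":
                anchor = ann.sequence[s - 1] if s else ""
                pos = s if s else 1
                ref, alt = anchor + ann.sequence[s:en], anchor or "."
            else:  # insert
                anchor = ann.sequence[s - 1] if s else ""
                pos = s if s else 1
                ref, alt = anchor or ".", anchor + e.replacement
            rows.append(
                {"CHROM": ann.name, "POS": pos, "ID": e.rule_id, "REF": ref,
                 "ALT": alt, "INFO": f"feature={e.feature_id}"}
            )
        return pd.DataFrame(rows, columns=["CHROM", "POS", "ID", "REF", "ALT", "INFO"])

    def total_insertion_bp(self) -> int:
        return sum(max(e.length_delta, 0) for e in self.edits)

    def total_deletion_bp(self) -> int:
        return sum(max(-e.length_delta, 0) for e in self.edits)


# ---------------------------------------------------------------------------
# Liftover
# ---------------------------------------------------------------------------

class Liftover:
    """Monotone coordinate map between wild-type and designed frames.

    Built from an :class:`EditPlan`; deleted wild-type positions map to
    ``None``, inserted designed positions map to ``None``.
    """

    def __init__(self, plan: EditPlan, wt_length: int) -> None:
        # segments: (wt_start, wt_end, designed_start, mapped) for stretches
        # where a base-to-base map exists (identity or equal-length
        # substitution); deletions recorded as unmapped wt stretches.
        self._segments: list[tuple[int, int, int | None]] = []
        self._wt_length = wt_length
        pos = 0
        dpos = 0
        for e in plan:
            s, en = e.wt_interval
            if s > pos:
                self._segments.append((pos, s, dpos))
                dpos += s - pos
            if e.kind == "substitute" and len(e.replacement) == en - s:
                self._segments.append((s, en, dpos))
                dpos += en - s
            elif e.kind == "insert":
                dpos += len(e.replacement)
            else:  # delete, or length-changing substitute
                if en > s:
                    self._segments.append((s, en, None))
                dpos += len(e.replacement)
            pos = en
        if pos < wt_length:
            self._segments.append((pos, wt_length, dpos))
            dpos += wt_length - pos
        self._designed_length = dpos
        self._starts = [seg[0] for seg in self._segments]

    @property
    def designed_length(self) -> int:
        return self._designed_length

    def wt_to_designed(self, pos: int) -> int | None:
        if not (0 <= pos < self._wt_length):
            raise IndexError(pos)
        i = bisect_right(self._starts, pos) - 1
        s, e, d = self._segments[i]
        if pos >= e or d is None:
            return None
        return d + (pos - s)

    def designed_to_wt(self, pos: int) -> int | None:
        if not (0 <= pos < self._designed_length):
            raise IndexError(pos)
        for s, e, d in self._segments:
            if d is None:
                continue
            if d <= pos < d + (e - s):
                return s + (pos - d)
        return None

    def lift_interval(self, interval: tuple[int, int]) -> tuple[int, int] | None:
        """Lift a wild-type interval, shrinking past deleted edges.

        Returns None when every base of the interval was deleted.
        """
        s, e = interval
        left = None
        for p in range(s, e):
            left = self.wt_to_designed(p)
            if left is not None:
                break
        if left is None:
            return None
        right = None
        for p in range(e - 1, s - 1, -1):
            right = self.wt_to_designed(p)
            if right is not None:
                break
        return (left, right + 1)


# ---------------------------------------------------------------------------
# Applying plans
# ---------------------------------------------------------------------------

@dataclass
class DesignedChromosome:
    sequence: str
    plan: EditPlan
    liftover: Liftover
    features_lifted: ChromosomeAnnotation
    wild_type: ChromosomeAnnotation
    dropped_features: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)


def apply_plan_to_sequence(sequence: str, plan: EditPlan) -> str:
    out: list[str] = []
    pos = 0
    for e in plan:
        s, en = e.wt_interval
        if en > len(sequence):
            raise DesignError(f"edit {e} beyond sequence end")
        out.append(sequence[pos:s])
        out.append(e.replacement)
        pos = en
    out.append(sequence[pos:])
    return "".join(out)


def apply_edits(ann: ChromosomeAnnotation, plan: EditPlan) -> DesignedChromosome:
    """Apply an edit plan, producing the designed sequence and liftover.

    Features are re-coordinated through the liftover; features whose every
    base falls inside deletions are dropped and logged.
    """
    designed_seq = apply_plan_to_sequence(ann.sequence, plan)
    lift = Liftover(plan, len(ann.sequence))
    assert lift.designed_length == len(designed_seq)

    dropped: list[str] = []
    orfs: list[OrfFeature] = []
    for orf in ann.orfs:
        exons = []
        for iv in orf.exons:
            lifted = lift.lift_interval(iv)
            if lifted is not None:
                exons.append(lifted)
        if not exons:
            dropped.append(orf.id)
            logger.info("feature %s dropped: fully inside deletions", orf.id)
            continue
        # adjacent lifted exons may have fused after intron removal
        merged: list[tuple[int, int]] = []
        for iv in exons:
            if merged and iv[0] <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], iv[1]))
            else:
                merged.append(iv)
        orfs.append(replace(orf, exons=tuple(merged)))

    def lift_simple(iv):
        return lift.lift_interval(iv)

    trnas = []
    for t in ann.trnas:
        lifted = lift_simple(t.interval)
        if lifted is None:
            dropped.append(t.id)
            logger.info("feature %s dropped: fully inside deletions", t.id)
        else:
            trnas.append(replace(t, interval=lifted))
    repeats = []
    for r in ann.repeats:
        lifted = lift_simple(r.interval)
        if lifted is None:
            dropped.append(f"repeat:{r.repeat_class}@{r.interval[0]}")
        else:
            repeats.append(replace(r, interval=lifted))
    centromere = lift_simple(ann.centromere) if ann.centromere else None
    telomeres = [iv for iv in (lift_simple(t) for t in ann.telomeres) if iv]
    others = []
    for o in ann.other_features:
        lifted = lift_simple(tuple(o["interval"]))
        if lifted is not None:
            others.append({**o, "interval": lifted})

    lifted_ann = ChromosomeAnnotation(
        name=f"{ann.name}_designed",
        sequence=designed_seq,
        orfs=orfs,
        trnas=trnas,
        repeats=repeats,
        centromere=centromere,
        telomeres=telomeres,
        other_features=others,
    )
    return DesignedChromosome(
        sequence=designed_seq,
        plan=plan,
        liftover=lift,
        features_lifted=lifted_ann,
        wild_type=ann,
        dropped_features=dropped,
    )


def invert_plan(plan: EditPlan, wt_sequence: str) -> EditPlan:
    """The inverse plan, in designed-frame coordinates.

    Applying the result to the designed sequence recovers the wild type
    bit-exactly.
    """
    inverted: list[Edit] = []
    offset = 0
    for e in plan:
        s, en = e.wt_interval
        ds = s + offset
        original = wt_sequence[s:en]
        if e.kind == "substitute":
            inverted.append(
                Edit("substitute", (ds, ds + len(e.replacement)), original,
                     e.rule_id, e.feature_id)
            )
        elif e.kind == "delete":
            inverted.append(Edit("insert", (ds, ds), original, e.rule_id, e.feature_id))
        else:  # insert
            inverted.append(
                Edit("delete", (ds, ds + len(e.replacement)), "", e.rule_id, e.feature_id)
            )
        offset += e.length_delta
    # adjacent wild-type deletions invert to insertions at the same designed
    # point; merge them (left-to-right order restores the original content)
    merged: list[Edit] = []
    for e in inverted:
        if (
            merged
            and e.kind == "insert"
            and merged[-1].kind == "insert"
            and merged[-1].wt_interval == e.wt_interval
        ):
            prev = merged.pop()
            e = Edit("insert", e.wt_interval, prev.replacement + e.replacement,
                     prev.rule_id, f"{prev.feature_id}+{e.feature_id}")
        merged.append(e)
    return EditPlan(merged)


# ---------------------------------------------------------------------------
# Rule: loxPsym placement
# ---------------------------------------------------------------------------

def place_loxpsym(ann: ChromosomeAnnotation, policy: DesignPolicy) -> EditPlan:
    """One loxPsym insertion 3' of the stop codon of every eligible ORF.

    Eligibility: non-essential, insertion point inside the chromosome and not
    inside another real (non-dubious) gene's CDS.  Under the v2 switches,
    dubious ORFs (all of them, and in particular those overlapping verified
    genes) are excluded, as is any insertion whose point falls within the
    exclusion window upstream of a verified start codon on either strand.
    Insertions colliding at the same point are merged into a single motif.
    """
    overlap_dubious: set[str] = set()
    if policy.exclude_dubious_overlap_loxpsym:
        overlap_dubious = {
            r.dubious_id for r in find_dubious_overlaps(ann, policy)
        }
    verified_windows = [
        (v.upstream_window(policy.utr_exclusion_bp), v.id)
        for v in ann.orfs_by_class("verified")
    ]
    real_genes = ann.orfs_by_class("verified", "uncharacterized")

    points: dict[int, list[str]] = {}
    for orf in ann.orfs:
        if orf.essential:
            continue
        if policy.exclude_all_dubious_loxpsym and orf.classification == "dubious":
            continue
        if (
            policy.exclude_dubious_overlap_loxpsym
            and orf.classification == "dubious"
            and orf.id in overlap_dubious
        ):
            continue
        p = orf.loxpsym_insertion_point(policy.loxpsym_offset_bp)
        if p < 0 or p > len(ann.sequence):
            logger.warning("loxPsym for %s beyond chromosome end; suppressed", orf.id)
            continue
        if any(g.contains(p) for g in real_genes if g.id != orf.id):
            logger.info("loxPsym for %s suppressed: point inside a gene CDS", orf.id)
            continue
        if policy.version == "v2":
            hit = next(
                ((lo, hi, vid) for (lo, hi), vid in verified_windows if lo <= p <= hi),
                None,
            )
            if hit is not None:
                logger.info(
                    "loxPsym for %s suppressed: within %d bp upstream of %s",
                    orf.id, policy.utr_exclusion_bp, hit[2],
                )
                continue
        points.setdefault(p, []).append(orf.id)

    edits = [
        Edit("insert", (p, p), policy.loxpsym_motif, "loxpsym", "+".join(ids))
        for p, ids in sorted(points.items())
    ]
    return EditPlan(edits)


# ---------------------------------------------------------------------------
# Rule: stop-codon swaps
# ---------------------------------------------------------------------------

def swap_stop_codons(ann: ChromosomeAnnotation, policy: DesignPolicy) -> EditPlan:
    """TAG→TAA third-position substitution for every ORF ending in TAG.

    Under ``revert_dubious_stop_swap`` (v2), dubious ORFs whose stop codon
    lies inside a verified gene's CDS keep their TAG stop.
    """
    verified = ann.orfs_by_class("verified")
    edits: list[Edit] = []
    for orf in ann.orfs:
        cds = orf.spliced_cds(ann.sequence)
        stop = cds[-3:]
        if stop not in STOP_CODONS:
            logger.warning("%s does not end in a stop codon; no edit", orf.id)
            continue
        if stop != "TAG":
            continue
        if policy.revert_dubious_stop_swap and orf.classification == "dubious":
            s, e = orf.stop_codon_interval()
            if any(
                v.contains(pos)
                for v in verified
                if v.id != orf.id
                for pos in range(s, e)
            ):
                continue
        if orf.strand == "+":
            g = orf.end - 1  # third stop base, genomic G
            edits.append(Edit("substitute", (g, g + 1), "A", "stop_swap", orf.id))
        else:
            g = orf.start  # third stop base on -, genomic C
            edits.append(Edit("substitute", (g, g + 1), "T", "stop_swap", orf.id))
    return EditPlan(edits)


# ---------------------------------------------------------------------------
# Rule: tandem-repeat smashing
# ---------------------------------------------------------------------------

def find_tandem_repeats(
    seq: str, min_unit: int = 3, min_copies: int = 3, max_unit: int = 12
) -> list[tuple[int, int, int]]:
    """Exact tandem repeats as (start, end, unit_len), primitive period only.

    A run qualifies when its smallest period is at least ``min_unit`` and it
    spans at least ``min_copies`` full units.  Homopolymers and dinucleotide
    runs therefore never qualify under the defaults.
    """
    hits: list[tuple[int, int, int]] = []
    n = len(seq)
    covered: set[int] = set()
    for u in range(min_unit, max_unit + 1):
        i = 0
        while i + u * min_copies <= n:
            if i in covered:
                i += 1
                continue
            j = i
            while j + u < n and seq[j + u] == seq[j]:
                j += 1
            run_len = (j + u) - i  # maximal stretch with period u
            if run_len >= u * min_copies:
                unit = seq[i : i + u]
                # primitive period check: unit must not itself be periodic
                primitive = all(
                    any(unit[k] != unit[k % d] for k in range(u))
                    for d in range(1, u)
                    if u % d == 0
                )
                if primitive:
                    span_end = i + (run_len // u) * u
                    hits.append((i, span_end, u))
                    covered.update(range(i, span_end))
                    i = span_end
                    continue
            i += 1
    hits.sort()
    return hits


def smash_repeats(ann: ChromosomeAnnotation, policy: DesignPolicy) -> EditPlan:
    """Break exact tandem repeats inside CDS by synonymous recoding.

    Edits are confined to the repeat span itself: in every second repeat
    unit, codons whose synonymous replacement changes only bases inside the
    span are recoded to the maximal-difference alternative.  The protein is
    unchanged, and no position outside the detected span is touched.
    """
    min_unit, min_copies = policy.min_tandem_repeat
    edits: list[Edit] = []
    for orf in ann.orfs_by_class("verified", "uncharacterized"):
        cds = orf.spliced_cds(ann.sequence)
        for start, end, unit in find_tandem_repeats(cds, min_unit, min_copies):
            c_first = -(-start // 3)  # first codon fully inside span
            c_last = end // 3  # exclusive
            changed_any = False
            for ci in range(c_first, c_last):
                unit_index = (ci * 3 - start) // unit
                if unit_index % 2 == 0:
                    continue  # leave every other unit untouched
                codon = cds[ci * 3 : ci * 3 + 3]
                for alt in ranked_synonyms(codon):
                    diff = [k for k in range(3) if alt[k] != codon[k]]
                    if all(start <= ci * 3 + k < end for k in diff):
                        for k in diff:
                            g = orf.cds_to_genomic(ci * 3 + k)
                            base = alt[k] if orf.strand == "+" else revcomp(alt[k])
                            edits.append(
                                Edit("substitute", (g, g + 1), base,
                                     "repeat_smash", orf.id)
                            )
                        changed_any = True
                        break
            if not changed_any:
                logger.warning(
                    "tandem repeat at %s[%d:%d]: no synonymous alternative; "
                    "left unmodified", orf.id, start, end,
                )
    return EditPlan(edits)


# ---------------------------------------------------------------------------
# Rule: restriction-site removal
# ---------------------------------------------------------------------------

def _motif_occurrences(seq: str, motif: str) -> list[tuple[int, int]]:
    """Occurrences of motif or its reverse complement, as intervals."""
    out = []
    pats = {motif}
    rc = revcomp(motif)
    pats.add(rc)
    for pat in sorted(pats):
        for m in re.finditer(f"(?={re.escape(pat)})", seq):
            out.append((m.start(), m.start() + len(motif)))
    return sorted(set(out))


def _region_clean(seq: str, lo: int, hi: int, motifs: Sequence[str]) -> bool:
    window = seq[max(lo, 0) : hi]
    return not any(
        m in window or revcomp(m) in window for m in motifs
    )


def recode_restriction_sites(
    ann: ChromosomeAnnotation, policy: DesignPolicy
) -> tuple[EditPlan, list[tuple[str, int]]]:
    """Destroy enzyme recognition sites inside real-gene CDS.

    Each occurrence (either strand) overlapping a verified/uncharacterized
    CDS is destroyed by the minimal number of synonymous substitutions.
    Occurrences spanning a CDS/intergenic boundary are recoded on the CDS
    side when sufficient, otherwise one intergenic base is substituted.
    Purely intergenic occurrences are left alone unless
    ``remove_intergenic_enzyme_sites`` is set.  Returns the plan plus a list
    of (motif, position) sites that could not be removed synonymously.
    """
    if not policy.enzyme_set:
        return EditPlan(), []
    seq = ann.sequence
    real_genes = ann.orfs_by_class("verified", "uncharacterized")
    edits: list[Edit] = []
    edited_positions: set[int] = set()
    failures: list[tuple[str, int]] = []

    for motif in policy.enzyme_set:
        for s, e in _motif_occurrences(seq, motif):
            covering = [
                (orf, [p for p in range(s, e) if orf.contains(p)])
                for orf in real_genes
                if any(orf.contains(p) for p in range(s, e))
            ]
            if not covering:
                if policy.remove_intergenic_enzyme_sites:
                    sub = _intergenic_kill(seq, s, e, motif, policy.enzyme_set)
                    if sub is not None:
                        pos, base = sub
                        if pos not in edited_positions:
                            edits.append(
                                Edit("substitute", (pos, pos + 1), base,
                                     "rs_removal", f"{motif}@{s}")
                            )
                            edited_positions.add(pos)
                continue
            success = _synonymous_kill(
                seq, s, e, motif, policy.enzyme_set, covering,
                edits, edited_positions, site_label=f"{motif}@{s}",
            )
            if not success:
                # try an intergenic base if the site pokes out of the CDS
                intergenic = [
                    p for p in range(s, e)
                    if not any(orf.contains(p) for orf, _ in covering)
                ]
                fixed = False
                for p in intergenic:
                    for base in "ACGT":
                        if base == seq[p]:
                            continue
                        trial = seq[:p] + base + seq[p + 1 :]
                        if _region_clean(trial, s - len(motif), e + len(motif),
                                         policy.enzyme_set) and p not in edited_positions:
                            edits.append(
                                Edit("substitute", (p, p + 1), base,
                                     "rs_removal", f"{motif}@{s}")
                            )
                            edited_positions.add(p)
                            fixed = True
                            break
                    if fixed:
                        break
                if not fixed:
                    failures.append((motif, s))
                    logger.warning(
                        "restriction site %s at %d not synonymously removable",
                        motif, s,
                    )
    return EditPlan(edits), failures


def _synonymous_kill(seq, s, e, motif, enzyme_set, covering, edits,
                     edited_positions, site_label):
    candidates: list[tuple[int, float, str, int, str, str]] = []
    for orf, _positions in covering:
        cds = orf.spliced_cds(seq)
        cds_len = len(cds)
        cds_indices = sorted(
            {_genomic_to_cds(orf, p) for p in range(s, e) if orf.contains(p)}
        )
        codon_ids = sorted({i // 3 for i in cds_indices if i is not None})
        for ci in codon_ids:
            if ci >= cds_len // 3 - 1:
                continue  # never touch the stop codon
            codon = cds[ci * 3 : ci * 3 + 3]
            for alt in minimal_change_synonyms(codon):
                from ._codons import YEAST_USAGE, hamming
                candidates.append(
                    (hamming(alt, codon), -YEAST_USAGE[alt], alt, ci, codon, orf.id)
                )
    candidates.sort(key=lambda t: (t[0], t[1], t[2], t[3]))
    for _h, _u, alt, ci, codon, orf_id in candidates:
        orf = next(o for o, _ in covering if o.id == orf_id)
        gpos = {}
        for k in range(3):
            if alt[k] != codon[k]:
                g = orf.cds_to_genomic(ci * 3 + k)
                gpos[g] = alt[k] if orf.strand == "+" else revcomp(alt[k])
        if any(p in edited_positions for p in gpos):
            continue
        trial = seq
        for p, b in gpos.items():
            trial = trial[:p] + b + trial[p + 1 :]
        if _region_clean(trial, s - len(motif), e + len(motif), enzyme_set):
            for p, b in sorted(gpos.items()):
                edits.append(
                    Edit("substitute", (p, p + 1), b, "rs_removal",
                         f"{orf_id}|{site_label}")
                )
                edited_positions.add(p)
            return True
    return False


def _intergenic_kill(seq, s, e, motif, enzyme_set):
    p = s
    order = {"A": "G", "G": "A", "C": "T", "T": "C"}
    for p in range(s, e):
        base = order[seq[p]]
        trial = seq[:p] + base + seq[p + 1 :]
        if _region_clean(trial, s - len(motif), e + len(motif), enzyme_set):
            return p, base
    return None


def _genomic_to_cds(orf: OrfFeature, pos: int) -> int | None:
    off = 0
    if orf.strand == "+":
        for s, e in orf.exons:
            if s <= pos < e:
                return off + (pos - s)
            off += e - s
    else:
        for s, e in reversed(orf.exons):
            if s <= pos < e:
                return off + (e - 1 - pos)
            off += e - s
    return None


# ---------------------------------------------------------------------------
# Rule: element deletion
# ---------------------------------------------------------------------------

def delete_elements(ann: ChromosomeAnnotation, policy: DesignPolicy) -> EditPlan:
    """Deletion edits for tRNA genes, introns and LTR/Ty/subtelomeric repeats."""
    edits: list[Edit] = []
    for t in ann.trnas:
        edits.append(Edit("delete", t.interval, "", "trna_del", t.id))
    for orf in ann.orfs:
        if len(orf.exons) < 2:
            continue
        if orf.cds_length() % 3:
            raise DesignError(
                f"intron removal would break frame of {orf.id}"
            )
        for (s1, e1), (s2, e2) in zip(orf.exons, orf.exons[1:]):
            edits.append(Edit("delete", (e1, s2), "", "intron_del", orf.id))
    for r in ann.repeats:
        if r.repeat_class in ("LTR", "Ty", "subtelomeric"):
            edits.append(
                Edit("delete", r.interval, "", "repeat_del",
                     f"{r.repeat_class}@{r.interval[0]}")
            )
    return EditPlan(edits)


def trna_array_records(ann: ChromosomeAnnotation, flank_bp: int = 100):
    """FASTA records of removed tRNAs with flanking context.

    Mirrors the complementation construct carrying every tRNA species from
    the wild-type chromosome on a centromeric plasmid.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = []
    for t in ann.trnas:
        s, e = t.interval
        lo, hi = max(0, s - flank_bp), min(len(ann.sequence), e + flank_bp)
        seq = ann.sequence[lo:hi]
        if t.strand == "-":
            seq = revcomp(seq)
        records.append(SeqRecord(Seq(seq), id=t.id, description=f"{lo}-{hi}"))
    return records


# ---------------------------------------------------------------------------
# Composite planning
# ---------------------------------------------------------------------------

def build_base_plan(ann: ChromosomeAnnotation, policy: DesignPolicy) -> EditPlan:
    """All sequence rules except PCR tags, combined into one plan."""
    plan = (
        delete_elements(ann, policy)
        + place_loxpsym(ann, policy)
        + swap_stop_codons(ann, policy)
        + smash_repeats(ann, policy)
    )
    rs_plan, _failures = recode_restriction_sites(ann, policy)
    return plan + rs_plan
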