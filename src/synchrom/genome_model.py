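"""Annotated-chromosome data model, readers/writers, and overlap analysis.

Internal coordinates are 0-based half-open on the forward strand throughout
the package; GenBank/GFF3 I/O converts from/to the 1-based inclusive file
convention.  An :class:`OrfFeature` carries the curation status used by the
design rules: *verified* and *uncharacterized* ORFs are treated as real genes
whose protein product must be preserved, *dubious* ORFs are annotation
artefacts that may overlap real genes and receive special handling in the
version-2 design policy.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence, TYPE_CHECKING

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from ._codons import STOP_CODONS, revcomp, translate

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .design_rules import DesignedChromosome, DesignPolicy
    from .segmenter import Segmentation

CLASSIFICATIONS = ("verified", "uncharacterized", "dubious")
CONDITIONAL_TAGS = ("respiratory", "mito_maintenance", "thermotolerance", "osmotic")
REPEAT_CLASSES = ("LTR", "Ty", "subtelomeric", "tandem_in_cds")


class AnnotationError(ValueError):
    """Raised for malformed annotations (bad coordinates, frame errors...)."""


@dataclass(frozen=True)
class OrfFeature:
    """A (possibly spliced) protein-coding gene on the chromosome."""

    id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    classification: str = "uncharacterized"
    essential: bool = False
    conditional_tags: frozenset[str] = frozenset()
    display_name: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"{self.id}: strand must be '+' or '-'")
        if self.classification not in CLASSIFICATIONS:
            raise AnnotationError(f"{self.id}: bad classification {self.classification!r}")
        exons = tuple(tuple(e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        object.__setattr__(self, "conditional_tags", frozenset(self.conditional_tags))
        last = -1
        for s, e in exons:
            if not (0 <= s < e):
                raise AnnotationError(f"{self.id}: bad exon interval ({s},{e})")
            if s < last:
                raise AnnotationError(f"{self.id}: exons overlap or are unsorted")
            last = e
        if self.classification == "dubious" and self.essential:
            raise AnnotationError(f"{self.id}: dubious ORFs cannot be essential")

    # -- geometry -----------------------------------------------------------

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def spliced_cds(self, sequence: str) -> str:
        cds = "".join(sequence[s:e] for s, e in self.exons)
        return revcomp(cds) if self.strand == "-" else cds

    def protein(self, sequence: str) -> str:
        return translate(self.spliced_cds(sequence))

    def stop_codon_interval(self) -> tuple[int, int]:
        """Genomic interval of the stop codon (assumed intron-free)."""
        if self.strand == "+":
            return (self.end - 3, self.end)
        return (self.start, self.start + 3)

    def loxpsym_insertion_point(self, offset_bp: int) -> int:
        """Insertion point ``offset_bp`` downstream of the stop, gene-3' side."""
        if self.strand == "+":
            return self.end + offset_bp
        return self.start - offset_bp

    def upstream_window(self, window_bp: int) -> tuple[int, int]:
        """The fixed window upstream of the start codon (a 5'-UTR surrogate)."""
        if self.strand == "+":
            return (self.start - window_bp, self.start)
        return (self.end, self.end + window_bp)

    def cds_to_genomic(self, i: int) -> int:
        """Map a spliced-CDS index to its genomic position (strand-aware)."""
        if i < 0 or i >= self.cds_length():
            raise IndexError(i)
        if self.strand == "+":
            for s, e in self.exons:
                if i < e - s:
                    return s + i
                i -= e - s
        else:
            for s, e in reversed(self.exons):
                if i < e - s:
                    return e - 1 - i
                i -= e - s
        raise AssertionError("unreachable")

    def contains(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.exons)

    def validate_against(self, sequence: str) -> None:
        if self.end > len(sequence):
            raise AnnotationError(f"{self.id}: exceeds chromosome bounds")
        if self.cds_length() % 3:
            raise AnnotationError(f"{self.id}: CDS length not divisible by 3")
        cds = self.spliced_cds(sequence)
        if cds[-3:] not in STOP_CODONS:
            raise AnnotationError(f"{self.id}: CDS does not end in a stop codon")


@dataclass(frozen=True)
class TrnaGene:
    id: str
    strand: str
    interval: tuple[int, int]


@dataclass(frozen=True)
class RepeatFeature:
    repeat_class: str
    interval: tuple[int, int]

    def __post_init__(self) -> None:
        if self.repeat_class not in REPEAT_CLASSES:
            raise AnnotationError(f"bad repeat class {self.repeat_class!r}")


@dataclass
class ChromosomeAnnotation:
    """Wild-type sequence plus typed features."""

    name: str
    sequence: str
    orfs: list[OrfFeature] = field(default_factory=list)
    trnas: list[TrnaGene] = field(default_factory=list)
    repeats: list[RepeatFeature] = field(default_factory=list)
    centromere: tuple[int, int] | None = None
    telomeres: list[tuple[int, int]] = field(default_factory=list)
    other_features: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise AnnotationError("empty sequence")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise AnnotationError(f"non-nucleotide characters: {sorted(bad)}")
        n = len(self.sequence)
        for orf in self.orfs:
            if orf.end > n:
                raise AnnotationError(f"{orf.id}: beyond chromosome end")
        for t in self.trnas:
            if not (0 <= t.interval[0] < t.interval[1] <= n):
                raise AnnotationError(f"{t.id}: bad tRNA interval")
        for r in self.repeats:
            if not (0 <= r.interval[0] < r.interval[1] <= n):
                raise AnnotationError(f"bad repeat interval {r.interval}")

    def __len__(self) -> int:
        return len(self.sequence)

    def orfs_by_class(self, *classifications: str) -> list[OrfFeature]:
        return [o for o in self.orfs if o.classification in classifications]

    def get_orf(self, orf_id: str) -> OrfFeature:
        for o in self.orfs:
            if o.id == orf_id:
                return o
        raise KeyError(orf_id)

    def validate(self) -> None:
        for orf in self.orfs:
            orf.validate_against(self.sequence)


@dataclass(frozen=True)
class OverlapRecord:
    """A (dubious, verified) gene pair that overlaps or sits in proximity."""

    dubious_id: str
    verified_id: str
    geometry: str  # same_strand_nested | same_strand_partial | antisense
    loxpsym_in_verified_5utr: bool
    stop_swap_hits_verified_cds: bool


# ---------------------------------------------------------------------------
# Classification table
# ---------------------------------------------------------------------------

def read_classification_table(path: str | Path) -> pd.DataFrame:
    """Read the ORF classification TSV.

    Columns: orf_id, classification, essential, conditional_tags (comma
    separated, may be empty), display_name.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"orf_id", "classification"}
    missing = required - set(df.columns)
    if missing:
        raise AnnotationError(f"classification table missing columns: {sorted(missing)}")
    return df


def _classification_lookup(table: pd.DataFrame | str | Path | None) -> dict[str, dict]:
    if table is None:
        return {}
    if not isinstance(table, pd.DataFrame):
        table = read_classification_table(table)
    out: dict[str, dict] = {}
    for row in table.itertuples(index=False):
        tags = getattr(row, "conditional_tags", "") or ""
        tagset = frozenset(t.strip() for t in str(tags).split(",") if t.strip())
        essential = str(getattr(row, "essential", "")).strip().lower() in ("1", "true", "yes")
        out[row.orf_id] = {
            "classification": row.classification,
            "essential": essential,
            "conditional_tags": tagset,
            "display_name": str(getattr(row, "display_name", "") or ""),
        }
    return out


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_annotation(
    path: str | Path,
    classification_table: pd.DataFrame | str | Path | None = None,
    fasta: str | Path | None = None,
) -> ChromosomeAnnotation:
    """Read a GenBank file (or GFF3 plus FASTA) into a ChromosomeAnnotation.

    ORFs not present in the classification table default to uncharacterized,
    non-essential, untagged (with a warning).
    """
    path = Path(path)
    lookup = _classification_lookup(classification_table)
    if path.suffix.lower() in (".gff", ".gff3"):
        if fasta is None:
            raise AnnotationError("GFF3 input requires a FASTA sequence file")
        ann = _read_gff3(path, fasta)
    else:
        ann = _read_genbank(path)
    ann.orfs = [_apply_classification(o, lookup) for o in ann.orfs]
    ann.validate()
    return ann


def _apply_classification(orf: OrfFeature, lookup: dict[str, dict]) -> OrfFeature:
    if orf.id not in lookup:
        if lookup:
            warnings.warn(
                f"ORF {orf.id} missing from classification table; "
                "defaulting to uncharacterized/non-essential",
                stacklevel=3,
            )
        return orf
    info = lookup[orf.id]
    return replace(
        orf,
        classification=info["classification"],
        essential=info["essential"],
        conditional_tags=info["conditional_tags"],
        display_name=info["display_name"],
    )


def _read_genbank(path: Path) -> ChromosomeAnnotation:
    record = SeqIO.read(str(path), "genbank")
    sequence = str(record.seq).upper()
    orfs: list[OrfFeature] = []
    trnas: list[TrnaGene] = []
    repeats: list[RepeatFeature] = []
    centromere = None
    telomeres: list[tuple[int, int]] = []
    others: list[dict] = []
    for feat in record.features:
        if feat.type == "source":
            continue
        try:
            parts = sorted(
                (int(p.start), int(p.end)) for p in feat.location.parts
            )
            strand = "-" if feat.location.strand == -1 else "+"
        except Exception as exc:  # pragma: no cover - biopython guards most
            raise AnnotationError(f"malformed coordinates in feature {feat}") from exc
        ident = (
            feat.qualifiers.get("locus_tag", [None])[0]
            or feat.qualifiers.get("gene", [None])[0]
            or f"{feat.type}_{parts[0][0]}"
        )
        if feat.type == "CDS":
            orfs.append(OrfFeature(id=ident, strand=strand, exons=tuple(parts)))
        elif feat.type == "tRNA":
            trnas.append(TrnaGene(id=ident, strand=strand, interval=parts[0]))
        elif feat.type == "repeat_region":
            cls = feat.qualifiers.get("rpt_family", ["LTR"])[0]
            repeats.append(RepeatFeature(repeat_class=cls, interval=parts[0]))
        elif feat.type == "centromere":
            centromere = parts[0]
        elif feat.type == "telomere":
            telomeres.append(parts[0])
        else:
            others.append(
                {"type": feat.type, "interval": parts[0], "strand": strand, "id": ident}
            )
    return ChromosomeAnnotation(
        name=record.id or path.stem,
        sequence=sequence,
        orfs=orfs,
        trnas=trnas,
        repeats=repeats,
        centromere=centromere,
        telomeres=telomeres,
        other_features=others,
    )


def _read_gff3(path: Path, fasta: str | Path) -> ChromosomeAnnotation:
    seq_record = SeqIO.read(str(fasta), "fasta")
    sequence = str(seq_record.seq).upper()
    cds_parts: dict[str, dict] = {}
    trnas: list[TrnaGene] = []
    repeats: list[RepeatFeature] = []
    centromere = None
    telomeres: list[tuple[int, int]] = []
    others: list[dict] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise AnnotationError(f"malformed GFF3 line: {line[:80]}")
            _, _, ftype, start_s, end_s, _, strand, _, attrs_s = cols
            try:
                start, end = int(start_s) - 1, int(end_s)  # to 0-based half-open
            except ValueError as exc:
                raise AnnotationError(f"bad coordinates in GFF3 line: {line[:80]}") from exc
            if not (0 <= start < end <= len(sequence)):
                raise AnnotationError(f"feature out of bounds: {line[:80]}")
            attrs = dict(
                kv.split("=", 1) for kv in attrs_s.split(";") if "=" in kv
            )
            ident = attrs.get("ID") or attrs.get("Parent") or f"{ftype}_{start}"
            if ftype == "CDS":
                key = attrs.get("Parent") or ident
                entry = cds_parts.setdefault(key, {"strand": strand, "exons": []})
                entry["exons"].append((start, end))
            elif ftype == "tRNA":
                trnas.append(TrnaGene(id=ident, strand=strand, interval=(start, end)))
            elif ftype == "repeat_region":
                cls = attrs.get("rpt_family", "LTR")
                repeats.append(RepeatFeature(repeat_class=cls, interval=(start, end)))
            elif ftype == "centromere":
                centromere = (start, end)
            elif ftype == "telomere":
                telomeres.append((start, end))
            elif ftype in ("gene", "mRNA", "region", "chromosome"):
                continue
            else:
                others.append(
                    {"type": ftype, "interval": (start, end), "strand": strand, "id": ident}
                )
    orfs = [
        OrfFeature(id=key, strand=entry["strand"], exons=tuple(sorted(entry["exons"])))
        for key, entry in cds_parts.items()
    ]
    orfs.sort(key=lambda o: o.start)
    return ChromosomeAnnotation(
        name=seq_record.id,
        sequence=sequence,
        orfs=orfs,
        trnas=trnas,
        repeats=repeats,
        centromere=centromere,
        telomeres=telomeres,
        other_features=others,
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def annotation_to_seqrecord(ann: ChromosomeAnnotation) -> SeqRecord:
    record = SeqRecord(Seq(ann.sequence), id=ann.name, name=ann.name[:16],
                       description="")
    record.annotations["molecule_type"] = "DNA"
    for orf in ann.orfs:
        strand = -1 if orf.strand == "-" else 1
        locs = [SimpleLocation(s, e, strand) for s, e in orf.exons]
        location = locs[0] if len(locs) == 1 else CompoundLocation(
            locs if strand == 1 else locs[::-1]
        )
        record.features.append(
            SeqFeature(location, type="CDS", qualifiers={"locus_tag": [orf.id]})
        )
    for t in ann.trnas:
        strand = -1 if t.strand == "-" else 1
        record.features.append(
            SeqFeature(SimpleLocation(*t.interval, strand), type="tRNA",
                       qualifiers={"locus_tag": [t.id]})
        )
    for r in ann.repeats:
        record.features.append(
            SeqFeature(SimpleLocation(*r.interval, 1), type="repeat_region",
                       qualifiers={"rpt_family": [r.repeat_class]})
        )
    if ann.centromere:
        record.features.append(
            SeqFeature(SimpleLocation(*ann.centromere, 1), type="centromere")
        )
    for tel in ann.telomeres:
        record.features.append(SeqFeature(SimpleLocation(*tel, 1), type="telomere"))
    for other in ann.other_features:
        strand = -1 if other.get("strand") == "-" else 1
        record.features.append(
            SeqFeature(SimpleLocation(*other["interval"], strand),
                       type=other["type"],
                       qualifiers={"locus_tag": [other.get("id", "")]})
        )
    record.features.sort(key=lambda f: int(f.location.start))
    return record


def write_genbank(ann: ChromosomeAnnotation, path: str | Path) -> None:
    SeqIO.write([annotation_to_seqrecord(ann)], str(path), "genbank")


def write_fasta(name: str, sequence: str, path: str | Path) -> None:
    record = SeqRecord(Seq(sequence), id=name, description="")
    SeqIO.write([record], str(path), "fasta")


def write_classification_table(ann: ChromosomeAnnotation, path: str | Path) -> None:
    rows = [
        {
            "orf_id": o.id,
            "classification": o.classification,
            "essential": str(o.essential),
            "conditional_tags": ",".join(sorted(o.conditional_tags)),
            "display_name": o.display_name,
        }
        for o in ann.orfs
    ]
    pd.DataFrame(rows, columns=["orf_id", "classification", "essential",
                                "conditional_tags", "display_name"]).to_csv(
        path, sep="\t", index=False
    )


def write_design(
    designed: "DesignedChromosome",
    segmentation: "Segmentation | None",
    outdir: str | Path,
    tags: Sequence | None = None,
    audit_report=None,
) -> dict[str, Path]:
    """Write the designed chromosome artefacts to ``outdir``.

    Emits designed GenBank + FASTA, per-chunk FASTA files, a tag TSV and an
    audit JSON (when provided).  Output is deterministic for fixed input.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    ann = designed.features_lifted
    gb = outdir / f"{ann.name}.gb"
    write_genbank(ann, gb)
    written["genbank"] = gb
    fa = outdir / f"{ann.name}.fasta"
    write_fasta(ann.name, designed.sequence, fa)
    written["fasta"] = fa

    if segmentation is not None:
        chunk_dir = outdir / "chunks"
        chunk_dir.mkdir(exist_ok=True)
        records = []
        for chunk in segmentation.chunks:
            s, e = chunk.interval
            records.append(
                SeqRecord(Seq(designed.sequence[s:e]), id=chunk.id, description="")
            )
        chunks_fa = chunk_dir / "chunks.fasta"
        SeqIO.write(records, str(chunks_fa), "fasta")
        for rec in records:
            SeqIO.write([rec], str(chunk_dir / f"{rec.id}.fasta"), "fasta")
        written["chunks"] = chunks_fa
        seg_json = outdir / "segmentation.json"
        seg_json.write_text(segmentation.to_json())
        written["segmentation"] = seg_json

    if tags is not None:
        from .pcr_tags import tag_report

        tags_tsv = outdir / "pcr_tags.tsv"
        tag_report(tags).to_csv(tags_tsv, sep="\t", index=False)
        written["tags"] = tags_tsv

    if audit_report is not None:
        audit_json = outdir / "audit.json"
        audit_json.write_text(json.dumps(audit_report.to_dict(), indent=2, sort_keys=True))
        written["audit"] = audit_json

    plan_tsv = outdir / "edit_plan.tsv"
    designed.plan.to_frame().to_csv(plan_tsv, sep="\t", index=False)
    written["plan"] = plan_tsv
    return written


# ---------------------------------------------------------------------------
# Overlap analysis
# ---------------------------------------------------------------------------

def _intervals_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    if _intervals_overlap(a, b):
        return 0
    return max(a[0], b[0]) - min(a[1], b[1])


def find_dubious_overlaps(ann: ChromosomeAnnotation, policy: "DesignPolicy") -> list[OverlapRecord]:
    """Report every (dubious, verified) pair that overlaps or sits proximal.

    Proximal means the gap between the two gene spans is at most
    ``policy.utr_exclusion_bp``.  For each pair the record notes whether the
    dubious ORF's prospective loxPsym insertion point falls inside the
    verified gene's upstream exclusion window, and whether the dubious stop
    codon lies inside the verified CDS.
    """
    records: list[OverlapRecord] = []
    verified = ann.orfs_by_class("verified")
    for dub in ann.orfs_by_class("dubious"):
        p = dub.loxpsym_insertion_point(policy.loxpsym_offset_bp)
        stop_iv = dub.stop_codon_interval()
        for ver in verified:
            if _gap(dub.span, ver.span) > policy.utr_exclusion_bp:
                continue
            if dub.strand == ver.strand:
                nested = (
                    ver.start <= dub.start and dub.end <= ver.end
                ) or (dub.start <= ver.start and ver.end <= dub.end)
                geometry = "same_strand_nested" if nested else "same_strand_partial"
            else:
                geometry = "antisense"
            lo, hi = ver.upstream_window(policy.utr_exclusion_bp)
            in_utr = lo <= p <= hi
            stop_in_cds = any(
                ver.contains(pos) for pos in range(stop_iv[0], stop_iv[1])
            )
            records.append(
                OverlapRecord(
                    dubious_id=dub.id,
                    verified_id=ver.id,
                    geometry=geometry,
                    loxpsym_in_verified_5utr=in_utr,
                    stop_swap_hits_verified_cds=stop_in_cds,
                )
            )
    return records
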