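"""Deterministic mini-chromosome generator with recorded ground truth.

Every design rule in the package is exercised on generated fixtures whose
expected rule firings are known by construction: mixed-strand ORFs of all
three curation classes, dubious ORFs overlapping verified genes in the two
geometries that caused real debugging campaigns (a dubious ORF whose 3' end
pokes into a verified gene's upstream region, and a dubious ORF nested
antisense inside a verified CDS with its stop codon in the host's coding
sequence), essential and conditionally essential genes, tRNA genes, introns,
LTR repeats, a tandem-repeat-bearing CDS, TAG stop codons and planted
restriction sites.

After assembly the sequence is scrubbed so that no rule fires by accident:
chance occurrences of enzyme motifs or coding tandem repeats outside the
planted ones are mutated away (inside CDS, by swapping a codon for another
non-stop codon — the fixture is wild type, so there is no protein to
preserve).  Ground truth is then exact, not approximate.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field, asdict

from ._codons import GENETIC_CODE, STOP_CODONS, revcomp
from .design_rules import find_tandem_repeats
from .genome_model import (
    ChromosomeAnnotation,
    OrfFeature,
    RepeatFeature,
    TrnaGene,
)

NONSTOP_CODONS = tuple(sorted(c for c in GENETIC_CODE if GENETIC_CODE[c] != "*"))

REPEAT_UNIT = "CAATCTGCT"  # Gln-Ser-Ala: every codon has synonymous room
REPEAT_COPIES = 5


class FixtureError(ValueError):
    """Raised when a fixture spec cannot be realized."""


@dataclass
class FixtureSpec:
    seed: int = 0
    length_bp: int = 60_000
    n_verified: int = 12
    n_uncharacterized: int = 4
    n_dubious: int = 3  # free-standing dubious ORFs
    n_dubious_overlapping_verified: int = 2  # antisense 5'-proximal geometry
    n_dubious_stop_in_verified: int = 1  # nested antisense, TAG stop in host CDS
    n_essential: int = 2
    blacklist_tags: dict = field(default_factory=dict)  # tag -> count
    n_trna: int = 3
    n_intron: int = 2
    n_ltr_repeat: int = 2
    n_tag_stop_codons: int = 4  # TAG stops among free-standing ORFs
    tandem_repeat_cds: bool = True
    n_enzyme_sites: int = 2
    enzyme_motifs: tuple[str, ...] = ("GGTACC", "GAATTC")
    gc: float = 0.38
    spacer_bp: int = 300
    telomere_len: int = 300
    with_centromere: bool = True
    duplicate_kmer_from: int | None = None  # copy seq[pos-40:pos] into end pad
    orf_len_codons: tuple[int, int] = (150, 350)
    name: str = "miniXVI"

    def __post_init__(self) -> None:
        if min(self.n_verified, self.n_uncharacterized, self.n_dubious,
               self.n_trna, self.n_intron, self.n_ltr_repeat,
               self.n_tag_stop_codons, self.n_enzyme_sites,
               self.n_dubious_overlapping_verified,
               self.n_dubious_stop_in_verified, self.n_essential) < 0:
            raise FixtureError("feature counts must be non-negative")
        special = (self.n_essential + sum(self.blacklist_tags.values())
                   + self.n_intron + int(self.tandem_repeat_cds)
                   + self.n_enzyme_sites)
        if special > self.n_verified:
            raise FixtureError(
                f"n_verified={self.n_verified} too small for "
                f"{special} specially-assigned verified ORFs"
            )
        n_regular = self.n_verified + self.n_uncharacterized + self.n_dubious
        if self.n_tag_stop_codons > n_regular:
            raise FixtureError("n_tag_stop_codons exceeds free-standing ORF count")
        if self.spacer_bp < 300:
            raise FixtureError(
                "spacer_bp below 300 would let the 250 bp exclusion window "
                "reach neighbouring genes and invalidate ground truth"
            )


@dataclass
class GroundTruth:
    """Expected rule firings for the v1 and v2 pipelines."""

    overlap_records: int
    loxpsym_v1: int
    loxpsym_v2: int
    stop_swaps_v1: int
    stop_swaps_v2: int
    trna_genes_removed: int
    trna_bp_removed: int
    introns_removed: int
    repeat_bp_deleted: int
    rs_sites: int
    repeat_smash_orfs: int

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def _rand_seq(rng: random.Random, n: int, gc: float) -> str:
    w = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choices("ACGT", weights=w, k=n))


def _rand_codons(rng: random.Random, n: int) -> list[str]:
    return rng.choices(NONSTOP_CODONS, k=n)


def _random_cds(rng: random.Random, n_codons: int, stop: str) -> str:
    if n_codons < 3:
        raise FixtureError("ORF below 3 codons")
    return "ATG" + "".join(_rand_codons(rng, n_codons - 2)) + stop


def _frame_has_stop(seq: str) -> bool:
    return any(
        seq[i : i + 3] in STOP_CODONS for i in range(0, len(seq) - 2, 3)
    )


# ---------------------------------------------------------------------------
# engineered overlap geometries
# ---------------------------------------------------------------------------

def _clean_region(region: str, motifs) -> bool:
    return not any(m in region or revcomp(m) in region for m in motifs)


def _make_overlap_pair(rng: random.Random, v_codons: int, motifs,
                       d_codons: int = 20) -> tuple[str, str, int]:
    """A dubious + ORF whose 3' end extends 7 bp past a verified - gene's 5' end.

    Returns (dubious_cds, verified_cds, overlap_bp).  The loxPsym point of
    the dubious ORF lands 10 bp from the verified start codon, inside its
    exclusion window — the geometry behind the GIP3-class defects.
    """
    L_d = d_codons * 3
    ov = L_d - 7
    for _ in range(500):
        d = "ATG" + "".join(_rand_codons(rng, d_codons - 2)) + "TAA"
        d = d[: ov - 3] + "CAT" + d[ov:]  # forces verified ATG on the other strand
        if _frame_has_stop(d[3:-3]) or d[:3] != "ATG":
            continue
        pref = revcomp(d[:ov])
        n_full = ov // 3
        if any(pref[i * 3 : i * 3 + 3] in STOP_CODONS for i in range(n_full)):
            continue
        rem = (3 - ov % 3) % 3
        fill = None
        for cand in ("".join(c) for c in itertools.product("ACGT", repeat=rem)):
            if rem == 0 or pref[n_full * 3 :] + cand not in STOP_CODONS:
                fill = cand
                break
        if fill is None:
            continue
        body_codons = max(v_codons - n_full - 2, 4)
        cds_v = pref + fill + "".join(_rand_codons(rng, body_codons)) + "TAA"
        if len(cds_v) % 3:
            continue
        if _frame_has_stop(cds_v[:-3]):
            continue
        region = revcomp(cds_v) + d[ov:]
        if not _clean_region(region, motifs):
            continue
        if find_tandem_repeats(cds_v) or find_tandem_repeats(d):
            continue
        return d, cds_v, ov
    raise FixtureError("could not construct overlap pair")


def _make_nested_pair(rng: random.Random, v_codons: int, motifs,
                      d_codons: int = 18) -> tuple[str, str, int]:
    """A dubious + ORF fully nested antisense inside a verified - gene.

    The dubious ORF ends in TAG, and that stop codon lies inside the host's
    CDS — the configuration whose TAG→TAA swap the v2 policy reverts.
    Returns (dubious_cds, verified_cds, cds_offset) where ``cds_offset`` is
    the (codon-aligned) position of revcomp(dubious) inside the verified CDS.
    """
    L_d = d_codons * 3
    for _ in range(500):
        d = "ATG" + "".join(_rand_codons(rng, d_codons - 2)) + "TAG"
        ins = revcomp(d)
        if _frame_has_stop(ins):
            continue
        pre = _rand_codons(rng, rng.randrange(3, 8))
        post_n = max(v_codons - len(pre) - d_codons - 2, 4)
        post = _rand_codons(rng, post_n)
        cds_v = "ATG" + "".join(pre) + ins + "".join(post) + "TAA"
        if _frame_has_stop(cds_v[:-3]):
            continue
        if not _clean_region(revcomp(cds_v), motifs):
            continue
        if find_tandem_repeats(cds_v) or find_tandem_repeats(d):
            continue
        offset = 3 * (1 + len(pre))
        return d, cds_v, offset
    raise FixtureError("could not construct nested pair")


def _make_repeat_cds(rng: random.Random, n_codons: int, motifs) -> tuple[str, int]:
    """A CDS carrying exactly one exact tandem repeat (unit 9 bp, 5 copies)."""
    block = REPEAT_UNIT * REPEAT_COPIES
    n_block = len(block) // 3
    for _ in range(500):
        pre = _rand_codons(rng, rng.randrange(10, 20))
        post = _rand_codons(rng, max(n_codons - len(pre) - n_block - 2, 6))
        cds = "ATG" + "".join(pre) + block + "".join(post) + "TAA"
        hits = find_tandem_repeats(cds)
        start = 3 * (1 + len(pre))
        if len(hits) == 1 and hits[0][0] == start and hits[0][1] == start + len(block):
            if _clean_region(cds, motifs):
                return cds, start
    raise FixtureError("could not construct tandem-repeat CDS")


def _plant_enzyme_site(rng: random.Random, n_codons: int, motif: str,
                       motifs) -> tuple[str, int]:
    """A CDS with the enzyme motif planted codon-aligned mid-CDS."""
    if len(motif) % 3:
        raise FixtureError("enzyme motif length must be codon-aligned here")
    m_codons = [motif[i : i + 3] for i in range(0, len(motif), 3)]
    if any(c in STOP_CODONS for c in m_codons):
        raise FixtureError(f"enzyme motif {motif} encodes a stop in frame")
    for _ in range(500):
        cds = list(_random_cds(rng, n_codons, "TAA"))
        k = rng.randrange(5, n_codons - 5 - len(m_codons))
        cds[k * 3 : k * 3 + len(motif)] = motif
        cds = "".join(cds)
        inner = cds
        if sum(inner.count(m) + (0 if m == revcomp(m) else revcomp(inner).count(m))
               for m in motifs) == 1 and not find_tandem_repeats(cds):
            return cds, k * 3
    raise FixtureError("could not plant enzyme site")


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

def make_mini_chromosome(spec: FixtureSpec) -> tuple[ChromosomeAnnotation, GroundTruth]:
    """Generate an annotated mini-chromosome and its exact ground truth.

    Deterministic under ``spec.seed``: the same spec yields byte-identical
    sequence and features.
    """
    rng = random.Random(spec.seed)
    motifs = tuple(spec.enzyme_motifs)

    # ---- plan the ORF roles -------------------------------------------
    vi = 0

    def vname() -> str:
        nonlocal vi
        vi += 1
        return f"YSM{vi:03d}"

    roles: list[dict] = []
    for _ in range(spec.n_essential):
        roles.append({"classification": "verified", "essential": True})
    for tag, count in sorted(spec.blacklist_tags.items()):
        for _ in range(count):
            roles.append({"classification": "verified", "tags": frozenset({tag})})
    for _ in range(spec.n_intron):
        roles.append({"classification": "verified", "intron": True})
    if spec.tandem_repeat_cds:
        roles.append({"classification": "verified", "repeat": True})
    for _ in range(spec.n_enzyme_sites):
        roles.append({"classification": "verified", "enzyme": True})
    while sum(r["classification"] == "verified" for r in roles) < spec.n_verified:
        roles.append({"classification": "verified"})
    for _ in range(spec.n_uncharacterized):
        roles.append({"classification": "uncharacterized"})
    for _ in range(spec.n_dubious):
        roles.append({"classification": "dubious", "short": True})

    # TAG stops go to free-standing ORFs whose constructors honour the stop
    # choice (the repeat/enzyme constructors fix a TAA stop)
    eligible = [r for r in roles if not r.get("repeat") and not r.get("enzyme")]
    if spec.n_tag_stop_codons > len(eligible):
        raise FixtureError("n_tag_stop_codons exceeds the TAG-capable ORF count")
    for r in eligible[: spec.n_tag_stop_codons]:
        r["tag_stop"] = True

    elements: list[tuple[str, dict]] = [("orf", r) for r in roles]
    elements += [("pair_overlap", {})] * spec.n_dubious_overlapping_verified
    elements += [("pair_nested", {})] * spec.n_dubious_stop_in_verified
    elements += [("trna", {})] * spec.n_trna
    elements += [("ltr", {})] * spec.n_ltr_repeat
    if spec.with_centromere:
        elements.append(("cen", {}))
    rng.shuffle(elements)

    # ---- emit ---------------------------------------------------------
    parts: list[str] = []
    cursor = 0
    orfs: list[OrfFeature] = []
    trnas: list[TrnaGene] = []
    repeats: list[RepeatFeature] = []
    centromere = None
    planted_enzyme: list[tuple[int, int]] = []
    planted_repeat: tuple[str, int, int] | None = None
    protected: list[tuple[int, int]] = []
    intron_count = 0
    trna_bp = 0
    ltr_bp = 0
    n_nested = 0
    n_over = 0

    def emit(seq: str) -> int:
        nonlocal cursor
        parts.append(seq)
        start = cursor
        cursor += len(seq)
        return start

    def spacer() -> None:
        emit(_rand_seq(rng, spec.spacer_bp + rng.randrange(0, 150), spec.gc))

    emit(_rand_seq(rng, spec.telomere_len, spec.gc))  # left telomere body
    telomeres = [(0, spec.telomere_len)]
    spacer()

    budget = spec.length_bp - spec.telomere_len - spec.spacer_bp - 200

    for kind, role in elements:
        if cursor > budget:
            raise FixtureError(f"infeasible packing: no room for element {kind}")
        if kind == "orf":
            n_codons = rng.randrange(*spec.orf_len_codons)
            if role.get("short"):
                n_codons = rng.randrange(60, 120)
            stop = "TAG" if role.get("tag_stop") else rng.choice(("TAA", "TGA"))
            strand = rng.choice("+-")
            name = vname()
            if role.get("repeat"):
                cds, rstart = _make_repeat_cds(rng, n_codons, motifs)
                strand = rng.choice("+-")
                genomic = cds if strand == "+" else revcomp(cds)
                s = emit(genomic)
                orf = OrfFeature(id=name, strand=strand, exons=((s, s + len(cds)),),
                                 classification="verified")
                planted_repeat = (name, rstart, rstart + len(REPEAT_UNIT) * REPEAT_COPIES)
            elif role.get("enzyme"):
                cds, mstart = _plant_enzyme_site(rng, n_codons, motifs[0], motifs)
                s = emit(cds)  # forward strand: planted interval is direct
                orf = OrfFeature(id=name, strand="+", exons=((s, s + len(cds)),),
                                 classification="verified")
                planted_enzyme.append((s + mstart, s + mstart + len(motifs[0])))
            elif role.get("intron"):
                cds = _random_cds(rng, n_codons, stop)
                k = 3 * rng.randrange(5, n_codons - 5)
                intron = "GT" + _rand_seq(rng, 80, spec.gc) + "AG"
                if strand == "+":
                    genomic = cds[:k] + intron + cds[k:]
                    s = emit(genomic)
                    exons = ((s, s + k), (s + k + len(intron), s + len(genomic)))
                else:
                    genomic = revcomp(cds[k:]) + revcomp(intron) + revcomp(cds[:k])
                    s = emit(genomic)
                    cut = len(cds) - k
                    exons = ((s, s + cut), (s + cut + len(intron), s + len(genomic)))
                orf = OrfFeature(id=name, strand=strand, exons=exons,
                                 classification="verified")
                intron_count += 1
            else:
                cds = _random_cds(rng, n_codons, stop)
                genomic = cds if strand == "+" else revcomp(cds)
                s = emit(genomic)
                orf = OrfFeature(
                    id=name, strand=strand, exons=((s, s + len(cds)),),
                    classification=role["classification"],
                    essential=role.get("essential", False),
                    conditional_tags=role.get("tags", frozenset()),
                )
            orfs.append(orf)
        elif kind == "pair_overlap":
            d, cds_v, ov = _make_overlap_pair(rng, rng.randrange(120, 200), motifs)
            region = revcomp(cds_v) + d[ov:]
            a = emit(region)
            b = a + len(cds_v)
            x, y = b - ov, b + (len(d) - ov)
            ver = vname()
            dub = vname()
            orfs.append(OrfFeature(id=ver, strand="-", exons=((a, b),),
                                   classification="verified"))
            orfs.append(OrfFeature(id=dub, strand="+", exons=((x, y),),
                                   classification="dubious"))
            protected.append((a, y))
            n_over += 1
        elif kind == "pair_nested":
            d, cds_v, offset = _make_nested_pair(rng, rng.randrange(120, 200), motifs)
            a = emit(revcomp(cds_v))
            b = a + len(cds_v)
            x, y = b - offset - len(d), b - offset
            ver = vname()
            dub = vname()
            orfs.append(OrfFeature(id=ver, strand="-", exons=((a, b),),
                                   classification="verified"))
            orfs.append(OrfFeature(id=dub, strand="+", exons=((x, y),),
                                   classification="dubious"))
            protected.append((a, b))
            n_nested += 1
        elif kind == "trna":
            body = _rand_seq(rng, 75, spec.gc)
            s = emit(body)
            trnas.append(TrnaGene(id=f"t{len(trnas) + 1}", strand="+",
                                  interval=(s, s + 75)))
            trna_bp += 75
        elif kind == "ltr":
            body = _rand_seq(rng, 320, spec.gc)
            s = emit(body)
            repeats.append(RepeatFeature(repeat_class="LTR", interval=(s, s + 320)))
            ltr_bp += 320
        elif kind == "cen":
            body = _rand_seq(rng, 120, spec.gc)
            s = emit(body)
            centromere = (s, s + 120)
        spacer()

    pad = spec.length_bp - spec.telomere_len - cursor
    if pad < 0:
        raise FixtureError("infeasible packing: elements exceed length_bp")
    pad_start = cursor
    emit(_rand_seq(rng, pad, spec.gc))
    emit(_rand_seq(rng, spec.telomere_len, spec.gc))
    telomeres.append((spec.length_bp - spec.telomere_len, spec.length_bp))

    seq = list("".join(parts))
    assert len(seq) == spec.length_bp

    _scrub(seq, orfs, motifs, planted_enzyme, planted_repeat, protected, rng)

    if spec.duplicate_kmer_from is not None:
        _plant_duplicate(seq, spec.duplicate_kmer_from, pad_start + 61, motifs)

    ann = ChromosomeAnnotation(
        name=spec.name,
        sequence="".join(seq),
        orfs=sorted(orfs, key=lambda o: o.start),
        trnas=trnas,
        repeats=repeats,
        centromere=centromere,
        telomeres=telomeres,
    )
    ann.validate()

    n_orfs = len(ann.orfs)
    lox_v1 = n_orfs - spec.n_essential - n_nested
    lox_v2 = lox_v1 - spec.n_dubious - n_over
    gt = GroundTruth(
        overlap_records=n_over + n_nested,
        loxpsym_v1=lox_v1,
        loxpsym_v2=lox_v2,
        stop_swaps_v1=spec.n_tag_stop_codons + n_nested,
        stop_swaps_v2=spec.n_tag_stop_codons,
        trna_genes_removed=spec.n_trna,
        trna_bp_removed=trna_bp,
        introns_removed=intron_count,
        repeat_bp_deleted=ltr_bp,
        rs_sites=spec.n_enzyme_sites,
        repeat_smash_orfs=1 if spec.tandem_repeat_cds else 0,
    )
    return ann, gt


# ---------------------------------------------------------------------------
# scrubbing
# ---------------------------------------------------------------------------

def _in_any(pos: int, intervals) -> bool:
    return any(s <= pos < e for s, e in intervals)


def _scrub(seq: list[str], orfs, motifs, planted_enzyme, planted_repeat,
           protected, rng: random.Random) -> None:
    """Remove chance rule triggers so ground truth is exact by construction."""
    keep_out = list(planted_enzyme) + list(protected)
    for orf in orfs:
        s, e = orf.span
        if orf.strand == "+":
            keep_out.append((s, s + 3))
            keep_out.append((e - 3, e))
        else:
            keep_out.append((s, s + 3))
            keep_out.append((e - 3, e))

    for _ in range(40):
        changed = False
        s = "".join(seq)
        # chance enzyme motifs (all motifs here are palindromic in practice,
        # but scan both strands regardless)
        for motif in motifs:
            pats = {motif, revcomp(motif)}
            for pat in sorted(pats):
                start = 0
                while True:
                    i = s.find(pat, start)
                    if i < 0:
                        break
                    start = i + 1
                    iv = (i, i + len(pat))
                    if any(iv == p or (iv[0] < p[1] and p[0] < iv[1])
                           for p in planted_enzyme):
                        continue
                    if _fix_position(seq, orfs, iv, keep_out, rng):
                        changed = True
                        s = "".join(seq)
        # chance coding tandem repeats
        for orf in orfs:
            cds = orf.spliced_cds("".join(seq))
            for hs, he, _u in find_tandem_repeats(cds):
                if planted_repeat and orf.id == planted_repeat[0] \
                        and hs >= planted_repeat[1] - 3 and he <= planted_repeat[2] + 3:
                    continue
                if _break_repeat(seq, orf, hs, he, keep_out, rng):
                    changed = True
        if not changed:
            return
    raise FixtureError("fixture scrub did not converge")


def _fix_position(seq, orfs, interval, keep_out, rng) -> bool:
    for p in range(*interval):
        if _in_any(p, keep_out):
            continue
        host = next((o for o in orfs if o.contains(p)), None)
        if host is None:
            old = seq[p]
            seq[p] = {"A": "G", "G": "A", "C": "T", "T": "C"}[old]
            return True
        ci = _codon_index_at(host, p)
        if ci is None:
            continue
        if _swap_codon(seq, host, ci, keep_out, rng):
            return True
    return False


def _break_repeat(seq, orf, hs, he, keep_out, rng) -> bool:
    c_first, c_last = hs // 3 + 1, (he - 1) // 3
    for ci in range(c_first, c_last):
        if _swap_codon(seq, orf, ci, keep_out, rng):
            return True
    return False


def _codon_index_at(orf, pos: int) -> int | None:
    off = 0
    if orf.strand == "+":
        for s, e in orf.exons:
            if s <= pos < e:
                return (off + pos - s) // 3
            off += e - s
    else:
        for s, e in reversed(orf.exons):
            if s <= pos < e:
                return (off + (e - 1 - pos)) // 3
            off += e - s
    return None


def _swap_codon(seq, orf, ci: int, keep_out, rng) -> bool:
    n_codons = orf.cds_length() // 3
    if ci <= 0 or ci >= n_codons - 1:
        return False
    gpos = [orf.cds_to_genomic(ci * 3 + k) for k in range(3)]
    if any(_in_any(p, keep_out) for p in gpos):
        return False
    current = "".join(
        seq[p] if orf.strand == "+" else revcomp(seq[p]) for p in gpos
    )
    choices = [c for c in NONSTOP_CODONS if c != current]
    alt = rng.choice(choices)
    for k, p in enumerate(gpos):
        seq[p] = alt[k] if orf.strand == "+" else revcomp(alt[k])
    return True


def _plant_duplicate(seq, source_end: int, target: int, motifs) -> None:
    kmer = "".join(seq[source_end - 40 : source_end])
    for shift in range(0, 70, 7):
        t = target + shift
        trial = seq[: t] + list(kmer) + seq[t + 40 :]
        window = "".join(trial[t - 10 : t + 50])
        if not any(m in window or revcomp(m) in window for m in motifs):
            seq[t : t + 40] = list(kmer)
            return
    seq[target : target + 40] = list(kmer)
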