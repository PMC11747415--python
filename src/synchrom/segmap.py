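"""Bulk-segregant defect mapping on synthetic × wild-type crosses.

A strain carrying a synthetic chromosome is crossed to wild type, progeny
are phenotyped (fit / unfit), and each progeny's chromosome is genotyped at
an ordered set of marker loci (conceptually one PCR tag per megachunk) as
SYN or WT.  A defective synthetic locus reveals itself as a region where
fit segregants carry little synthetic DNA and unfit segregants carry a lot.

The meiotic model is deliberately minimal: each haploid progeny chromosome
starts from a fair random parental phase and recombines through a
homogeneous Poisson crossover process (no interference).  A strain is unfit
with probability ``penetrance`` when ANY defect locus is SYN, else with a
baseline rate.  CRISPR-assisted arm replacement is modeled as a single
forced crossover at a chosen marker.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

SYN, WT = "SYN", "WT"


@dataclass(frozen=True)
class Marker:
    id: str
    position: int  # bp


@dataclass
class SegregantPanel:
    """Genotype-by-marker matrix plus per-strain phenotype."""

    markers: list[Marker]
    genotypes: np.ndarray  # strains x markers, bool: True = SYN
    phenotype: np.ndarray  # strains, bool: True = unfit

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=bool)
        self.phenotype = np.asarray(self.phenotype, dtype=bool)
        if self.genotypes.shape != (len(self.phenotype), len(self.markers)):
            raise ValueError("genotype matrix shape mismatch")

    @property
    def n_strains(self) -> int:
        return self.genotypes.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            np.where(self.genotypes, SYN, WT),
            columns=[m.id for m in self.markers],
        )
        df.insert(0, "strain", [f"S{i + 1}" for i in range(self.n_strains)])
        df["phenotype"] = np.where(self.phenotype, "unfit", "fit")
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, markers: Sequence[Marker]) -> "SegregantPanel":
        ids = [m.id for m in markers]
        geno = df[ids].to_numpy() == SYN
        pheno = df["phenotype"].to_numpy() == "unfit"
        return cls(markers=list(markers), genotypes=geno, phenotype=pheno)


@dataclass
class LocusFrequencyTable:
    """Per-marker synthetic-allele frequency by fitness class."""

    markers: list[Marker]
    f_syn_fit: np.ndarray
    f_syn_unfit: np.ndarray
    n_fit: int
    n_unfit: int

    @property
    def delta(self) -> np.ndarray:
        return self.f_syn_unfit - self.f_syn_fit

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": [m.id for m in self.markers],
                "position": [m.position for m in self.markers],
                "f_syn_fit": self.f_syn_fit,
                "f_syn_unfit": self.f_syn_unfit,
                "n_fit": self.n_fit,
                "n_unfit": self.n_unfit,
                "delta": self.delta,
            }
        )


def simulate_cross(
    markers: Sequence[Marker],
    n_strains: int,
    crossover_rate_per_bp: float,
    defect_loci: Sequence[str],
    penetrance: float,
    seed: int | np.random.Generator,
    baseline_unfit_rate: float = 0.05,
    chromosome_length: int | None = None,
    forced_crossover_at: str | None = None,
) -> SegregantPanel:
    """Simulate a panel of haploid progeny from a SYN × WT cross.

    ``forced_crossover_at`` adds one deterministic crossover at the named
    marker's position in every strain (the Cas9-cut arm-replacement
    abstraction); the Poisson process still runs on top unless the rate is 0.
    """
    markers = list(markers)
    if not markers:
        raise ValueError("at least one marker is required")
    if not 0.0 <= penetrance <= 1.0:
        raise ValueError("penetrance must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    positions = np.array([m.position for m in markers], dtype=float)
    if np.any(np.diff(positions) <= 0):
        raise ValueError("markers must be ordered by position")
    length = float(chromosome_length or (positions[-1] + 1))

    defect_idx = [i for i, m in enumerate(markers) if m.id in set(defect_loci)]
    if set(defect_loci) - {m.id for m in markers}:
        missing = set(defect_loci) - {m.id for m in markers}
        raise ValueError(f"unknown defect loci: {sorted(missing)}")

    forced_pos = None
    if forced_crossover_at is not None:
        forced_pos = next(
            m.position for m in markers if m.id == forced_crossover_at
        )

    geno = np.empty((n_strains, len(markers)), dtype=bool)
    for i in range(n_strains):
        phase = bool(rng.integers(2))  # True = SYN parent at the left end
        n_xo = rng.poisson(crossover_rate_per_bp * length)
        xo = np.sort(rng.uniform(0, length, size=n_xo))
        if forced_pos is not None:
            xo = np.sort(np.append(xo, forced_pos + 0.5))
        crossings = np.searchsorted(xo, positions)
        geno[i] = phase ^ (crossings % 2).astype(bool)

    any_defect = (
        geno[:, defect_idx].any(axis=1) if defect_idx else np.zeros(n_strains, bool)
    )
    p_unfit = np.where(any_defect, penetrance, baseline_unfit_rate)
    pheno = rng.uniform(size=n_strains) < p_unfit
    return SegregantPanel(markers=markers, genotypes=geno, phenotype=pheno)


def locus_frequency(panel: SegregantPanel) -> LocusFrequencyTable:
    """Exact per-class SYN allele frequencies at every marker."""
    fit = ~panel.phenotype
    unfit = panel.phenotype
    n_fit, n_unfit = int(fit.sum()), int(unfit.sum())
    if n_fit == 0 or n_unfit == 0:
        raise ValueError(
            f"need at least one strain per class (fit={n_fit}, unfit={n_unfit})"
        )
    f_fit = panel.genotypes[fit].sum(axis=0) / n_fit
    f_unfit = panel.genotypes[unfit].sum(axis=0) / n_unfit
    return LocusFrequencyTable(
        markers=panel.markers,
        f_syn_fit=f_fit,
        f_syn_unfit=f_unfit,
        n_fit=n_fit,
        n_unfit=n_unfit,
    )


def call_defect_intervals(
    table: LocusFrequencyTable,
    low_thresh: float,
    high_thresh: float,
) -> list[tuple[str, str]]:
    """Maximal runs of markers depleted of SYN in fit and enriched in unfit.

    A marker qualifies when ``f_syn_fit <= low_thresh`` and
    ``f_syn_unfit >= high_thresh``; qualifying runs are returned as
    (first_marker_id, last_marker_id) intervals.
    """
    if not (0.0 <= low_thresh < high_thresh <= 1.0):
        raise ValueError("need 0 <= low_thresh < high_thresh <= 1")
    qualifies = (table.f_syn_fit <= low_thresh) & (table.f_syn_unfit >= high_thresh)
    intervals: list[tuple[str, str]] = []
    run_start: int | None = None
    for i, q in enumerate(qualifies):
        if q and run_start is None:
            run_start = i
        elif not q and run_start is not None:
            intervals.append((table.markers[run_start].id, table.markers[i - 1].id))
            run_start = None
    if run_start is not None:
        intervals.append((table.markers[run_start].id, table.markers[-1].id))
    return intervals


def markers_from_segmentation(seg, designed_length: int | None = None) -> list[Marker]:
    """One marker per megachunk, at the midpoint of its span (a PCR-tag proxy)."""
    markers = []
    for m in seg.megachunks:
        first = seg.chunk(m.chunk_ids[0]).interval
        last = seg.chunk(m.chunk_ids[-1]).interval
        markers.append(Marker(id=m.letter, position=(first[0] + last[1]) // 2))
    return markers


def recovery_rate(
    n_panels: int,
    markers: Sequence[Marker],
    defect_loci: Sequence[str],
    n_strains: int = 30,
    crossover_rate_per_bp: float = 3.5e-6,
    penetrance: float = 0.9,
    baseline_unfit_rate: float = 0.05,
    low_thresh: float = 0.45,
    high_thresh: float = 0.55,
    seed: int = 0,
    tolerance_markers: int = 1,
) -> float:
    """Fraction of replicate panels in which every defect locus is recovered.

    A defect locus counts as recovered when some called interval comes within
    ``tolerance_markers`` marker positions of it.  Panels in which one
    phenotype class is empty (so frequencies are undefined) count as misses.
    """
    rng = np.random.default_rng(seed)
    index = {m.id: i for i, m in enumerate(markers)}
    hits = 0
    for _ in range(n_panels):
        panel = simulate_cross(
            markers, n_strains, crossover_rate_per_bp, defect_loci,
            penetrance, rng, baseline_unfit_rate=baseline_unfit_rate,
        )
        try:
            table = locus_frequency(panel)
        except ValueError:
            continue
        intervals = call_defect_intervals(table, low_thresh, high_thresh)
        called: set[int] = set()
        for a, b in intervals:
            called.update(range(index[a], index[b] + 1))
        if all(
            any(abs(index[d] - c) <= tolerance_markers for c in called)
            for d in defect_loci
        ):
            hits += 1
    return hits / n_panels
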