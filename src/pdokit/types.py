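"""Domain types shared by every pipeline stage.

Coordinates are 0-based half-open internally; the on-disk SEG dialect is
1-based inclusive (see :mod:`pdokit.io`). Copy numbers are stored as
``(cnA, cnB)`` with the convention cnA >= cnB >= 0 (major/minor allele).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum


class SampleClass(str, Enum):
    """Origin of a sequenced sample: parental tumor or derived organoid."""

    PT = "PT"
    PDO = "PDO"


class TumorClass(str, Enum):
    """Ordered bladder-cancer classes: low-grade NMIBC < high-grade NMIBC < MIBC."""

    NMIBC_LG = "NMIBC_LG"
    NMIBC_HG = "NMIBC_HG"
    MIBC = "MIBC"

    @property
    def rank(self) -> int:
        return _TUMOR_CLASS_ORDER[self]


_TUMOR_CLASS_ORDER = {
    TumorClass.NMIBC_LG: 0,
    TumorClass.NMIBC_HG: 1,
    TumorClass.MIBC: 2,
}


class Impact(str, Enum):
    """Predicted functional impact tier of a variant (annotator vocabulary)."""

    HIGH = "HIGH"
    MODERATE = "MODERATE"
    LOW = "LOW"
    MODIFIER = "MODIFIER"


#: Impact tiers treated as deleterious downstream.
DELETERIOUS_IMPACTS = frozenset({Impact.HIGH, Impact.MODERATE})


class VehicleClass(str, Enum):
    """Solvent used as the negative control for a drug condition."""

    DMSO = "DMSO"
    H2O = "H2O"


@dataclass(frozen=True)
class Segment:
    """One allele-specific copy-number segment (0-based half-open)."""

    chrom: str
    start: int
    end: int
    cn_a: float
    cn_b: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"segment {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.cn_b < 0:
            raise ValueError(f"segment {self.chrom}:{self.start}-{self.end}: cnB < 0")
        if self.cn_a < self.cn_b:
            raise ValueError(
                f"segment {self.chrom}:{self.start}-{self.end}: cnA "
                f"({self.cn_a}) < cnB ({self.cn_b}); major allele must come first"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def total_cn(self) -> float:
        return self.cn_a + self.cn_b

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass
class SegmentProfile:
    """A sample's allele-specific copy-number segmentation plus metadata."""

    sample_id: str
    sample_class: SampleClass
    tumor_class: TumorClass
    purity: float
    segments: list[Segment]

    def __post_init__(self) -> None:
        self.sample_class = SampleClass(self.sample_class)
        self.tumor_class = TumorClass(self.tumor_class)
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError(f"{self.sample_id}: purity {self.purity} outside [0, 1]")
        by_chrom: dict[str, list[Segment]] = {}
        for seg in self.segments:
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for chrom, segs in by_chrom.items():
            segs = sorted(segs, key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"{self.sample_id}: overlapping segments on {chrom}: "
                        f"{a.start}-{a.end} and {b.start}-{b.end}"
                    )

    def segment_at(self, chrom: str, pos: int) -> Segment | None:
        """Segment covering ``chrom:pos`` (0-based), or None."""
        for seg in self.segments:
            if seg.contains(chrom, pos):
                return seg
        return None


@dataclass(frozen=True)
class GeneRecord:
    gene: str
    chrom: str
    start: int  # 0-based half-open
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene}: start must be < end")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class GenePanel:
    """Ordered list of gene intervals used to discretise copy number gene-wise."""

    genes: list[GeneRecord]

    def __post_init__(self) -> None:
        names = [g.gene for g in self.genes]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate gene names in panel: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    @property
    def gene_names(self) -> list[str]:
        return [g.gene for g in self.genes]


@dataclass
class GeneSetCollection:
    """Named gene sets plus an optional explicit background universe.

    When ``background`` is None the union of all set members is used.
    """

    sets: dict[str, list[str]]
    background: list[str] | None = None

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if any(not g for g in genes):
                raise ValueError(f"gene set {name!r} contains an empty gene symbol")
            # collapse duplicates, keep first-seen order
            self.sets[name] = list(dict.fromkeys(genes))

    def effective_background(self) -> list[str]:
        if self.background is not None:
            return list(self.background)
        seen: dict[str, None] = {}
        for genes in self.sets.values():
            for g in genes:
                seen.setdefault(g)
        return list(seen)


@dataclass(frozen=True)
class Well:
    """A single plate well. Vehicle wells carry condition == vehicle_class value."""

    condition: str
    vehicle_class: VehicleClass
    readout: float

    def __post_init__(self) -> None:
        if self.readout < 0:
            raise ValueError(f"negative readout {self.readout} in condition {self.condition}")

    @property
    def is_vehicle(self) -> bool:
        return self.condition == self.vehicle_class.value


@dataclass
class PlateData:
    """Raw replicate luminescence readouts for one screened sample."""

    sample_id: str
    wells: list[Well]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        by_condition: dict[str, list[Well]] = {}
        for w in self.wells:
            by_condition.setdefault(w.condition, []).append(w)
        vehicle_classes = {
            w.vehicle_class for w in self.wells if w.is_vehicle
        }
        for cond, wells in by_condition.items():
            if len(wells) < 2:
                raise ValueError(
                    f"{self.sample_id}: condition {cond!r} has {len(wells)} replicate(s); "
                    "need >= 2 for variance-based statistics"
                )
            vc = wells[0].vehicle_class
            if not wells[0].is_vehicle and vc not in vehicle_classes:
                raise ValueError(
                    f"{self.sample_id}: drug condition {cond!r} references vehicle "
                    f"{vc.value} but the plate has no such vehicle wells"
                )

    def vehicle_readouts(self, vehicle_class: VehicleClass) -> list[float]:
        return [
            w.readout
            for w in self.wells
            if w.is_vehicle and w.vehicle_class == vehicle_class
        ]

    def condition_readouts(self, condition: str) -> list[float]:
        return [w.readout for w in self.wells if w.condition == condition]

    def drug_conditions(self) -> list[tuple[str, VehicleClass]]:
        """Distinct non-vehicle conditions in first-seen order."""
        seen: dict[str, VehicleClass] = {}
        for w in self.wells:
            if not w.is_vehicle and w.condition not in seen:
                seen[w.condition] = w.vehicle_class
        return list(seen.items())


@dataclass(frozen=True)
class FilterThresholds:
    """Quality filters applied to somatic SNV calls (all boundaries inclusive)."""

    min_tumor_coverage: int = 20
    min_af: float = 0.08
    min_alt_reads: int = 5
    max_normal_alt: int = 0

    def __post_init__(self) -> None:
        if min(self.min_tumor_coverage, self.min_af, self.min_alt_reads, self.max_normal_alt) < 0:
            raise ValueError("filter thresholds must be non-negative")


#: Canonical column order of an SNV table (pandas DataFrame).
SNV_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "tumor_coverage",
    "tumor_alt_reads",
    "normal_alt_reads",
    "allelic_fraction",
    "gene",
    "impact",
]
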