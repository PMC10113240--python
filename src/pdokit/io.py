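"""Readers and writers for the plain-text formats the pipeline touches.

Dialects
--------
* Segments: SEG-like TSV, columns ``sample_id chrom start end cnA cnB``,
  coordinates 1-based inclusive on disk, converted to 0-based half-open
  in memory (and back on write).
* SNVs: TSV with the :data:`pdokit.types.SNV_COLUMNS` columns, or VCF
  (uncompressed v4.x, read via cyvcf2 when installed).
* Gene panel: BED (0-based half-open on disk, same convention in memory),
  columns ``chrom start end gene``.
* Gene sets: standard GMT (name, description, genes...).
* Plates: CSV with columns ``sample_id condition vehicle_class replicate
  readout``; vehicle wells are rows whose condition equals the vehicle
  class name (``DMSO`` or ``H2O``).
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path
from typing import Iterable

import pandas as pd

from .types import (
    SNV_COLUMNS,
    GenePanel,
    GeneRecord,
    GeneSetCollection,
    Impact,
    PlateData,
    SampleClass,
    Segment,
    SegmentProfile,
    TumorClass,
    VehicleClass,
    Well,
)


class ParseError(ValueError):
    """Raised for malformed rows; message names the offending line."""


# ---------------------------------------------------------------------------
# coordinate conversion (1-based inclusive <-> 0-based half-open)

def disk_to_internal(start1: int, end1: int) -> tuple[int, int]:
    return start1 - 1, end1


def internal_to_disk(start0: int, end0: int) -> tuple[int, int]:
    return start0 + 1, end0


# ---------------------------------------------------------------------------
# segments

_SEG_HEADER = ["sample_id", "chrom", "start", "end", "cnA", "cnB"]
_META_HEADER = ["sample_id", "sample_class", "tumor_class", "purity"]


def read_segments(path: str | Path, metadata: pd.DataFrame) -> list[SegmentProfile]:
    """Read a SEG-like TSV into validated :class:`SegmentProfile` objects.

    ``metadata`` must have columns ``sample_id, sample_class, tumor_class,
    purity``; every sample_id appearing in the segment table must be present.
    """
    missing = [c for c in _META_HEADER if c not in metadata.columns]
    if missing:
        raise ParseError(f"metadata table missing column(s): {missing}")
    meta = metadata.set_index("sample_id")

    by_sample: dict[str, list[Segment]] = {}
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _SEG_HEADER:
            raise ParseError(
                f"{path}: expected header {_SEG_HEADER}, found {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(_SEG_HEADER):
                raise ParseError(f"{path}:{lineno}: expected 6 fields, found {len(fields)}")
            sid, chrom, start1, end1, cn_a, cn_b = fields
            try:
                start0, end0 = disk_to_internal(int(start1), int(end1))
                seg = Segment(chrom, start0, end0, float(cn_a), float(cn_b))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            by_sample.setdefault(sid, []).append(seg)

    profiles = []
    for sid, segs in by_sample.items():
        if sid not in meta.index:
            raise ParseError(f"sample {sid!r} in {path} has no metadata row")
        row = meta.loc[sid]
        profiles.append(
            SegmentProfile(
                sample_id=sid,
                sample_class=SampleClass(row["sample_class"]),
                tumor_class=TumorClass(row["tumor_class"]),
                purity=float(row["purity"]),
                segments=segs,
            )
        )
    return profiles


def _format_cn(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def write_segments(profiles: Iterable[SegmentProfile], path: str | Path) -> None:
    """Write profiles back to the SEG-like TSV dialect (canonical formatting)."""
    with Path(path).open("w") as fh:
        fh.write("\t".join(_SEG_HEADER) + "\n")
        for prof in profiles:
            for seg in sorted(prof.segments, key=lambda s: (s.chrom, s.start)):
                start1, end1 = internal_to_disk(seg.start, seg.end)
                fh.write(
                    f"{prof.sample_id}\t{seg.chrom}\t{start1}\t{end1}\t"
                    f"{_format_cn(seg.cn_a)}\t{_format_cn(seg.cn_b)}\n"
                )


def metadata_frame(profiles: Iterable[SegmentProfile]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": p.sample_id,
            "sample_class": p.sample_class.value,
            "tumor_class": p.tumor_class.value,
            "purity": p.purity,
        }
        for p in profiles
    ]
    return pd.DataFrame(rows, columns=_META_HEADER)


# ---------------------------------------------------------------------------
# SNVs

def read_snvs(path: str | Path) -> pd.DataFrame:
    """Read somatic SNVs from TSV (or VCF) into the canonical table.

    The allelic fraction is computed from read counts when the column is
    absent. Duplicate (chrom, pos, ref, alt) records are dropped with a
    warning.
    """
    path = Path(path)
    if path.suffix.lower() in {".vcf"} or str(path).endswith(".vcf.gz"):
        df = _read_snvs_vcf(path)
    else:
        df = _read_snvs_tsv(path)

    dup = df.duplicated(subset=["chrom", "pos", "ref", "alt"])
    if dup.any():
        warnings.warn(
            f"{path}: dropped {int(dup.sum())} duplicate SNV record(s)",
            stacklevel=2,
        )
        df = df[~dup].reset_index(drop=True)

    bad = df["tumor_alt_reads"] > df["tumor_coverage"]
    if bad.any():
        raise ParseError(f"{path}: tumor_alt_reads > tumor_coverage in {int(bad.sum())} row(s)")
    df["impact"] = [Impact(i).value for i in df["impact"]]
    return df[SNV_COLUMNS]


def _read_snvs_tsv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    required = [c for c in SNV_COLUMNS if c != "allelic_fraction"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s): {missing}")
    if "allelic_fraction" not in df.columns:
        df["allelic_fraction"] = df["tumor_alt_reads"] / df["tumor_coverage"]
    return df


def _read_snvs_vcf(path: Path) -> pd.DataFrame:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise ImportError(
            "reading VCF requires cyvcf2; supply a TSV variant table instead"
        ) from exc
    rows = []
    for var in VCF(str(path)):
        if var.INFO.get("DP") is None and var.format("DP") is None:
            raise ParseError(f"{path}: VCF record {var.CHROM}:{var.POS} lacks depth (DP)")
        dp = var.INFO.get("DP")
        if dp is None:
            dp = int(var.format("DP")[0][0])
        alt_reads = var.INFO.get("TAR")
        if alt_reads is None and var.format("AD") is not None:
            alt_reads = int(var.format("AD")[0][-1])
        if alt_reads is None:
            raise ParseError(
                f"{path}: VCF record {var.CHROM}:{var.POS} lacks alt read support (TAR/AD)"
            )
        rows.append(
            {
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0],
                "tumor_coverage": int(dp),
                "tumor_alt_reads": int(alt_reads),
                "normal_alt_reads": int(var.INFO.get("NAR", 0)),
                "allelic_fraction": (
                    float(var.INFO.get("AF")) if var.INFO.get("AF") is not None
                    else int(alt_reads) / int(dp)
                ),
                "gene": var.INFO.get("GENE", ""),
                "impact": var.INFO.get("IMPACT", "MODIFIER"),
            }
        )
    return pd.DataFrame(rows, columns=SNV_COLUMNS)


def write_snvs(df: pd.DataFrame, path: str | Path) -> None:
    df[SNV_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene panel (BED)

def read_gene_panel(path: str | Path) -> GenePanel:
    """Read a 4-column BED (chrom, start, end, gene) into a GenePanel."""
    genes = []
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: BED row needs 4 fields")
            chrom, start, end, gene = fields[:4]
            genes.append(GeneRecord(gene=gene, chrom=chrom, start=int(start), end=int(end)))
    return GenePanel(genes=genes)


def write_gene_panel(panel: GenePanel, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for g in panel:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene}\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file; duplicate genes within a set are collapsed."""
    sets: dict[str, list[str]] = {}
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >= 3 fields (name, description, genes)"
                )
            name, _desc, *genes = fields
            sets[name] = genes
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


# ---------------------------------------------------------------------------
# drug-screen plates (CSV)

_PLATE_HEADER = ["sample_id", "condition", "vehicle_class", "replicate", "readout"]


def read_plates(path: str | Path) -> list[PlateData]:
    """Read plate CSV into one PlateData per sample (file order preserved)."""
    path = Path(path)
    wells_by_sample: dict[str, list[Well]] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in _PLATE_HEADER if c not in (reader.fieldnames or [])]
        if missing:
            raise ParseError(f"{path}: missing plate column(s): {missing}")
        for lineno, row in enumerate(reader, start=2):
            try:
                well = Well(
                    condition=row["condition"],
                    vehicle_class=VehicleClass(row["vehicle_class"]),
                    readout=float(row["readout"]),
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            wells_by_sample.setdefault(row["sample_id"], []).append(well)
    return [PlateData(sample_id=sid, wells=wells) for sid, wells in wells_by_sample.items()]


def write_plates(plates: Iterable[PlateData], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_PLATE_HEADER)
        for plate in plates:
            counters: dict[str, int] = {}
            for w in plate.wells:
                counters[w.condition] = counters.get(w.condition, 0) + 1
                writer.writerow(
                    [
                        plate.sample_id,
                        w.condition,
                        w.vehicle_class.value,
                        counters[w.condition],
                        _format_cn(w.readout) if float(w.readout).is_integer() else repr(w.readout),
                    ]
                )
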