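"""Synthetic matched tumor/organoid cohort generator.

Generates cohorts with the statistical structure the downstream analyses
assume, so the full pipeline is exercisable without sequencing data:

* matched PT/PDO pairs share a segment backbone (per-chromosome random
  breakpoints) with sparse per-segment perturbations on the organoid
  side; a configurable fraction of pairs is polyploid, with
  near-universal gains across the genome;
* somatic SNVs are placed in panel genes; a configurable fraction of
  each pair's loci is shared between PT and PDO, private loci carry a
  depressed cancer-cell fraction; read support is drawn binomially from
  the expected allelic fraction
  AF = purity * m * CCF / (purity * CN_t + (1 - purity) * 2)
  with coverage ~ Poisson(mean 80);
* drug plates draw vehicle readouts from Normal(mu, cv * mu) and shift
  treated wells by a per-sample random sensitivity plus any planted
  genotype-drug effect (in vehicle-SD units) for carrier samples.

Every stochastic draw derives from one global seed through independent
sub-streams, so identical configs yield identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .types import (
    SNV_COLUMNS,
    GenePanel,
    GeneRecord,
    GeneSetCollection,
    PlateData,
    SampleClass,
    Segment,
    SegmentProfile,
    TumorClass,
    VehicleClass,
    Well,
)

_BASES = ["A", "C", "G", "T"]

#: Default drug panel: standard-of-care chemotherapy plus targeted agents.
#: Platinum/gemcitabine conditions are referenced to the H2O vehicle.
DEFAULT_DRUG_PANEL: tuple[tuple[str, str], ...] = (
    ("cisplatin", "H2O"),
    ("gemcitabine", "H2O"),
    ("cisplatin+gemcitabine", "H2O"),
    ("epirubicin", "DMSO"),
    ("doxorubicin", "DMSO"),
    ("mitomycin_c", "DMSO"),
    ("docetaxel", "DMSO"),
    ("lapatinib", "DMSO"),
    ("erdafitinib", "DMSO"),
    ("ponatinib", "DMSO"),
    ("everolimus", "DMSO"),
)


@dataclass(frozen=True)
class PlantedEffect:
    """A genotype-drug effect to plant: carriers of ``gene`` shift their
    treated wells for ``drug`` by ``effect`` vehicle-SD units."""

    gene: str
    drug: str
    effect: float


@dataclass(frozen=True)
class CohortConfig:
    n_pairs: int = 13
    seed: int = 0
    purity_range: tuple[float, float] = (0.6, 0.9)
    polyploid_fraction: float = 0.25
    shared_snv_fraction: float = 0.73
    private_ccf_scale: float = 0.4
    snvs_per_sample: int = 400
    target_mb: float = 30.0
    drug_panel: tuple[tuple[str, str], ...] = DEFAULT_DRUG_PANEL
    planted_effects: tuple[PlantedEffect, ...] = ()
    vehicle_mu: float = 10000.0
    vehicle_cv: float = 0.08
    replicates_per_condition: int = 3
    vehicle_replicates: int = 7
    n_genes: int = 200
    n_chromosomes: int = 5
    mean_coverage: float = 80.0
    sample_sensitivity_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2 (pairwise analyses undefined)")
        lo, hi = self.purity_range
        for name, frac in [
            ("purity lower bound", lo),
            ("purity upper bound", hi),
            ("polyploid_fraction", self.polyploid_fraction),
            ("shared_snv_fraction", self.shared_snv_fraction),
            ("private_ccf_scale", self.private_ccf_scale),
        ]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {frac}")
        if lo > hi:
            raise ValueError("purity_range must be (lo, hi) with lo <= hi")


@dataclass
class Cohort:
    """One generated cohort plus the ground truth that produced it."""

    profiles: list[SegmentProfile]
    snv_tables: dict[str, pd.DataFrame]
    panel: GenePanel
    gene_sets: GeneSetCollection
    plates: list[PlateData]
    truth: dict

    @property
    def matched_pairs(self) -> list[tuple[str, str]]:
        return [(p["pt_id"], p["pdo_id"]) for p in self.truth["pairs"]]


# ---------------------------------------------------------------------------
# panel

_GENE_SPACING = 500_000
_GENE_LENGTH = 20_000


def make_panel(n_genes: int = 200, n_chromosomes: int = 5) -> GenePanel:
    """Deterministic gene panel: equally spaced genes on pseudo-chromosomes."""
    per_chrom = [n_genes // n_chromosomes] * n_chromosomes
    for i in range(n_genes % n_chromosomes):
        per_chrom[i] += 1
    genes = []
    counter = 1
    for c, count in enumerate(per_chrom, start=1):
        for i in range(count):
            start = i * _GENE_SPACING + 100_000
            genes.append(
                GeneRecord(
                    gene=f"G{counter:03d}",
                    chrom=f"chr{c}",
                    start=start,
                    end=start + _GENE_LENGTH,
                )
            )
            counter += 1
    return GenePanel(genes=genes)


def _chrom_lengths(panel: GenePanel) -> dict[str, int]:
    lengths: dict[str, int] = {}
    for g in panel:
        lengths[g.chrom] = max(lengths.get(g.chrom, 0), g.end + 100_000)
    return lengths


# ---------------------------------------------------------------------------
# segments

_DIPLOID_ABERRANT = [(2, 1), (2, 2), (1, 0), (2, 0), (0, 0), (3, 1)]
_DIPLOID_ABERRANT_P = np.array([0.35, 0.15, 0.2, 0.1, 0.08, 0.12])
_POLYPLOID_BASE = [(2, 1), (2, 2)]
_POLYPLOID_AMP = [(3, 2), (4, 2)]


def _pair_backbone(rng: np.random.Generator, lengths: dict[str, int], polyploid: bool):
    backbone = []
    for chrom, length in lengths.items():
        n_segments = int(rng.integers(2, 6))
        cuts = np.sort(rng.integers(1, length, size=n_segments - 1))
        bounds = [0, *map(int, cuts), length]
        for s, e in zip(bounds, bounds[1:]):
            if s >= e:
                continue
            if polyploid:
                if rng.random() < 0.15:
                    cn = _POLYPLOID_AMP[int(rng.integers(len(_POLYPLOID_AMP)))]
                else:
                    cn = _POLYPLOID_BASE[int(rng.integers(len(_POLYPLOID_BASE)))]
            else:
                if rng.random() < 0.65:
                    cn = (1, 1)
                else:
                    p = _DIPLOID_ABERRANT_P / _DIPLOID_ABERRANT_P.sum()
                    cn = _DIPLOID_ABERRANT[int(rng.choice(len(_DIPLOID_ABERRANT), p=p))]
            backbone.append((chrom, s, e, cn[0], cn[1]))
    return backbone


def _perturb_backbone(rng: np.random.Generator, backbone, rate: float = 0.05):
    out = []
    for chrom, s, e, a, b in backbone:
        if rng.random() < rate:
            if rng.random() < 0.5:
                a = max(a + int(rng.choice([-1, 1])), b)
            else:
                b = int(np.clip(b + int(rng.choice([-1, 1])), 0, a))
        out.append((chrom, s, e, a, b))
    return out


# ---------------------------------------------------------------------------
# SNVs

_IMPACTS = ["HIGH", "MODERATE", "LOW", "MODIFIER"]
_IMPACT_P = [0.15, 0.45, 0.2, 0.2]


def _draw_loci(
    rng: np.random.Generator,
    panel: GenePanel,
    n: int,
    used: set,
    reserved_genes: frozenset = frozenset(),
) -> list:
    loci = []
    genes = [g for g in panel.genes if g.gene not in reserved_genes]
    while len(loci) < n:
        g = genes[int(rng.integers(len(genes)))]
        pos = int(rng.integers(g.start, g.end)) + 1  # 1-based
        key = (g.chrom, pos)
        if key in used:
            continue
        used.add(key)
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        loci.append((g.chrom, pos, str(ref), str(alt), g.gene))
    return loci


def _read_support(
    rng: np.random.Generator,
    profile: SegmentProfile,
    chrom: str,
    pos: int,
    ccf: float,
    multiplicity: int,
    mean_coverage: float,
):
    seg = profile.segment_at(chrom, pos - 1)
    cn_t = seg.total_cn if seg is not None else 2.0
    p = profile.purity
    af_expected = p * multiplicity * ccf / (p * cn_t + (1.0 - p) * 2.0)
    af_expected = float(np.clip(af_expected, 0.0, 1.0))
    cov = max(int(rng.poisson(mean_coverage)), 1)
    alt = int(rng.binomial(cov, af_expected))
    return cov, alt


# ---------------------------------------------------------------------------
# main generator

def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full matched cohort (profiles, SNVs, plates, gene sets)."""
    ss = np.random.SeedSequence(config.seed)
    rng_seg, rng_snv, rng_plate, rng_sets = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    panel = make_panel(config.n_genes, config.n_chromosomes)
    lengths = _chrom_lengths(panel)
    genes_by_name = {g.gene: g for g in panel}

    planted_genes = [e.gene for e in config.planted_effects]
    unknown = [g for g in planted_genes if g not in genes_by_name]
    if unknown:
        raise ValueError(f"planted effect gene(s) not in panel: {unknown}")

    # choose carrier pairs per planted gene (~1/3 of pairs, at least 2)
    n_carriers = max(2, round(config.n_pairs / 3))
    carrier_pairs: dict[str, set[int]] = {}
    for gene in dict.fromkeys(planted_genes):
        chosen = rng_snv.choice(config.n_pairs, size=min(n_carriers, config.n_pairs), replace=False)
        carrier_pairs[gene] = set(int(i) for i in chosen)

    profiles: list[SegmentProfile] = []
    snv_tables: dict[str, pd.DataFrame] = {}
    pair_records = []
    snv_truth_frames = []

    lo, hi = config.purity_range
    tumor_classes = [TumorClass.NMIBC_LG, TumorClass.NMIBC_HG, TumorClass.MIBC]

    for pair_idx in range(config.n_pairs):
        pair_id = f"P{pair_idx + 1:02d}"
        pt_id, pdo_id = f"{pair_id}_PT", f"{pair_id}_PDO"
        tumor_class = tumor_classes[int(rng_seg.choice(3, p=[0.3, 0.3, 0.4]))]
        polyploid = bool(rng_seg.random() < config.polyploid_fraction)

        backbone = _pair_backbone(rng_seg, lengths, polyploid)
        pdo_backbone = _perturb_backbone(rng_seg, backbone)
        purity_pt = float(rng_seg.uniform(lo, hi))
        purity_pdo = float(rng_seg.uniform(lo, hi))

        pt_profile = SegmentProfile(
            sample_id=pt_id,
            sample_class=SampleClass.PT,
            tumor_class=tumor_class,
            purity=purity_pt,
            segments=[Segment(*row) for row in backbone],
        )
        pdo_profile = SegmentProfile(
            sample_id=pdo_id,
            sample_class=SampleClass.PDO,
            tumor_class=tumor_class,
            purity=purity_pdo,
            segments=[Segment(*row) for row in pdo_backbone],
        )
        profiles += [pt_profile, pdo_profile]

        # --- loci ---------------------------------------------------------
        n = config.snvs_per_sample
        n_shared = round(config.shared_snv_fraction * n)
        n_private = n - n_shared
        used: set = set()
        # planted feature genes are reserved for carriers, so the carrier
        # indicator downstream reflects the planted truth exactly
        reserved = frozenset(planted_genes)
        shared_loci = _draw_loci(rng_snv, panel, n_shared, used, reserved)
        private_pt_loci = _draw_loci(rng_snv, panel, n_private, used, reserved)
        private_pdo_loci = _draw_loci(rng_snv, panel, n_private, used, reserved)

        # planted clonal HIGH-impact SNVs in carrier pairs (shared)
        planted_here = [
            gene for gene, pairs in carrier_pairs.items() if pair_idx in pairs
        ]
        for gene in planted_here:
            g = genes_by_name[gene]
            pos = (g.start + g.end) // 2 + 1
            shared_loci.append((g.chrom, pos, "C", "T", gene))

        shared_ccf = np.where(
            rng_snv.random(len(shared_loci)) < 0.7,
            1.0,
            rng_snv.uniform(0.3, 1.0, size=len(shared_loci)),
        )
        shared_ccf[len(shared_loci) - len(planted_here) :] = 1.0  # planted are clonal

        rows_pt, rows_pdo, truth_rows = [], [], []

        def emit(profile, loci, ccfs, side, planted_flags):
            rows = []
            for (chrom, pos, ref, alt, gene), ccf, planted in zip(loci, ccfs, planted_flags):
                impact = (
                    "HIGH"
                    if planted
                    else _IMPACTS[int(rng_snv.choice(4, p=_IMPACT_P))]
                )
                cov, alt_reads = _read_support(
                    rng_snv, profile, chrom, pos, float(ccf), 1, config.mean_coverage
                )
                rows.append(
                    {
                        "chrom": chrom,
                        "pos": pos,
                        "ref": ref,
                        "alt": alt,
                        "tumor_coverage": cov,
                        "tumor_alt_reads": alt_reads,
                        "normal_alt_reads": 0,
                        "allelic_fraction": alt_reads / cov,
                        "gene": gene,
                        "impact": impact,
                    }
                )
                truth_rows.append(
                    {
                        "pair": pair_id,
                        "sample_id": profile.sample_id,
                        "chrom": chrom,
                        "pos": pos,
                        "ref": ref,
                        "alt": alt,
                        "gene": gene,
                        "ccf": float(ccf),
                        "side": side,
                        "planted": planted,
                    }
                )
            return rows

        n_plain_shared = len(shared_loci) - len(planted_here)
        planted_flags = [False] * n_plain_shared + [True] * len(planted_here)
        # shared impacts must agree between PT and PDO: draw once
        shared_impacts = [
            "HIGH" if planted else _IMPACTS[int(rng_snv.choice(4, p=_IMPACT_P))]
            for planted in planted_flags
        ]
        for profile, rows in [(pt_profile, rows_pt), (pdo_profile, rows_pdo)]:
            for (chrom, pos, ref, alt, gene), ccf, planted, impact in zip(
                shared_loci, shared_ccf, planted_flags, shared_impacts
            ):
                cov, alt_reads = _read_support(
                    rng_snv, profile, chrom, pos, float(ccf), 1, config.mean_coverage
                )
                rows.append(
                    {
                        "chrom": chrom,
                        "pos": pos,
                        "ref": ref,
                        "alt": alt,
                        "tumor_coverage": cov,
                        "tumor_alt_reads": alt_reads,
                        "normal_alt_reads": 0,
                        "allelic_fraction": alt_reads / cov,
                        "gene": gene,
                        "impact": impact,
                    }
                )
                truth_rows.append(
                    {
                        "pair": pair_id,
                        "sample_id": profile.sample_id,
                        "chrom": chrom,
                        "pos": pos,
                        "ref": ref,
                        "alt": alt,
                        "gene": gene,
                        "ccf": float(ccf),
                        "side": "shared",
                        "planted": planted,
                    }
                )
        private_ccf_pt = np.full(len(private_pt_loci), config.private_ccf_scale)
        private_ccf_pdo = np.full(len(private_pdo_loci), config.private_ccf_scale)
        rows_pt += emit(
            pt_profile, private_pt_loci, private_ccf_pt, "private_pt",
            [False] * len(private_pt_loci),
        )
        rows_pdo += emit(
            pdo_profile, private_pdo_loci, private_ccf_pdo, "private_pdo",
            [False] * len(private_pdo_loci),
        )

        snv_tables[pt_id] = pd.DataFrame(rows_pt, columns=SNV_COLUMNS)
        snv_tables[pdo_id] = pd.DataFrame(rows_pdo, columns=SNV_COLUMNS)
        snv_truth_frames.append(pd.DataFrame(truth_rows))

        pair_records.append(
            {
                "pair_id": pair_id,
                "pt_id": pt_id,
                "pdo_id": pdo_id,
                "tumor_class": tumor_class.value,
                "polyploid": polyploid,
                "purity_pt": purity_pt,
                "purity_pdo": purity_pdo,
                "n_shared": len(shared_loci),
                "n_private_per_side": n_private,
            }
        )

    # --- gene sets ---------------------------------------------------------
    gene_names = panel.gene_names
    sets: dict[str, list[str]] = {}
    for i in range(20):
        members = rng_sets.choice(gene_names, size=12, replace=False)
        sets[f"SET{i + 1:02d}"] = [str(g) for g in members]
    for gene in dict.fromkeys(planted_genes):
        others = rng_sets.choice(
            [g for g in gene_names if g != gene], size=9, replace=False
        )
        sets[f"{gene}_pathway"] = [gene, *map(str, others)]
    gene_sets = GeneSetCollection(sets=sets, background=list(gene_names))

    # --- drug plates --------------------------------------------------------
    effects_by_drug: dict[str, list[PlantedEffect]] = {}
    for e in config.planted_effects:
        effects_by_drug.setdefault(e.drug, []).append(e)
    carriers_by_effect: dict[tuple[str, str], list[str]] = {
        (e.gene, e.drug): [
            pair_records[i]["pdo_id"] for i in sorted(carrier_pairs[e.gene])
        ]
        for e in config.planted_effects
    }

    mu, sd = config.vehicle_mu, config.vehicle_cv * config.vehicle_mu
    vehicle_classes = {VehicleClass(vc) for _, vc in config.drug_panel}
    plates = []
    for rec in pair_records:
        sid = rec["pdo_id"]
        sensitivity = float(rng_plate.normal(0.0, config.sample_sensitivity_sd))
        wells = []
        for vc in sorted(vehicle_classes, key=lambda v: v.value):
            for _ in range(config.vehicle_replicates):
                wells.append(
                    Well(
                        condition=vc.value,
                        vehicle_class=vc,
                        readout=max(float(rng_plate.normal(mu, sd)), 0.0),
                    )
                )
        for drug, vc_name in config.drug_panel:
            vc = VehicleClass(vc_name)
            shift = sensitivity
            for e in effects_by_drug.get(drug, []):
                if sid in carriers_by_effect[(e.gene, e.drug)]:
                    shift += e.effect
            for _ in range(config.replicates_per_condition):
                wells.append(
                    Well(
                        condition=drug,
                        vehicle_class=vc,
                        readout=max(float(rng_plate.normal(mu + shift * sd, sd)), 0.0),
                    )
                )
        plates.append(PlateData(sample_id=sid, wells=wells))

    truth = {
        "config": config,
        "pairs": pair_records,
        "snvs": pd.concat(snv_truth_frames, ignore_index=True),
        "planted_effects": [
            {
                "gene": e.gene,
                "drug": e.drug,
                "effect": e.effect,
                "carriers": carriers_by_effect[(e.gene, e.drug)],
            }
            for e in config.planted_effects
        ],
    }
    return Cohort(
        profiles=profiles,
        snv_tables=snv_tables,
        panel=panel,
        gene_sets=gene_sets,
        plates=plates,
        truth=truth,
    )


def truth_report(truth: dict) -> pd.DataFrame:
    """Flat table of planted parameters: one row per planted effect,
    config keys broadcast as columns (empty table when nothing planted)."""
    config: CohortConfig = truth["config"]
    config_cols = {
        f.name: getattr(config, f.name)
        for f in fields(config)
        if f.name not in ("drug_panel", "planted_effects")
    }
    columns = ["gene", "drug", "effect", "n_carriers", *config_cols]
    rows = []
    for e in truth["planted_effects"]:
        rows.append(
            {
                "gene": e["gene"],
                "drug": e["drug"],
                "effect": e["effect"],
                "n_carriers": len(e["carriers"]),
                **{k: (str(v) if isinstance(v, tuple) else v) for k, v in config_cols.items()},
            }
        )
    return pd.DataFrame(rows, columns=columns)
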