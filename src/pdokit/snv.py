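"""Somatic SNV filtering, mutational burden, clonality, and tumor/organoid
concordance statistics.

High-quality calls must satisfy all four filters simultaneously (tumor
coverage >= 20, allelic fraction >= 0.08, alt reads >= 5, zero alt reads
in the matched normal). Deleterious calls are those with HIGH or MODERATE
predicted impact. Matched-pair concordance partitions calls into shared
and private sets keyed by (chrom, pos, ref, alt).

Clonality (cancer cell fraction, CCF) corrects the observed allelic
fraction for tumor purity, local total copy number and mutation
multiplicity:

    D   = purity * CN_t + (1 - purity) * 2          (expected locus DNA)
    m   = clamp(round(AF * D / purity), 1, max(cnA, cnB))
    CCF = AF * D / (purity * m)

The raw CCF is retained; the reported value is capped at 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import rank_sum_test
from .types import DELETERIOUS_IMPACTS, FilterThresholds, Impact, SegmentProfile

#: SNV identity key columns.
KEY = ["chrom", "pos", "ref", "alt"]


def snv_keys(table: pd.DataFrame) -> set[tuple]:
    return set(map(tuple, table[KEY].itertuples(index=False, name=None)))


def filter_snvs(calls: pd.DataFrame, thresholds: FilterThresholds | None = None) -> pd.DataFrame:
    """Keep calls meeting all quality filters (boundaries inclusive)."""
    t = thresholds or FilterThresholds()
    keep = (
        (calls["tumor_coverage"] >= t.min_tumor_coverage)
        & (calls["allelic_fraction"] >= t.min_af)
        & (calls["tumor_alt_reads"] >= t.min_alt_reads)
        & (calls["normal_alt_reads"] <= t.max_normal_alt)
    )
    return calls[keep].reset_index(drop=True)


def compute_tmb(filtered: pd.DataFrame, territory_mb: float) -> float:
    """High-quality SNV count per megabase of sequenced territory."""
    if territory_mb <= 0:
        raise ValueError(f"territory_mb must be > 0, got {territory_mb}")
    return len(filtered) / territory_mb


def select_deleterious(calls: pd.DataFrame) -> pd.DataFrame:
    """Keep calls with HIGH or MODERATE predicted impact."""
    impacts = []
    for label in calls["impact"]:
        try:
            impacts.append(Impact(label))
        except ValueError as exc:
            raise ValueError(f"unknown impact label: {label!r}") from exc
    keep = [i in DELETERIOUS_IMPACTS for i in impacts]
    return calls[keep].reset_index(drop=True)


@dataclass
class PairConcordance:
    """Shared/private partition of deleterious SNVs for one matched pair."""

    shared: set[tuple]
    private_pt: set[tuple]
    private_pdo: set[tuple]
    chi2_p: float

    @property
    def shared_fraction_pt(self) -> float:
        n = len(self.shared) + len(self.private_pt)
        return len(self.shared) / n if n else float("nan")

    @property
    def shared_fraction_pdo(self) -> float:
        n = len(self.shared) + len(self.private_pdo)
        return len(self.shared) / n if n else float("nan")


def partition_pair(pt: pd.DataFrame, pdo: pd.DataFrame) -> PairConcordance:
    """Partition a matched pair's SNVs into shared and private sets.

    The chi-squared statistic compares shared vs private counts between
    the two samples on a 2x2 table (no continuity correction; counts in
    the intended setting are large).
    """
    keys_pt, keys_pdo = snv_keys(pt), snv_keys(pdo)
    if not keys_pt and not keys_pdo:
        raise ValueError("both SNV tables are empty")
    shared = keys_pt & keys_pdo
    private_pt = keys_pt - shared
    private_pdo = keys_pdo - shared
    table = np.array(
        [
            [len(shared), len(private_pt)],
            [len(shared), len(private_pdo)],
        ]
    )
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        chi2_p = float("nan")
    else:
        chi2_p = float(stats.chi2_contingency(table, correction=False).pvalue)
    return PairConcordance(
        shared=shared, private_pt=private_pt, private_pdo=private_pdo, chi2_p=chi2_p
    )


@dataclass
class ClonalityRecord:
    """Purity/copy-number corrected clonality of one SNV."""

    key: tuple
    ccf: float  # reported, capped at 1
    ccf_raw: float
    multiplicity: int
    purity: float
    cn_a: int
    cn_b: int


def compute_clonality(
    snv: pd.Series | dict,
    purity: float,
    cn_at_locus: tuple[int, int],
) -> ClonalityRecord:
    """Cancer cell fraction of one SNV given purity and local copy number."""
    if purity <= 0:
        raise ValueError("purity must be > 0 to correct allelic fractions")
    cn_a, cn_b = cn_at_locus
    cn_t = cn_a + cn_b
    if cn_t < 1:
        raise ValueError("total copy number at locus must be >= 1")
    af = float(snv["allelic_fraction"])
    expected_dna = purity * cn_t + (1.0 - purity) * 2.0
    m = int(np.clip(np.floor(af * expected_dna / purity + 0.5), 1, max(cn_a, cn_b)))
    ccf_raw = af * expected_dna / (purity * m)
    ccf_raw = min(ccf_raw, 1.25)
    return ClonalityRecord(
        key=(snv["chrom"], snv["pos"], snv["ref"], snv["alt"]),
        ccf=min(ccf_raw, 1.0),
        ccf_raw=ccf_raw,
        multiplicity=m,
        purity=purity,
        cn_a=int(cn_a),
        cn_b=int(cn_b),
    )


def clonality_table(calls: pd.DataFrame, profile: SegmentProfile) -> pd.DataFrame:
    """Per-SNV clonality for one sample; copy number looked up per locus.

    SNV positions are 1-based; loci with no covering segment fall back to
    the diploid state (1, 1).
    """
    records = []
    for _, row in calls.iterrows():
        seg = profile.segment_at(row["chrom"], int(row["pos"]) - 1)
        if seg is None:
            cn = (1, 1)
        else:
            cn = (int(round(seg.cn_a)), int(round(seg.cn_b)))
        rec = compute_clonality(row, profile.purity, cn)
        records.append(
            {
                "chrom": row["chrom"],
                "pos": row["pos"],
                "ref": row["ref"],
                "alt": row["alt"],
                "gene": row.get("gene", ""),
                "ccf": rec.ccf,
                "ccf_raw": rec.ccf_raw,
                "multiplicity": rec.multiplicity,
            }
        )
    return pd.DataFrame(
        records,
        columns=["chrom", "pos", "ref", "alt", "gene", "ccf", "ccf_raw", "multiplicity"],
    )


def compare_af_distributions(shared, private) -> float:
    """Two-sided rank-sum p between shared and private allelic fractions."""
    shared = list(shared)
    private = list(private)
    if not shared or not private:
        raise ValueError("both AF groups must be non-empty")
    return rank_sum_test(shared, private)


def clonality_correlation(
    pt_clonality: pd.DataFrame, pdo_clonality: pd.DataFrame
) -> tuple[float, float]:
    """Pearson correlation of PT vs PDO clonality over shared SNVs."""
    merged = pt_clonality.merge(pdo_clonality, on=KEY, suffixes=("_pt", "_pdo"))
    if len(merged) < 3:
        raise ValueError(f"need >= 3 shared SNVs, found {len(merged)}")
    res = stats.pearsonr(merged["ccf_pt"], merged["ccf_pdo"])
    return float(res.statistic), float(res.pvalue)


@dataclass
class LongitudinalShift:
    """Clonality comparison between a baseline and a relapse sample."""

    p_clonality: float
    paired: bool
    lost_snvs: set[tuple]
    p_lost_vs_kept: float


def longitudinal_clonality_shift(
    baseline: pd.DataFrame, relapse: pd.DataFrame
) -> LongitudinalShift:
    """Compare clonality between longitudinal samples of one patient.

    Shared SNVs are compared with a two-sided paired Wilcoxon signed-rank
    test; with no shared SNVs an unpaired rank-sum test over all values is
    reported instead (with a warning). SNVs observed at baseline only
    ("lost") are compared against the conserved baseline SNVs with a
    rank-sum test.
    """
    if baseline.empty or relapse.empty:
        raise ValueError("both clonality tables must be non-empty")
    merged = baseline.merge(relapse, on=KEY, suffixes=("_base", "_rel"))
    if len(merged) > 0:
        diffs = merged["ccf_rel"] - merged["ccf_base"]
        if np.allclose(diffs, 0):
            p_clon = 1.0
        else:
            p_clon = float(
                stats.wilcoxon(
                    merged["ccf_base"], merged["ccf_rel"], alternative="two-sided"
                ).pvalue
            )
        paired = True
    else:
        warnings.warn("no shared SNVs; reporting unpaired clonality test", stacklevel=2)
        p_clon = rank_sum_test(baseline["ccf"], relapse["ccf"])
        paired = False

    lost = snv_keys(baseline) - snv_keys(relapse)
    base_keys = list(map(tuple, baseline[KEY].itertuples(index=False, name=None)))
    is_lost = [k in lost for k in base_keys]
    lost_ccf = baseline.loc[is_lost, "ccf"]
    kept_ccf = baseline.loc[[not x for x in is_lost], "ccf"]
    if len(lost_ccf) and len(kept_ccf):
        p_lk = rank_sum_test(lost_ccf, kept_ccf)
    else:
        p_lk = float("nan")
    return LongitudinalShift(
        p_clonality=p_clon, paired=paired, lost_snvs=lost, p_lost_vs_kept=p_lk
    )
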