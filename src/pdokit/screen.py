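"""Drug-screen normalization, hit calling, and response comparisons.

Raw luminescence readouts are normalized per sample against the matching
vehicle wells:

    z = (X_s - mean(X_v)) / SD(X_v)

where X_s is a treated replicate and X_v the vehicle replicates of the
drug's vehicle class (H2O for cisplatin/gemcitabine and their
combination, DMSO otherwise); SD is the sample (n-1) standard deviation.
Fold-change is readout / mean vehicle readout and growth inhibition is
1 - fold-change.

A drug is called a hit on a sample when its mean z-score is <= -1.5 and
its Dunnett many-to-one adjusted p-value (vs the vehicle, after a
one-way ANOVA across all conditions sharing that vehicle class) is
<= 0.05. Both thresholds are inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import rank_sum_test
from .types import PlateData, VehicleClass

#: z-score hit threshold (inclusive).
HIT_Z = -1.5
#: adjusted-p hit threshold (inclusive).
HIT_P = 0.05
# internal seed for the randomized multivariate-t integration in Dunnett
_DUNNETT_SEED = 20230418


@dataclass
class DrugResponse:
    """Normalized response of one sample to one drug condition."""

    sample_id: str
    drug: str
    vehicle_class: VehicleClass
    z_scores: list[float]
    fold_changes: list[float]
    growth_inhibition: list[float]
    mean_z: float = field(init=False)
    anova_p: float = float("nan")
    adj_p: float = float("nan")
    hit: bool = False

    def __post_init__(self) -> None:
        self.mean_z = float(np.mean(self.z_scores))


def _vehicle_stats(plate: PlateData, vc: VehicleClass) -> tuple[np.ndarray, float, float]:
    veh = np.array(plate.vehicle_readouts(vc), dtype=float)
    if veh.size < 2:
        raise ValueError(f"{plate.sample_id}: vehicle {vc.value} needs >= 2 replicates")
    sd = float(np.std(veh, ddof=1))
    if sd == 0:
        raise ValueError(f"{plate.sample_id}: vehicle {vc.value} SD is zero")
    return veh, float(np.mean(veh)), sd


def normalize_plate(plate: PlateData) -> list[DrugResponse]:
    """z-score, fold-change and growth inhibition per treated replicate."""
    responses = []
    for drug, vc in plate.drug_conditions():
        _, mu_v, sd_v = _vehicle_stats(plate, vc)
        if mu_v <= 0:
            raise ValueError(f"{plate.sample_id}: vehicle {vc.value} mean <= 0")
        readouts = np.array(plate.condition_readouts(drug), dtype=float)
        z = (readouts - mu_v) / sd_v
        fc = readouts / mu_v
        responses.append(
            DrugResponse(
                sample_id=plate.sample_id,
                drug=drug,
                vehicle_class=vc,
                z_scores=list(z),
                fold_changes=list(fc),
                growth_inhibition=list(1.0 - fc),
            )
        )
    return responses


def growth_inhibition(plate: PlateData) -> dict[str, list[float]]:
    """Per-replicate growth inhibition (1 - fold-change) per drug condition."""
    return {r.drug: r.growth_inhibition for r in normalize_plate(plate)}


def call_hits(plate: PlateData, responses: list[DrugResponse] | None = None) -> list[DrugResponse]:
    """Annotate responses with ANOVA/Dunnett p-values and the hit flag.

    For each vehicle class on the plate: a one-way ANOVA across the
    vehicle and all drug conditions referencing it, then Dunnett
    many-to-one comparisons of every drug against the vehicle. Singleton
    conditions are excluded with a warning (the plate validator normally
    prevents them).
    """
    responses = responses if responses is not None else normalize_plate(plate)
    by_class: dict[VehicleClass, list[DrugResponse]] = {}
    for r in responses:
        by_class.setdefault(r.vehicle_class, []).append(r)

    for vc, group in by_class.items():
        veh, _, _ = _vehicle_stats(plate, vc)
        testable = []
        for r in group:
            if len(r.z_scores) < 2:
                warnings.warn(
                    f"{plate.sample_id}: condition {r.drug!r} has a single replicate; "
                    "excluded from hit testing",
                    stacklevel=2,
                )
                continue
            testable.append(r)
        if not testable:
            continue
        samples = [np.array(plate.condition_readouts(r.drug), dtype=float) for r in testable]
        anova_p = float(stats.f_oneway(veh, *samples).pvalue)
        dunnett = stats.dunnett(
            *samples,
            control=veh,
            alternative="two-sided",
            random_state=np.random.default_rng(_DUNNETT_SEED),
        )
        for r, adj_p in zip(testable, dunnett.pvalue):
            r.anova_p = anova_p
            r.adj_p = float(adj_p)
            r.hit = bool(r.mean_z <= HIT_Z and r.adj_p <= HIT_P)
    return responses


def compare_samples_for_drug(z_a, z_b) -> float:
    """Two-sided rank-sum p between two samples' replicate z-scores."""
    if len(z_a) < 2 or len(z_b) < 2:
        raise ValueError("each group needs >= 2 replicates")
    return rank_sum_test(z_a, z_b)


def mean_z_matrix(responses: list[DrugResponse]) -> pd.DataFrame:
    """Samples x drugs matrix of mean z-scores (NaN where unmeasured)."""
    rows: dict[str, dict[str, float]] = {}
    for r in responses:
        rows.setdefault(r.sample_id, {})[r.drug] = r.mean_z
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def interdrug_correlation(mean_z: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlation of drug effects across samples.

    Pairwise-complete; entries with fewer than 3 complete sample pairs
    are masked (NaN).
    """
    drugs = list(mean_z.columns)
    n = len(drugs)
    r = pd.DataFrame(np.full((n, n), np.nan), index=drugs, columns=drugs)
    p = r.copy()
    for i, a in enumerate(drugs):
        r.loc[a, a], p.loc[a, a] = 1.0, 0.0
        for b in drugs[i + 1 :]:
            sub = mean_z[[a, b]].dropna()
            if len(sub) < 3:
                continue
            if sub[a].nunique() < 2 or sub[b].nunique() < 2:
                continue
            res = stats.pearsonr(sub[a], sub[b])
            r.loc[a, b] = r.loc[b, a] = float(res.statistic)
            p.loc[a, b] = p.loc[b, a] = float(res.pvalue)
    return r, p


def formation_rate_test(
    successes_a: int, total_a: int, successes_b: int, total_b: int
) -> float:
    """Two-sided Fisher exact p for two formation-success proportions."""
    if min(successes_a, total_a, successes_b, total_b) < 0:
        raise ValueError("counts must be non-negative")
    if successes_a > total_a or successes_b > total_b:
        raise ValueError("successes cannot exceed totals")
    if total_a == 0 or total_b == 0:
        raise ValueError("totals must be > 0")
    table = [
        [successes_a, total_a - successes_a],
        [successes_b, total_b - successes_b],
    ]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])
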