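"""Pharmacogenomic association between binary genomic features and drug
response, with multiplicity control.

Features are sample-level indicators: a gene carries a deleterious SNV;
a gene is gained/amplified (total copy number above the sample's rounded
allele-specific ploidy, or >= ploidy + 3 for amplification), hemi-deleted
(1, 0) or homo-deleted (0, 0); or a pathway is mutation-enriched in the
sample (q < 0.2).

The association model is a linear mixed model on replicate-level
z-scores with the feature as the fixed effect and a per-sample random
intercept (REML). The reported effect is the fixed-effect coefficient in
z-score units with a two-sided Wald p. Degenerate designs (one replicate
per sample, singular fits) fall back to an ordinary least-squares fit on
per-sample mean z, where the coefficient equals the two-group mean
difference. FDR is controlled per drug across features with
Benjamini-Hochberg at the 10% level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import bh_adjust
from .copynumber import GeneCnMatrix
from .enrichment import EnrichmentResult
from .snv import select_deleterious

#: FDR significance level.
FDR_LEVEL = 0.10


def build_features(
    snv_tables: dict[str, pd.DataFrame],
    cn_matrix: GeneCnMatrix,
    asp_by_sample: dict[str, float],
    enrichment: dict[str, EnrichmentResult] | None = None,
    q_cut: float = 0.2,
    amp_offset: int = 3,
) -> pd.DataFrame:
    """Samples x features binary indicator matrix (NaN = sample missing).

    Feature names are ``GENE|snv``, ``GENE|gain``, ``GENE|amp``,
    ``GENE|hemi_del``, ``GENE|homo_del`` and ``SET|pathway``.
    """
    samples = sorted(
        set(snv_tables) | set(cn_matrix.samples) | set(enrichment or {})
    )
    columns: dict[str, dict[str, float]] = {}

    def put(feature: str, sample: str, value: float) -> None:
        columns.setdefault(feature, {})[sample] = value

    # deleterious-SNV indicators
    all_genes = sorted(
        {g for tbl in snv_tables.values() for g in select_deleterious(tbl)["gene"]}
    )
    for sid in samples:
        if sid not in snv_tables:
            continue
        mutated = set(select_deleterious(snv_tables[sid])["gene"])
        for gene in all_genes:
            put(f"{gene}|snv", sid, float(gene in mutated))

    # copy-number category indicators
    for sid in cn_matrix.samples:
        if sid not in asp_by_sample:
            continue
        baseline = int(round(asp_by_sample[sid]))
        i = cn_matrix.index_of(sid)
        for j, gene in enumerate(cn_matrix.genes):
            a, b = int(cn_matrix.cn_a[i, j]), int(cn_matrix.cn_b[i, j])
            total = a + b
            put(f"{gene}|homo_del", sid, float((a, b) == (0, 0)))
            put(f"{gene}|hemi_del", sid, float((a, b) == (1, 0)))
            put(f"{gene}|gain", sid, float(total > baseline))
            put(f"{gene}|amp", sid, float(total >= baseline + amp_offset))

    # pathway-enrichment indicators
    if enrichment:
        terms = sorted(
            {t for res in enrichment.values() for t in res.table["set_name"]}
        )
        for sid, res in enrichment.items():
            sig = res.significant_sets(q_cut)
            for term in terms:
                put(f"{term}|pathway", sid, float(term in sig))

    features = pd.DataFrame(index=samples, columns=sorted(columns), dtype=float)
    for feature, values in columns.items():
        for sid, v in values.items():
            features.loc[sid, feature] = v
    return features


@dataclass
class AssociationResult:
    feature: str
    drug: str
    effect: float  # fixed-effect coefficient, z-score units
    p: float
    n_mutated: int
    n_wildtype: int
    method: str  # "lmm" or "ols"
    fdr: float = float("nan")
    significant: bool = False
    reason: str = ""

    @property
    def testable(self) -> bool:
        return not self.reason


def lmm_association(
    feature: pd.Series,
    z_by_sample: dict[str, list[float]],
    feature_name: str = "",
    drug: str = "",
) -> AssociationResult:
    """Fit replicate z ~ feature with a per-sample random intercept."""
    rows = []
    for sid, zs in z_by_sample.items():
        x = feature.get(sid, np.nan)
        if pd.isna(x):
            continue
        for z in zs:
            rows.append((sid, float(x), float(z)))
    if not rows:
        raise ValueError("no overlapping samples between feature and responses")
    df = pd.DataFrame(rows, columns=["sample", "x", "z"])
    per_level = df.groupby("x")["sample"].nunique()
    n_mut = int(per_level.get(1.0, 0))
    n_wt = int(per_level.get(0.0, 0))
    if len(per_level) < 2 or per_level.min() < 2:
        return AssociationResult(
            feature=feature_name,
            drug=drug,
            effect=float("nan"),
            p=float("nan"),
            n_mutated=n_mut,
            n_wildtype=n_wt,
            method="none",
            reason="fewer than 2 samples per feature level",
        )

    max_reps = df.groupby("sample").size().max()
    if max_reps >= 2:
        result = _fit_mixed(df)
        if result is not None:
            effect, p = result
            return AssociationResult(
                feature=feature_name, drug=drug, effect=effect, p=p,
                n_mutated=n_mut, n_wildtype=n_wt, method="lmm",
            )
        warnings.warn(
            f"singular mixed-model fit for {feature_name!r}/{drug!r}; "
            "falling back to per-sample-mean linear model",
            stacklevel=2,
        )
    effect, p = _fit_ols(df)
    return AssociationResult(
        feature=feature_name, drug=drug, effect=effect, p=p,
        n_mutated=n_mut, n_wildtype=n_wt, method="ols",
    )


def _fit_mixed(df: pd.DataFrame) -> tuple[float, float] | None:
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    exog = sm.add_constant(df[["x"]])
    # lbfgs first; if the random-effect variance collapses to zero its score
    # step can hit a singular matrix, so retry with gradient-free powell
    for method in ("lbfgs", "powell"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", ConvergenceWarning)
                warnings.filterwarnings(
                    "ignore", message="Random effects covariance is singular"
                )
                model = sm.MixedLM(df["z"], exog, groups=df["sample"])
                fit = model.fit(reml=True, method=method)
        except (np.linalg.LinAlgError, ValueError, ConvergenceWarning):
            continue
        effect = float(fit.params["x"])
        p = float(fit.pvalues["x"])
        if np.isfinite(p):
            return effect, p
    return None


def _fit_ols(df: pd.DataFrame) -> tuple[float, float]:
    import statsmodels.api as sm

    means = df.groupby("sample").agg(x=("x", "first"), z=("z", "mean"))
    exog = sm.add_constant(means[["x"]])
    fit = sm.OLS(means["z"], exog).fit()
    return float(fit.params["x"]), float(fit.pvalues["x"])


def associate_all(
    features: pd.DataFrame,
    z_by_drug: dict[str, dict[str, list[float]]],
) -> list[AssociationResult]:
    """Test every feature against every drug; FDR adjusted per drug."""
    results: list[AssociationResult] = []
    for drug, z_by_sample in z_by_drug.items():
        for feature_name in features.columns:
            results.append(
                lmm_association(
                    features[feature_name], z_by_sample,
                    feature_name=feature_name, drug=drug,
                )
            )
    return adjust_fdr(results)


def adjust_fdr(results: list[AssociationResult], level: float = FDR_LEVEL) -> list[AssociationResult]:
    """Benjamini-Hochberg per drug across features; flags fdr <= level."""
    by_drug: dict[str, list[AssociationResult]] = {}
    for r in results:
        if r.testable and np.isfinite(r.p):
            by_drug.setdefault(r.drug, []).append(r)
    for drug, group in by_drug.items():
        fdrs = bh_adjust([r.p for r in group])
        for r, fdr in zip(group, fdrs):
            r.fdr = float(fdr)
            r.significant = bool(fdr <= level)
    return results


def results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature": r.feature,
                "drug": r.drug,
                "effect": r.effect,
                "p": r.p,
                "fdr": r.fdr,
                "significant": r.significant,
                "n_mutated": r.n_mutated,
                "n_wildtype": r.n_wildtype,
                "method": r.method,
                "reason": r.reason,
            }
            for r in results
        ]
    )
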