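"""Chemotype enrichment workflow (CTEW).

For each binary substructure feature a 2x2 contingency table against the
binary activity labels is built, from which the odds ratio
TP*TN/(FN*FP), a one-sided Fisher exact p-value (enrichment direction),
the per-chemotype balanced accuracy and the positive predictive value
are computed. Chemotypes passing the odds/p thresholds are flagged as
enriched; enriched sets support a simple >=k-hits rule classifier and a
cross-endpoint relevance tiering by PPV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .featurization import FeatureMatrix


@dataclass(frozen=True)
class ContingencyCounts:
    """Chemotype-vs-activity 2x2 table.

    tp: carries the chemotype, active. fp: carries it, inactive.
    fn: lacks it, active. tn: lacks it, inactive.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class EnrichmentThresholds:
    """Enrichment filter: odds ratio >= odds_min and p < p_max.

    The default significance level is 0.05; p_max is configurable for
    deliberately permissive screens.
    """

    odds_min: float = 3.0
    p_max: float = 0.05

    def __post_init__(self) -> None:
        if self.odds_min <= 0:
            raise ValueError("odds_min must be positive")
        if not 0 < self.p_max <= 1:
            raise ValueError("p_max must be in (0, 1]")


def contingency_for_feature(
    feature_bits: np.ndarray, labels: np.ndarray
) -> ContingencyCounts:
    """Count the 2x2 table of one binary feature against binary labels."""
    bits = np.asarray(feature_bits).astype(int)
    y = np.asarray(labels).astype(int)
    if bits.shape != y.shape:
        raise ValueError("feature and label vectors must have equal length")
    if not np.isin(bits, (0, 1)).all() or not np.isin(y, (0, 1)).all():
        raise ValueError("feature and label vectors must be binary")
    return ContingencyCounts(
        tp=int(((bits == 1) & (y == 1)).sum()),
        fp=int(((bits == 1) & (y == 0)).sum()),
        fn=int(((bits == 0) & (y == 1)).sum()),
        tn=int(((bits == 0) & (y == 0)).sum()),
    )


def odds_ratio(c: ContingencyCounts, haldane: bool = False) -> float:
    """Association strength TP*TN/(FN*FP).

    A zero denominator with a positive numerator gives +inf; 0/0 gives
    NaN (undefined, treated downstream as not enriched). ``haldane``
    applies the +0.5 continuity correction to every cell instead.
    """
    tp, fp, fn, tn = c.tp, c.fp, c.fn, c.tn
    if haldane:
        return ((tp + 0.5) * (tn + 0.5)) / ((fn + 0.5) * (fp + 0.5))
    num = tp * tn
    den = fn * fp
    if den == 0:
        return float("inf") if num > 0 else float("nan")
    return num / den


def fisher_exact_one_sided(c: ContingencyCounts) -> float:
    """One-sided Fisher exact p for enrichment.

    Probability, under the hypergeometric null with fixed margins, of a
    table with at least the observed TP count: P(X >= tp) with
    X ~ Hypergeom(N, K=tp+fn actives, n=tp+fp carriers). Exact.
    """
    n_total = c.n
    k_active = c.tp + c.fn
    n_carrier = c.tp + c.fp
    if n_total == 0:
        return 1.0
    return float(hypergeom.sf(c.tp - 1, n_total, k_active, n_carrier))


def positive_predictive_value(c: ContingencyCounts) -> float:
    """Fraction of chemotype-bearing compounds that are active: TP/(TP+FP).

    NaN when no compound carries the chemotype.
    """
    if c.tp + c.fp == 0:
        return float("nan")
    return c.tp / (c.tp + c.fp)


def chemotype_balanced_accuracy(c: ContingencyCounts) -> float:
    """(SE + SP)/2 treating chemotype presence as a positive prediction."""
    se = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else float("nan")
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else float("nan")
    return (se + sp) / 2


def relevance_tier(ppv: float) -> str:
    """PPV tier: >=0.70 high, (0.50, 0.70) moderate, <=0.50 poor."""
    if np.isnan(ppv):
        return "not_evaluable"
    if ppv >= 0.70:
        return "high"
    if ppv > 0.50:
        return "moderate"
    return "poor"


def is_enriched(odds: float, p_value: float, th: EnrichmentThresholds) -> bool:
    """Pure threshold test; NaN odds (0/0 table) never qualifies."""
    return bool(odds >= th.odds_min and p_value < th.p_max)


def run_enrichment(
    fm: FeatureMatrix,
    labels: np.ndarray,
    th: EnrichmentThresholds | None = None,
) -> pd.DataFrame:
    """Per-feature enrichment table.

    One row per feature with the contingency counts, odds ratio,
    one-sided exact p, balanced accuracy, PPV, relevance tier and the
    enriched flag; sorted by descending odds then ascending p.
    """
    th = th or EnrichmentThresholds()
    if not fm.binary:
        raise ValueError("enrichment requires a binary feature matrix")
    y = np.asarray(labels).astype(int)
    if len(y) != fm.n_compounds:
        raise ValueError("labels must align with matrix rows")
    if fm.n_features and len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")

    rows = []
    for j, name in enumerate(fm.feature_names):
        c = contingency_for_feature(fm.values[:, j], y)
        odds = odds_ratio(c)
        p = fisher_exact_one_sided(c)
        ppv = positive_predictive_value(c)
        rows.append(
            {
                "ct_name": name,
                "tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn,
                "odds": odds,
                "p_value": p,
                "ba": chemotype_balanced_accuracy(c),
                "ppv": ppv,
                "enriched": is_enriched(odds, p, th),
                "tier": relevance_tier(ppv),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["ct_name", "tp", "fp", "fn", "tn", "odds", "p_value", "ba",
                 "ppv", "enriched", "tier"],
    )
    if len(table):
        # NaN odds (0/0 tables) sort last; +inf first.
        sort_key = table["odds"].fillna(-np.inf)
        table = (
            table.assign(_k=sort_key)
            .sort_values(["_k", "p_value"], ascending=[False, True], kind="mergesort")
            .drop(columns="_k")
            .reset_index(drop=True)
        )
    return table


def rule_based_classifier(
    fingerprints: FeatureMatrix,
    enriched_cts: list[str],
    min_hits: int = 1,
) -> np.ndarray:
    """Predict positive iff a compound carries >= min_hits enriched chemotypes."""
    if min_hits < 1:
        raise ValueError("min_hits must be >= 1")
    if not enriched_cts:
        warnings.warn("empty enriched chemotype set: all predictions negative")
        return np.zeros(fingerprints.n_compounds, dtype=int)
    idx = [fingerprints.feature_names.index(name) for name in enriched_cts]
    hits = fingerprints.values[:, idx].sum(axis=1)
    return (hits >= min_hits).astype(int)


def balanced_accuracy(pred: np.ndarray, labels: np.ndarray) -> float:
    """Mean of sensitivity and specificity of binary predictions."""
    y = np.asarray(labels).astype(int)
    p = np.asarray(pred).astype(int)
    if p.shape != y.shape:
        raise ValueError("prediction and label vectors must have equal length")
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    se = ((p == 1) & (y == 1)).sum() / (y == 1).sum()
    sp = ((p == 0) & (y == 0)).sum() / (y == 0).sum()
    return float((se + sp) / 2)


def cross_endpoint_relevance(
    ct_name: str,
    fingerprints_b: FeatureMatrix,
    labels_b: np.ndarray,
) -> dict:
    """Relevance of a chemotype (enriched in endpoint A) for endpoint B.

    Computes the chemotype's PPV on dataset B and assigns the tier
    (high / moderate / poor); a chemotype matching zero compounds in B
    is ``not_evaluable``.
    """
    if ct_name not in fingerprints_b.feature_names:
        raise ValueError(f"chemotype {ct_name!r} absent from endpoint-B features")
    j = fingerprints_b.feature_names.index(ct_name)
    c = contingency_for_feature(fingerprints_b.values[:, j], labels_b)
    ppv = positive_predictive_value(c)
    return {"ct_name": ct_name, "ppv": ppv, "tier": relevance_tier(ppv), "counts": c}
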