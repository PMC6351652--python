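"""Inverse-variance-weighted fixed-effects meta-analysis across waves.

Per-wave effect estimates for one trait are pooled with weights 1/SE^2
under a common-effect assumption; the pooled z is referred to the standard
normal (two-sided).  Cochran's Q is reported as a heterogeneity diagnostic.
Experiment-wide significance uses a Bonferroni threshold over the number of
topics tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .association import AssociationResult, P_FLOOR

__all__ = [
    "MetaResult",
    "fixed_effects_meta",
    "bonferroni_threshold",
    "select_significant_topics",
]


@dataclass
class MetaResult:
    """Pooled association for one trait across genotyping waves."""

    trait_id: str
    beta_pooled: float
    se_pooled: float
    z: float
    p: float
    q_het: float
    df_het: int
    n_waves_used: int
    n_waves_skipped: int = 0
    significant: bool = False

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta_pooled))


def fixed_effects_meta(results: list[AssociationResult]) -> MetaResult:
    """Pool per-wave results for a single trait.

    Waves with status other than ``ok`` are excluded from the pool and
    counted in ``n_waves_skipped``.  With w_i = 1/se_i^2:
    beta_pooled = sum(w_i b_i)/sum(w_i), se_pooled = sum(w_i)^(-1/2),
    z = beta_pooled/se_pooled with a two-sided normal p, and
    Q = sum(w_i (b_i - beta_pooled)^2) on n_waves_used - 1 df.
    """
    if not results:
        raise ValueError("no results to pool")
    trait_ids = {r.trait_id for r in results}
    if len(trait_ids) > 1:
        raise ValueError(f"results mix traits: {sorted(trait_ids)}")
    usable = [r for r in results if r.status == "ok"]
    skipped = len(results) - len(usable)
    if not usable:
        raise ValueError(
            f"no usable wave for trait {results[0].trait_id!r}"
        )
    betas = np.array([r.beta for r in usable])
    ses = np.array([r.se for r in usable])
    w = 1.0 / ses**2
    beta_pooled = float(np.sum(w * betas) / np.sum(w))
    se_pooled = float(1.0 / math.sqrt(np.sum(w)))
    z = beta_pooled / se_pooled
    p = max(float(2.0 * norm.sf(abs(z))), P_FLOOR)
    q = float(np.sum(w * (betas - beta_pooled) ** 2))
    return MetaResult(
        trait_id=results[0].trait_id,
        beta_pooled=beta_pooled,
        se_pooled=se_pooled,
        z=float(z),
        p=p,
        q_het=q,
        df_het=len(usable) - 1,
        n_waves_used=len(usable),
        n_waves_skipped=skipped,
    )


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return alpha / n_tests


def select_significant_topics(
    meta: list[MetaResult], threshold: float
) -> list[str]:
    """Trait ids with pooled p strictly below the threshold, p ascending."""
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    hits = [m for m in meta if m.p < threshold]
    for m in meta:
        m.significant = m.p < threshold
    return [m.trait_id for m in sorted(hits, key=lambda m: m.p)]
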