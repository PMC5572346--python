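"""Pathway mapping and dual-test enrichment.

Entities (EC numbers or compound ids) are mapped to pathways; a pathway is
called enriched in a subset relative to a background when it passes BOTH an
exact upper-tail hypergeometric over-representation test and a Pearson
chi-square goodness-of-fit test, each at p < alpha (default 0.05).  No
multiple-testing correction is applied to the dual test by default; an
optional Benjamini-Hochberg correction on the hypergeometric p-values can be
switched on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from rhizoscope._errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    pathway_id: str
    k: int  # subset members in the pathway
    n: int  # subset size (pathway-mapped)
    K: int  # background members in the pathway
    N: int  # background size (pathway-mapped)
    p_hyper: float
    p_chisq: float
    enriched: bool


def map_to_pathways(
    entities: Iterable[str], pathway_map: Mapping[str, Iterable[str]]
) -> tuple[dict[str, frozenset[str]], frozenset[str]]:
    """Group entities by pathway; an entity in several pathways is counted in
    each.  Returns (pathway -> entity set, unmapped entities)."""
    groups: dict[str, set[str]] = {}
    unmapped: set[str] = set()
    for e in entities:
        pws = pathway_map.get(e)
        if not pws:
            unmapped.add(e)
            continue
        for pw in pws:
            groups.setdefault(pw, set()).add(e)
    return {pw: frozenset(s) for pw, s in groups.items()}, frozenset(unmapped)


def hypergeom_test(k: int, n: int, K: int, N: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= k) of drawing k or
    more pathway members in a subset of n from a background of N containing
    K members."""
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValidationError(
            f"hypergeom_test: invalid bounds k={k}, n={n}, K={K}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def chisq_fit(
    observed: Sequence[int | float], background_proportions: Sequence[float]
) -> float:
    """Pearson chi-square goodness of fit of subset category counts against
    expected = background proportion x subset size, df = #categories - 1.

    Categories with expected count < 5 trigger a logged warning (the
    asymptotic approximation weakens there)."""
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(background_proportions, dtype=float)
    if obs.shape != props.shape:
        raise ValidationError("chisq_fit: observed and proportions differ in length")
    total = obs.sum()
    if total <= 0:
        raise ValidationError("chisq_fit: all-zero subset counts")
    expected = props / props.sum() * total
    keep = expected > 0
    if keep.sum() < 2:
        raise ValidationError("chisq_fit: need >= 2 categories with nonzero expected count")
    if obs[~keep].sum() > 0:
        raise ValidationError("chisq_fit: observed counts in zero-expectation categories")
    obs, expected = obs[keep], expected[keep]
    if (expected < 5).any():
        logger.warning(
            "chisq_fit: %d cell(s) with expected count < 5", int((expected < 5).sum())
        )
    stat, p = stats.chisquare(obs, expected)
    return float(p)


def enriched_pathways(
    subset: Iterable[str],
    background: Iterable[str],
    pathway_map: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
    fdr: bool = False,
) -> list[EnrichmentResult]:
    """Dual-test pathway enrichment of a subset against its background.

    Per pathway, the hypergeometric test asks whether the subset over-draws
    the pathway's background members; the chi-square test compares the
    subset's in/out-of-pathway split with the background proportions.  A
    pathway is enriched iff both p-values are below ``alpha``.  With
    ``fdr=True`` the hypergeometric p-values are Benjamini-Hochberg adjusted
    before thresholding (off by default).
    """
    subset = frozenset(subset)
    background = frozenset(background)
    if not subset <= background:
        raise ValidationError("enriched_pathways: subset must be contained in background")
    bg_groups, _ = map_to_pathways(background, pathway_map)
    sub_groups, _ = map_to_pathways(subset, pathway_map)
    mapped_bg = frozenset().union(*bg_groups.values()) if bg_groups else frozenset()
    mapped_sub = subset & mapped_bg
    N, n = len(mapped_bg), len(mapped_sub)

    results: list[EnrichmentResult] = []
    for pw in sorted(bg_groups):
        K = len(bg_groups[pw])
        k = len(sub_groups.get(pw, frozenset()) & mapped_sub)
        p_h = hypergeom_test(k, n, K, N) if n > 0 else 1.0
        if n > 0 and 0 < K < N:
            p_c = chisq_fit([k, n - k], [K / N, (N - K) / N])
        else:
            p_c = 1.0
        results.append(EnrichmentResult(pw, k, n, K, N, p_h, p_c, False))

    if results:
        p_hyper = [r.p_hyper for r in results]
        adj = multipletests(p_hyper, method="fdr_bh")[1] if fdr else p_hyper
        for r, ph in zip(results, adj):
            r.enriched = bool(ph < alpha and r.p_chisq < alpha)
    return results
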