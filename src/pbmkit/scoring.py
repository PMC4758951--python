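"""In-vivo scoring: promoter affinities, GO association, ChIP saturation.

Total promoter affinity sums the model's relative affinity over every
window (both strands unless the model's strand policy restricts them) and
every binding mode, weighted by relative Ka.  Genes ranked by this score
are tested for Gene Ontology association with a Wilcoxon-Mann-Whitney
rank-sum test, Bonferroni-corrected over the categories tested.  ChIP
enrichments are related to model affinities through a basic equilibrium
occupancy curve with a single free-protein parameter,

    enrichment ~ scale * P*a / (P*a + 1),

which accounts for saturation of high-affinity sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .core import encode_sequences, view_codes, view_ddG
from .multimode import BindingModeSet

logger = logging.getLogger(__name__)

__all__ = [
    "PromoterAffinity",
    "GOResult",
    "ChipSaturationFit",
    "total_promoter_affinity",
    "score_promoters",
    "go_association",
    "fit_chip_saturation",
    "trimmed_group_means",
]


@dataclass
class PromoterAffinity:
    gene_id: str
    total_affinity: float


@dataclass
class GOResult:
    category: str
    n_in: int
    U_statistic: float
    p_raw: float
    p_bonferroni: float


@dataclass
class ChipSaturationFit:
    free_protein: float
    scale: float
    rmse: float


def total_promoter_affinity(seq: str, modeset: BindingModeSet) -> float:
    """Sliding-window total affinity of one sequence:
    sum_m relKa_m * sum_v exp(-ddG_m(S_v)/RT) over all views (no
    positional bias; that is a PBM artifact, not a property of the TF)."""
    total = 0.0
    any_fit = False
    for model, ka in zip(modeset.modes, modeset.rel_ka):
        if model.L > len(seq):
            continue
        any_fit = True
        codes = view_codes(
            encode_sequences([seq]), model.L, model.strand_policy
        )
        total += ka * float(np.exp(-view_ddG(codes, model)).sum())
    if not any_fit:
        logger.warning("sequence shorter than every mode; affinity 0")
        return 0.0
    return total


def score_promoters(
    promoters: Dict[str, str], modeset: BindingModeSet
) -> List[PromoterAffinity]:
    return [
        PromoterAffinity(g, total_promoter_affinity(s, modeset))
        for g, s in promoters.items()
    ]


def go_association(
    affinities: Sequence[PromoterAffinity],
    annotation: Dict[str, Sequence[str]],
    alternative: str = "two-sided",
    exact_max_n: int = 10,
) -> List[GOResult]:
    """Rank-sum association of per-category promoter affinities.

    For each category, in-category gene affinities are compared with all
    remaining genes by the Mann-Whitney U test (exact enumeration when
    the smaller group has <= `exact_max_n` members and the total stays
    modest, otherwise the tie-corrected normal approximation).  Categories with fewer than 2 genes on either
    side are skipped.  Bonferroni correction uses the number of categories
    actually tested.  Results are sorted by raw p-value.
    """
    aff = {a.gene_id: a.total_affinity for a in affinities}
    missing = [g for g in annotation if g not in aff]
    if missing:
        logger.info(
            "%d annotated gene(s) missing from affinities; excluded", len(missing)
        )
    categories: Dict[str, List[float]] = {}
    for g, cats in annotation.items():
        if g not in aff:
            continue
        for c in cats:
            categories.setdefault(c, []).append(aff[g])
    values = np.array(list(aff.values()))
    tested: List[Tuple[str, int, float, float]] = []
    for c, in_vals in categories.items():
        n_in = len(in_vals)
        n_out = len(values) - n_in
        if n_in < 2 or n_out < 2:
            logger.info("category %s skipped (n_in=%d n_out=%d)", c, n_in, n_out)
            continue
        in_arr = np.asarray(in_vals)
        out_arr = _complement(values, in_arr)
        method = (
            "exact"
            if (min(n_in, n_out) <= exact_max_n and n_in + n_out <= 5 * exact_max_n)
            else "asymptotic"
        )
        res = stats.mannwhitneyu(
            in_arr, out_arr, alternative=alternative, method=method
        )
        tested.append((c, n_in, float(res.statistic), float(res.pvalue)))
    m = len(tested)
    results = [
        GOResult(c, n_in, U, p, min(1.0, p * m)) for c, n_in, U, p in tested
    ]
    results.sort(key=lambda r: r.p_raw)
    return results


def _complement(values: np.ndarray, in_arr: np.ndarray) -> np.ndarray:
    """Out-of-category values: all values minus the in-category multiset."""
    out = list(values)
    for v in in_arr:
        out.remove(v)
    return np.asarray(out)


def fit_chip_saturation(
    rel_affinity: Sequence[float], enrichment: Sequence[float]
) -> ChipSaturationFit:
    """Fit the single-parameter equilibrium occupancy curve to per-site
    ChIP enrichments (normalised to max 1 before fitting)."""
    a = np.asarray(rel_affinity, dtype=float)
    e = np.asarray(enrichment, dtype=float)
    if a.size < 3 or np.unique(a).size < 3:
        raise ValueError("need >= 3 sites with distinct affinities")
    scale0 = e.max()
    e = e / scale0

    # parametrised by the low-concentration slope (always identifiable)
    # and P, so the linear regime P -> 0 is a well-behaved boundary
    def f(a, slope, P):
        return slope * a / (1.0 + P * a)

    med = np.median(a[a > 0]) if (a > 0).any() else 1.0
    p0 = [e.max() / max(a.max(), 1e-12), 1.0 / med]
    (slope, P), _ = optimize.curve_fit(
        f, a, e, p0=p0, bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10000
    )
    pred = f(a, slope, P)
    rmse = float(np.sqrt(np.mean((e - pred) ** 2)))
    P = max(P, 1e-12)
    return ChipSaturationFit(
        free_protein=float(P), scale=float(slope / P * scale0), rmse=rmse
    )


def trimmed_group_means(
    keys: Sequence[str], values: Sequence[float], trim: float = 0.10,
    min_count: int = 1,
) -> Dict[str, float]:
    """Per-group trimmed means (e.g. ChIP fold-enrichment per 10-mer):
    within each key group, drop the floor(trim*n) smallest and largest
    values and average the rest; groups below `min_count` are dropped."""
    from .seed import trimmed_mean

    groups: Dict[str, List[float]] = {}
    for k, v in zip(keys, values):
        groups.setdefault(k, []).append(float(v))
    return {
        k: trimmed_mean(v, trim)
        for k, v in groups.items()
        if len(v) >= min_count
    }
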