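"""Community structure and biodiversity metrics for replicated quadrat surveys.

Implements the classical descriptors used to compare motile-invertebrate
communities between sites: Sorensen similarity between taxon sets, Shannon
diversity H' (log base 2 by default), Pielou evenness J' = H'/H'max, densities
per m^2, trophic-group composition, plus the univariate site comparisons
(two-sample t-tests and Kruskal-Wallis with a Dunn-type post-hoc used to decide
whether ecologically related groups may be pooled).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    DegenerateInputError,
    InsufficientDataError,
    UndefinedInputError,
)

TROPHIC_GROUPS = (
    "herbivore",
    "herbivore/detritivore",
    "carnivore",
    "omnivore/detritivore",
    "filter-feeder",
)
UNASSIGNED = "unassigned"


@dataclass
class CommunityTable:
    """Taxon counts for one replicate quadrat at one site.

    Parameters
    ----------
    site, replicate : str
        Labels identifying the sample.
    quadrat_area : float
        Sampled surface in m^2 (0.09 for a 30 x 30 cm quadrat). Must be > 0.
    counts : mapping taxon -> int
        Non-negative abundance of each taxon in the quadrat.
    trophic_group : mapping taxon -> str
        Trophic-group assignment per taxon; taxa with positive counts and no
        assignment are treated as ``"unassigned"`` (reported, never dropped).
    """

    site: str
    replicate: str
    quadrat_area: float
    counts: dict[str, int]
    trophic_group: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.quadrat_area > 0:
            raise UndefinedInputError(
                f"quadrat_area must be > 0, got {self.quadrat_area}"
            )
        for taxon, c in self.counts.items():
            if c < 0 or int(c) != c:
                raise UndefinedInputError(
                    f"count for taxon {taxon!r} must be a non-negative integer, got {c}"
                )

    @property
    def total_individuals(self) -> int:
        return int(sum(self.counts.values()))

    def taxa_present(self) -> set[str]:
        return {t for t, c in self.counts.items() if c > 0}

    def group_of(self, taxon: str) -> str:
        return self.trophic_group.get(taxon, UNASSIGNED)


@dataclass(frozen=True)
class DiversitySummary:
    """Per-sample diversity indices (Shannon H', Pielou J', richness, N)."""

    shannon_H: float
    pielou_J: float
    richness: int
    total_individuals: int


def sorensen_index(taxa_a: Iterable[str], taxa_b: Iterable[str]) -> float:
    """Sorensen similarity S = 2a / (2a + b + c) between two taxon sets.

    ``a`` is the number of shared taxa, ``b`` and ``c`` the numbers unique to
    each set. Symmetric; 1 for identical non-empty sets, 0 for disjoint ones.
    """
    A, B = set(taxa_a), set(taxa_b)
    if not A and not B:
        raise UndefinedInputError("Sorensen index is undefined for two empty sets")
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    return 2 * a / (2 * a + b + c)


def shannon_index(counts: Sequence[float], log_base: float = 2.0) -> float:
    """Shannon diversity H' = -sum p_i log(p_i), log base 2 by default.

    Zero-count taxa contribute nothing. Raises for an all-zero vector.
    """
    c = np.asarray(list(counts), dtype=float)
    if c.size and (c < 0).any():
        raise UndefinedInputError("counts must be non-negative")
    total = c.sum()
    if not total > 0:
        raise UndefinedInputError("Shannon index undefined for all-zero counts")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum() / math.log(log_base))


def pielou_evenness(counts: Sequence[float], log_base: float = 2.0) -> float:
    """Pielou evenness J' = H' / H'max with H'max = log(richness).

    Requires at least two taxa with positive counts; the log base cancels.
    """
    c = np.asarray(list(counts), dtype=float)
    richness = int((c > 0).sum())
    if richness < 2:
        raise UndefinedInputError(
            "Pielou evenness undefined with fewer than two taxa present"
        )
    h = shannon_index(c, log_base=log_base)
    return float(h / (math.log(richness) / math.log(log_base)))


def diversity_summary(
    counts: Sequence[float], log_base: float = 2.0
) -> DiversitySummary:
    """Shannon, Pielou, richness and abundance for one count vector.

    Pielou is reported as NaN when only one taxon is present (H'max = 0).
    """
    c = np.asarray(list(counts), dtype=float)
    richness = int((c > 0).sum())
    h = shannon_index(c, log_base=log_base)
    j = pielou_evenness(c, log_base=log_base) if richness >= 2 else float("nan")
    return DiversitySummary(h, j, richness, int(c.sum()))


def density_per_m2(count: float, quadrat_area: float) -> float:
    """Individuals per m^2 from a count over a sampled area (m^2)."""
    if not quadrat_area > 0:
        raise UndefinedInputError(f"quadrat_area must be > 0, got {quadrat_area}")
    if count < 0:
        raise UndefinedInputError("count must be non-negative")
    return count / quadrat_area


def trophic_group_composition(
    tables: CommunityTable | Iterable[CommunityTable],
) -> dict[str, float]:
    """Percentage of individuals per trophic group, pooled over tables.

    Percentages are over individuals (not taxa) and sum to 100. Taxa with
    positive counts but no group assignment appear under ``"unassigned"``.
    """
    if isinstance(tables, CommunityTable):
        tables = [tables]
    totals: dict[str, float] = {}
    grand = 0.0
    for t in tables:
        for taxon, n in t.counts.items():
            if n <= 0:
                continue
            g = t.group_of(taxon)
            totals[g] = totals.get(g, 0.0) + n
            grand += n
    if grand <= 0:
        raise UndefinedInputError("no individuals counted")
    return {g: 100.0 * n / grand for g, n in totals.items()}


def pooled_counts(tables: Iterable[CommunityTable]) -> dict[str, int]:
    """Summed counts per taxon across a collection of replicate tables."""
    out: dict[str, int] = {}
    for t in tables:
        for taxon, n in t.counts.items():
            out[taxon] = out.get(taxon, 0) + int(n)
    return out


def replicate_diversity(
    tables: Iterable[CommunityTable], log_base: float = 2.0
) -> pd.DataFrame:
    """Per-replicate diversity indices over the site's pooled taxon list.

    Taxa observed at a site but absent from a given replicate enter that
    replicate's index with a zero count (they simply contribute nothing); no
    pseudo-counts are added. One row per (site, replicate).
    """
    tables = list(tables)
    rows = []
    for t in tables:
        s = diversity_summary(list(t.counts.values()), log_base=log_base)
        rows.append(
            {
                "site": t.site,
                "replicate": t.replicate,
                "shannon_H": s.shannon_H,
                "pielou_J": s.pielou_J,
                "richness": s.richness,
                "total_individuals": s.total_individuals,
            }
        )
    return pd.DataFrame(rows)


def density_table(tables: Iterable[CommunityTable]) -> pd.DataFrame:
    """Pooled density (ind m^-2) per taxon and site across replicates."""
    tables = list(tables)
    acc: dict[tuple[str, str], dict[str, float]] = {}
    site_area: dict[str, float] = {}
    for t in tables:
        site_area[t.site] = site_area.get(t.site, 0.0) + t.quadrat_area
        for taxon, n in t.counts.items():
            key = (t.site, taxon)
            d = acc.setdefault(key, {"count": 0.0, "group": t.group_of(taxon)})
            d["count"] += n
    rows = []
    for (site, taxon), d in sorted(acc.items()):
        rows.append(
            {
                "site": site,
                "taxon": taxon,
                "trophic_group": d["group"],
                "total_count": int(d["count"]),
                "density_per_m2": density_per_m2(d["count"], site_area[site]),
            }
        )
    return pd.DataFrame(rows)


def two_sample_t_test(
    x: Sequence[float], y: Sequence[float], variant: str = "student"
) -> tuple[float, float]:
    """Two-sided two-sample t-test; ``student`` pools variance, ``welch`` does not.

    Returns ``(statistic, p_value)``. Raises if either group has n < 2 or the
    pooled within-group variance is zero.
    """
    if variant not in ("student", "welch"):
        raise ValueError(f"variant must be 'student' or 'welch', got {variant!r}")
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.size < 2 or ya.size < 2:
        raise InsufficientDataError("each group needs at least two observations")
    if np.var(xa, ddof=1) == 0 and np.var(ya, ddof=1) == 0:
        raise DegenerateInputError("zero pooled variance: both groups are constant")
    res = stats.ttest_ind(xa, ya, equal_var=(variant == "student"))
    return float(res.statistic), float(res.pvalue)


@dataclass
class KruskalPosthocResult:
    """Kruskal-Wallis H test with Dunn-type pairwise merge decisions.

    ``pairwise`` has one row per group pair with the Dunn z statistic, the
    Bonferroni-adjusted two-sided p-value, and a ``mergeable`` flag. When the
    global test is not significant at ``alpha`` every pair is mergeable.
    """

    statistic: float
    p_value: float
    alpha: float
    labels: list[str]
    pairwise: pd.DataFrame
    all_mergeable: bool

    def mergeable_pairs(self) -> list[tuple[str, str]]:
        return [
            (r.group_a, r.group_b)
            for r in self.pairwise.itertuples()
            if r.mergeable
        ]


def _dunn_pairwise(
    groups: list[np.ndarray], labels: list[str], alpha: float
) -> pd.DataFrame:
    """Dunn (1964) rank comparisons with tie correction, Bonferroni-adjusted."""
    pooled = np.concatenate(groups)
    N = pooled.size
    ranks = stats.rankdata(pooled)
    # tie correction term sum(t^3 - t) over tied groups
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3) - tie_counts).sum())
    mean_ranks = []
    i = 0
    for g in groups:
        mean_ranks.append(ranks[i : i + g.size].mean())
        i += g.size
    n_pairs = len(groups) * (len(groups) - 1) // 2
    rows = []
    for (ia, ib) in itertools.combinations(range(len(groups)), 2):
        na, nb = groups[ia].size, groups[ib].size
        var = (N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))) * (
            1.0 / na + 1.0 / nb
        )
        if var <= 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[ia] - mean_ranks[ib]) / math.sqrt(var)
            p = 2.0 * stats.norm.sf(abs(z))
        p_adj = min(1.0, p * n_pairs)
        rows.append(
            {
                "group_a": labels[ia],
                "group_b": labels[ib],
                "z": z,
                "p_adj": p_adj,
                "mergeable": p_adj >= alpha,
            }
        )
    return pd.DataFrame(rows)


def kruskal_wallis_with_posthoc(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
    labels: Sequence[str] | None = None,
) -> KruskalPosthocResult:
    """Kruskal-Wallis H (tie-corrected) plus Dunn pairwise merge decisions.

    Used to decide whether ecologically related source species may be pooled:
    if the global rank test finds no difference at ``alpha``, all groups are
    flagged mergeable; otherwise Dunn-type pairwise comparisons with a
    Bonferroni correction decide per pair.
    """
    arrays = [np.asarray(list(g), dtype=float) for g in groups]
    if len(arrays) < 2:
        raise UndefinedInputError("need at least two groups")
    if any(a.size < 1 for a in arrays):
        raise InsufficientDataError("every group needs at least one observation")
    if sum(a.size for a in arrays) < 3:
        raise InsufficientDataError("need at least three observations in total")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    labels = list(labels)

    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        # all observations identical: H = 0 after tie correction, nothing to split
        pairwise = pd.DataFrame(
            [
                {"group_a": labels[i], "group_b": labels[j], "z": 0.0,
                 "p_adj": 1.0, "mergeable": True}
                for i, j in itertools.combinations(range(len(arrays)), 2)
            ]
        )
        return KruskalPosthocResult(0.0, 1.0, alpha, labels, pairwise, True)

    H, p = stats.kruskal(*arrays)
    if p > alpha:
        pairwise = pd.DataFrame(
            [
                {"group_a": labels[i], "group_b": labels[j], "z": float("nan"),
                 "p_adj": float("nan"), "mergeable": True}
                for i, j in itertools.combinations(range(len(arrays)), 2)
            ]
        )
        return KruskalPosthocResult(float(H), float(p), alpha, labels, pairwise, True)

    pairwise = _dunn_pairwise(arrays, labels, alpha)
    return KruskalPosthocResult(
        float(H), float(p), alpha, labels, pairwise, bool(pairwise["mergeable"].all())
    )
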