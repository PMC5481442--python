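"""Isotopic niche metrics: delta notation, trophic position, Layman metrics,
standard ellipse areas (ML and Bayesian) and ellipse overlap.

All isotope values are per-mil (permil) deviations from the international
standards (vPDB for carbon, atmospheric N2 for nitrogen). Points are
(d13C, d15N) pairs; areas are in permil^2.

Conventions
-----------
* Layman metrics are computed on whatever points are passed in; the pipeline
  passes one point per species (species mean signatures), while ellipse areas
  are computed on specimen-level points for each site, matching how the two
  families of metrics are usually drawn in two-site vent comparisons.
* SEA = pi * sqrt(det(S)) with S the n-1 sample covariance; the standard
  ellipse is the Mahalanobis unit ellipse. SEAc multiplies by (n-1)/(n-2).
* SDNND is the sample standard deviation (ddof=1) of the nearest-neighbour
  distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .exceptions import (
    DegenerateGeometryError,
    InsufficientDataError,
    MissingBaselineError,
    UndefinedInputError,
)

PLAUSIBLE_DELTA_BOUND = 100.0  # |delta| beyond this triggers a warning, not an error


class LaymanMetrics(NamedTuple):
    """Community-wide trophic-diversity metrics of Layman et al."""

    NR: float  # d15N range: trophic length
    CR: float  # d13C range: diversity of exploited basal resources
    CD: float  # mean Euclidean distance to the centroid
    NND: float  # mean nearest-neighbour distance (trophic redundancy)
    SDNND: float  # SD of nearest-neighbour distances (evenness of packing)


@dataclass
class NicheSummary:
    """Layman metrics plus standard ellipse areas for one community."""

    NR: float
    CR: float
    CD: float
    NND: float
    SDNND: float
    SEA: float
    SEAc: float
    SEA_posterior: np.ndarray = field(repr=False)
    n_points: int

    def to_dict(self) -> dict[str, float]:
        return {
            "NR": self.NR,
            "CR": self.CR,
            "CD": self.CD,
            "NND": self.NND,
            "SDNND": self.SDNND,
            "SEA": self.SEA,
            "SEAc": self.SEAc,
            "n_points": self.n_points,
        }


@dataclass(frozen=True)
class TrophicLevelEstimate:
    """Trophic position of one entity relative to a d15N baseline."""

    entity: str
    TL: float
    TL_sd: float
    n: int
    baseline_entity: str
    lam: float
    delta_n: float


def delta_notation(R_sample: float, R_standard: float) -> float:
    """delta X = [(R_sample - R_standard) / R_standard] * 1000 (permil)."""
    Rs = np.asarray(R_sample, dtype=float)
    Rstd = np.asarray(R_standard, dtype=float)
    if np.any(Rstd <= 0):
        raise UndefinedInputError("R_standard must be > 0")
    if np.any(Rs < 0):
        raise UndefinedInputError("R_sample must be >= 0")
    out = (Rs - Rstd) / Rstd * 1000.0
    return float(out) if out.ndim == 0 else out


def trophic_level(
    d15N_consumer: float,
    d15N_baseline: float,
    delta_n: float = 2.5,
    lam: float = 2.0,
) -> float:
    """Trophic level TL = (d15N_c - d15N_b) / delta_n + lambda.

    ``delta_n`` is the per-step d15N enrichment (default 2.5 permil, the
    herbivore value) and ``lam`` the trophic level of the baseline (2 for a
    primary consumer). Values below ``lam`` are reported as-is, not clamped.
    """
    if not delta_n > 0:
        raise UndefinedInputError(f"delta_n must be > 0, got {delta_n}")
    out = (np.asarray(d15N_consumer, float) - d15N_baseline) / delta_n + lam
    return float(out) if np.ndim(out) == 0 else out


def select_baseline(
    records: pd.DataFrame,
    primary_consumer_entities: Iterable[str],
    site: str | None = None,
) -> str:
    """Pick the baseline entity: the designated primary consumer with the
    lowest mean d15N (ties broken by larger n, then lexicographic label).

    ``records`` needs columns ``entity``, ``d15N`` and (if ``site`` given)
    ``site``. Baseline designation is user-supplied metadata, never inferred.
    """
    candidates = set(primary_consumer_entities)
    df = records
    if site is not None:
        df = df[df["site"] == site]
    df = df[df["entity"].isin(candidates)]
    if df.empty:
        raise MissingBaselineError(
            f"no designated primary consumers present"
            + (f" at site {site!r}" if site is not None else "")
        )
    g = df.groupby("entity")["d15N"].agg(["mean", "size"]).reset_index()
    g = g.sort_values(["mean", "size", "entity"], ascending=[True, False, True])
    return str(g.iloc[0]["entity"])


def trophic_level_table(
    records: pd.DataFrame,
    baseline_entity: str,
    site: str | None = None,
    delta_n: float = 2.5,
    lam: float = 2.0,
) -> pd.DataFrame:
    """Per-entity trophic level (mean over specimens) and its SD.

    Each consumer specimen's d15N is evaluated against the baseline entity's
    mean d15N; the SD is taken across specimens of the entity. Baseline
    variance is not propagated into TL_sd (documented limitation).
    """
    df = records
    if site is not None:
        df = df[df["site"] == site]
    base = df[df["entity"] == baseline_entity]["d15N"]
    if base.empty:
        raise MissingBaselineError(
            f"baseline entity {baseline_entity!r} has no records"
        )
    b_mean = float(base.mean())
    rows = []
    consumers = df[df["entity_class"] == "consumer"] if "entity_class" in df else df
    for entity, grp in consumers.groupby("entity"):
        tls = trophic_level(grp["d15N"].to_numpy(), b_mean, delta_n, lam)
        tls = np.atleast_1d(tls)
        rows.append(
            {
                "entity": entity,
                "site": site if site is not None else "",
                "TL": float(np.mean(tls)),
                "TL_sd": float(np.std(tls, ddof=1)) if tls.size > 1 else 0.0,
                "n": int(tls.size),
                "baseline_entity": baseline_entity,
                "lambda": lam,
                "delta_n": delta_n,
            }
        )
    return pd.DataFrame(rows).sort_values("entity").reset_index(drop=True)


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise UndefinedInputError("points must be an (n, 2) array of (d13C, d15N)")
    if not np.isfinite(pts).all():
        raise UndefinedInputError("points must be finite")
    if np.abs(pts).max(initial=0.0) > PLAUSIBLE_DELTA_BOUND:
        warnings.warn(
            "isotope values exceed |delta| = 100 permil; check units",
            stacklevel=3,
        )
    return pts


def layman_metrics(points: Sequence[Sequence[float]]) -> LaymanMetrics:
    """The five Layman community metrics of a (d13C, d15N) point set.

    NR and CR are the d15N and d13C ranges; CD the mean Euclidean distance to
    the bivariate centroid; NND the mean distance of each point to its nearest
    other point; SDNND the sample SD of those nearest-neighbour distances.
    Needs >= 2 points (>= 3 for SDNND to carry information).
    """
    pts = _as_points(points)
    n = pts.shape[0]
    if n < 2:
        raise InsufficientDataError("Layman metrics need at least two points")
    nr = float(pts[:, 1].max() - pts[:, 1].min())
    cr = float(pts[:, 0].max() - pts[:, 0].min())
    centroid = pts.mean(axis=0)
    cd = float(np.linalg.norm(pts - centroid, axis=1).mean())
    dist = squareform(pdist(pts))
    np.fill_diagonal(dist, np.inf)
    nnd = dist.min(axis=1)
    return LaymanMetrics(
        NR=nr,
        CR=cr,
        CD=cd,
        NND=float(nnd.mean()),
        SDNND=float(np.std(nnd, ddof=1)),
    )


def _sample_cov(pts: np.ndarray) -> np.ndarray:
    cov = np.cov(pts.T, ddof=1)
    evals = np.linalg.eigvalsh(cov)
    if evals[0] <= 1e-12 * max(evals[-1], 1e-12):
        raise DegenerateGeometryError(
            "sample covariance is singular (collinear or duplicated points)"
        )
    return cov


def standard_ellipse_area(
    points: Sequence[Sequence[float]], corrected: bool = True
) -> float:
    """Standard ellipse area SEA = pi * sqrt(det(S)) in permil^2.

    With ``corrected`` (default) applies the small-sample correction
    SEAc = SEA * (n-1)/(n-2), which removes the downward bias at small n so
    that niche widths of sites with different sample sizes are comparable.
    """
    pts = _as_points(points)
    n = pts.shape[0]
    if n < 3:
        raise InsufficientDataError("standard ellipse needs at least three points")
    cov = _sample_cov(pts)
    sea = float(np.pi * np.sqrt(np.linalg.det(cov)))
    if corrected:
        sea *= (n - 1) / (n - 2)
    return sea


def bayesian_sea(
    points: Sequence[Sequence[float]],
    n_draws: int = 10_000,
    seed: int | None = None,
    prior_df: float = 3.0,
    prior_scale: float = 1e-3,
    corrected: bool = True,
) -> np.ndarray:
    """Posterior draws of the (corrected) standard ellipse area.

    Conjugate normal-inverse-Wishart model with a vague prior: the posterior
    of the covariance is inverse-Wishart(prior_df + n, prior_scale * I + S)
    with S the centred scatter matrix (the flat limit of the mean's prior).
    Each draw's area is pi * sqrt(det(Sigma_draw)), multiplied by the
    (n-1)/(n-2) small-sample correction when ``corrected``. Deterministic
    given ``seed``; all draws are strictly positive.
    """
    pts = _as_points(points)
    n = pts.shape[0]
    if n < 4:
        raise InsufficientDataError("Bayesian SEA needs at least four points")
    if n_draws < 1:
        raise UndefinedInputError("n_draws must be >= 1")
    _sample_cov(pts)  # reject degenerate geometry up front
    centred = pts - pts.mean(axis=0)
    scatter = centred.T @ centred
    scale = prior_scale * np.eye(2) + scatter
    rng = np.random.default_rng(seed)
    draws = stats.invwishart.rvs(df=prior_df + n, scale=scale, size=n_draws,
                                 random_state=rng)
    draws = np.asarray(draws).reshape(n_draws, 2, 2)
    areas = np.pi * np.sqrt(np.linalg.det(draws))
    if corrected:
        areas *= (n - 1) / (n - 2)
    return areas


def _seac_ellipse(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Centre, covariance and squared Mahalanobis radius of the SEAc ellipse.

    The SEAc ellipse is {x : (x-mu)' S^-1 (x-mu) <= c} with c = (n-1)/(n-2),
    whose area is exactly SEAc.
    """
    n = pts.shape[0]
    if n < 3:
        raise InsufficientDataError("standard ellipse needs at least three points")
    cov = _sample_cov(pts)
    return pts.mean(axis=0), cov, (n - 1) / (n - 2)


def ellipse_overlap(
    points_a: Sequence[Sequence[float]],
    points_b: Sequence[Sequence[float]],
    resolution: int = 1000,
) -> float:
    """Area of intersection of the two maximum-likelihood SEAc ellipses.

    Rasterises the union bounding box on a ``resolution`` x ``resolution``
    grid and counts cells falling inside both ellipses; converges to the
    exact lens area as the resolution increases. Symmetric in its arguments
    by construction (the grid depends only on the unordered pair).
    """
    if resolution < 2:
        raise UndefinedInputError("resolution must be >= 2")
    mu1, S1, c1 = _seac_ellipse(_as_points(points_a))
    mu2, S2, c2 = _seac_ellipse(_as_points(points_b))
    P1 = np.linalg.inv(S1)
    P2 = np.linalg.inv(S2)

    hw1 = np.sqrt(c1 * np.diag(S1))
    hw2 = np.sqrt(c2 * np.diag(S2))
    lo = np.minimum(mu1 - hw1, mu2 - hw2)
    hi = np.maximum(mu1 + hw1, mu2 + hw2)
    dx = (hi - lo) / resolution
    xs = lo[0] + (np.arange(resolution) + 0.5) * dx[0]
    ys = lo[1] + (np.arange(resolution) + 0.5) * dx[1]

    dxa = (xs - mu1[0])[:, None]
    dya = (ys - mu1[1])[None, :]
    q1 = P1[0, 0] * dxa**2 + 2 * P1[0, 1] * dxa * dya + P1[1, 1] * dya**2
    inside = q1 <= c1
    del q1
    dxb = (xs - mu2[0])[:, None]
    dyb = (ys - mu2[1])[None, :]
    q2 = P2[0, 0] * dxb**2 + 2 * P2[0, 1] * dxb * dyb + P2[1, 1] * dyb**2
    inside &= q2 <= c2
    return float(inside.sum() * dx[0] * dx[1])


def summarize_niche(
    specimen_points: Sequence[Sequence[float]],
    species_points: Sequence[Sequence[float]] | None = None,
    n_draws: int = 10_000,
    seed: int | None = None,
) -> NicheSummary:
    """Full niche summary for one site.

    Layman metrics are computed on ``species_points`` (one point per species;
    defaults to the specimen points), ellipse areas on the specimen-level
    points.
    """
    spec = _as_points(specimen_points)
    spp = _as_points(species_points) if species_points is not None else spec
    lay = layman_metrics(spp)
    sea = standard_ellipse_area(spec, corrected=False)
    seac = standard_ellipse_area(spec, corrected=True)
    post = bayesian_sea(spec, n_draws=n_draws, seed=seed)
    return NicheSummary(
        NR=lay.NR,
        CR=lay.CR,
        CD=lay.CD,
        NND=lay.NND,
        SDNND=lay.SDNND,
        SEA=sea,
        SEAc=seac,
        SEA_posterior=post,
        n_points=spec.shape[0],
    )
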