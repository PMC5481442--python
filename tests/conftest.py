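"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from isofoodweb.mixing import TEF, SourceGroup


# --------------------------------------------------------------------------
# geometry helpers
# --------------------------------------------------------------------------

def points_with_moments(n, mean, cov, rng):
    """Random points whitened to have *exactly* the given sample moments."""
    mean = np.asarray(mean, float)
    cov = np.asarray(cov, float)
    x = rng.normal(size=(n, 2))
    x -= x.mean(axis=0)
    # whiten by the sample covariance, then colour with the target
    s = np.cov(x.T, ddof=1)
    l_inv = np.linalg.inv(np.linalg.cholesky(s))
    l_tgt = np.linalg.cholesky(cov)
    return x @ l_inv.T @ l_tgt.T + mean


def unit_circle_points(n, centre, rng):
    """Point set whose SEAc ellipse is exactly the unit circle at ``centre``.

    The SEAc ellipse is the Mahalanobis ellipse of squared radius
    c = (n-1)/(n-2); choosing sample covariance I/c makes it the unit circle.
    """
    c = (n - 1) / (n - 2)
    return points_with_moments(n, centre, np.eye(2) / c, rng)


# --------------------------------------------------------------------------
# brute-force Layman oracle (exhaustive distance enumeration)
# --------------------------------------------------------------------------

def layman_brute_force(points):
    pts = [tuple(map(float, p)) for p in points]
    n = len(pts)
    ys = [p[1] for p in pts]
    xs = [p[0] for p in pts]
    nr = max(ys) - min(ys)
    cr = max(xs) - min(xs)
    cx = sum(xs) / n
    cy = sum(ys) / n
    cd = sum(math.hypot(x - cx, y - cy) for x, y in pts) / n
    nnds = []
    for i in range(n):
        nnds.append(
            min(
                math.hypot(pts[i][0] - pts[j][0], pts[i][1] - pts[j][1])
                for j in range(n)
                if j != i
            )
        )
    mean_nnd = sum(nnds) / n
    var = sum((d - mean_nnd) ** 2 for d in nnds) / (n - 1)
    return nr, cr, cd, mean_nnd, math.sqrt(var)


# --------------------------------------------------------------------------
# simplex-grid importance-sampling oracle for the mixing posterior
# --------------------------------------------------------------------------

def simplex_grid(k, step):
    """All probability vectors of length k on a grid of the given step."""
    m = round(1.0 / step)
    out = []
    for combo in itertools.combinations_with_replacement(range(k), m):
        counts = [0] * k
        for c in combo:
            counts[c] += 1
        out.append([c / m for c in counts])
    return np.array(out)


def grid_posterior_means(X, sources, tef, step=0.02, prior_alpha=1.0, tau=0.0):
    """Posterior means of diet proportions by dense-grid quadrature.

    Evaluates the mixing likelihood (source + TEF variance scaled by p^2,
    fixed residual SD ``tau``) and the Dirichlet prior on a simplex grid and
    averages. Independent of the MCMC implementation.
    """
    X = np.asarray(X, float)
    mu = np.array([[s.mean_d13C, s.mean_d15N] for s in sources])
    var = np.array([[s.sd_d13C**2, s.sd_d15N**2] for s in sources])
    mu = mu + np.array([tef.mean_d13C, tef.mean_d15N])
    var = var + np.array([tef.sd_d13C**2, tef.sd_d15N**2])
    P = simplex_grid(len(sources), step)
    logw = np.zeros(len(P))
    for g, p in enumerate(P):
        m = p @ mu
        v = (p**2) @ var + tau**2
        ll = 0.0
        for j in range(2):
            ll += (
                -0.5 * len(X) * math.log(2 * math.pi * v[j])
                - 0.5 * ((X[:, j] - m[j]) ** 2).sum() / v[j]
            )
        prior = 0.0
        if prior_alpha != 1.0:
            if (p <= 0).any():
                prior = -np.inf
            else:
                prior = (prior_alpha - 1.0) * np.log(p).sum()
        logw[g] = ll + prior
    w = np.exp(logw - logw.max())
    w /= w.sum()
    return w @ P


# --------------------------------------------------------------------------
# fixtures
# --------------------------------------------------------------------------

@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def two_far_sources():
    """Two sources 10 permil apart on both axes, tight SDs."""
    return [
        SourceGroup("plant", -20.0, 0.5, 0.0, 0.5, 10),
        SourceGroup("detritus", -10.0, 0.5, 10.0, 0.5, 10),
    ]


@pytest.fixture
def paper_tef():
    return TEF()


def draw_consumers(rng, p, sources, tef, n, residual_sd=0.0):
    """Specimens from the mixing likelihood at true proportions ``p``."""
    p = np.asarray(p, float)
    mu = np.array([[s.mean_d13C, s.mean_d15N] for s in sources])
    var = np.array([[s.sd_d13C**2, s.sd_d15N**2] for s in sources])
    mu = mu + np.array([tef.mean_d13C, tef.mean_d15N])
    var = var + np.array([tef.sd_d13C**2, tef.sd_d15N**2])
    mean = p @ mu
    sd = np.sqrt((p**2) @ var + residual_sd**2)
    return rng.normal(mean, sd, size=(n, 2))
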