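"""Two-state (telegraph) model of stochastic gene transcription.

A gene promoter switches stochastically between an OFF and an ON state with
rates ``theta_on`` (activation) and ``theta_off`` (inactivation).  While ON,
mRNA is transcribed at rate ``theta_t``; transcripts degrade at rate
``theta_d``, which is used as the unit of time and therefore fixed at 1.

At stationarity the mRNA copy number follows the Poisson-Beta mixture

    m | p ~ Poisson(theta_t * p),    p ~ Beta(theta_on, theta_off),

which is the classical steady-state law of the two-state model.  This module
provides the stationary PMF, an exact sampler, per-count negative
log-likelihoods, a cached-grid maximum-likelihood fit, and the burst
statistics derived from the fitted rates (burst size S = theta_t/theta_off,
burst frequency F = theta_on).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln, gammaln, roots_jacobi

__all__ = [
    "TelegraphParams",
    "ParamGrid",
    "TruncationError",
    "stationary_pmf",
    "sample_stationary",
    "gene_nll",
    "fit_mle_grid",
    "burst_size",
    "burst_frequency",
]

# Number of Gauss-Jacobi nodes used to integrate the Poisson kernel against
# the Beta density.  512 nodes are ample for the rate ranges of the default
# fitting grid; the Jacobi weight absorbs the Beta endpoint singularities.
N_QUAD = 512

# Probabilities below this are treated as numerical zeros in log space.
_PMF_FLOOR = 1e-300


class TruncationError(ValueError):
    """Raised when the truncated support 0..m_max misses too much mass."""


@dataclass(frozen=True)
class TelegraphParams:
    """Rates of the two-state model, in units of the mRNA degradation rate.

    Parameters
    ----------
    theta_on : float
        Promoter activation rate (> 0).
    theta_off : float
        Promoter inactivation rate (> 0).
    theta_t : float
        Transcription rate while the promoter is ON (>= 0).
    theta_d : float
        Degradation rate; the time unit of the model, always 1.
    """

    theta_on: float
    theta_off: float
    theta_t: float
    theta_d: float = field(default=1.0)

    def __post_init__(self) -> None:
        for name in ("theta_on", "theta_off", "theta_t"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.theta_on <= 0:
            raise ValueError(f"theta_on must be > 0, got {self.theta_on}")
        if self.theta_off <= 0:
            raise ValueError(f"theta_off must be > 0, got {self.theta_off}")
        if self.theta_t < 0:
            raise ValueError(f"theta_t must be >= 0, got {self.theta_t}")
        if self.theta_d != 1.0:
            raise ValueError("theta_d is the time unit and must equal 1")

    @property
    def mean(self) -> float:
        """Stationary mean copy number, theta_t * theta_on/(theta_on+theta_off)."""
        return self.theta_t * self.theta_on / (self.theta_on + self.theta_off)


def burst_size(params: TelegraphParams) -> float:
    """Transcriptional burst size S = theta_t / theta_off.

    The mean number of transcripts produced per ON episode.
    """
    if params.theta_off == 0:
        raise ZeroDivisionError("burst size undefined for theta_off = 0")
    return params.theta_t / params.theta_off


def burst_frequency(params: TelegraphParams) -> float:
    """Transcriptional burst frequency F = theta_on (bursts per degradation time)."""
    return params.theta_on


def _jacobi_nodes(theta_on: float, theta_off: float, n_quad: int = N_QUAD):
    """Beta-density quadrature: nodes p_i in (0,1) and weights summing to 1.

    Gauss-Jacobi with weight (1-x)^(theta_off-1) (1+x)^(theta_on-1) on [-1,1]
    maps to the Beta(theta_on, theta_off) density on [0,1]; the endpoint
    singularities for rates < 1 are handled exactly by the weight function.
    """
    x, w = roots_jacobi(n_quad, theta_off - 1.0, theta_on - 1.0)
    p = 0.5 * (1.0 + x)
    log_norm = (1.0 - theta_on - theta_off) * math.log(2.0) - betaln(
        theta_on, theta_off
    )
    weights = w * math.exp(log_norm)
    # The constant function is integrated exactly; renormalise to absorb the
    # last few ulps of rounding so weights sum to 1.
    weights /= weights.sum()
    return p, weights


def _pmf_from_quadrature(
    theta_on: float, theta_off: float, theta_t: np.ndarray, m_max: int
) -> np.ndarray:
    """Unnormalised truncated PMFs, shape (len(theta_t), m_max+1).

    Each row sums to (1 - tail mass beyond m_max) for its theta_t.
    """
    theta_t = np.atleast_1d(np.asarray(theta_t, dtype=float))
    out = np.zeros((theta_t.size, m_max + 1))
    zero = theta_t == 0
    out[zero, 0] = 1.0
    if np.all(zero):
        return out
    p, weights = _jacobi_nodes(theta_on, theta_off)
    m = np.arange(m_max + 1)
    lam = theta_t[~zero, None] * p[None, :]  # (nt, nq)
    log_pois = (
        m[None, None, :] * np.log(lam)[:, :, None]
        - lam[:, :, None]
        - gammaln(m + 1.0)[None, None, :]
    )
    out[~zero] = np.einsum("q,tqm->tm", weights, np.exp(log_pois))
    return out


def stationary_pmf(params: TelegraphParams, m_max: int) -> np.ndarray:
    """Stationary mRNA distribution on counts 0..m_max.

    Evaluates the Poisson-Beta mixture by fixed-node Gauss-Jacobi quadrature
    over the Beta density.  The result is renormalised only when the mass
    beyond ``m_max`` is below 1e-6; a tail above 1e-3 raises
    :class:`TruncationError` advising a larger ``m_max``.
    """
    if m_max < 1:
        raise ValueError("m_max must be >= 1")
    pmf = _pmf_from_quadrature(params.theta_on, params.theta_off,
                               params.theta_t, m_max)[0]
    total = pmf.sum()
    tail = max(0.0, 1.0 - total)
    if tail > 1e-3:
        raise TruncationError(
            f"{tail:.3g} of the probability mass lies beyond m_max={m_max}; "
            "increase m_max"
        )
    if tail < 1e-6:
        pmf = pmf / total
    return pmf


def sample_stationary(
    params: TelegraphParams, n_cells: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n_cells`` i.i.d. stationary counts (exact Poisson-Beta sampler).

    The sampler is exact: p ~ Beta(theta_on, theta_off), m ~ Poisson(theta_t*p).
    Identical seeds give identical output.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    if params.theta_t == 0:
        return np.zeros(n_cells, dtype=np.int64)
    p = rng.beta(params.theta_on, params.theta_off, size=n_cells)
    return rng.poisson(params.theta_t * p).astype(np.int64)


# ---------------------------------------------------------------------------
# Fitting grid


class ParamGrid:
    """Discrete (theta_on, theta_off, theta_t) fitting grid with cached PMFs.

    Grid points are enumerated with theta_t as the slowest axis, then
    theta_off, then theta_on, all ascending, so the first index attaining a
    likelihood maximum is the lexicographically smallest (theta_t, theta_off,
    theta_on) — the deterministic tie-break used by :func:`fit_mle_grid`.

    Cached PMFs are conditioned on the truncated support 0..m_max (each row
    renormalised to sum to 1), which is the correct likelihood for count data
    capped at m_max.
    """

    def __init__(
        self,
        theta_on: np.ndarray,
        theta_off: np.ndarray,
        theta_t: np.ndarray,
        m_max: int = 200,
    ) -> None:
        self.theta_on = np.asarray(theta_on, dtype=float)
        self.theta_off = np.asarray(theta_off, dtype=float)
        self.theta_t = np.asarray(theta_t, dtype=float)
        for name, ax in (("theta_on", self.theta_on),
                         ("theta_off", self.theta_off),
                         ("theta_t", self.theta_t)):
            if ax.ndim != 1 or ax.size == 0 or np.any(np.diff(ax) <= 0):
                raise ValueError(f"{name} axis must be 1-D strictly increasing")
        if m_max < 1:
            raise ValueError("m_max must be >= 1")
        self.m_max = int(m_max)
        self._pmf: np.ndarray | None = None
        self._log_pmf: np.ndarray | None = None

    @classmethod
    def default(cls, m_max: int = 200) -> "ParamGrid":
        """The standard fitting grid: log-spaced rates at desk-scale memory.

        theta_on in [1e-2, 1e1] and theta_off in [1e-2, 1e2] (20 points
        each), theta_t in [1e-1, 2*m_max] (25 points).  The theta_on axis
        stops at 10 because stationary counts cannot distinguish faster
        switching from the Poisson limit; the extra decade would only host
        degenerate fits.
        """
        return cls(
            theta_on=np.logspace(-2, 1, 20),
            theta_off=np.logspace(-2, 2, 20),
            theta_t=np.logspace(np.log10(0.1), np.log10(2.0 * m_max), 25),
            m_max=m_max,
        )

    @classmethod
    def from_config(cls, cfg: dict) -> "ParamGrid":
        """Build a grid from flat config keys ``grid.*``."""
        return cls(
            theta_on=np.logspace(
                np.log10(cfg["grid.theta_on_min"]),
                np.log10(cfg["grid.theta_on_max"]),
                int(cfg["grid.theta_on_n"]),
            ),
            theta_off=np.logspace(
                np.log10(cfg["grid.theta_off_min"]),
                np.log10(cfg["grid.theta_off_max"]),
                int(cfg["grid.theta_off_n"]),
            ),
            theta_t=np.logspace(
                np.log10(cfg["grid.theta_t_min"]),
                np.log10(cfg["grid.theta_t_max"]),
                int(cfg["grid.theta_t_n"]),
            ),
            m_max=int(cfg["grid.m_max"]),
        )

    @property
    def n_points(self) -> int:
        return self.theta_on.size * self.theta_off.size * self.theta_t.size

    def params_at(self, index: int) -> TelegraphParams:
        """Telegraph parameters of the flat grid index."""
        n_on = self.theta_on.size
        n_off = self.theta_off.size
        i_t, rem = divmod(int(index), n_off * n_on)
        i_off, i_on = divmod(rem, n_on)
        return TelegraphParams(
            theta_on=float(self.theta_on[i_on]),
            theta_off=float(self.theta_off[i_off]),
            theta_t=float(self.theta_t[i_t]),
        )

    def index_of(self, params: TelegraphParams) -> int:
        """Flat index of a grid point; raises if params are not on the grid."""
        i_on = int(np.argmin(np.abs(self.theta_on - params.theta_on)))
        i_off = int(np.argmin(np.abs(self.theta_off - params.theta_off)))
        i_t = int(np.argmin(np.abs(self.theta_t - params.theta_t)))
        if not (
            np.isclose(self.theta_on[i_on], params.theta_on)
            and np.isclose(self.theta_off[i_off], params.theta_off)
            and np.isclose(self.theta_t[i_t], params.theta_t)
        ):
            raise KeyError(f"{params} is not a grid point")
        n_on = self.theta_on.size
        return (i_t * self.theta_off.size + i_off) * n_on + i_on

    def _build(self) -> None:
        n_on = self.theta_on.size
        n_off = self.theta_off.size
        n_t = self.theta_t.size
        pmf = np.empty((n_t * n_off * n_on, self.m_max + 1))
        for i_off, b in enumerate(self.theta_off):
            for i_on, a in enumerate(self.theta_on):
                rows = _pmf_from_quadrature(a, b, self.theta_t, self.m_max)
                rows /= rows.sum(axis=1, keepdims=True)
                idx = (np.arange(n_t) * n_off + i_off) * n_on + i_on
                pmf[idx] = rows
        self._pmf = pmf
        self._log_pmf = np.log(np.maximum(pmf, _PMF_FLOOR))

    @property
    def pmf(self) -> np.ndarray:
        """(n_points, m_max+1) cached PMF matrix; built lazily."""
        if self._pmf is None:
            self._build()
        return self._pmf

    @property
    def log_pmf(self) -> np.ndarray:
        if self._log_pmf is None:
            self._build()
        return self._log_pmf

    def pmf_for(self, params: TelegraphParams) -> np.ndarray:
        """PMF row for a grid point (cached) or any parameters (computed)."""
        try:
            return self.pmf[self.index_of(params)]
        except KeyError:
            row = _pmf_from_quadrature(params.theta_on, params.theta_off,
                                       params.theta_t, self.m_max)[0]
            return row / row.sum()


def gene_nll(
    count: int, params: TelegraphParams, grid: ParamGrid
) -> float:
    """Per-gene negative log-likelihood -log P(count) of one mRNA count.

    This is the gene-wise summand of a cell's transcriptional uncertainty
    NLL_n = sum_g NLL_{g,n}.
    """
    if count < 0 or count > grid.m_max:
        raise ValueError(
            f"count {count} outside the grid support 0..{grid.m_max}")
    p = float(gridded_probability(params, grid)[int(count)])
    if p <= 0:
        return math.inf
    return -math.log(p)


def gridded_probability(params: TelegraphParams, grid: ParamGrid) -> np.ndarray:
    """PMF used by likelihood computations (truncation-conditioned)."""
    return grid.pmf_for(params)


def fit_mle_grid(
    counts: np.ndarray, grid: ParamGrid
) -> tuple[TelegraphParams, float]:
    """Grid-search maximum-likelihood fit of the telegraph model.

    Returns the grid point maximising ``sum_m log P(m)`` over the observed
    counts together with its log-likelihood.  Ties are broken by the smallest
    (theta_t, theta_off, theta_on) in lexicographic order, which is the grid
    enumeration order, so the first argmax wins.
    """
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("cannot fit an empty count vector")
    if counts.min() < 0 or counts.max() > grid.m_max:
        raise ValueError(
            f"counts outside the grid support 0..{grid.m_max}")
    hist = np.bincount(counts.astype(np.int64), minlength=grid.m_max + 1)
    ll = grid.log_pmf @ hist.astype(float)
    best = int(np.argmax(ll))
    return grid.params_at(best), float(ll[best])
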