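"""Independent oracles used by the tests.

These deliberately avoid the implementation paths they check: the stationary
law is re-derived via the confluent-hypergeometric series and via a direct
Gillespie simulation of the promoter/transcription/degradation reaction
network; the grid MLE is re-run as a naive Python loop.
"""

import numpy as np
from scipy.special import gammaln, hyp1f1


def series_pmf(theta_on: float, theta_off: float, theta_t: float,
               m_max: int) -> np.ndarray:
    """Stationary PMF via the confluent-hypergeometric series form.

    P(m) = theta_t^m/m! * (a)_m/(a+b)_m * 1F1(a+m; a+b+m; -theta_t).
    Accurate for moderate theta_t where the series does not cancel.
    """
    a, b = theta_on, theta_off
    m = np.arange(m_max + 1)
    log_coeff = (
        m * np.log(theta_t)
        - gammaln(m + 1.0)
        + gammaln(a + m) - gammaln(a)
        + gammaln(a + b) - gammaln(a + b + m)
    )
    return np.exp(log_coeff) * hyp1f1(a + m, a + b + m, -theta_t)


def gillespie_stationary(theta_on: float, theta_off: float, theta_t: float,
                         n_cells: int, t_end: float,
                         seed: int) -> np.ndarray:
    """Final mRNA counts of n_cells independent exact SSA trajectories.

    Reactions: OFF->ON (theta_on), ON->OFF (theta_off), transcription while
    ON (theta_t), first-order degradation (rate = copy number).  Trajectories
    start OFF with zero transcripts and run to t_end (several degradation
    times), vectorised across cells.
    """
    rng = np.random.default_rng(seed)
    on = np.zeros(n_cells, dtype=bool)
    m = np.zeros(n_cells, dtype=np.int64)
    t = np.zeros(n_cells)
    active = np.ones(n_cells, dtype=bool)
    while active.any():
        idx = np.flatnonzero(active)
        r_switch = np.where(on[idx], theta_off, theta_on)
        r_tx = np.where(on[idx], theta_t, 0.0)
        r_deg = m[idx].astype(float)
        total = r_switch + r_tx + r_deg
        dt = rng.exponential(1.0 / total)
        t_new = t[idx] + dt
        done = t_new >= t_end
        t[idx] = np.where(done, t_end, t_new)
        live = idx[~done]
        if live.size:
            u = rng.random(live.size) * total[~done]
            sw = u < r_switch[~done]
            tx = (~sw) & (u < (r_switch + r_tx)[~done])
            deg = ~(sw | tx)
            on[live[sw]] = ~on[live[sw]]
            m[live[tx]] += 1
            m[live[deg]] -= 1
        active[idx[done]] = False
    return m


def naive_grid_search(counts: np.ndarray, grid) -> tuple[int, float]:
    """Exhaustive Python-loop MLE over every cached grid point."""
    counts = np.asarray(counts, dtype=np.int64)
    best_idx, best_ll = -1, -np.inf
    for i in range(grid.n_points):
        row = grid.pmf[i]
        ll = 0.0
        for c in counts:
            ll += np.log(max(row[c], 1e-300))
        if ll > best_ll:
            best_idx, best_ll = i, ll
    return best_idx, best_ll


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    n = max(p.size, q.size)
    pp = np.zeros(n)
    qq = np.zeros(n)
    pp[: p.size] = p
    qq[: q.size] = q
    return 0.5 * np.abs(pp - qq).sum()
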