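"""Hierarchical switching state-space model for Argos telemetry.

The model estimates, from irregular and error-prone Argos fixes, latent
whale locations on a regular time grid (default 3 h) together with a
discrete two-state behavioural sequence: transit (b = 1, fast and
directionally persistent) versus area-restricted search (ARS, b = 2,
slow with frequent turns).

Process model (first-difference correlated random walk, per segment)::

    x_t - x_{t-1} = gamma[b_t] * (x_{t-1} - x_{t-2}) + eps_t,
    eps_t ~ N(0, Sigma),         b_t a 2-state Markov chain,

with state-specific move persistence ``gamma`` (identifiability:
``gamma_transit > gamma_ars``) and shared process covariance ``Sigma``.
Each Argos fix at an irregular time is tied to its two flanking regular
states by linear interpolation weight j::

    y_i = (1 - j_i) x_k + j_i x_{k+1} + t-distributed error (per class).

Inference is blocked Gibbs sampling: the Student-t measurement errors
are represented as scale mixtures of normals, making latent locations
conditionally Gaussian (updated exactly in three interleaved colour
classes), behavioural states are single-site Gibbs in two colour
classes, move persistence is a truncated-normal Gibbs draw respecting
the ordering constraint, ``Sigma`` an inverse-Wishart draw, and switch
probabilities Beta draws.  In hierarchical mode all segments share
(gamma, Sigma, switch probabilities) with per-segment latent paths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import invwishart

from arstrack.argos_io import TrackSegment
from arstrack.simulate import ArgosErrorModel

logger = logging.getLogger(__name__)


@dataclass
class ModelSpec:
    """Model structure and fixed quantities for :func:`fit_hssm`."""

    dt: float = 3.0  # hours
    gamma_init: tuple[float, float] = (0.7, 0.3)  # (transit, ars)
    sigma_init: np.ndarray | None = None
    switch_init: np.ndarray = field(
        default_factory=lambda: np.array([[0.9, 0.1], [0.1, 0.9]])
    )
    error_model: ArgosErrorModel = field(default_factory=ArgosErrorModel)
    hierarchy: bool = True
    estimate_sigma: bool = True  # shared across states; config switch, not state-specific
    anchor_sd: float = 3.0  # degrees; weak prior on the first two states

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        g1, g2 = self.gamma_init
        if not (0 < g2 < g1 < 1):
            raise ValueError("require 0 < gamma_ars < gamma_transit < 1")


@dataclass
class McmcPlan:
    """Sampler regimen.

    Defaults mirror the full analysis (2 chains, 80,000 burn-in, 30,000
    post-burn-in samples thinned by 30, i.e. 2000 retained draws); scale
    them down for tests and desk runs — the plan is configuration, not a
    constant.
    """

    n_chains: int = 2
    burn_in: int = 80_000
    post_burn_in: int = 30_000
    thin: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.burn_in < 0 or self.post_burn_in < 1 or self.thin < 1:
            raise ValueError("invalid MCMC plan")

    @property
    def retained(self) -> int:
        """Total retained draws: n_chains * floor(post_burn_in / thin)."""
        return self.n_chains * (self.post_burn_in // self.thin)


@dataclass
class RegularGrid:
    """Regular estimation grid for one segment, with observation ties."""

    t0: pd.Timestamp
    dt: float
    n_states: int
    obs_state: np.ndarray  # index k of the left flanking state, per fix
    j_weight: np.ndarray  # interpolation weight in [0, 1), per fix

    @property
    def times_h(self) -> np.ndarray:
        return np.arange(self.n_states) * self.dt

    def timestamps(self) -> pd.DatetimeIndex:
        return self.t0 + pd.to_timedelta(self.times_h, unit="h")


def build_regular_grid(segment: TrackSegment, dt: float = 3.0) -> RegularGrid:
    """Lay a regular ``dt``-hour grid over a segment and tie each fix.

    The grid starts at the first fix.  For a span that is an exact
    multiple of ``dt`` the grid has ``span/dt + 1`` states; otherwise one
    extra state is appended so every fix has a right flanking state.
    Observation i receives its left state index k and the interpolation
    weight ``j = (t_i - t_k)/dt`` in [0, 1).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    hours = segment.hours_since_start()
    span = hours[-1]
    if span < 2 * dt:
        raise ValueError(
            f"segment span {span:.1f} h is shorter than two time steps ({2 * dt} h)"
        )
    r = span / dt
    n = int(np.floor(r + 1e-9)) + 1
    if span - (n - 1) * dt > 1e-9:
        n += 1
    k = np.floor(hours / dt + 1e-9).astype(int)
    j = hours / dt - k
    j = np.clip(j, 0.0, 1.0 - 1e-12)
    j[np.abs(j) < 1e-9] = 0.0
    # a fix exactly on the last grid time has single-state attribution
    k = np.clip(k, 0, n - 1)
    assert np.all((k < n - 1) | (j == 0.0))
    return RegularGrid(t0=segment.start, dt=dt, n_states=n, obs_state=k, j_weight=j)


@dataclass
class StateSeries:
    """Posterior location and behaviour summaries on the regular grid.

    ``data`` columns: ``timestamp, lon, lat, lon_lo, lon_hi, lat_lo,
    lat_hi, mean_b, p_ars, mode_state``.  ``p_ars = mean_b - 1``;
    ``mode_state`` is 2 (ARS) iff ``mean_b > 1.5`` (a tie at exactly 1.5
    is assigned transit).
    """

    tag_id: str
    segment_index: int
    data: pd.DataFrame

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class PosteriorDraws:
    """Retained joint MCMC samples of locations, states and parameters.

    Per segment s: ``x[s]`` has shape (n_draws, n_states, 2) and
    ``b[s]`` (n_draws, n_states) with values in {1, 2}.  ``chain`` and
    ``draw`` index the provenance of each retained sample.
    """

    segment_meta: list[dict]
    x: list[np.ndarray]
    b: list[np.ndarray]
    gamma: np.ndarray  # (n_draws, 2): (transit, ars)
    sigma: np.ndarray  # (n_draws, 2, 2)
    switch: np.ndarray  # (n_draws, 2, 2)
    chain: np.ndarray
    draw: np.ndarray

    @property
    def n_draws(self) -> int:
        return len(self.chain)

    def param_chains(self) -> dict[str, np.ndarray]:
        """Scalar parameter traces reshaped to (n_chains, n_per_chain)."""
        chains = np.unique(self.chain)
        series = {
            "gamma_transit": self.gamma[:, 0],
            "gamma_ars": self.gamma[:, 1],
            "sigma_lon": self.sigma[:, 0, 0],
            "sigma_lat": self.sigma[:, 1, 1],
            "switch_stay_transit": self.switch[:, 0, 0],
            "switch_stay_ars": self.switch[:, 1, 1],
        }
        out = {}
        for name, v in series.items():
            per = [v[self.chain == c] for c in chains]
            m = min(len(p) for p in per)
            out[name] = np.stack([p[:m] for p in per])
        return out

    def locations_for_draw(self, i: int) -> list[pd.DataFrame]:
        """One joint realisation of every segment's path and states."""
        out = []
        for meta, xs, bs in zip(self.segment_meta, self.x, self.b):
            out.append(
                pd.DataFrame(
                    {
                        "tag_id": meta["tag_id"],
                        "segment": meta["segment_index"],
                        "timestamp": meta["timestamps"],
                        "lon": xs[i, :, 0],
                        "lat": xs[i, :, 1],
                        "b": bs[i],
                    }
                )
            )
        return out


@dataclass
class ConvergenceReport:
    """Per-parameter MCMC diagnostics."""

    table: pd.DataFrame  # parameter, shrink_factor, ess, acf_lag1
    converged: bool
    threshold: float
    notes: list[str] = field(default_factory=list)


def gelman_rubin(chains: np.ndarray) -> float:
    """Gelman–Rubin potential scale reduction for one scalar parameter.

    ``chains`` has shape (n_chains, n_draws).  The classical
    between/within variance-ratio estimate is clipped below at 1 (the
    shrink factor is a ratio of variance estimates and values below 1
    are finite-sample noise), so identical chains report exactly 1.
    Undefined (NaN) for a single chain.
    """
    m, n = chains.shape
    if m < 2 or n < 2:
        return float("nan")
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return 1.0 if B == 0 else float("inf")
    v_hat = (n - 1) / n * W + B / n
    return float(max(1.0, np.sqrt(v_hat / W)))


def _acf(x: np.ndarray, max_lag: int) -> np.ndarray:
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0:
        return np.zeros(max_lag + 1)
    return np.array(
        [1.0] + [float(x[lag:] @ x[:-lag]) / denom for lag in range(1, max_lag + 1)]
    )


def effective_sample_size(chains: np.ndarray, max_lag: int = 50) -> float:
    """Initial-positive-sequence ESS estimate pooled across chains."""
    m, n = chains.shape
    rho = np.mean([_acf(c, min(max_lag, n - 2)) for c in chains], axis=0)
    s = 0.0
    for lag in range(1, len(rho)):
        if rho[lag] <= 0:
            break
        s += rho[lag]
    return float(m * n / (1.0 + 2.0 * s))


def diagnose(
    chains: dict[str, np.ndarray], threshold: float = 1.1
) -> ConvergenceReport:
    """Gelman–Rubin shrink factors, ESS and lag-1 autocorrelation.

    ``chains`` maps parameter names to (n_chains, n_draws) arrays.  With
    a single chain the shrink factor is reported as NaN (undefined), and
    convergence is judged on the remaining diagnostics.
    """
    rows, notes = [], []
    for name, arr in chains.items():
        arr = np.atleast_2d(np.asarray(arr, dtype=float))
        rhat = gelman_rubin(arr)
        ess = effective_sample_size(arr)
        acf1 = float(np.mean([_acf(c, 1)[1] for c in arr if len(c) > 2] or [np.nan]))
        rows.append((name, rhat, ess, acf1))
        if np.isnan(rhat):
            notes.append(f"{name}: shrink factor undefined (single chain)")
    table = pd.DataFrame(rows, columns=["parameter", "shrink_factor", "ess", "acf_lag1"])
    finite = table["shrink_factor"].dropna()
    converged = bool((finite <= threshold).all()) if len(finite) else True
    if not converged:
        bad = table.loc[table["shrink_factor"] > threshold, "parameter"].tolist()
        notes.append(f"non-convergence flagged: shrink factor > {threshold} for {bad}")
    return ConvergenceReport(table=table, converged=converged, threshold=threshold, notes=notes)


def prob_ars(mean_b: np.ndarray | float) -> np.ndarray | float:
    """Probability of ARS: 1 subtracted from the posterior mean state.

    Values close to 1 indicate a high probability of the whale being in
    ARS.  ``mean_b`` must lie in [1, 2].
    """
    arr = np.asarray(mean_b, dtype=float)
    if (arr < 1.0 - 1e-9).any() or (arr > 2.0 + 1e-9).any():
        raise ValueError("posterior mean behavioural state must lie in [1, 2]")
    out = np.clip(arr - 1.0, 0.0, 1.0)
    return float(out) if np.isscalar(mean_b) else out


# ---------------------------------------------------------------------------
# Gibbs sampler internals


class _SegmentData:
    """Per-segment precomputed arrays for the sampler."""

    def __init__(self, segment: TrackSegment, grid: RegularGrid, error_model: ArgosErrorModel):
        self.tag_id = segment.tag_id
        self.segment_index = segment.segment_index
        self.grid = grid
        self.n = grid.n_states
        self.y = segment.data[["lon", "lat"]].to_numpy(dtype=float)
        self.k = grid.obs_state
        self.k2 = np.minimum(grid.obs_state + 1, self.n - 1)
        self.j = grid.j_weight
        lc = segment.data["lc"].to_numpy()
        scales = np.maximum(error_model.scale_arrays(lc), 1e-6)
        self.inv_s2 = 1.0 / scales**2
        self.nu = error_model.df_array(lc)
        # initial path: interpolate observed positions onto the grid
        th = segment.hours_since_start()
        gh = grid.times_h
        self.x0_init = np.column_stack(
            [np.interp(gh, th, self.y[:, 0]), np.interp(gh, th, self.y[:, 1])]
        )


class _SegmentState:
    def __init__(self, data: _SegmentData, rng: np.random.Generator):
        self.d = data
        n = data.n
        self.x = data.x0_init + rng.normal(0.0, 1e-4, size=(n, 2))
        self.b = (rng.random(n) < 0.5).astype(np.int8)  # 0 = transit, 1 = ARS
        self.w = np.ones_like(data.y)  # t scale-mixture weights, per coordinate


def _update_w(st: _SegmentState, rng) -> None:
    d = st.d
    pred = (1.0 - d.j)[:, None] * st.x[d.k] + d.j[:, None] * st.x[d.k2]
    r2 = (d.y - pred) ** 2 * d.inv_s2
    shape = (d.nu[:, None] + 1.0) / 2.0
    rate = (d.nu[:, None] + r2) / 2.0
    st.w = rng.gamma(np.broadcast_to(shape, r2.shape)) / rate


def _update_x(st: _SegmentState, gamma: np.ndarray, sig_inv: np.ndarray, anchor_prec: float, rng) -> None:
    d = st.d
    n = d.n
    x = st.x
    g = gamma[st.b]  # per-time persistence
    W = st.w * d.inv_s2  # per-obs diagonal precisions
    for color in range(3):
        u = np.arange(color, n, 3)
        alpha = np.zeros(len(u))
        m = np.zeros((len(u), 2))
        # eq at t = u (needs u >= 2)
        msk = u >= 2
        uu = u[msk]
        m[msk] += (1.0 + g[uu])[:, None] * x[uu - 1] - g[uu][:, None] * x[uu - 2]
        alpha[msk] += 1.0
        # eq at t = u+1 (needs 1 <= u <= n-2)
        msk = (u >= 1) & (u <= n - 2)
        uu = u[msk]
        a = -(1.0 + g[uu + 1])
        c = x[uu + 1] + g[uu + 1][:, None] * x[uu - 1]
        m[msk] += -a[:, None] * c
        alpha[msk] += a**2
        # eq at t = u+2 (needs u <= n-3)
        msk = u <= n - 3
        uu = u[msk]
        a = g[uu + 2]
        c = x[uu + 2] - (1.0 + g[uu + 2])[:, None] * x[uu + 1]
        m[msk] += -a[:, None] * c
        alpha[msk] += a**2
        # observation ties
        beta = np.zeros((len(u), 2))
        dvec = np.zeros((len(u), 2))
        pos = np.full(n, -1)
        pos[u] = np.arange(len(u))
        left = pos[d.k] >= 0
        if left.any():
            i = np.where(left)[0]
            s = pos[d.k[i]]
            a_o = (1.0 - d.j[i])[:, None]
            resid = d.y[i] - d.j[i][:, None] * x[d.k2[i]]
            np.add.at(beta, s, a_o**2 * W[i])
            np.add.at(dvec, s, a_o * W[i] * resid)
        right = (pos[d.k2] >= 0) & (d.j > 0)
        if right.any():
            i = np.where(right)[0]
            s = pos[d.k2[i]]
            a_o = d.j[i][:, None]
            resid = d.y[i] - (1.0 - d.j[i])[:, None] * x[d.k[i]]
            np.add.at(beta, s, a_o**2 * W[i])
            np.add.at(dvec, s, a_o * W[i] * resid)
        # weak anchor on the first two states (proper posterior at the edge)
        anchor = u < 2
        if anchor.any():
            beta[anchor] += anchor_prec
            dvec[anchor] += anchor_prec * st.d.x0_init[u[anchor]]
        # assemble 2x2 precisions: alpha * Sigma^-1 + diag(beta)
        p11 = alpha * sig_inv[0, 0] + beta[:, 0]
        p12 = alpha * sig_inv[0, 1]
        p22 = alpha * sig_inv[1, 1] + beta[:, 1]
        h = m @ sig_inv + dvec
        # mean = P^-1 h, then x = mean + L^-T z with P = L L^T
        det = p11 * p22 - p12**2
        mu1 = (p22 * h[:, 0] - p12 * h[:, 1]) / det
        mu2 = (p11 * h[:, 1] - p12 * h[:, 0]) / det
        l11 = np.sqrt(p11)
        l21 = p12 / l11
        l22 = np.sqrt(np.maximum(p22 - l21**2, 1e-300))
        z = rng.standard_normal((len(u), 2))
        e2 = z[:, 1] / l22
        e1 = (z[:, 0] - l21 * e2) / l11
        x[u, 0] = mu1 + e1
        x[u, 1] = mu2 + e2


def _update_b(st: _SegmentState, gamma: np.ndarray, sig_inv: np.ndarray, logA: np.ndarray, rng) -> None:
    d = st.d
    n = d.n
    x = st.x
    for color in (0, 1):
        u = np.arange(color, n, 2)
        ll = np.zeros((len(u), 2))
        msk = u >= 2
        uu = u[msk]
        du = x[uu] - x[uu - 1]
        dv = x[uu - 1] - x[uu - 2]
        for s in (0, 1):
            r = du - gamma[s] * dv
            ll[msk, s] = -0.5 * (
                r[:, 0] ** 2 * sig_inv[0, 0]
                + 2.0 * r[:, 0] * r[:, 1] * sig_inv[0, 1]
                + r[:, 1] ** 2 * sig_inv[1, 1]
            )
        lp = np.zeros((len(u), 2))
        msk = u >= 1
        lp[msk] += logA[st.b[u[msk] - 1]]
        msk = u <= n - 2
        lp[msk] += logA[:, st.b[u[msk] + 1]].T
        logit = (ll[:, 1] + lp[:, 1]) - (ll[:, 0] + lp[:, 0])
        p_ars = 1.0 / (1.0 + np.exp(-np.clip(logit, -700, 700)))
        st.b[u] = (rng.random(len(u)) < p_ars).astype(np.int8)


def _truncnorm_draw(mu: float, sd: float, lo: float, hi: float, rng) -> float:
    margin = max(1e-12 * (hi - lo), 1e-15)
    a = ndtr((lo - mu) / sd)
    b = ndtr((hi - mu) / sd)
    if b - a < 1e-12:  # numerically degenerate tail: clamp
        return float(np.clip(mu, lo + margin, hi - margin))
    u = a + rng.random() * (b - a)
    # the inverse CDF loses precision in extreme tails; keep the draw
    # strictly inside the open interval
    return float(np.clip(mu + sd * ndtri(u), lo + margin, hi - margin))


def _update_gamma(states: list[_SegmentState], gamma: np.ndarray, sig_inv: np.ndarray, rng) -> None:
    # conditional for gamma_s is normal (linear model u = gamma v + eps),
    # truncated to the ordering constraint gamma_transit > gamma_ars
    q = np.zeros(2)
    num = np.zeros(2)
    for st in states:
        x = st.x
        if st.d.n < 3:
            continue
        du = x[2:] - x[1:-1]
        dv = x[1:-1] - x[:-2]
        b = st.b[2:]
        vSv = (
            dv[:, 0] ** 2 * sig_inv[0, 0]
            + 2.0 * dv[:, 0] * dv[:, 1] * sig_inv[0, 1]
            + dv[:, 1] ** 2 * sig_inv[1, 1]
        )
        vSu = (
            dv[:, 0] * (sig_inv[0, 0] * du[:, 0] + sig_inv[0, 1] * du[:, 1])
            + dv[:, 1] * (sig_inv[1, 0] * du[:, 0] + sig_inv[1, 1] * du[:, 1])
        )
        for s in (0, 1):
            sel = b == s
            q[s] += vSv[sel].sum()
            num[s] += vSu[sel].sum()
    # transit on (gamma_ars, 1), then ars on (0, the *updated* gamma_transit)
    for s in (0, 1):
        lo, hi = (gamma[1], 1.0) if s == 0 else (0.0, gamma[0])
        if q[s] > 0:
            gamma[s] = _truncnorm_draw(num[s] / q[s], 1.0 / np.sqrt(q[s]), lo, hi, rng)
        else:
            gamma[s] = rng.uniform(lo, hi)


def _update_sigma(states: list[_SegmentState], gamma: np.ndarray, rng) -> np.ndarray:
    nu0, S0 = 4.0, np.eye(2) * 1e-6
    S = S0.copy()
    n = 0
    for st in states:
        if st.d.n < 3:
            continue
        x = st.x
        du = x[2:] - x[1:-1]
        dv = x[1:-1] - x[:-2]
        e = du - gamma[st.b[2:]][:, None] * dv
        S += e.T @ e
        n += len(e)
    return invwishart.rvs(df=nu0 + n, scale=S, random_state=rng)


def _update_switch(states: list[_SegmentState], rng) -> np.ndarray:
    counts = np.zeros((2, 2))
    for st in states:
        b = st.b
        for i in (0, 1):
            for jj in (0, 1):
                counts[i, jj] += np.sum((b[:-1] == i) & (b[1:] == jj))
    A = np.empty((2, 2))
    for i in (0, 1):
        stay = rng.beta(1.0 + counts[i, i], 1.0 + counts[i, 1 - i])
        A[i, i] = stay
        A[i, 1 - i] = 1.0 - stay
    return A


def _run_chain(
    seg_data: list[_SegmentData],
    spec: ModelSpec,
    n_iter: int,
    burn_in: int,
    thin: int,
    seed: int,
):
    rng = np.random.default_rng(seed)
    states = [_SegmentState(d, rng) for d in seg_data]
    gamma = np.clip(
        np.array(spec.gamma_init, dtype=float) + rng.uniform(-0.05, 0.05, 2),
        1e-3,
        1.0 - 1e-3,
    )
    if gamma[0] <= gamma[1]:  # restore the ordering constraint after jitter
        gamma = np.array([max(gamma) + 1e-3, min(gamma)])
        gamma = np.clip(gamma, 1e-3, 1.0 - 1e-3)
    if spec.sigma_init is not None:
        sigma = np.asarray(spec.sigma_init, dtype=float).copy()
    else:
        d0 = np.concatenate([np.diff(st.d.x0_init, axis=0) for st in states])
        sigma = np.cov(d0.T) + np.eye(2) * 1e-6
    A = np.asarray(spec.switch_init, dtype=float).copy()
    anchor_prec = 1.0 / spec.anchor_sd**2

    n_keep = (n_iter - burn_in) // thin
    kept_x = [np.empty((n_keep, d.n, 2)) for d in seg_data]
    kept_b = [np.empty((n_keep, d.n), dtype=np.int8) for d in seg_data]
    kept_gamma = np.empty((n_keep, 2))
    kept_sigma = np.empty((n_keep, 2, 2))
    kept_switch = np.empty((n_keep, 2, 2))
    kept_idx = np.empty(n_keep, dtype=int)

    stored = 0
    sig_inv = np.linalg.inv(sigma)
    logA = np.log(np.clip(A, 1e-12, None))
    for it in range(n_iter):
        for st in states:
            _update_w(st, rng)
            _update_x(st, gamma, sig_inv, anchor_prec, rng)
            for _ in range(3):  # extra state sweeps: cheap, improves b mixing
                _update_b(st, gamma, sig_inv, logA, rng)
        _update_gamma(states, gamma, sig_inv, rng)
        if spec.estimate_sigma:
            sigma = _update_sigma(states, gamma, rng)
            sig_inv = np.linalg.inv(sigma)
        A = _update_switch(states, rng)
        logA = np.log(np.clip(A, 1e-12, None))
        post = it - burn_in
        if post >= 0 and (post + 1) % thin == 0 and stored < n_keep:
            for s, st in enumerate(states):
                kept_x[s][stored] = st.x
                kept_b[s][stored] = st.b + 1
            kept_gamma[stored] = gamma
            kept_sigma[stored] = sigma
            kept_switch[stored] = A
            kept_idx[stored] = it
            stored += 1
    return kept_x, kept_b, kept_gamma, kept_sigma, kept_switch, kept_idx


def fit_hssm(
    segments: list[TrackSegment],
    spec: ModelSpec | None = None,
    plan: McmcPlan | None = None,
) -> tuple[list[StateSeries], PosteriorDraws, ConvergenceReport]:
    """Fit the switching state-space model to one or more track segments.

    In hierarchical mode (``spec.hierarchy``, the default) all segments
    share the movement parameters (gamma, Sigma, switch probabilities)
    while keeping per-segment latent paths; otherwise each segment is
    fitted independently and draws are concatenated segment-wise with
    parameters taken from the first segment's run.

    Returns per-segment :class:`StateSeries`, the retained
    :class:`PosteriorDraws` (``plan.retained`` samples), and a
    :class:`ConvergenceReport`.  Non-convergence is flagged in the
    report, never silenced.
    """
    spec = spec or ModelSpec()
    plan = plan or McmcPlan()
    if not segments:
        raise ValueError("need at least one track segment")
    if not spec.hierarchy and len(segments) > 1:
        results = [
            fit_hssm([s], replace(spec, hierarchy=True), plan) for s in segments
        ]
        return _merge_independent(results, plan)

    seg_data = [
        _SegmentData(s, build_regular_grid(s, spec.dt), spec.error_model)
        for s in segments
    ]
    n_iter = plan.burn_in + plan.post_burn_in
    seed_seq = np.random.SeedSequence(plan.seed)
    chain_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(plan.n_chains)]

    all_x = [[] for _ in seg_data]
    all_b = [[] for _ in seg_data]
    g_list, s_list, a_list, c_list, i_list = [], [], [], [], []
    for c, cs in enumerate(chain_seeds):
        kx, kb, kg, ks, ka, ki = _run_chain(
            seg_data, spec, n_iter, plan.burn_in, plan.thin, cs
        )
        for s in range(len(seg_data)):
            all_x[s].append(kx[s])
            all_b[s].append(kb[s])
        g_list.append(kg)
        s_list.append(ks)
        a_list.append(ka)
        c_list.append(np.full(len(kg), c))
        i_list.append(ki)

    draws = PosteriorDraws(
        segment_meta=[
            {
                "tag_id": d.tag_id,
                "segment_index": d.segment_index,
                "timestamps": d.grid.timestamps(),
                "n_states": d.n,
            }
            for d in seg_data
        ],
        x=[np.concatenate(xs) for xs in all_x],
        b=[np.concatenate(bs) for bs in all_b],
        gamma=np.concatenate(g_list),
        sigma=np.concatenate(s_list),
        switch=np.concatenate(a_list),
        chain=np.concatenate(c_list),
        draw=np.concatenate(i_list),
    )
    # ordering constraint must hold in every retained draw
    if not (draws.gamma[:, 0] > draws.gamma[:, 1]).all():
        raise AssertionError("gamma ordering constraint violated in retained draws")
    series = _summarise(draws)
    report = diagnose(draws.param_chains())
    if not report.converged:
        logger.warning("; ".join(report.notes))
    return series, draws, report


def _merge_independent(results, plan: McmcPlan):
    series = [r[0][0] for r in results]
    first = results[0][1]
    draws = PosteriorDraws(
        segment_meta=[r[1].segment_meta[0] for r in results],
        x=[r[1].x[0] for r in results],
        b=[r[1].b[0] for r in results],
        gamma=first.gamma,
        sigma=first.sigma,
        switch=first.switch,
        chain=first.chain,
        draw=first.draw,
    )
    report = diagnose(first.param_chains())
    return series, draws, report


def _summarise(draws: PosteriorDraws) -> list[StateSeries]:
    out = []
    for meta, xs, bs in zip(draws.segment_meta, draws.x, draws.b):
        lon = xs[:, :, 0]
        lat = xs[:, :, 1]
        mean_b = bs.mean(axis=0)
        df = pd.DataFrame(
            {
                "tag_id": meta["tag_id"],
                "segment": meta["segment_index"],
                "timestamp": meta["timestamps"],
                "lon": lon.mean(axis=0),
                "lat": lat.mean(axis=0),
                "lon_lo": np.quantile(lon, 0.025, axis=0),
                "lon_hi": np.quantile(lon, 0.975, axis=0),
                "lat_lo": np.quantile(lat, 0.025, axis=0),
                "lat_hi": np.quantile(lat, 0.975, axis=0),
                "mean_b": mean_b,
                "p_ars": mean_b - 1.0,
                "mode_state": np.where(mean_b > 1.5, 2, 1),
            }
        )
        out.append(StateSeries(meta["tag_id"], meta["segment_index"], df))
    return out


def export_state_series(series: list[StateSeries], path, sep: str = ",") -> None:
    """Write concatenated state series as delimited text."""
    pd.concat([s.data for s in series], ignore_index=True).to_csv(
        path, sep=sep, index=False
    )
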