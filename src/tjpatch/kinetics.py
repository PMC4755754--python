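"""Amplitude and dwell-time statistics.

All-points amplitude histograms (0.1 pA bins, normalized to record
duration as samples/s) are fitted with 1–3 component Gaussian mixtures
by weighted EM on the binned densities.  Dwell-time distributions are
fitted on the raw (unbinned) durations by maximum likelihood with one or
two exponential components; the number of kinetic states is chosen by a
likelihood-ratio test.  Log-spaced dwell histograms (2 bins per decade)
are provided for display.

Dwell fits subtract the detection dead time before fitting: left
truncation of an exponential mixture at the dead time preserves each
component's time constant under this shift, so the tau estimates remain
consistent despite the unavoidable censoring of brief events.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .recording import CurrentTrace

__all__ = [
    "AmplitudeHistogram",
    "DwellTimeFit",
    "all_points_histogram",
    "fit_gaussian_mixture",
    "dwell_histogram",
    "fit_dwell_exponentials",
    "compare_dwell_models",
    "classify_kinetic_states",
]

AMPLITUDE_BIN_PA = 0.1
LRT_ALPHA = 0.01


@dataclass
class AmplitudeHistogram:
    """All-points histogram: 0.1 pA bins, density in samples/s."""

    bin_edges: np.ndarray
    counts: np.ndarray
    density: np.ndarray  # samples/s per bin
    duration_s: float
    components: list[tuple[float, float, float]] | None = None  # (mean, sd, weight)
    degenerate: bool = False  # set when a fitted sd hit the bin-width floor

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class DwellTimeFit:
    """Exponential-mixture ML fit of dwell durations.

    ``components`` are (tau_s, fraction) pairs sorted by ascending tau;
    fractions refer to detected (dead-time-truncated) events.
    """

    state_class: str  # "open" | "closed"
    components: list[tuple[float, float]]
    n_events: int
    log_likelihood: float
    dead_time_s: float = 0.0
    degenerate: bool = False

    @property
    def taus(self) -> list[float]:
        return [t for t, _ in self.components]


def all_points_histogram(trace: CurrentTrace, bin_pa: float = AMPLITUDE_BIN_PA) -> AmplitudeHistogram:
    """Histogram every sample of the trace on a fixed 0.1 pA grid."""
    x = trace.samples
    if x.size == 0:
        raise ValueError("empty trace")
    # edges on exact integer multiples of the bin width, covering all data
    k0 = int(np.floor(x.min() / bin_pa))
    k1 = int(np.floor(x.max() / bin_pa)) + 1
    edges = bin_pa * np.arange(k0, k1 + 1)
    counts, edges = np.histogram(x, bins=edges)
    duration = trace.duration_s
    return AmplitudeHistogram(edges, counts, counts / duration, duration)


def fit_gaussian_mixture(
    hist: AmplitudeHistogram,
    k: int,
    n_starts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> list[tuple[float, float, float]]:
    """Weighted-EM Gaussian mixture fit of a binned amplitude histogram.

    Bin centers act as observations weighted by their counts, which is
    the ML problem for binned data in the fine-bin limit.  Multi-starts
    are deterministic: component means are spread over the occupied
    range at ``n_starts`` different quantile offsets.  SDs are floored
    at the bin width; hitting the floor marks the fit degenerate.

    Returns (mean, sd, weight) per component, sorted by mean, and stores
    them on ``hist.components``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x = hist.centers
    w = hist.counts.astype(float)
    occupied = w > 0
    if occupied.sum() < 3 * k - 2:
        raise ValueError("fewer occupied bins than mixture parameters")
    x, w = x[occupied], w[occupied]
    n = w.sum()
    bin_w = float(hist.bin_edges[1] - hist.bin_edges[0])
    mean_all = float(np.sum(w * x) / n)
    sd_all = float(np.sqrt(np.sum(w * (x - mean_all) ** 2) / n)) or bin_w

    def em(mu0: np.ndarray) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
        mu = mu0.copy()
        sd = np.full(k, max(sd_all / k, bin_w))
        pi = np.full(k, 1.0 / k)
        ll_old = -np.inf
        for _ in range(max_iter):
            logp = (
                np.log(pi)[:, None]
                + stats.norm.logpdf(x[None, :], mu[:, None], sd[:, None])
            )
            m = logp.max(axis=0)
            lse = m + np.log(np.exp(logp - m).sum(axis=0))
            ll = float(np.sum(w * lse))
            r = np.exp(logp - lse)  # responsibilities (k, nbins)
            wk = (r * w).sum(axis=1)
            pi = wk / n
            mu = (r * w * x).sum(axis=1) / wk
            var = (r * w * (x[None, :] - mu[:, None]) ** 2).sum(axis=1) / wk
            sd = np.sqrt(np.maximum(var, bin_w**2))
            if abs(ll - ll_old) < tol * (1 + abs(ll)):
                break
            ll_old = ll
        return ll, mu, sd, pi

    # deterministic multi-starts: means at shifted quantiles of the data
    qgrid = np.linspace(0.0, 1.0, k + 2)[1:-1]
    starts = []
    for s in range(n_starts):
        shift = (s - (n_starts - 1) / 2) / (2 * n_starts)
        q = np.clip(qgrid + shift, 0.01, 0.99)
        cdf = np.cumsum(w) / n
        starts.append(np.interp(q, cdf, x))
    best = max((em(np.asarray(m0)) for m0 in starts), key=lambda r: r[0])
    _, mu, sd, pi = best
    order = np.argsort(mu)
    comps = [(float(mu[i]), float(sd[i]), float(pi[i])) for i in order]
    hist.components = comps
    hist.degenerate = bool(np.any(sd <= bin_w * (1 + 1e-9)))
    return comps


def dwell_histogram(
    durations: np.ndarray, bins_per_decade: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Log-spaced dwell histogram (edges, counts); counts are conserved.

    A coarse 2-bins-per-decade grid gives adequate occupancy even for
    sparse, very long closed dwells.
    """
    d = np.asarray(durations, dtype=float)
    if d.size == 0:
        raise ValueError("no durations")
    if np.any(d <= 0):
        raise ValueError("durations must be > 0")
    lo = np.floor(np.log10(d.min()) * bins_per_decade) / bins_per_decade
    hi = np.ceil(np.log10(d.max()) * bins_per_decade) / bins_per_decade
    if hi <= lo:
        hi = lo + 1.0 / bins_per_decade
    n_edges = int(round((hi - lo) * bins_per_decade)) + 1
    edges = 10 ** np.linspace(lo, hi, n_edges)
    edges[-1] *= 1 + 1e-12  # right-inclusive top edge
    counts, _ = np.histogram(d, bins=edges)
    return edges, counts


def _exp_mixture_ll(y: np.ndarray, taus: np.ndarray, fracs: np.ndarray) -> float:
    logp = np.log(fracs)[:, None] - np.log(taus)[:, None] - y[None, :] / taus[:, None]
    m = logp.max(axis=0)
    return float(np.sum(m + np.log(np.exp(logp - m).sum(axis=0))))


def fit_dwell_exponentials(
    durations: np.ndarray,
    n_components: int = 1,
    state_class: str = "open",
    dead_time_s: float = 0.0,
    max_iter: int = 2000,
    tol: float = 1e-12,
) -> DwellTimeFit:
    """Maximum-likelihood exponential(-mixture) fit of raw dwell durations.

    For one component the ML estimate is the sample mean (of the
    dead-time-shifted durations) in closed form.  For two components a
    deterministic multi-start EM is used.  Requires at least 10 events
    per free parameter.
    """
    d = np.asarray(durations, dtype=float)
    d = d[np.isfinite(d)]
    if np.any(d <= 0):
        raise ValueError("durations must be > 0")
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    n_params = 2 * n_components - 1
    if d.size < 10 * n_params:
        raise ValueError(f"need at least {10 * n_params} events for {n_components} component(s)")
    y = d - dead_time_s
    y = y[y > 0]
    if y.size < 10 * n_params:
        raise ValueError("too few events above the dead time")

    if n_components == 1:
        tau = float(np.mean(y))
        ll = _exp_mixture_ll(y, np.array([tau]), np.array([1.0]))
        return DwellTimeFit(state_class, [(tau, 1.0)], int(y.size), ll, dead_time_s)

    mean = float(np.mean(y))
    q = np.quantile(y, [0.10, 0.25, 0.50, 0.75, 0.90])
    starts = [
        (q[1], q[4]),
        (q[0], q[3]),
        (mean / 10, mean),
        (mean, mean * 10),
        (q[2] / 5, q[2] * 5),
    ]

    def em(t0: tuple[float, float]):
        taus = np.array(t0, dtype=float)
        fracs = np.array([0.5, 0.5])
        ll_old = -np.inf
        for _ in range(max_iter):
            logp = np.log(fracs)[:, None] - np.log(taus)[:, None] - y[None, :] / taus[:, None]
            m = logp.max(axis=0)
            lse = m + np.log(np.exp(logp - m).sum(axis=0))
            ll = float(np.sum(lse))
            r = np.exp(logp - lse)
            wk = r.sum(axis=1)
            fracs = np.clip(wk / y.size, 1e-12, None)
            fracs /= fracs.sum()
            taus = np.clip((r * y[None, :]).sum(axis=1) / np.maximum(wk, 1e-300), 1e-12, None)
            if abs(ll - ll_old) < tol * (1 + abs(ll)):
                break
            ll_old = ll
        return ll, taus, fracs

    ll, taus, fracs = max((em(t0) for t0 in starts), key=lambda r: r[0])
    order = np.argsort(taus)
    comps = [(float(taus[i]), float(fracs[i])) for i in order]
    degenerate = bool(min(fracs) < 1e-6 or abs(taus[0] - taus[1]) < 1e-9 * max(taus))
    return DwellTimeFit(state_class, comps, int(y.size), ll, dead_time_s, degenerate)


def compare_dwell_models(
    durations: np.ndarray,
    state_class: str = "open",
    dead_time_s: float = 0.0,
    alpha: float = LRT_ALPHA,
) -> tuple[DwellTimeFit, DwellTimeFit | None, float]:
    """Fit 1 and 2 exponential components and pick by likelihood ratio.

    Returns (preferred fit, the other fit or None, LRT p-value).  The
    two-component model is accepted when the likelihood-ratio statistic
    2·ΔlogL exceeds the χ²₂ critical value at ``alpha`` (the extra
    component adds a tau and a fraction).
    """
    fit1 = fit_dwell_exponentials(durations, 1, state_class, dead_time_s)
    try:
        fit2 = fit_dwell_exponentials(durations, 2, state_class, dead_time_s)
    except ValueError:
        return fit1, None, 1.0
    lam = max(0.0, 2.0 * (fit2.log_likelihood - fit1.log_likelihood))
    p = float(stats.chi2.sf(lam, df=2))
    if p < alpha and not fit2.degenerate:
        return fit2, fit1, p
    return fit1, fit2, p


def classify_kinetic_states(
    open_durations: np.ndarray,
    closed_durations: np.ndarray,
    dead_time_s: float = 0.0,
    alpha: float = LRT_ALPHA,
) -> dict:
    """Count kinetic states from dwell-time distributions.

    One open state is reported iff a single exponential is preferred for
    open durations; two closed states iff a double exponential is
    preferred for closed durations, with the fast/slow components
    labelled transient/stable.  A fitted component with zero weight
    collapses the count.
    """
    open_fit, _, p_open = compare_dwell_models(open_durations, "open", dead_time_s, alpha)
    closed_fit, _, p_closed = compare_dwell_models(closed_durations, "closed", dead_time_s, alpha)

    def effective(fit: DwellTimeFit) -> list[tuple[float, float]]:
        return [(t, f) for t, f in fit.components if f > 1e-6]

    open_comps = effective(open_fit)
    closed_comps = effective(closed_fit)
    out = {
        "n_open_states": len(open_comps),
        "n_closed_states": len(closed_comps),
        "tau_open_s": open_comps[-1][0] if len(open_comps) == 1 else None,
        "open_fit": open_fit,
        "closed_fit": closed_fit,
        "p_open": p_open,
        "p_closed": p_closed,
    }
    if len(closed_comps) == 2:
        out["tau_closed_transient_s"] = closed_comps[0][0]
        out["tau_closed_stable_s"] = closed_comps[1][0]
    elif len(closed_comps) == 1:
        out["tau_closed_s"] = closed_comps[0][0]
    return out
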