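"""Windowed Spearman connectivity with a surrogate-data null model.

Functional connections are inferred per 150-s window: every neuron pair's
Spearman rank correlation is compared against an empirical null built from
spectral surrogates of the same window — synthetic signals that keep each
trace's Fourier amplitude spectrum but draw phases (per frequency bin,
with replacement) from the pooled empirical phases of all recorded signals
of that window.  Pairs whose correlation falls outside two null standard
deviations are candidate connections; Benjamini–Hochberg FDR over all
pairs of the window refines them into the final adjacency matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .core import CalnetError

__all__ = [
    "AnalysisWindows",
    "SurrogateNull",
    "WindowedCorrelation",
    "FunctionalNetwork",
    "segment_windows",
    "spearman_matrix",
    "build_phase_pool",
    "make_surrogates",
    "pair_significance",
    "fdr_refine",
    "window_connectivity",
    "build_adjacency",
]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_SECONDS = 150.0
DEFAULT_N_WINDOWS = 5
DEFAULT_N_SURROGATES = 1000
DEFAULT_K_SD = 2.0
DEFAULT_Q = 0.05


@dataclass(frozen=True)
class AnalysisWindows:
    """Non-overlapping, contiguous half-open frame intervals."""

    boundaries: tuple[tuple[int, int], ...]
    labels: tuple[str, ...]
    window_seconds: float
    fs: float

    def __len__(self) -> int:
        return len(self.boundaries)

    def slice(self, traces: np.ndarray, k: int) -> np.ndarray:
        a, b = self.boundaries[k]
        return traces[..., a:b]


def segment_windows(
    n_frames: int,
    fs: float,
    window_seconds: float = DEFAULT_WINDOW_SECONDS,
    n_windows: int = DEFAULT_N_WINDOWS,
) -> AnalysisWindows:
    """Cut a recording into ``n_windows`` consecutive equal windows.

    Windows start at frame 0 and each spans ``round(window_seconds * fs)``
    frames; trailing frames beyond the last window are dropped (logged).
    The first window is labelled ``before`` (pre-stimulus), the rest
    ``window 1`` .. ``window n-1``.
    """
    if fs <= 0 or window_seconds <= 0 or n_windows < 1:
        raise CalnetError("fs, window_seconds and n_windows must be positive")
    frames_per = int(round(window_seconds * fs))
    needed = frames_per * n_windows
    if n_frames < needed:
        raise CalnetError(
            f"recording of {n_frames} frames is too short for {n_windows} windows "
            f"of {frames_per} frames (need {needed})"
        )
    dropped = n_frames - needed
    if dropped:
        logger.info("segment_windows: dropping %d trailing frames", dropped)
    bounds = tuple(
        (k * frames_per, (k + 1) * frames_per) for k in range(n_windows)
    )
    labels = tuple(
        "before" if k == 0 else f"window {k}" for k in range(n_windows)
    )
    return AnalysisWindows(bounds, labels, window_seconds, fs)


def spearman_matrix(traces: np.ndarray) -> np.ndarray:
    """Spearman rank-correlation matrix of neuron x frame traces.

    Ties receive average ranks.  The diagonal is exactly 1.  Rows with zero
    variance produce NaN in their off-diagonal entries (logged); callers
    exclude those pairs downstream.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    n, m = traces.shape
    if m < 3:
        raise CalnetError("need at least 3 frames per window")
    if n < 2:
        raise CalnetError("need at least 2 neurons")
    valid = traces.var(axis=1) > 0
    if not valid.all():
        logger.warning(
            "spearman_matrix: %d zero-variance trace(s); their pairs are NaN",
            int((~valid).sum()),
        )
    ranks = rankdata(traces, axis=1)
    rho = np.full((n, n), np.nan)
    if valid.sum() >= 2:
        sub = np.corrcoef(ranks[valid])
        idx = np.flatnonzero(valid)
        rho[np.ix_(idx, idx)] = np.clip(sub, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def build_phase_pool(traces: np.ndarray) -> np.ndarray:
    """Per-frequency-bin empirical phase pool from the window's real signals.

    Returns an (n_signals, n_inner_bins) array of phases at the positive,
    non-Nyquist frequency bins of the rFFT.  Pooling is per bin: a
    surrogate's phase at bin j is drawn from column j only, so the
    low-frequency phase structure of the data is not mixed into other bands.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    spec = np.fft.rfft(traces, axis=1)
    n = traces.shape[1]
    last = spec.shape[1] - 1 if n % 2 == 0 else spec.shape[1]
    return np.angle(spec[:, 1:last])


def make_surrogates(
    trace: np.ndarray,
    phase_pool: np.ndarray | None,
    n: int = DEFAULT_N_SURROGATES,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Spectral surrogates of one trace (amplitude kept, phases resampled).

    Each surrogate keeps the trace's rFFT amplitude spectrum bin for bin and
    assigns each inner frequency bin a phase drawn with replacement from the
    corresponding column of ``phase_pool``.  The DC and (for even lengths)
    Nyquist components are kept verbatim, so the surrogate is real, has the
    trace's length, amplitude spectrum and variance.  An empty pool falls
    back to uniform random phases with a logged warning.
    """
    trace = np.asarray(trace, dtype=float)
    L = trace.size
    if L < 8:
        raise CalnetError("trace too short for surrogate construction")
    if n < 1:
        raise CalnetError("need at least one surrogate")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spec = np.fft.rfft(trace)
    nf = spec.size
    inner = slice(1, nf - 1) if L % 2 == 0 else slice(1, nf)
    n_inner = (nf - 2) if L % 2 == 0 else (nf - 1)
    amp = np.abs(spec[inner])

    if phase_pool is None or phase_pool.size == 0:
        logger.warning("make_surrogates: empty phase pool, using uniform phases")
        phases = rng.uniform(-np.pi, np.pi, size=(n, n_inner))
    else:
        if phase_pool.shape[1] != n_inner:
            raise CalnetError(
                f"phase pool has {phase_pool.shape[1]} bins, trace needs {n_inner}"
            )
        pick = rng.integers(0, phase_pool.shape[0], size=(n, n_inner))
        phases = phase_pool[pick, np.arange(n_inner)]

    out_spec = np.empty((n, nf), dtype=complex)
    out_spec[:, 0] = spec[0]
    if L % 2 == 0:
        out_spec[:, -1] = spec[-1]
    out_spec[:, inner] = amp * np.exp(1j * phases)
    return np.fft.irfft(out_spec, n=L, axis=1)


@dataclass
class SurrogateNull:
    """Null-distribution summary for one neuron pair."""

    pair: tuple[int, int]
    n_surrogates: int
    null_mean: float
    null_sd: float
    empirical_p: float
    rng_seed: int

    def __post_init__(self) -> None:
        if self.n_surrogates < 1:
            raise CalnetError("n_surrogates must be >= 1")
        if self.null_sd < 0:
            raise CalnetError("null_sd must be non-negative")
        if not (0 < self.empirical_p <= 1):
            raise CalnetError("empirical_p must lie in (0, 1]")


def pair_significance(
    rho_ij: float,
    null_mean: float,
    null_sd: float,
    null_samples: np.ndarray | None = None,
    k_sd: float = DEFAULT_K_SD,
) -> tuple[bool, float]:
    """Two-sided 2-SD selection plus add-one empirical p for one pair.

    flag = |rho - mu_null| > k_sd * sd_null (strict inequality on the
    deviation itself when sd_null is 0); the empirical p uses the add-one
    rule ``(1 + #{|null - mu| >= |rho - mu|}) / (n + 1)`` so it is never 0.
    """
    dev = abs(rho_ij - null_mean)
    flag = dev > k_sd * null_sd if null_sd > 0 else dev > 0
    if null_samples is None:
        return flag, np.nan
    null_samples = np.asarray(null_samples, dtype=float)
    n = null_samples.size
    count = int(np.sum(np.abs(null_samples - null_mean) >= dev))
    return flag, (1 + count) / (n + 1)


def fdr_refine(
    pvals: np.ndarray,
    q: float = DEFAULT_Q,
    raw_flags: np.ndarray | None = None,
) -> np.ndarray:
    """Benjamini–Hochberg step-up over all pairs of one window.

    Returns a boolean mask, true where BH rejects at level ``q`` and (when
    given) the 2-SD raw flag also holds, so the refined mask is always a
    subset of the raw mask.  NaN p values (undefined pairs) are never
    selected.
    """
    pvals = np.asarray(pvals, dtype=float)
    if not (0 < q < 1):
        raise CalnetError("q must lie in (0, 1)")
    if pvals.size == 0:
        return np.zeros(0, dtype=bool)
    ok = np.isfinite(pvals)
    reject = np.zeros(pvals.shape, dtype=bool)
    if ok.any():
        reject[ok] = multipletests(pvals[ok], alpha=q, method="fdr_bh")[0]
    if raw_flags is not None:
        reject &= np.asarray(raw_flags, dtype=bool)
    return reject


@dataclass
class WindowedCorrelation:
    """Per-window Spearman matrix with its surrogate-null statistics."""

    rho: np.ndarray           # (n, n), unit diagonal
    null_mean: np.ndarray     # (n, n), NaN on diagonal / invalid pairs
    null_sd: np.ndarray
    pvals: np.ndarray         # p used for FDR (per p_mode), NaN where undefined
    empirical_pvals: np.ndarray  # add-one empirical p, NaN where undefined
    raw_mask: np.ndarray      # |rho - mu| > k_sd * sd
    fdr_mask: np.ndarray      # BH-refined, subset of raw_mask
    k_sd: float
    q_level: float
    n_surrogates: int
    null_mode: str
    p_mode: str
    rng_seed: int
    window_label: str = ""
    invalid_neurons: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    def null_for(self, i: int, j: int) -> SurrogateNull:
        return SurrogateNull(
            pair=(min(i, j), max(i, j)),
            n_surrogates=self.n_surrogates,
            null_mean=float(self.null_mean[i, j]),
            null_sd=float(self.null_sd[i, j]),
            empirical_p=float(self.empirical_pvals[i, j]),
            rng_seed=self.rng_seed,
        )


def _standardized_ranks(x: np.ndarray) -> np.ndarray:
    """Rank-transform along the last axis and z-score each series."""
    r = rankdata(x, axis=-1).astype(float)
    r -= r.mean(axis=-1, keepdims=True)
    sd = r.std(axis=-1, keepdims=True)
    sd[sd == 0] = np.nan
    return r / sd


def window_connectivity(
    traces: np.ndarray,
    n_surrogates: int = DEFAULT_N_SURROGATES,
    seed: int = 0,
    k_sd: float = DEFAULT_K_SD,
    q: float = DEFAULT_Q,
    null_mode: str = "paired",
    p_mode: str = "normal",
    window_label: str = "",
) -> WindowedCorrelation:
    """Full significance pipeline for one window's traces.

    Builds ``n_surrogates`` spectral surrogates per signal (phases pooled
    across the window's signals), then for every pair forms the null of
    Spearman correlations between the k-th surrogate of each endpoint
    (``null_mode='paired'``, the default).  ``null_mode='pooled'`` instead
    pools all surrogate-pair correlations into a single window-wide null —
    cheaper in memory for very large populations, recorded in the output.
    The 2-SD rule gives the raw mask; BH-FDR over all pairs refines it.

    ``p_mode`` selects the per-pair p fed to the FDR step: ``'normal'``
    (default) evaluates the two-sided Gaussian tail of the null z-score
    ``(rho - mu_null) / sd_null`` — matching the mean/SD summary the 2-SD
    rule itself uses, and fine-grained enough for step-up correction over
    few pairs; ``'empirical'`` uses the add-one tail proportion of the
    surrogate null, whose resolution is limited to 1/(n_surrogates+1).
    Both p sets are stored.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    n, L = traces.shape
    if null_mode not in ("paired", "pooled"):
        raise CalnetError("null_mode must be 'paired' or 'pooled'")
    if p_mode not in ("normal", "empirical"):
        raise CalnetError("p_mode must be 'normal' or 'empirical'")
    if n_surrogates < 100:
        raise CalnetError("need at least 100 surrogates for a stable null SD")
    rho = spearman_matrix(traces)
    valid = traces.var(axis=1) > 0
    invalid_idx = np.flatnonzero(~valid)

    pool = build_phase_pool(traces[valid]) if valid.any() else None
    rng = np.random.default_rng(seed)
    # surrogate -> standardized ranks, one neuron at a time to bound memory
    Z = np.empty((n, n_surrogates, L))
    for i in range(n):
        if not valid[i]:
            Z[i] = np.nan
            continue
        S = make_surrogates(traces[i], pool, n=n_surrogates, seed=rng)
        Z[i] = _standardized_ranks(S)

    # null correlation matrices, one per surrogate index
    null = np.empty((n_surrogates, n, n))
    for k in range(n_surrogates):
        Zk = Z[:, k, :]
        null[k] = (Zk @ Zk.T) / L
    del Z

    eye = np.eye(n, dtype=bool)
    if null_mode == "pooled":
        offdiag = ~eye
        pooled = null[:, offdiag]
        pooled = pooled[np.isfinite(pooled)]
        mu = np.full((n, n), pooled.mean())
        sd = np.full((n, n), pooled.std(ddof=1))
        dev = np.abs(rho - mu)
        # tail counts against the pooled sample
        flat = np.abs(pooled - pooled.mean())
        counts = np.searchsorted(np.sort(flat), dev, side="left")
        emp_pvals = (1 + (flat.size - counts)) / (flat.size + 1)
    else:
        mu = null.mean(axis=0)
        sd = null.std(axis=0, ddof=1)
        dev = np.abs(rho - mu)
        exceed = (np.abs(null - mu[None]) >= dev[None]).sum(axis=0)
        emp_pvals = (1 + exceed) / (n_surrogates + 1)

    raw = dev > k_sd * sd
    zero_sd = sd == 0
    raw[zero_sd] = dev[zero_sd] > 0
    bad = ~np.isfinite(rho) | ~np.isfinite(mu)
    raw[bad] = False
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, dev / sd, np.inf)
    norm_pvals = 2.0 * stats.norm.sf(z)
    emp_pvals = np.asarray(emp_pvals, dtype=float)
    pvals = norm_pvals if p_mode == "normal" else emp_pvals
    for arr in (pvals, emp_pvals):
        arr[bad] = np.nan
        np.fill_diagonal(arr, np.nan)
    np.fill_diagonal(raw, False)
    mu[eye] = np.nan
    sd[eye] = np.nan

    iu = np.triu_indices(n, k=1)
    fdr_flat = fdr_refine(pvals[iu], q=q, raw_flags=raw[iu])
    fdr = np.zeros((n, n), dtype=bool)
    fdr[iu] = fdr_flat
    fdr |= fdr.T

    return WindowedCorrelation(
        rho=rho, null_mean=mu, null_sd=sd, pvals=pvals,
        empirical_pvals=emp_pvals if p_mode == "normal" else emp_pvals.copy(),
        raw_mask=raw, fdr_mask=fdr, k_sd=k_sd, q_level=q,
        n_surrogates=n_surrogates, null_mode=null_mode, p_mode=p_mode,
        rng_seed=seed, window_label=window_label, invalid_neurons=invalid_idx,
    )


@dataclass
class FunctionalNetwork:
    """Unweighted functional network of one window."""

    adjacency: np.ndarray     # bool, symmetric, hollow
    depths: np.ndarray
    window_label: str
    edge_rho: dict[tuple[int, int], float]

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise CalnetError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency)):
            raise CalnetError("adjacency must be hollow")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for i in range(self.n_nodes):
            g.add_node(i, depth=float(self.depths[i]))
        for (i, j), r in self.edge_rho.items():
            g.add_edge(i, j, rho=float(r))
        return g


def build_adjacency(
    wc: WindowedCorrelation, depths: np.ndarray
) -> FunctionalNetwork:
    """Turn the FDR-refined mask into an undirected functional network."""
    depths = np.asarray(depths, dtype=float)
    n = wc.rho.shape[0]
    if depths.shape != (n,):
        raise CalnetError("one depth per neuron required")
    adj = wc.fdr_mask.copy()
    iu = np.triu_indices(n, k=1)
    edge_rho = {
        (int(i), int(j)): float(wc.rho[i, j])
        for i, j in zip(*iu)
        if adj[i, j]
    }
    return FunctionalNetwork(
        adjacency=adj, depths=depths, window_label=wc.window_label, edge_rho=edge_rho
    )
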