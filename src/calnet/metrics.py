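"""Graph metrics per window, depth-binned degree, and group comparisons.

Per-window networks are summarized by three global metrics (mean local
clustering coefficient, global efficiency, degree assortativity), the node
degree is resolved along the normalized cortical depth in 0.1 steps
relative to the pre-stimulus (basal) window, inter-layer connection counts
are contrasted between groups with t-tests and Cohen's d, and the temporal
evolution of the metrics is compared between groups with a linear mixed
model (random intercept per subject, likelihood-ratio tests).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import FunctionalNetwork
from .core import CalnetError

__all__ = [
    "node_degrees",
    "clustering_coefficient",
    "global_efficiency",
    "degree_assortativity",
    "depth_degree_profile",
    "depth_profile_group_test",
    "interlayer_contrast",
    "cohens_d",
    "network_metric_rows",
    "compare_groups_over_time",
    "LRTResult",
]

logger = logging.getLogger(__name__)

DEPTH_STEP = 0.1


def node_degrees(net: FunctionalNetwork) -> np.ndarray:
    """Node degree k = number of significant connections per neuron."""
    return net.adjacency.sum(axis=1).astype(int)


def clustering_coefficient(net: FunctionalNetwork) -> float:
    """Mean local clustering coefficient; nodes with k < 2 contribute 0."""
    g = net.to_networkx()
    if g.number_of_nodes() == 0:
        raise CalnetError("empty graph")
    return float(nx.average_clustering(g))


def global_efficiency(net: FunctionalNetwork) -> float:
    """Mean inverse shortest-path length over node pairs (0 if unreachable)."""
    g = net.to_networkx()
    if g.number_of_nodes() < 2:
        raise CalnetError("need at least 2 nodes")
    return float(nx.global_efficiency(g))


def degree_assortativity(net: FunctionalNetwork) -> float:
    """Pearson correlation of endpoint degrees over edges; NaN if undefined.

    Graphs in which every edge endpoint has the same degree (e.g. cycles)
    have zero degree variance across edges and no defined assortativity;
    these return NaN (an explicit missing marker), never a silent 0.
    """
    g = net.to_networkx()
    if g.number_of_edges() == 0:
        raise CalnetError("assortativity needs at least one edge")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = nx.degree_assortativity_coefficient(g)
    return float(r) if np.isfinite(r) else float("nan")


def _depth_bins(step: float = DEPTH_STEP) -> np.ndarray:
    edges = np.arange(0.0, 1.0 + step / 2, step)
    edges[-1] = 1.0 + 1e-12  # include depth == 1 in the top bin
    return edges


def depth_degree_profile(
    net: FunctionalNetwork,
    basal_net: FunctionalNetwork,
    step: float = DEPTH_STEP,
) -> pd.DataFrame:
    """Mean node degree per 0.1 depth bin, relative to the basal window.

    Returns one row per bin with the bin occupancy, the mean degree in this
    window, the mean basal degree, and their difference (``rel_degree``).
    Bins without neurons carry NaN.
    """
    if net.n_nodes != basal_net.n_nodes:
        raise CalnetError("window and basal networks must share the node set")
    edges = _depth_bins(step)
    k = node_degrees(net).astype(float)
    k0 = node_degrees(basal_net).astype(float)
    which = np.digitize(net.depths, edges) - 1
    rows = []
    for b in range(edges.size - 1):
        sel = which == b
        n_in = int(sel.sum())
        rows.append(
            {
                "bin_lo": round(edges[b], 10),
                "bin_hi": round(min(edges[b + 1], 1.0), 10),
                "n": n_in,
                "mean_degree": k[sel].mean() if n_in else np.nan,
                "mean_degree_basal": k0[sel].mean() if n_in else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    df["rel_degree"] = df["mean_degree"] - df["mean_degree_basal"]
    return df


def depth_profile_group_test(
    group_a: list[pd.DataFrame], group_b: list[pd.DataFrame]
) -> pd.DataFrame:
    """Per-bin between-group t-test and Cohen's d on relative degree.

    Each element of a group is one subject's depth-degree profile; bins
    that are empty in any subject are excluded from that subject and bins
    with fewer than two subjects per group are skipped.
    """
    if not group_a or not group_b:
        raise CalnetError("both groups must contain at least one profile")
    bins = group_a[0][["bin_lo", "bin_hi"]]
    rows = []
    for b in range(len(bins)):
        xa = np.array([p["rel_degree"].iloc[b] for p in group_a])
        xb = np.array([p["rel_degree"].iloc[b] for p in group_b])
        xa, xb = xa[np.isfinite(xa)], xb[np.isfinite(xb)]
        row = {
            "bin_lo": bins["bin_lo"].iloc[b],
            "bin_hi": bins["bin_hi"].iloc[b],
            "n_a": xa.size,
            "n_b": xb.size,
            "mean_a": xa.mean() if xa.size else np.nan,
            "mean_b": xb.mean() if xb.size else np.nan,
            "t": np.nan,
            "p": np.nan,
            "cohens_d": np.nan,
        }
        if xa.size >= 2 and xb.size >= 2:
            t, p = stats.ttest_ind(xa, xb)
            row["t"], row["p"] = float(t), float(p)
            row["cohens_d"] = cohens_d(xa, xb)
        rows.append(row)
    return pd.DataFrame(rows)


def _bin_pair_counts(net: FunctionalNetwork, step: float) -> np.ndarray:
    """Connection counts between (unordered) depth-bin pairs, (nb, nb)."""
    edges = _depth_bins(step)
    nb = edges.size - 1
    which = np.digitize(net.depths, edges) - 1
    counts = np.zeros((nb, nb))
    iu = np.triu_indices(net.n_nodes, k=1)
    for i, j in zip(*iu):
        if net.adjacency[i, j]:
            a, b = sorted((which[i], which[j]))
            counts[a, b] += 1
    return counts


def interlayer_contrast(
    group_a: list[FunctionalNetwork],
    group_b: list[FunctionalNetwork],
    step: float = DEPTH_STEP,
) -> pd.DataFrame:
    """Between-group contrast of layer-to-layer connection counts.

    For each unordered depth-bin pair the number of significant connections
    is counted per subject (one network per subject for a given window);
    groups are compared with a two-sample t-test and Cohen's d (pooled SD).
    With fewer than two subjects in a group only the effect size is
    reported.  Bin occupancy (mean neurons per bin over subjects) is
    reported alongside the raw counts.
    """
    if not group_a or not group_b:
        raise CalnetError("both groups must be non-empty")
    step_edges = _depth_bins(step)
    nb = step_edges.size - 1
    ca = np.stack([_bin_pair_counts(n, step) for n in group_a])
    cb = np.stack([_bin_pair_counts(n, step) for n in group_b])

    def occupancy(nets: list[FunctionalNetwork]) -> np.ndarray:
        occ = np.stack(
            [np.histogram(n.depths, bins=step_edges)[0] for n in nets]
        )
        return occ.mean(axis=0)

    occ_a, occ_b = occupancy(group_a), occupancy(group_b)
    rows = []
    for a in range(nb):
        for b in range(a, nb):
            if occ_a[a] + occ_b[a] == 0 or occ_a[b] + occ_b[b] == 0:
                continue  # bin never populated in either group
            xa, xb = ca[:, a, b], cb[:, a, b]
            row = {
                "bin_i": round(step_edges[a], 10),
                "bin_j": round(step_edges[b], 10),
                "mean_count_a": float(xa.mean()),
                "mean_count_b": float(xb.mean()),
                "diff": float(xa.mean() - xb.mean()),
                "occupancy_a": float(occ_a[a] if a == b else (occ_a[a] + occ_a[b]) / 2),
                "occupancy_b": float(occ_b[a] if a == b else (occ_b[a] + occ_b[b]) / 2),
                "t": np.nan,
                "p": np.nan,
                "cohens_d": cohens_d(xa, xb) if xa.size >= 2 and xb.size >= 2 else np.nan,
            }
            if xa.size >= 2 and xb.size >= 2:
                t, p = stats.ttest_ind(xa, xb)
                row["t"], row["p"] = float(t), float(p)
            rows.append(row)
    return pd.DataFrame(rows)


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's d with pooled SD ((n-1)-weighted); NaN when the SD is zero."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise CalnetError("need at least 2 values per sample")
    nx_, ny_ = x.size, y.size
    pooled = ((nx_ - 1) * x.var(ddof=1) + (ny_ - 1) * y.var(ddof=1)) / (nx_ + ny_ - 2)
    if pooled <= 0:
        return float("nan")
    return float((x.mean() - y.mean()) / np.sqrt(pooled))


def network_metric_rows(
    nets: dict[str, FunctionalNetwork], subject: str, group: str
) -> pd.DataFrame:
    """Tidy metric table (one row per window) for one subject."""
    rows = []
    for label, net in nets.items():
        try:
            assort = degree_assortativity(net) if net.n_edges else float("nan")
        except CalnetError:
            assort = float("nan")
        rows.append(
            {
                "subject": subject,
                "group": group,
                "window": label,
                "clustering": clustering_coefficient(net),
                "efficiency": global_efficiency(net),
                "assortativity": assort,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class LRTResult:
    """Likelihood-ratio test of one fixed effect in the mixed model."""

    effect: str
    statistic: float
    df: int
    pvalue: float
    converged: bool
    fallback_ols: bool


def compare_groups_over_time(
    table: pd.DataFrame,
    value_col: str,
    effect: str = "group",
) -> LRTResult:
    """Group x time mixed-model comparison of one network metric.

    Fits ``value ~ C(group) + C(window)`` with a random intercept per
    subject (maximum likelihood) and compares it by likelihood-ratio test
    against the model without the tested effect.  Rows with missing values
    (e.g. undefined assortativity) are dropped.  If either mixed fit fails
    or is singular, the test falls back to ordinary least squares with a
    logged warning and ``fallback_ols=True``.
    """
    import statsmodels.formula.api as smf

    if effect not in ("group", "window"):
        raise CalnetError("effect must be 'group' or 'window'")
    df = table.dropna(subset=[value_col]).copy()
    if df["group"].nunique() < 2 or df.groupby("group")["subject"].nunique().min() < 2:
        raise CalnetError("need at least 2 subjects per group")
    if df["window"].nunique() < 2:
        raise CalnetError("need at least 2 windows")

    full_f = f"{value_col} ~ C(group) + C(window)"
    red_f = (
        f"{value_col} ~ C(window)" if effect == "group" else f"{value_col} ~ C(group)"
    )

    def _fit_mixed(formula: str):
        # a singular hessian at the optimum aborts some optimizers after the
        # likelihood itself has converged; walk a fallback chain before
        # declaring the mixed fit unusable
        last_err: Exception | None = None
        for method in ("lbfgs", "bfgs", "powell", "cg", "nm"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = smf.mixedlm(formula, df, groups=df["subject"])
                    res = model.fit(reml=False, method=method)
                if np.isfinite(res.llf):
                    return res
            except Exception as err:  # LinAlgError and friends
                last_err = err
        raise ValueError(f"all mixed-model optimizers failed: {last_err}")

    fallback = False
    try:
        full = _fit_mixed(full_f)
        red = _fit_mixed(red_f)
        converged = bool(full.converged and red.converged)
        if not converged or not np.isfinite(full.llf) or not np.isfinite(red.llf):
            raise ValueError("mixed model did not converge")
        llf_full, llf_red = full.llf, red.llf
        df_diff = len(full.fe_params) - len(red.fe_params)
    except Exception as err:  # singular / non-converged fits
        logger.warning("mixed model failed (%s); falling back to OLS", err)
        fallback = True
        full = smf.ols(full_f, df).fit()
        red = smf.ols(red_f, df).fit()
        converged = True
        llf_full, llf_red = full.llf, red.llf
        df_diff = int(full.df_model - red.df_model)

    stat = max(0.0, 2.0 * (llf_full - llf_red))
    p = float(stats.chi2.sf(stat, df_diff)) if df_diff > 0 else float("nan")
    return LRTResult(
        effect=effect,
        statistic=float(stat),
        df=int(df_diff),
        pvalue=p,
        converged=converged,
        fallback_ols=fallback,
    )
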