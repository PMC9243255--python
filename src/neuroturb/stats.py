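"""Group comparisons between brain states.

Scalar measures (amplitude turbulence, cascade flow, transfer slope,
susceptibility, ...) are compared between states with the two-sided
Wilcoxon rank-sum test per spatial scale, with Benjamini-Hochberg FDR
correction across scales within each measure and state pair.  Node-level
metastability distributions are compared with the Kolmogorov-Smirnov
distance (and its test p-value), and the nodes in the top quantile of
absolute between-state differences are attributed to networks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupSamples",
    "wilcoxon_ranksum",
    "fdr_correct",
    "ks_distance",
    "top_quantile_nodes",
    "build_report",
    "significance_marker",
]

EXACT_MAX_N = 12  # exact enumeration up to this combined sample size


@dataclass(frozen=True)
class GroupSamples:
    """Two labelled groups of per-subject scalars."""

    label_a: str
    label_b: str
    values_a: np.ndarray
    values_b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.values_a, dtype=float)
        b = np.asarray(self.values_b, dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError("each group needs >= 2 values")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValueError("group values must be finite")
        object.__setattr__(self, "values_a", a)
        object.__setattr__(self, "values_b", b)


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided exact rank-sum p by full enumeration with midranks."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks handle ties
    n_a = len(a)
    w_obs = ranks[:n_a].sum()
    mu = ranks.sum() * n_a / len(pooled)
    dev_obs = abs(w_obs - mu)
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mu) >= dev_obs - 1e-12:
            count += 1
    return float(w_obs), count / total


def wilcoxon_ranksum(samples: GroupSamples) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank-sum of A, p).

    Exact enumeration (mid-ranks, so ties are handled) when the combined
    sample size is <= 12; otherwise the tie-corrected normal approximation
    of the rank-sum statistic.
    """
    a, b = samples.values_a, samples.values_b
    if len(a) + len(b) <= EXACT_MAX_N:
        return _exact_ranksum_p(a, b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n_a, n = len(a), len(pooled)
    w = ranks[: len(a)].sum()
    mu = n_a * (n + 1) / 2.0
    # tie correction to the rank-sum variance
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var = n_a * (n - n_a) / 12.0 * ((n + 1) - tie_term)
    if var == 0:
        return float(w), 1.0
    z = (w - mu) / np.sqrt(var)
    p = 2 * sps.norm.sf(abs(z))
    return float(w), float(min(1.0, p))


def fdr_correct(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up; returns (adjusted p, rejected mask)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    rejected, adjusted, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return adjusted, rejected


def ks_distance(values_a, values_b) -> float:
    """Sup-norm distance between the two empirical CDFs, in [0, 1]."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    return float(sps.ks_2samp(a, b).statistic)


def top_quantile_nodes(
    nlm_a: np.ndarray,
    nlm_b: np.ndarray,
    q: float = 0.15,
    network_label: tuple[str, ...] | None = None,
) -> dict:
    """Nodes in the top ``q`` quantile of |mean_a - mean_b|.

    ``nlm_a``/``nlm_b`` are per-node values or (subjects x nodes) arrays
    (subject means are taken).  Returns the selected node indices, a tie
    flag (the quantile threshold was attained by more nodes than q*n), and
    per-network counts when labels are given.
    """
    if not (0 < q < 1):
        raise ValueError("q must be in (0, 1)")
    a = np.atleast_2d(np.asarray(nlm_a, dtype=float)).mean(axis=0)
    b = np.atleast_2d(np.asarray(nlm_b, dtype=float)).mean(axis=0)
    if a.shape != b.shape:
        raise ValueError("node order/length mismatch between groups")
    diff = np.abs(a - b)
    thresh = np.quantile(diff, 1 - q)
    selected = np.nonzero(diff >= thresh)[0]
    expected = int(np.ceil(q * diff.size))
    tied = selected.size > expected
    counts: dict[str, int] = {}
    if network_label:
        for i in selected:
            counts[network_label[i]] = counts.get(network_label[i], 0) + 1
    return {
        "nodes": selected,
        "abs_diff": diff[selected],
        "threshold": float(thresh),
        "tied": bool(tied),
        "network_counts": counts,
    }


def significance_marker(p: float) -> str:
    """Figure-legend style markers mapped to 0.05 / 0.01 / 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def build_report(
    measures: pd.DataFrame,
    nlm: dict[str, np.ndarray] | None = None,
    network_label: tuple[str, ...] | None = None,
    q: float = 0.05,
    top_q: float = 0.15,
) -> dict:
    """All pairwise state comparisons per measure and scale.

    ``measures`` needs columns (subject, state, lam) plus one column per
    scalar measure; the FDR family is the set of scales within one measure
    for one state pair.  ``nlm`` optionally maps state -> (subjects x
    nodes) node-level-metastability arrays at the readout scale, feeding
    the KS distances and the top-quantile node attribution.

    Returns a dict with a tidy comparison table (DataFrame), KS results
    and top-node summaries, JSON-serialisable apart from the DataFrame.
    """
    required = {"subject", "state", "lam"}
    if not required.issubset(measures.columns):
        raise ValueError(f"measures table must contain columns {sorted(required)}")
    states = list(dict.fromkeys(measures["state"]))
    if len(states) < 2:
        raise ValueError("need >= 2 states to compare")
    value_cols = [c for c in measures.columns if c not in required]
    rows = []
    for m in value_cols:
        for sa, sb in itertools.combinations(states, 2):
            lams = sorted(measures["lam"].unique())
            family = []
            for lam in lams:
                sub = measures[np.isclose(measures["lam"], lam)]
                va = sub[sub["state"] == sa].sort_values("subject")[m].to_numpy()
                vb = sub[sub["state"] == sb].sort_values("subject")[m].to_numpy()
                va, vb = va[np.isfinite(va)], vb[np.isfinite(vb)]
                if len(va) < 2 or len(vb) < 2:
                    family.append((lam, np.nan, np.nan))
                    continue
                stat, p = wilcoxon_ranksum(GroupSamples(sa, sb, va, vb))
                family.append((lam, stat, p))
            pvals = np.array([p for _, _, p in family])
            finite = np.isfinite(pvals)
            adj = np.full_like(pvals, np.nan)
            rej = np.zeros(pvals.size, dtype=bool)
            if finite.any():
                adj[finite], rej[finite] = fdr_correct(pvals[finite], q=q)
            for (lam, stat, p), pa, r in zip(family, adj, rej):
                rows.append(
                    {
                        "measure": m,
                        "state_a": sa,
                        "state_b": sb,
                        "lam": lam,
                        "statistic": stat,
                        "p_raw": p,
                        "p_fdr": pa,
                        "significant": bool(r),
                        "marker": significance_marker(pa) if np.isfinite(pa) else "",
                    }
                )
    table = pd.DataFrame(rows)

    ks_results = []
    top_nodes = {}
    if nlm:
        for sa, sb in itertools.combinations(list(nlm), 2):
            a = np.atleast_2d(nlm[sa])
            b = np.atleast_2d(nlm[sb])
            ksd = ks_distance(a.reshape(-1), b.reshape(-1))
            ks_p = float(sps.ks_2samp(a.reshape(-1), b.reshape(-1)).pvalue)
            ks_results.append(
                {"state_a": sa, "state_b": sb, "ksd": ksd, "p": ks_p}
            )
            sel = top_quantile_nodes(a, b, q=top_q, network_label=network_label)
            top_nodes[f"{sa}_vs_{sb}"] = {
                "nodes": sel["nodes"].tolist(),
                "tied": sel["tied"],
                "network_counts": sel["network_counts"],
            }
    return {"comparisons": table, "ks": ks_results, "top_nodes": top_nodes}
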