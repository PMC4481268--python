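"""Rank-based robust comparison machinery.

All procedures work on the *relative effect* scale: the probability that a
randomly chosen observation from the pooled data is smaller than one drawn
from a specific group, estimated from global midranks as
``p_hat = (mean rank - 0.5) / N``. Everything here is invariant under
strictly increasing transforms of the values.

Contents
--------
- :func:`bdm_two_way` — heteroscedasticity-robust two-way ANOVA-type
  statistic (ATS) on ranks with Box-approximated fractional degrees of
  freedom, after Brunner, Dette & Munk.
- :func:`tukey_relative_contrasts` — all-pairs contrasts of relative
  effects with an influence-function covariance estimate and simultaneous
  (equicoordinate multivariate-normal) confidence intervals.
- :func:`patel_hoel` — 2x2 nonparametric interaction test on differences
  of pairwise-dominance probabilities across the second factor.
- :func:`build_tgraph` — digraph of significant outperformance relations,
  transitively reduced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# shared rank helpers
# ---------------------------------------------------------------------------

def _as_groups(values, labels) -> tuple[np.ndarray, list, list[np.ndarray]]:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have equal length")
    uniq = sorted(pd.unique(labels).tolist())
    idx = [np.flatnonzero(labels == g) for g in uniq]
    return values, uniq, idx


def relative_effects(values, groups) -> pd.Series:
    """Per-group relative effects (mean global midrank - 0.5) / N."""
    values, uniq, idx = _as_groups(values, groups)
    ranks = stats.rankdata(values, method="average")
    n = values.size
    return pd.Series(
        [(ranks[i].mean() - 0.5) / n for i in idx], index=uniq, name="relative_effect"
    )


def _normalized_cdf_at(sample: np.ndarray, points: np.ndarray) -> np.ndarray:
    """F(x) = (#{< x} + 0.5 #{= x}) / n, the midrank-consistent cdf."""
    s = np.sort(sample)
    less = np.searchsorted(s, points, side="left")
    leq = np.searchsorted(s, points, side="right")
    return (less + 0.5 * (leq - less)) / s.size


def _relative_effect_covariance(
    values: np.ndarray, idx: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Relative effects and the estimated covariance of their vector.

    Uses the asymptotic linearization of p_hat_i = integral of the pooled
    (weighted) empirical cdf H with respect to F_i: each observation (j, k)
    contributes its own-group term (H(X_ik) - p_i)/n_i plus the cross term
    (c_ij - F_i(X_jk))/N from estimating H itself, where
    c_ij = E F_i(X_j). The covariance is the sum of products of these
    estimated influence contributions.
    """
    n = values.size
    g = len(idx)
    ranks = stats.rankdata(values, method="average")
    h_hat = (ranks - 0.5) / n  # pooled normalized cdf at each observation
    p_hat = np.array([h_hat[i].mean() for i in idx])

    psi = np.zeros((g, n))
    for i in range(g):
        f_i = _normalized_cdf_at(values[idx[i]], values)  # F_i at every obs
        for j in range(g):
            c_ij = f_i[idx[j]].mean()
            psi[i, idx[j]] += (c_ij - f_i[idx[j]]) / n
        psi[i, idx[i]] += (h_hat[idx[i]] - p_hat[i]) / idx[i].size
    return p_hat, psi @ psi.T


# ---------------------------------------------------------------------------
# ANOVA-type statistic (two-way)
# ---------------------------------------------------------------------------

@dataclass
class AtsResult:
    """One effect's ANOVA-type test on ranks."""

    effect: str
    statistic: float
    df1: float
    df2: float
    p: float
    eta_p2: float
    relative_effects: pd.DataFrame
    degenerate: bool = False

    def __repr__(self) -> str:  # compact, report-style
        return (
            f"AtsResult({self.effect}: F({self.df1:.2f}, {self.df2:.2f}) "
            f"= {self.statistic:.2f}, p = {self.p:.4g}, eta_p2 = {self.eta_p2:.3f})"
        )


def _ats(
    p_hat: np.ndarray,
    t_mat: np.ndarray,
    v_mat: np.ndarray,
    n_total: int,
    counts: np.ndarray,
) -> tuple[float, float, float, float]:
    """ATS value, Box-approximated (df1, df2) and p for one hypothesis
    projection matrix ``t_mat``."""
    tv = t_mat @ v_mat
    trace_tv = float(np.trace(tv))
    if trace_tv <= 0:
        return np.nan, np.nan, np.nan, np.nan
    f_stat = n_total * float(p_hat @ t_mat @ p_hat) / trace_tv
    df1 = trace_tv**2 / float(np.trace(tv @ tv))
    d_t = np.diag(t_mat)
    lam = 1.0 / (counts - 1)
    denom = float(np.sum(d_t**2 * np.diag(v_mat) ** 2 * lam))
    df2 = trace_tv**2 / denom if denom > 0 else np.inf
    p = float(stats.f.sf(f_stat, df1, df2))
    return f_stat, df1, df2, p


def bdm_two_way(values, factor_a, factor_b) -> dict[str, AtsResult]:
    """Rank-based two-way ANOVA-type tests for both main effects and the
    interaction, with Box-type fractional degrees of freedom.

    Global midranks are taken over all observations; cell relative effects
    are (mean cell rank - 0.5) / N, and their cell-size-weighted mean is
    exactly 0.5. Returns a dict keyed ``factorA``, ``factorB``,
    ``interaction``. Partial eta squared is derived from the ATS as
    df1*F / (df1*F + df2) and is an approximation.
    """
    values = np.asarray(values, dtype=float)
    factor_a = np.asarray(factor_a)
    factor_b = np.asarray(factor_b)
    if not (values.shape == factor_a.shape == factor_b.shape):
        raise ValueError("values and factor labels must have equal length")
    a_levels = sorted(pd.unique(factor_a).tolist())
    b_levels = sorted(pd.unique(factor_b).tolist())
    a, b = len(a_levels), len(b_levels)
    if a < 2 or b < 2:
        raise ValueError("each factor needs >= 2 levels")

    cell_idx, counts = [], []
    for la in a_levels:
        for lb in b_levels:
            sel = np.flatnonzero((factor_a == la) & (factor_b == lb))
            if sel.size == 0:
                raise ValueError(f"empty cell ({la!r}, {lb!r})")
            if sel.size < 2:
                raise ValueError(f"cell ({la!r}, {lb!r}) needs >= 2 observations")
            cell_idx.append(sel)
            counts.append(sel.size)
    counts = np.array(counts)
    n_total = values.size

    ranks = stats.rankdata(values, method="average")
    degenerate = bool(np.all(values == values[0]))
    p_hat = np.array([(ranks[i].mean() - 0.5) / n_total for i in cell_idx])
    sigma2 = np.array(
        [np.var(ranks[i] / n_total, ddof=1) for i in cell_idx]
    )
    v_mat = n_total * np.diag(sigma2 / counts)

    rel = pd.DataFrame(
        p_hat.reshape(a, b), index=pd.Index(a_levels, name="A"),
        columns=pd.Index(b_levels, name="B"),
    )

    def proj(k: int) -> np.ndarray:
        return np.eye(k) - np.ones((k, k)) / k

    j_a, j_b = np.ones((a, a)) / a, np.ones((b, b)) / b
    hypotheses = {
        "factorA": np.kron(proj(a), j_b),
        "factorB": np.kron(j_a, proj(b)),
        "interaction": np.kron(proj(a), proj(b)),
    }

    out = {}
    for effect, t_mat in hypotheses.items():
        f_stat, df1, df2, p = _ats(p_hat, t_mat, v_mat, n_total, counts)
        if degenerate or np.isnan(f_stat):
            out[effect] = AtsResult(effect, 0.0, np.nan, np.nan, np.nan, np.nan,
                                    rel, degenerate=True)
            continue
        eta = df1 * f_stat / (df1 * f_stat + df2) if np.isfinite(df2) else np.nan
        out[effect] = AtsResult(effect, f_stat, df1, df2, p, eta, rel)
    return out


# ---------------------------------------------------------------------------
# Tukey-type simultaneous contrasts of relative effects
# ---------------------------------------------------------------------------

@dataclass
class ContrastResult:
    """One pairwise contrast of global relative effects.

    ``effect`` is p_hat(group_j) - p_hat(group_i): positive means group j
    tends to have larger values than the pooled data more often than
    group i does (j outperforms i when larger is better).
    """

    group_i: object
    group_j: object
    effect: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    significant: bool

    def winner(self):
        return self.group_j if self.effect > 0 else self.group_i

    def loser(self):
        return self.group_i if self.effect > 0 else self.group_j


def _equicoordinate_critical(
    corr: np.ndarray, alpha: float, rng: np.random.Generator, n_draws: int = 200_000
) -> tuple[float, np.ndarray]:
    """(1-alpha) quantile of max |Z| for Z ~ N(0, corr), by seeded Monte
    Carlo on the estimated correlation; also returns the sampled maxima so
    adjusted p-values can reuse them. Falls back to Bonferroni when the
    correlation matrix is not usable."""
    m = corr.shape[0]
    try:
        chol = np.linalg.cholesky(corr + 1e-10 * np.eye(m))
    except np.linalg.LinAlgError:
        crit = stats.norm.ppf(1 - alpha / (2 * m))
        return float(crit), np.array([])
    z = rng.standard_normal((n_draws, m)) @ chol.T
    maxima = np.abs(z).max(axis=1)
    return float(np.quantile(maxima, 1 - alpha)), maxima


def tukey_relative_contrasts(
    values,
    groups,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> list[ContrastResult]:
    """All-pairs contrasts of global-rank relative effects with simultaneous
    two-sided confidence intervals.

    The covariance of the relative-effect vector is estimated from its
    influence function; the simultaneous critical value is the
    equicoordinate quantile of the maximum absolute coordinate of a
    multivariate normal with the contrasts' estimated correlation
    (Bonferroni when that matrix is degenerate). A contrast is significant
    when its interval excludes zero.
    """
    values, uniq, idx = _as_groups(values, groups)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    for g, i in zip(uniq, idx):
        if i.size < 2:
            raise ValueError(f"group {g!r} needs >= 2 observations")
    rng = np.random.default_rng(1830280571 if rng is None else rng)

    p_hat, cov = _relative_effect_covariance(values, idx)
    pairs = [(i, j) for i in range(len(uniq)) for j in range(i + 1, len(uniq))]
    effects = np.array([p_hat[j] - p_hat[i] for i, j in pairs])
    variances = np.array([cov[i, i] + cov[j, j] - 2 * cov[i, j] for i, j in pairs])
    variances = np.maximum(variances, 0.0)
    ses = np.sqrt(variances)

    # correlation of the contrast statistics
    c_mat = np.zeros((len(pairs), len(uniq)))
    for m, (i, j) in enumerate(pairs):
        c_mat[m, i], c_mat[m, j] = -1.0, 1.0
    contrast_cov = c_mat @ cov @ c_mat.T
    d = np.sqrt(np.diag(contrast_cov))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = contrast_cov / np.outer(d, d)
    usable = np.all(np.isfinite(corr))
    if usable:
        crit, maxima = _equicoordinate_critical(corr, alpha, rng)
    else:
        crit, maxima = stats.norm.ppf(1 - alpha / (2 * len(pairs))), np.array([])

    results = []
    for m, (i, j) in enumerate(pairs):
        eff, se = float(effects[m]), float(ses[m])
        if se == 0:
            z = np.inf if eff != 0 else 0.0
        else:
            z = abs(eff) / se
        if maxima.size:
            p = float(np.mean(maxima >= z)) if np.isfinite(z) else 0.0
        else:
            p = float(min(1.0, 2 * len(pairs) * stats.norm.sf(z)))
        lo, hi = eff - crit * se, eff + crit * se
        results.append(
            ContrastResult(
                group_i=uniq[i],
                group_j=uniq[j],
                effect=eff,
                se=se,
                ci_low=float(lo),
                ci_high=float(hi),
                p=p,
                significant=bool(lo > 0 or hi < 0),
            )
        )
    return results


# ---------------------------------------------------------------------------
# Patel-Hoel 2x2 interaction test
# ---------------------------------------------------------------------------

@dataclass
class PatelHoelResult:
    """Difference of pairwise-dominance probabilities across the two levels
    of factor B: delta = P(A1 < A2 | B = b1) - P(A1 < A2 | B = b2), ties
    counted half."""

    delta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    a_levels: tuple
    b_levels: tuple
    dominance_by_b: dict


def _bm_probability(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Brunner-Munzel estimate of P(X < Y) + 0.5 P(X = Y) and its variance,
    via placement variances."""
    n1, n2 = x.size, y.size
    p_hat = float(_normalized_cdf_at(x, y).mean())
    fx_at_y = _normalized_cdf_at(x, y)  # F_x evaluated at each y
    fy_at_x = _normalized_cdf_at(y, x)
    var = float(np.var(fx_at_y, ddof=1) / n2 + np.var(fy_at_x, ddof=1) / n1)
    return p_hat, var


def patel_hoel(
    values, factor_a, factor_b, alpha: float = 0.05
) -> PatelHoelResult:
    """Nonparametric 2x2 interaction test after Patel and Hoel.

    Within each level of factor B, the dominance probability
    P(A-level-1 < A-level-2) is estimated from midrank placements
    (Brunner-Munzel); delta is the difference of the two estimates with a
    normal-approximation confidence interval.
    """
    values = np.asarray(values, dtype=float)
    factor_a = np.asarray(factor_a)
    factor_b = np.asarray(factor_b)
    a_levels = sorted(pd.unique(factor_a).tolist())
    b_levels = sorted(pd.unique(factor_b).tolist())
    if len(a_levels) != 2 or len(b_levels) != 2:
        raise ValueError("patel_hoel requires exactly 2 levels per factor")

    p_by_b, var_by_b = {}, {}
    for lb in b_levels:
        x = values[(factor_a == a_levels[0]) & (factor_b == lb)]
        y = values[(factor_a == a_levels[1]) & (factor_b == lb)]
        if x.size < 2 or y.size < 2:
            raise ValueError(
                f"cell with < 2 observations at B = {lb!r}"
            )
        p_by_b[lb], var_by_b[lb] = _bm_probability(x, y)

    delta = p_by_b[b_levels[0]] - p_by_b[b_levels[1]]
    se = float(np.sqrt(var_by_b[b_levels[0]] + var_by_b[b_levels[1]]))
    z = stats.norm.ppf(1 - alpha / 2)
    if se == 0:
        p = 1.0 if delta == 0 else 0.0
    else:
        p = float(2 * stats.norm.sf(abs(delta) / se))
    return PatelHoelResult(
        delta=float(delta),
        se=se,
        ci_low=float(delta - z * se),
        ci_high=float(delta + z * se),
        p=p,
        a_levels=tuple(a_levels),
        b_levels=tuple(b_levels),
        dominance_by_b={k: float(v) for k, v in p_by_b.items()},
    )


# ---------------------------------------------------------------------------
# T-graphs
# ---------------------------------------------------------------------------

@dataclass
class TGraph:
    """Directed graph of significant outperformance relations, with direct
    edges omitted whenever an indirect path connects the two nodes
    (transitive reduction)."""

    graph: nx.DiGraph
    full_graph: nx.DiGraph = field(repr=False, default=None)

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple]:
        return list(self.graph.edges)

    def to_dot(self) -> str:
        lines = ["digraph tgraph {"]
        for node in self.graph.nodes:
            lines.append(f'  "{node}";')
        for u, v in self.graph.edges:
            lines.append(f'  "{u}" -> "{v}";')
        lines.append("}")
        return "\n".join(lines)

    def to_json(self) -> str:
        data = nx.node_link_data(self.graph, edges="links")
        return json.dumps(data, indent=2, default=str)


def build_tgraph(contrasts: Sequence[ContrastResult]) -> TGraph:
    """Build the T-graph from pairwise contrasts: an edge runs from winner
    to loser for every significant contrast, then transitive reduction
    drops edges implied by longer paths (reachability is preserved).

    Raises if the significant relations contain a cycle, which would
    violate the transitivity the contrast method guarantees.
    """
    full = nx.DiGraph()
    for c in contrasts:
        full.add_node(c.group_i)
        full.add_node(c.group_j)
    for c in contrasts:
        if c.significant and c.effect != 0:
            full.add_edge(c.winner(), c.loser())
    if not nx.is_directed_acyclic_graph(full):
        raise ValueError("significant contrasts form a cycle; transitivity violated")
    reduced = nx.transitive_reduction(full)
    reduced.add_nodes_from(full.nodes)
    return TGraph(graph=reduced, full_graph=full)
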