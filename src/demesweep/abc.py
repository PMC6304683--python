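"""Approximate Bayesian computation: summary statistics, correlation
pruning, rejection sampling, regression adjustment, marginal densities,
posterior P-values, Bayes factors and scenario ranking.

The marginal density of a scenario is a Gaussian product-kernel density of
its retained simulated summary vectors evaluated at the observed vector;
Bayes factors are quotients of marginal densities and a scenario is
rejected when the best scenario's Bayes factor against it exceeds a
threshold (default 3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .panel import GenotypePanel, PopulationMap, wc_components
from .simulate import DEFAULT_PRIORS

logger = logging.getLogger(__name__)


@dataclass
class AbcConfig:
    retain_fraction: float = 0.005
    rho_max: float = 0.95
    bf_reject_threshold: float = 3.0

    def __post_init__(self) -> None:
        if not 0 < self.retain_fraction < 1:
            raise ValueError("retain_fraction must lie in (0, 1)")
        if self.bf_reject_threshold <= 1:
            raise ValueError("bf_reject_threshold must exceed 1")


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------


def _group_het(panel: GenotypePanel, sample_idx: np.ndarray) -> np.ndarray:
    """Unbiased expected heterozygosity per locus within one group."""
    g = panel.genotypes[:, sample_idx]
    called = g != -1
    n_gene = 2 * called.sum(axis=1).astype(float)
    alt = np.where(called, g, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_gene > 0, alt / n_gene, np.nan)
        h = (n_gene / (n_gene - 1)) * 2 * p * (1 - p)
    h[n_gene < 2] = np.nan
    return h


def summarize(
    panel: GenotypePanel,
    groups: Mapping[str, Sequence[str]],
    reference_group: str | None = None,
) -> pd.Series:
    """Seventeen-statistic summary vector over four analysis groups.

    Per group (declared order): mean and SD over loci of unbiased expected
    heterozygosity, and the polymorphic-site count. Then the pairwise FST of
    each non-reference group against the reference group, the mean pairwise
    FST among the non-reference groups, and the global multi-population FST.
    With four groups this yields 17 named statistics in a fixed order.

    The exact statistic set of the original analysis is not published; this
    set is a documented stand-in with the same roles.
    """
    names = list(groups)
    if reference_group is None:
        reference_group = names[0]
    if reference_group not in names:
        raise ValueError(f"reference group {reference_group!r} not in groups")
    out: dict[str, float] = {}
    idx = {g: panel.sample_indices(groups[g]) for g in names}
    for g in names:
        h = _group_het(panel, idx[g])
        h = h[np.isfinite(h)]
        poly = int((h > 0).sum())
        out[f"H_mean_{g}"] = float(h.mean()) if h.size else np.nan
        out[f"H_sd_{g}"] = float(h.std(ddof=1)) if poly > 0 and h.size > 1 else np.nan
        out[f"S_{g}"] = poly
    others = [g for g in names if g != reference_group]
    for g in others:
        comps = wc_components(panel, [groups[g], groups[reference_group]])
        out[f"FST_{g}_vs_{reference_group}"] = comps.fst
    pair_fsts = []
    for i, ga in enumerate(others):
        for gb in others[i + 1 :]:
            pair_fsts.append(wc_components(panel, [groups[ga], groups[gb]]).fst)
    out["FST_mean_nonref_pairs"] = float(np.nanmean(pair_fsts)) if pair_fsts else np.nan
    out["FST_global"] = wc_components(panel, [groups[g] for g in names]).fst
    return pd.Series(out)


def prune_correlated(sim_stats: pd.DataFrame, rho_max: float = 0.95) -> list[str]:
    """Greedy Spearman pruning: walk statistics in declared order, dropping
    any with |rho| > ``rho_max`` against an already retained one."""
    if len(sim_stats) < 2:
        raise ValueError("need at least two simulations")
    retained: list[str] = []
    for name in sim_stats.columns:
        col = sim_stats[name].to_numpy(dtype=float)
        drop = False
        for kept in retained:
            other = sim_stats[kept].to_numpy(dtype=float)
            ok = np.isfinite(col) & np.isfinite(other)
            if ok.sum() < 3:
                continue
            rho = stats.spearmanr(col[ok], other[ok]).statistic
            if np.isfinite(rho) and abs(rho) > rho_max:
                drop = True
                break
        if not drop:
            retained.append(name)
    return retained


# ---------------------------------------------------------------------------
# Rejection sampling
# ---------------------------------------------------------------------------


def _standardize(
    stats_matrix: np.ndarray, observed: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardize by simulation mean/SD; zero-SD statistics are dropped."""
    mean = stats_matrix.mean(axis=0)
    sd = stats_matrix.std(axis=0)
    keep = sd > 0
    if not keep.all():
        logger.debug("dropping %d zero-variance statistics", (~keep).sum())
    z = (stats_matrix[:, keep] - mean[keep]) / sd[keep]
    z_obs = (observed[keep] - mean[keep]) / sd[keep]
    return z, z_obs, keep


def abc_reject(
    observed: pd.Series,
    sim_stats: pd.DataFrame,
    cfg: AbcConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection step: retain the closest ``ceil(retain_fraction * N)``
    simulations by Euclidean distance on mean/SD-standardized statistics.

    Returns (retained row indices, their distances), ties broken by
    simulation index (stable sort).
    """
    n = len(sim_stats)
    n_keep = int(np.ceil(cfg.retain_fraction * n))
    if n < 1 / cfg.retain_fraction:
        raise ValueError("too few simulations for the requested retain fraction")
    cols = [c for c in sim_stats.columns if c in observed.index]
    mat = sim_stats[cols].to_numpy(dtype=float)
    obs = observed[cols].to_numpy(dtype=float)
    z, z_obs, _ = _standardize(mat, obs)
    dist = np.sqrt(((z - z_obs) ** 2).sum(axis=1))
    order = np.argsort(dist, kind="stable")
    kept = order[:n_keep]
    return kept, dist[kept]


# ---------------------------------------------------------------------------
# Regression adjustment
# ---------------------------------------------------------------------------


def regression_adjust(
    retained_params: pd.DataFrame,
    retained_stats: pd.DataFrame,
    observed: pd.Series,
    prior_table: Mapping[str, tuple[str, float, float]] | None = None,
) -> pd.DataFrame:
    """Linear (homoscedastic) regression adjustment of retained draws.

    Each parameter is regressed on the standardized retained statistics and
    every retained draw shifted to the observed statistic values. Parameters
    with a log10 prior are adjusted on the log10 scale and back-transformed;
    adjusted draws are clipped to the prior support. A singular design falls
    back to the unadjusted draws with a warning.
    """
    priors = dict(DEFAULT_PRIORS) if prior_table is None else dict(prior_table)
    if len(retained_params) <= len(retained_stats.columns):
        raise ValueError("retained count must exceed statistic count")
    cols = [c for c in retained_stats.columns if c in observed.index]
    mat = retained_stats[cols].to_numpy(dtype=float)
    obs = observed[cols].to_numpy(dtype=float)
    z, z_obs, _ = _standardize(mat, obs)
    design = np.column_stack([np.ones(len(z)), z])
    target = np.concatenate([[1.0], z_obs])

    adjusted = {}
    for name in retained_params.columns:
        y = retained_params[name].to_numpy(dtype=float)
        scale, lo, hi = priors.get(name, ("linear", -np.inf, np.inf))
        if scale == "log10":
            y = np.log10(y)
        try:
            beta, *_ = np.linalg.lstsq(design, y, rcond=None)
            if not np.all(np.isfinite(beta)):
                raise np.linalg.LinAlgError("non-finite coefficients")
            y_adj = y + (target - design) @ beta
        except np.linalg.LinAlgError:
            logger.warning("singular design for %s; keeping unadjusted draws", name)
            y_adj = y
        if scale == "log10":
            y_adj = np.clip(10**y_adj, lo, hi)
        else:
            y_adj = np.clip(y_adj, lo, hi)
        adjusted[name] = y_adj
    return pd.DataFrame(adjusted, index=retained_params.index)


# ---------------------------------------------------------------------------
# Marginal density, P-value, Bayes factors
# ---------------------------------------------------------------------------


def _product_kde(
    points: np.ndarray, queries: np.ndarray, bandwidth: np.ndarray | None = None
) -> np.ndarray:
    """Gaussian product-kernel density with per-dimension Silverman bandwidth
    (or an explicit common bandwidth, needed for cross-scenario comparability)."""
    n, d = points.shape
    if bandwidth is None:
        sd = points.std(axis=0, ddof=1)
        sd[sd == 0] = 1e-12
        h = sd * (4.0 / ((d + 2) * n)) ** (1.0 / (d + 4))
    else:
        h = np.broadcast_to(np.asarray(bandwidth, dtype=float), (d,))
    dens = np.empty(len(queries))
    norm = 1.0 / (np.sqrt(2 * np.pi) * h)
    for qi, q in enumerate(queries):
        u = (q - points) / h
        dens[qi] = np.mean(np.prod(np.exp(-0.5 * u**2) * norm, axis=1))
    return dens


def _common_scale(
    retained_stats: pd.DataFrame,
    observed: pd.Series,
    scale: tuple[pd.Series, pd.Series] | None,
) -> tuple[np.ndarray, np.ndarray]:
    cols = [c for c in retained_stats.columns if c in observed.index]
    mat = retained_stats[cols].to_numpy(dtype=float)
    obs = observed[cols].to_numpy(dtype=float)
    if scale is None:
        mean, sd = mat.mean(axis=0), mat.std(axis=0)
    else:
        mean = scale[0][cols].to_numpy(dtype=float)
        sd = scale[1][cols].to_numpy(dtype=float)
    keep = sd > 0
    return (mat[:, keep] - mean[keep]) / sd[keep], (obs[keep] - mean[keep]) / sd[keep]


def marginal_density(
    retained_stats: pd.DataFrame,
    observed: pd.Series,
    scale: tuple[pd.Series, pd.Series] | None = None,
    bandwidth: float | np.ndarray | None = None,
) -> float:
    """KDE of the retained summary vectors evaluated at the observed vector.

    ``scale`` optionally supplies (mean, SD) Series for standardization and
    ``bandwidth`` a common kernel width (in standardized units) so that
    densities are comparable across scenarios; by default the retained
    simulations' own moments and Silverman's rule are used.
    """
    if len(retained_stats) == 0:
        raise ValueError("retained set is empty")
    z, z_obs = _common_scale(retained_stats, observed, scale)
    md = float(_product_kde(z, z_obs[None, :], bandwidth=bandwidth)[0])
    return max(md, np.finfo(float).tiny)


def posterior_pvalue(
    retained_stats: pd.DataFrame,
    observed: pd.Series,
    scale: tuple[pd.Series, pd.Series] | None = None,
) -> float:
    """Fraction of retained vectors whose KDE density is <= the observed
    vector's density."""
    if len(retained_stats) == 0:
        raise ValueError("retained set is empty")
    z, z_obs = _common_scale(retained_stats, observed, scale)
    dens = _product_kde(z, z)
    d_obs = _product_kde(z, z_obs[None, :])[0]
    return float(np.mean(dens <= d_obs))


def bayes_factor(md_a: float, md_b: float) -> float:
    """Quotient of two marginal densities; infinite when ``md_b`` is 0."""
    if md_b < 0 or md_a < 0:
        raise ValueError("marginal densities must be non-negative")
    if md_b == 0:
        logger.warning("zero denominator marginal density; Bayes factor infinite")
        return np.inf
    return md_a / md_b


@dataclass
class ModelComparison:
    """Per-scenario marginal densities and P-values with the full pairwise
    Bayes-factor matrix (BF[i, j] = MD_i / MD_j)."""

    marginal_densities: pd.Series
    pvalues: pd.Series
    bf_matrix: pd.DataFrame
    ranking: list[str]
    rejected: list[str]
    best: str


def compare_scenarios(
    results: Mapping[str, tuple[float, float]],
    bf_reject_threshold: float = 3.0,
) -> ModelComparison:
    """Rank scenarios by marginal density and reject those the best scenario
    beats with a Bayes factor above the threshold."""
    if len(results) < 1:
        raise ValueError("need at least one scenario")
    names = list(results)
    md = pd.Series({k: results[k][0] for k in names}, dtype=float)
    pv = pd.Series({k: results[k][1] for k in names}, dtype=float)
    bf = pd.DataFrame(
        md.to_numpy()[:, None] / md.to_numpy()[None, :], index=names, columns=names
    )
    ranking = list(md.sort_values(ascending=False).index)
    best = ranking[0]
    rejected = [k for k in names if k != best and bf.loc[best, k] > bf_reject_threshold]
    return ModelComparison(
        marginal_densities=md, pvalues=pv, bf_matrix=bf,
        ranking=ranking, rejected=rejected, best=best,
    )


# ---------------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------------


def posterior_summaries(
    samples: pd.DataFrame,
    prior_table: Mapping[str, tuple[str, float, float]] | None = None,
) -> pd.DataFrame:
    """Mode (KDE peak on the prior's sampling scale) and central 50%/90%
    intervals per parameter."""
    if len(samples) < 100:
        raise ValueError("need at least 100 posterior samples")
    priors = dict(DEFAULT_PRIORS) if prior_table is None else dict(prior_table)
    rows = {}
    for name in samples.columns:
        x = samples[name].to_numpy(dtype=float)
        scale = priors.get(name, ("linear", None, None))[0]
        y = np.log10(x) if scale == "log10" else x
        if np.ptp(y) == 0:
            mode = y[0]
        else:
            kde = stats.gaussian_kde(y)
            grid = np.linspace(y.min(), y.max(), 512)
            mode = grid[np.argmax(kde(grid))]
        q = np.quantile(y, [0.25, 0.75, 0.05, 0.95])
        vals = np.array([mode, q[0], q[1], q[2], q[3]])
        if scale == "log10":
            vals = 10**vals
        rows[name] = dict(
            zip(["mode", "q50_lower", "q50_upper", "q90_lower", "q90_upper"], vals)
        )
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# Reference tables and end-to-end model choice
# ---------------------------------------------------------------------------


def build_reference_table(
    spec,
    draws,
    samples_per_population: Mapping[str, int],
    n_loci: int,
    seed: int | None = None,
    reference_group: str = "source",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one summary vector per prior draw under a scenario.

    Returns (params, stats) DataFrames with aligned rows; the per-draw
    simulation seeds derive deterministically from ``seed``.
    """
    from .simulate import simulate_scenario

    rng = np.random.default_rng(seed)
    sim_seeds = rng.integers(1, 2**31 - 1, size=len(draws))
    param_rows, stat_rows = [], []
    for params, s in zip(draws, sim_seeds):
        panel, popmap = simulate_scenario(
            spec, params, samples_per_population, n_loci, seed=int(s)
        )
        groups = {p: popmap.samples_for(p) for p in spec.sampled}
        stat_rows.append(summarize(panel, groups, reference_group=reference_group))
        param_rows.append(params.as_dict())
    return pd.DataFrame(param_rows), pd.DataFrame(stat_rows)


def model_choice(
    observed: pd.Series,
    tables: Mapping[str, tuple[pd.DataFrame, pd.DataFrame]],
    cfg: AbcConfig | None = None,
    statistic_names: Sequence[str] | None = None,
) -> ModelComparison:
    """Full model choice: per scenario (params, stats) reference tables ->
    rejection, marginal density under a pooled standardization, P-value and
    the resulting comparison."""
    cfg = cfg or AbcConfig()
    pooled = pd.concat([t[1] for t in tables.values()], ignore_index=True)
    if statistic_names is None:
        statistic_names = prune_correlated(pooled, cfg.rho_max)
    scale = (pooled[statistic_names].mean(), pooled[statistic_names].std())
    # common bandwidth in standardized units: Silverman at the smallest
    # retained count, shared by every scenario so MDs are comparable
    d = len(statistic_names)
    n_min = min(int(np.ceil(cfg.retain_fraction * len(t[1]))) for t in tables.values())
    h = (4.0 / ((d + 2) * n_min)) ** (1.0 / (d + 4))
    results = {}
    for name, (params, sim_stats) in tables.items():
        sub = sim_stats[list(statistic_names)]
        kept, _ = abc_reject(observed[list(statistic_names)], sub, cfg)
        retained = sub.iloc[kept]
        md = marginal_density(retained, observed, scale=scale, bandwidth=h)
        pv = posterior_pvalue(retained, observed, scale=scale)
        results[name] = (md, pv)
    return compare_scenarios(results, cfg.bf_reject_threshold)
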