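"""LD-based effective population size trajectories and the slope statistic.

Pairs of SNPs at physical distance d map to a recombination rate c; the
sample-size-corrected mean r-squared in a distance bin yields an estimate
of Ne at t = 1/(2c) generations ago via Ne = (1/(4c)) (1/r2_adj - alpha),
where alpha = 2 applies the mutation-rate modifier and alpha = 1 ignores
mutation.

The slope statistic normalizes each segment slope S_n of the (t, Ne)
trajectory by the median of itself and the two more-past slopes:
``NeS_n = (S_n - med{S_n, S_n+1, S_n+2}) / (1 + med{...})``. A
constant-slope trajectory therefore scores identically zero, and the two
most-past segments have no defined value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel

logger = logging.getLogger(__name__)


@dataclass
class LDBin:
    """One physical-distance bin of SNP pairs."""

    d_lo: float  # bp, inclusive
    d_hi: float  # bp, exclusive
    c: float  # Morgans
    r2_adj: float  # corrected mean r-squared
    n_pairs: int

    @property
    def t(self) -> float:
        """Generations ago probed by this bin."""
        return 1.0 / (2.0 * self.c)


@dataclass
class NeTrajectory:
    """(t, Ne) points ordered by increasing t (toward the past)."""

    t: np.ndarray
    ne: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ne = np.asarray(self.ne, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if np.any(self.ne <= 0):
            raise ValueError("Ne must be positive")

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "ne": self.ne})


@dataclass
class NeSlopeSeries:
    """Per-segment slopes and their median-normalized values.

    ``nes`` is NaN for the two most-past segments (no two more-past
    neighbours) and wherever the median equals -1.
    """

    t_mid: np.ndarray
    slope: np.ndarray
    median3: np.ndarray
    nes: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n": np.arange(len(self.slope)),
                "t_mid": self.t_mid,
                "S": self.slope,
                "median3": self.median3,
                "NeS": self.nes,
            }
        )


@dataclass
class NeConfig:
    """Binning and estimator settings for the LD-Ne trajectory."""

    bin_edges: Sequence[float] = field(
        default_factory=lambda: list(np.geomspace(1.0e6, 4.0e6, 11))
    )
    min_pairs: int = 20
    alpha: float = 2.0  # 2 = with mutation-rate modifier, 1 = without
    map_function: Literal["linear", "haldane"] = "linear"
    cm_per_mb: float = 1.0
    t_range: tuple[float, float] | None = (13.0, 50.0)


def _map_to_morgans(d_bp: np.ndarray, cfg: NeConfig) -> np.ndarray:
    """Physical distance -> recombination rate in Morgans."""
    c_lin = d_bp * cfg.cm_per_mb * 1e-8
    if cfg.map_function == "linear":
        return c_lin
    if cfg.map_function == "haldane":
        return 0.5 * (1.0 - np.exp(-2.0 * c_lin))
    raise ValueError(f"unknown map function {cfg.map_function!r}")


def binned_r2(
    panel: GenotypePanel,
    sample_ids: Sequence[str],
    cfg: NeConfig | None = None,
) -> list[LDBin]:
    """Mean adjusted r-squared of intra-chromosomal SNP pairs per distance bin.

    Phased panels use haplotype r-squared with a 1/(2n) sample-size
    correction; unphased panels use composite (dosage) r-squared with a 1/n
    correction. Bins whose corrected value is non-positive or whose pair
    count falls below ``min_pairs`` are dropped with a warning.
    """
    cfg = cfg or NeConfig()
    if len(sample_ids) < 10:
        logger.warning("only %d individuals; LD-Ne will be noisy", len(sample_ids))
    edges = np.asarray(cfg.bin_edges, dtype=float)
    sidx = panel.sample_indices(sample_ids)
    use_haps = panel.phased and panel.haplotypes is not None
    if use_haps:
        cols = np.column_stack([2 * sidx, 2 * sidx + 1]).ravel()
        data_full = panel.haplotypes[:, cols].astype(float)
        correction = 1.0 / (2 * len(sidx))
    else:
        data_full = panel.genotypes[:, sidx].astype(float)
        data_full[data_full == MISSING] = np.nan
        correction = 1.0 / len(sidx)

    sums = np.zeros(len(edges) - 1)
    counts = np.zeros(len(edges) - 1, dtype=int)
    dist_sums = np.zeros(len(edges) - 1)
    for chrom, sub in panel.variants.groupby("chrom", sort=False):
        vidx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy(dtype=float)
        x = data_full[vidx]
        # pairwise complete standardization; missing handled by masking
        mask = np.isfinite(x)
        xm = np.where(mask, x, 0.0)
        n_obs = mask.astype(float) @ mask.T.astype(float)
        sx = xm @ mask.T.astype(float)
        sxx = (xm**2) @ mask.T.astype(float)
        sxy = xm @ xm.T
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = sxy / n_obs - (sx / n_obs) * (sx.T / n_obs)
            var_i = sxx / n_obs - (sx / n_obs) ** 2
            r2 = cov**2 / (var_i * var_i.T)
        iu, ju = np.triu_indices(len(vidx), k=1)
        d = pos[ju] - pos[iu]
        vals = r2[iu, ju]
        ok = (
            np.isfinite(vals)
            & (d >= edges[0])
            & (d < edges[-1])
            & (n_obs[iu, ju] >= 2)
        )
        which = np.digitize(d[ok], edges) - 1
        np.add.at(sums, which, vals[ok])
        np.add.at(counts, which, 1)
        np.add.at(dist_sums, which, d[ok])

    bins: list[LDBin] = []
    for bi in range(len(edges) - 1):
        if counts[bi] < max(cfg.min_pairs, 1):
            logger.warning(
                "bin [%g, %g) has %d pairs (min %d); dropped",
                edges[bi], edges[bi + 1], counts[bi], cfg.min_pairs,
            )
            continue
        mean_d = dist_sums[bi] / counts[bi]
        c = float(_map_to_morgans(np.array([mean_d]), cfg)[0])
        r2_adj = sums[bi] / counts[bi] - correction
        if r2_adj <= 0:
            logger.warning("bin [%g, %g) corrected r2 <= 0; dropped",
                           edges[bi], edges[bi + 1])
            continue
        bins.append(
            LDBin(d_lo=float(edges[bi]), d_hi=float(edges[bi + 1]), c=c,
                  r2_adj=float(r2_adj), n_pairs=int(counts[bi]))
        )
    return bins


def ne_from_bin(bin: LDBin, alpha: float = 2.0) -> tuple[float, float] | None:
    """Invert the LD expectation for one bin: returns (t, Ne) or None when
    the corrected r-squared gives a non-positive estimate."""
    if bin.c <= 0:
        raise ValueError("bin recombination rate must be positive")
    if bin.r2_adj <= 0:
        return None
    ne = (1.0 / (4.0 * bin.c)) * (1.0 / bin.r2_adj - alpha)
    if ne <= 0:
        return None
    return bin.t, ne


def ne_trajectory(
    panel: GenotypePanel,
    sample_ids: Sequence[str],
    cfg: NeConfig | None = None,
) -> NeTrajectory:
    """LD-based Ne trajectory for one population (deterministic, no RNG).

    One point per surviving distance bin, restricted to ``cfg.t_range``
    (default 13-50 generations ago).
    """
    cfg = cfg or NeConfig()
    bins = binned_r2(panel, sample_ids, cfg)
    pts = []
    for b in bins:
        res = ne_from_bin(b, alpha=cfg.alpha)
        if res is None:
            continue
        t, ne = res
        if cfg.t_range is not None and not (cfg.t_range[0] <= t <= cfg.t_range[1]):
            continue
        pts.append((t, ne))
    if not pts:
        raise ValueError("no usable LD bins for a trajectory")
    pts.sort()
    t = np.array([p[0] for p in pts])
    ne = np.array([p[1] for p in pts])
    return NeTrajectory(t=t, ne=ne)


def nes(trajectory: NeTrajectory) -> NeSlopeSeries:
    """Median-normalized trajectory slopes.

    Slopes are oriented with the index increasing toward the past
    (S_n = delta Ne / delta t along increasing t). The normalizing median
    for segment n runs over {S_n, S_n+1, S_n+2}; the last two segments have
    no value, and a median of exactly -1 yields NaN.
    """
    if len(trajectory) < 4:
        raise ValueError("need at least 4 trajectory points (3 slopes)")
    t, ne = trajectory.t, trajectory.ne
    slope = np.diff(ne) / np.diff(t)
    t_mid = 0.5 * (t[:-1] + t[1:])
    m = len(slope)
    median3 = np.full(m, np.nan)
    nes_vals = np.full(m, np.nan)
    for n in range(m - 2):
        med = float(np.median(slope[n : n + 3]))
        median3[n] = med
        if med == -1.0:
            logger.warning("median slope of -1 at segment %d; value undefined", n)
            continue
        nes_vals[n] = (slope[n] - med) / (1.0 + med)
    return NeSlopeSeries(t_mid=t_mid, slope=slope, median3=median3, nes=nes_vals)
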