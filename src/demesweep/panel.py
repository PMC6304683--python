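"""Genotype panel data model and elementary population-genetic statistics.

The :class:`GenotypePanel` is the central data structure consumed by every
downstream stage: a biallelic variant table, a dosage matrix (alt-allele
counts per diploid sample) and, for phased data, a binary haplotype matrix.
Alongside it live the building blocks the scans and inference modules reuse:
pooled allele frequencies, composite-genotype r-squared, Weir-Cockerham
variance components, Reynolds distances and classical MDS on Hamming
distances.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

#: Sample roles recognised by :class:`PopulationMap`.
ROLES = ("focal", "reference", "ancestral", "outgroup")


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------


@dataclass
class GenotypePanel:
    """Biallelic SNP panel with optional phased haplotypes.

    Parameters
    ----------
    variants
        DataFrame with columns ``chrom`` (str), ``pos`` (int, 1-based
        inclusive), ``ref`` and ``alt`` (allele codes). Positions must be
        strictly increasing within each chromosome.
    samples
        Ordered sample identifiers.
    genotypes
        ``(n_variants, n_samples)`` integer array of alt-allele dosages in
        ``{0, 1, 2}`` with ``-1`` for missing.
    haplotypes
        Optional ``(n_variants, 2 * n_samples)`` binary array; columns
        ``2*i`` and ``2*i + 1`` are the two haplotypes of sample ``i``.
    phased
        Whether the haplotypes carry phase information.
    """

    variants: pd.DataFrame
    samples: list[str]
    genotypes: np.ndarray
    haplotypes: np.ndarray | None = None
    phased: bool = False

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.haplotypes is not None:
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.validate()

    # -- invariants ---------------------------------------------------

    def validate(self) -> None:
        if self.genotypes.shape != (self.n_variants, self.n_samples):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{self.n_variants} variants x {self.n_samples} samples"
            )
        for chrom, sub in self.variants.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
        if self.phased and self.haplotypes is None:
            raise ValueError("phased panel requires haplotypes")
        if self.haplotypes is not None:
            if self.haplotypes.shape != (self.n_variants, 2 * self.n_samples):
                raise ValueError("haplotype matrix shape mismatch")
            hap_sum = self.haplotypes[:, 0::2] + self.haplotypes[:, 1::2]
            both = (self.genotypes != MISSING) & np.all(
                self.haplotypes.reshape(self.n_variants, -1, 2) != MISSING, axis=2
            )
            if not np.array_equal(hap_sum[both], self.genotypes[both]):
                raise ValueError("dosages disagree with haplotype sums")

    # -- basic properties ---------------------------------------------

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, sample_ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        return np.array([lookup[s] for s in sample_ids], dtype=int)

    # -- subsetting ---------------------------------------------------

    def take_variants(self, index: np.ndarray | Sequence[int]) -> "GenotypePanel":
        index = np.asarray(index, dtype=int)
        return GenotypePanel(
            variants=self.variants.iloc[index],
            samples=list(self.samples),
            genotypes=self.genotypes[index],
            haplotypes=None if self.haplotypes is None else self.haplotypes[index],
            phased=self.phased,
        )

    def take_samples(self, sample_ids: Sequence[str]) -> "GenotypePanel":
        idx = self.sample_indices(sample_ids)
        hap = None
        if self.haplotypes is not None:
            cols = np.column_stack([2 * idx, 2 * idx + 1]).ravel()
            hap = self.haplotypes[:, cols]
        return GenotypePanel(
            variants=self.variants.copy(),
            samples=list(sample_ids),
            genotypes=self.genotypes[:, idx],
            haplotypes=hap,
            phased=self.phased,
        )

    # -- per-variant summaries ----------------------------------------

    def allele_frequencies(self, sample_index: np.ndarray | None = None) -> np.ndarray:
        """Pooled alt-allele frequency per variant (NaN where no calls)."""
        g = self.genotypes if sample_index is None else self.genotypes[:, sample_index]
        called = g != MISSING
        n_alleles = 2 * called.sum(axis=1)
        alt = np.where(called, g, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / n_alleles, np.nan)

    def maf(self) -> np.ndarray:
        p = self.allele_frequencies()
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        return (self.genotypes != MISSING).mean(axis=1)


@dataclass
class PopulationMap:
    """sample id -> (population, role) assignment.

    Roles: ``focal`` (scanned populations), ``reference`` (comparison
    panels), ``ancestral`` (donor panels for local-ancestry models) and
    ``outgroup``.
    """

    assignments: pd.DataFrame  # columns: sample_id, population, role

    def __post_init__(self) -> None:
        req = {"sample_id", "population", "role"}
        if not req.issubset(self.assignments.columns):
            raise ValueError(f"population map needs columns {sorted(req)}")
        bad = set(self.assignments["role"]) - set(ROLES)
        if bad:
            raise ValueError(f"unknown roles {sorted(bad)}; expected one of {ROLES}")
        counts = self.assignments.groupby("population").size()
        if (counts == 0).any():
            raise ValueError("empty population in map")

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.assignments["population"]))

    def samples_for(self, population: str) -> list[str]:
        sel = self.assignments["population"] == population
        if not sel.any():
            raise KeyError(f"unknown population {population!r}")
        return list(self.assignments.loc[sel, "sample_id"])

    def populations_with_role(self, role: str) -> list[str]:
        sel = self.assignments["role"] == role
        return list(dict.fromkeys(self.assignments.loc[sel, "population"]))

    def check_covers(self, panel: GenotypePanel) -> None:
        mapped = set(self.assignments["sample_id"])
        for s in panel.samples:
            if s not in mapped:
                raise ValueError(f"sample {s!r} missing from population map")


@dataclass
class FilterConfig:
    """Variant filtering thresholds (fractions in [0, 1])."""

    maf_min: float = 0.01
    call_rate_min: float = 0.90
    ld_prune: tuple[float, int, int] | None = None  # (r2 ceiling, window, step)

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf_min <= 1.0 and 0.0 <= self.call_rate_min <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
        if self.ld_prune is not None:
            r2, window, step = self.ld_prune
            if not 0.0 <= r2 <= 1.0:
                raise ValueError("r2 ceiling must lie in [0, 1]")
            if not window >= step >= 1:
                raise ValueError("need window >= step >= 1")


@dataclass
class FstComponents:
    """Per-variant Weir-Cockerham variance components."""

    a: np.ndarray  # among populations
    b: np.ndarray  # among individuals within populations
    c: np.ndarray  # within individuals

    @property
    def fst(self) -> float:
        """Ratio-of-sums FST over all variants with data."""
        ok = np.isfinite(self.a) & np.isfinite(self.b) & np.isfinite(self.c)
        denom = (self.a[ok] + self.b[ok] + self.c[ok]).sum()
        if denom == 0 or not ok.any():
            return np.nan
        return float(self.a[ok].sum() / denom)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def filter_variants(panel: GenotypePanel, cfg: FilterConfig) -> GenotypePanel:
    """Retain variants with pooled MAF > ``maf_min`` and call rate >= ``call_rate_min``.

    MAF and call rate are computed over all samples pooled. Raises if no
    variant survives. Optionally LD-prunes afterwards.
    """
    keep = (panel.maf() > cfg.maf_min) & (panel.call_rate() >= cfg.call_rate_min)
    keep &= ~np.isnan(panel.maf())
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise ValueError("no variants survive filtering")
    out = panel.take_variants(idx)
    if cfg.ld_prune is not None:
        r2_max, window, step = cfg.ld_prune
        out = ld_prune(out, r2_max=r2_max, window=window, step=step)
    return out


def composite_r2(panel: GenotypePanel, i: int, j: int) -> float:
    """Squared Pearson correlation of dosages at variants ``i`` and ``j``.

    Missing genotypes are excluded pairwise. Returns NaN when fewer than two
    shared calls remain or either variant has zero variance.
    """
    gi = panel.genotypes[i].astype(float)
    gj = panel.genotypes[j].astype(float)
    ok = (gi != MISSING) & (gj != MISSING)
    if ok.sum() < 2:
        return np.nan
    x, y = gi[ok], gj[ok]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    r = np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy)
    return float(r * r)


def _r2_matrix(g: np.ndarray) -> np.ndarray:
    """Pairwise dosage r-squared for a (variants x samples) block.

    Assumes no missing data (callers fall back to pairwise loops otherwise).
    Zero-variance rows yield NaN.
    """
    x = g.astype(float)
    x = x - x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        xn = x / sd[:, None]
    r = (xn @ xn.T) / g.shape[1]
    return r * r


def ld_prune(
    panel: GenotypePanel, r2_max: float, window: int, step: int
) -> GenotypePanel:
    """Greedy left-to-right windowed LD pruning (PLINK indep-pairwise style).

    Within each window of ``window`` retained-or-not SNPs (advancing by
    ``step``), any later SNP with r-squared above ``r2_max`` against an
    earlier retained SNP is dropped.
    """
    if not window >= step >= 1:
        raise ValueError("need window >= step >= 1")
    has_missing = np.any(panel.genotypes == MISSING)
    keep = np.ones(panel.n_variants, dtype=bool)
    for chrom, sub in panel.variants.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        for start in range(0, len(idx), step):
            widx = idx[start : start + window]
            live = widx[keep[widx]]
            if len(live) < 2:
                continue
            if has_missing:
                for a_pos, a in enumerate(live):
                    if not keep[a]:
                        continue
                    for b in live[a_pos + 1 :]:
                        if not keep[b]:
                            continue
                        r2 = composite_r2(panel, int(a), int(b))
                        if np.isfinite(r2) and r2 > r2_max:
                            keep[b] = False
            else:
                r2m = _r2_matrix(panel.genotypes[live])
                for a_pos in range(len(live)):
                    if not keep[live[a_pos]]:
                        continue
                    for b_pos in range(a_pos + 1, len(live)):
                        b = live[b_pos]
                        if not keep[b]:
                            continue
                        r2 = r2m[a_pos, b_pos]
                        if np.isfinite(r2) and r2 > r2_max:
                            keep[b] = False
    return panel.take_variants(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# Weir-Cockerham FST
# ---------------------------------------------------------------------------


def wc_components(
    panel: GenotypePanel,
    pop_sample_ids: Sequence[Sequence[str]],
    variant_index: np.ndarray | None = None,
) -> FstComponents:
    """Weir & Cockerham (1984) per-variant variance components for r populations.

    Returns the among-population (a), among-individual (b) and
    within-individual (c) components; variants without data in two or more
    populations get NaN components.
    """
    if variant_index is None:
        variant_index = np.arange(panel.n_variants)
    variant_index = np.asarray(variant_index, dtype=int)
    r = len(pop_sample_ids)
    if r < 2:
        raise ValueError("need at least two populations")
    m = len(variant_index)
    n = np.zeros((r, m))  # genotyped diploids
    p = np.zeros((r, m))  # alt freq
    h = np.zeros((r, m))  # observed het freq
    for k, ids in enumerate(pop_sample_ids):
        g = panel.genotypes[np.ix_(variant_index, panel.sample_indices(ids))]
        called = g != MISSING
        nk = called.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[k] = np.where(nk > 0, np.where(called, g, 0).sum(axis=1) / (2 * nk), np.nan)
            h[k] = np.where(nk > 0, ((g == 1) & called).sum(axis=1) / nk, np.nan)
        n[k] = nk

    ok = np.all(n >= 1, axis=0) & (n.sum(axis=0) >= 2)
    nbar = n.mean(axis=0)
    nsum = n.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (nsum - (n**2).sum(axis=0) / nsum) / (r - 1)
        pbar = (n * p).sum(axis=0) / nsum
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n * h).sum(axis=0) / nsum
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - s2 * (r - 1) / r
            - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
    bad = ~ok | (nbar <= 1) | (nc <= 0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return FstComponents(a=a, b=b, c=c)


def wc_fst(
    panel: GenotypePanel,
    pop_a_ids: Sequence[str],
    pop_b_ids: Sequence[str],
    variant_index: np.ndarray | None = None,
) -> tuple[FstComponents, float]:
    """Two-population Weir-Cockerham FST as a ratio of summed components."""
    comps = wc_components(panel, [pop_a_ids, pop_b_ids], variant_index)
    return comps, comps.fst


# ---------------------------------------------------------------------------
# Reynolds distance
# ---------------------------------------------------------------------------


def reynolds_distance_matrix(
    panel: GenotypePanel,
    popmap: PopulationMap,
    populations: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Pairwise Reynolds (coancestry) distances between populations.

    Per pair the distance is the ratio-of-sums over loci of the squared
    allele-frequency differences against total gene diversity,
    ``sum_l (p1 - p2)^2 / sum_l (p1 + p2 - 2 p1 p2)`` (the classic
    allele-frequency form), clipped at zero. Populations with no data get
    a row of NaN.
    """
    pops = list(populations) if populations is not None else popmap.populations
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    freqs = {}
    for pop in pops:
        idx = panel.sample_indices(popmap.samples_for(pop))
        freqs[pop] = panel.allele_frequencies(sample_index=idx)
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, pa in enumerate(pops):
        for pb in pops[i + 1 :]:
            p1, p2 = freqs[pa], freqs[pb]
            ok = np.isfinite(p1) & np.isfinite(p2)
            if not ok.any():
                d = np.nan
            else:
                num = ((p1[ok] - p2[ok]) ** 2).sum()
                den = (p1[ok] + p2[ok] - 2 * p1[ok] * p2[ok]).sum()
                d = 0.0 if den == 0 else max(num / den, 0.0)
            mat.loc[pa, pb] = mat.loc[pb, pa] = d
    return mat


# ---------------------------------------------------------------------------
# Hamming MDS
# ---------------------------------------------------------------------------


def hamming_distance_matrix(
    panel: GenotypePanel, metric: Literal["allele-count", "binary"] = "allele-count"
) -> np.ndarray:
    """Pairwise per-site Hamming distance between samples.

    ``allele-count``: mean |dosage difference| / 2 over shared calls (PLINK's
    1 - IBS). ``binary``: fraction of shared calls with unequal dosage.
    Both are squared-Euclidean-embeddable, so classical scaling below treats
    them as squared distances.
    """
    g = panel.genotypes.astype(float)
    g[panel.genotypes == MISSING] = np.nan
    n = panel.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(g[:, i : i + 1] - g[:, i:])
        if metric == "binary":
            diff = (diff > 0).astype(float) * np.where(np.isnan(diff), np.nan, 1.0)
        else:
            diff = diff / 2.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            row = np.nanmean(diff, axis=0)
        d[i, i:] = row
        d[i:, i] = row
    np.fill_diagonal(d, 0.0)
    return d


def hamming_mds(
    panel: GenotypePanel,
    k: int,
    metric: Literal["allele-count", "binary"] = "allele-count",
) -> tuple[np.ndarray, np.ndarray]:
    """Classical metric MDS of the Hamming distance matrix.

    Returns per-sample coordinates ``(n_samples, k)`` and the eigenvalue
    share of each axis. ``k`` is clipped to ``n_samples - 1`` with a
    warning. Coordinates are deterministic up to sign (signs fixed so each
    axis has non-negative maximum-magnitude loading).
    """
    n = panel.n_samples
    if k > n - 1:
        logger.warning("k=%d too large for %d samples; clipping to %d", k, n, n - 1)
        k = n - 1
    d = hamming_distance_matrix(panel, metric=metric)
    # Treat the Hamming distance itself as a squared distance: both metrics
    # are coordinate-wise squared-Euclidean embeddable, making B PSD.
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = np.clip(evals, 0.0, None)
    coords = evecs[:, :k] * np.sqrt(pos[:k])
    for axis in range(coords.shape[1]):
        col = coords[:, axis]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col
    total = pos.sum()
    shares = pos[:k] / total if total > 0 else np.zeros(k)
    return coords, shares
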