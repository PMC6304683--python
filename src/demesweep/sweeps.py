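"""XP-EHH and windowed-FST genome scans with region-calling rules.

Scores are ln(iHH_focal / iHH_reference) per core SNP, standardized genome
wide. Significant SNPs (upper tail by default) validated across reference
replicates are merged into candidate regions: runs of significant SNPs may
contain at most one non-significant SNP, isolated singletons are discarded,
and each region is extended by half the distance to the neighbouring
non-significant marker on both sides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import GenotypePanel, wc_components

logger = logging.getLogger(__name__)


@dataclass
class ScanConfig:
    max_gap: float = 500_000.0  # bp between adjacent SNPs before truncation
    ehh_cutoff: float = 0.05
    sig_quantile: float = 0.99  # upper tail for XP-EHH z scores
    min_reference_support: int = 2
    two_sided: bool = False
    fst_window: float = 500_000.0
    fst_quantile: float = 0.99
    fst_min_snps: int = 2
    fst_required_support: int | None = None  # None -> all references

    def __post_init__(self) -> None:
        for q in (self.sig_quantile, self.fst_quantile):
            if not 0 < q < 1:
                raise ValueError("quantiles must lie in (0, 1)")
        if self.fst_window <= 0 or self.max_gap <= 0:
            raise ValueError("windows must be positive")


@dataclass
class CandidateRegion:
    """Merged significant interval (1-based inclusive coordinates)."""

    chrom: str
    start: int
    end: int
    members: list[int]  # positions of member significant SNPs
    method: str  # XP-EHH | FST | both
    cluster: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start must not exceed end")
        if len(self.members) < 2:
            raise ValueError("regions need at least two member variants")

    @property
    def length_kbp(self) -> float:
        return region_length_kbp(self.start, self.end)

    def overlaps(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos <= self.end

    def to_bed_fields(self) -> tuple[str, int, int]:
        """0-based half-open BED coordinates."""
        return self.chrom, self.start - 1, self.end


def region_length_kbp(start: int, end: int) -> float:
    """(end - start) / 1000, rounded half-up to one decimal."""
    kbp = Decimal(end - start) / Decimal(1000)
    return float(kbp.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# EHH / iHH
# ---------------------------------------------------------------------------


def _ehh_value(group_ids: np.ndarray) -> float:
    n = len(group_ids)
    counts = np.bincount(group_ids)
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


class _GroupTracker:
    """Incrementally tracks haplotype identity groups away from a core.

    Only groups of two or more haplotypes contribute to EHH (singletons can
    never regrow), so they alone are carried; under a sweep the one large
    carrier group survives cheaply while neutral groups shatter within a
    few markers.
    """

    __slots__ = ("groups", "denom")

    def __init__(self, alleles: np.ndarray):
        n = len(alleles)
        self.denom = n * (n - 1)
        self.groups = [
            idx for a in (0, 1)
            if len(idx := np.flatnonzero(alleles == a)) >= 2
        ]

    def step(self, alleles: np.ndarray) -> float:
        new_groups = []
        acc = 0
        for grp in self.groups:
            sub = alleles[grp]
            ones = grp[sub == 1]
            zeros = grp[sub != 1]
            for part in (ones, zeros):
                if len(part) >= 2:
                    new_groups.append(part)
                    acc += len(part) * (len(part) - 1)
        self.groups = new_groups
        return acc / self.denom

    @property
    def ehh(self) -> float:
        return sum(len(g) * (len(g) - 1) for g in self.groups) / self.denom


def ehh_curve(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    core_index: int,
    direction: int,
    max_gap: float = 500_000.0,
    min_ehh: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Extended haplotype homozygosity from a core marker outward.

    ``haplotypes`` is a (markers x haplotypes) binary matrix for one
    chromosome; ``direction`` is +1 (toward larger positions) or -1. The
    curve starts at the core with EHH 1 and is truncated at inter-marker
    gaps larger than ``max_gap``; extension stops early once EHH falls
    below ``min_ehh``.
    """
    n = haplotypes.shape[1]
    if n < 4:
        raise ValueError("need at least four haplotypes")
    if direction not in (-1, 1):
        raise ValueError("direction must be +1 or -1")
    out_pos = [int(positions[core_index])]
    out_ehh = [1.0]
    tracker = _GroupTracker(haplotypes[core_index])
    j = core_index
    while True:
        j2 = j + direction
        if j2 < 0 or j2 >= len(positions):
            break
        if abs(positions[j2] - positions[j]) > max_gap:
            break
        e = tracker.step(haplotypes[j2])
        out_pos.append(int(positions[j2]))
        out_ehh.append(e)
        j = j2
        if e < min_ehh or not tracker.groups:
            break
    return np.array(out_pos), np.array(out_ehh)


def _integrate_flank(positions: np.ndarray, ehh: np.ndarray, cutoff: float) -> float:
    """Trapezoidal integral outward from the core, stopping after the first
    segment whose far end drops below the cutoff."""
    total = 0.0
    for k in range(1, len(positions)):
        d = abs(float(positions[k]) - float(positions[k - 1]))
        total += 0.5 * (ehh[k] + ehh[k - 1]) * d
        if ehh[k] < cutoff:
            break
    return total


def ihh(
    flanks: Sequence[tuple[np.ndarray, np.ndarray]],
    ehh_cutoff: float = 0.05,
) -> float:
    """Integrated EHH: sum of the trapezoidal integrals of each flank curve
    over physical distance, each stopping where EHH drops below the cutoff."""
    return float(sum(_integrate_flank(p, e, ehh_cutoff) for p, e in flanks))


# ---------------------------------------------------------------------------
# XP-EHH scan
# ---------------------------------------------------------------------------


def _flank_ihh(
    hap_f: np.ndarray,
    hap_r: np.ndarray,
    positions: np.ndarray,
    cfg: ScanConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Right-flank iHH for every core, via per-pair first-mismatch indices.

    EHH at marker k for core c is the fraction of haplotype pairs without a
    mismatch on [c, k]; the trapezoidal integral therefore decomposes into
    one term per pair, so a single descending sweep maintaining each pair's
    next-mismatch index covers all cores in O(m * pairs). The stop marker
    (first combined-sample EHH below the cutoff) is an order statistic of
    the pairs' agreement extents.
    """
    m = len(positions)
    x = positions.astype(float)
    n_f = hap_f.shape[1]
    n_r = hap_r.shape[1]
    hap_all = np.hstack([hap_f, hap_r])
    iu, ju = np.triu_indices(n_f + n_r, k=1)
    is_f = ju < n_f
    is_r = iu >= n_f
    c_f = n_f * (n_f - 1) / 2
    c_r = n_r * (n_r - 1) / 2
    c_all = len(iu)
    # stop once the combined agree count drops to s or fewer pairs
    s = int(np.ceil(cfg.ehh_cutoff * c_all)) - 1
    kth = c_all - (s + 1)  # partition index of the (s+1)-th largest extent

    # first right gap break: cores at index > break_at[g] - 1 cannot cross it
    gap_breaks = np.flatnonzero(np.diff(x) > cfg.max_gap) # segment j -> j+1 broken
    ihh_f = np.zeros(m)
    ihh_r = np.zeros(m)
    nxt = np.full(len(iu), m, dtype=np.int64)
    d_mat = hap_all[:, iu] != hap_all[:, ju]
    for c in range(m - 1, -1, -1):
        nxt = np.where(d_mat[c], c, nxt)
        if c == m - 1:
            continue
        a = nxt - 1  # last marker each pair agrees through (>= c, or c-1)
        if s >= 0:
            a_stop = np.partition(a, kth)[kth]
            j_end = min(max(int(a_stop) + 1, c + 1), m - 1)
        else:
            j_end = m - 1  # cutoff 0: integrate to chromosome end
        gi = np.searchsorted(gap_breaks, c)
        if gi < len(gap_breaks):
            j_end = min(j_end, int(gap_breaks[gi]))
        if j_end <= c:
            continue
        for sel, c_n, out in ((is_f, c_f, ihh_f), (is_r, c_r, ihh_r)):
            ap = a[sel]
            j = np.minimum(ap, j_end)
            agree_core = ap >= c
            t = np.where(
                agree_core,
                x[np.clip(j, c, None)] - x[c]
                + np.where(j < j_end, 0.5 * (x[np.minimum(j + 1, m - 1)] - x[np.clip(j, c, None)]), 0.0),
                0.0,
            )
            e0_raw = agree_core.sum() / c_n
            out[c] = t.sum() / c_n + 0.5 * (x[c + 1] - x[c]) * (1.0 - e0_raw)
    return ihh_f, ihh_r


def _scan_chromosome(
    hap_f: np.ndarray,
    hap_r: np.ndarray,
    positions: np.ndarray,
    cfg: ScanConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """iHH per core SNP for the focal and reference samples of one
    chromosome, integrating both flanks over the extent where the
    combined-sample EHH stays above the cutoff (so the statistic is
    antisymmetric under a population swap)."""
    f_right, r_right = _flank_ihh(hap_f, hap_r, positions, cfg)
    f_left, r_left = _flank_ihh(
        hap_f[::-1], hap_r[::-1], -positions[::-1], cfg
    )
    return f_right + f_left[::-1], r_right + r_left[::-1]


def xpehh_scan(
    panel: GenotypePanel,
    focal_ids: Sequence[str],
    reference_ids: Sequence[str],
    cfg: ScanConfig | None = None,
    reference_label: str = "",
) -> pd.DataFrame:
    """Cross-population EHH scan of ``focal_ids`` against ``reference_ids``.

    Returns one row per scored core SNP with iHH in both groups, the raw
    ln(iHH_focal / iHH_ref) score and the genome-wide standardized z.
    Cores where either iHH is 0 are dropped.
    """
    cfg = cfg or ScanConfig()
    if not panel.phased or panel.haplotypes is None:
        raise ValueError("XP-EHH requires phased haplotypes; phase the VCF first")
    f_idx = panel.sample_indices(focal_ids)
    r_idx = panel.sample_indices(reference_ids)
    f_cols = np.column_stack([2 * f_idx, 2 * f_idx + 1]).ravel()
    r_cols = np.column_stack([2 * r_idx, 2 * r_idx + 1]).ravel()
    rows = []
    for chrom, sub in panel.variants.groupby("chrom", sort=False):
        vidx = sub.index.to_numpy()
        positions = sub["pos"].to_numpy()
        hap_f = panel.haplotypes[np.ix_(vidx, f_cols)]
        hap_r = panel.haplotypes[np.ix_(vidx, r_cols)]
        ihh_f, ihh_r = _scan_chromosome(hap_f, hap_r, positions, cfg)
        for k in range(len(vidx)):
            rows.append((str(chrom), int(positions[k]), ihh_f[k], ihh_r[k]))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ihh_obs", "ihh_ref"])
    df = df[(df["ihh_obs"] > 0) & (df["ihh_ref"] > 0)].reset_index(drop=True)
    df["raw"] = np.log(df["ihh_obs"] / df["ihh_ref"])
    sd = df["raw"].std(ddof=0)
    df["z"] = (df["raw"] - df["raw"].mean()) / (sd if sd > 0 else 1.0)
    df["ref_label"] = reference_label
    return df


def significant_snps(scores: pd.DataFrame, cfg: ScanConfig | None = None) -> set[tuple[str, int]]:
    """Upper-tail significant SNPs of a standardized scan.

    Takes the top ``floor(n * (1 - sig_quantile))`` SNPs by z (both tails
    by |z| when ``two_sided``); ties broken by scan order.
    """
    cfg = cfg or ScanConfig()
    n = len(scores)
    if n < 1000:
        logger.warning("only %d scored SNPs; tail quantiles will be coarse", n)
    k = int(np.floor(n * (1.0 - cfg.sig_quantile) + 1e-9))
    if k == 0:
        return set()
    key = scores["z"].abs() if cfg.two_sided else scores["z"]
    order = np.argsort(-key.to_numpy(), kind="stable")[:k]
    sub = scores.iloc[order]
    return set(zip(sub["chrom"], sub["pos"]))


def validate_replicates(
    sets: Sequence[set[tuple[str, int]]], min_support: int = 2
) -> set[tuple[str, int]]:
    """SNPs significant in at least ``min_support`` reference comparisons."""
    if len(sets) < 1:
        raise ValueError("need at least one reference set")
    counts: dict[tuple[str, int], int] = {}
    for s in sets:
        for snp in s:
            counts[snp] = counts.get(snp, 0) + 1
    return {snp for snp, c in counts.items() if c >= min_support}


def merge_regions(
    validated: set[tuple[str, int]],
    scored_positions: pd.DataFrame,
    cfg: ScanConfig | None = None,
    method: str = "XP-EHH",
    cluster: str = "",
    allow_gap: bool = True,
) -> list[CandidateRegion]:
    """Merge validated significant SNPs into candidate regions.

    Runs of significant SNPs may be interrupted by at most one consecutive
    non-significant scored SNP (when ``allow_gap``); runs of a single SNP
    are discarded. Region bounds extend half way to the neighbouring
    non-significant marker (clipped to the chromosome's scored extent).
    """
    cfg = cfg or ScanConfig()
    regions: list[CandidateRegion] = []
    for chrom, sub in scored_positions.groupby("chrom", sort=False):
        pos = np.sort(sub["pos"].to_numpy())
        sig = np.array([(str(chrom), int(p)) in validated for p in pos])
        sig_idx = np.flatnonzero(sig)
        if sig_idx.size == 0:
            continue
        max_skip = 2 if allow_gap else 1
        runs: list[list[int]] = [[int(sig_idx[0])]]
        for i in sig_idx[1:]:
            if i - runs[-1][-1] <= max_skip:
                runs[-1].append(int(i))
            else:
                runs.append([int(i)])
        for run in runs:
            if len(run) < 2:
                continue  # isolated significant SNPs are discarded
            first, last = run[0], run[-1]
            if first > 0:
                start = int(pos[first] - (pos[first] - pos[first - 1]) // 2)
            else:
                start = int(pos[first])
            if last < len(pos) - 1:
                end = int(pos[last] + (pos[last + 1] - pos[last]) // 2)
            else:
                end = int(pos[last])
            regions.append(
                CandidateRegion(
                    chrom=str(chrom), start=start, end=end,
                    members=[int(pos[i]) for i in run],
                    method=method, cluster=cluster,
                )
            )
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


# ---------------------------------------------------------------------------
# Windowed FST scan
# ---------------------------------------------------------------------------


def fst_window_scan(
    panel: GenotypePanel,
    focal_ids: Sequence[str],
    reference_groups: Mapping[str, Sequence[str]],
    cfg: ScanConfig | None = None,
    cluster: str = "",
    snp_sig_sets: Mapping[str, set[tuple[str, int]]] | None = None,
) -> tuple[pd.DataFrame, list[CandidateRegion]]:
    """Non-overlapping windowed FST scan against each reference group.

    Windows are anchored at position 1 (window k spans
    ``[k*W + 1, (k+1)*W]``). Per comparison, a window's FST is the
    ratio-of-sums of Weir-Cockerham components over its SNPs; outliers
    exceed the comparison's empirical ``fst_quantile``. A window is called
    when it is an outlier in the required number of comparisons (default:
    all) and holds at least ``fst_min_snps`` significant SNPs, where SNP
    significance defaults to the per-comparison top tail of per-SNP FST
    (or the supplied companion sets, e.g. from an XP-EHH scan).
    """
    cfg = cfg or ScanConfig()
    w = int(cfg.fst_window)
    required = cfg.fst_required_support or len(reference_groups)
    chroms = panel.variants["chrom"].to_numpy()
    pos = panel.variants["pos"].to_numpy()
    win_id = (pos - 1) // w
    keys = pd.DataFrame({"chrom": chroms, "win": win_id, "pos": pos})

    per_comparison: dict[str, pd.DataFrame] = {}
    snp_sig: dict[str, set[tuple[str, int]]] = {}
    for ref_name, ref_ids in reference_groups.items():
        comps = wc_components(panel, [focal_ids, ref_ids])
        df = keys.copy()
        df["a"] = comps.a
        df["abc"] = comps.a + comps.b + comps.c
        grouped = (
            df.dropna(subset=["a", "abc"])
            .groupby(["chrom", "win"], sort=False)
            .agg(a_sum=("a", "sum"), abc_sum=("abc", "sum"), n_snps=("a", "size"))
            .reset_index()
        )
        grouped = grouped[grouped["abc_sum"] != 0]
        grouped["fst"] = grouped["a_sum"] / grouped["abc_sum"]
        thr = grouped["fst"].quantile(cfg.fst_quantile)
        grouped["outlier"] = grouped["fst"] > thr
        per_comparison[ref_name] = grouped
        if snp_sig_sets is not None:
            snp_sig[ref_name] = set(snp_sig_sets.get(ref_name, set()))
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                snp_fst = comps.a / (comps.a + comps.b + comps.c)
            finite = np.isfinite(snp_fst)
            if finite.any():
                snp_thr = np.quantile(snp_fst[finite], cfg.fst_quantile)
                sel = finite & (snp_fst > snp_thr)
            else:
                sel = np.zeros(len(pos), dtype=bool)
            snp_sig[ref_name] = {
                (str(c), int(p)) for c, p in zip(chroms[sel], pos[sel])
            }

    # windows validated across comparisons
    support: dict[tuple[str, int], int] = {}
    for grouped in per_comparison.values():
        for _, row in grouped[grouped["outlier"]].iterrows():
            key = (str(row["chrom"]), int(row["win"]))
            support[key] = support.get(key, 0) + 1
    validated_windows = {k for k, c in support.items() if c >= required}

    sig_all = validate_replicates(list(snp_sig.values()), min_support=required)
    regions: list[CandidateRegion] = []
    for chrom, win in sorted(validated_windows):
        start, end = win * w + 1, (win + 1) * w
        members = [
            int(p)
            for c, p in sig_all
            if c == chrom and start <= p <= end
        ]
        if len(members) < cfg.fst_min_snps:
            continue
        regions.append(
            CandidateRegion(
                chrom=chrom, start=start, end=end, members=sorted(members),
                method="FST", cluster=cluster,
            )
        )

    table = pd.concat(
        [g.assign(reference=name) for name, g in per_comparison.items()],
        ignore_index=True,
    )
    return table, regions


def combine_methods(regions: Iterable[CandidateRegion]) -> list[CandidateRegion]:
    """Mark overlapping XP-EHH and FST regions of one cluster as 'both'."""
    regions = sorted(regions, key=lambda r: (r.chrom, r.start))
    out: list[CandidateRegion] = []
    for reg in regions:
        merged = False
        for prev in out:
            if prev.chrom == reg.chrom and prev.cluster == reg.cluster and not (
                reg.start > prev.end or reg.end < prev.start
            ) and prev.method != reg.method:
                prev.start = min(prev.start, reg.start)
                prev.end = max(prev.end, reg.end)
                prev.members = sorted(set(prev.members) | set(reg.members))
                prev.method = "both"
                merged = True
                break
        if not merged:
            out.append(
                CandidateRegion(
                    chrom=reg.chrom, start=reg.start, end=reg.end,
                    members=list(reg.members), method=reg.method,
                    cluster=reg.cluster,
                )
            )
    return out


def regions_to_frame(regions: Sequence[CandidateRegion]) -> pd.DataFrame:
    """Tabular view of candidate regions (lengths in kbp, 1 decimal)."""
    return pd.DataFrame(
        [
            {
                "cluster": r.cluster,
                "n_snps": len(r.members),
                "method": r.method,
                "position": f"{r.chrom}:{r.start}-{r.end}",
                "length_kbp": r.length_kbp,
            }
            for r in regions
        ]
    )
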