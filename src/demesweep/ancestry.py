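"""Local-ancestry inference and ancestry excess/deficiency scoring.

A hidden-Markov chain over ancestry labels runs along each chromosome:
the initial distribution is the genome-wide mixing vector alpha, the
transition over an inter-marker distance d re-draws the ancestry from
alpha with probability 1 - exp(-g * r * d) (g generations since admixture,
r recombination rate per bp), and emissions are the ancestral allele
frequencies. Forward-backward posteriors give per-variant ancestry
dosages summing to 2 per sample.

Candidate regions are scored by the difference between the mean ancestry
fraction at their member SNPs and the genome-wide mean; deviations beyond
two genome-wide standard deviations are flagged as strong.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel
from .sweeps import CandidateRegion

logger = logging.getLogger(__name__)


@dataclass
class AncestryModel:
    """Ancestral allele frequencies plus the admixture pulse parameters."""

    labels: list[str]
    frequencies: np.ndarray  # (n_variants, n_ancestries), alt-allele freq
    alpha: np.ndarray  # genome-wide mixing proportions, sums to 1
    variants: pd.DataFrame
    g: float = 83.0
    recombination_rate: float = 1e-8  # per bp
    generation_length_years: float = 5.0

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if np.any(self.frequencies < 0) or np.any(self.frequencies > 1):
            raise ValueError("frequencies must lie in [0, 1]")
        if not np.isclose(self.alpha.sum(), 1.0):
            raise ValueError("alpha must sum to 1")


@dataclass
class AncestryDosage:
    """Posterior ancestry dosages per sample, variant and ancestry.

    ``dosage[s, v, k]`` lies in [0, 2] and sums to 2 over k at every
    genotyped variant.
    """

    labels: list[str]
    samples: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray  # (n_samples, n_variants, n_ancestries)
    hap_posterior: np.ndarray | None = None  # (2 * n_samples, n_variants, K), phased only

    def fractions(self) -> np.ndarray:
        """Per-sample per-variant ancestry fractions (dosage / 2)."""
        return self.dosage / 2.0

    def hard_calls(self) -> np.ndarray:
        """Most probable ancestry index per sample and variant."""
        return np.argmax(self.dosage, axis=2)


@dataclass
class AncestryDeviation:
    """Region-level ancestry excess/deficiency against the genome mean."""

    labels: list[str]
    genome_mean: np.ndarray
    genome_sd: np.ndarray
    table: pd.DataFrame  # one row per region: delta per ancestry + flags


def build_ancestry_model(
    ancestral_panels: Mapping[str, GenotypePanel],
    alpha: Mapping[str, float],
    g: float = 83.0,
    recombination_rate: float = 1e-8,
) -> AncestryModel:
    """Ancestral allele frequencies with a 0.5 pseudocount per allele class.

    ``alpha`` is normalized to sum to 1. Panels must share the variant list;
    panels with fewer than five individuals trigger a warning.
    """
    labels = list(alpha)
    for lab in labels:
        if lab not in ancestral_panels:
            raise ValueError(f"missing ancestral panel for {lab!r}")
    ref = ancestral_panels[labels[0]]
    freqs = np.zeros((ref.n_variants, len(labels)))
    for k, lab in enumerate(labels):
        pan = ancestral_panels[lab]
        if not pan.variants[["chrom", "pos"]].equals(ref.variants[["chrom", "pos"]]):
            raise ValueError("ancestral panels must share the variant list")
        if pan.n_samples < 5:
            logger.warning("ancestral panel %s has only %d individuals", lab, pan.n_samples)
        g_mat = pan.genotypes
        called = g_mat != MISSING
        n_gene = 2 * called.sum(axis=1)
        alt = np.where(called, g_mat, 0).sum(axis=1)
        freqs[:, k] = (alt + 0.5) / (n_gene + 1.0)
    avec = np.array([alpha[lab] for lab in labels], dtype=float)
    avec = avec / avec.sum()
    return AncestryModel(
        labels=labels, frequencies=freqs, alpha=avec,
        variants=ref.variants.copy(), g=g, recombination_rate=recombination_rate,
    )


def _forward_backward(
    emissions: np.ndarray,  # (m, H, K)
    stay: np.ndarray,  # (m - 1,) probability of no ancestry switch
    alpha: np.ndarray,  # (K,)
) -> np.ndarray:
    """Vectorized forward-backward over H independent chains.

    The transition matrix is ``stay * I + (1 - stay) * 1 alpha^T``, so the
    matrix products collapse to a scalar mixture with the stationary draw.
    Returns posteriors of shape (m, H, K).
    """
    m, n_chains, k = emissions.shape
    fwd = np.empty((m, n_chains, k))
    scale = np.empty((m, n_chains))
    f = alpha[None, :] * emissions[0]
    scale[0] = f.sum(axis=1)
    fwd[0] = f / scale[0][:, None]
    for v in range(1, m):
        e = stay[v - 1]
        pred = e * fwd[v - 1] + (1 - e) * alpha[None, :]
        f = pred * emissions[v]
        scale[v] = f.sum(axis=1)
        fwd[v] = f / scale[v][:, None]
    bwd = np.ones((n_chains, k))
    post = np.empty_like(fwd)
    post[m - 1] = fwd[m - 1]
    for v in range(m - 2, -1, -1):
        e = stay[v]
        msg = emissions[v + 1] * bwd
        bwd = e * msg + (1 - e) * (msg @ alpha)[:, None]
        bwd /= bwd.max(axis=1, keepdims=True)
        p = fwd[v] * bwd
        post[v] = p / p.sum(axis=1, keepdims=True)
    return post


def local_ancestry(panel: GenotypePanel, model: AncestryModel) -> AncestryDosage:
    """Posterior ancestry dosages for an admixed panel.

    Phased panels run one chain per haplotype (emission = ancestral allele
    frequency of the observed allele). Unphased panels run one diploid
    chain per sample with binomial genotype emissions, an approximation
    that ties the two chromosomes to a common ancestry state. Variants
    absent from the model are skipped (count logged).
    """
    key_cols = ["chrom", "pos"]
    model_index = pd.MultiIndex.from_frame(model.variants[key_cols])
    panel_index = pd.MultiIndex.from_frame(panel.variants[key_cols])
    locator = model_index.get_indexer(panel_index)
    keep = locator >= 0
    skipped = int((~keep).sum())
    if skipped:
        logger.warning("%d panel variants absent from the ancestry model; skipped", skipped)
    vidx = np.flatnonzero(keep)
    fidx = locator[keep]
    freqs = model.frequencies[fidx]  # (m, K)
    variants = panel.variants.iloc[vidx].reset_index(drop=True)
    k = len(model.labels)
    n_samples = panel.n_samples
    dosage = np.zeros((n_samples, len(vidx), k))

    phased = panel.phased and panel.haplotypes is not None
    hap_post = np.zeros((2 * n_samples, len(vidx), k)) if phased else None
    for chrom, sub in variants.groupby("chrom", sort=False):
        rows = sub.index.to_numpy()
        pos = sub["pos"].to_numpy(dtype=float)
        stay = np.exp(-model.g * model.recombination_rate * np.diff(pos))
        f = freqs[rows]  # (m, K)
        if phased:
            hap = panel.haplotypes[np.ix_(vidx[rows], np.arange(2 * n_samples))]
            obs = hap.T.astype(float)  # (2N, m)
            emis = np.where(
                obs[:, :, None] == 1, f[None, :, :], 1.0 - f[None, :, :]
            )
            emis = np.where(obs[:, :, None] >= 0, emis, 1.0)
            post = _forward_backward(np.swapaxes(emis, 0, 1), stay, model.alpha)
            per_hap = np.swapaxes(post, 0, 1)  # (2N, m, K)
            hap_post[:, rows, :] = per_hap
            dosage[:, rows, :] = (
                per_hap.reshape(n_samples, 2, len(rows), k).sum(axis=1)
            )
        else:
            g_mat = panel.genotypes[vidx[rows]].T.astype(float)  # (N, m)
            p = f[None, :, :]
            emis = np.ones((n_samples, len(rows), k))
            emis = np.where(g_mat[:, :, None] == 0, (1 - p) ** 2, emis)
            emis = np.where(g_mat[:, :, None] == 1, 2 * p * (1 - p), emis)
            emis = np.where(g_mat[:, :, None] == 2, p**2, emis)
            post = _forward_backward(np.swapaxes(emis, 0, 1), stay, model.alpha)
            dosage[:, rows, :] = 2.0 * np.swapaxes(post, 0, 1)
    return AncestryDosage(
        labels=list(model.labels), samples=list(panel.samples),
        variants=variants, dosage=dosage, hap_posterior=hap_post,
    )


def global_proportions(
    dosages: AncestryDosage, breed_of: Mapping[str, str]
) -> pd.DataFrame:
    """Per-breed mean and SD of genome-wide ancestry fractions, plus an
    unweighted across-breed mean row labelled ``mean``.

    Per sample, the genome-wide ancestry fraction is the mean over variants
    of dosage / 2; breed rows average over the breed's samples and the mean
    row averages the breed means (and breed SDs) without weighting.
    """
    frac = dosages.fractions().mean(axis=1)  # (n_samples, K)
    df = pd.DataFrame(frac, index=dosages.samples, columns=dosages.labels)
    df["breed"] = [breed_of[s] for s in dosages.samples]
    means = df.groupby("breed", sort=False)[dosages.labels].mean()
    sds = df.groupby("breed", sort=False)[dosages.labels].std(ddof=0)
    out = pd.concat(
        {"mean": means, "sd": sds}, axis=1
    ).swaplevel(axis=1).sort_index(axis=1, level=0, sort_remaining=False)
    out = out.reindex(columns=pd.MultiIndex.from_product([dosages.labels, ["mean", "sd"]]))
    overall = out.mean(axis=0)
    out.loc["mean"] = overall
    return out


def region_deviation(
    dosages: AncestryDosage,
    regions: Sequence[CandidateRegion],
) -> AncestryDeviation:
    """Ancestry excess/deficiency at candidate regions.

    Per ancestry, the genome-wide distribution of per-SNP population-mean
    ancestry fractions supplies the mean and SD; a region's delta is the
    mean over its member significant SNPs minus the genome mean, flagged
    strong when |delta| exceeds two SDs. Deltas sum to zero per region.
    """
    per_snp = dosages.fractions().mean(axis=0)  # (n_variants, K)
    genome_mean = per_snp.mean(axis=0)
    genome_sd = per_snp.std(axis=0)
    key = pd.MultiIndex.from_frame(dosages.variants[["chrom", "pos"]])
    rows = []
    for reg in regions:
        member_idx = [
            key.get_loc((reg.chrom, p)) for p in reg.members
            if (reg.chrom, p) in key
        ]
        if not member_idx:
            raise ValueError(
                f"region {reg.chrom}:{reg.start}-{reg.end} has no member with dosages"
            )
        delta = per_snp[member_idx].mean(axis=0) - genome_mean
        row = {"region": f"{reg.chrom}:{reg.start}-{reg.end}", "cluster": reg.cluster}
        for k, lab in enumerate(dosages.labels):
            row[f"delta_{lab}"] = delta[k]
            row[f"strong_{lab}"] = bool(abs(delta[k]) > 2 * genome_sd[k])
        rows.append(row)
    return AncestryDeviation(
        labels=list(dosages.labels),
        genome_mean=genome_mean,
        genome_sd=genome_sd,
        table=pd.DataFrame(rows),
    )
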