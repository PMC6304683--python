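"""Synthetic data with known truth: coalescent scenario panels, admixed
genomes with recorded ancestry tracks, planted hard sweeps and array-like
SNP ascertainment.

Every stochastic operation is a pure function of its inputs and a seed.

The demographic scenarios are event-based configurations over five
populations: a persisting ``source`` population, a ``founder_lineage``
founded from it at ``t3``, an ``early_colony`` splitting off at ``t2`` and
two terminal colonies (``colony_a``, ``colony_b``) splitting at ``t1``.
Eight canonical scenario configurations combine this topology with optional
growth phases on the founder lineage and three migration patterns; they are
shipped as editable JSON under :mod:`demesweep.scenarios`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import msprime
import numpy as np
import pandas as pd

from .panel import GenotypePanel, PopulationMap

logger = logging.getLogger(__name__)

#: Default priors: name -> (scale, minimum, maximum). ``log10``-scaled
#: priors are uniform on the log10 of the value.
DEFAULT_PRIORS: dict[str, tuple[str, float, float]] = {
    "mutation_rate": ("log10", 1e-4, 0.05),
    "ne_recent": ("log10", 100, 500_000),
    "ne_mid": ("log10", 100, 500_000),
    "ne_founder": ("log10", 100, 5_000),
    "ne_source": ("log10", 100, 50_000),
    "ne_early_colony": ("log10", 10, 5_000),
    "ne_colony_a": ("log10", 10, 50_000),
    "ne_colony_b": ("log10", 10, 5_000),
    "t1": ("linear", 5, 150),
    "t2": ("linear", 20, 150),
    "t3": ("linear", 50, 150),
}

#: Prior used for migration rates when a scenario includes migration epochs.
MIGRATION_PRIOR: tuple[str, float, float] = ("log10", 1e-5, 1e-1)

PARAM_NAMES = list(DEFAULT_PRIORS) + ["mig_rate"]


@dataclass
class ScenarioParams:
    """One draw of the 11 sampled demographic parameters (+ optional
    migration rate). Times are in generations before present; effective
    sizes are diploid."""

    mutation_rate: float
    ne_recent: float
    ne_mid: float
    ne_founder: float
    ne_source: float
    ne_early_colony: float
    ne_colony_a: float
    ne_colony_b: float
    t1: float
    t2: float
    t3: float
    mig_rate: float | None = None

    def __post_init__(self) -> None:
        if not self.t1 < self.t2 < self.t3:
            raise ValueError("need t1 < t2 < t3")
        for name in (
            "ne_recent", "ne_mid", "ne_founder", "ne_source",
            "ne_early_colony", "ne_colony_a", "ne_colony_b",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def as_dict(self) -> dict[str, float]:
        d = {k: getattr(self, k) for k in PARAM_NAMES}
        if d["mig_rate"] is None:
            d.pop("mig_rate")
        return d


def sample_priors(
    prior_table: Mapping[str, tuple[str, float, float]] | None = None,
    n: int = 1,
    seed: int | None = None,
) -> list[ScenarioParams]:
    """Draw ``n`` parameter sets from the prior table.

    Draws violating ``t1 < t2 < t3`` are rejected and resampled. Raises if
    the time-ordering constraint is infeasible.
    """
    table = dict(prior_table) if prior_table is not None else dict(DEFAULT_PRIORS)
    for name, (scale, lo, hi) in table.items():
        if lo > hi:
            raise ValueError(f"prior for {name} has min > max")
    if table["t1"][1] >= table["t3"][2]:
        raise ValueError("empty feasible region: t1 min >= t3 max")
    rng = np.random.default_rng(seed)

    def draw_one() -> dict[str, float]:
        out = {}
        for name, (scale, lo, hi) in table.items():
            if scale == "log10":
                out[name] = 10 ** rng.uniform(np.log10(lo), np.log10(hi))
            elif scale == "linear":
                out[name] = rng.uniform(lo, hi)
            else:
                raise ValueError(f"unknown prior scale {scale!r}")
        return out

    draws: list[ScenarioParams] = []
    attempts = 0
    while len(draws) < n:
        attempts += 1
        if attempts > 1000 * n + 1000:
            raise ValueError("time-ordering constraint rejected too many draws")
        d = draw_one()
        if d["t1"] < d["t2"] < d["t3"]:
            draws.append(ScenarioParams(**d))
    return draws


# ---------------------------------------------------------------------------
# Scenario specifications
# ---------------------------------------------------------------------------


@dataclass
class ScenarioSpec:
    """Event-based demographic model.

    ``populations`` maps label -> initial size (a number or the name of a
    :class:`ScenarioParams` field). Events are dicts with a ``kind`` of
    ``split``, ``size_change``, ``growth_phase`` or ``migration_epoch``;
    times and sizes may likewise be symbolic parameter names. Sampled
    populations are those listed in ``sampled``.
    """

    name: str
    populations: dict[str, float | str]
    events: list[dict]
    sampled: list[str]
    generation_length_years: float = 5.0

    @classmethod
    def from_json(cls, path: str | Path) -> "ScenarioSpec":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)

    @classmethod
    def canonical(cls, name: str) -> "ScenarioSpec":
        """Load one of the eight shipped scenario configurations (sc1..sc8)."""
        ref = resources.files("demesweep").joinpath("scenarios", f"{name}.json")
        with resources.as_file(ref) as path:
            return cls.from_json(path)


def _resolve(value, params: ScenarioParams) -> float:
    if isinstance(value, str):
        out = getattr(params, value, None)
        if out is None:
            raise ValueError(f"scenario refers to undefined parameter {value!r}")
        return float(out)
    return float(value)


def build_demography(spec: ScenarioSpec, params: ScenarioParams) -> msprime.Demography:
    """Translate a scenario spec plus one parameter draw into an msprime
    Demography (backward in time)."""
    dem = msprime.Demography()
    for pop, size in spec.populations.items():
        dem.add_population(name=pop, initial_size=_resolve(size, params))
    for ev in spec.events:
        kind = ev["kind"]
        if kind == "split":
            dem.add_population_split(
                time=_resolve(ev["time"], params),
                derived=list(ev["derived"]),
                ancestral=ev["ancestral"],
            )
        elif kind == "size_change":
            dem.add_population_parameters_change(
                time=_resolve(ev["time"], params),
                population=ev["population"],
                initial_size=_resolve(ev["size"], params),
                growth_rate=0,
            )
        elif kind == "growth_phase":
            start = _resolve(ev["start"], params)  # recent end of the phase
            end = _resolve(ev["end"], params)  # older end
            size_start = _resolve(ev["size_start"], params)
            size_end = _resolve(ev["size_end"], params)
            if end <= start:
                raise ValueError("growth phase needs end > start")
            rate = np.log(size_start / size_end) / (end - start)
            dem.add_population_parameters_change(
                time=start, population=ev["population"],
                initial_size=size_start, growth_rate=rate,
            )
            dem.add_population_parameters_change(
                time=end, population=ev["population"],
                initial_size=size_end, growth_rate=0,
            )
        elif kind == "migration_epoch":
            # Forward-time migration from ev["from"] into each population of
            # ev["to"]: backward in time, lineages in the destination trace
            # back to the source.
            start = _resolve(ev["start"], params)
            end = _resolve(ev["end"], params)
            rate = _resolve(ev["rate"], params)
            for dest in ev["to"]:
                dem.add_migration_rate_change(
                    time=start, source=dest, dest=ev["from"], rate=rate
                )
                dem.add_migration_rate_change(
                    time=end, source=dest, dest=ev["from"], rate=0
                )
        else:
            raise ValueError(f"unknown event kind {kind!r}")
    dem.sort_events()
    return dem


# ---------------------------------------------------------------------------
# Coalescent simulation of unlinked array loci
# ---------------------------------------------------------------------------


def simulate_scenario(
    spec: ScenarioSpec,
    params: ScenarioParams,
    samples_per_population: Mapping[str, int],
    n_loci: int,
    seed: int | None = None,
    n_chromosomes: int = 29,
) -> tuple[GenotypePanel, PopulationMap]:
    """Simulate ``n_loci`` unlinked biallelic loci under a scenario.

    Each locus is an independent coalescent tree; mutations are applied at
    ``params.mutation_rate`` per locus per generation under a binary
    (0 <-> 1) model, so a locus can come back monomorphic at low rates.
    Haplotypes are returned phased. Loci are laid out on
    ``n_chromosomes`` pseudo-chromosomes at 1 Mb spacing.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    dem = build_demography(spec, params)
    samples = {p: int(samples_per_population[p]) for p in spec.sampled}
    rng = np.random.default_rng(seed)
    anc_seed, mut_seed = rng.integers(1, 2**31 - 1, size=2)
    n_hap = 2 * sum(samples.values())
    hap = np.zeros((n_loci, n_hap), dtype=np.int8)
    reps = msprime.sim_ancestry(
        samples=samples,
        demography=dem,
        sequence_length=1,
        discrete_genome=True,
        num_replicates=n_loci,
        random_seed=int(anc_seed),
        ploidy=2,
        record_provenance=False,
    )
    mut_model = msprime.BinaryMutationModel()
    mut_rate = msprime.RateMap(position=[0, 1], rate=[params.mutation_rate])
    for li, ts in enumerate(reps):
        mts = msprime.sim_mutations(
            ts,
            rate=mut_rate,
            model=mut_model,
            random_seed=int(mut_seed) + li,
            record_provenance=False,
        )
        if mts.num_sites:
            hap[li] = mts.genotype_matrix()[0]

    per_chrom = int(np.ceil(n_loci / n_chromosomes))
    chroms = [str(1 + li // per_chrom) for li in range(n_loci)]
    pos = [1_000_000 * (1 + li % per_chrom) for li in range(n_loci)]
    variants = pd.DataFrame({"chrom": chroms, "pos": pos, "ref": "A", "alt": "B"})

    sample_ids, pops = [], []
    for pop, n in samples.items():
        sample_ids += [f"{pop}_{i}" for i in range(n)]
        pops += [pop] * n
    genotypes = hap[:, 0::2] + hap[:, 1::2]
    panel = GenotypePanel(
        variants=variants,
        samples=sample_ids,
        genotypes=genotypes,
        haplotypes=hap,
        phased=True,
    )
    roles = ["reference" if p == "source" else "focal" for p in pops]
    popmap = PopulationMap(
        assignments=pd.DataFrame(
            {"sample_id": sample_ids, "population": pops, "role": roles}
        )
    )
    return panel, popmap


def simulate_recombining_panel(
    demography: msprime.Demography | None = None,
    ne: float | None = None,
    samples: Mapping[str, int] | int = 20,
    n_chromosomes: int = 5,
    chrom_length: float = 5e6,
    mutation_rate: float = 1e-8,
    recombination_rate: float = 1e-8,
    seed: int | None = None,
) -> tuple[GenotypePanel, PopulationMap]:
    """Simulate a phased multi-chromosome SNP panel with recombination.

    Convenience generator for the LD, sweep-scan and ancestry stages (the
    unlinked-locus generator above serves the ABC stage). Either a full
    ``demography`` or a single-population ``ne`` must be given.
    """
    if demography is None:
        if ne is None:
            raise ValueError("give a demography or an Ne")
        demography = msprime.Demography()
        demography.add_population(name="pop0", initial_size=ne)
    if isinstance(samples, int):
        samples = {demography.populations[0].name: samples}
    rng = np.random.default_rng(seed)
    seeds = rng.integers(1, 2**31 - 1, size=(n_chromosomes, 2))
    var_frames, hap_blocks = [], []
    sample_ids: list[str] | None = None
    pops: list[str] | None = None
    for ci in range(n_chromosomes):
        ts = msprime.sim_ancestry(
            samples=samples,
            demography=demography,
            sequence_length=chrom_length,
            recombination_rate=recombination_rate,
            random_seed=int(seeds[ci, 0]),
            ploidy=2,
        )
        mts = msprime.sim_mutations(
            ts,
            rate=mutation_rate,
            model=msprime.BinaryMutationModel(),
            random_seed=int(seeds[ci, 1]),
        )
        g = mts.genotype_matrix()
        positions = np.array([int(s.position) + 1 for s in mts.sites()])
        # keep strictly increasing integer coordinates
        keep = np.concatenate([[True], np.diff(positions) > 0])
        g, positions = g[keep], positions[keep]
        poly = (g.sum(axis=1) > 0) & (g.sum(axis=1) < g.shape[1])
        g, positions = g[poly], positions[poly]
        var_frames.append(
            pd.DataFrame(
                {"chrom": str(ci + 1), "pos": positions, "ref": "A", "alt": "B"}
            )
        )
        hap_blocks.append(g.astype(np.int8))
        if sample_ids is None:
            sample_ids, pops = [], []
            for pop, n in samples.items():
                sample_ids += [f"{pop}_{i}" for i in range(n)]
                pops += [pop] * n
    variants = pd.concat(var_frames, ignore_index=True)
    hap = np.vstack(hap_blocks)
    panel = GenotypePanel(
        variants=variants,
        samples=sample_ids,
        genotypes=hap[:, 0::2] + hap[:, 1::2],
        haplotypes=hap,
        phased=True,
    )
    roles = ["focal"] * len(pops)
    popmap = PopulationMap(
        assignments=pd.DataFrame(
            {"sample_id": sample_ids, "population": pops, "role": roles}
        )
    )
    return panel, popmap


# ---------------------------------------------------------------------------
# Admixture with recorded truth
# ---------------------------------------------------------------------------


@dataclass
class AdmixtureTruth:
    """True ancestry tracks of a simulated admixed panel.

    ``tracks[h]`` lists ``(chrom, start_bp, end_bp, ancestry)`` tuples that
    tile each chromosome of haplotype ``h`` without overlap (1-based
    inclusive coordinates).
    """

    tracks: list[list[tuple[str, int, int, str]]]
    generations: float
    proportions: dict[str, float]

    def ancestry_fraction(self, label: str) -> float:
        """Genome-wide length-weighted fraction of one ancestry."""
        total = covered = 0
        for hap_tracks in self.tracks:
            for chrom, start, end, anc in hap_tracks:
                length = end - start + 1
                total += length
                if anc == label:
                    covered += length
        return covered / total if total else 0.0


def generate_admixed(
    ancestral_panels: Mapping[str, GenotypePanel],
    proportions: Mapping[str, float],
    g: float,
    recombination_rate: float,
    n_samples: int,
    seed: int | None = None,
) -> tuple[GenotypePanel, AdmixtureTruth]:
    """Build admixed diploid genomes by copying ancestral haplotype tracks.

    Track boundaries follow a Poisson breakpoint process of rate
    ``g * recombination_rate`` per bp (exponential track lengths with mean
    ``1 / (g r)``); each track's ancestry is drawn independently from
    ``proportions`` and its alleles copied from a random donor haplotype of
    that ancestry.
    """
    labels = list(proportions)
    props = np.array([proportions[k] for k in labels], dtype=float)
    if not np.isclose(props.sum(), 1.0):
        raise ValueError("proportions must sum to 1")
    ref = next(iter(ancestral_panels.values()))
    for lab in labels:
        if lab not in ancestral_panels:
            raise ValueError(f"no ancestral panel for {lab!r}")
        pan = ancestral_panels[lab]
        if pan.haplotypes is None:
            raise ValueError(f"ancestral panel {lab!r} must be phased")
        if not pan.variants[["chrom", "pos"]].equals(ref.variants[["chrom", "pos"]]):
            raise ValueError("ancestral panels must share the variant list")

    rng = np.random.default_rng(seed)
    n_hap = 2 * n_samples
    m = ref.n_variants
    hap = np.zeros((m, n_hap), dtype=np.int8)
    tracks: list[list[tuple[str, int, int, str]]] = [[] for _ in range(n_hap)]

    chrom_groups = [
        (chrom, sub.index.to_numpy(), sub["pos"].to_numpy())
        for chrom, sub in ref.variants.groupby("chrom", sort=False)
    ]
    rate = g * recombination_rate
    for h in range(n_hap):
        for chrom, vidx, pos in chrom_groups:
            length = int(pos[-1])
            n_breaks = rng.poisson(rate * max(length - 1, 0))
            breaks = np.sort(rng.integers(1, length, size=n_breaks)) if n_breaks else np.array([], dtype=int)
            starts = np.concatenate([[1], breaks + 1])
            ends = np.concatenate([breaks, [length]])
            anc_idx = rng.choice(len(labels), size=len(starts), p=props)
            for s, e, ai in zip(starts, ends, anc_idx):
                if s > e:
                    continue
                lab = labels[ai]
                pan = ancestral_panels[lab]
                donor = rng.integers(0, pan.haplotypes.shape[1])
                sel = vidx[(pos >= s) & (pos <= e)]
                hap[sel, h] = pan.haplotypes[sel, donor]
                # one record per copied segment (adjacent same-ancestry
                # segments stay separate: they may use different donors)
                tracks[h].append((chrom, int(s), int(e), lab))

    samples = [f"adm_{i}" for i in range(n_samples)]
    panel = GenotypePanel(
        variants=ref.variants.copy(),
        samples=samples,
        genotypes=hap[:, 0::2] + hap[:, 1::2],
        haplotypes=hap,
        phased=True,
    )
    truth = AdmixtureTruth(
        tracks=tracks, generations=g, proportions={k: float(proportions[k]) for k in labels}
    )
    return panel, truth


# ---------------------------------------------------------------------------
# Planted sweeps and ascertainment
# ---------------------------------------------------------------------------


def plant_sweep(
    panel: GenotypePanel,
    sample_ids: Sequence[str],
    core_index: int,
    carrier_fraction: float,
    decay_length: float,
    seed: int | None = None,
) -> GenotypePanel:
    """Overwrite a fraction of a population's haplotypes with a shared donor
    haplotype around a core variant.

    Each carrier copies the donor over an interval around the core whose
    per-side extent is exponential with mean ``decay_length`` bp. Other
    samples are untouched; ``carrier_fraction`` 0 returns the panel as is.
    """
    if not 0 <= carrier_fraction <= 1:
        raise ValueError("carrier fraction must lie in [0, 1]")
    if panel.haplotypes is None:
        raise ValueError("plant_sweep needs a phased panel")
    if carrier_fraction == 0:
        return panel
    rng = np.random.default_rng(seed)
    sidx = panel.sample_indices(sample_ids)
    hap_cols = np.column_stack([2 * sidx, 2 * sidx + 1]).ravel()
    n_carriers = int(np.ceil(carrier_fraction * len(hap_cols)))
    donor = int(rng.choice(hap_cols))
    carriers = rng.choice(hap_cols, size=n_carriers, replace=False)

    chrom = panel.variants.loc[core_index, "chrom"]
    core_pos = int(panel.variants.loc[core_index, "pos"])
    on_chrom = panel.variants["chrom"] == chrom
    pos = panel.variants.loc[on_chrom, "pos"].to_numpy()
    vidx = panel.variants.index[on_chrom].to_numpy()

    hap = panel.haplotypes.copy()
    donor_alleles = panel.haplotypes[:, donor]
    for h in carriers:
        left = rng.exponential(decay_length)
        right = rng.exponential(decay_length)
        sel = vidx[(pos >= core_pos - left) & (pos <= core_pos + right)]
        hap[sel, h] = donor_alleles[sel]
    return GenotypePanel(
        variants=panel.variants.copy(),
        samples=list(panel.samples),
        genotypes=hap[:, 0::2] + hap[:, 1::2],
        haplotypes=hap,
        phased=panel.phased,
    )


def ascertain_snps(
    panel: GenotypePanel,
    maf_min: float,
    n_target: int,
    seed: int | None = None,
) -> GenotypePanel:
    """Array-like ascertainment: uniform subsample of variants above
    ``maf_min``, preserving coordinate order."""
    eligible = np.flatnonzero(panel.maf() > maf_min)
    if n_target >= eligible.size:
        if n_target > eligible.size:
            logger.warning(
                "requested %d variants but only %d pass MAF %g; keeping all",
                n_target, eligible.size, maf_min,
            )
        return panel.take_variants(eligible)
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(eligible, size=n_target, replace=False))
    return panel.take_variants(chosen)
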