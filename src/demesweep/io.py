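"""Readers and writers for panels: VCF, PLINK text, population maps, PHYLIP.

All deliverable formats are plain text. VCF reading goes through cyvcf2;
writing emits a minimal VCF 4.2 with a GT field ("|" separators when the
panel is phased). The PLINK text dialect is the classic .ped/.map pair with
one allele pair per SNP; on load, the major allele becomes REF and the minor
allele ALT (ties broken lexicographically), so dosages count minor alleles.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel, PopulationMap

logger = logging.getLogger(__name__)


def _chrom_sort_key(chrom: str):
    try:
        return (0, int(chrom), "")
    except ValueError:
        return (1, 0, chrom)


def _sort_variants(
    variants: pd.DataFrame, genotypes: np.ndarray, haplotypes: np.ndarray | None
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray | None]:
    keys = [(_chrom_sort_key(c), p) for c, p in zip(variants["chrom"], variants["pos"])]
    order = np.array(sorted(range(len(keys)), key=keys.__getitem__))
    if not np.array_equal(order, np.arange(len(keys))):
        logger.warning("input variants were not coordinate-sorted; sorting")
    return (
        variants.iloc[order].reset_index(drop=True),
        genotypes[order],
        None if haplotypes is None else haplotypes[order],
    )


# ---------------------------------------------------------------------------
# Population map
# ---------------------------------------------------------------------------


def read_popmap(path: str | Path) -> PopulationMap:
    """Read a TSV with columns sample_id, population, role (header optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:3]) != ["sample_id", "population", "role"]:
        df = pd.read_csv(
            path, sep="\t", header=None, names=["sample_id", "population", "role"],
            dtype=str,
        )
    return PopulationMap(assignments=df[["sample_id", "population", "role"]])


def write_popmap(popmap: PopulationMap, path: str | Path) -> None:
    popmap.assignments.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def _read_vcf(path: str | Path) -> GenotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    geno_rows = []
    hap_rows = []
    all_phased = True
    for v in vcf:
        alts = v.ALT
        if len(alts) != 1:
            raise ValueError(f"non-biallelic record at {v.CHROM}:{v.POS}")
        rows.append((str(v.CHROM), int(v.POS), v.REF, alts[0]))
        g = np.full(len(samples), MISSING, dtype=np.int8)
        h = np.full(2 * len(samples), MISSING, dtype=np.int8)
        for i, call in enumerate(v.genotypes):  # [a0, a1, phased]
            a0, a1, phased = call[0], call[1], bool(call[-1])
            if a0 >= 0 and a1 >= 0:
                g[i] = a0 + a1
                h[2 * i] = a0
                h[2 * i + 1] = a1
                if not phased:
                    all_phased = False
            else:
                all_phased = False
        geno_rows.append(g)
        hap_rows.append(h)
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    genotypes = np.array(geno_rows, dtype=np.int8).reshape(len(rows), len(samples))
    haplotypes = np.array(hap_rows, dtype=np.int8).reshape(len(rows), 2 * len(samples))
    variants, genotypes, haplotypes = _sort_variants(variants, genotypes, haplotypes)
    if not all_phased:
        haplotypes = None
    return GenotypePanel(
        variants=variants,
        samples=samples,
        genotypes=genotypes,
        haplotypes=haplotypes,
        phased=all_phased,
    )


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Write a minimal uncompressed VCF 4.2 with GT calls."""
    sep = "|" if panel.phased else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(panel.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples)
            + "\n"
        )
        for vi, row in panel.variants.iterrows():
            fields = [
                str(row.chrom), str(row.pos), ".", str(row.ref), str(row.alt),
                ".", ".", ".", "GT",
            ]
            for si in range(panel.n_samples):
                if panel.haplotypes is not None:
                    a0 = panel.haplotypes[vi, 2 * si]
                    a1 = panel.haplotypes[vi, 2 * si + 1]
                    if a0 == MISSING or a1 == MISSING:
                        fields.append(f".{sep}.")
                    else:
                        fields.append(f"{a0}{sep}{a1}")
                else:
                    g = panel.genotypes[vi, si]
                    if g == MISSING:
                        fields.append("./.")
                    else:
                        fields.append({0: "0/0", 1: "0/1", 2: "1/1"}[int(g)])
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# PLINK text (.ped/.map)
# ---------------------------------------------------------------------------


def _read_plink(prefix: str | Path) -> GenotypePanel:
    prefix = str(prefix)
    if prefix.endswith(".ped") or prefix.endswith(".map"):
        prefix = prefix[:-4]
    mapdf = pd.read_csv(
        f"{prefix}.map", sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos"], dtype={"chrom": str},
    )
    m = len(mapdf)
    samples: list[str] = []
    allele_rows: list[list[str]] = []
    with open(f"{prefix}.ped") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"ped line for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts) - 6} allele fields, expected {2 * m}"
                )
            samples.append(parts[1])
            allele_rows.append(parts[6:])
    alleles = np.array(allele_rows, dtype=object).T  # (2m, n)
    genotypes = np.full((m, len(samples)), MISSING, dtype=np.int8)
    refs, alts = [], []
    for vi in range(m):
        a = alleles[2 * vi]
        b = alleles[2 * vi + 1]
        pair = np.stack([a, b])
        obs = pair[(pair != "0") & (pair != ".")]
        uniq, counts = np.unique(obs, return_counts=True)
        if len(uniq) == 0:
            refs.append("A")
            alts.append("B")
            continue
        order = np.lexsort((uniq, -counts))  # major first, ties lexicographic
        ref = uniq[order[0]]
        alt = uniq[order[1]] if len(uniq) > 1 else ("B" if ref != "B" else "A")
        refs.append(ref)
        alts.append(alt)
        called = (a != "0") & (b != "0") & (a != ".") & (b != ".")
        genotypes[vi, called] = (
            (a[called] == alt).astype(np.int8) + (b[called] == alt).astype(np.int8)
        )
    variants = pd.DataFrame(
        {"chrom": mapdf["chrom"], "pos": mapdf["pos"].astype(int),
         "ref": refs, "alt": alts}
    )
    variants, genotypes, _ = _sort_variants(variants, genotypes, None)
    return GenotypePanel(
        variants=variants, samples=samples, genotypes=genotypes, phased=False
    )


def write_plink(panel: GenotypePanel, prefix: str | Path) -> None:
    prefix = str(prefix)
    with open(f"{prefix}.map", "w") as fh:
        for _, row in panel.variants.iterrows():
            fh.write(f"{row.chrom}\tsnp_{row.chrom}_{row.pos}\t0\t{row.pos}\n")
    ref = panel.variants["ref"].to_numpy()
    alt = panel.variants["alt"].to_numpy()
    with open(f"{prefix}.ped", "w") as fh:
        for si, sample in enumerate(panel.samples):
            fields = [sample, sample, "0", "0", "0", "-9"]
            for vi in range(panel.n_variants):
                g = panel.genotypes[vi, si]
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [ref[vi], ref[vi]]
                elif g == 1:
                    fields += [ref[vi], alt[vi]]
                else:
                    fields += [alt[vi], alt[vi]]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Entry point
# ---------------------------------------------------------------------------


def load_panel(
    path: str | Path,
    format: Literal["vcf", "plink_text"],
    popmap_path: str | Path,
) -> tuple[GenotypePanel, PopulationMap]:
    """Load a genotype panel plus its population map.

    Variants are coordinate-sorted on load; missing genotypes are preserved.
    Every panel sample must appear in the population map.
    """
    if format == "vcf":
        panel = _read_vcf(path)
    elif format == "plink_text":
        panel = _read_plink(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    popmap = read_popmap(popmap_path)
    popmap.check_covers(panel)
    return panel, popmap


def write_phylip(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a square distance matrix in PHYLIP format."""
    with open(path, "w") as fh:
        fh.write(f"{len(matrix)}\n")
        for name, row in matrix.iterrows():
            label = f"{str(name)[:10]:<10}"
            fh.write(label + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")
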