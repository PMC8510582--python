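"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as uncompressed VCF with phased GT fields (read back via
cyvcf2, which validates the format); case/control labels as a two-column
TSV; genetic maps as tab-delimited chrom/bp/cM with a header; score files
as whitespace-delimited variant-id / effect-allele / weight without a
header, PLINK-score style.
"""

from __future__ import annotations

import os
from typing import Dict, List

import numpy as np
import pandas as pd

from .cohort import PhasedCohort, VARIANT_COLUMNS
from .gmap import GeneticMap
from .scoring import ScoreModel


def write_vcf(cohort: PhasedCohort, path: str) -> None:
    chroms = list(dict.fromkeys(cohort.variants["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=embryoscreen-synthetic\n")
        for chrom, grp in cohort.variants.groupby("chrom", sort=False):
            fh.write(
                f"##contig=<ID={chrom},length={int(grp['pos'].max()) + 1_000_000}>\n"
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.samples)
            + "\n"
        )
        hap = cohort.haplotypes
        for vi, row in enumerate(cohort.variants.itertuples(index=False)):
            gts = "\t".join(
                f"{hap[si, 0, vi]}|{hap[si, 1, vi]}" for si in range(cohort.n_samples)
            )
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )
    _ = chroms


def write_status_tsv(cohort: PhasedCohort, path: str) -> None:
    pd.DataFrame(
        {
            "sample": cohort.samples,
            "status": np.where(cohort.is_case, "case", "control"),
        }
    ).to_csv(path, sep="\t", index=False)


def read_cohort(vcf_path: str, status_path: str) -> PhasedCohort:
    """Load a phased cohort from a VCF plus a sample-status TSV.

    Every genotype must be phased and biallelic; unphased calls raise.
    """
    from cyvcf2 import VCF

    vcf = VCF(vcf_path)
    samples: List[str] = list(vcf.samples)
    records = []
    hap_cols = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"variant {var.ID} is not biallelic")
        gts = np.asarray(var.genotypes)  # (n_samples, 3): a0, a1, phased
        if not np.all(gts[:, 2]):
            raise ValueError(f"unphased genotype at {var.ID}")
        if gts[:, :2].min() < 0:
            raise ValueError(f"missing genotype at {var.ID}")
        records.append((var.CHROM, var.POS, var.ID, var.REF, var.ALT[0]))
        hap_cols.append(gts[:, :2].astype(np.uint8))
    variants = pd.DataFrame(records, columns=VARIANT_COLUMNS)
    haplotypes = np.stack(hap_cols, axis=2)  # (n_samples, 2, n_variants)

    status = pd.read_csv(status_path, sep="\t")
    status_of = dict(zip(status["sample"], status["status"]))
    missing = [s for s in samples if s not in status_of]
    if missing:
        raise ValueError(f"samples missing from status file: {missing[:5]}")
    is_case = np.array([status_of[s] == "case" for s in samples])
    return PhasedCohort(samples, is_case, variants, haplotypes)


def write_genetic_map(gmap: GeneticMap, path: str) -> None:
    rows = []
    for chrom, (bp, cm) in gmap.tables.items():
        for b, c in zip(bp, cm):
            rows.append((chrom, int(b), float(c)))
    pd.DataFrame(rows, columns=["chrom", "bp", "cM"]).to_csv(
        path, sep="\t", index=False
    )


def read_genetic_map(path: str) -> GeneticMap:
    df = pd.read_csv(path, sep="\t")
    expected = {"chrom", "bp", "cM"}
    if set(df.columns) != expected:
        raise ValueError(f"genetic map must have columns {sorted(expected)}")
    tables: Dict[str, tuple] = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        tables[chrom] = (grp["bp"].to_numpy(float), grp["cM"].to_numpy(float))
    return GeneticMap(tables)


def write_score_file(model: ScoreModel, path: str) -> None:
    model.table[["id", "effect_allele", "weight"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_score_file(path: str) -> ScoreModel:
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["id", "effect_allele", "weight"],
        dtype={"id": str, "effect_allele": str},
    )
    df["weight"] = df["weight"].astype(float)
    return ScoreModel(df)


def write_cohort_bundle(
    cohort: PhasedCohort,
    gmap: GeneticMap,
    model: ScoreModel,
    outdir: str,
    prefix: str = "cohort",
) -> Dict[str, str]:
    """Write the VCF/status/map/score quartet; returns the path map."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "vcf": os.path.join(outdir, f"{prefix}.vcf"),
        "status": os.path.join(outdir, f"{prefix}.status.tsv"),
        "map": os.path.join(outdir, f"{prefix}.map.tsv"),
        "score": os.path.join(outdir, f"{prefix}.score.txt"),
    }
    write_vcf(cohort, paths["vcf"])
    write_status_tsv(cohort, paths["status"])
    write_genetic_map(gmap, paths["map"])
    write_score_file(model, paths["score"])
    return paths
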