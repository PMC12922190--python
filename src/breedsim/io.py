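"""Export of simulated data to standard text formats.

Genotypes go out as a phased diploid VCF, pedigrees as 3-column TSV
(id, sire, dam with 0 = unknown), the genetic map as 4-column TSV,
kinship matrices as square CSV and mating plans as TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeSpec, Pedigree, Population
from .evaluation import KinshipMatrix
from .mating import MatingPlan

__all__ = [
    "export_vcf", "export_pedigree", "export_map", "export_kinship_csv",
    "export_matings", "write_manifest",
]

# bp placeholder: 1 cM == 1 Mb, positions 1-based
_BP_PER_MORGAN = 100_000_000


def export_vcf(pop: Population, genome: GenomeSpec, path: str | Path) -> None:
    """Write phased diploid genotypes of one cohort as an uncompressed VCF."""
    path = Path(path)
    sample_names = [f"ind{int(i)}" for i in pop.ids]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=breedsim\n")
        for c in range(genome.n_chr):
            fh.write(f"##contig=<ID=chr{c + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_names) + "\n")
        h0 = pop.haplo[:, 0, :]
        h1 = pop.haplo[:, 1, :]
        for j in range(genome.n_snp):
            chrom = int(genome.chr_index[j]) + 1
            bp = int(round(genome.map_pos[j] * _BP_PER_MORGAN)) + 1
            gts = "\t".join(f"{a}|{b}" for a, b in zip(h0[:, j], h1[:, j]))
            fh.write(f"chr{chrom}\t{bp}\tsnp{j}\tA\tB\t.\tPASS\t.\tGT\t{gts}\n")


def export_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    """3-column TSV: id, sire, dam; 0 denotes an unknown (founder) parent.
    Ids are shifted to 1-based so 0 stays free for 'unknown'."""
    df = pd.DataFrame({
        "id": np.arange(len(pedigree)) + 1,
        "sire": np.where(pedigree.sire < 0, 0, pedigree.sire + 1),
        "dam": np.where(pedigree.dam < 0, 0, pedigree.dam + 1),
    })
    df.to_csv(path, sep="\t", index=False)


def export_map(genome: GenomeSpec, path: str | Path) -> None:
    """4-column TSV: chromosome, SNP id, position in cM, bp placeholder."""
    df = pd.DataFrame({
        "chr": genome.chr_index + 1,
        "snp_id": [f"snp{j}" for j in range(genome.n_snp)],
        "cM": genome.map_pos * 100.0,
        "bp": (genome.map_pos * _BP_PER_MORGAN).round().astype(np.int64) + 1,
    })
    df.to_csv(path, sep="\t", index=False)


def export_kinship_csv(kinship: KinshipMatrix, path: str | Path) -> None:
    """Square CSV with the individual ids as header row and column."""
    ids = (kinship.ids if kinship.ids is not None
           else np.arange(kinship.values.shape[0]))
    df = pd.DataFrame(kinship.values, index=ids, columns=ids)
    df.to_csv(path, index_label="id")


def export_matings(plan: MatingPlan, path: str | Path) -> None:
    """TSV: offspring row number, sire id, dam id."""
    df = pd.DataFrame({
        "offspring": np.arange(plan.pairs.shape[0]),
        "sire_id": plan.pairs[:, 0],
        "dam_id": plan.pairs[:, 1],
    })
    df.to_csv(path, sep="\t", index=False)


def write_manifest(path: str | Path, config_dict: dict, seeds: list[int]) -> None:
    """Run manifest: configuration, seeds and package version."""
    from . import __version__
    payload = {"config": config_dict, "seeds": seeds, "version": __version__}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
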