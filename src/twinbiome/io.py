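"""File formats: VCF v4.2 with phased genotypes, metadata TSV, square
distance-matrix TSV (QIIME 1 dialect), and Newick trees."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .genotypes import PhasedGenotypes


# ---------------------------------------------------------------------------
# VCF

def write_vcf(geno: PhasedGenotypes, path: str | Path) -> None:
    """Write phased genotypes as an uncompressed VCF v4.2 (GT only, '|')."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        for c in sorted(set(geno.chrom.astype(str))):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.samples) + "\n")
        order = np.lexsort((geno.pos, geno.chrom.astype(str)))
        for j in order:
            gts = "\t".join(
                f"{geno.haplotypes[i, j, 0]}|{geno.haplotypes[i, j, 1]}"
                for i in range(len(geno.samples)))
            fh.write(f"{geno.chrom[j]}\t{geno.pos[j]}\t{geno.snp_ids[j]}\t"
                     f"{geno.ref[j]}\t{geno.alt[j]}\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path: str | Path) -> PhasedGenotypes:
    """Read a VCF v4.2 with phased GT calls into a PhasedGenotypes."""
    import cyvcf2

    vcf = cyvcf2.VCF(str(path))
    samples = list(vcf.samples)
    snp_ids, chrom, pos, ref, alt, haps = [], [], [], [], [], []
    for v in vcf:
        snp_ids.append(v.ID)
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0] if v.ALT else ".")
        g = np.array(v.genotypes)  # (n, 3): a1, a2, phased flag
        if not np.all(g[:, 2]):
            raise ValueError(f"unphased genotype at {v.ID}")
        haps.append(g[:, :2])
    hap = np.stack(haps, axis=1).astype(np.int8)  # (n, s, 2)
    return PhasedGenotypes(samples, np.array(snp_ids), np.array(chrom),
                           np.array(pos), np.array(ref), np.array(alt), hap)


# ---------------------------------------------------------------------------
# tables

def write_metadata(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id",
                       dtype={"family_id": str})


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    df = dm.to_data_frame()
    df.to_csv(path, sep="\t", index_label="")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.values, ids=[str(i) for i in df.index])


# ---------------------------------------------------------------------------
# trees

def write_tree(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_tree(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
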