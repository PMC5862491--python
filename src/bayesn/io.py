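"""Readers/writers for the standard formats shared by all subcommands.

PLINK .bed/.bim/.fam (SNP-major .bed, 2 bits per genotype) is encoded and
decoded here directly; missing genotype codes are a hard error because the
simulated data never contains them. Phased haplotypes come from VCF (via
cyvcf2, phased GT required) or from a plain-text TSV dialect with two
gamete rows per individual — the text-only fixture format of this package.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenotypeMatrix, HaplotypePanel, MarkerMap, PanelSummary

__all__ = [
    "write_plink",
    "read_plink",
    "read_vcf_haplotypes",
    "write_haplotype_tsv",
    "read_haplotype_tsv",
    "write_phenotypes",
    "read_phenotypes",
    "write_effects",
    "read_effects",
    "write_windows_table",
    "write_panel_summary",
    "write_replicate",
]

_BED_MAGIC = b"\x6c\x1b\x01"
# 2-bit codes, SNP-major: value = count of the A1 allele
_CODE_OF_SCORE = {2: 0b00, 1: 0b10, 0: 0b11}
_SCORE_OF_CODE = {0b00: 2, 0b10: 1, 0b11: 0}


def write_plink(prefix, Z: GenotypeMatrix, sample_ids=None) -> None:
    """Write raw 0/1/2 genotypes + map as PLINK bed/bim/fam."""
    prefix = Path(prefix)
    if Z.centered:
        raise ValueError("write raw (uncentered) genotypes to PLINK")
    if Z.map is None:
        raise ValueError("a marker map is required to write .bim")
    scores = np.asarray(np.rint(Z.scores), dtype=np.int64)
    if np.any((scores < 0) | (scores > 2)):
        raise ValueError("PLINK output needs integer scores in {0,1,2}")
    n, m = scores.shape
    if sample_ids is None:
        sample_ids = [f"ind_{i}" for i in range(n)]
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        nbytes = (n + 3) // 4
        buf = np.zeros((m, nbytes), dtype=np.uint8)
        for j in range(m):
            col = scores[:, j]
            for i in range(n):
                code = _CODE_OF_SCORE[int(col[i])]
                buf[j, i // 4] |= code << (2 * (i % 4))
        fh.write(buf.tobytes())
    bim = pd.DataFrame(
        {
            "chrom": Z.map.chrom,
            "id": Z.map.snp_id,
            "cm": 0.0,
            "bp": Z.map.pos_bp,
            "a1": "A",
            "a2": "B",
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": sample_ids,
            "iid": sample_ids,
            "pat": 0,
            "mat": 0,
            "sex": 0,
            "phen": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


def read_plink(prefix):
    """Read bed/bim/fam; returns (GenotypeMatrix, sample_ids)."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "bp", "a1", "a2"],
    )
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None)
    n = len(fam)
    m = len(bim)
    mp = MarkerMap(
        bim["id"].to_numpy(dtype=object),
        bim["chrom"].to_numpy(),
        bim["bp"].to_numpy(),
    )
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed is not a SNP-major PLINK bed file")
    nbytes = (n + 3) // 4
    body = raw[3:].reshape(m, nbytes)
    scores = np.empty((n, m), dtype=np.float64)
    for j in range(m):
        for i in range(n):
            code = (body[j, i // 4] >> (2 * (i % 4))) & 0b11
            if code == 0b01:
                raise ValueError(
                    f"missing genotype at SNP {bim['id'][j]}, sample {i}: "
                    "missing data are not supported"
                )
            scores[i, j] = _SCORE_OF_CODE[code]
    return GenotypeMatrix(scores, map=mp), fam[1].astype(str).tolist()


def read_vcf_haplotypes(path) -> HaplotypePanel:
    """Phased GT (e.g. 0|1) from a VCF; unphased records are an error."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    chroms, poss, ids, cols = [], [], [], []
    for var in vcf:
        ph = var.genotype.array()
        if np.any(ph[:, 2] == 0):
            raise ValueError(f"unphased genotype at {var.CHROM}:{var.POS}")
        chroms.append(int(var.CHROM.lstrip("chr") or 0))
        poss.append(var.POS - 1)  # VCF is 1-based; the map is 0-based
        ids.append(var.ID or f"snp_{var.CHROM}_{var.POS}")
        cols.append(ph[:, :2].reshape(-1))
    alleles = np.array(cols, dtype=np.int8).T
    mp = MarkerMap(np.array(ids, dtype=object), np.array(chroms), np.array(poss))
    return HaplotypePanel(alleles, mp)


def write_haplotype_tsv(path, panel: HaplotypePanel, sample_ids=None) -> None:
    """Two gamete rows per individual; columns are SNPs (map in the header)."""
    n = panel.n_individuals
    if sample_ids is None:
        sample_ids = [f"ind_{i}" for i in range(n)]
    with open(path, "w") as fh:
        fh.write("#chrom\t" + "\t".join(map(str, panel.map.chrom)) + "\n")
        fh.write("#pos_bp\t" + "\t".join(map(str, panel.map.pos_bp)) + "\n")
        fh.write("#snp_id\t" + "\t".join(map(str, panel.map.snp_id)) + "\n")
        for i in range(n):
            for g in range(2):
                row = panel.alleles[2 * i + g]
                fh.write(
                    f"{sample_ids[i]}.{g}\t" + "\t".join(map(str, row)) + "\n"
                )


def read_haplotype_tsv(path) -> HaplotypePanel:
    with open(path) as fh:
        chrom = np.array(fh.readline().rstrip("\n").split("\t")[1:], dtype=np.int64)
        pos = np.array(fh.readline().rstrip("\n").split("\t")[1:], dtype=np.int64)
        ids = np.array(fh.readline().rstrip("\n").split("\t")[1:], dtype=object)
        rows = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rows.append(np.array(parts[1:], dtype=np.int8))
    return HaplotypePanel(np.array(rows), MarkerMap(ids, chrom, pos))


def write_phenotypes(path, ids, y, tbv=None) -> None:
    df = pd.DataFrame({"id": ids, "y": y})
    if tbv is not None:
        df["tbv"] = tbv
    df.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_effects(path, summary, column_means=None) -> None:
    """Posterior-mean effects + inclusion probabilities (+ centering means)."""
    ids = (
        summary.snp_id
        if summary.snp_id is not None
        else [f"snp{j}" for j in range(len(summary.mean_effect))]
    )
    df = pd.DataFrame(
        {
            "snp_id": ids,
            "mean_effect": summary.mean_effect,
            "incl_prob": summary.incl_prob_snp,
        }
    )
    cm = column_means if column_means is not None else summary.column_means
    if cm is not None:
        df["column_mean"] = cm
    df.to_csv(path, sep="\t", index=False)


def read_effects(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_windows_table(path, summary) -> None:
    if summary.windows is None or summary.incl_prob_window is None:
        raise ValueError("summary carries no window information")
    wp = summary.windows
    df = pd.DataFrame(
        {
            "window_id": np.arange(wp.w),
            "chrom": wp.window_chrom,
            "start_bp": wp.window_start_bp,
            "n_snps": wp.m_i,
            "incl_prob": summary.incl_prob_window,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_panel_summary(prefix, summary: PanelSummary, map: MarkerMap) -> None:
    prefix = Path(prefix)
    pd.DataFrame(
        {
            "snp_id": map.snp_id,
            "chrom": map.chrom,
            "pos_bp": map.pos_bp,
            "maf": summary.maf,
        }
    ).to_csv(prefix.parent / (prefix.name + "_maf.tsv"), sep="\t", index=False)
    pd.DataFrame(
        {
            "snp_a": summary.pair_index[:, 0],
            "snp_b": summary.pair_index[:, 1],
            "dist_bp": summary.pair_dist_bp,
            "r2": summary.pair_r2,
        }
    ).to_csv(prefix.parent / (prefix.name + "_ld.tsv"), sep="\t", index=False)


def write_replicate(outdir, rep) -> None:
    """One replicate as PLINK per panel + phenotype/TBV/QTL/manifest TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geno = rep.offspring.genotypes()
    ids = [f"ind_{i}" for i in range(geno.n_individuals)]
    for name, panel in rep.panels.items():
        idx = panel["panel_index"]
        sub = geno.subset_loci(idx)
        write_plink(outdir / name, sub, sample_ids=ids)
    write_phenotypes(
        outdir / "phenotypes.tsv", ids, rep.phenotypes.y, tbv=rep.trait.tbv
    )
    pd.DataFrame(
        {
            "snp_id": rep.offspring.map.snp_id[rep.qtl_index],
            "effect": rep.trait.qtl_effect,
        }
    ).to_csv(outdir / "qtl_truth.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "id": ids,
            "set": ["train"] * len(rep.train_idx) + ["validate"] * len(rep.validate_idx),
        }
    ).to_csv(outdir / "split.tsv", sep="\t", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(rep.manifest, fh, indent=2, default=str)
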