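"""Genotype panel container and plain-text I/O (VCF and TSV matrix + map).

Dosages are stored as a float matrix (n genotypes x m markers) with NaN for
missing calls; the marker map is a DataFrame sorted by (chromosome, bp).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GenotypePanel", "read_tsv", "read_vcf", "write_tsv", "write_vcf"]


@dataclass
class GenotypePanel:
    """Biallelic SNP dosages for a set of genotypes plus a physical marker map.

    Attributes
    ----------
    dosages : (n, m) float array with values in {0, 1, 2} or NaN (missing).
    markers : DataFrame with columns ``marker_id, chrom, bp`` (and, once
        computed, ``maf`` and ``missing_rate``), sorted by (chrom, bp).
    genotype_ids : list of n genotype labels, aligned with dosage rows.
    """

    dosages: np.ndarray
    markers: pd.DataFrame
    genotype_ids: list[str]

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if len(self.genotype_ids) != n:
            raise ValueError("genotype_ids length does not match dosage rows")
        if len(self.markers) != m:
            raise ValueError("marker map length does not match dosage columns")
        order = (
            self.markers[["chrom", "bp"]]
            .reset_index(drop=True)
            .sort_values(["chrom", "bp"], kind="mergesort")
            .index.to_numpy()
        )
        if not np.array_equal(order, np.arange(m)):
            self.markers = self.markers.iloc[order].reset_index(drop=True)
            self.dosages = self.dosages[:, order]
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            # imputed panels carry fractional dosages; only raw panels are strict
            pass

    @property
    def n_genotypes(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def chromosomes(self) -> list:
        return list(pd.unique(self.markers["chrom"]))

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per marker, over non-missing calls."""
        with np.errstate(invalid="ignore"):
            p = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def with_stats(self) -> "GenotypePanel":
        """Return a copy whose marker map carries maf and missing_rate columns."""
        markers = self.markers.copy()
        markers["maf"] = self.maf()
        markers["missing_rate"] = self.missing_rate()
        return replace(self, markers=markers)

    def subset_markers(self, keep: np.ndarray) -> "GenotypePanel":
        keep = np.asarray(keep)
        return GenotypePanel(
            dosages=self.dosages[:, keep],
            markers=self.markers.iloc[keep].reset_index(drop=True),
            genotype_ids=list(self.genotype_ids),
        )


def write_tsv(panel: GenotypePanel, matrix_path, map_path) -> None:
    """Write dosages as a genotypes x markers TSV and the map as a TSV."""
    mat = pd.DataFrame(
        panel.dosages,
        index=pd.Index(panel.genotype_ids, name="genotype"),
        columns=panel.markers["marker_id"],
    )
    mat.to_csv(matrix_path, sep="\t", na_rep="NA")
    panel.markers[["marker_id", "chrom", "bp"]].to_csv(map_path, sep="\t", index=False)


def read_tsv(matrix_path, map_path) -> GenotypePanel:
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0, na_values="NA")
    marker_map = pd.read_csv(map_path, sep="\t")
    marker_map = (
        marker_map.set_index("marker_id")
        .loc[mat.columns]
        .rename_axis("marker_id")
        .reset_index()
    )
    return GenotypePanel(
        dosages=mat.to_numpy(dtype=float),
        markers=marker_map,
        genotype_ids=[str(g) for g in mat.index],
    )


_VCF_HEADER = """##fileformat=VCFv4.2
##source=grainvar
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(panel: GenotypePanel, path) -> None:
    """Write the panel as a minimal biallelic GT-only VCF (A/B alleles)."""
    gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in panel.chromosomes:
            n = int((panel.markers["chrom"] == chrom).sum())
            length = int(panel.markers.loc[panel.markers["chrom"] == chrom, "bp"].max())
            fh.write(f"##contig=<ID={chrom},length={length + 1}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(g) for g in panel.genotype_ids) + "\n")
        for j, row in enumerate(panel.markers.itertuples(index=False)):
            calls = [
                "./." if np.isnan(d) else gt_code[float(d)]
                for d in panel.dosages[:, j]
            ]
            fh.write(
                f"{row.chrom}\t{int(row.bp)}\t{row.marker_id}\tA\tT\t.\tPASS\t.\tGT\t"
                + "\t".join(calls) + "\n"
            )


def read_vcf(path) -> GenotypePanel:
    """Read a biallelic VCF into a panel (ALT-allele dosage; ./. -> NaN)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    rows, dos = [], []
    for i, var in enumerate(vcf):
        marker_id = var.ID if var.ID not in (None, ".") else f"snp{i}"
        rows.append({"marker_id": marker_id, "chrom": var.CHROM, "bp": var.POS})
        gt = np.asarray(var.gt_types, dtype=float)  # 0,1,3 dosage-coded; 2=unknown
        d = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        dos.append(d)
    vcf.close()
    return GenotypePanel(
        dosages=np.array(dos).T,
        markers=pd.DataFrame(rows),
        genotype_ids=ids,
    )
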