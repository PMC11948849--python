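"""In-memory genotype container and VCF 4.2 round-trip.

The package works on biallelic SNP matrices coded as alternate-allele
dosages (0/1/2, -1 for missing) with a per-call read depth, the shape of
data a genotyping-by-sequencing pipeline emits after variant calling.
Reading goes through :mod:`cyvcf2`; writing produces plain-text VCF 4.2
with ``GT:DP`` FORMAT fields.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

MISSING = -1

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=pollenpop
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


@dataclass
class GenotypeTable:
    """Individuals x variants genotype matrix.

    Parameters
    ----------
    individuals : list of str
        Sample identifiers, one per matrix row.
    chrom, pos, ref, alt : arrays of length m
        Variant coordinates (1-based positions, strictly increasing within
        each chromosome) and alleles. ``alt`` may hold comma-joined allele
        lists for multi-allelic records read from a VCF.
    calls : (n, m) int8 array
        Alternate-allele dosage per call; ``-1`` marks a missing call.
    depths : (n, m) int32 array
        Read depth supporting each call.
    """

    individuals: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    calls: np.ndarray
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.depths = np.asarray(self.depths, dtype=np.int32)
        n, m = len(self.individuals), len(self.pos)
        if self.calls.shape != (n, m) or self.depths.shape != (n, m):
            raise ValueError(
                f"calls/depths shape mismatch: expected {(n, m)}, "
                f"got {self.calls.shape} and {self.depths.shape}"
            )
        for c in np.unique(self.chrom.astype(str)):
            p = self.pos[self.chrom.astype(str) == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    # ------------------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def called_mask(self) -> np.ndarray:
        return self.calls != MISSING

    def allele_freq(self) -> np.ndarray:
        """Per-site alternate-allele frequency among called genotypes."""
        called = self.called_mask()
        n_called = called.sum(axis=0)
        tot = np.where(self.calls == MISSING, 0, self.calls).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, tot / (2.0 * n_called), np.nan)

    def take_sites(self, index: np.ndarray) -> "GenotypeTable":
        return GenotypeTable(
            individuals=list(self.individuals),
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            calls=self.calls[:, index],
            depths=self.depths[:, index],
        )

    def take_individuals(self, ids: list[str]) -> "GenotypeTable":
        lookup = {s: i for i, s in enumerate(self.individuals)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise KeyError(f"unknown individuals: {missing}")
        idx = np.array([lookup[s] for s in ids])
        return GenotypeTable(
            individuals=list(ids),
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            calls=self.calls[idx],
            depths=self.depths[idx],
        )

    def dosage_matrix(self, impute: str = "mean") -> np.ndarray:
        """Float dosage matrix with missing calls imputed.

        ``impute='mean'`` replaces missing calls with 2p (the per-site mean
        dosage); ``impute='nan'`` leaves NaN.
        """
        x = self.calls.astype(float)
        x[self.calls == MISSING] = np.nan
        if impute == "mean":
            p = self.allele_freq()
            fill = np.broadcast_to(2.0 * p, x.shape)
            x = np.where(np.isnan(x), fill, x)
        elif impute != "nan":
            raise ValueError(f"unknown impute mode {impute!r}")
        return x


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(geno: GenotypeTable, path: str | os.PathLike) -> None:
    """Write a genotype table as uncompressed VCF 4.2 with GT:DP fields."""
    chroms = []
    for c in geno.chrom:
        if c not in chroms:
            chroms.append(c)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in chroms:
            maxpos = int(geno.pos[geno.chrom == c].max()) if geno.n_sites else 0
            fh.write(f"##contig=<ID={c},length={max(maxpos, 1)}>\n")
        if not chroms:
            fh.write("##contig=<ID=1,length=1>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(cols + list(geno.individuals)) + "\n")
        for j in range(geno.n_sites):
            fields = [
                str(geno.chrom[j]),
                str(int(geno.pos[j])),
                ".",
                str(geno.ref[j]),
                str(geno.alt[j]),
                ".",
                "PASS",
                ".",
                "GT:DP",
            ]
            for i in range(geno.n_individuals):
                fields.append(
                    f"{_GT_STR[int(geno.calls[i, j])]}:{int(geno.depths[i, j])}"
                )
            fh.write("\t".join(fields) + "\n")


def read_vcf(path: str | os.PathLike) -> GenotypeTable:
    """Read a VCF (any cyvcf2-readable flavour) into a GenotypeTable.

    Multi-allelic records are kept with comma-joined ALT strings; their
    dosage coding follows cyvcf2's het/hom-alt classification and they are
    expected to be removed downstream by the biallelic site filter.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    chrom, pos, ref, alt, calls, depths = [], [], [], [], [], []
    # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
    recode = np.array([0, 1, MISSING, 2], dtype=np.int8)
    for rec in vcf:
        chrom.append(rec.CHROM)
        pos.append(rec.POS)
        ref.append(rec.REF)
        alt.append(",".join(rec.ALT) if rec.ALT else ".")
        calls.append(recode[rec.gt_types])
        dp = rec.format("DP")
        if dp is None:
            depths.append(np.zeros(len(individuals), dtype=np.int32))
        else:
            dp = dp.astype(np.int32).reshape(-1)
            dp[dp < 0] = 0
            depths.append(dp)
    vcf.close()
    m = len(pos)
    n = len(individuals)
    calls_arr = (
        np.stack(calls, axis=1) if m else np.zeros((n, 0), dtype=np.int8)
    )
    depths_arr = (
        np.stack(depths, axis=1) if m else np.zeros((n, 0), dtype=np.int32)
    )
    return GenotypeTable(
        individuals=individuals,
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        calls=calls_arr,
        depths=depths_arr,
    )
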