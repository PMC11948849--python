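"""Genotype- and site-level VCF quality control, ploidy classification
from heterozygosity, and LD decay.

Two named filter presets encode the emulated study's chains:

* ``gwas``   — per-genotype minDP 4; biallelic SNPs only; site call rate
  >= 0.9; MAF >= 0.05.
* ``popgen`` — per-genotype minDP 10 and maxDP 100; biallelic SNPs only;
  site call rate >= 0.7; MAF >= 0.01.

Per-genotype depth masking is applied *before* the site-level filters, so
a site can fail the call-rate rule purely through depth masking — the
semantics of running per-genotype ``--minDP`` and per-site filters in one
VCFtools pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genotypes import MISSING, GenotypeTable, read_vcf, write_vcf  # noqa: F401

log = logging.getLogger(__name__)


@dataclass
class FilterSpec:
    """Site/genotype filter thresholds; ``None`` disables a rule."""

    min_dp: int | None = None
    max_dp: int | None = None
    max_missing: float = 0.0   # minimum called fraction per site
    maf: float = 0.0
    biallelic_only: bool = False
    remove_indels: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"maf={self.maf} outside [0, 0.5]")
        if (
            self.min_dp is not None
            and self.max_dp is not None
            and self.min_dp > self.max_dp
        ):
            raise ValueError("min_dp exceeds max_dp")
        if not 0.0 <= self.max_missing <= 1.0:
            raise ValueError("max_missing (minimum called fraction) outside [0,1]")


GWAS_PRESET = FilterSpec(
    min_dp=4, max_missing=0.9, maf=0.05, biallelic_only=True, remove_indels=True
)
POPGEN_PRESET = FilterSpec(
    min_dp=10,
    max_dp=100,
    max_missing=0.7,
    maf=0.01,
    biallelic_only=True,
    remove_indels=True,
)
PRESETS = {"gwas": GWAS_PRESET, "popgen": POPGEN_PRESET}


@dataclass
class FilterReport:
    """Per-rule accounting; site-removal counts sum to sites in − sites out."""

    masked_calls: int = 0
    removed: dict[str, int] = field(default_factory=dict)


def filter_variants(
    geno: GenotypeTable, spec: FilterSpec
) -> tuple[GenotypeTable, FilterReport]:
    """Apply the filter chain in its fixed order.

    1. per-genotype depth masking (calls outside [min_dp, max_dp] set
       missing);
    2. drop non-biallelic sites and indels;
    3. drop sites whose called fraction falls below ``max_missing``;
    4. drop sites with minor-allele frequency (computed on remaining
       calls) below ``maf``.
    """
    report = FilterReport()
    calls = geno.calls.copy()

    if spec.min_dp is not None or spec.max_dp is not None:
        bad = np.zeros(calls.shape, dtype=bool)
        if spec.min_dp is not None:
            bad |= geno.depths < spec.min_dp
        if spec.max_dp is not None:
            bad |= geno.depths > spec.max_dp
        bad &= calls != MISSING
        report.masked_calls = int(bad.sum())
        calls[bad] = MISSING
    work = GenotypeTable(
        individuals=list(geno.individuals),
        chrom=geno.chrom,
        pos=geno.pos,
        ref=geno.ref,
        alt=geno.alt,
        calls=calls,
        depths=geno.depths,
    )

    keep = np.ones(work.n_sites, dtype=bool)
    if spec.biallelic_only or spec.remove_indels:
        alt = work.alt.astype(str)
        ref = work.ref.astype(str)
        bad = np.zeros(work.n_sites, dtype=bool)
        if spec.biallelic_only:
            bad |= np.char.count(alt, ",") > 0
            bad |= alt == "."
        if spec.remove_indels:
            first_alt = np.array([a.split(",")[0] for a in alt])
            bad |= (np.char.str_len(ref.astype(str)) > 1) | (
                np.char.str_len(first_alt) > 1
            )
        bad &= keep
        report.removed["non_biallelic_or_indel"] = int(bad.sum())
        keep &= ~bad
    else:
        report.removed["non_biallelic_or_indel"] = 0

    called_frac = (work.calls != MISSING).mean(axis=0)
    bad = (called_frac < spec.max_missing) & keep
    report.removed["low_callrate"] = int(bad.sum())
    keep &= ~bad

    p = work.allele_freq()
    with np.errstate(invalid="ignore"):
        maf = np.minimum(p, 1.0 - p)
    bad = (~np.isfinite(maf) | (maf < spec.maf)) & keep
    report.removed["low_maf"] = int(bad.sum())
    keep &= ~bad

    return work.take_sites(np.flatnonzero(keep)), report


# ----------------------------------------------------------------------
# ploidy from heterozygosity
# ----------------------------------------------------------------------

def het_proportion(geno: GenotypeTable, individual: str) -> float:
    """Fraction of heterozygous calls among this individual's called sites."""
    try:
        i = geno.individuals.index(individual)
    except ValueError:
        raise KeyError(f"individual {individual!r} not in table") from None
    row = geno.calls[i]
    called = row != MISSING
    n = int(called.sum())
    if n == 0:
        raise ValueError(f"individual {individual!r} has no called genotypes")
    return float((row[called] == 1).sum() / n)


def classify_ploidy(
    het_props: dict[str, float], reference_labels: dict[str, int]
) -> tuple[dict[str, int], dict[tuple[int, int], float]]:
    """Assign each individual the ploidy of the nearest reference-class mean.

    ``reference_labels`` maps reference individuals (keys of ``het_props``)
    to known ploidies; at least two ploidy classes are required. Ties at a
    class midpoint break toward the lower ploidy (conservative; logged).
    Returns (per-individual calls, midpoints between adjacent class means).
    """
    classes: dict[int, list[float]] = {}
    for ind, ploidy in reference_labels.items():
        if ind not in het_props:
            raise KeyError(f"reference individual {ind!r} lacks a heterozygosity value")
        classes.setdefault(int(ploidy), []).append(het_props[ind])
    if len(classes) < 2:
        raise ValueError(
            "need reference individuals from at least two ploidy classes; "
            f"got {sorted(classes)}"
        )
    means = {k: float(np.mean(v)) for k, v in classes.items()}
    order = sorted(means, key=means.get)
    midpoints = {
        (order[i], order[i + 1]): (means[order[i]] + means[order[i + 1]]) / 2.0
        for i in range(len(order) - 1)
    }
    calls = {}
    for ind, h in het_props.items():
        dists = {k: abs(h - mu) for k, mu in means.items()}
        best = min(dists.values())
        tied = sorted(k for k, d in dists.items() if d <= best + 1e-12)
        if len(tied) > 1:
            log.info(
                "individual %s at class midpoint; tie broken toward ploidy %d",
                ind,
                tied[0],
            )
        calls[ind] = tied[0]
    return calls, midpoints


# ----------------------------------------------------------------------
# LD decay
# ----------------------------------------------------------------------

@dataclass
class LDBin:
    distance_lo: int
    distance_hi: int
    mean_r2: float
    n_pairs: int


def ld_r2_by_distance(
    geno: GenotypeTable,
    min_dist: int = 1_000_000,
    max_dist: int = 20_000_000,
    bin_width: int = 1_000_000,
) -> list[LDBin]:
    """Mean squared dosage correlation by intra-chromosome SNP distance.

    All pairs with separation in [min_dist, max_dist] enter; correlations
    use pairwise-complete observations; pairs involving a site that is
    monomorphic among the shared calls are skipped (undefined r).
    """
    bins: dict[int, list[float]] = {}
    x_all = geno.calls.astype(float)
    x_all[geno.calls == MISSING] = np.nan
    for c in np.unique(geno.chrom.astype(str)):
        idx = np.flatnonzero(geno.chrom.astype(str) == c)
        if idx.size < 2:
            continue
        pos = geno.pos[idx]
        x = np.ma.masked_invalid(x_all[:, idx])
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.ma.corrcoef(x, rowvar=False)
        d = np.abs(pos[:, None] - pos[None, :])
        iu = np.triu_indices(idx.size, k=1)
        dist = d[iu]
        r = np.ma.filled(corr[iu], np.nan)
        ok = (dist >= min_dist) & (dist <= max_dist) & np.isfinite(r)
        skipped = int(((dist >= min_dist) & (dist <= max_dist) & ~np.isfinite(r)).sum())
        if skipped:
            log.info("chromosome %s: skipped %d undefined-r pairs", c, skipped)
        for dd, rr in zip(dist[ok], r[ok]):
            b = int((dd - min_dist) // bin_width)
            bins.setdefault(b, []).append(float(rr) ** 2)
    out = []
    for b in sorted(bins):
        vals = bins[b]
        out.append(
            LDBin(
                distance_lo=int(min_dist + b * bin_width),
                distance_hi=int(min(min_dist + (b + 1) * bin_width, max_dist)),
                mean_r2=float(np.mean(vals)),
                n_pairs=len(vals),
            )
        )
    return out
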