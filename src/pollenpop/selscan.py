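"""Windowed selection statistics between two subpopulations.

Computes, on a shared sliding-window tiling (1 Mb windows, 250 Kb overlap
by default), the Weir–Cockerham F_ST (ratio of sums of the per-site
variance components), nucleotide diversity pi per population, the
diversity reduction index DRI = pi_feral / pi_domesticated, and a
cross-population composite-likelihood-ratio (XP-CLR) sweep score; flags
windows above the genome-wide 95th percentile of each statistic and
screens +/-5 Mb neighbourhoods around QTL for selection evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .genotypes import MISSING, GenotypeTable


# ----------------------------------------------------------------------
# window tiling
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class Window:
    chrom: str
    start: int   # 1-based, closed
    end: int
    step: int

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2.0

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def make_windows(
    chrom_lengths: dict[str, int],
    size: int = 1_000_000,
    overlap: int = 250_000,
) -> list[Window]:
    """Deterministic sliding tiling from position 1; the last window of a
    chromosome may be truncated. Step = size - overlap."""
    if overlap >= size:
        raise ValueError(f"overlap {overlap} must be smaller than window size {size}")
    step = size - overlap
    out = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length {length}")
        start = 1
        while start <= length:
            out.append(
                Window(str(chrom), start, min(start + size - 1, length), step)
            )
            if start + size - 1 >= length:
                break
            start += step
    return out


def _sites_in(window: Window, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
    return np.flatnonzero(
        (chrom.astype(str) == window.chrom)
        & (pos >= window.start)
        & (pos <= window.end)
    )


def _group_indices(
    geno: GenotypeTable, groups: dict[str, str]
) -> dict[str, np.ndarray]:
    out: dict[str, list[int]] = {}
    for i, s in enumerate(geno.individuals):
        g = groups.get(s)
        if g is not None:
            out.setdefault(g, []).append(i)
    return {k: np.array(v) for k, v in out.items()}


# ----------------------------------------------------------------------
# Weir-Cockerham F_ST
# ----------------------------------------------------------------------

def weir_cockerham_components(
    geno: GenotypeTable, groups: dict[str, str], pops: tuple[str, str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site variance components (a, b, c) of the two-population
    Weir–Cockerham estimator, plus a validity mask.

    a: among-population; b: between individuals within populations;
    c: within individuals. Per-site F_ST = a/(a+b+c); a windowed estimate
    is the ratio of sums. Negative components are retained (standard
    estimator; no clipping). Sites where any population has < 2 called
    individuals, or where the estimator is undefined, are masked out.
    """
    idx = _group_indices(geno, groups)
    for p in pops:
        if p not in idx or idx[p].size == 0:
            raise ValueError(f"group {p!r} is empty")
    r = 2
    n_i, p_i, h_i = [], [], []
    for p in pops:
        calls = geno.calls[idx[p]]
        called = calls != MISSING
        n = called.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(calls == MISSING, 0, calls).sum(axis=0) / (2.0 * n)
            het = (calls == 1).sum(axis=0) / n
        n_i.append(n)
        p_i.append(freq)
        h_i.append(het)
    n_i = np.stack(n_i)
    p_i = np.stack(p_i)
    h_i = np.stack(h_i)
    if np.all(n_i.sum(axis=0) < 2):
        raise ValueError("fewer than 2 called individuals in a group at all sites")

    valid = np.all(n_i >= 2, axis=0)
    n_i = np.where(n_i > 0, n_i, np.nan)
    nbar = n_i.mean(axis=0)
    nc = (r * nbar - (n_i**2).sum(axis=0) / (r * nbar)) / (r - 1)
    pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
    s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n_i * h_i).sum(axis=0) / (r * nbar)

    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0
    valid &= np.isfinite(a) & np.isfinite(b) & np.isfinite(c) & (nc > 0)
    # monomorphic across both populations: estimator undefined (0/0)
    valid &= ~((pbar <= 0) | (pbar >= 1)) | (s2 > 0)
    return a, b, c, valid


def weir_fst(
    geno: GenotypeTable,
    groups: dict[str, str],
    pops: tuple[str, str],
    windows: list[Window] | None = None,
) -> tuple[pd.DataFrame | None, np.ndarray]:
    """Windowed (ratio-of-sums) and per-site Weir–Cockerham F_ST.

    Returns (per-window DataFrame or None if no windows given, per-site
    F_ST array with NaN at undefined sites).
    """
    a, b, c, valid = weir_cockerham_components(geno, groups, pops)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = a + b + c
        per_site = np.where(valid & (denom != 0), a / denom, np.nan)
    if windows is None:
        return None, per_site
    rows = []
    for w in windows:
        sites = _sites_in(w, geno.chrom, geno.pos)
        sites = sites[valid[sites]]
        if sites.size == 0:
            rows.append((w, 0, np.nan))
            continue
        denom = float((a[sites] + b[sites] + c[sites]).sum())
        fst = float(a[sites].sum() / denom) if denom != 0 else np.nan
        rows.append((w, int(sites.size), fst))
    df = pd.DataFrame(
        {
            "chrom": [w.chrom for w, _, _ in rows],
            "start": [w.start for w, _, _ in rows],
            "end": [w.end for w, _, _ in rows],
            "n_snps": [n for _, n, _ in rows],
            "fst": [f for _, _, f in rows],
        }
    )
    return df, per_site


def genomewide_fst(
    geno: GenotypeTable, groups: dict[str, str], pops: tuple[str, str]
) -> float:
    """Weighted (ratio-of-sums) Weir–Cockerham F_ST over all sites."""
    a, b, c, valid = weir_cockerham_components(geno, groups, pops)
    return float(a[valid].sum() / (a[valid] + b[valid] + c[valid]).sum())


# ----------------------------------------------------------------------
# nucleotide diversity and DRI
# ----------------------------------------------------------------------

def windowed_pi(
    geno: GenotypeTable,
    groups: dict[str, str],
    pop: str,
    windows: list[Window],
) -> np.ndarray:
    """Per-window nucleotide diversity per bp for one population.

    Per-site pi = 2 p (1-p) * n/(n-1) with n the number of called alleles;
    the window value sums site pi over the window and divides by window
    length in bp (invariant sites contribute zero).
    """
    idx = _group_indices(geno, groups)
    if pop not in idx or idx[pop].size == 0:
        raise ValueError(f"group {pop!r} is empty")
    calls = geno.calls[idx[pop]]
    called = calls != MISSING
    n_alleles = 2.0 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(calls == MISSING, 0, calls).sum(axis=0) / n_alleles
        site_pi = np.where(
            n_alleles >= 2, 2.0 * p * (1.0 - p) * n_alleles / (n_alleles - 1.0), 0.0
        )
    out = np.empty(len(windows))
    for k, w in enumerate(windows):
        sites = _sites_in(w, geno.chrom, geno.pos)
        out[k] = float(site_pi[sites].sum()) / w.length
    return out


def dri(pi_feral: np.ndarray, pi_dom: np.ndarray) -> np.ndarray:
    """Diversity reduction index pi_feral / pi_domesticated per window.

    Windows where the domesticated diversity is zero are undefined (NaN)
    and excluded from percentile ranking downstream.
    """
    pi_feral = np.asarray(pi_feral, dtype=float)
    pi_dom = np.asarray(pi_dom, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(pi_dom > 0, pi_feral / pi_dom, np.nan)


# ----------------------------------------------------------------------
# XP-CLR
# ----------------------------------------------------------------------

@dataclass
class XPCLRConfig:
    """Settings for the composite-likelihood sweep scan.

    The object population is scanned for sweeps against the reference
    population's allele frequencies. Genetic distance is physical distance
    times a uniform recombination rate (cM/Mb); the drift variance omega is
    estimated genome-wide by method of moments unless given.
    """

    object_pop: str = "domesticated"
    reference_pop: str = "feral"
    sel_coeff_grid: tuple[float, ...] = (0.0, 1e-4, 1e-3, 1e-2, 1e-1)
    rec_rate: float = 1.0       # cM/Mb
    max_snps_per_window: int = 200
    omega: float | None = None

    def __post_init__(self) -> None:
        if 0.0 not in self.sel_coeff_grid:
            raise ValueError("sel_coeff_grid must include 0 (the neutral model)")
        if self.rec_rate <= 0:
            raise ValueError("rec_rate must be positive")


def estimate_omega(p_obj: np.ndarray, p_ref: np.ndarray) -> float:
    """Method-of-moments drift variance: mean (p1-p0)^2 / (p0 (1-p0))."""
    ok = (p_ref > 0.0) & (p_ref < 1.0) & np.isfinite(p_obj)
    if not ok.any():
        raise ValueError("no usable sites for drift-variance estimation")
    omega = float(np.mean((p_obj[ok] - p_ref[ok]) ** 2 / (p_ref[ok] * (1 - p_ref[ok]))))
    if omega <= 0:
        raise ValueError(f"estimated drift variance omega={omega} is not positive")
    return omega


def _truncnorm_logpdf(x: np.ndarray, mu: np.ndarray, var: np.ndarray) -> np.ndarray:
    """Log density of Normal(mu, var) truncated to [0, 1]."""
    sd = np.sqrt(var)
    z = (x - mu) / sd
    log_norm = -0.5 * z**2 - 0.5 * np.log(2 * np.pi * var)
    mass = ndtr((1.0 - mu) / sd) - ndtr((0.0 - mu) / sd)
    mass = np.clip(mass, 1e-300, None)
    return log_norm - np.log(mass)


def xpclr_scan(
    geno: GenotypeTable,
    groups: dict[str, str],
    windows: list[Window],
    config: XPCLRConfig | None = None,
) -> np.ndarray:
    """Per-window XP-CLR sweep score.

    Under neutral drift the object-population frequency p1 at a site is
    modelled as truncated-Normal(p0, omega * p0 (1-p0)) around the
    reference frequency p0. A sweep of selection coefficient s at the
    window center lets a site at genetic distance d escape hitchhiking
    with probability c = 1 - exp(-d/s); the non-escaping mass inflates the
    drift variance by (1-c)/4 (allele frequencies dragged toward fixation
    or loss). The window score is twice the composite log-likelihood gain
    of the best grid s over s = 0, hence non-negative.
    """
    config = config or XPCLRConfig()
    idx = _group_indices(geno, groups)
    for p in (config.object_pop, config.reference_pop):
        if p not in idx or idx[p].size == 0:
            raise ValueError(f"group {p!r} is empty")

    def freqs(pop: str) -> tuple[np.ndarray, np.ndarray]:
        calls = geno.calls[idx[pop]]
        called = calls != MISSING
        n = 2.0 * called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(calls == MISSING, 0, calls).sum(axis=0) / n
        return f, n

    p1, _ = freqs(config.object_pop)
    p0, n0 = freqs(config.reference_pop)
    # clamp the reference frequency away from the boundary (frequency 0/1
    # in a finite sample still permits drift in the underlying population)
    eps = 0.5 / np.where(n0 > 0, n0, 1.0)
    p0c = np.clip(p0, eps, 1.0 - eps)
    usable = np.isfinite(p1) & np.isfinite(p0c)

    omega = config.omega
    if omega is None:
        omega = estimate_omega(p1[usable], p0c[usable])

    scores = np.full(len(windows), np.nan)
    for k, w in enumerate(windows):
        sites = _sites_in(w, geno.chrom, geno.pos)
        sites = sites[usable[sites]]
        if sites.size == 0:
            continue
        if sites.size > config.max_snps_per_window:
            pick = np.linspace(0, sites.size - 1, config.max_snps_per_window)
            sites = sites[np.round(pick).astype(int)]
        x1 = p1[sites]
        x0 = p0c[sites]
        base_var = omega * x0 * (1.0 - x0)
        d_morgan = np.abs(geno.pos[sites] - w.center) * config.rec_rate / 1e6 / 100.0
        ll = {}
        for s in config.sel_coeff_grid:
            if s == 0.0:
                var = base_var
            else:
                escape = 1.0 - np.exp(-d_morgan / s)
                var = base_var + (1.0 - escape) * 0.25
            ll[s] = float(_truncnorm_logpdf(x1, x0, var).sum())
        scores[k] = 2.0 * (max(ll.values()) - ll[0.0])
    return scores


# ----------------------------------------------------------------------
# outlier calling and QTL screening
# ----------------------------------------------------------------------

def call_significant(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Flag values strictly above the genome-wide 95th percentile.

    NaN entries (e.g. undefined DRI windows) are excluded from the
    percentile computation and never flagged. Requires >= 20 defined
    windows for a stable percentile.
    """
    values = np.asarray(values, dtype=float)
    defined = np.isfinite(values)
    if defined.sum() < 20:
        raise ValueError(
            f"only {int(defined.sum())} defined windows; "
            "need >= 20 for a stable 95th percentile"
        )
    cut = float(np.percentile(values[defined], 95))
    flags = np.zeros(values.shape, dtype=bool)
    flags[defined] = values[defined] > cut
    return flags, cut


def z_transform(values: np.ndarray) -> np.ndarray:
    """Genome-wide Z-transform ((x - mean) / sd) over defined windows."""
    values = np.asarray(values, dtype=float)
    defined = np.isfinite(values)
    mu = values[defined].mean()
    sd = values[defined].std()
    out = np.full(values.shape, np.nan)
    out[defined] = (values[defined] - mu) / sd if sd > 0 else 0.0
    return out


def scan_windows(
    geno: GenotypeTable,
    groups: dict[str, str],
    chrom_lengths: dict[str, int],
    feral: str = "feral",
    domesticated: str = "domesticated",
    size: int = 1_000_000,
    overlap: int = 250_000,
    xpclr_config: XPCLRConfig | None = None,
) -> pd.DataFrame:
    """Full windowed scan: F_ST, Z(F_ST), pi per population, DRI, XP-CLR,
    and per-statistic significance flags on a shared tiling.

    Windows without SNPs are dropped (consistent with restricting to
    windows containing at least one SNP).
    """
    windows = make_windows(chrom_lengths, size=size, overlap=overlap)
    fst_df, _ = weir_fst(geno, groups, (feral, domesticated), windows)
    pi_f = windowed_pi(geno, groups, feral, windows)
    pi_d = windowed_pi(geno, groups, domesticated, windows)
    cfg = xpclr_config or XPCLRConfig(object_pop=domesticated, reference_pop=feral)
    xp = xpclr_scan(geno, groups, windows, cfg)

    df = fst_df.copy()
    df["pi_feral"] = pi_f
    df["pi_dom"] = pi_d
    df["dri"] = dri(pi_f, pi_d)
    df["xpclr"] = xp
    df = df[df["n_snps"] > 0].reset_index(drop=True)
    df["z_fst"] = z_transform(df["fst"].to_numpy())
    for stat, flag in [("fst", "fst_sig"), ("dri", "dri_sig"), ("xpclr", "xpclr_sig")]:
        flags, _ = call_significant(df[stat].to_numpy())
        df[flag] = flags
    return df


def screen_qtl(
    qtl_positions: list[tuple[str, int]],
    window_stats: pd.DataFrame,
    span: int = 5_000_000,
) -> pd.DataFrame:
    """Selection evidence within +/-``span`` of each QTL.

    For each QTL and each statistic, reports whether any flagged window
    overlaps [pos - span, pos + span]; ``any_sig`` is their union. The
    fraction of QTL with evidence is ``out["any_sig"].mean()``.
    """
    rows = []
    for chrom, pos in qtl_positions:
        lo, hi = pos - span, pos + span
        near = window_stats[
            (window_stats["chrom"].astype(str) == str(chrom))
            & (window_stats["end"] >= lo)
            & (window_stats["start"] <= hi)
        ]
        row = {"chrom": str(chrom), "pos": int(pos)}
        for flag in ("fst_sig", "dri_sig", "xpclr_sig"):
            row[flag] = bool(near[flag].any()) if len(near) else False
        row["any_sig"] = row["fst_sig"] or row["dri_sig"] or row["xpclr_sig"]
        rows.append(row)
    return pd.DataFrame(rows)
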