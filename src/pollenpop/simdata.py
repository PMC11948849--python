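"""Synthetic data with the statistical structure of a two-population
domestication panel.

Generates (i) biallelic SNP genotypes for a "feral" population A and a
"domesticated" population B under the Balding–Nichols drift model with
optional planted selective sweeps, (ii) polygenic phenotypes with a
target narrow-sense heritability and an optional between-population mean
shift, and (iii) per-particle imaging-flow-cytometry feature tables mixing
fertile pollen with contaminant classes that each violate one designated
gate. Every generator returns a ground-truth record for parameter-recovery
tests.

All randomness flows from a single integer seed; component sub-streams are
derived with fixed offsets so outputs are reproducible call by call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeTable, write_vcf  # noqa: F401  (re-export)

SWEEP_DECAY_BP = 1_000_000  # linear decay of the sweep push to zero at +/-1 Mb

# fixed offsets for per-component RNG sub-streams
_STREAM_GENO = 0
_STREAM_PHENO = 1
_STREAM_MIFC = 2


@dataclass
class SimConfig:
    """Study-condition knobs for the synthetic panel.

    Defaults mirror the emulated study: ~50 individuals per subpopulation
    (the selection-scan outgroups), 2000 SNPs over two 30 Mb chromosomes
    (about 33 SNPs/Mb), mild drift (F = 0.05), mean read depth 19, a highly
    heritable polygenic trait (h2 = 0.8 on 200 causal SNPs), and ~600
    imaged pollen per individual with low contaminant rates.
    """

    seed: int = 0
    n_pop_a: int = 50
    n_pop_b: int = 50
    n_snps: int = 2000
    n_chrom: int = 2
    chrom_length: int = 30_000_000
    drift_F: float = 0.05
    sweep_loci: list[tuple[int, int, float]] = field(default_factory=list)
    missing_rate: float = 0.02
    depth_mean: float = 19.0
    tetraploid_ids: list[str] = field(default_factory=list)
    h2: float = 0.8
    n_qtl: int = 200
    group_shift_sd: float = 0.0
    contaminant_rates: dict[str, float] = field(
        default_factory=lambda: {
            "aborted": 0.05,
            "stacked": 0.05,
            "debris": 0.05,
            "blurred": 0.05,
        }
    )
    pollen_per_individual: int = 600

    def __post_init__(self) -> None:
        if not 0.0 <= self.drift_F < 1.0:
            raise ValueError(f"drift_F={self.drift_F} outside [0, 1)")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError(f"missing_rate={self.missing_rate} outside [0, 1]")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError(f"h2={self.h2} outside [0, 1]")
        if self.n_qtl > self.n_snps:
            raise ValueError("n_qtl exceeds n_snps")
        for chrom, position, strength in self.sweep_loci:
            if not 1 <= position <= self.chrom_length:
                raise ValueError(
                    f"sweep locus (chrom {chrom}, pos {position}) lies outside "
                    f"[1, {self.chrom_length}]"
                )
            if not 0.0 <= strength <= 1.0:
                raise ValueError(f"sweep strength {strength} outside [0, 1]")
            if not 1 <= chrom <= self.n_chrom:
                raise ValueError(
                    f"sweep locus chromosome {chrom} not among the "
                    f"{self.n_chrom} simulated chromosomes"
                )
        bad = [k for k, v in self.contaminant_rates.items() if not 0 <= v <= 1]
        if bad:
            raise ValueError(f"contaminant rates outside [0,1]: {bad}")
        if sum(self.contaminant_rates.values()) > 1.0:
            raise ValueError("contaminant rates sum to more than 1")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng((int(self.seed), int(stream)))

    def individual_ids(self) -> tuple[list[str], dict[str, str]]:
        ids_a = [f"A{i:03d}" for i in range(self.n_pop_a)]
        ids_b = [f"B{i:03d}" for i in range(self.n_pop_b)]
        groups = {s: "feral" for s in ids_a}
        groups.update({s: "domesticated" for s in ids_b})
        return ids_a + ids_b, groups


@dataclass
class TruthTable:
    """Ground truth carried alongside each simulated table."""

    causal_effects: dict[int, float] = field(default_factory=dict)
    sweep_windows: list[tuple[str, int, int]] = field(default_factory=list)
    true_h2: float = float("nan")
    realized_h2: float = float("nan")
    particle_labels: pd.Series | None = None
    groups: dict[str, str] = field(default_factory=dict)
    ancestral_freq: np.ndarray | None = None


# ----------------------------------------------------------------------
# genotypes
# ----------------------------------------------------------------------

def simulate_genotypes(config: SimConfig) -> tuple[GenotypeTable, TruthTable]:
    """Two-population Balding–Nichols genotypes with planted sweeps.

    Ancestral frequencies are uniform on [0.05, 0.95]; each population's
    frequency is Beta-distributed around the ancestral value with variance
    F p(1-p). At a sweep locus the domesticated-population frequency is
    pushed deterministically toward fixation of the alternate allele, the
    push decaying linearly to zero at +/-1 Mb from the locus. Calls are
    Binomial(2, p); depths Poisson; missingness Bernoulli. Individuals in
    ``tetraploid_ids`` get a doubled heterozygote probability (capped at 1),
    emulating the elevated apparent heterozygosity of tetraploids in
    diploid-coded calls.
    """
    rng = config.rng(_STREAM_GENO)
    m = config.n_snps
    ids, groups = config.individual_ids()
    n_a, n_b = config.n_pop_a, config.n_pop_b

    # variant coordinates: sites spread over chromosomes, sorted positions
    per_chrom = np.full(config.n_chrom, m // config.n_chrom)
    per_chrom[: m % config.n_chrom] += 1
    chrom_arr, pos_arr = [], []
    for c in range(config.n_chrom):
        k = int(per_chrom[c])
        pos = np.sort(rng.choice(config.chrom_length, size=k, replace=False)) + 1
        chrom_arr.append(np.full(k, f"{c + 1}", dtype=object))
        pos_arr.append(pos)
    chrom = np.concatenate(chrom_arr)
    pos = np.concatenate(pos_arr)

    p_anc = rng.uniform(0.05, 0.95, size=m)
    if config.drift_F > 0:
        F = config.drift_F
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        p_a = rng.beta(a, b)
        p_b = rng.beta(a, b)
    else:
        p_a = p_anc.copy()
        p_b = p_anc.copy()

    sweep_windows: list[tuple[str, int, int]] = []
    for c, position, strength in config.sweep_loci:
        on = chrom == f"{c}"
        dist = np.abs(pos - position)
        w = strength * np.clip(1.0 - dist / SWEEP_DECAY_BP, 0.0, 1.0)
        w = np.where(on, w, 0.0)
        p_b = p_b + w * (1.0 - p_b)
        sweep_windows.append(
            (f"{c}", max(1, position - SWEEP_DECAY_BP),
             min(config.chrom_length, position + SWEEP_DECAY_BP))
        )

    def draw_pop(p: np.ndarray, n: int, pop_ids: list[str]) -> np.ndarray:
        calls = rng.binomial(2, p[None, :], size=(n, m)).astype(np.int8)
        tets = [i for i, s in enumerate(pop_ids) if s in config.tetraploid_ids]
        if tets:
            # redraw tetraploid genotypes with inflated heterozygote mass
            p_hom_alt = p**2
            p_het = np.minimum(2.0 * 2.0 * p * (1 - p), 1.0)
            rest = 1.0 - p_het
            denom = np.where(p**2 + (1 - p) ** 2 > 0, p**2 + (1 - p) ** 2, 1.0)
            p_hom_alt = rest * (p**2) / denom
            u = rng.uniform(size=(len(tets), m))
            g = np.where(u < p_het, 1, np.where(u < p_het + p_hom_alt, 2, 0))
            calls[tets] = g.astype(np.int8)
        return calls

    calls = np.vstack([draw_pop(p_a, n_a, ids[:n_a]), draw_pop(p_b, n_b, ids[n_a:])])
    depths = rng.poisson(config.depth_mean, size=calls.shape).astype(np.int32)
    miss = rng.uniform(size=calls.shape) < config.missing_rate
    calls[miss] = MISSING

    geno = GenotypeTable(
        individuals=ids,
        chrom=chrom,
        pos=pos,
        ref=np.full(m, "A", dtype=object),
        alt=np.full(m, "T", dtype=object),
        calls=calls,
        depths=depths,
    )
    truth = TruthTable(
        sweep_windows=sweep_windows, groups=groups, ancestral_freq=p_anc
    )
    return geno, truth


# ----------------------------------------------------------------------
# phenotypes
# ----------------------------------------------------------------------

def simulate_phenotypes(
    geno: GenotypeTable, config: SimConfig, trait: str = "trait"
) -> tuple[pd.DataFrame, TruthTable]:
    """Polygenic trait y = X beta + shift + e at a target heritability.

    ``n_qtl`` causal SNPs get standard-normal effects on the dosage scale;
    the environmental variance is scaled against the realized genetic
    variance so that var(g)/var(g+e) equals ``h2`` up to Monte-Carlo error
    in e. A between-group mean shift of ``group_shift_sd`` phenotypic SDs
    is then added to the domesticated population.
    """
    if not 0.0 <= config.h2 <= 1.0:
        raise ValueError(f"h2={config.h2} outside [0, 1]")
    rng = config.rng(_STREAM_PHENO)
    n = geno.n_individuals
    x = geno.dosage_matrix(impute="mean")

    causal = np.sort(rng.choice(geno.n_sites, size=config.n_qtl, replace=False))
    beta = rng.normal(size=config.n_qtl)
    g = x[:, causal] @ beta
    var_g = float(np.var(g))

    if config.h2 == 0.0 or var_g == 0.0:
        g = np.zeros(n)
        beta = np.zeros_like(beta)
        e = rng.normal(0.0, 1.0, size=n)
    elif config.h2 == 1.0:
        e = np.zeros(n)
    else:
        sigma_e = np.sqrt(var_g * (1.0 - config.h2) / config.h2)
        e = rng.normal(0.0, sigma_e, size=n)
    y = g + e

    groups = dict(config.individual_ids()[1])
    if config.group_shift_sd != 0.0:
        shift = config.group_shift_sd * float(np.std(y))
        is_b = np.array(
            [groups.get(s) == "domesticated" for s in geno.individuals]
        )
        y = y + shift * is_b

    var_tot = float(np.var(g) + np.var(e))
    realized = float(np.var(g) / var_tot) if var_tot > 0 else 0.0
    pheno = pd.DataFrame({"individual_id": geno.individuals, trait: y})
    truth = TruthTable(
        causal_effects={int(j): float(b) for j, b in zip(causal, beta)},
        true_h2=config.h2,
        realized_h2=realized,
        groups=groups,
    )
    return pheno, truth


# ----------------------------------------------------------------------
# imaging-flow-cytometry particle tables
# ----------------------------------------------------------------------

#: feature columns of a simulated particle table, in gate order
PARTICLE_COLUMNS = [
    "individual_id",
    "diameter",
    "brightfield_intensity",
    "median_pixel",
    "symmetry3",
    "symmetry4",
    "correlation_mean",
    "gradient_rms",
    "pollen_length",
    "pollen_width",
    "pollen_area",
    "fluor_ch2",
    "fluor_ch3",
    "fluor_ch4",
    "fluor_ch5",
]

# gate interiors used when drawing fertile features (safely inside every gate)
_FERTILE_RANGES = {
    "brightfield_intensity": (-1.1e6, -4.0e5),
    "median_pixel": (-450.0, -150.0),
    "symmetry3": (0.5, 2.5),
    "symmetry4": (0.5, 2.5),
    "correlation_mean": (0.25, 0.55),
    "gradient_rms": (9.0, 18.0),
}
# out-of-gate draws for each contaminant class (violate only that gate)
_VIOLATIONS = {
    "aborted": ("median_pixel", (-95.0, 50.0)),
    "stacked": ("symmetry3", (3.5, 6.0)),
    "debris": ("diameter", (3.0, 18.0)),
    "blurred": ("gradient_rms", (20.0, 40.0)),
}


def simulate_mifc_particles(
    individuals: list[str], config: SimConfig
) -> tuple[pd.DataFrame, TruthTable]:
    """Per-particle MIFC feature table with labelled contaminant classes.

    Fertile particles carry every feature strictly inside its gate, with
    per-individual pollen length Normal(mu_ind, 2 um) and mu_ind spread
    uniformly over [39, 57] um (the within-species span of the emulated
    panel). Each contaminant class violates exactly one designated gate:
    aborted pollen fail the brightfield/median-pixel step, stacked images
    the symmetry step, debris the diameter step and blurred images the
    focus (correlation-mean/gradient-RMS) step. Fluorescence channels are
    correlated log-normals (pairwise r ~ 0.9).
    """
    rng = config.rng(_STREAM_MIFC)
    rates = config.contaminant_rates
    n_per = config.pollen_per_individual
    mu_by_ind = {
        s: 39.0 + 18.0 * (i / max(len(individuals) - 1, 1))
        for i, s in enumerate(individuals)
    }

    frames = []
    labels = []
    class_names = ["fertile"] + list(_VIOLATIONS)
    probs = np.array(
        [1.0 - sum(rates.get(k, 0.0) for k in _VIOLATIONS)]
        + [rates.get(k, 0.0) for k in _VIOLATIONS]
    )
    for ind in individuals:
        cls = rng.choice(len(class_names), size=n_per, p=probs)
        mu = mu_by_ind[ind]
        length = rng.normal(mu, 2.0, size=n_per)
        # clip keeps fertile diameters (mean of axes) strictly inside 20-100 um
        length = np.clip(length, 30.0, 70.0)
        elong = rng.uniform(1.0, 1.3, size=n_per)
        width = length / elong
        area = np.pi / 4.0 * length * width
        df = pd.DataFrame(
            {
                "individual_id": ind,
                "diameter": (length + width) / 2.0,
                "pollen_length": length,
                "pollen_width": width,
                "pollen_area": area,
            }
        )
        for col, (lo, hi) in _FERTILE_RANGES.items():
            df[col] = rng.uniform(lo, hi, size=n_per)
        # correlated log-normal fluorescence: shared log-scale factor
        z = rng.normal(size=n_per)
        for k, ch in enumerate(["fluor_ch2", "fluor_ch3", "fluor_ch4", "fluor_ch5"]):
            eps = rng.normal(scale=0.15, size=n_per)
            df[ch] = np.exp(8.0 + 0.1 * k + 0.45 * z + eps)
        for ci, name in enumerate(class_names[1:], start=1):
            colv, (lo, hi) = _VIOLATIONS[name]
            sel = cls == ci
            if sel.any():
                df.loc[sel, colv] = rng.uniform(lo, hi, size=int(sel.sum()))
        frames.append(df)
        labels.append(pd.Series([class_names[c] for c in cls]))

    particles = pd.concat(frames, ignore_index=True)[PARTICLE_COLUMNS]
    label_series = pd.concat(labels, ignore_index=True)
    label_series.name = "particle_class"
    truth = TruthTable(particle_labels=label_series)
    return particles, truth


def write_truth_json(truth: TruthTable, path) -> None:
    """Serialize a truth table (labels as a list) to JSON."""
    import json

    payload = {
        "causal_effects": {str(k): v for k, v in truth.causal_effects.items()},
        "sweep_windows": truth.sweep_windows,
        "true_h2": truth.true_h2,
        "realized_h2": truth.realized_h2,
        "groups": truth.groups,
        "particle_labels": (
            truth.particle_labels.tolist()
            if truth.particle_labels is not None
            else None
        ),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
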