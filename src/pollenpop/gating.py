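"""Stepwise imaging-flow-cytometry gating and trait summarization.

Reproduces the analysis cascade applied to exported per-particle cytometer
features: (1) a diameter gate isolating pollen-sized objects, (2) a
brightfield-intensity + median-pixel gate excluding aborted pollen, (3) a
symmetry gate excluding stacked images, (4) a correlation-mean +
gradient-RMS focus gate excluding blurred images; then individuals with
fewer than 50 retained images are dropped, pooled 1%/99% pollen-length
outliers trimmed, and per-individual trait medians computed. All gate
ranges are closed intervals — endpoint values pass, the usual semantics of
cytometry-software regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class GateConfig:
    """Gate ranges (a.u. unless noted); defaults are the study's regions."""

    diameter_range: tuple[float, float] = (20.0, 100.0)          # um
    brightfield_range: tuple[float, float] = (-1.2e6, -3.0e5)
    median_pixel_range: tuple[float, float] = (-500.0, -100.0)
    symmetry3_range: tuple[float, float] = (0.0, 3.0)
    symmetry4_range: tuple[float, float] = (0.0, 3.0)
    correlation_mean_range: tuple[float, float] = (0.2, 0.6)
    gradient_rms_range: tuple[float, float] = (8.0, 19.0)
    min_particles_per_individual: int = 50
    trim_quantiles: tuple[float, float] = (0.01, 0.99)
    trim_per_individual: bool = False

    def __post_init__(self) -> None:
        for name in (
            "diameter_range",
            "brightfield_range",
            "median_pixel_range",
            "symmetry3_range",
            "symmetry4_range",
            "correlation_mean_range",
            "gradient_rms_range",
        ):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: lower bound {lo} not below upper {hi}")
        qlo, qhi = self.trim_quantiles
        if not (0.0 <= qlo < qhi <= 1.0):
            raise ValueError(f"trim_quantiles {self.trim_quantiles} not ordered in [0,1]")


@dataclass
class GatingReport:
    """Audit trail of the cascade: particle counts per step."""

    counts_after_each_gate: list[tuple[str, int]] = field(default_factory=list)
    individuals_dropped: list[str] = field(default_factory=list)
    particles_trimmed: int = 0

    def to_dict(self) -> dict:
        return {
            "counts_after_each_gate": self.counts_after_each_gate,
            "individuals_dropped": self.individuals_dropped,
            "particles_trimmed": self.particles_trimmed,
        }


# the cascade, in order: (step name, [(column, range attribute), ...])
_CASCADE = [
    ("diameter", [("diameter", "diameter_range")]),
    (
        "brightfield_median_pixel",
        [
            ("brightfield_intensity", "brightfield_range"),
            ("median_pixel", "median_pixel_range"),
        ],
    ),
    (
        "symmetry",
        [("symmetry3", "symmetry3_range"), ("symmetry4", "symmetry4_range")],
    ),
    (
        "focus",
        [
            ("correlation_mean", "correlation_mean_range"),
            ("gradient_rms", "gradient_rms_range"),
        ],
    ),
]


def apply_gates(
    particles: pd.DataFrame, config: GateConfig | None = None
) -> tuple[pd.DataFrame, GatingReport]:
    """Run the four-step gate cascade; returns kept particles and a report.

    Range tests are inclusive of both endpoints. Raises ``KeyError`` naming
    the first missing feature column.
    """
    config = config or GateConfig()
    needed = [col for _, tests in _CASCADE for col, _ in tests]
    for col in needed:
        if col not in particles.columns:
            raise KeyError(f"particle table lacks required feature column {col!r}")

    report = GatingReport()
    report.counts_after_each_gate.append(("input", len(particles)))
    kept = particles
    for step, tests in _CASCADE:
        mask = np.ones(len(kept), dtype=bool)
        for col, attr in tests:
            lo, hi = getattr(config, attr)
            v = kept[col].to_numpy()
            mask &= (v >= lo) & (v <= hi)
        kept = kept.loc[mask]
        report.counts_after_each_gate.append((step, len(kept)))
    return kept, report


def filter_individuals(
    kept_particles: pd.DataFrame,
    config: GateConfig | None = None,
    report: GatingReport | None = None,
) -> pd.DataFrame:
    """Drop individuals with fewer than the minimum retained particle count."""
    config = config or GateConfig()
    if len(kept_particles) == 0:
        return kept_particles
    counts = kept_particles.groupby("individual_id").size()
    drop = counts.index[counts < config.min_particles_per_individual].tolist()
    if report is not None:
        report.individuals_dropped = [str(s) for s in drop]
    out = kept_particles[~kept_particles["individual_id"].isin(drop)]
    if report is not None:
        report.counts_after_each_gate.append(("min_particles", len(out)))
    return out


def trim_length_outliers(
    particles: pd.DataFrame,
    config: GateConfig | None = None,
    report: GatingReport | None = None,
) -> pd.DataFrame:
    """Remove pollen-length outliers outside the [q01, q99] quantile band.

    Quantiles use linear interpolation. By default they are computed on
    the pooled retained particles; ``trim_per_individual=True`` switches to
    per-individual bands. Particles strictly outside the band are removed
    (values equal to a quantile stay).
    """
    config = config or GateConfig()
    if len(particles) < 2:
        raise ValueError("need at least 2 particles to compute trim quantiles")
    qlo, qhi = config.trim_quantiles

    def band_mask(df: pd.DataFrame) -> pd.Series:
        lengths = df["pollen_length"].to_numpy(dtype=float)
        lo, hi = np.quantile(lengths, [qlo, qhi])
        return (df["pollen_length"] >= lo) & (df["pollen_length"] <= hi)

    if config.trim_per_individual:
        mask = particles.groupby("individual_id", group_keys=False).apply(
            band_mask, include_groups=False
        )
        mask = mask.reindex(particles.index)
    else:
        mask = band_mask(particles)
    out = particles.loc[mask]
    if report is not None:
        report.particles_trimmed = len(particles) - len(out)
        report.counts_after_each_gate.append(("length_trim", len(out)))
    return out


TRAIT_COLUMNS = [
    "pollen_length",
    "pollen_area",
    "pollen_elongatedness",
    "fluor_ch2",
    "fluor_ch3",
    "fluor_ch4",
    "fluor_ch5",
]


def summarize_traits(particles: pd.DataFrame) -> pd.DataFrame:
    """Per-individual medians of pollen morphology and fluorescence traits.

    Elongatedness (length/width, dimensionless, >= 1 for valid particles)
    is derived per particle before taking medians. The retained particle
    count per individual is kept as ``n_particles``.
    """
    df = particles.copy()
    df["pollen_elongatedness"] = df["pollen_length"] / df["pollen_width"]
    cols = [c for c in TRAIT_COLUMNS if c in df.columns]
    out = df.groupby("individual_id")[cols].median()
    out["n_particles"] = df.groupby("individual_id").size()
    return out.reset_index()


def gate_pipeline(
    particles: pd.DataFrame, config: GateConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, GatingReport]:
    """Full cascade: gates -> individual filter -> length trim -> medians.

    Returns (trimmed particle table, per-individual trait table, report).
    """
    config = config or GateConfig()
    kept, report = apply_gates(particles, config)
    kept = filter_individuals(kept, config, report)
    if len(kept) >= 2:
        kept = trim_length_outliers(kept, config, report)
    traits = summarize_traits(kept) if len(kept) else pd.DataFrame(
        columns=["individual_id"] + TRAIT_COLUMNS + ["n_particles"]
    )
    return kept, traits, report


def anther_median(anther_lengths: dict[str, list[float]]) -> pd.Series:
    """Median anther length (mm) per individual.

    The emulated protocol measures six anthers from one flower per
    individual; a warning is logged for any individual with a different
    measurement count. An individual with no measurements is an error.
    """
    out = {}
    for ind, values in anther_lengths.items():
        if len(values) == 0:
            raise ValueError(f"individual {ind!r} has no anther measurements")
        if len(values) != 6:
            log.warning(
                "individual %s has %d anther measurements (expected 6)",
                ind,
                len(values),
            )
        out[ind] = float(np.median(values))
    s = pd.Series(out, name="anther_length_mm")
    s.index.name = "individual_id"
    return s
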