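"""P_ST estimation and comparison with genome-wide F_ST.

P_ST is the phenotypic analogue of Q_ST:

    P_ST = (c/h2) sigma2_b / ( (c/h2) sigma2_b + 2 sigma2_w )

with sigma2_b and sigma2_w the between- and within-population variance
components of the trait and csh = c/h2 the ratio of the across-population
additive proportion to the within-population heritability (csh = 1 under
a common-garden assumption). Variance components come from a one-way
ANOVA method-of-moments decomposition; confidence intervals from a
percentile bootstrap resampling individuals within groups. A trait is
called under selection when the lower CI bound exceeds the genome-wide
Weir–Cockerham F_ST of the same two populations, consistent with drift
when the CI contains it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)


@dataclass
class PSTComponents:
    sigma2_b: float
    sigma2_w: float
    csh: float = 1.0
    truncated: bool = False   # True when a negative sigma2_b was clipped to 0


@dataclass
class PSTResult:
    trait: str
    pst: float
    ci_low: float
    ci_high: float
    fst_genomewide: float = float("nan")
    verdict: str = ""
    n_boot: int = 0
    redrawn_resamples: int = 0


def _split_groups(
    trait_values: np.ndarray, group_labels: np.ndarray
) -> list[np.ndarray]:
    values = np.asarray(trait_values, dtype=float)
    labels = np.asarray(group_labels)
    names = sorted(set(labels.tolist()))
    if len(names) != 2:
        raise ValueError(f"exactly 2 groups required, got {len(names)}: {names}")
    out = [values[labels == g] for g in names]
    for g, v in zip(names, out):
        if v.size < 3:
            raise ValueError(f"group {g!r} has n={v.size} < 3")
    return out


def variance_components(
    trait_values: np.ndarray, group_labels: np.ndarray, csh: float = 1.0
) -> PSTComponents:
    """One-way ANOVA decomposition into between/within variance components.

    sigma2_w is the error mean square; sigma2_b = (MSB - MSW)/n0 with n0
    the unbalanced-design coefficient (N - sum n_i^2 / N)/(k - 1). A
    negative between-group component estimate is truncated to 0 (flagged).
    """
    groups = _split_groups(trait_values, group_labels)
    return _components_from_arrays(groups, csh)


def _components_from_arrays(groups: list[np.ndarray], csh: float) -> PSTComponents:
    k = len(groups)
    n_i = np.array([g.size for g in groups], dtype=float)
    n_tot = n_i.sum()
    means = np.array([g.mean() for g in groups])
    grand = float(np.concatenate(groups).mean())
    ssb = float((n_i * (means - grand) ** 2).sum())
    ssw = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    msb = ssb / (k - 1)
    msw = ssw / (n_tot - k)
    n0 = (n_tot - (n_i**2).sum() / n_tot) / (k - 1)
    sigma2_b = (msb - msw) / n0
    truncated = sigma2_b < 0
    return PSTComponents(
        sigma2_b=max(sigma2_b, 0.0),
        sigma2_w=msw,
        csh=csh,
        truncated=bool(truncated),
    )


def pst(components: PSTComponents) -> float:
    """Point evaluation of P_ST = csh*s2b / (csh*s2b + 2*s2w)."""
    if components.csh <= 0:
        raise ValueError("csh must be positive")
    b, w = components.sigma2_b, components.sigma2_w
    if b == 0.0 and w == 0.0:
        raise ValueError("both variance components are zero; P_ST undefined")
    num = components.csh * b
    return float(num / (num + 2.0 * w))


def pst_bootstrap(
    trait_values: np.ndarray,
    group_labels: np.ndarray,
    n_boot: int = 1000,
    level: float = 0.95,
    csh: float = 1.0,
    seed: int = 0,
    trait: str = "trait",
) -> PSTResult:
    """Percentile-bootstrap P_ST: individuals resampled with replacement
    within groups; the point estimate comes from the unresampled data.

    A degenerate resample in which some group is constant (its within
    variance collapses) is redrawn; the redraw count is logged and
    reported.
    """
    groups = _split_groups(trait_values, group_labels)
    point = pst(_components_from_arrays(groups, csh))
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    redrawn = 0
    for b in range(n_boot):
        for _attempt in range(1000):
            resampled = [g[rng.integers(0, g.size, size=g.size)] for g in groups]
            if all(np.ptp(g) > 0 for g in resampled):
                break
            redrawn += 1
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap resample")
        boots[b] = pst(_components_from_arrays(resampled, csh))
    if redrawn:
        log.info("redrew %d degenerate bootstrap resamples", redrawn)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(boots, [100 * alpha, 100 * (1 - alpha)])
    return PSTResult(
        trait=trait,
        pst=point,
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        redrawn_resamples=redrawn,
    )


def compare_pst_fst(result: PSTResult, fst_genomewide: float) -> PSTResult:
    """Classify trait divergence against neutral expectation.

    selection: CI entirely above genome-wide F_ST; drift: CI contains it;
    inconclusive (flagged as unexpected): CI entirely below it.
    """
    verdict = "drift"
    if result.ci_low > fst_genomewide:
        verdict = "selection"
    elif result.ci_high < fst_genomewide:
        verdict = "inconclusive"
        log.warning(
            "trait %s: P_ST CI [%.3f, %.3f] entirely below F_ST=%.3f "
            "(unexpected under the drift/selection dichotomy)",
            result.trait,
            result.ci_low,
            result.ci_high,
            fst_genomewide,
        )
    result.fst_genomewide = float(fst_genomewide)
    result.verdict = verdict
    return result
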