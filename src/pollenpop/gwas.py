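"""SNP heritability and iterative association scanning.

Three pieces:

* a VanRaden genetic relationship matrix (GRM);
* single-component GREML — average-information (AI) REML updates with an
  expectation-maximization fallback — estimating the SNP heritability
  h2 = sigma2_g / (sigma2_g + sigma2_e) with a delta-method standard error;
* an iterative association scan in the FarmCPU mould: a fixed-effect
  per-marker test alternating with a random-effect kinship model used to
  select pseudo-QTL covariates, plus the two resampling validation
  wrappers (repeated 95% subsampling and phenotype permutation) and
  +/-5 Mb candidate-window assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genotypes import GenotypeTable

log = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# GRM
# ----------------------------------------------------------------------

@dataclass
class GRM:
    matrix: np.ndarray
    n_snps_used: int


def compute_grm(geno: GenotypeTable) -> GRM:
    """VanRaden relationship matrix.

    A_jk = (1/m) sum_i (x_ij - 2p_i)(x_ik - 2p_i) / (2 p_i (1 - p_i)),
    with missing genotypes imputed to their site mean 2p_i. Requires every
    site polymorphic (apply a MAF filter first).
    """
    p = geno.allele_freq()
    if np.any(~np.isfinite(p) | (p <= 0.0) | (p >= 1.0)):
        raise ValueError("monomorphic site(s) in GRM input; apply a MAF filter")
    x = geno.dosage_matrix(impute="mean")
    z = (x - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    return GRM(matrix=(z @ z.T) / geno.n_sites, n_snps_used=geno.n_sites)


# ----------------------------------------------------------------------
# GREML
# ----------------------------------------------------------------------

@dataclass
class REMLResult:
    sigma2_g: float
    sigma2_e: float
    h2: float
    se_h2: float
    loglik: float
    n_iter: int


class REMLConvergenceError(RuntimeError):
    """REML failed to converge; carries the log-likelihood trajectory."""

    def __init__(self, message: str, trajectory: list[float]):
        super().__init__(message)
        self.trajectory = trajectory


def reml_h2(
    grm: GRM,
    phenotype: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> REMLResult:
    """GREML for the model y = mu + g + e with g ~ N(0, sigma2_g * K).

    The GRM is eigendecomposed once; each AI/EM iteration then costs O(n).
    An AI step is attempted first and replaced by an EM step whenever it
    would leave the parameter space or decrease the restricted likelihood.
    Convergence: relative log-likelihood change < ``tol``.
    """
    y = np.asarray(phenotype, dtype=float)
    n = y.size
    vary = float(np.var(y, ddof=1))
    if vary <= 0:
        raise ValueError("phenotype has zero variance")
    lam, u = np.linalg.eigh(grm.matrix)
    lam = np.clip(lam, 0.0, None)
    if np.ptp(lam) < 1e-8:
        raise ValueError(
            "GRM is (numerically) proportional to the identity; "
            "heritability is unidentifiable"
        )
    yt = u.T @ y
    xt = u.T @ np.ones(n)  # intercept, rotated

    floor = 1e-6 * vary

    def quantities(sg: float, se: float):
        v = sg * lam + se
        d = 1.0 / v
        dx = d * xt
        c = float(xt @ dx)          # X' V^-1 X (scalar, intercept only)
        alpha = float(dx @ yt) / c

        def pvec(t: np.ndarray) -> np.ndarray:
            dt = d * t
            return dt - dx * (float(dx @ t) / c)

        py = pvec(yt)
        ypy = float(yt @ py)
        ll = -0.5 * (float(np.log(v).sum()) + np.log(c) + ypy)
        # tr(P K) and tr(P I)
        tr_pk = float((d * lam).sum()) - float((dx * lam) @ dx) / c
        tr_pi = float(d.sum()) - float(dx @ dx) / c
        return py, pvec, ypy, ll, tr_pk, tr_pi

    sg = se = vary / 2.0
    traj: list[float] = []
    ll_old = -np.inf
    ai = np.eye(2)
    converged = False
    for it in range(1, max_iter + 1):
        py, pvec, ypy, ll, tr_pk, tr_pi = quantities(sg, se)
        traj.append(ll)
        if it > 1 and abs(ll - ll_old) < tol * max(1.0, abs(ll)):
            converged = True
            n_iter = it
            break
        ll_old = ll

        kpy = lam * py
        pkpy = pvec(kpy)
        pipy = pvec(py)
        score = np.array(
            [-0.5 * (tr_pk - float(py @ kpy)), -0.5 * (tr_pi - float(py @ py))]
        )
        ai = 0.5 * np.array(
            [
                [float(kpy @ pkpy), float(kpy @ pipy)],
                [float(py @ pkpy), float(py @ pipy)],
            ]
        )
        stepped = False
        try:
            delta = np.linalg.solve(ai, score)
            # truncated AI proposal with step halving on likelihood decrease
            for factor in (1.0, 0.5, 0.25, 0.1):
                cand = np.maximum(np.array([sg, se]) + factor * delta, floor)
                ll_cand = quantities(*cand)[3]
                if ll_cand >= ll - 1e-10:
                    sg, se = cand
                    stepped = True
                    break
        except np.linalg.LinAlgError:
            pass
        if not stepped:  # EM fallback: guaranteed uphill, stays positive
            sg = max(sg + sg**2 * (float(py @ kpy) - tr_pk) / n, floor)
            se = max(se + se**2 * (float(py @ py) - tr_pi) / n, floor)
    else:
        raise REMLConvergenceError(
            f"REML did not converge in {max_iter} iterations", traj
        )
    if not converged:
        n_iter = max_iter

    total = sg + se
    h2 = sg / total
    try:
        ai_inv = np.linalg.inv(ai)
        grad = np.array([se, -sg]) / total**2
        var_h2 = float(grad @ ai_inv @ grad)
        se_h2 = float(np.sqrt(max(var_h2, 0.0)))
    except np.linalg.LinAlgError:
        se_h2 = float("nan")
    return REMLResult(
        sigma2_g=float(sg),
        sigma2_e=float(se),
        h2=float(h2),
        se_h2=se_h2,
        loglik=float(traj[-1]),
        n_iter=n_iter,
    )


# ----------------------------------------------------------------------
# FarmCPU-style scan
# ----------------------------------------------------------------------

@dataclass
class GWASResult:
    pvalues: np.ndarray
    effects: np.ndarray
    maf: np.ndarray
    pseudo_qtls: list[list[int]]   # selected covariate SNPs per iteration
    threshold: float
    significant: list[int]
    pve: dict[int, float]
    n_iter: int


def _drop_collinear(c: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """QR-based removal of (near-)collinear covariate columns."""
    keep: list[int] = []
    for j in range(c.shape[1]):
        trial = c[:, keep + [j]]
        if np.linalg.matrix_rank(trial, tol=1e-8) == len(keep) + 1:
            keep.append(j)
        else:
            log.warning("dropping collinear covariate column %d", j)
    return c[:, keep], keep


def _marker_tests(
    y: np.ndarray, x: np.ndarray, covariates: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-marker OLS t-tests given a fixed covariate design.

    Returns (p-values, effect estimates). Monomorphic markers (zero
    residual variance after projection) get p = 1, effect 0.
    """
    n = y.size
    c, _ = _drop_collinear(covariates)
    q, _r = np.linalg.qr(c)
    yr = y - q @ (q.T @ y)
    xr = x - q @ (q.T @ x)
    sxx = np.einsum("ij,ij->j", xr, xr)
    sxy = xr.T @ yr
    syy = float(yr @ yr)
    df = n - c.shape[1] - 1
    if df <= 0:
        raise ValueError("not enough residual degrees of freedom for marker tests")
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(sxx > 1e-12, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
        rss = syy - beta * sxy
        sigma2 = np.clip(rss, 0.0, None) / df
        se = np.sqrt(np.where(sxx > 1e-12, sigma2 / np.where(sxx > 0, sxx, 1.0), np.inf))
        t = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(sxx > 1e-12, np.clip(p, np.finfo(float).tiny, 1.0), 1.0)
    return p, beta


def _lowrank_ml_loglik(y: np.ndarray, z: np.ndarray) -> float:
    """Profiled Gaussian log-likelihood of y = mu + u + e, u ~ N(0, s2g ZZ'/t).

    Low-rank Woodbury evaluation; the variance ratio is profiled over a
    fixed h2 grid and the residual variance analytically. Used to rank
    candidate pseudo-QTL sets, where Z holds the standardized candidate
    dosages.
    """
    yc = y - y.mean()
    n = y.size
    t = z.shape[1]
    ztz = z.T @ z
    zty = z.T @ yc
    yy = float(yc @ yc)
    best = -np.inf
    for h2 in np.linspace(0.0, 0.98, 25):
        if h2 == 0.0:
            quad = yy
            logdet = 0.0
        else:
            gamma = h2 / (1.0 - h2)
            a = ztz + (t / gamma) * np.eye(t)
            try:
                sol = np.linalg.solve(a, zty)
            except np.linalg.LinAlgError:
                continue
            quad = yy - float(zty @ sol)
            sign, ld = np.linalg.slogdet(np.eye(t) + (gamma / t) * ztz)
            if sign <= 0:
                continue
            logdet = ld
        if quad <= 0:
            continue
        s2 = quad / n
        ll = -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)
        best = max(best, ll)
    return best


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd


def farmcpu_scan(
    geno: GenotypeTable,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    max_iter: int = 10,
    bin_size: int = 10_000_000,
    candidacy_p: float = 1e-4,
    alpha: float = 0.05,
    max_pseudo_qtls: int = 15,
) -> GWASResult:
    """Iterative fixed-effect scan with model-selected pseudo-QTL covariates.

    Iteration 0 tests every SNP by least squares given the base covariates.
    The genome is then split into ``bin_size`` bins; the most significant
    SNP per bin below ``candidacy_p`` becomes a pseudo-QTL candidate, and
    the candidate set actually used is the p-ordered prefix maximizing the
    likelihood of the random-effect model y = u + e with kinship built from
    those SNPs. Subsequent iterations re-test every SNP with the selected
    pseudo-QTLs as fixed covariates, excluding any pseudo-QTL lying in the
    tested SNP's own bin. The loop stops when the pseudo-QTL set repeats or
    ``max_iter`` is reached. Significance is Bonferroni at ``alpha`` over
    the tested SNP count; per-significant-SNP PVE is the R-squared
    increment of adding the SNP to the final covariate model.
    """
    y = np.asarray(phenotype, dtype=float)
    n = y.size
    if n != geno.n_individuals:
        raise ValueError("phenotype length does not match genotype table")
    if n < 30:
        raise ValueError(f"need at least 30 individuals, got {n}")
    if np.var(y) <= 0:
        raise ValueError("phenotype has zero variance")
    m = geno.n_sites
    x = geno.dosage_matrix(impute="mean")
    p_freq = geno.allele_freq()
    maf = np.minimum(p_freq, 1.0 - p_freq)

    base = np.ones((n, 1))
    if covariates is not None:
        base = np.column_stack([base, np.asarray(covariates, dtype=float)])

    chrom_codes = np.unique(geno.chrom.astype(str), return_inverse=True)[1]
    bin_ids = chrom_codes.astype(np.int64) * 10_000 + geno.pos // bin_size

    pseudo: list[int] = []
    history: list[list[int]] = []
    seen: set[tuple[int, ...]] = set()
    pvals = np.ones(m)
    effects = np.zeros(m)
    n_iter = 0
    for it in range(max_iter + 1):
        n_iter = it + 1
        cov = base if not pseudo else np.column_stack([base, x[:, pseudo]])
        pvals, effects = _marker_tests(y, x, cov)
        # re-test SNPs sharing a bin with a pseudo-QTL without that covariate
        for q in pseudo:
            in_bin = np.flatnonzero(bin_ids == bin_ids[q])
            others = [s for s in pseudo if s != q]
            cov_q = base if not others else np.column_stack([base, x[:, others]])
            p_q, b_q = _marker_tests(y, x[:, in_bin], cov_q)
            pvals[in_bin] = p_q
            effects[in_bin] = b_q

        # pseudo-QTL candidacy: best sub-threshold SNP per bin
        cand_mask = pvals < candidacy_p
        candidates: list[int] = []
        for b in np.unique(bin_ids[cand_mask]):
            members = np.flatnonzero((bin_ids == b) & cand_mask)
            candidates.append(int(members[np.argmin(pvals[members])]))
        candidates.sort(key=lambda j: pvals[j])
        candidates = candidates[:max_pseudo_qtls]

        if not candidates:
            new_pseudo: list[int] = []
        else:
            best_ll, best_t = -np.inf, 1
            zs = _standardize(x[:, candidates])
            for t in range(1, len(candidates) + 1):
                ll = _lowrank_ml_loglik(y, zs[:, :t])
                if ll > best_ll:
                    best_ll, best_t = ll, t
            new_pseudo = sorted(candidates[:best_t])

        history.append(new_pseudo)
        key = tuple(new_pseudo)
        if key == tuple(sorted(pseudo)) or key in seen:
            pseudo = new_pseudo
            break
        seen.add(tuple(sorted(pseudo)))
        pseudo = new_pseudo

    threshold = alpha / m
    significant = [int(j) for j in np.flatnonzero(pvals < threshold)]

    pve: dict[int, float] = {}
    for j in significant:
        others = [s for s in pseudo if bin_ids[s] != bin_ids[j]]
        cov = base if not others else np.column_stack([base, x[:, others]])
        c, _ = _drop_collinear(cov)
        q, _r = np.linalg.qr(c)
        yr = y - q @ (q.T @ y)
        xr = x[:, j] - q @ (q.T @ x[:, j])
        syy = float(yr @ yr)
        sxx = float(xr @ xr)
        tot = float(((y - y.mean()) ** 2).sum())
        if sxx > 1e-12 and tot > 0:
            pve[j] = float((xr @ yr) ** 2 / sxx / tot)
        else:
            pve[j] = 0.0

    return GWASResult(
        pvalues=pvals,
        effects=effects,
        maf=maf,
        pseudo_qtls=history,
        threshold=threshold,
        significant=significant,
        pve=pve,
        n_iter=n_iter,
    )


# ----------------------------------------------------------------------
# resampling validation
# ----------------------------------------------------------------------

@dataclass
class ValidationResult:
    detection_rate: np.ndarray | None = None
    permutation_fp_rate: float = float("nan")
    significant_by_run: list[list[int]] = field(default_factory=list)
    n_runs: int = 0


def subsample_detection_rate(
    geno: GenotypeTable,
    phenotype: np.ndarray,
    n_runs: int = 1000,
    frac: float = 0.95,
    seed: int = 0,
    **scan_kwargs,
) -> ValidationResult:
    """Per-SNP detection rate over repeated random subsampling scans.

    Each run keeps a random ``frac`` of individuals and re-runs the full
    scan; a SNP's detection rate is the fraction of runs in which it
    exceeds the Bonferroni threshold.
    """
    if not 0.0 < frac < 1.0:
        raise ValueError(f"frac={frac} outside (0, 1)")
    y = np.asarray(phenotype, dtype=float)
    rng = np.random.default_rng(seed)
    n = geno.n_individuals
    k = max(int(round(frac * n)), 2)
    hits = np.zeros(geno.n_sites)
    by_run = []
    for _ in range(n_runs):
        idx = np.sort(rng.choice(n, size=k, replace=False))
        sub = geno.take_individuals([geno.individuals[i] for i in idx])
        res = farmcpu_scan(sub, y[idx], **scan_kwargs)
        hits[res.significant] += 1
        by_run.append(res.significant)
    return ValidationResult(
        detection_rate=hits / n_runs, significant_by_run=by_run, n_runs=n_runs
    )


def permutation_null(
    geno: GenotypeTable,
    phenotype: np.ndarray,
    n_runs: int = 1000,
    seed: int = 0,
    perms: list[np.ndarray] | None = None,
    **scan_kwargs,
) -> ValidationResult:
    """Experiment-wise false-positive rate under phenotype permutation.

    Phenotype labels are shuffled in each run (or taken from ``perms`` if
    given, e.g. to check that the identity permutation reproduces the
    unpermuted scan); the result records which runs produced any
    Bonferroni-significant SNP and which SNPs those were.
    """
    y = np.asarray(phenotype, dtype=float)
    rng = np.random.default_rng(seed)
    n = y.size
    if perms is None:
        perms = [rng.permutation(n) for _ in range(n_runs)]
    by_run = []
    any_sig = 0
    constant = np.var(y) <= 0  # a constant trait can associate with nothing
    for perm in perms:
        if constant:
            by_run.append([])
            continue
        res = farmcpu_scan(geno, y[np.asarray(perm)], **scan_kwargs)
        by_run.append(res.significant)
        any_sig += bool(res.significant)
    n_runs = len(perms)
    return ValidationResult(
        permutation_fp_rate=any_sig / n_runs,
        significant_by_run=by_run,
        n_runs=n_runs,
    )


def candidate_windows(
    significant_snps: list[tuple[str, int]],
    chrom_lengths: dict[str, int],
    window: int = 5_000_000,
) -> list[tuple[str, int, int]]:
    """Closed +/-``window`` interval around each significant SNP, clipped
    to [1, chromosome length]."""
    out = []
    for chrom, pos in significant_snps:
        length = chrom_lengths[str(chrom)]
        out.append((str(chrom), max(1, pos - window), min(length, pos + window)))
    return out
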