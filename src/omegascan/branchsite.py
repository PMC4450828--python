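"""Branch-site model A positive-selection scan.

The scan fits, for a designated foreground branch, the four-class
branch-site model A (classes: purifying omega0 everywhere; neutral
everywhere; omega0 background with omega2 >= 1 on the foreground;
neutral background with omega2 on the foreground) and its null with
omega2 fixed at 1, compares them by a likelihood ratio test against
chi-square with 1 df, and computes Bayes empirical Bayes (BEB) per-site
posteriors of the positively selected classes by averaging over a
discrete prior grid on (p0, p1, omega0, omega2).

Branch lengths and kappa are estimated once under the one-ratio model
and held fixed for both branch-site fits (see docs/methods.md).  During
those fits the per-branch rate normalisation is recomputed from the
current mixture, so a branch length always means "expected substitutions
per codon under the model being scored" (the codeml convention); for the
BEB averaging the normalisation is frozen at the alternative-model MLE —
grid points re-weight the site classes but do not re-time the tree.

A gene is called a PSG when all three of the strict criteria hold:
LRT p < 0.05, fitted foreground omega2 > 1, and at least one site with
BEB posterior > 0.95.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

from .alignment import CodonAlignment
from .freeratio import fit_one_ratio
from .likelihood import SiteClassModel, TreeLikelihood
from .model import CodonModelParams
from .trees import PhyloTree

log = logging.getLogger(__name__)

OMEGA0_BOUNDS = (1e-4, 0.999)
OMEGA2_BOUNDS = (1.0, 50.0)


@dataclass
class BranchSiteFit:
    """Alternative + null branch-site fits and the derived PSG verdict."""

    gene_id: str
    foreground: str
    p0: float
    p1: float
    omega0: float
    omega2: float
    lnL_alt: float
    lnL_null: float
    two_delta: float
    p_value: float
    beb_posterior: np.ndarray        # P(class 2a or 2b | site), per codon
    sites_gt95: list[int]            # 1-based codon positions, posterior > 0.95
    psg: bool = False
    reasons: dict[str, bool] = field(default_factory=dict)
    alignment_error_screen: bool = False   # True when dropped by the screen
    kappa: float = float("nan")

    @property
    def class_proportions(self) -> np.ndarray:
        p2 = max(0.0, 1.0 - self.p0 - self.p1)
        split = self.p0 / (self.p0 + self.p1) if self.p0 + self.p1 > 0 else 0.5
        return np.array([self.p0, self.p1, p2 * split, p2 * (1 - split)])


def _stick(u0: float, u1: float) -> tuple[float, float]:
    """Map two (0,1) variables to (p0, p1) with p0 + p1 <= 1."""
    p0 = u0
    p1 = (1.0 - u0) * u1
    return p0, p1


def _stick_inverse(p0: float, p1: float) -> list[float]:
    eps = 1e-4
    u0 = min(max(p0, eps), 1 - eps)
    u1 = min(max(p1 / (1.0 - u0), eps), 1 - eps)
    return [u0, u1]


def _fit_mixture(
    engine: TreeLikelihood,
    tree: PhyloTree,
    params: CodonModelParams,
    lengths: np.ndarray,
    fix_omega2: bool,
    n_starts: int,
    seed: int,
    tol: float,
    maxiter: int,
    warm_starts: list | None = None,
):
    """Optimize (p0, p1, omega0[, omega2]) of model A at fixed branches."""
    rng = np.random.default_rng(seed)

    def build(x):
        p0, p1 = _stick(x[0], x[1])
        w0 = x[2]
        w2 = 1.0 if fix_omega2 else x[3]
        return p0, p1, w0, w2

    def negll(x):
        p0, p1, w0, w2 = build(x)
        mix = SiteClassModel.model_a(p0, p1, w0, w2, tree)
        # scales recomputed from the current mixture: a branch length is
        # expected substitutions per codon under the model being scored
        ll = engine.log_likelihood(params, mix, lengths=lengths)
        return -ll if np.isfinite(ll) else np.inf

    eps = 1e-4
    bounds = [(eps, 1 - eps), (eps, 1 - eps), OMEGA0_BOUNDS]
    if not fix_omega2:
        bounds.append(OMEGA2_BOUNDS)
    base = [0.7, 0.8, 0.2] + ([2.0] if not fix_omega2 else [])
    x0s = [np.array(base)]
    presets = [
        [0.45, 0.5, 0.5] + ([1.05] if not fix_omega2 else []),
        [0.9, 0.9, 0.1] + ([5.0] if not fix_omega2 else []),
    ]
    for p in presets[: max(0, n_starts - 1)]:
        x0s.append(np.array(p))
    while len(x0s) < n_starts:
        draw = [rng.uniform(0.1, 0.9), rng.uniform(0.1, 0.9),
                rng.uniform(0.05, 0.9)]
        if not fix_omega2:
            draw.append(np.exp(rng.uniform(np.log(1.01), np.log(10.0))))
        x0s.append(np.array(draw))
    for w in warm_starts or []:
        x0s.append(np.asarray(w, dtype=float))
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    best = None
    for x0 in x0s:
        res = minimize(
            negll,
            np.clip(x0, lo, hi),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": tol, "gtol": 1e-7, "maxiter": maxiter},
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise FloatingPointError("branch-site optimisation failed from every start")
    p0, p1, w0, w2 = build(best.x)
    return -best.fun, p0, p1, w0, w2


def _one_ratio_stage(aln, tree, freq_scheme, seed, tol):
    """Branch lengths, kappa and pi estimated under the one-ratio model."""
    lnL0, w_m0, lengths, kappa, utree, params = fit_one_ratio(
        aln, tree, freq_scheme=freq_scheme, seed=seed, tol=tol
    )
    if tree.foreground is None:
        raise ValueError(f"gene {aln.gene_id!r}: no foreground branch flagged")
    return lengths, kappa, utree, params


def fit_model_a(
    aln: CodonAlignment,
    tree: PhyloTree,
    foreground: str | None = None,
    freq_scheme: str = "f3x4",
    fix_omega2: bool = False,
    n_starts: int = 5,
    seed: int = 0,
    tol: float = 1e-8,
    maxiter: int = 300,
    _stage=None,
    _warm_starts=None,
):
    """Fit branch-site model A (or its null with ``fix_omega2=True``).

    Returns ``(lnL, {p0, p1, omega0, omega2, kappa}, posteriors)`` where
    posteriors is the per-site posterior matrix over the four classes at
    the MLE (naive empirical Bayes; use :func:`beb_posteriors` for the
    BEB version used by the PSG filter).
    """
    if foreground is not None:
        tree = tree.with_foreground(foreground)
    if tree.foreground is None:
        raise ValueError("a foreground branch must be flagged or named")
    stage = _stage or _one_ratio_stage(aln, tree, freq_scheme, seed, tol)
    lengths, kappa, utree, params = stage
    engine = TreeLikelihood(aln, utree)
    warm = list(_warm_starts or [])
    if not fix_omega2 and not warm:
        # the omega2 = 1 boundary is an attractor under the null; seeding
        # the alternative from the null optimum guarantees nesting
        _, n_p0, n_p1, n_w0, _ = _fit_mixture(
            engine, utree, params, lengths, fix_omega2=True,
            n_starts=2, seed=seed + 17, tol=tol, maxiter=maxiter,
        )
        warm.append(_stick_inverse(n_p0, n_p1) + [n_w0, 1.0])
    lnL, p0, p1, w0, w2 = _fit_mixture(
        engine, utree, params, lengths,
        fix_omega2=fix_omega2, n_starts=n_starts, seed=seed + 17,
        tol=tol, maxiter=maxiter, warm_starts=warm,
    )
    mix = SiteClassModel.model_a(p0, p1, w0, w2, utree)
    post = engine.site_class_posteriors(params, mix, lengths=lengths)
    est = {"p0": p0, "p1": p1, "omega0": w0, "omega2": w2, "kappa": kappa}
    return lnL, est, post


def fit_null_model_a(aln, tree, foreground=None, **kw):
    """Null branch-site fit: omega2 fixed at 1.  Returns lnL only."""
    lnL, _, _ = fit_model_a(aln, tree, foreground, fix_omega2=True,
                            n_starts=max(2, kw.pop("n_starts", 3)), **kw)
    return lnL


def lrt(lnL_alt: float, lnL_null: float) -> tuple[float, float]:
    """Likelihood ratio test of the branch-site pair against chi2(1).

    2*Delta is clipped at 0 (the models are nested; small negative values
    are optimizer noise).  chi2(1) rather than the 50:50 boundary mixture
    is used, the conservative common practice.
    """
    if not (np.isfinite(lnL_alt) and np.isfinite(lnL_null)):
        raise ValueError("log-likelihoods must be finite")
    two_delta = max(0.0, 2.0 * (lnL_alt - lnL_null))
    return two_delta, float(chi2.sf(two_delta, df=1))


# ----------------------------------------------------------------------
# Bayes empirical Bayes
# ----------------------------------------------------------------------

def beb_posteriors(
    aln: CodonAlignment,
    tree: PhyloTree,
    foreground: str | None,
    mle: dict,
    grid_size: int = 10,
    freq_scheme: str = "f3x4",
    seed: int = 0,
    tol: float = 1e-8,
    _stage=None,
) -> np.ndarray:
    """Per-site posterior of the positively selected classes (2a + 2b).

    Averages over a uniform discrete prior grid: ``grid_size`` points per
    dimension for omega0 in (0, 1) and omega2 in [1, 11), and the
    triangular (p0, p1) grid with the same resolution.  Branch lengths,
    kappa, pi, and per-branch scalings stay at their MLEs; only the four
    mixture parameters are integrated out, weighting every grid point by
    its data likelihood.
    """
    if foreground is not None:
        tree = tree.with_foreground(foreground)
    if tree.foreground is None:
        raise ValueError("a foreground branch must be flagged or named")
    if mle is None:
        raise ValueError("fit the alternative model first")
    stage = _stage or _one_ratio_stage(aln, tree, freq_scheme, seed, tol)
    lengths, kappa, utree, params = stage
    engine = TreeLikelihood(aln, utree)
    # branch durations frozen at the alternative-model MLE: grid points
    # re-weight the site classes but do not re-time the tree
    mix_mle = SiteClassModel.model_a(
        mle["p0"], mle["p1"], mle["omega0"], mle["omega2"], utree
    )
    scales = engine._branch_scales(params, mix_mle)
    G = grid_size
    w0_grid = (np.arange(G) + 0.5) / G            # (0, 1)
    w2_grid = 1.0 + 10.0 * (np.arange(G) + 0.5) / G  # [1, 11)

    # class-conditional log site likelihoods for every needed omega pair
    def class_logf(omega_bg: float, omega_fg: float) -> np.ndarray:
        om = np.full(utree.n_nodes, omega_bg)
        om[utree.foreground] = omega_fg
        eig_cache = {}
        return engine._class_log_site_likelihoods(
            params, om, scales, eig_cache, lengths
        )

    npat = engine.patterns.shape[1]
    logf0 = np.stack([class_logf(w, w) for w in w0_grid])          # (G, npat)
    logf1 = class_logf(1.0, 1.0)                                   # (npat,)
    logf2a = np.stack([
        np.stack([class_logf(w0, w2) for w2 in w2_grid]) for w0 in w0_grid
    ])                                                             # (G, G, npat)
    logf2b = np.stack([class_logf(1.0, w2) for w2 in w2_grid])     # (G, npat)

    # triangular proportion grid
    pairs = [
        ((i + 0.5) / G, (j + 0.5) / G)
        for i in range(G)
        for j in range(G)
        if (i + 0.5) / G + (j + 0.5) / G < 1.0
    ]
    weights = engine.weights
    post_num = np.zeros(npat)   # sum_g w_g P(2a or 2b | site, g)
    log_marg = []
    posts = []
    for p0, p1 in pairs:
        p2 = 1.0 - p0 - p1
        split = p0 / (p0 + p1)
        props = np.array([p0, p1, p2 * split, p2 * (1 - split)])
        logp = np.log(props)
        for i in range(G):
            for j in range(G):
                stackd = np.stack([
                    logp[0] + logf0[i],
                    np.full(npat, logp[1]) + logf1,
                    logp[2] + logf2a[i, j],
                    logp[3] + logf2b[j],
                ])
                m = stackd.max(axis=0)
                lik = np.exp(stackd - m)
                tot = lik.sum(axis=0)
                site_post = (lik[2] + lik[3]) / tot
                log_sites = m + np.log(tot)
                log_marg.append(float(np.dot(weights, log_sites)))
                posts.append(site_post)
    log_marg = np.asarray(log_marg)
    log_w = log_marg - log_marg.max()
    w = np.exp(log_w)
    w /= w.sum()
    post_pat = np.einsum("g,gp->p", w, np.asarray(posts))
    return post_pat[engine.site_to_pattern]


# ----------------------------------------------------------------------
# scan driver, PSG classification, alignment-error screen
# ----------------------------------------------------------------------

def branch_site_scan(
    aln: CodonAlignment,
    tree: PhyloTree,
    foreground: str,
    freq_scheme: str = "f3x4",
    n_starts_alt: int = 5,
    seed: int = 0,
    tol: float = 1e-8,
    alpha: float = 0.05,
    post_min: float = 0.95,
    omega_min: float = 1.0,
    beb_grid: int = 10,
    qc_window: int = 5,
) -> BranchSiteFit:
    """Full branch-site test of one gene on one foreground lineage."""
    ftree = tree.with_foreground(foreground)
    stage = _one_ratio_stage(aln, ftree, freq_scheme, seed, tol)
    lnL_null, null_est, _ = fit_model_a(
        aln, ftree, freq_scheme=freq_scheme, fix_omega2=True,
        n_starts=3, seed=seed, tol=tol, _stage=stage,
    )
    warm = [_stick_inverse(null_est["p0"], null_est["p1"])
            + [null_est["omega0"], 1.0]]
    lnL_alt, est, _ = fit_model_a(
        aln, ftree, freq_scheme=freq_scheme, n_starts=n_starts_alt,
        seed=seed, tol=tol, _stage=stage, _warm_starts=warm,
    )
    two_delta, p = lrt(lnL_alt, lnL_null)
    beb = beb_posteriors(aln, ftree, None, est, grid_size=beb_grid,
                         freq_scheme=freq_scheme, seed=seed, tol=tol,
                         _stage=stage)
    sites = [int(i) + 1 for i in np.nonzero(beb > post_min)[0]]
    fit = BranchSiteFit(
        gene_id=aln.gene_id,
        foreground=foreground,
        p0=est["p0"],
        p1=est["p1"],
        omega0=est["omega0"],
        omega2=est["omega2"],
        lnL_alt=lnL_alt,
        lnL_null=lnL_null,
        two_delta=two_delta,
        p_value=p,
        beb_posterior=beb,
        sites_gt95=sites,
        kappa=est["kappa"],
    )
    classify_psg(fit, alpha=alpha, omega_min=omega_min, post_min=post_min)
    if fit.psg and aln.removed_columns is not None and len(aln.removed_columns):
        screen_alignment_errors(fit, aln.removed_columns, window=qc_window)
    return fit


def classify_psg(
    fit: BranchSiteFit,
    alpha: float = 0.05,
    omega_min: float = 1.0,
    post_min: float = 0.95,
) -> BranchSiteFit:
    """Apply the strict PSG criteria, recording each pass/fail.

    PSG iff: foreground omega2 strictly greater than ``omega_min`` (1),
    at least one site with BEB posterior strictly above ``post_min``
    (0.95), and LRT p strictly below ``alpha`` (0.05).
    """
    reasons = {
        "omega2_gt_1": fit.omega2 > omega_min,
        "site_posterior_gt_0.95": bool((fit.beb_posterior > post_min).any()),
        "lrt_p_lt_0.05": fit.p_value < alpha,
    }
    fit.reasons = reasons
    fit.psg = all(reasons.values())
    return fit


def screen_alignment_errors(
    fit: BranchSiteFit, removed_columns: np.ndarray, window: int = 5
) -> BranchSiteFit:
    """Automated stand-in for manual alignment curation.

    A candidate PSG whose every supporting site (BEB > 0.95) lies within
    ``window`` codons of a column removed during QC is treated as a
    potential alignment artifact and dropped (flagged, verdict revoked).
    Positions here are in QC'd-alignment coordinates mapped back to the
    original columns.
    """
    if not fit.sites_gt95 or removed_columns is None or not len(removed_columns):
        return fit
    removed = np.asarray(removed_columns)
    n_orig = len(fit.beb_posterior) + len(removed)
    kept = np.setdiff1d(np.arange(n_orig), removed)
    suspicious = []
    for pos1 in fit.sites_gt95:
        orig = kept[pos1 - 1]
        suspicious.append(bool((np.abs(removed - orig) <= window).any()))
    if all(suspicious):
        fit.alignment_error_screen = True
        fit.psg = False
        fit.reasons["alignment_error_screen"] = False
        log.info("%s: PSG dropped by the alignment-error screen", fit.gene_id)
    return fit


def psg_table(fits: list[BranchSiteFit]) -> pd.DataFrame:
    rows = []
    for f in fits:
        rows.append(
            {
                "gene": f.gene_id,
                "lineage": f.foreground,
                "lnL_alt": f.lnL_alt,
                "lnL_null": f.lnL_null,
                "twoDelta": f.two_delta,
                "p": f.p_value,
                "omega2": f.omega2,
                "n_sites_gt95": len(f.sites_gt95),
                "sites_1based": ",".join(map(str, f.sites_gt95)),
                "verdict": f.psg,
                "reasons": ";".join(
                    f"{k}={'pass' if v else 'fail'}" for k, v in f.reasons.items()
                ),
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        from .accel import _benjamini_hochberg

        df["fdr"] = _benjamini_hochberg(df["p"].to_numpy())
    return df
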