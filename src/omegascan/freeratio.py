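"""Per-branch Ka/Ks estimation.

Two estimators live here:

* :func:`ng86_pairwise` — the Nei–Gojobori (1986) counting estimator with
  Jukes–Cantor correction, used as an independent cross-check on the
  likelihood machinery (it shares no code with the pruning engine).
* :func:`fit_free_ratio` — maximum likelihood under the codon model with
  an independent omega on every branch of the (unrooted) tree, the
  free-ratio model.  Fitted (t, omega) pairs are converted to per-branch
  Ka and Ks through the mutational-opportunity site counts.

Conventions for NG86: synonymous-site fractions exclude mutations to
stop codons from both numerator and denominator; multi-hit codons are
averaged over all minimal substitution pathways with pathways through
stop codons excluded and the weights renormalised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .alignment import CodonAlignment
from .genetics import GeneticCode, STANDARD_CODE
from .likelihood import SiteClassModel, TreeLikelihood
from .model import (
    CodonModelParams,
    codon_frequencies,
    count_site_opportunities,
    ka_ks_from_branch,
)
from .trees import PhyloTree

log = logging.getLogger(__name__)

# optimizer bounds (natural scale)
KAPPA_BOUNDS = (0.1, 50.0)
OMEGA_BOUNDS = (1e-4, 50.0)
T_BOUNDS = (1e-6, 20.0)


# ----------------------------------------------------------------------
# Nei–Gojobori 1986
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class NG86Result:
    ka: float
    ks: float
    S: float
    N: float
    Sd: float
    Nd: float
    #: saturation flags: True when the JC correction was undefined (p >= 3/4)
    ka_saturated: bool = False
    ks_saturated: bool = False


@lru_cache(maxsize=None)
def _syn_sites_per_codon(table_id: int) -> np.ndarray:
    """Synonymous sites of each sense codon (stop mutations excluded)."""
    code: GeneticCode = _code_by_id(table_id)
    out = np.zeros(code.n_sense)
    for i, codon in enumerate(code.codons):
        s = 0.0
        for pos in range(3):
            syn = 0
            valid = 0
            for n in "TCAG":
                if n == codon[pos]:
                    continue
                alt = codon[:pos] + n + codon[pos + 1 :]
                if code.is_stop(alt):
                    continue
                valid += 1
                if code.translate(alt) == code.translate(codon):
                    syn += 1
            if valid:
                s += syn / valid
        out[i] = s
    return out


@lru_cache(maxsize=None)
def _code_by_id(table_id: int) -> GeneticCode:
    from .genetics import get_code

    return get_code(table_id)


@lru_cache(maxsize=None)
def _pathway_counts(table_id: int, i: int, j: int) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between sense codons i, j,
    averaged over minimal substitution pathways that avoid stop codons."""
    code = _code_by_id(table_id)
    a, b = code.codons[i], code.codons[j]
    diffs = [k for k in range(3) if a[k] != b[k]]
    if not diffs:
        return 0.0, 0.0
    totals = []
    for order in permutations(diffs):
        cur = a
        syn = nsyn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if code.is_stop(nxt):
                ok = False
                break
            if code.translate(nxt) == code.translate(cur):
                syn += 1
            else:
                nsyn += 1
            cur = nxt
        if ok:
            totals.append((syn, nsyn))
    if not totals:  # every pathway crosses a stop; fall back to including them
        for order in permutations(diffs):
            cur = a
            syn = nsyn = 0
            for pos in order:
                nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
                same = (not code.is_stop(nxt) and not code.is_stop(cur)
                        and code.translate(nxt) == code.translate(cur))
                if same:
                    syn += 1
                else:
                    nsyn += 1
                cur = nxt
            totals.append((syn, nsyn))
    sd = sum(t[0] for t in totals) / len(totals)
    nd = sum(t[1] for t in totals) / len(totals)
    return sd, nd


def _jukes_cantor(p: float) -> tuple[float, bool]:
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        return float("nan"), True
    if p == 0:
        return 0.0, False
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0), False


def ng86_pairwise(
    seq1: np.ndarray | list[int],
    seq2: np.ndarray | list[int],
    code: GeneticCode = STANDARD_CODE,
) -> NG86Result:
    """Nei–Gojobori Ka/Ks between two equal-length sense-codon sequences.

    ``seq1``/``seq2`` are sense-codon state vectors (as in
    :class:`~omegascan.alignment.CodonAlignment`).  Returns per-gene site
    counts S and N (S + N = 3 x length), observed synonymous and
    nonsynonymous differences Sd and Nd (pathway-averaged), and the
    Jukes–Cantor-corrected rates.  When a proportion reaches the JC
    saturation point (p >= 3/4) the corresponding rate is NaN and
    flagged.
    """
    s1 = np.asarray(seq1, dtype=int)
    s2 = np.asarray(seq2, dtype=int)
    if s1.shape != s2.shape or s1.ndim != 1:
        raise ValueError("sequences must be equal-length 1-D codon vectors")
    if (s1 < 0).any() or (s2 < 0).any():
        raise ValueError("sequences must contain only sense codons (QC first)")
    sites = _syn_sites_per_codon(code.table_id)
    S = float((sites[s1] + sites[s2]).sum() / 2.0)
    N = 3.0 * len(s1) - S
    Sd = Nd = 0.0
    for i, j in zip(s1, s2):
        sd, nd = _pathway_counts(code.table_id, int(i), int(j))
        Sd += sd
        Nd += nd
    ks, ks_sat = _jukes_cantor(Sd / S) if S > 0 else (float("nan"), False)
    ka, ka_sat = _jukes_cantor(Nd / N) if N > 0 else (float("nan"), False)
    return NG86Result(ka=ka, ks=ks, S=S, N=N, Sd=Sd, Nd=Nd,
                      ka_saturated=ka_sat, ks_saturated=ks_sat)


# ----------------------------------------------------------------------
# Free-ratio maximum likelihood
# ----------------------------------------------------------------------

@dataclass
class BranchRates:
    """Free-ratio fit of one gene: per-branch rates on the unrooted tree."""

    gene_id: str
    branch_labels: list[str]
    t: np.ndarray
    omega: np.ndarray          # NaN where undefined (branch at zero length)
    ka: np.ndarray
    ks: np.ndarray
    n: np.ndarray              # expected nonsynonymous substitution counts
    s: np.ndarray              # expected synonymous substitution counts
    S_gene: float              # synonymous sites in the gene
    N_gene: float
    kappa: float
    lnL: float
    converged: bool
    n_codons: int
    freq_scheme: str = "f3x4"
    tree: PhyloTree = field(default=None, repr=False)
    params: CodonModelParams = field(default=None, repr=False)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.gene_id,
                "branch": self.branch_labels,
                "t": self.t,
                "omega": self.omega,
                "Ka": self.ka,
                "Ks": self.ks,
                "n": self.n,
                "s": self.s,
                "S": self.S_gene,
                "N": self.N_gene,
                "lnL": self.lnL,
                "converged": self.converged,
            }
        )


def _multistart_minimize(fun, x0s, bounds, tol, maxiter):
    best = None
    for x0 in x0s:
        res = minimize(
            fun,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": tol, "gtol": 1e-7, "maxiter": maxiter},
        )
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise FloatingPointError("optimizer failed from every start")
    return best


def fit_free_ratio(
    aln: CodonAlignment,
    tree: PhyloTree,
    freq_scheme: str = "f3x4",
    n_starts: int = 3,
    seed: int = 0,
    tol: float = 1e-8,
    maxiter: int = 500,
) -> BranchRates:
    """Joint ML fit of kappa, all branch lengths, and one omega per branch.

    The tree is collapsed to its unrooted form first (a degree-2 root's
    two branches are a single estimable branch).  Optimisation is
    multi-start bounded L-BFGS-B in log-parameter space; the best start
    wins.  Branches driven to the lower length bound carry no
    substitutions, so their omega is reported as NaN (undefined) rather
    than a pseudo-count.
    """
    if aln.n_taxa < 2:
        raise ValueError("free-ratio fit needs at least two taxa")
    utree = tree.unrooted()
    engine = TreeLikelihood(aln, utree)
    pi = codon_frequencies(aln.states, freq_scheme, aln.code)
    branches = utree.branch_nodes()
    B = len(branches)
    rng = np.random.default_rng(seed)

    def unpack(x):
        kappa = np.exp(x[0])
        t = np.exp(x[1 : 1 + B])
        w = np.exp(x[1 + B :])
        return kappa, t, w

    def negll(x):
        kappa, t, w = unpack(x)
        params = CodonModelParams(kappa=kappa, pi=pi, code=aln.code)
        lengths = np.zeros(utree.n_nodes)
        omegas = np.ones(utree.n_nodes)
        lengths[branches] = t
        omegas[branches] = w
        mix = SiteClassModel.single(omegas)
        try:
            ll = engine.log_likelihood(params, mix, lengths=lengths)
        except FloatingPointError:
            return np.inf
        return -ll if np.isfinite(ll) else np.inf

    t_init = np.clip(utree.lengths[branches], 0.02, 5.0)
    x0 = np.concatenate([[np.log(2.0)], np.log(t_init), np.full(B, np.log(0.5))])
    x0s = [x0]
    for k in range(1, n_starts):
        jitter = rng.normal(0.0, 0.5, size=x0.shape)
        alt = x0 + jitter
        alt[1 + B :] = np.log([0.2, 1.5][k % 2]) + rng.normal(0, 0.3, B)
        x0s.append(alt)
    lb = np.concatenate([
        [np.log(KAPPA_BOUNDS[0])], np.full(B, np.log(T_BOUNDS[0])),
        np.full(B, np.log(OMEGA_BOUNDS[0])),
    ])
    ub = np.concatenate([
        [np.log(KAPPA_BOUNDS[1])], np.full(B, np.log(T_BOUNDS[1])),
        np.full(B, np.log(OMEGA_BOUNDS[1])),
    ])
    x0s = [np.clip(x, lb, ub) for x in x0s]
    best = _multistart_minimize(negll, x0s, list(zip(lb, ub)), tol, maxiter)

    kappa, t, w = unpack(best.x)
    params = CodonModelParams(kappa=kappa, pi=pi, code=aln.code)
    S, N = count_site_opportunities(params)
    L = aln.n_codons
    ka = np.empty(B)
    ks = np.empty(B)
    omega = w.copy()
    for b in range(B):
        ka[b], ks[b] = ka_ks_from_branch(t[b], w[b], params)
    # a branch pinned at the lower length bound has no substitutions
    # (omega = 0/0), and one pinned at the omega ceiling has essentially
    # no synonymous substitutions (Ks = 0): both ratios are undefined
    # and reported as missing rather than a pseudo-value
    undefined = (t <= T_BOUNDS[0] * 1.5) | (w >= OMEGA_BOUNDS[1] * 0.999)
    omega[undefined] = np.nan
    # expected substitution numbers: per-site rate x per-gene sites
    n_counts = ka * N * L
    s_counts = ks * S * L
    return BranchRates(
        gene_id=aln.gene_id,
        branch_labels=[utree.branch_label(b) for b in branches],
        t=t,
        omega=omega,
        ka=ka,
        ks=ks,
        n=n_counts,
        s=s_counts,
        S_gene=S * L,  # per-codon sites x codons; S_gene + N_gene = 3L
        N_gene=N * L,
        kappa=kappa,
        lnL=-best.fun,
        converged=bool(best.success),
        n_codons=L,
        freq_scheme=freq_scheme,
        tree=utree,
        params=params,
    )


def fit_one_ratio(
    aln: CodonAlignment,
    tree: PhyloTree,
    freq_scheme: str = "f3x4",
    n_starts: int = 2,
    seed: int = 0,
    tol: float = 1e-8,
    maxiter: int = 500,
) -> tuple[float, float, np.ndarray, float, PhyloTree, CodonModelParams]:
    """One-ratio (M0) fit: single omega shared by all branches.

    Returns ``(lnL, omega, lengths_by_node, kappa, unrooted_tree, params)``.
    Used both as the nested null of the free-ratio model and as the
    branch-length stage of the branch-site scan.
    """
    utree = tree.unrooted()
    engine = TreeLikelihood(aln, utree)
    pi = codon_frequencies(aln.states, freq_scheme, aln.code)
    branches = utree.branch_nodes()
    B = len(branches)
    rng = np.random.default_rng(seed)

    def negll(x):
        kappa = np.exp(x[0])
        w = np.exp(x[1])
        t = np.exp(x[2:])
        params = CodonModelParams(kappa=kappa, pi=pi, code=aln.code)
        lengths = np.zeros(utree.n_nodes)
        lengths[branches] = t
        mix = SiteClassModel.one_ratio(w, utree)
        ll = engine.log_likelihood(params, mix, lengths=lengths)
        return -ll if np.isfinite(ll) else np.inf

    t_init = np.clip(utree.lengths[branches], 0.02, 5.0)
    x0 = np.concatenate([[np.log(2.0), np.log(0.4)], np.log(t_init)])
    x0s = [x0] + [
        x0 + rng.normal(0, 0.4, size=x0.shape) for _ in range(n_starts - 1)
    ]
    lb = np.concatenate([
        [np.log(KAPPA_BOUNDS[0]), np.log(OMEGA_BOUNDS[0])],
        np.full(B, np.log(T_BOUNDS[0])),
    ])
    ub = np.concatenate([
        [np.log(KAPPA_BOUNDS[1]), np.log(OMEGA_BOUNDS[1])],
        np.full(B, np.log(T_BOUNDS[1])),
    ])
    x0s = [np.clip(x, lb, ub) for x in x0s]
    best = _multistart_minimize(negll, x0s, list(zip(lb, ub)), tol, maxiter)
    kappa = float(np.exp(best.x[0]))
    omega = float(np.exp(best.x[1]))
    lengths = np.zeros(utree.n_nodes)
    lengths[branches] = np.exp(best.x[2:])
    params = CodonModelParams(kappa=kappa, pi=pi, code=aln.code)
    return -best.fun, omega, lengths, kappa, utree, params


def lineage_rates_table(
    genes: list[BranchRates], lineages: list[str]
) -> pd.DataFrame:
    """Tidy per-(gene, lineage) table of t, omega, Ka, Ks, n, s, S, N.

    Lineage labels are branch labels (taxon name for a terminal branch).
    Genes fitted on a topology lacking a requested lineage raise KeyError.
    Undefined omegas are carried as NaN.
    """
    rows = []
    for fit in genes:
        index = {lab: k for k, lab in enumerate(fit.branch_labels)}
        for lineage in lineages:
            if lineage not in index:
                raise KeyError(
                    f"gene {fit.gene_id!r} has no branch labelled {lineage!r}"
                )
            b = index[lineage]
            rows.append(
                {
                    "gene": fit.gene_id,
                    "lineage": lineage,
                    "t": fit.t[b],
                    "omega": fit.omega[b],
                    "Ka": fit.ka[b],
                    "Ks": fit.ks[b],
                    "n": fit.n[b],
                    "s": fit.s[b],
                    "S": fit.S_gene,
                    "N": fit.N_gene,
                    "lnL": fit.lnL,
                    "converged": fit.converged,
                }
            )
    return pd.DataFrame(rows)
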