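"""Felsenstein pruning likelihood for codon models with site-class mixtures.

The engine works on unique site patterns with multiplicity weights.  A
:class:`SiteClassModel` assigns each site class a proportion and one
omega per branch; the single-class case covers one-ratio and free-ratio
models, the four-class case covers branch-site model A.

Branch scaling follows the codeml convention: each branch length is
expected substitutions per codon under the model, so the unscaled rate
matrix for class c on branch b is run for time t_b / rbar_b where
rbar_b is the class-proportion-averaged substitution rate on that
branch.  For a single-class (free-ratio) model this reduces to scaling
each branch by its own omega's rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .alignment import CodonAlignment
from .model import CodonModelParams, EigenQ, eigen_decompose, rate_matrix_unscaled, scale_factor
from .trees import PhyloTree

_LOG_TINY = -745.0  # log of the smallest positive double


@dataclass
class SiteClassModel:
    """Proportions over site classes and a per-class, per-branch omega."""

    proportions: np.ndarray  # (C,)
    omegas: np.ndarray       # (C, n_nodes); the root column is ignored

    def __post_init__(self):
        self.proportions = np.asarray(self.proportions, dtype=float)
        self.omegas = np.asarray(self.omegas, dtype=float)
        if self.proportions.ndim != 1 or self.omegas.ndim != 2:
            raise ValueError("bad mixture shapes")
        if self.omegas.shape[0] != self.proportions.shape[0]:
            raise ValueError("one omega row per class required")
        if abs(self.proportions.sum() - 1.0) > 1e-8 or (self.proportions < 0).any():
            raise ValueError("class proportions must be a distribution")

    @classmethod
    def single(cls, omega_by_node: np.ndarray) -> "SiteClassModel":
        return cls(np.ones(1), np.asarray(omega_by_node, float)[None, :])

    @classmethod
    def one_ratio(cls, omega: float, tree: PhyloTree) -> "SiteClassModel":
        return cls.single(np.full(tree.n_nodes, omega))

    @classmethod
    def model_a(cls, p0: float, p1: float, omega0: float, omega2: float,
                tree: PhyloTree) -> "SiteClassModel":
        """Branch-site model A.

        Classes: 0 (omega0 everywhere), 1 (neutral everywhere),
        2a (omega0 background / omega2 foreground), 2b (1 background /
        omega2 foreground).  The leftover mass p2 = 1 - p0 - p1 is split
        between 2a and 2b in proportion p0 : p1.
        """
        if tree.foreground is None:
            raise ValueError("model A requires a foreground branch")
        if p0 < 0 or p1 < 0 or p0 + p1 > 1 + 1e-12:
            raise ValueError("invalid class proportions")
        p2 = max(0.0, 1.0 - p0 - p1)
        denom = p0 + p1
        if denom <= 0:
            split = 0.5
        else:
            split = p0 / denom
        props = np.array([p0, p1, p2 * split, p2 * (1 - split)])
        props = props / props.sum()
        n = tree.n_nodes
        om = np.empty((4, n))
        om[0] = omega0
        om[1] = 1.0
        om[2] = omega0
        om[3] = 1.0
        fg = tree.foreground
        om[2, fg] = omega2
        om[3, fg] = omega2
        return cls(props, om)


def compress_patterns(states: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique alignment columns and their multiplicities."""
    cols, counts = np.unique(states.T, axis=0, return_counts=True)
    return cols.T.copy(), counts.astype(float)


class TreeLikelihood:
    """Pruning likelihood of one clean codon alignment on one tree."""

    def __init__(self, aln: CodonAlignment, tree: PhyloTree):
        if not aln.is_clean:
            raise ValueError(f"alignment {aln.gene_id!r} contains non-sense codons; QC first")
        leaves = set(tree.leaf_names)
        if leaves != set(aln.taxa):
            raise ValueError(
                f"taxa mismatch for {aln.gene_id!r}: alignment {sorted(aln.taxa)} "
                f"vs tree {sorted(leaves)}"
            )
        self.tree = tree
        self.code = aln.code
        self.n_codons = aln.n_codons
        cols, self.site_to_pattern, counts = np.unique(
            aln.states.T, axis=0, return_inverse=True, return_counts=True
        )
        self.patterns = cols.T.copy()
        self.weights = counts.astype(float)
        # pattern row per tree leaf node
        row = {t: i for i, t in enumerate(aln.taxa)}
        self.leaf_states = {
            node: self.patterns[row[tree.names[node]]] for node in tree.leaves
        }

    # ------------------------------------------------------------------
    def _branch_scales(self, params: CodonModelParams, mixture: SiteClassModel
                       ) -> np.ndarray:
        cache: dict[float, float] = {}
        n = self.tree.n_nodes
        scales = np.ones(n)
        for b in self.tree.branch_nodes():
            r = 0.0
            for c, p in enumerate(mixture.proportions):
                w = float(mixture.omegas[c, b])
                if w not in cache:
                    cache[w] = scale_factor(params, w)
                r += p * cache[w]
            scales[b] = r
        return scales

    def _class_log_site_likelihoods(
        self,
        params: CodonModelParams,
        omega_by_node: np.ndarray,
        scales: np.ndarray,
        eig_cache: dict[float, EigenQ],
        lengths: np.ndarray,
    ) -> np.ndarray:
        """log f(pattern | class) for one class, shape (n_patterns,)."""
        tree = self.tree
        npat = self.patterns.shape[1]
        partial: dict[int, np.ndarray] = {}
        logscale = np.zeros(npat)
        for node in tree.postorder:
            if not tree.children[node]:
                continue
            part = np.ones((npat, params.code.n_sense))
            for child in tree.children[node]:
                w = float(omega_by_node[child])
                if w not in eig_cache:
                    eig_cache[w] = eigen_decompose(
                        rate_matrix_unscaled(params, w), params.pi
                    )
                P = eig_cache[w].transition_probabilities(
                    lengths[child] / scales[child]
                )
                if not tree.children[child]:
                    part *= P.T[self.leaf_states[child]]
                else:
                    part *= partial.pop(child) @ P.T
            if node in self.leaf_states:
                # a named node with children (collapsed 2-taxon root):
                # condition on its observed state
                obs = self.leaf_states[node]
                mask = np.zeros_like(part)
                mask[np.arange(npat), obs] = 1.0
                part *= mask
            m = part.max(axis=1)
            safe = m > 0
            part[safe] /= m[safe, None]
            logscale[safe] += np.log(m[safe])
            logscale[~safe] = -np.inf
            partial[node] = part
        root = tree.root
        if tree.children[root]:
            root_part = partial[root]
            lik = root_part @ params.pi
        else:  # degenerate single-node tree
            lik = params.pi[self.leaf_states[root]]
        # exact zeros are clipping artifacts of the eigendecomposition at
        # tiny branch lengths; floor at the smallest representable log so
        # optimizers see a steep but finite penalty instead of -inf
        with np.errstate(divide="ignore"):
            out = np.where(lik > 0, np.log(np.maximum(lik, 1e-320)), _LOG_TINY)
        return np.maximum(out + logscale, _LOG_TINY)

    # ------------------------------------------------------------------
    def log_site_likelihood_matrix(
        self,
        params: CodonModelParams,
        mixture: SiteClassModel,
        scales: np.ndarray | None = None,
        lengths: np.ndarray | None = None,
    ) -> np.ndarray:
        """log f(pattern | class) for all classes, shape (C, n_patterns)."""
        if scales is None:
            scales = self._branch_scales(params, mixture)
        if lengths is None:
            lengths = self.tree.lengths
        eig_cache: dict[float, EigenQ] = {}
        return np.stack([
            self._class_log_site_likelihoods(
                params, mixture.omegas[c], scales, eig_cache, lengths
            )
            for c in range(mixture.omegas.shape[0])
        ])

    def log_likelihood(
        self,
        params: CodonModelParams,
        mixture: SiteClassModel,
        scales: np.ndarray | None = None,
        lengths: np.ndarray | None = None,
    ) -> float:
        logf = self.log_site_likelihood_matrix(params, mixture, scales, lengths)
        with np.errstate(divide="ignore"):
            logp = np.log(np.maximum(mixture.proportions, 1e-320))
        site = logsumexp(logf + logp[:, None], axis=0)
        return float(np.dot(self.weights, site))

    def site_class_posteriors(
        self,
        params: CodonModelParams,
        mixture: SiteClassModel,
        scales: np.ndarray | None = None,
        lengths: np.ndarray | None = None,
    ) -> np.ndarray:
        """Posterior P(class | site) per original site, shape (C, n_codons)."""
        logf = self.log_site_likelihood_matrix(params, mixture, scales, lengths)
        with np.errstate(divide="ignore"):
            logp = np.log(np.maximum(mixture.proportions, 1e-320))
        joint = logf + logp[:, None]
        post = np.exp(joint - logsumexp(joint, axis=0, keepdims=True))
        return post[:, self.site_to_pattern]


def log_likelihood(
    aln: CodonAlignment,
    tree: PhyloTree,
    params: CodonModelParams,
    site_class_mixture: SiteClassModel | None = None,
) -> float:
    """Log-likelihood of an alignment under the codon model.

    Without a mixture, a one-class model using the tree's branch lengths
    and omega = 1 on every branch is assumed (callers normally pass a
    mixture).
    """
    engine = TreeLikelihood(aln, tree)
    if site_class_mixture is None:
        site_class_mixture = SiteClassModel.one_ratio(1.0, tree)
    return engine.log_likelihood(params, site_class_mixture)
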