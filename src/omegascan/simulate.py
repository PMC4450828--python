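"""Codon-evolution simulator and study-scenario generator.

The simulator evolves codon sequences down a fixed tree under the same
Goldman–Yang model (and the same branch-scaling conventions) that the
estimators assume, so planted parameters are recoverable in
expectation.  :func:`simulate_study` produces a complete pipeline input
set — per-gene FASTA alignments, a tagged newick tree, a GO map with
planted accelerated categories, planted positively selected genes, and
machine-readable truth — deterministically from one seed.

The default scenario emulates the statistical shape of a two-pair
comparative transcriptome study: two congeneric high/low-altitude pairs
plus an outgroup, a few hundred single-copy orthologs of 200–400
codons, strong purifying selection background (omega 0.2), and a small
number of planted effects.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .alignment import CodonAlignment, write_codon_fasta
from .genetics import GeneticCode, STANDARD_CODE
from .likelihood import SiteClassModel
from .model import CodonModelParams, eigen_decompose, rate_matrix_unscaled, scale_factor
from .trees import PhyloTree, parse_newick, write_tree

DEFAULT_TREE = (
    "((highPhryno:0.03,lowPhryno:0.03):0.12,"
    "(highRana:0.04,lowRana:0.04):0.12,outgroup:0.25);"
)


@dataclass
class SimulationScenario:
    """Everything needed to generate one synthetic study."""

    newick: str = DEFAULT_TREE
    foreground: str = "highPhryno"
    comparison: str = "lowPhryno"
    kappa: float = 2.0
    pi_scheme: str = "uniform"       # uniform | skewed
    background_omega: float = 0.2
    n_genes: int = 200
    codons_range: tuple[int, int] = (200, 400)
    n_categories: int = 10
    category_size: int = 25
    n_accel_categories: int = 2
    accel_multiplier: float = 3.0    # foreground omega multiplier
    n_psg: int = 5
    psg_p0: float = 0.6
    psg_p1: float = 0.2              # leaves p2 = 0.2 of sites under selection
    psg_omega2: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.n_accel_categories > self.n_categories:
            raise ValueError("more accelerated categories than categories")
        if self.category_size * self.n_accel_categories > self.n_genes:
            raise ValueError("category sizes exceed gene count")
        if not (0 <= self.psg_p0 and 0 <= self.psg_p1
                and self.psg_p0 + self.psg_p1 <= 1):
            raise ValueError("PSG class proportions must sum to <= 1")
        for name in ("kappa", "background_omega", "accel_multiplier", "psg_omega2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _scenario_pi(scheme: str, code: GeneticCode) -> np.ndarray:
    if scheme == "uniform":
        return np.full(code.n_sense, 1.0 / code.n_sense)
    if scheme == "skewed":
        # GC-rich third positions, a caricature of vertebrate CDS bias
        w = np.array([
            1.0 + (c[2] in "GC") * 1.5 + (c[0] in "GC") * 0.5 for c in code.codons
        ])
        return w / w.sum()
    raise ValueError(f"unknown pi scheme {scheme!r}")


def simulate_alignment(
    tree: PhyloTree,
    n_codons: int,
    seed: int,
    kappa: float = 2.0,
    pi: np.ndarray | None = None,
    branch_omegas: dict[str, float] | float = 0.2,
    site_classes: SiteClassModel | None = None,
    code: GeneticCode = STANDARD_CODE,
    gene_id: str = "",
) -> tuple[CodonAlignment, np.ndarray]:
    """Evolve one codon alignment down ``tree``; returns truth labels.

    ``branch_omegas`` may be a single omega or a map from branch label to
    omega (missing branches keep the scalar default it is merged over).
    ``site_classes`` overrides it with an explicit mixture (e.g. model A
    for a planted PSG).  Branch lengths are expected substitutions per
    codon under the realised model, matching the likelihood engine's
    scaling, so fitted t and omega estimate the planted values.
    Returns ``(alignment, site_class_labels)``.
    """
    rng = np.random.default_rng(seed)
    if pi is None:
        pi = np.full(code.n_sense, 1.0 / code.n_sense)
    params = CodonModelParams(kappa=kappa, pi=pi, code=code)
    if site_classes is None:
        if np.isscalar(branch_omegas):
            om = np.full(tree.n_nodes, float(branch_omegas))
        else:
            om = np.full(tree.n_nodes, float(branch_omegas.get("default", 0.2)))
            label_map = tree.label_to_node()
            for lab, w in branch_omegas.items():
                if lab == "default":
                    continue
                if lab not in label_map:
                    raise KeyError(f"no branch labelled {lab!r}")
                om[label_map[lab]] = float(w)
        mixture = SiteClassModel.single(om)
    else:
        mixture = site_classes
    C = len(mixture.proportions)
    labels = rng.choice(C, size=n_codons, p=mixture.proportions)

    # per-branch scale: class-proportion-averaged substitution rate
    rate_cache: dict[float, float] = {}

    def rate(w: float) -> float:
        if w not in rate_cache:
            rate_cache[w] = scale_factor(params, w)
        return rate_cache[w]

    eig_cache: dict[float, object] = {}

    def eig(w: float):
        if w not in eig_cache:
            eig_cache[w] = eigen_decompose(rate_matrix_unscaled(params, w), pi)
        return eig_cache[w]

    root = tree.root
    states = np.empty((tree.n_nodes, n_codons), dtype=np.int16)
    states[root] = rng.choice(code.n_sense, size=n_codons, p=pi)
    for node in reversed(tree.postorder):  # preorder
        for child in tree.children[node]:
            rbar = float(np.dot(
                mixture.proportions,
                [rate(float(w)) for w in mixture.omegas[:, child]],
            ))
            t = tree.lengths[child] / rbar
            out = np.empty(n_codons, dtype=np.int16)
            for c in range(C):
                mask = labels == c
                if not mask.any():
                    continue
                P = eig(float(mixture.omegas[c, child])).transition_probabilities(t)
                cum = np.cumsum(P, axis=1)
                cum[:, -1] = 1.0
                u = rng.random(mask.sum())
                rows = cum[states[node, mask]]
                out[mask] = (rows < u[:, None]).sum(axis=1)
            states[child] = out
    leaf_ids = tree.leaves
    aln = CodonAlignment(
        taxa=[tree.names[i] for i in leaf_ids],
        states=states[leaf_ids].copy(),
        gene_id=gene_id,
        code=code,
    )
    return aln, labels


@dataclass
class SimulatedStudy:
    scenario: SimulationScenario
    tree: PhyloTree
    alignments: list[CodonAlignment]
    go_pairs: list[tuple[str, str]]
    truth: dict
    seed: int

    def write(self, outdir) -> Path:
        out = Path(outdir)
        (out / "alignments").mkdir(parents=True, exist_ok=True)
        for aln in self.alignments:
            write_codon_fasta(aln, out / "alignments" / f"{aln.gene_id}.fasta")
        write_tree(self.tree, out / "tree.nwk")
        with open(out / "go_map.tsv", "w") as fh:
            for gene, cat in sorted(self.go_pairs):
                fh.write(f"{gene}\t{cat}\n")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)
        with open(out / "scenario.json", "w") as fh:
            json.dump(asdict(self.scenario), fh, indent=2, sort_keys=True)
        return out


def simulate_study(scenario: SimulationScenario, seed: int | None = None,
                   outdir=None) -> SimulatedStudy:
    """Generate the full synthetic study a pipeline run consumes.

    Gene lengths are uniform over ``codons_range``.  The first
    ``n_accel_categories`` categories receive disjoint dedicated member
    genes whose foreground-branch omega is multiplied by
    ``accel_multiplier``; remaining categories sample members from the
    unaccelerated pool (overlaps allowed, as in real GO annotations).
    The first ``n_psg`` genes of the unaccelerated pool evolve under
    branch-site model A with ``psg_omega2`` on the foreground branch.
    Deterministic given the seed.
    """
    sc = scenario
    if seed is None:
        seed = sc.seed
    code = STANDARD_CODE
    tree = parse_newick(sc.newick)
    tree = tree.with_foreground(sc.foreground) if tree.foreground is None else tree
    pi = _scenario_pi(sc.pi_scheme, code)
    ss = np.random.SeedSequence(seed)
    master = np.random.default_rng(ss)
    gene_seeds = [int(s) for s in
                  master.integers(0, 2**31 - 1, size=sc.n_genes)]

    n_accel_genes = sc.n_accel_categories * sc.category_size
    accel_genes = list(range(n_accel_genes))
    pool = list(range(n_accel_genes, sc.n_genes))
    if sc.n_psg > len(pool):
        raise ValueError("not enough unaccelerated genes to plant PSGs")
    psg_genes = pool[: sc.n_psg]

    gene_ids = [f"gene_{g:04d}" for g in range(sc.n_genes)]
    lengths = master.integers(sc.codons_range[0], sc.codons_range[1] + 1,
                              size=sc.n_genes)
    fg_label = sc.foreground
    alignments = []
    truth_omegas = {}
    for g in range(sc.n_genes):
        n_codons = int(lengths[g])
        if g in psg_genes:
            mix = SiteClassModel.model_a(
                sc.psg_p0, sc.psg_p1, sc.background_omega, sc.psg_omega2, tree
            )
            aln, labels = simulate_alignment(
                tree, n_codons, gene_seeds[g], kappa=sc.kappa, pi=pi,
                site_classes=mix, code=code, gene_id=gene_ids[g],
            )
            truth_omegas[gene_ids[g]] = {
                "model": "branch_site",
                "omega0": sc.background_omega,
                "omega2": sc.psg_omega2,
                "p_selected": round(1.0 - sc.psg_p0 - sc.psg_p1, 10),
                "selected_sites_1based":
                    [int(i) + 1 for i in np.nonzero(labels >= 2)[0]],
            }
        else:
            fg_omega = sc.background_omega * (
                sc.accel_multiplier if g in accel_genes else 1.0
            )
            aln, _ = simulate_alignment(
                tree, n_codons, gene_seeds[g], kappa=sc.kappa, pi=pi,
                branch_omegas={"default": sc.background_omega, fg_label: fg_omega},
                code=code, gene_id=gene_ids[g],
            )
            truth_omegas[gene_ids[g]] = {
                "model": "branch",
                "background_omega": sc.background_omega,
                "foreground_omega": fg_omega,
            }
        alignments.append(aln)

    # GO design
    cats = [f"GO:{c + 1:07d}" for c in range(sc.n_categories)]
    go_pairs: list[tuple[str, str]] = []
    for c in range(sc.n_accel_categories):
        members = accel_genes[c * sc.category_size : (c + 1) * sc.category_size]
        go_pairs += [(gene_ids[g], cats[c]) for g in members]
    for c in range(sc.n_accel_categories, sc.n_categories):
        take = min(sc.category_size, len(pool))
        members = master.choice(pool, size=take, replace=False)
        go_pairs += [(gene_ids[g], cats[c]) for g in sorted(members)]

    truth = {
        "seed": seed,
        "foreground": sc.foreground,
        "accelerated_categories": cats[: sc.n_accel_categories],
        "psg_genes": [gene_ids[g] for g in psg_genes],
        "gene_models": truth_omegas,
    }
    study = SimulatedStudy(
        scenario=sc, tree=tree, alignments=alignments,
        go_pairs=go_pairs, truth=truth, seed=seed,
    )
    if outdir is not None:
        study.write(outdir)
    return study
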