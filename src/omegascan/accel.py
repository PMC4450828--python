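"""Lineage- and GO-category-level accelerated-evolution statistics.

Three statistics, all built on the one-sided binomial tail:

* :func:`lineage_sign_test` — per-gene sign test between two lineages'
  omega values (the headline lineage comparison).
* :func:`category_accel_test` — per-category binomial test of aggregated
  nonsynonymous substitution counts against the genome-wide proportion
  (the chimpanzee-genome-style acceleration test).
* :func:`resample_concatenations` — the concatenation resample: repeated
  random draws of k orthologs, concatenated and refitted, giving a
  distribution of lineage-level omega.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .alignment import CodonAlignment, concatenate
from .freeratio import BranchRates, fit_free_ratio, lineage_rates_table
from .trees import PhyloTree


# ----------------------------------------------------------------------
# binomial tail
# ----------------------------------------------------------------------

def binomial_sf(x: int, n: int, p0: float) -> float:
    """One-sided binomial p-value P(X >= x | n, p0).

    Computed by direct summation of the pmf in log space (stable for the
    extreme tails these scans produce, e.g. 2^-80).
    """
    if not (0 <= x <= n):
        raise ValueError(f"need 0 <= x <= n, got x={x}, n={n}")
    if not (0.0 < p0 < 1.0):
        raise ValueError(f"null probability must be in (0, 1), got {p0}")
    if x == 0:
        return 1.0
    k = np.arange(x, n + 1)
    logpmf = (
        gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        + k * np.log(p0) + (n - k) * np.log1p(-p0)
    )
    return float(min(1.0, np.exp(logsumexp(logpmf))))


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


# ----------------------------------------------------------------------
# lineage sign test
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class SignTestResult:
    lineage_a: str
    lineage_b: str
    n_a_greater: int
    n_b_greater: int
    n_informative: int
    p_value: float          # one-sided, H1: lineage A's omega tends higher
    low_power: bool


def lineage_sign_test(
    rates: pd.DataFrame, lineage_a: str, lineage_b: str, min_informative: int = 10
) -> SignTestResult:
    """Sign test of per-gene omega between two lineages.

    Genes with omega defined on both lineages and unequal values are the
    trials; ties and missing values are excluded.  The p-value is
    P(X >= #(omega_A > omega_B)) under Binomial(n, 1/2).
    """
    wide = rates.pivot_table(index="gene", columns="lineage", values="omega",
                             aggfunc="first")
    for lin in (lineage_a, lineage_b):
        if lin not in wide.columns:
            raise KeyError(f"lineage {lin!r} absent from rates table")
    sub = wide[[lineage_a, lineage_b]].dropna()
    diff = sub[lineage_a] - sub[lineage_b]
    informative = diff[diff != 0]
    n = len(informative)
    x = int((informative > 0).sum())
    p = binomial_sf(x, n, 0.5) if n else 1.0
    return SignTestResult(
        lineage_a=lineage_a,
        lineage_b=lineage_b,
        n_a_greater=x,
        n_b_greater=n - x,
        n_informative=n,
        p_value=p,
        low_power=n < min_informative,
    )


# ----------------------------------------------------------------------
# GO map and category test
# ----------------------------------------------------------------------

@dataclass
class GOMap:
    """Gene -> categories map with a consistent inverse index."""

    gene_to_cats: dict[str, frozenset[str]]
    cat_to_genes: dict[str, frozenset[str]] = field(default=None)

    def __post_init__(self):
        inv: dict[str, set[str]] = {}
        for g, cats in self.gene_to_cats.items():
            self.gene_to_cats[g] = frozenset(cats)
            for c in cats:
                inv.setdefault(c, set()).add(g)
        self.cat_to_genes = {c: frozenset(gs) for c, gs in inv.items()}

    @classmethod
    def from_pairs(cls, pairs) -> "GOMap":
        fwd: dict[str, set[str]] = {}
        for gene, cat in pairs:
            fwd.setdefault(str(gene), set()).add(str(cat))
        return cls(gene_to_cats=fwd)

    @classmethod
    def from_tsv(cls, path) -> "GOMap":
        df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "category_id"],
                         dtype=str, comment="#")
        return cls.from_pairs(df.itertuples(index=False))

    def to_tsv(self, path) -> None:
        rows = sorted(
            (g, c) for g, cats in self.gene_to_cats.items() for c in cats
        )
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)

    @property
    def categories(self) -> list[str]:
        return sorted(self.cat_to_genes)


def category_accel_test(
    rates: pd.DataFrame,
    gomap: GOMap,
    lineage_f: str,
    lineage_l: str,
    min_genes: int = 20,
    alpha: float = 0.05,
    method: str = "counts",
) -> pd.DataFrame:
    """Per-category accelerated-evolution binomial test.

    For every category with *more than* ``min_genes`` member genes in the
    rates table, aggregate the expected nonsynonymous substitution counts
    on the focal (F) and comparison (L) lineages and test the rounded
    counts against the genome-wide proportion
    p_hat = sum(n_F) / (sum(n_F) + sum(n_L)) over all genes, one-sided in
    each direction.  A category is flagged accelerated in a lineage when
    its p-value is below ``alpha`` (raw, as in the headline analysis; a
    Benjamini–Hochberg column is included but not used for the flag).

    ``method="genes"`` is the gene-level variant: each member gene with
    defined omega on both lineages is one trial, successes are genes with
    omega_F > omega_L, and the null probability is the genome-wide
    fraction of such genes.
    """
    if method not in ("counts", "genes"):
        raise ValueError(f"unknown method {method!r}")
    sub = rates[rates["lineage"].isin([lineage_f, lineage_l])]
    genes_avail = set(sub["gene"].unique())
    overlap = genes_avail & set(gomap.gene_to_cats)
    if not overlap:
        raise ValueError("no overlap between GO map and rates table")
    wide_n = sub.pivot_table(index="gene", columns="lineage", values="n",
                             aggfunc="first")
    wide_w = sub.pivot_table(index="gene", columns="lineage", values="omega",
                             aggfunc="first")
    total_f = float(wide_n[lineage_f].sum(skipna=True))
    total_l = float(wide_n[lineage_l].sum(skipna=True))
    if total_f + total_l <= 0:
        raise ValueError("no substitutions available for the genome-wide null")
    p_hat = total_f / (total_f + total_l)

    ww = wide_w.dropna()
    genome_up = int((ww[lineage_f] > ww[lineage_l]).sum())
    genome_informative = int((ww[lineage_f] != ww[lineage_l]).sum())

    rows = []
    for cat in gomap.categories:
        members = sorted(gomap.cat_to_genes[cat] & genes_avail)
        if len(members) <= min_genes:  # "more than 20 genes" is strict
            continue
        if method == "counts":
            nf = float(wide_n.loc[members, lineage_f].sum(skipna=True))
            nl = float(wide_n.loc[members, lineage_l].sum(skipna=True))
            x = _round_half_up(nf)
            m = x + _round_half_up(nl)
            p_f = binomial_sf(x, m, p_hat) if m else 1.0
            p_l = binomial_sf(m - x, m, 1.0 - p_hat) if m else 1.0
        else:
            mem = ww.loc[ww.index.intersection(members)]
            up = int((mem[lineage_f] > mem[lineage_l]).sum())
            down = int((mem[lineage_f] < mem[lineage_l]).sum())
            m = up + down
            p_null = genome_up / genome_informative if genome_informative else 0.5
            p_null = min(max(p_null, 1e-12), 1 - 1e-12)
            nf, nl, x = float(up), float(down), up
            p_f = binomial_sf(up, m, p_null) if m else 1.0
            p_l = binomial_sf(down, m, 1.0 - p_null) if m else 1.0
        agg = {}
        for lin, tag in ((lineage_f, "F"), (lineage_l, "L")):
            gsub = sub[(sub["lineage"] == lin) & sub["gene"].isin(members)]
            ka = gsub["Ka"].sum() / len(members)
            ks = gsub["Ks"].sum() / len(members)
            agg[f"Ka_{tag}"] = ka
            agg[f"Ks_{tag}"] = ks
            agg[f"omega_{tag}"] = ka / ks if ks > 0 else np.nan
        rows.append(
            {
                "category": cat,
                "n_genes": len(members),
                "nF": nf,
                "nL": nl,
                **agg,
                "p_F": p_f,
                "p_L": p_l,
                "accel_F": p_f < alpha,
                "accel_L": p_l < alpha,
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["fdr_F"] = _benjamini_hochberg(out["p_F"].to_numpy())
        out["fdr_L"] = _benjamini_hochberg(out["p_L"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ----------------------------------------------------------------------
# concatenation resample
# ----------------------------------------------------------------------

@dataclass
class ResampleSummary:
    lineage: str
    n_replicates: int
    genes_per_replicate: int
    omegas: np.ndarray          # per-replicate concatenated omega (NaN-able)
    seed: int

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.omegas))

    @property
    def sd(self) -> float:
        return float(np.nanstd(self.omegas, ddof=1))

    def percentile_ci(self, level: float = 0.95) -> tuple[float, float]:
        lo = 100 * (1 - level) / 2
        vals = self.omegas[~np.isnan(self.omegas)]
        return tuple(np.percentile(vals, [lo, 100 - lo]))

    def summary_dict(self) -> dict:
        lo, hi = self.percentile_ci()
        return {
            "lineage": self.lineage,
            "R": self.n_replicates,
            "k": self.genes_per_replicate,
            "mean_omega": self.mean,
            "sd_omega": self.sd,
            "ci95_low": lo,
            "ci95_high": hi,
            "seed": self.seed,
        }


def resample_concatenations(
    genes: list[CodonAlignment],
    tree: PhyloTree,
    lineages: list[str],
    k: int = 150,
    R: int = 10000,
    seed: int = 0,
    freq_scheme: str = "f3x4",
    n_starts: int = 1,
    tol: float = 1e-7,
) -> tuple[dict[str, ResampleSummary], pd.DataFrame]:
    """Estimate lineage-level omega from R random k-gene concatenations.

    Each replicate draws k genes without replacement (independently
    across replicates), concatenates them, and fits the free-ratio model;
    the fitted omega of each requested lineage branch is recorded.  Fully
    deterministic given ``seed``.  Returns per-lineage summaries and the
    tidy replicate table.
    """
    if k > len(genes):
        raise ValueError(f"k={k} exceeds the {len(genes)} available genes")
    taxa = sorted(tree.unrooted().leaf_names)
    rng = np.random.default_rng(seed)
    records = []
    omegas = {lin: np.empty(R) for lin in lineages}
    for r in range(R):
        idx = rng.choice(len(genes), size=k, replace=False)
        concat = concatenate([genes[i] for i in sorted(idx)], taxa)
        concat.gene_id = f"replicate_{r}"
        fit = fit_free_ratio(concat, tree, freq_scheme=freq_scheme,
                             n_starts=n_starts, seed=seed + 1 + r, tol=tol)
        table = {lab: i for i, lab in enumerate(fit.branch_labels)}
        for lin in lineages:
            if lin not in table:
                raise KeyError(f"no branch labelled {lin!r} on the tree")
            w = fit.omega[table[lin]]
            omegas[lin][r] = w
            records.append({"lineage": lin, "replicate": r, "omega": w})
    summaries = {
        lin: ResampleSummary(
            lineage=lin,
            n_replicates=R,
            genes_per_replicate=k,
            omegas=omegas[lin],
            seed=seed,
        )
        for lin in lineages
    }
    return summaries, pd.DataFrame.from_records(records)
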