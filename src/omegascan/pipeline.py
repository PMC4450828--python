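"""End-to-end pipeline: QC -> rates -> acceleration tests -> PSG scan.

The pipeline is a thin orchestration layer over the library modules; it
reads a directory of per-gene FASTA codon alignments, a newick tree and
a gene->GO TSV, and writes TSV/JSON results plus a manifest recording
the seed, parameters, configuration hash and per-stage gene counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .accel import GOMap, category_accel_test, lineage_sign_test, resample_concatenations
from .alignment import (
    CodonAlignment,
    passes_min_length,
    read_codon_fasta,
    remove_ambiguous_columns,
)
from .branchsite import branch_site_scan, psg_table
from .freeratio import fit_free_ratio, lineage_rates_table
from .orthologs import filter_single_copy_clusters, read_clusters_tsv
from .trees import read_tree

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline knobs; thresholds default to the strict published ones."""

    alignments_dir: str = ""
    tree_file: str = ""
    go_map_file: str = ""
    clusters_file: str = ""          # optional
    species: list[str] = field(default_factory=list)  # for the cluster filter
    focal_lineage: str = ""
    sister_lineage: str = ""
    possel_lineages: list[str] = field(default_factory=list)
    out_dir: str = "results"
    seed: int = 0
    # QC
    min_nt: int = 150
    # rates
    freq_scheme: str = "f3x4"
    rates_n_starts: int = 2
    rates_tol: float = 1e-8
    # acceleration
    min_genes: int = 20
    alpha: float = 0.05
    resample_k: int = 150
    resample_R: int = 10000
    # PSG
    psg_alpha: float = 0.05
    post_min: float = 0.95
    omega_min: float = 1.0
    beb_grid: int = 10

    def validate(self):
        for name, lo, hi in (
            ("alpha", 0, 1), ("psg_alpha", 0, 1), ("post_min", 0, 1),
        ):
            v = getattr(self, name)
            if not (lo < v < hi):
                raise ValueError(f"{name}={v} outside ({lo}, {hi})")
        if self.min_nt < 0 or self.min_genes < 0:
            raise ValueError("thresholds must be non-negative")
        if self.resample_k < 1 or self.resample_R < 1:
            raise ValueError("resample_k and resample_R must be positive")
        if not self.focal_lineage or not self.sister_lineage:
            raise ValueError("focal and sister lineages must be named")
        if self.seed is None:
            raise ValueError("a seed is mandatory (stochastic stages)")
        return self

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Flat key = value config; values parsed as JSON when possible."""
        values = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"bad config line: {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            try:
                values[key] = json.loads(val)
            except json.JSONDecodeError:
                values[key] = val
        unknown = set(values) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**values)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def load_and_qc(config: PipelineConfig) -> tuple[list[CodonAlignment], dict]:
    """Cluster filter (optional) + column QC + length filter."""
    aln_dir = Path(config.alignments_dir)
    paths = sorted(aln_dir.glob("*.fasta")) + sorted(aln_dir.glob("*.fa"))
    if not paths:
        raise PipelineError("qc", f"no FASTA alignments under {aln_dir}")
    counts = {"input": len(paths)}
    keep_genes = None
    if config.clusters_file:
        clusters = read_clusters_tsv(config.clusters_file)
        kept = filter_single_copy_clusters(clusters, set(config.species))
        keep_genes = {m.gene_id for c in kept for m in c.members}
        counts["single_copy_clusters"] = len(kept)
    alignments = []
    for p in paths:
        aln = read_codon_fasta(p)
        if keep_genes is not None and aln.gene_id not in keep_genes:
            continue
        aln = remove_ambiguous_columns(aln)
        if passes_min_length(aln, config.min_nt):
            alignments.append(aln)
    counts["after_qc"] = len(alignments)
    if not alignments:
        raise PipelineError("qc", "no alignments survive QC")
    return alignments, counts


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the results bundle.

    Stage order: cluster filter -> QC -> free-ratio rates -> lineage
    tests + resample -> category scan -> branch-site scan -> PSG table.
    Raises :class:`PipelineError` naming the stage on failure.  The
    manifest is deterministic for a given configuration and inputs.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "omegascan",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stages": {},
    }

    alignments, counts = load_and_qc(config)
    manifest["stages"]["qc"] = counts
    tree = read_tree(config.tree_file)

    if config.resample_k > len(alignments):
        raise PipelineError(
            "accel",
            f"resample_k={config.resample_k} exceeds the "
            f"{len(alignments)} genes that survive QC",
        )

    # ---- free-ratio rates -------------------------------------------
    fits = []
    for aln in alignments:
        try:
            fits.append(
                fit_free_ratio(
                    aln, tree, freq_scheme=config.freq_scheme,
                    n_starts=config.rates_n_starts, seed=config.seed,
                    tol=config.rates_tol,
                )
            )
        except FloatingPointError as e:
            log.warning("rates: gene %s excluded (%s)", aln.gene_id, e)
    if not fits:
        raise PipelineError("rates", "no gene could be fitted")
    lineages = sorted({config.focal_lineage, config.sister_lineage}
                      | set(config.possel_lineages))
    rates = lineage_rates_table(fits, lineages)
    rates.to_csv(out / "rates.tsv", sep="\t", index=False)
    full = pd.concat([f.as_frame() for f in fits], ignore_index=True)
    full.to_csv(out / "rates_all_branches.tsv", sep="\t", index=False)
    manifest["stages"]["rates"] = {
        "genes_fitted": len(fits),
        "freq_scheme": config.freq_scheme,
    }

    # ---- lineage comparison + resample ------------------------------
    sign = lineage_sign_test(rates, config.focal_lineage, config.sister_lineage)
    summaries, reps = resample_concatenations(
        alignments, tree, [config.focal_lineage, config.sister_lineage],
        k=config.resample_k, R=config.resample_R, seed=config.seed,
        freq_scheme=config.freq_scheme,
    )
    reps.to_csv(out / "resample.tsv", sep="\t", index=False)
    accel_summary = {
        "sign_test": asdict(sign),
        "resample": {lin: s.summary_dict() for lin, s in summaries.items()},
        "seed": config.seed,
        "config_hash": config.config_hash(),
    }
    with open(out / "lineage_summary.json", "w") as fh:
        json.dump(accel_summary, fh, indent=2, sort_keys=True)
    manifest["stages"]["accel"] = {
        "sign_test_p": sign.p_value,
        "replicates": config.resample_R,
    }

    # ---- GO category scan -------------------------------------------
    gomap = GOMap.from_tsv(config.go_map_file)
    categories = category_accel_test(
        rates, gomap, config.focal_lineage, config.sister_lineage,
        min_genes=config.min_genes, alpha=config.alpha,
    )
    categories.to_csv(out / "categories.tsv", sep="\t", index=False)
    manifest["stages"]["categories"] = {
        "tested": int(len(categories)),
        "accel_focal": int(categories["accel_F"].sum()) if len(categories) else 0,
        "accel_sister": int(categories["accel_L"].sum()) if len(categories) else 0,
    }

    # ---- branch-site scan -------------------------------------------
    possel = config.possel_lineages or [config.focal_lineage]
    bs_fits = []
    for lineage in possel:
        for aln in alignments:
            try:
                bs_fits.append(
                    branch_site_scan(
                        aln, tree, lineage, freq_scheme=config.freq_scheme,
                        seed=config.seed, alpha=config.psg_alpha,
                        post_min=config.post_min, omega_min=config.omega_min,
                        beb_grid=config.beb_grid,
                    )
                )
            except (FloatingPointError, ValueError) as e:
                raise PipelineError("possel", f"gene {aln.gene_id}: {e}") from e
    psgs = psg_table(bs_fits)
    psgs.to_csv(out / "psg.tsv", sep="\t", index=False)
    manifest["stages"]["possel"] = {
        "genes_tested": len(bs_fits),
        "psgs": int(psgs["verdict"].sum()) if len(psgs) else 0,
    }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
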