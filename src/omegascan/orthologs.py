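"""Ortholog cluster records and the strict single-copy filter."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class ClusterMember:
    species: str
    gene_id: str
    score: float  # orthology confidence in [0, 1]


@dataclass
class OrthologCluster:
    cluster_id: str
    members: list[ClusterMember]

    def species_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for m in self.members:
            counts[m.species] = counts.get(m.species, 0) + 1
        return counts


def read_clusters_tsv(path) -> list[OrthologCluster]:
    """Read clusters from a TSV with columns cluster_id, species, gene_id, score."""
    df = pd.read_csv(path, sep="\t", dtype={"cluster_id": str, "gene_id": str})
    required = {"cluster_id", "species", "gene_id", "score"}
    if missing := required - set(df.columns):
        raise ValueError(f"cluster table missing columns {sorted(missing)}")
    clusters = []
    for cid, grp in df.groupby("cluster_id", sort=True):
        members = [
            ClusterMember(r.species, r.gene_id, float(r.score))
            for r in grp.itertuples()
        ]
        clusters.append(OrthologCluster(str(cid), members))
    return clusters


def write_clusters_tsv(clusters: list[OrthologCluster], path) -> None:
    rows = [
        (c.cluster_id, m.species, m.gene_id, m.score)
        for c in clusters
        for m in c.members
    ]
    pd.DataFrame(rows, columns=["cluster_id", "species", "gene_id", "score"]).to_csv(
        path, sep="\t", index=False
    )


def filter_single_copy_clusters(
    clusters: list[OrthologCluster], species: set[str]
) -> list[OrthologCluster]:
    """Keep only high-confidence 1:1 clusters.

    A cluster survives iff every member's confidence score is >= 1.0
    (members below 1 disqualify the whole cluster: the rule removes the
    gene and the cluster then lacks that species) and it contains exactly
    one gene from each species in ``species`` and none from outside it.
    """
    if not species:
        raise ValueError("species set must be non-empty")
    kept = []
    for c in clusters:
        for m in c.members:
            if not 0.0 <= m.score <= 1.0:
                raise ValueError(
                    f"cluster {c.cluster_id}: score {m.score} outside [0, 1]"
                )
            if m.species not in species:
                raise ValueError(
                    f"cluster {c.cluster_id}: unknown species {m.species!r}"
                )
        survivors = [m for m in c.members if m.score >= 1.0]
        counts: dict[str, int] = {}
        for m in survivors:
            counts[m.species] = counts.get(m.species, 0) + 1
        if set(counts) == set(species) and all(v == 1 for v in counts.values()):
            kept.append(OrthologCluster(c.cluster_id, survivors))
    return kept
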