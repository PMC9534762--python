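"""Build the binary pan-gene presence/absence (PAV) matrix.

Two complementary sources of evidence are combined, mirroring common
pan-genome practice:

* *annotation*: a gene predicted in an accession contributes that accession
  to its pan-gene cluster (clusters here come from a greedy length-sorted
  sequence clustering, a documented stand-in for phylogenetic orthogroup
  inference — the downstream contract is only "one cluster id per pan-gene");
* *map-to-pan recovery*: an accession whose reads cover a pan-gene at
  >= 99% of its length and >= 3x mean depth is marked present even when the
  annotation missed the gene.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("panpav")

__all__ = [
    "GeneCluster",
    "CoverageRecord",
    "PAVMatrix",
    "greedy_cluster_genes",
    "gapfree_identity",
    "call_presence",
    "build_pav_matrix",
]


@dataclass
class GeneCluster:
    """A pan-gene: one cluster of cross-accession gene copies."""

    cluster_id: str
    members: list[tuple[str, str]]        # (accession, gene_id)
    representative: str                   # representative sequence

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"cluster {self.cluster_id} has no members")


@dataclass
class CoverageRecord:
    """Read-coverage summary of one accession over one pan-gene."""

    accession: str
    cluster_id: str
    breadth: float    # fraction of gene length covered, in [0, 1]
    depth: float      # mean fold-coverage, >= 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.breadth <= 1.0:
            raise ValueError(f"breadth {self.breadth} outside [0, 1]")
        if self.depth < 0:
            raise ValueError(f"negative depth {self.depth}")


@dataclass
class PAVMatrix:
    """Boolean pan-gene x accession occupancy table with group labels.

    ``provenance`` records, per presence, whether it was asserted by
    annotation or recovered by coverage ("annotated" / "recovered" / "").
    """

    matrix: pd.DataFrame                  # bool, clusters x accessions
    labels: dict[str, str]                # accession -> group
    provenance: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.matrix = self.matrix.astype(bool)
        if not set(self.matrix.columns) <= set(self.labels):
            missing = set(self.matrix.columns) - set(self.labels)
            raise ValueError(f"accessions without group label: {sorted(missing)}")
        empty = ~self.matrix.any(axis=1)
        if empty.any():
            raise ValueError(
                f"{int(empty.sum())} clusters present in no accession")

    @property
    def cluster_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def accessions(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def n_accessions(self) -> int:
        return self.matrix.shape[1]

    def group_columns(self, group: str) -> list[str]:
        return [a for a in self.matrix.columns if self.labels[a] == group]


# ---------------------------------------------------------------------------
# greedy clustering
# ---------------------------------------------------------------------------

def _kmer_set(seq: str, k: int, stride: int = 1) -> set[str]:
    return {seq[i:i + k] for i in range(0, len(seq) - k + 1, stride)}


def gapfree_identity(a: str, b: str, k: int = 11) -> float:
    """Gap-free identity between two sequences.

    Shared k-mers vote for a diagonal offset; the best offset induces an
    ungapped correspondence whose exact matches are counted.  Identity is
    matches over max(len(a), len(b)) — the alignment-column count of the
    induced gap-free global correspondence.  N never counts as a match.
    """
    if len(b) > len(a):
        a, b = b, a
    if len(b) < k:
        m = sum(1 for x, y in zip(a, b) if x == y and x != "N")
        return m / max(len(a), len(b))
    pos: dict[str, list[int]] = defaultdict(list)
    for i in range(len(a) - k + 1):
        pos[a[i:i + k]].append(i)
    votes: dict[int, int] = defaultdict(int)
    for j in range(len(b) - k + 1):
        for i in pos.get(b[j:j + k], ()):
            votes[i - j] += 1
    if not votes:
        return 0.0
    # deterministic tie-break: highest vote, then smallest |offset|
    offset = min(votes, key=lambda d: (-votes[d], abs(d), d))
    lo = max(0, offset)
    hi = min(len(a), len(b) + offset)
    m = sum(1 for i in range(lo, hi)
            if a[i] == b[i - offset] and a[i] != "N")
    return m / max(len(a), len(b))


def greedy_cluster_genes(
    genes: list[tuple[str, str, str]],
    identity_threshold: float = 0.90,
    k: int = 11,
    index_stride: int = 4,
) -> list[GeneCluster]:
    """Cluster gene sequences greedily into pan-gene clusters.

    Genes are sorted by decreasing length (ties keep input order); each gene
    joins the first existing cluster — in cluster-creation order — whose
    representative shares k-mers and validates at gap-free identity
    >= ``identity_threshold``; otherwise it founds a new cluster.  Exactly
    identical input rows are deduplicated first, so clustering is idempotent
    under concatenation of the same gene list.
    """
    seen: set[tuple[str, str, str]] = set()
    uniq: list[tuple[str, str, str]] = []
    for g in genes:
        if not g[2]:
            raise ValueError(f"empty sequence for gene {g[1]!r}")
        if g not in seen:
            seen.add(g)
            uniq.append(g)
    order = sorted(range(len(uniq)), key=lambda i: (-len(uniq[i][2]), i))

    clusters: list[GeneCluster] = []
    kmer_index: dict[str, set[int]] = defaultdict(set)
    for idx in order:
        accession, gene_id, seq = uniq[idx]
        candidates: set[int] = set()
        for i in range(0, max(1, len(seq) - k + 1), index_stride):
            candidates |= kmer_index.get(seq[i:i + k], set())
        joined = False
        for ci in sorted(candidates):
            if gapfree_identity(seq, clusters[ci].representative, k=k) >= identity_threshold:
                clusters[ci].members.append((accession, gene_id))
                joined = True
                break
        if not joined:
            ci = len(clusters)
            clusters.append(GeneCluster(f"pg{ci:06d}", [(accession, gene_id)], seq))
            for km in _kmer_set(seq, k):
                kmer_index[km].add(ci)
    return clusters


# ---------------------------------------------------------------------------
# map-to-pan
# ---------------------------------------------------------------------------

def call_presence(record: CoverageRecord,
                  breadth_min: float = 0.99,
                  depth_min: float = 3.0) -> bool:
    """Coverage-based presence call; both thresholds are inclusive (>=)."""
    return record.breadth >= breadth_min and record.depth >= depth_min


def build_pav_matrix(
    clusters: list[GeneCluster],
    coverage: list[CoverageRecord],
    labels: dict[str, str],
    breadth_min: float = 0.99,
    depth_min: float = 3.0,
) -> PAVMatrix:
    """Combine annotation membership and map-to-pan recovery into a PAVMatrix.

    presence = (accession contributed a member gene) OR (coverage passes the
    breadth/depth rule).  Clusters with zero presences are dropped with a
    logged count; coverage referring to an unknown cluster is a hard error.
    """
    cluster_ids = [c.cluster_id for c in clusters]
    accessions = list(labels)
    ci = {cid: i for i, cid in enumerate(cluster_ids)}
    ai = {acc: j for j, acc in enumerate(accessions)}
    present = np.zeros((len(cluster_ids), len(accessions)), dtype=bool)
    prov = np.full_like(present, "", dtype=object)

    for c in clusters:
        for accession, _gene in c.members:
            if accession not in ai:
                raise ValueError(f"accession {accession!r} has no group label")
            present[ci[c.cluster_id], ai[accession]] = True
            prov[ci[c.cluster_id], ai[accession]] = "annotated"

    for rec in coverage:
        if rec.cluster_id not in ci:
            raise ValueError(f"coverage for unknown cluster {rec.cluster_id!r}")
        if rec.accession not in ai:
            raise ValueError(f"coverage for unknown accession {rec.accession!r}")
        i, j = ci[rec.cluster_id], ai[rec.accession]
        if call_presence(rec, breadth_min, depth_min) and not present[i, j]:
            present[i, j] = True
            prov[i, j] = "recovered"

    mat = pd.DataFrame(present, index=cluster_ids, columns=accessions)
    provdf = pd.DataFrame(prov, index=cluster_ids, columns=accessions)
    empty = ~mat.any(axis=1)
    if empty.any():
        logger.info("build_pav_matrix: dropped %d clusters with zero presences",
                    int(empty.sum()))
        mat = mat.loc[~empty]
        provdf = provdf.loc[~empty]
    return PAVMatrix(mat, labels, provdf)
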