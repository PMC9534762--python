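"""Readers and writers for the external formats the pipeline touches.

Conventions
-----------
All genomic intervals inside the package are 0-based half-open.  VCF is the
only 1-based surface; :func:`read_vcf` and :func:`write_vcf` convert at the
boundary.  Every writer is deterministic given identical input, so pipeline
manifests can be compared by content hash.

Per-file counters (skipped records, dropped clusters, ...) are reported
through the module logger on stderr.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger("panpav")

__all__ = [
    "SequenceRecord",
    "GenotypeMatrix",
    "WindowTrack",
    "TreeNode",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_vcf",
    "write_vcf",
    "write_bed",
    "write_newick",
    "newick_string",
    "read_pav_tsv",
    "write_pav_tsv",
    "read_window_track",
    "write_window_track",
    "read_labels_tsv",
    "write_labels_tsv",
    "read_coverage_tsv",
    "write_coverage_tsv",
]


class FormatError(ValueError):
    """A file violated the subset of its format this package supports."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class SequenceRecord:
    """A named uppercase nucleotide sequence over {A, C, G, T, N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        if len(self.seq) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        self.seq = self.seq.upper()

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GenotypeMatrix:
    """Biallelic SNP sites x samples diploid allele-dosage table.

    ``dosage`` holds alt-allele counts in {0, 1, 2} with -1 for missing.
    ``haplotypes`` (sites x samples x 2, entries in {0, 1}, -1 missing) is
    present only when every non-missing genotype in the source was phased;
    where present, ``dosage`` equals the haplotype sum.
    """

    sites: pd.DataFrame          # columns: chrom, pos (1-based), ref, alt
    samples: list[str]
    dosage: np.ndarray           # int8, (n_sites, n_samples)
    haplotypes: np.ndarray | None = None  # int8, (n_sites, n_samples, 2)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.sites), len(self.samples)):
            raise ValueError("dosage dimensions do not match sites x samples")
        key = list(zip(self.sites["chrom"], self.sites["pos"]))
        if key != sorted(key):
            raise ValueError("sites must be sorted by (chrom, pos)")
        if len(set(key)) != len(key):
            raise ValueError("duplicate (chrom, pos) site")
        if self.haplotypes is not None:
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
            hs = self.haplotypes.sum(axis=2)
            ok = self.haplotypes.min(axis=2) >= 0
            if not np.array_equal(hs[ok], self.dosage[ok]):
                raise ValueError("dosage does not equal haplotype sum")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset_samples(self, names: list[str]) -> "GenotypeMatrix":
        idx = [self.samples.index(n) for n in names]
        hap = self.haplotypes[:, idx, :] if self.haplotypes is not None else None
        return GenotypeMatrix(self.sites, list(names), self.dosage[:, idx], hap)


@dataclass
class WindowTrack:
    """Ordered genomic windows carrying one statistic."""

    chroms: np.ndarray           # str per window
    starts: np.ndarray           # 0-based inclusive
    ends: np.ndarray             # exclusive
    values: np.ndarray           # float, NaN = missing
    stat_name: str = "value"

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.chroms)
        if not (len(self.starts) == len(self.ends) == len(self.values) == n):
            raise ValueError("window track field lengths differ")
        if np.any(self.starts >= self.ends):
            raise ValueError("window with start >= end")
        key = list(zip(self.chroms, self.starts))
        if key != sorted(key):
            raise ValueError("windows must be sorted by (chrom, start)")

    def __len__(self) -> int:
        return len(self.chroms)

    def same_grid(self, other: "WindowTrack") -> bool:
        return (
            len(self) == len(other)
            and bool(np.all(self.chroms == other.chroms))
            and bool(np.all(self.starts == other.starts))
            and bool(np.all(self.ends == other.ends))
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chroms, "start": self.starts, "end": self.ends,
             self.stat_name: self.values}
        )


@dataclass
class TreeNode:
    """Node of an (unrooted) phylogenetic tree.

    ``length`` is the branch length to the parent (None at the top node).
    Leaves have a name and no children; an unrooted tree of n >= 3 leaves is
    represented with a trifurcating top node.
    """

    name: str | None = None
    length: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects, in file order.

    Lowercase input is uppercased.  Duplicate ids and empty files are hard
    errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq)))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path, wrap: int = 80) -> None:
    """Write records wrapped at ``wrap`` columns (default 80)."""
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as handle:
        FastaWriter(handle, wrap=wrap).write_file(bio)


# ---------------------------------------------------------------------------
# VCF (GT-only v4.2 subset)
# ---------------------------------------------------------------------------

_GT_MAP = {"0/0": 0, "0/1": 1, "1/0": 1, "1/1": 2, "./.": -1,
           "0|0": 0, "0|1": 1, "1|0": 1, "1|1": 2, ".|.": -1}
_HAP_MAP = {"0|0": (0, 0), "0|1": (0, 1), "1|0": (1, 0), "1|1": (1, 1)}
_SNP_ALLELES = frozenset("ACGT")


def read_vcf(path) -> GenotypeMatrix:
    """Read the GT-only biallelic-SNP subset of VCF v4.2.

    Dosage coding: 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2, ./. -> missing.
    Multiallelic or non-SNP rows are skipped with a logged count.  Phased
    haplotypes are returned when every non-missing genotype is phased.
    A malformed GT field is a hard error naming the offending line.
    """
    samples: list[str] = []
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    dosage_rows: list[list[int]] = []
    hap_rows: list[list[tuple[int, int]]] = []
    n_skipped = 0
    all_phased = True

    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                fields = line.split("\t")
                if len(fields) < 10 or fields[8:9] != ["FORMAT"]:
                    raise FormatError(f"{path}:{lineno}: unsupported VCF header")
                samples = fields[9:]
                continue
            if not samples:
                raise FormatError(f"{path}:{lineno}: data before #CHROM header")
            fields = line.split("\t")
            chrom, pos, _id, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            fmt = fields[8]
            if "," in alt or ref not in _SNP_ALLELES or alt not in _SNP_ALLELES:
                n_skipped += 1
                continue
            gt_idx = fmt.split(":").index("GT")
            row: list[int] = []
            hrow: list[tuple[int, int]] = []
            for call in fields[9:]:
                gt = call.split(":")[gt_idx]
                if gt not in _GT_MAP:
                    raise FormatError(f"{path}:{lineno}: malformed GT field {gt!r}")
                row.append(_GT_MAP[gt])
                if gt in _HAP_MAP:
                    hrow.append(_HAP_MAP[gt])
                elif _GT_MAP[gt] == -1:
                    hrow.append((-1, -1))
                else:
                    all_phased = False
                    hrow.append((-1, -1))
            chroms.append(chrom)
            poss.append(int(pos))
            refs.append(ref)
            alts.append(alt)
            dosage_rows.append(row)
            hap_rows.append(hrow)

    if n_skipped:
        logger.info("read_vcf: skipped %d multiallelic/non-SNP rows", n_skipped)
    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    dosage = (np.array(dosage_rows, dtype=np.int8)
              if dosage_rows else np.empty((0, len(samples)), dtype=np.int8))
    haplotypes = None
    if all_phased and dosage_rows:
        haplotypes = np.array(hap_rows, dtype=np.int8)
    gm = GenotypeMatrix(sites, samples, dosage, haplotypes)
    gm.n_skipped = n_skipped  # type: ignore[attr-defined]
    return gm


def write_vcf(geno: GenotypeMatrix, path, contig_lengths: dict[str, int] | None = None) -> None:
    """Write a GT-only VCF v4.2; phased pipes are used when haplotypes exist."""
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write("##source=panpav\n")
        if contig_lengths:
            for chrom, ln in contig_lengths.items():
                out.write(f"##contig=<ID={chrom},length={ln}>\n")
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                  + "\t".join(geno.samples) + "\n")
        phased = geno.haplotypes is not None
        for i in range(geno.n_sites):
            s = geno.sites.iloc[i]
            calls = []
            for j in range(geno.n_samples):
                d = geno.dosage[i, j]
                if d < 0:
                    calls.append("./.")
                elif phased:
                    a, b = geno.haplotypes[i, j]
                    calls.append(f"{a}|{b}")
                else:
                    calls.append({0: "0/0", 1: "0/1", 2: "1/1"}[int(d)])
            out.write(f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t.\tGT\t"
                      + "\t".join(calls) + "\n")


# ---------------------------------------------------------------------------
# BED / Newick / TSV matrices
# ---------------------------------------------------------------------------

def write_bed(intervals, path) -> None:
    """Write (chrom, start, end, name[, score]) tuples as BED.

    Intervals must already be sorted by (chrom, start); unsorted input is a
    hard error because downstream merging assumes sorted BED.
    """
    rows = list(intervals)
    key = [(r[0], r[1]) for r in rows]
    if key != sorted(key):
        raise ValueError("BED intervals must be sorted by (chrom, start)")
    with open(path, "w") as out:
        for r in rows:
            out.write("\t".join(str(x) for x in r) + "\n")


def newick_string(tree: TreeNode) -> str:
    """Serialize a tree to Newick with 6-decimal branch lengths."""
    def fmt(node: TreeNode) -> str:
        if node.is_leaf():
            body = node.name or ""
        else:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.name:
                body += node.name
        if node.length is not None:
            body += f":{node.length:.6f}"
        return body

    return fmt(tree) + ";"


def write_newick(tree: TreeNode, path) -> None:
    with open(path, "w") as out:
        out.write(newick_string(tree) + "\n")


def write_pav_tsv(matrix: pd.DataFrame, path) -> None:
    """Write a binary PAV matrix (clusters x accessions) as TSV.

    Header row holds accession ids; first column is the cluster id; cells are
    "0"/"1".
    """
    out = matrix.astype(int)
    out.index.name = "cluster_id"
    out.to_csv(path, sep="\t")


def read_pav_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(bool)


def write_window_track(track: WindowTrack, path) -> None:
    track.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_window_track(path, stat_name: str | None = None) -> WindowTrack:
    df = pd.read_csv(path, sep="\t")
    value_col = stat_name or df.columns[3]
    return WindowTrack(df["chrom"].to_numpy(dtype=object), df["start"].to_numpy(),
                       df["end"].to_numpy(), df[value_col].to_numpy(), value_col)


def write_labels_tsv(labels: dict[str, str], path) -> None:
    with open(path, "w") as out:
        out.write("accession\tgroup\n")
        for acc, grp in labels.items():
            out.write(f"{acc}\t{grp}\n")


def read_labels_tsv(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["accession"].astype(str), df["group"].astype(str)))


def write_coverage_tsv(records, path) -> None:
    """Write map-to-pan coverage records (accession, cluster_id, breadth, depth)."""
    with open(path, "w") as out:
        out.write("accession\tcluster_id\tbreadth\tdepth\n")
        for r in records:
            out.write(f"{r.accession}\t{r.cluster_id}\t{r.breadth:.6g}\t{r.depth:.6g}\n")


def read_coverage_tsv(path):
    from .pav_build import CoverageRecord

    df = pd.read_csv(path, sep="\t")
    return [CoverageRecord(str(a), str(c), float(b), float(d))
            for a, c, b, d in zip(df["accession"], df["cluster_id"],
                                  df["breadth"], df["depth"])]
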