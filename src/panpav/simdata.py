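"""Synthetic populations with known truth for the pan-genome pipeline.

The generators emulate the statistical structure a crop resequencing panel
presents to the downstream analyses:

* a panel of accessions in three species-like groups (default 79 + 22 + 15
  = 116 genomes) with planted pan-gene occupancy classes (core / soft-core /
  shell / cloud) and group-preferred genes;
* per-accession draft assemblies that are reference fragments with
  substitution noise plus inserted accession-specific novel sequence;
* Balding–Nichols population differentiation, whose parameter F equals the
  expected Weir–Cockerham theta and is therefore recoverable;
* a windowed selection-score track with planted sweeps that jointly raise
  the score and depress domesticated-population diversity.

Every generator is a pure function of (config, seed): identical inputs give
byte-identical outputs.  Truth (class labels, planted segments and sweeps,
the differentiation parameter) is returned machine-readable so every
pipeline stage can be validated against it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, SequenceRecord, WindowTrack
from .pav_build import CoverageRecord, PAVMatrix

logger = logging.getLogger("panpav")

__all__ = [
    "SweepSpec",
    "NovelSegmentSpec",
    "CoverageNoise",
    "SimConfig",
    "NovelSegment",
    "SimTruth",
    "random_reference",
    "simulate_pav",
    "simulate_assemblies",
    "simulate_genotypes",
    "simulate_sweep_tracks",
    "simulate_coverage",
    "simulate_gene_sequences",
    "simulate_term_map",
    "simulate_all",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _ceil_frac(num: int, den: int) -> int:
    """Exact ceil(num/den) for nonnegative integers (no float thresholds)."""
    return -(-num // den)


@dataclass
class SweepSpec:
    """A planted selective sweep on the single simulated chromosome."""

    start: int
    end: int
    score_multiplier: float = 10.0
    pi_reduction: float = 0.2     # multiplier on domesticated pi inside the sweep


@dataclass
class NovelSegmentSpec:
    """Accession-specific novel sequence planted into assembly contigs."""

    per_contig: int = 2
    length_range: tuple[int, int] = (150, 1000)
    shared_fraction: float = 0.0  # probability an insert is drawn from a shared pool


@dataclass
class CoverageNoise:
    """Noise on the per-gene breadth/depth table."""

    dropout: float = 0.02         # present gene reported with failing coverage
    depth_jitter: float = 0.3     # lognormal sigma on depth
    spurious: float = 0.0         # absent gene reported with passing coverage


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with panel-scale defaults.

    The default panel is 116 accessions in three groups; pan-gene class
    counts are the field-typical proportions at 1/100 of a full crop
    pan-genome; the genome is a single 10-Mb chromosome.
    """

    seed: int = 0
    groups: tuple[tuple[str, int], ...] = (("PS", 79), ("PF", 22), ("PA", 15))
    n_core_genes: int = 155
    n_softcore: int = 62
    n_shell: int = 410
    n_cloud: int = 501
    group_preferred: dict[str, int] = field(
        default_factory=lambda: {"PS": 25, "PF": 25, "PA": 25})
    preferred_leak_max: float = 0.02   # max fraction of other accessions carrying a preferred gene
    fst_param: float = 0.3
    n_sites: int = 5000
    chrom_name: str = "chr1"
    chrom_length: int = 10_000_000
    sweep_specs: tuple[SweepSpec, ...] | None = None   # None -> one sweep at [0.2L, 0.3L)
    novel_segment_spec: NovelSegmentSpec = field(default_factory=NovelSegmentSpec)
    coverage_noise: CoverageNoise = field(default_factory=CoverageNoise)
    # assemblies
    backbone_sub_rate: float = 0.01
    n_contigs_per_accession: int = 2
    contig_length_range: tuple[int, int] = (60_000, 120_000)
    # score / pi tracks
    track_window: int = 1_000_000
    track_step: int = 100_000
    score_sigma: float = 0.3
    pi_level: float = 1e-3
    pi_sigma: float = 0.25
    # gene sequences and annotation
    gene_length_range: tuple[int, int] = (300, 900)
    gene_mut_rate: float = 0.01
    annotation_miss_rate: float = 0.05

    def __post_init__(self) -> None:
        for name in ("n_core_genes", "n_softcore", "n_shell", "n_cloud", "n_sites"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 < self.fst_param < 1.0:
            raise ValueError("fst_param must be in (0, 1)")
        if self.sweep_specs is None:
            self.sweep_specs = (SweepSpec(
                self.chrom_length // 5, 3 * self.chrom_length // 10, 10.0, 0.2),)
        for sw in self.sweep_specs:
            if not (0 <= sw.start < sw.end <= self.chrom_length):
                raise ValueError(f"sweep ({sw.start}, {sw.end}) outside chromosome")
        if any(n <= 0 for _, n in self.groups):
            raise ValueError("every group needs >= 1 accession")
        names = {g for g, _ in self.groups}
        if not set(self.group_preferred) <= names:
            raise ValueError("group_preferred names not among groups")

    @property
    def accessions(self) -> list[str]:
        return [f"{g}{i:03d}" for g, n in self.groups for i in range(1, n + 1)]

    @property
    def labels(self) -> dict[str, str]:
        return {f"{g}{i:03d}": g for g, n in self.groups for i in range(1, n + 1)}

    @property
    def n_accessions(self) -> int:
        return sum(n for _, n in self.groups)


@dataclass
class NovelSegment:
    contig: str
    start: int
    end: int
    seq: str


@dataclass
class SimTruth:
    """Machine-readable ground truth; fields are filled by the generators."""

    group_labels: dict[str, str]
    fst_param: float
    pav_matrix: pd.DataFrame | None = None        # bool, clusters x accessions
    gene_class: pd.Series | None = None           # cluster -> planted class
    novel_segments: dict[str, list[NovelSegment]] | None = None
    sweep_intervals: list[tuple[str, int, int]] | None = None

    def to_json(self, path) -> None:
        obj = {
            "group_labels": self.group_labels,
            "fst_param": self.fst_param,
            "gene_class": (None if self.gene_class is None
                           else self.gene_class.to_dict()),
            "novel_segments": (None if self.novel_segments is None else {
                acc: [asdict(s) for s in segs]
                for acc, segs in self.novel_segments.items()}),
            "sweep_intervals": self.sweep_intervals,
        }
        with open(path, "w") as out:
            json.dump(obj, out, indent=1, sort_keys=True)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode()


def random_reference(config: SimConfig, gc: float = 0.5) -> SequenceRecord:
    """The simulated base reference: one random chromosome."""
    rng = _rng(config, 0)
    return SequenceRecord(config.chrom_name,
                          _random_seq(rng, config.chrom_length, gc))


# ---------------------------------------------------------------------------
# PAV matrix with planted classes
# ---------------------------------------------------------------------------

def _class_bands(n: int) -> dict[str, tuple[int, int]]:
    """Inclusive occupancy-count bands for the four classes at panel size n.

    Thresholds are the standard occupancy bands: core >= 99%, soft-core
    [90%, 99%), shell [15%, 90%), cloud (0, 15%).  Computed in exact integer
    arithmetic.
    """
    c99, c90, c15 = _ceil_frac(99 * n, 100), _ceil_frac(90 * n, 100), _ceil_frac(15 * n, 100)
    return {
        "core": (c99, n),
        "softcore": (c90, c99 - 1),
        "shell": (c15, c90 - 1),
        "cloud": (1, c15 - 1),
    }


def simulate_pav(config: SimConfig) -> tuple[PAVMatrix, SimTruth]:
    """Plant a PAV matrix whose genes occupy known classes.

    Occupancy counts are sampled uniformly within each class band; carrier
    accessions are sampled uniformly.  Group-preferred genes are present in
    >= 80% of their own group and in at most ``preferred_leak_max`` of the
    remaining accessions.  Infeasible bands (panel too small to separate the
    thresholds) are a hard error.
    """
    rng = _rng(config, 1)
    accs = config.accessions
    n = len(accs)
    bands = _class_bands(n)
    counts = {"core": config.n_core_genes, "softcore": config.n_softcore,
              "shell": config.n_shell, "cloud": config.n_cloud}
    for cls, (lo, hi) in bands.items():
        if counts[cls] > 0 and lo > hi:
            raise ValueError(
                f"class band {cls!r} infeasible at N={n}: [{lo}, {hi}]")

    rows: list[np.ndarray] = []
    classes: list[str] = []
    for cls in ("core", "softcore", "shell", "cloud"):
        lo, hi = bands[cls]
        for _ in range(counts[cls]):
            occ = int(rng.integers(lo, hi + 1))
            row = np.zeros(n, dtype=bool)
            row[rng.choice(n, size=occ, replace=False)] = True
            rows.append(row)
            classes.append(cls)

    group_idx = {g: [i for i, a in enumerate(accs) if config.labels[a] == g]
                 for g, _ in config.groups}
    for g, n_pref in config.group_preferred.items():
        own = group_idx[g]
        others = [i for i in range(n) if i not in own]
        lo_own = _ceil_frac(80 * len(own), 100)
        max_leak = int(config.preferred_leak_max * len(others))
        for _ in range(n_pref):
            row = np.zeros(n, dtype=bool)
            occ = int(rng.integers(lo_own, len(own) + 1))
            row[rng.choice(own, size=occ, replace=False)] = True
            leak = int(rng.integers(0, max_leak + 1))
            if leak:
                row[rng.choice(others, size=leak, replace=False)] = True
            rows.append(row)
            classes.append(f"preferred_{g}")

    ids = [f"pg{i:06d}" for i in range(len(rows))]
    mat = pd.DataFrame(np.array(rows), index=ids, columns=accs)
    truth = SimTruth(group_labels=config.labels, fst_param=config.fst_param,
                     pav_matrix=mat.copy(),
                     gene_class=pd.Series(classes, index=ids, name="class"))
    return PAVMatrix(mat, config.labels), truth


# ---------------------------------------------------------------------------
# assemblies with planted novel segments
# ---------------------------------------------------------------------------

def _mutate(rng: np.random.Generator, arr: np.ndarray, rate: float) -> np.ndarray:
    """Substitute bases at the given rate (always to a different base)."""
    if rate <= 0:
        return arr.copy()
    out = arr.copy()
    hit = np.flatnonzero(rng.random(arr.size) < rate)
    if hit.size:
        shift = rng.integers(1, 4, size=hit.size).astype(np.uint8)
        # map A,C,G,T codes via index in _BASES
        code = np.zeros(256, dtype=np.uint8)
        code[_BASES] = np.arange(4)
        out[hit] = _BASES[(code[out[hit]] + shift) % 4]
    return out


def simulate_assemblies(
    config: SimConfig, reference: SequenceRecord
) -> tuple[dict[str, list[SequenceRecord]], SimTruth]:
    """Per-accession contigs: reference fragments + noise + novel inserts.

    Each contig is a random reference substring with substitutions at
    ``backbone_sub_rate``, into which GC-matched random novel segments are
    spliced at recorded positions.  Truth lists every planted segment with
    its final contig coordinates.
    """
    rng = _rng(config, 2)
    ref = np.frombuffer(reference.seq.encode(), dtype=np.uint8)
    gc = float(np.isin(ref, np.frombuffer(b"GC", dtype=np.uint8)).mean())
    spec = config.novel_segment_spec
    lo_c, hi_c = config.contig_length_range
    if spec.length_range[1] > lo_c:
        raise ValueError("requested novel length exceeds contig length")

    shared_pool: list[str] = []
    assemblies: dict[str, list[SequenceRecord]] = {}
    novel: dict[str, list[NovelSegment]] = {}
    for acc in config.accessions:
        contigs: list[SequenceRecord] = []
        segs: list[NovelSegment] = []
        acc_used: set[str] = set()
        for ci in range(config.n_contigs_per_accession):
            clen = int(rng.integers(lo_c, hi_c + 1))
            start = int(rng.integers(0, len(ref) - clen + 1))
            backbone = _mutate(rng, ref[start:start + clen], config.backbone_sub_rate)
            name = f"{acc}_ctg{ci}"
            inserts: list[str] = []
            for _ in range(spec.per_contig):
                # a shared segment is reused across accessions but never
                # twice within one accession (duplicates within an accession
                # would make total novel bp depend on iteration order)
                pool_fresh = [s for s in shared_pool if s not in acc_used]
                if pool_fresh and rng.random() < spec.shared_fraction:
                    pick = pool_fresh[int(rng.integers(len(pool_fresh)))]
                    acc_used.add(pick)
                    inserts.append(pick)
                else:
                    ln = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
                    s = _random_seq(rng, ln, gc)
                    inserts.append(s)
                    acc_used.add(s)
                    if spec.shared_fraction > 0:
                        shared_pool.append(s)
            # splice at sorted interior positions, well away from contig ends
            margin = 1000
            points = sorted(int(rng.integers(margin, clen - margin))
                            for _ in inserts)
            pieces: list[np.ndarray] = []
            prev = 0
            offset = 0
            for p, ins in zip(points, inserts):
                pieces.append(backbone[prev:p])
                ins_arr = np.frombuffer(ins.encode(), dtype=np.uint8)
                pieces.append(ins_arr)
                segs.append(NovelSegment(name, p + offset, p + offset + len(ins), ins))
                offset += len(ins)
                prev = p
            pieces.append(backbone[prev:])
            contigs.append(SequenceRecord(name, np.concatenate(pieces).tobytes().decode()))
        assemblies[acc] = contigs
        novel[acc] = segs
    truth = SimTruth(group_labels=config.labels, fst_param=config.fst_param,
                     novel_segments=novel)
    return assemblies, truth


# ---------------------------------------------------------------------------
# genotypes (Balding–Nichols)
# ---------------------------------------------------------------------------

def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Balding–Nichols genotypes with phased haplotypes.

    Per site the ancestral frequency is Uniform(0.05, 0.95); each group's
    frequency is Beta(p(1-F)/F, (1-p)(1-F)/F); haplotypes are independent
    Bernoulli draws at the group frequency, so dosage is Binomial(2, p_g).
    """
    rng = _rng(config, 3)
    F = config.fst_param
    S = config.n_sites
    pos = np.sort(rng.choice(config.chrom_length, size=S, replace=False)) + 1
    p_anc = rng.uniform(0.05, 0.95, size=S)
    ref_alt = rng.integers(0, 4, size=S)
    refs = _BASES[ref_alt]
    alts = _BASES[(ref_alt + 1 + rng.integers(0, 3, size=S)) % 4]

    haps: list[np.ndarray] = []
    group_freqs: dict[str, np.ndarray] = {}
    for g, n_g in config.groups:
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        p_g = rng.beta(a, b)
        group_freqs[g] = p_g
        h = (rng.random((S, n_g, 2)) < p_g[:, None, None]).astype(np.int8)
        haps.append(h)
    haplotypes = np.concatenate(haps, axis=1)
    dosage = haplotypes.sum(axis=2, dtype=np.int8)
    sites = pd.DataFrame({
        "chrom": config.chrom_name, "pos": pos.astype(int),
        "ref": [chr(x) for x in refs], "alt": [chr(x) for x in alts]})
    gm = GenotypeMatrix(sites, config.accessions, dosage, haplotypes)
    gm.ancestral_freq = p_anc          # type: ignore[attr-defined]
    gm.group_frequencies = group_freqs  # type: ignore[attr-defined]
    return gm


# ---------------------------------------------------------------------------
# sweep tracks
# ---------------------------------------------------------------------------

def _merge_intervals(iv: list[tuple[int, int, float, float]]):
    """Merge overlapping planted sweeps; keep the strongest parameters."""
    iv = sorted(iv)
    out: list[list[float]] = []
    merged = False
    for s, e, m, r in iv:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
            out[-1][2] = max(out[-1][2], m)
            out[-1][3] = min(out[-1][3], r)
            merged = True
        else:
            out.append([s, e, m, r])
    return out, merged


def simulate_sweep_tracks(
    config: SimConfig,
) -> tuple[WindowTrack, WindowTrack, WindowTrack, list[tuple[str, int, int]]]:
    """Score track plus wild/domesticated pi tracks with planted sweeps.

    Background scores are lognormal; every window overlapping a planted
    sweep has its score multiplied by the sweep's multiplier and the
    domesticated-population pi multiplied by its reduction factor (< 1).
    Returns (score, pi_wild, pi_dom, truth intervals); overlapping planted
    sweeps are merged in the truth with a warning.
    """
    rng = _rng(config, 4)
    L, w, step = config.chrom_length, config.track_window, config.track_step
    starts = np.arange(0, L, step, dtype=np.int64)
    ends = np.minimum(starts + w, L)
    W = len(starts)
    chroms = np.array([config.chrom_name] * W, dtype=object)

    score = rng.lognormal(0.0, config.score_sigma, size=W)
    pi_wild = rng.lognormal(np.log(config.pi_level), config.pi_sigma, size=W)
    pi_dom = pi_wild * rng.lognormal(0.0, 0.1, size=W)

    merged, did_merge = _merge_intervals(
        [(s.start, s.end, s.score_multiplier, s.pi_reduction)
         for s in config.sweep_specs])
    if did_merge:
        logger.warning("simulate_sweep_tracks: overlapping planted sweeps merged")
    for s, e, mult, red in merged:
        hit = (starts < e) & (ends > s)
        score[hit] *= mult
        pi_dom[hit] *= red

    truth = [(config.chrom_name, int(s), int(e)) for s, e, _, _ in merged]
    return (
        WindowTrack(chroms, starts, ends, score, "score"),
        WindowTrack(chroms.copy(), starts.copy(), ends.copy(), pi_wild, "pi_wild"),
        WindowTrack(chroms.copy(), starts.copy(), ends.copy(), pi_dom, "pi_dom"),
        truth,
    )


# ---------------------------------------------------------------------------
# coverage table and annotated gene sets
# ---------------------------------------------------------------------------

def simulate_coverage(
    config: SimConfig, pav_truth: pd.DataFrame
) -> tuple[list[CoverageRecord], dict[str, set[str]]]:
    """Emit the per-gene breadth/depth table and the annotated gene sets.

    Truly present genes get full breadth and ~10x depth (lognormal jitter);
    with probability ``dropout`` a present gene instead reports failing
    coverage.  Absent genes report low breadth/depth, except for rare
    ``spurious`` passes.  Annotation misses a present gene with probability
    ``annotation_miss_rate``; at zero noise the combined presence evidence
    reproduces truth exactly.
    """
    rng = _rng(config, 5)
    noise = config.coverage_noise
    records: list[CoverageRecord] = []
    annotated: dict[str, set[str]] = {acc: set() for acc in pav_truth.columns}
    mat = pav_truth.to_numpy()
    clusters = list(pav_truth.index)
    for j, acc in enumerate(pav_truth.columns):
        for i, cid in enumerate(clusters):
            if mat[i, j]:
                if rng.random() >= config.annotation_miss_rate:
                    annotated[acc].add(cid)
                if noise.dropout > 0 and rng.random() < noise.dropout:
                    breadth = float(rng.uniform(0.2, 0.9))
                    depth = float(rng.uniform(0.0, 2.5))
                else:
                    breadth = 1.0
                    depth = (10.0 if noise.depth_jitter == 0
                             else float(rng.lognormal(np.log(10.0), noise.depth_jitter)))
            else:
                if noise.spurious > 0 and rng.random() < noise.spurious:
                    breadth, depth = 1.0, 5.0
                else:
                    breadth = 0.0 if noise.dropout == 0 and noise.depth_jitter == 0 \
                        else float(rng.uniform(0.0, 0.5))
                    depth = 0.0 if noise.dropout == 0 and noise.depth_jitter == 0 \
                        else float(rng.uniform(0.0, 2.0))
            records.append(CoverageRecord(acc, cid, breadth, depth))
    # a pan-gene cluster only exists if somebody annotated it: keep at least
    # one annotated carrier per planted cluster
    for i, cid in enumerate(clusters):
        if not any(cid in annotated[acc] for acc in pav_truth.columns):
            carriers = np.flatnonzero(mat[i])
            if carriers.size:
                annotated[pav_truth.columns[carriers[0]]].add(cid)
    return records, annotated


def simulate_gene_sequences(
    config: SimConfig, pav_truth: pd.DataFrame, annotated: dict[str, set[str]] | None = None
) -> list[tuple[str, str, str]]:
    """Per-accession gene copies: one random template per cluster, mutated
    at ``gene_mut_rate`` in each carrier accession.

    When ``annotated`` is given only annotated copies are emitted (the
    map-to-pan step recovers the rest).
    """
    rng = _rng(config, 6)
    lo, hi = config.gene_length_range
    genes: list[tuple[str, str, str]] = []
    for cid in pav_truth.index:
        ln = int(rng.integers(lo, hi + 1))
        template = np.frombuffer(_random_seq(rng, ln).encode(), dtype=np.uint8)
        for acc in pav_truth.columns:
            if not pav_truth.loc[cid, acc]:
                continue
            copy = _mutate(rng, template, config.gene_mut_rate).tobytes().decode()
            if annotated is None or cid in annotated.get(acc, ()):
                genes.append((acc, f"{acc}.{cid}", copy))
    return genes


def simulate_term_map(
    config: SimConfig, gene_class: pd.Series, n_background_terms: int = 20
) -> dict[str, list[str]]:
    """A gene -> terms map in which each group-preferred gene set carries an
    enriched marker term, on top of uniform background terms."""
    rng = _rng(config, 7)
    term_map: dict[str, list[str]] = {g: [] for g in gene_class.index}
    for g in gene_class.index:
        cls = gene_class[g]
        if cls.startswith("preferred_") and rng.random() < 0.9:
            term_map[g].append(f"T_{cls.removeprefix('preferred_')}")
        k = int(rng.integers(1, 4))
        for t in rng.choice(n_background_terms, size=k, replace=False):
            term_map[g].append(f"T_bg{int(t):02d}")
    return term_map


def simulate_all(config: SimConfig):
    """Run every generator; returns a dict of artifacts plus merged truth."""
    pav, truth = simulate_pav(config)
    reference = random_reference(config)
    assemblies, atruth = simulate_assemblies(config, reference)
    geno = simulate_genotypes(config)
    score, pi_wild, pi_dom, sweeps = simulate_sweep_tracks(config)
    coverage, annotated = simulate_coverage(config, truth.pav_matrix)
    genes = simulate_gene_sequences(config, truth.pav_matrix, annotated)
    term_map = simulate_term_map(config, truth.gene_class)
    truth.novel_segments = atruth.novel_segments
    truth.sweep_intervals = sweeps
    return {
        "config": config, "pav": pav, "truth": truth, "reference": reference,
        "assemblies": assemblies, "genotypes": geno, "score_track": score,
        "pi_wild": pi_wild, "pi_dom": pi_dom, "coverage": coverage,
        "annotated": annotated, "genes": genes, "term_map": term_map,
    }
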