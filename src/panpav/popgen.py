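"""Windowed population-genetic statistics and the composite sweep filter.

Nucleotide diversity per window sums the per-site unbiased heterozygosity
pi_site = 2 c (n - c) / (n (n - 1)) (c alt alleles among n non-missing
alleles) and divides by the window span in bp.  Differentiation uses the
Weir & Cockerham (1984) variance-component estimator theta = sum(a) /
sum(a + b + c); negative estimates are reported raw.  LD decay bins
pairwise r-squared by distance and reports the half-decay distance.  The
sweep filter combines a normalized selection-score track (top 5% of
windows) with a reduction-of-diversity filter (top 50% of the selected
windows by ROD = pi_wild / pi_domesticated) and merges surviving windows
into sweeps.

Default window parameters are a 1,000-kb window sliding in 100-kb steps;
windowing helpers accept an optional cap on the number of SNPs assayed per
window (600 by convention for score scans).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, WindowTrack

logger = logging.getLogger("panpav")

__all__ = [
    "SweepInterval",
    "window_grid",
    "site_pi",
    "window_pi",
    "weir_cockerham_fst",
    "ld_decay",
    "half_decay_distance",
    "rod_track",
    "sweep_filter",
    "lai",
]

WINDOW_DEFAULT = 1_000_000
STEP_DEFAULT = 100_000
SNP_CAP_DEFAULT = 600


def window_grid(chrom_lengths: dict[str, int], window: int = WINDOW_DEFAULT,
                step: int = STEP_DEFAULT) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sliding windows tiling each chromosome (0-based half-open)."""
    if window < step:
        raise ValueError("window must be >= step")
    chroms, starts, ends = [], [], []
    for chrom in chrom_lengths:
        L = chrom_lengths[chrom]
        s = np.arange(0, L, step, dtype=np.int64)
        chroms.extend([chrom] * len(s))
        starts.append(s)
        ends.append(np.minimum(s + window, L))
    return (np.array(chroms, dtype=object), np.concatenate(starts),
            np.concatenate(ends))


def site_pi(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site pi and a validity mask from a dosage block (sites x samples).

    Sites with fewer than two non-missing alleles are flagged invalid and
    skipped by callers (with a log message).
    """
    missing = dosage < 0
    n = 2 * (dosage.shape[1] - missing.sum(axis=1))
    c = np.where(missing, 0, dosage).sum(axis=1)
    valid = n >= 2
    pi = np.zeros(dosage.shape[0])
    nn = n[valid].astype(float)
    cc = c[valid].astype(float)
    pi[valid] = 2.0 * cc * (nn - cc) / (nn * (nn - 1.0))
    return pi, valid


def window_pi(
    geno: GenotypeMatrix,
    samples: list[str] | None = None,
    window: int = WINDOW_DEFAULT,
    step: int = STEP_DEFAULT,
    chrom_lengths: dict[str, int] | None = None,
    max_snps_per_window: int | None = None,
) -> WindowTrack:
    """Windowed nucleotide diversity (pi per bp of window span).

    Missing genotypes are excluded site-wise.  ``max_snps_per_window``
    optionally caps the number of (genomically first) SNPs assayed per
    window, the convention used for score scans; it is off by default.
    """
    sub = geno if samples is None else geno.subset_samples(samples)
    if sub.n_samples == 0:
        raise ValueError("empty sample subset")
    if chrom_lengths is None:
        chrom_lengths = {
            str(chrom): int(grp["pos"].max())
            for chrom, grp in sub.sites.groupby("chrom", sort=True)}
    chroms, starts, ends = window_grid(chrom_lengths, window, step)
    pi, valid = site_pi(sub.dosage)
    if (~valid).any():
        logger.info("window_pi: skipped %d sites with < 2 alleles",
                    int((~valid).sum()))
    values = np.zeros(len(chroms))
    pos0 = sub.sites["pos"].to_numpy() - 1   # site position, 0-based
    site_chrom = sub.sites["chrom"].to_numpy()
    for w in range(len(chroms)):
        on = site_chrom == chroms[w]
        lo = np.searchsorted(pos0[on], starts[w], side="left")
        hi = np.searchsorted(pos0[on], ends[w], side="left")
        idx = np.flatnonzero(on)[lo:hi]
        idx = idx[valid[idx]]
        if max_snps_per_window is not None:
            idx = idx[:max_snps_per_window]
        values[w] = pi[idx].sum() / (ends[w] - starts[w])
    return WindowTrack(chroms, starts, ends, values, "pi")


# ---------------------------------------------------------------------------
# Weir–Cockerham FST
# ---------------------------------------------------------------------------

def _wc_components(dosage: np.ndarray, group_idx: list[np.ndarray]
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site WC84 variance components (a, b, c) and a validity mask.

    Diploid formulation with heterozygote correction: per population i,
    n_i = non-missing individuals, p_i = alt frequency, h_i = observed
    heterozygote frequency.
    """
    r = len(group_idx)
    S = dosage.shape[0]
    n_i = np.empty((r, S))
    p_i = np.empty((r, S))
    h_i = np.empty((r, S))
    for gi, idx in enumerate(group_idx):
        d = dosage[:, idx]
        miss = d < 0
        n = (~miss).sum(axis=1)
        n_i[gi] = n
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[gi] = np.where(miss, 0, d).sum(axis=1) / (2.0 * n)
            h_i[gi] = np.where(miss, 0, d == 1).sum(axis=1) / n

    valid = (n_i >= 1).all(axis=0) & (n_i.sum(axis=0) > r)
    n_bar = n_i.mean(axis=0)
    sum_n = n_i.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_bar = (n_i * p_i).sum(axis=0) / (r * n_bar)
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / (r * n_bar)
        n_c = (sum_n - (n_i ** 2).sum(axis=0) / sum_n) / (r - 1)
        pq = p_bar * (1 - p_bar)
        a = (n_bar / n_c) * (
            s2 - (pq - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1))
        b = (n_bar / (n_bar - 1)) * (
            pq - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
        c = h_bar / 2
    # a site contributes only when every pop has data and the denominators exist
    valid &= np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    return a, b, c, valid


def weir_cockerham_fst(
    geno: GenotypeMatrix,
    labels: dict[str, str],
    windows: tuple[int, int] | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> float | tuple[float, WindowTrack]:
    """Weir & Cockerham (1984) theta, genome-wide and optionally per window.

    The estimate is sum(a) / sum(a + b + c) over the contributing sites.
    Negative estimates are reported raw (not clamped).  ``windows`` is an
    optional (window, step) pair; when given, a per-window track is
    returned alongside the genome-wide value.
    """
    groups = sorted(set(labels[s] for s in geno.samples))
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    group_idx = [np.array([i for i, s in enumerate(geno.samples)
                           if labels[s] == g]) for g in groups]
    for g, idx in zip(groups, group_idx):
        if len(idx) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    a, b, c, valid = _wc_components(geno.dosage, group_idx)
    denom = (a + b + c)[valid].sum()
    genome = float(a[valid].sum() / denom) if denom != 0 else math.nan

    if windows is None:
        return genome
    window, step = windows
    if chrom_lengths is None:
        chrom_lengths = {
            str(chrom): int(grp["pos"].max())
            for chrom, grp in geno.sites.groupby("chrom", sort=True)}
    chroms, starts, ends = window_grid(chrom_lengths, window, step)
    values = np.full(len(chroms), np.nan)
    pos0 = geno.sites["pos"].to_numpy() - 1
    site_chrom = geno.sites["chrom"].to_numpy()
    for w in range(len(chroms)):
        on = site_chrom == chroms[w]
        lo = np.searchsorted(pos0[on], starts[w], side="left")
        hi = np.searchsorted(pos0[on], ends[w], side="left")
        idx = np.flatnonzero(on)[lo:hi]
        idx = idx[valid[idx]]
        den = (a + b + c)[idx].sum()
        if den != 0:
            values[w] = a[idx].sum() / den
    track = WindowTrack(chroms, starts, ends, values, "fst")
    return genome, track


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------

def _smooth(y: np.ndarray, width: int = 3) -> np.ndarray:
    if width <= 1 or y.size < 2:
        return y
    kernel = np.ones(width)
    num = np.convolve(y, kernel, mode="same")
    den = np.convolve(np.ones_like(y), kernel, mode="same")
    return num / den


def half_decay_distance(midpoints: np.ndarray, mean_r2: np.ndarray,
                        smooth_width: int = 3) -> float:
    """Smallest bin midpoint where smoothed mean r2 <= half its maximum."""
    sm = _smooth(np.asarray(mean_r2, dtype=float), smooth_width)
    half = sm.max() / 2.0
    below = np.flatnonzero(sm <= half)
    return float(midpoints[below[0]]) if below.size else math.nan


def ld_decay(
    geno: GenotypeMatrix,
    samples: list[str] | None = None,
    max_dist: int = 500_000,
    bin_width: int = 1_000,
    smooth_width: int = 3,
) -> tuple[pd.DataFrame, float]:
    """Binned mean r-squared versus distance, plus the half-decay distance.

    With phased haplotypes r2 = D^2 / (pA qA pB qB) from haplotype
    frequencies; otherwise the fallback is the squared Pearson correlation
    of dosages.  Monomorphic sites are skipped.
    """
    sub = geno if samples is None else geno.subset_samples(samples)
    nbins = max(1, math.ceil(max_dist / bin_width))
    sums = np.zeros(nbins)
    counts = np.zeros(nbins, dtype=np.int64)
    phased = sub.haplotypes is not None

    for chrom, grp in sub.sites.groupby("chrom", sort=True):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        if phased:
            hap = sub.haplotypes[idx].reshape(len(idx), -1).astype(float)
            freq = hap.mean(axis=1)
            poly = (freq > 0) & (freq < 1)
        else:
            dos = sub.dosage[idx].astype(float)
            dos[dos < 0] = np.nan
            poly = np.nanstd(dos, axis=1) > 0
        for ii in range(len(idx)):
            if not poly[ii]:
                continue
            hi = np.searchsorted(pos, pos[ii] + max_dist, side="right")
            js = np.arange(ii + 1, hi)
            js = js[poly[js]]
            if js.size == 0:
                continue
            dist = pos[js] - pos[ii]
            if phased:
                pa = freq[ii]
                pb = freq[js]
                pab = hap[js] @ hap[ii] / hap.shape[1]
                d = pab - pa * pb
                r2 = d ** 2 / (pa * (1 - pa) * pb * (1 - pb))
            else:
                x = dos[ii]
                y = dos[js]
                ok = ~np.isnan(x)[None, :] & ~np.isnan(y)
                r2 = np.empty(js.size)
                for t in range(js.size):
                    sel = ok[t]
                    if sel.sum() < 2 or np.std(x[sel]) == 0 or np.std(y[t][sel]) == 0:
                        r2[t] = np.nan
                        continue
                    r2[t] = np.corrcoef(x[sel], y[t][sel])[0, 1] ** 2
            keep = np.isfinite(r2)
            b = np.minimum((dist[keep] - 1) // bin_width, nbins - 1).astype(int)
            np.add.at(sums, b, r2[keep])
            np.add.at(counts, b, 1)

    mid = (np.arange(nbins) + 0.5) * bin_width
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    curve = pd.DataFrame({"dist_mid": mid, "mean_r2": mean, "n_pairs": counts})
    have = counts > 0
    hd = half_decay_distance(mid[have], mean[have], smooth_width) if have.any() else math.nan
    return curve, hd


# ---------------------------------------------------------------------------
# composite sweep filter
# ---------------------------------------------------------------------------

@dataclass
class SweepInterval:
    """A merged run of windows that survived both sweep filters."""

    chrom: str
    start: int
    end: int
    windows: list[int] = field(default_factory=list)   # indices into the track
    max_score: float = math.nan                        # max normalized score
    min_rod_rank: int = 0                              # best (smallest) ROD rank

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("empty sweep interval")


def rod_track(pi_wild: WindowTrack, pi_dom: WindowTrack) -> WindowTrack:
    """Reduction of diversity per window: ROD = pi_wild / pi_dom.

    pi_dom = 0 yields +inf (flagged infinite, ranked strongest downstream).
    """
    if not pi_wild.same_grid(pi_dom):
        raise ValueError("pi tracks on different window grids")
    with np.errstate(divide="ignore", invalid="ignore"):
        rod = pi_wild.values / pi_dom.values
    return WindowTrack(pi_wild.chroms, pi_wild.starts, pi_wild.ends, rod, "rod")


def sweep_filter(
    score: WindowTrack,
    pi_wild: WindowTrack,
    pi_dom: WindowTrack,
    top_score: float = 0.05,
    top_rod: float = 0.50,
) -> tuple[list[SweepInterval], dict[str, pd.DataFrame]]:
    """Composite selective-sweep filter.

    1. z-normalize the score track genome-wide;
    2. select the top ceil(top_score * W) windows by normalized score (ties
       broken by genomic order);
    3. among the selected windows (dropping pi_wild = 0 windows with a log
       message) compute ROD = pi_wild / pi_dom and keep the top
       ceil(top_rod * n_selected) by ROD, infinite ROD ranked highest;
    4. merge overlapping or bookended survivors into sweeps.

    Returns the merged sweeps plus an audit dict with every intermediate
    window list.
    """
    if not (score.same_grid(pi_wild) and score.same_grid(pi_dom)):
        raise ValueError("score and pi tracks on different window grids")
    W = len(score)
    z = (score.values - score.values.mean()) / score.values.std()
    n_sel = math.ceil(top_score * W)
    order = np.lexsort((np.arange(W), -z))
    selected = np.sort(order[:n_sel])

    zero_wild = selected[pi_wild.values[selected] == 0]
    if zero_wild.size:
        logger.info("sweep_filter: excluded %d selected windows with pi_wild = 0",
                    int(zero_wild.size))
        selected = selected[pi_wild.values[selected] != 0]

    with np.errstate(divide="ignore"):
        rod = pi_wild.values[selected] / pi_dom.values[selected]
    n_keep = math.ceil(top_rod * len(selected))
    rod_order = np.lexsort((selected, -rod))    # -inf first for rod = +inf
    ranks = np.empty(len(selected), dtype=int)
    ranks[rod_order] = np.arange(1, len(selected) + 1)
    survivors = np.sort(selected[rod_order[:n_keep]])
    rank_of = dict(zip(selected.tolist(), ranks.tolist()))

    sweeps: list[SweepInterval] = []
    for w in survivors:
        w = int(w)
        chrom = score.chroms[w]
        s, e = int(score.starts[w]), int(score.ends[w])
        if sweeps and sweeps[-1].chrom == chrom and s <= sweeps[-1].end:
            cur = sweeps[-1]
            cur.end = max(cur.end, e)
            cur.windows.append(w)
            cur.max_score = max(cur.max_score, z[w])
            cur.min_rod_rank = min(cur.min_rod_rank, rank_of[w])
        else:
            sweeps.append(SweepInterval(chrom, s, e, [w], float(z[w]), rank_of[w]))

    def frame(idx: np.ndarray) -> pd.DataFrame:
        idx = np.asarray(idx, dtype=int)
        return pd.DataFrame({
            "window": idx, "chrom": score.chroms[idx],
            "start": score.starts[idx], "end": score.ends[idx],
            "score": score.values[idx], "z": z[idx],
            "pi_wild": pi_wild.values[idx], "pi_dom": pi_dom.values[idx]})

    audit = {
        "all": frame(np.arange(W)),
        "selected": frame(selected),
        "survivors": frame(survivors),
    }
    audit["selected"]["rod_rank"] = [rank_of[int(w)] for w in selected]
    return sweeps, audit


def lai(intact_ltr_bp: float, total_ltr_bp: float) -> float:
    """LTR Assembly Index: intact LTR-RT length over total, times 100."""
    if total_ltr_bp <= 0:
        raise ValueError("total LTR-RT length must be > 0")
    if not 0 <= intact_ltr_bp <= total_ltr_bp:
        raise ValueError("intact length must be in [0, total]")
    return 100.0 * intact_ltr_bp / total_ltr_bp
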