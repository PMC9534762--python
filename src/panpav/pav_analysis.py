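"""Pan-gene occupancy analytics on the PAV matrix.

Occupancy classes follow the bands standard in bacterial and plant
pan-genomics: core >= 99% of genomes, soft-core [90%, 99%), shell
[15%, 90%), cloud (0, 15%).  Accumulation curves are computed over random
accession orderings; the pan curve is fitted with a Heaps-type power law
P(n) = A n^gamma + C and the core curve with an exponential decay
K(n) = kappa exp(-n / tau) + Omega (the Tettelin convention).  Term
enrichment uses the one-sided Fisher exact test (hypergeometric upper tail)
with Benjamini–Hochberg adjustment over the tested terms only.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .pav_build import PAVMatrix

logger = logging.getLogger("panpav")

__all__ = [
    "CLASS_ORDER",
    "AccumulationCurve",
    "SaturationFit",
    "classify_occupancy",
    "classify_pan_genes",
    "pan_core_curves",
    "fit_saturation_models",
    "unique_group_genes",
    "enrich_terms",
]

CLASS_ORDER = ("core", "softcore", "shell", "cloud")


def classify_occupancy(count: int, n: int) -> str:
    """Class of one gene given its occupancy count out of n genomes.

    Band membership is decided in exact integer arithmetic (count/n >= q/100
    iff 100*count >= q*n), so printed-threshold boundary cases are exact.
    """
    if not 1 <= count <= n:
        raise ValueError(f"occupancy count {count} outside [1, {n}]")
    scaled = 100 * count
    if scaled >= 99 * n:
        return "core"
    if scaled >= 90 * n:
        return "softcore"
    if scaled >= 15 * n:
        return "shell"
    return "cloud"


def classify_pan_genes(pav: PAVMatrix, group: str | None = None) -> tuple[pd.DataFrame, pd.Series]:
    """Classify every pan-gene into core/softcore/shell/cloud.

    With ``group`` set, classification is restricted to that group's columns
    (genes absent from the whole group are dropped).  Returns a per-cluster
    table (count, fraction, class) and the per-class totals.
    """
    mat = pav.matrix if group is None else pav.matrix[pav.group_columns(group)]
    if mat.shape[1] < 2:
        raise ValueError("classification needs >= 2 accessions")
    counts = mat.sum(axis=1).astype(int)
    if group is None and (counts == 0).any():
        raise ValueError("cluster with zero presences")
    counts = counts[counts > 0]
    n = mat.shape[1]
    classes = counts.map(lambda c: classify_occupancy(int(c), n))
    table = pd.DataFrame({
        "count": counts, "fraction": counts / n, "class": classes})
    totals = classes.value_counts().reindex(CLASS_ORDER, fill_value=0)
    return table, totals


@dataclass
class AccumulationCurve:
    """Pan/core gene counts versus number of sampled genomes."""

    n_genomes: np.ndarray        # 1..N
    pan_mean: np.ndarray
    pan_sd: np.ndarray
    core_mean: np.ndarray        # strict intersection of sampled genomes
    core_sd: np.ndarray
    n_perm: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "n_genomes": self.n_genomes, "pan_mean": self.pan_mean,
            "pan_sd": self.pan_sd, "core_mean": self.core_mean,
            "core_sd": self.core_sd})


def pan_core_curves(pav: PAVMatrix, n_perm: int = 100,
                    seed: int | None = 0, exhaustive: bool = False) -> AccumulationCurve:
    """Accumulation curves over permutations of accession order.

    pan(n) is the union and core(n) the strict intersection of presences
    over the first n genomes of each ordering.  ``exhaustive`` enumerates
    all N! orderings (small panels only) instead of sampling.
    """
    mat = pav.matrix.to_numpy()
    n_acc = mat.shape[1]
    if exhaustive:
        perms = [np.array(p) for p in itertools.permutations(range(n_acc))]
    else:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(n_acc) for _ in range(n_perm)]
    pans = np.empty((len(perms), n_acc), dtype=np.int64)
    cores = np.empty_like(pans)
    for i, p in enumerate(perms):
        m = mat[:, p]
        pans[i] = np.logical_or.accumulate(m, axis=1).sum(axis=0)
        cores[i] = np.logical_and.accumulate(m, axis=1).sum(axis=0)
    return AccumulationCurve(
        np.arange(1, n_acc + 1), pans.mean(axis=0), pans.std(axis=0),
        cores.mean(axis=0), cores.std(axis=0), len(perms))


@dataclass
class SaturationFit:
    """Least-squares fit of the pan and core accumulation models."""

    pan_params: tuple[float, float, float] | None   # (A, gamma, C)
    pan_se: tuple[float, float, float] | None
    core_params: tuple[float, float, float] | None  # (kappa, tau, omega)
    pan_residual: float
    core_residual: float
    verdict: str                                    # open / closed / uncertain
    flags: list[str]


def _heaps(n, a, gamma, c):
    return a * np.power(n, gamma) + c


def _expdecay(n, kappa, tau, omega):
    return kappa * np.exp(-n / tau) + omega


def fit_saturation_models(curve: AccumulationCurve) -> SaturationFit:
    """Fit P(n) = A n^gamma + C and K(n) = kappa e^(-n/tau) + Omega.

    The pan-genome is called "open" when gamma is significantly positive
    (gamma > 2 SE); non-convergence or a degenerate core curve is flagged,
    never silent.
    """
    if len(curve.n_genomes) < 4:
        raise ValueError("need >= 4 curve points to fit")
    n = curve.n_genomes.astype(float)
    flags: list[str] = []

    pan_params = pan_se = None
    pan_resid = math.nan
    try:
        p0 = (max(curve.pan_mean[-1] - curve.pan_mean[0], 1.0), 0.5, 0.0)
        popt, pcov = optimize.curve_fit(_heaps, n, curve.pan_mean, p0=p0, maxfev=20000)
        pan_params = tuple(popt)
        pan_se = tuple(np.sqrt(np.diag(pcov)))
        pan_resid = float(np.linalg.norm(curve.pan_mean - _heaps(n, *popt)))
    except (RuntimeError, ValueError):
        flags.append("pan_fit_failed")

    core_params = None
    core_resid = math.nan
    if np.ptp(curve.core_mean) == 0:
        core_params = (0.0, math.inf, float(curve.core_mean[0]))
        core_resid = 0.0
        flags.append("core_degenerate_constant")
    else:
        try:
            p0 = (curve.core_mean[0] - curve.core_mean[-1],
                  max(len(n) / 3.0, 1.0), curve.core_mean[-1])
            popt, _ = optimize.curve_fit(_expdecay, n, curve.core_mean, p0=p0,
                                         maxfev=20000)
            core_params = tuple(popt)
            core_resid = float(np.linalg.norm(curve.core_mean - _expdecay(n, *popt)))
        except (RuntimeError, ValueError):
            flags.append("core_fit_failed")

    if pan_params is None:
        verdict = "uncertain"
    else:
        gamma, g_se = pan_params[1], pan_se[1]
        if not np.isfinite(g_se):
            verdict = "uncertain"
        elif gamma - 2 * g_se > 0:
            verdict = "open"
        else:
            verdict = "closed"
    return SaturationFit(pan_params, pan_se, core_params, pan_resid,
                         core_resid, verdict, flags)


def unique_group_genes(pav: PAVMatrix, labels: dict[str, str] | None = None
                       ) -> dict[str, dict[str, list[str]]]:
    """Per-group unique pan-genes and unique core genes.

    A cluster is unique to a group when it is present in >= 1 accession of
    exactly one group (genes shared between at least two groups are
    removed); unique-core additionally requires core occupancy within the
    group's own columns.
    """
    labels = labels or pav.labels
    groups = sorted(set(labels[a] for a in pav.accessions))
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    present = {}
    for g in groups:
        cols = [a for a in pav.accessions if labels[a] == g]
        if not cols:
            raise ValueError(f"group {g!r} has no accessions")
        present[g] = pav.matrix[cols]
    any_present = pd.DataFrame({g: present[g].any(axis=1) for g in groups})
    n_groups_present = any_present.sum(axis=1)

    out: dict[str, dict[str, list[str]]] = {}
    for g in groups:
        unique_mask = any_present[g] & (n_groups_present == 1)
        unique_pan = list(pav.matrix.index[unique_mask])
        n_g = present[g].shape[1]
        counts = present[g].sum(axis=1)
        core_mask = unique_mask & (100 * counts >= 99 * n_g)
        out[g] = {"unique_pan": unique_pan,
                  "unique_core": list(pav.matrix.index[core_mask])}
    return out


def enrich_terms(
    foreground: set[str],
    background: set[str],
    term_map: dict[str, list[str]],
) -> pd.DataFrame:
    """One-sided Fisher enrichment of terms in ``foreground`` vs ``background``.

    p is the hypergeometric upper tail P(X >= overlap); q is the
    Benjamini–Hochberg adjustment over the tested terms.  Terms with zero
    background members are skipped with a log message.
    """
    if not foreground <= background:
        raise ValueError("foreground must be a subset of background")
    terms: dict[str, set[str]] = {}
    for gene, ts in term_map.items():
        for t in ts:
            members = terms.setdefault(t, set())
            if gene in background:
                members.add(gene)
    m_universe = len(background)
    n_fg = len(foreground)
    rows = []
    skipped = 0
    for term in sorted(terms):
        members = terms[term]
        big_k = len(members)
        if big_k == 0:
            skipped += 1
            continue
        overlap = len(members & foreground)
        p = float(stats.hypergeom.sf(overlap - 1, m_universe, big_k, n_fg))
        rows.append({"term": term, "overlap": overlap, "term_size": big_k,
                     "fg_size": n_fg, "universe": m_universe, "p": p})
    if skipped:
        logger.info("enrich_terms: skipped %d terms with empty background", skipped)
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
        df = df.sort_values(["p", "term"]).reset_index(drop=True)
    return df
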