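"""Extended haplotype homozygosity (EHH), relative EHH, and the long
range haplotype (LRH) test.

EHH of a core haplotype at a marker is the probability that two
distinct, randomly chosen carrier chromosomes are identical over the
whole interval from the core out to that marker.  REHH relates a core's
EHH to the pooled EHH of all other chromosomes at the same span, which
cancels locus-wide recombination-rate variation.  The LRH test asks
whether a core's log REHH at a fixed genetic distance is extreme
relative to frequency-matched cores drawn from background regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .datamodel import GeneticMap, HaplotypeMatrix


@dataclass
class CoreHaplotype:
    """A distinct allele string over a contiguous core span of 1-20 SNPs."""

    start: int               # site index, inclusive
    stop: int                # site index, exclusive
    allele_string: str
    carriers: np.ndarray     # chromosome row indices
    n: int                   # total chromosomes in the sample

    @property
    def span_length(self) -> int:
        return self.stop - self.start

    @property
    def frequency(self) -> float:
        return len(self.carriers) / self.n


def pair_identity(group_sizes: np.ndarray, total: int) -> float:
    """Σ C(e_h, 2) / C(total, 2) — probability two random distinct
    chromosomes fall in the same identity class."""
    g = np.asarray(group_sizes, dtype=float)
    if total < 2:
        raise ValueError("need at least 2 chromosomes")
    return float(np.sum(g * (g - 1) / 2.0) / (total * (total - 1) / 2.0))


def _group_sizes(alleles: np.ndarray) -> np.ndarray:
    _, counts = np.unique(alleles, axis=0, return_counts=True)
    return counts


def ehh_at(matrix: HaplotypeMatrix, core: CoreHaplotype, to_site: int) -> float:
    """EHH of a core at ``to_site`` (site index outside the core span).

    Identity is over all columns from the core through ``to_site``
    inclusive.  Returns NaN when the core has fewer than 2 carriers.
    """
    if core.start <= to_site < core.stop:
        raise ValueError("to_site must lie outside the core span")
    if len(core.carriers) < 2:
        return float("nan")
    lo = min(core.start, to_site)
    hi = max(core.stop, to_site + 1)
    matrix.require_complete(slice(lo, hi))
    sub = matrix.alleles[np.asarray(core.carriers)][:, lo:hi]
    return pair_identity(_group_sizes(sub), len(core.carriers))


def ehh_profile(matrix: HaplotypeMatrix, rows: np.ndarray, anchor_lo: int,
                anchor_hi: int, direction: int) -> np.ndarray:
    """EHH among ``rows`` at each successive marker outward from the
    anchor span ``[anchor_lo, anchor_hi)``.

    direction +1 walks right from ``anchor_hi``, −1 walks left from
    ``anchor_lo − 1``.  Incremental grouping keeps this O(sites x rows).
    """
    rows = np.asarray(rows)
    m = len(rows)
    if m < 2:
        raise ValueError("need >= 2 chromosomes in the class")
    sub = matrix.alleles[rows]
    base = sub[:, anchor_lo:anchor_hi]
    _, labels = np.unique(base, axis=0, return_inverse=True) if base.shape[1] else (None, np.zeros(m, dtype=np.int64))
    sites = (range(anchor_hi, matrix.n_sites) if direction > 0
             else range(anchor_lo - 1, -1, -1))
    out = []
    for j in sites:
        col = sub[:, j]
        if np.any(col < 0):
            raise ValueError("missing data inside the analyzed span")
        key = labels * 2 + col
        _, labels = np.unique(key, return_inverse=True)
        counts = np.bincount(labels).astype(float)
        out.append(float(np.sum(counts * (counts - 1)) / (m * (m - 1))))
    return np.asarray(out)


@dataclass
class EHHCurve:
    """EHH decay of one core in one direction, with distances from the
    nearer core edge in bp and cM."""

    direction: int           # +1 downstream, -1 upstream
    site_index: np.ndarray
    distance_bp: np.ndarray
    distance_cm: np.ndarray
    ehh: np.ndarray


def ehh_curve(matrix: HaplotypeMatrix, core: CoreHaplotype, direction: int,
              gmap: GeneticMap | None = None) -> EHHCurve:
    vals = ehh_profile(matrix, core.carriers, core.start, core.stop, direction)
    pos = matrix.sites.pos
    if direction > 0:
        idx = np.arange(core.stop, matrix.n_sites)
        edge = pos[core.stop - 1]
    else:
        idx = np.arange(core.start - 1, -1, -1)
        edge = pos[core.start]
    d_bp = np.abs(pos[idx] - edge)
    if gmap is not None:
        d_cm = np.abs(gmap.interpolate(pos[idx]) - gmap.interpolate(edge))
    else:
        d_cm = np.full(len(idx), np.nan)
    return EHHCurve(direction, idx, d_bp.astype(float), d_cm, vals)


def find_cores(matrix: HaplotypeMatrix, min_core_freq: float = 0.04,
               max_snps: int = 20) -> list[CoreHaplotype]:
    """Greedy left-to-right segmentation into non-overlapping core spans.

    A span starts at the first unassigned site and is extended one site
    at a time while every observed haplotype over the extended span has
    frequency >= ``min_core_freq`` and the span stays within
    ``max_snps``.  Each distinct allele string over a closed span is
    emitted as one core.
    """
    matrix.require_complete()
    n, m = matrix.alleles.shape
    cores: list[CoreHaplotype] = []
    start = 0
    while start < m:
        stop = start + 1
        while stop < m and (stop + 1 - start) <= max_snps:
            sizes = _group_sizes(matrix.alleles[:, start:stop + 1])
            if sizes.min() / n < min_core_freq:
                break
            stop += 1
        strings, inverse = np.unique(matrix.alleles[:, start:stop], axis=0,
                                     return_inverse=True)
        for h, row in enumerate(strings):
            carriers = np.flatnonzero(inverse == h)
            cores.append(CoreHaplotype(start, stop,
                                       "".join(str(int(a)) for a in row),
                                       carriers, n))
        start = stop
    return cores


def rehh_at(core_ehh: float, others_ehh: float) -> float:
    """REHH = EHH(core) / EHH(all other chromosomes pooled)."""
    if not np.isfinite(others_ehh) or others_ehh <= 0:
        return float("nan")
    return core_ehh / others_ehh


def rehh(matrix: HaplotypeMatrix, core: CoreHaplotype, to_site: int) -> float:
    """REHH of ``core`` at ``to_site``, pooling every non-carrier as the
    comparison set."""
    others = np.setdiff1d(np.arange(matrix.n_chromosomes), core.carriers)
    if len(others) < 2:
        return float("nan")
    pooled = CoreHaplotype(core.start, core.stop, "pooled", others, core.n)
    return rehh_at(ehh_at(matrix, core, to_site), ehh_at(matrix, pooled, to_site))


def distance_at_marker_h(profiles: list[np.ndarray], distances: np.ndarray,
                         marker_h: float) -> tuple[float, bool]:
    """Distance at which the mean per-marker EHH decay first reaches
    ``marker_h``.

    ``profiles`` are per-core EHH values on a shared outward marker
    grid (EHH at distance 0 is 1 by definition).  The decay at marker j
    is the drop from the previous marker, averaged over cores.  Returns
    ``(distance, reached)``; when the decay never reaches the
    threshold the region edge is returned with ``reached=False`` and a
    warning.
    """
    if not 0 < marker_h < 1:
        raise ValueError("marker_h must be in (0, 1)")
    prof = np.vstack(profiles)
    prev = np.column_stack([np.ones(prof.shape[0]), prof[:, :-1]])
    decay = (prev - prof).mean(axis=0)
    hit = np.flatnonzero(decay >= marker_h)
    if len(hit) == 0:
        warnings.warn("mean EHH decay never reached marker H; returning region edge")
        return float(distances[-1]), False
    return float(distances[hit[0]]), True


MARKER_H_PRESETS = {"strict": 0.04, "relaxed": 0.02}


def lrh_test(tested: pd.DataFrame, background: pd.DataFrame,
             bin_width: float = 0.05, fdr_method: str = "bh") -> pd.DataFrame:
    """Long range haplotype test against frequency-binned backgrounds.

    Both frames need columns ``frequency`` and ``log_rehh``.  Within
    each frequency bin a normal distribution is fitted to the background
    log REHH; the p-value of each tested core is the upper-tail
    probability (selection inflates REHH).  q-values are
    Benjamini-Hochberg over all testable cores (``storey`` optional).
    Cores in bins with fewer than 2 background values are flagged
    untestable (p = q = NaN).
    """
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)

    def bin_of(f):
        return np.clip(np.digitize(f, edges, right=True) - 1, 0, len(edges) - 2)

    bg_bins = bin_of(background["frequency"].to_numpy())
    out = tested.copy()
    pvals = np.full(len(tested), np.nan)
    for i, (f, lr) in enumerate(zip(tested["frequency"], tested["log_rehh"])):
        sel = background["log_rehh"].to_numpy()[bg_bins == bin_of(f)]
        sel = sel[np.isfinite(sel)]
        if len(sel) < 2 or not np.isfinite(lr):
            continue
        mu, sd = float(np.mean(sel)), float(np.std(sel, ddof=1))
        if sd == 0:
            continue
        pvals[i] = float(norm.sf((lr - mu) / sd))
    out["p"] = pvals
    qvals = np.full(len(tested), np.nan)
    ok = np.isfinite(pvals)
    if ok.any():
        if fdr_method == "bh":
            qvals[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
        elif fdr_method == "storey":
            p = pvals[ok]
            pi0 = min(1.0, np.mean(p > 0.5) * 2.0) or 1.0
            qvals[ok] = pi0 * multipletests(p, method="fdr_bh")[1]
        else:
            raise ValueError(f"unknown FDR method {fdr_method!r}")
    out["q"] = np.clip(qvals, 0, 1)
    out["testable"] = ok
    return out
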