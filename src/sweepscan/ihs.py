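"""Integrated haplotype score (iHS), windowed composite-likelihood-ratio
scan, and gene-level ranking.

iHS compares the area under the EHH decay curve (integrated against
genetic distance) for ancestral- versus derived-allele carriers at a
focal SNP.  Raw ln(iHH_A/iHH_D) scores are standardized within
derived-allele-frequency bins against a genome-wide background, so
|iHS| is comparable across frequencies.  Regions enriched for extreme
|iHS| are then found with a composite likelihood ratio over sliding
windows of SNPs, comparing the window's |iHS| bin distribution with the
genome-wide one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import GeneticMap, HaplotypeMatrix
from .ehh import ehh_profile

EHH_CUTOFF = 0.05


def integrate_decay(distance_cm: np.ndarray, ehh: np.ndarray,
                    cutoff: float = EHH_CUTOFF) -> tuple[float, bool]:
    """Trapezoid area under an EHH decay curve, from distance 0 (EHH 1)
    out to where EHH first drops below ``cutoff``.

    The crossing point is located by linear interpolation and the curve
    is integrated down to the cutoff value there.  Returns
    ``(area, truncated)``; ``truncated`` is True when EHH never reached
    the cutoff before the last marker (region edge).
    """
    d = np.concatenate([[0.0], np.asarray(distance_cm, dtype=float)])
    e = np.concatenate([[1.0], np.asarray(ehh, dtype=float)])
    area = 0.0
    for j in range(1, len(d)):
        if e[j] >= cutoff:
            area += 0.5 * (e[j - 1] + e[j]) * (d[j] - d[j - 1])
            continue
        # crossing between j-1 and j
        frac = (e[j - 1] - cutoff) / (e[j - 1] - e[j])
        dx = (d[j] - d[j - 1]) * frac
        area += 0.5 * (e[j - 1] + cutoff) * dx
        return float(area), False
    return float(area), True


def ihh(matrix: HaplotypeMatrix, focal: int, allele: int, gmap: GeneticMap,
        cutoff: float = EHH_CUTOFF) -> tuple[float, bool]:
    """Integrated EHH for one allele class at the focal SNP.

    EHH is computed among carriers of ``allele`` at site ``focal``,
    outward in both directions, and trapezoid-integrated over genetic
    distance (cM) until EHH < ``cutoff``.  Returns ``(iHH, truncated)``
    with iHH the sum of both one-sided areas; NaN when the class has
    fewer than 2 chromosomes.
    """
    rows = np.flatnonzero(matrix.alleles[:, focal] == allele)
    if len(rows) < 2:
        return float("nan"), False
    pos = matrix.sites.pos
    cm = gmap.interpolate(pos)
    focal_cm = cm[focal]
    truncated = False
    total = 0.0
    for direction in (+1, -1):
        vals = ehh_profile(matrix, rows, focal, focal + 1, direction)
        if direction > 0:
            idx = np.arange(focal + 1, matrix.n_sites)
        else:
            idx = np.arange(focal - 1, -1, -1)
        dist = np.abs(cm[idx] - focal_cm)
        area, trunc = integrate_decay(dist, vals, cutoff)
        total += area
        truncated = truncated or trunc
    return float(total), truncated


@dataclass
class IhsResult:
    """Per-SNP iHS table plus the DAF bins used for standardization."""

    frame: pd.DataFrame  # id, pos, daf, ihh_a, ihh_d, raw, ihs


def ihs_raw(matrix: HaplotypeMatrix, gmap: GeneticMap,
            cutoff: float = EHH_CUTOFF, min_maf: float = 0.05) -> pd.DataFrame:
    """Unstandardized ln(iHH_A/iHH_D) for every eligible SNP.

    SNPs that are unpolarized, below ``min_maf``, or with an allele
    class smaller than 2 get NaN.
    """
    rows = []
    daf = matrix.daf()
    maf = matrix.maf()
    for j in range(matrix.n_sites):
        rec = {"id": matrix.sites.ids[j], "pos": int(matrix.sites.pos[j]),
               "daf": float(daf[j]), "ihh_a": np.nan, "ihh_d": np.nan,
               "raw": np.nan, "truncated": False}
        if matrix.sites.polarized[j] and maf[j] >= min_maf:
            ihh_a, trunc_a = ihh(matrix, j, 0, gmap, cutoff)
            ihh_d, trunc_d = ihh(matrix, j, 1, gmap, cutoff)
            rec.update(ihh_a=ihh_a, ihh_d=ihh_d, truncated=trunc_a or trunc_d)
            if np.isfinite(ihh_a) and np.isfinite(ihh_d) and ihh_a > 0 and ihh_d > 0:
                rec["raw"] = float(np.log(ihh_a / ihh_d))
        rows.append(rec)
    return pd.DataFrame(rows)


def standardize_ihs(scores: pd.DataFrame, background: pd.DataFrame,
                    n_bins: int = 20) -> pd.DataFrame:
    """Standardize raw scores within DAF bins using background moments.

    Under the usual sign convention a long derived haplotype gives a
    large iHH_D, hence a negative raw score and negative iHS; sweeps of
    the derived allele therefore show up as iHS < 0.  SNPs whose DAF bin
    is empty in the background are flagged unstandardizable (NaN).
    """
    edges = np.linspace(0.0, 1.0, n_bins + 1)

    def bin_of(f):
        return np.clip(np.digitize(f, edges, right=False) - 1, 0, n_bins - 1)

    bg = background.dropna(subset=["raw"])
    bg_bins = bin_of(bg["daf"].to_numpy())
    mu = np.full(n_bins, np.nan)
    sd = np.full(n_bins, np.nan)
    for b in range(n_bins):
        v = bg["raw"].to_numpy()[bg_bins == b]
        if len(v) >= 2:
            mu[b] = v.mean()
            sd[b] = v.std(ddof=0)
    out = scores.copy()
    b = bin_of(out["daf"].to_numpy())
    with np.errstate(invalid="ignore"):
        out["ihs"] = (out["raw"].to_numpy() - mu[b]) / sd[b]
    return out


def genome_bin_distribution(abs_ihs: np.ndarray, bin_width: float = 0.1,
                            n_bins: int = 60) -> np.ndarray:
    """Empirical bin probabilities of |iHS| with 0.5/(count+bins)
    smoothing of empty bins; the last bin is open-ended."""
    v = np.asarray(abs_ihs, dtype=float)
    v = v[np.isfinite(v)]
    b = np.minimum((v / bin_width).astype(int), n_bins - 1)
    counts = np.bincount(b, minlength=n_bins).astype(float)
    pseudo = 0.5 / (len(v) + n_bins)
    probs = counts / len(v)
    probs[probs == 0] = pseudo
    return probs / probs.sum()


def clr_value(abs_ihs_window: np.ndarray, genome_probs: np.ndarray,
              bin_width: float = 0.1) -> float:
    """CLR of one explicit window of |iHS| values: sum over member SNPs
    of ln(p̂_window(bin) / p̂_genome(bin))."""
    v = np.asarray(abs_ihs_window, dtype=float)
    n_bins = len(genome_probs)
    b = np.minimum((v / bin_width).astype(int), n_bins - 1)
    counts = np.bincount(b, minlength=n_bins).astype(float)
    p_win = counts / len(v)
    occ = counts > 0
    return float(np.sum(counts[occ] * np.log(p_win[occ] / genome_probs[occ])))


def windowed_clr(ihs: np.ndarray, genome_probs: np.ndarray, window: int = 31,
                 bin_width: float = 0.1) -> np.ndarray:
    """Composite log-likelihood ratio per SNP over centered sliding
    windows.

    For each SNP i in a window, with b(i) the |iHS| bin, the window
    contributes ln(p̂_window(b(i)) / p̂_genome(b(i))); the CLR is the sum
    over the window's SNPs.  Windows slide one SNP at a time; SNPs whose
    centered window would extend past the region edge (or contain a NaN
    score) get NaN — no partial windows.
    """
    ihs = np.asarray(ihs, dtype=float)
    n_bins = len(genome_probs)
    half = window // 2
    out = np.full(len(ihs), np.nan)
    finite = np.isfinite(ihs)
    bins = np.full(len(ihs), -1, dtype=int)
    bins[finite] = np.minimum((np.abs(ihs[finite]) / bin_width).astype(int),
                              n_bins - 1)
    for i in range(half, len(ihs) - half):
        wb = bins[i - half:i + half + 1]
        if np.any(wb < 0):
            continue
        counts = np.bincount(wb, minlength=n_bins).astype(float)
        p_win = counts / window
        occupied = counts > 0
        out[i] = float(np.sum(counts[occupied]
                              * np.log(p_win[occupied] / genome_probs[occupied])))
    return out


def window_pvalue(clr: float, genome_clrs: np.ndarray) -> float:
    """Empirical upper-tail p: fraction of genome windows with CLR >= observed."""
    g = np.asarray(genome_clrs, dtype=float)
    g = g[np.isfinite(g)]
    if len(g) == 0:
        return float("nan")
    return float(np.sum(g >= clr) / len(g))


def gene_rank_p(gene_scores: pd.DataFrame, score_col: str = "score") -> pd.DataFrame:
    """Rank genes by score (rank 1 = most extreme) and attach
    p = rank / total."""
    out = gene_scores.copy()
    out["rank"] = out[score_col].rank(ascending=False, method="min").astype(int)
    out["p"] = out["rank"] / len(out)
    return out


def gene_scores(genes: pd.DataFrame, snp_pos: np.ndarray, stat: np.ndarray,
                flank: int = 2000) -> pd.DataFrame:
    """Maximum windowed statistic within each gene span ± ``flank`` bp.

    Genes with no scored SNP in their span get NaN and are excluded from
    ranking by :func:`gene_rank_p` callers.
    """
    snp_pos = np.asarray(snp_pos)
    stat = np.asarray(stat, dtype=float)
    rows = []
    for _, g in genes.iterrows():
        lo, hi = g["start"] - flank, g["end"] + flank
        sel = (snp_pos >= lo) & (snp_pos < hi) & np.isfinite(stat)
        rows.append({"name": g["name"],
                     "score": float(stat[sel].max()) if sel.any() else np.nan,
                     "n_snps": int(sel.sum())})
    return pd.DataFrame(rows)
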