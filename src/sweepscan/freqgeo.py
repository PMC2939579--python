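"""Allele-frequency sliding-window scans and frequency-latitude clines.

The window scans flag genomic segments enriched for low-MAF or
high-DAF SNPs relative to empirical background distributions — the
frequency-spectrum footprints of ongoing or completed sweeps.  The
geographic analyses correlate per-population allele frequencies with
absolute latitude, optionally partialling out great-circle distance to
East Africa (Nairobi) to control for the out-of-Africa expansion axis.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

NAIROBI = (-1.2864, 36.8172)  # decimal degrees
EARTH_RADIUS_KM = 6371.0
MIN_MAF_PANEL_2N = 10  # populations below this are excluded from MAF scans


def sliding_proportion(pos: np.ndarray, values: np.ndarray, predicate,
                       region: tuple[int, int], window: int = 100_000,
                       step: int = 20_000) -> pd.DataFrame:
    """Per-window proportion of SNPs satisfying ``predicate``.

    Windows are half-open ``[start, start+window)`` with starts at
    ``region_start + k*step`` for every window fully inside the region.
    Windows containing no SNP get NaN.
    """
    pos = np.asarray(pos)
    flags = predicate(np.asarray(values, dtype=float))
    starts = np.arange(region[0], region[1] - window + 1, step)
    rows = []
    for s in starts:
        sel = (pos >= s) & (pos < s + window)
        n = int(sel.sum())
        rows.append({"start": int(s), "end": int(s + window), "n_snps": n,
                     "proportion": float(flags[sel].mean()) if n else np.nan})
    return pd.DataFrame(rows)


def maf_below(threshold: float = 0.10):
    return lambda maf: maf < threshold


def daf_above(threshold: float = 0.80):
    return lambda daf: daf > threshold


def outlier_windows(table: pd.DataFrame, background: np.ndarray,
                    percentile: float = 95.0) -> pd.DataFrame:
    """Flag windows strictly above the background percentile."""
    bg = np.asarray(background, dtype=float)
    bg = bg[np.isfinite(bg)]
    if len(bg) < 20:
        warnings.warn("background has fewer than 20 windows; outlier "
                      "threshold unstable")
    cut = float(np.percentile(bg, percentile))
    out = table.copy()
    out["threshold"] = cut
    out["outlier"] = table["proportion"] > cut
    out.loc[~np.isfinite(table["proportion"]), "outlier"] = False
    return out


def maf_difference_filter(maf_a: float, maf_b: float,
                          threshold: float = 0.2) -> bool:
    """Candidate retained iff |MAF_A − MAF_B| >= threshold (candidates
    with smaller differences are removed; equality retains)."""
    if not (np.isfinite(maf_a) and np.isfinite(maf_b)):
        raise ValueError("missing MAF; candidate unevaluable")
    return bool(abs(maf_a - maf_b) >= threshold - 1e-12)


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km (haversine, Earth radius 6371 km)."""
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (np.sin((la2 - la1) / 2) ** 2
         + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2) ** 2)
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def distance_to_east_africa(panel) -> dict[str, float]:
    """Great-circle km from each panel population to Nairobi."""
    return {pop: haversine_km(panel.latitude[pop], panel.longitude[pop], *NAIROBI)
            for pop in panel.latitude}


def latitude_correlation(freqs: np.ndarray, latitudes: np.ndarray
                         ) -> tuple[float, float]:
    """Pearson r of allele frequency vs |latitude| with two-sided p.

    Returns (NaN, NaN) when the frequency has zero variance.
    """
    f = np.asarray(freqs, dtype=float)
    lat = np.abs(np.asarray(latitudes, dtype=float))
    if len(f) < 3:
        raise ValueError("need >= 3 populations")
    if np.std(lat) == 0:
        raise ValueError("zero latitude variance")
    if np.std(f) == 0:
        return float("nan"), float("nan")
    r, p = pearsonr(f, lat)
    return float(r), float(p)


def partial_correlation(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation r_xy·z."""
    if abs(r_xz) >= 1 or abs(r_yz) >= 1:
        return float("nan")
    return float((r_xy - r_xz * r_yz)
                 / np.sqrt((1 - r_xz**2) * (1 - r_yz**2)))


def partial_latitude_correlation(freqs: np.ndarray, latitudes: np.ndarray,
                                 distances_km: np.ndarray) -> float:
    """r between frequency and |latitude| controlling for distance to
    East Africa."""
    f = np.asarray(freqs, dtype=float)
    lat = np.abs(np.asarray(latitudes, dtype=float))
    d = np.asarray(distances_km, dtype=float)
    if np.std(f) == 0 or np.std(d) == 0:
        return float("nan")
    r_xy = pearsonr(f, lat)[0]
    r_xz = pearsonr(f, d)[0]
    r_yz = pearsonr(lat, d)[0]
    return partial_correlation(r_xy, r_xz, r_yz)


def geo_correlation_table(freq_table: pd.DataFrame, panel,
                          alpha: float = 0.01) -> pd.DataFrame:
    """Latitude (partial) correlations for every SNP row.

    ``freq_table``: index = SNP id, columns = population frequencies.
    Bonferroni adjustment multiplies p by the number of tested SNPs.
    """
    pops = [p for p in freq_table.columns if p in panel.latitude]
    lats = np.array([panel.latitude[p] for p in pops])
    dists = distance_to_east_africa(panel)
    dvec = np.array([dists[p] for p in pops])
    rows = []
    for snp, rec in freq_table.iterrows():
        f = rec[pops].to_numpy(dtype=float)
        if np.std(f) == 0:
            rows.append({"id": snp, "r": np.nan, "p": np.nan,
                         "p_bonferroni": np.nan, "partial_r": np.nan})
            continue
        r, p = latitude_correlation(f, lats)
        rows.append({"id": snp, "r": r, "p": p,
                     "p_bonferroni": min(1.0, p * len(freq_table)),
                     "partial_r": partial_latitude_correlation(f, lats, dvec)})
    out = pd.DataFrame(rows)
    out["significant"] = out["p_bonferroni"] < alpha
    return out


def genome_percentile(r_observed: float, background_r: np.ndarray) -> float:
    """Fraction of background SNPs with |r| at least as extreme."""
    bg = np.abs(np.asarray(background_r, dtype=float))
    bg = bg[np.isfinite(bg)]
    return float(np.sum(bg >= abs(r_observed)) / len(bg))
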