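"""Cross-population Rsb scan.

EHHS is the site-specific EHH: the probability that two random distinct
chromosomes — regardless of which allele they carry at the focal SNP —
are identical over the interval from the focal site outward.  Its
integral against genetic distance (iES) measures how far homozygosity
extends around a site in a population, including after a completed
sweep.  XP-Rsb contrasts ln iES of a target population with the mean
over all other populations, standardized against a genome-wide
background, with upper-tail empirical rank p-values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import GeneticMap, HaplotypeMatrix
from .ehh import ehh_profile, pair_identity, _group_sizes
from .ihs import integrate_decay, EHH_CUTOFF


def ehhs(matrix: HaplotypeMatrix, focal: int, to_site: int) -> float:
    """Site-specific EHH between ``focal`` and ``to_site`` over all
    chromosomes (the focal column itself is part of the identity
    interval, which conditions on the focal site)."""
    n = matrix.n_chromosomes
    if n < 2:
        raise ValueError("need >= 2 chromosomes")
    lo, hi = min(focal, to_site), max(focal, to_site) + 1
    matrix.require_complete(slice(lo, hi))
    return pair_identity(_group_sizes(matrix.alleles[:, lo:hi]), n)


def ies(matrix: HaplotypeMatrix, focal: int, gmap: GeneticMap,
        cutoff: float = EHH_CUTOFF) -> tuple[float, bool]:
    """Integrated EHHS at the focal SNP (both directions, trapezoid in
    cM, stopping at the cutoff crossing).  Returns (iES, truncated)."""
    rows = np.arange(matrix.n_chromosomes)
    pos = matrix.sites.pos
    cm = gmap.interpolate(pos)
    total, truncated = 0.0, False
    for direction in (+1, -1):
        vals = ehh_profile(matrix, rows, focal, focal + 1, direction)
        idx = (np.arange(focal + 1, matrix.n_sites) if direction > 0
               else np.arange(focal - 1, -1, -1))
        dist = np.abs(cm[idx] - cm[focal])
        area, trunc = integrate_decay(dist, vals, cutoff)
        total += area
        truncated = truncated or trunc
    return float(total), truncated


def ies_table(matrices: dict[str, HaplotypeMatrix], gmap: GeneticMap,
              cutoff: float = EHH_CUTOFF) -> pd.DataFrame:
    """iES per population per SNP (populations share the site table)."""
    first = next(iter(matrices.values()))
    rows = []
    for j in range(first.n_sites):
        rec = {"id": first.sites.ids[j], "pos": int(first.sites.pos[j])}
        for pop, mat in matrices.items():
            rec[pop] = ies(mat, j, gmap, cutoff)[0]
        rows.append(rec)
    return pd.DataFrame(rows)


MIN_TARGET_2N = 10  # small samples are unreliable targets


def xp_rsb_raw(ies_by_pop: pd.DataFrame, target: str,
               weights: dict[str, float] | None = None) -> np.ndarray:
    """Raw ln(iES_target / reference) per SNP, reference being the
    (optionally 2N-weighted) mean iES over all other populations."""
    pops = [c for c in ies_by_pop.columns if c not in ("id", "pos")]
    others = [p for p in pops if p != target]
    if not others:
        raise ValueError("need at least 2 populations")
    mat = ies_by_pop[others].to_numpy(dtype=float)
    if weights is None:
        ref = mat.mean(axis=1)
    else:
        w = np.array([weights[p] for p in others], dtype=float)
        ref = mat @ (w / w.sum())
    tgt = ies_by_pop[target].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where((ref > 0) & (tgt > 0), np.log(tgt / ref), np.nan)
    return out


def rank_pvalue(observed: float, background: np.ndarray) -> float:
    """Upper-tail empirical rank p with a 1/N floor (the observed value
    can never look rarer than one background draw)."""
    bg = np.asarray(background, dtype=float)
    bg = bg[np.isfinite(bg)]
    if len(bg) == 0:
        return float("nan")
    return float(max(int(np.sum(bg >= observed)), 1) / len(bg))


def xp_rsb(ies_by_pop: pd.DataFrame, target: str, background: np.ndarray,
           two_n: dict[str, int] | None = None,
           weights: dict[str, float] | None = None) -> pd.DataFrame:
    """Standardized XP-Rsb with empirical p for one target population.

    ``background`` is the genome-wide pool of raw ln ratios for the same
    target; standardization uses its mean/sd and p-values its upper-tail
    rank.  Targets with 2N below ``MIN_TARGET_2N`` are refused.
    """
    if two_n is not None and two_n.get(target, MIN_TARGET_2N) < MIN_TARGET_2N:
        raise ValueError(f"population {target!r} has 2N < {MIN_TARGET_2N}; "
                         "too small to serve as a target")
    raw = xp_rsb_raw(ies_by_pop, target, weights)
    bg = np.asarray(background, dtype=float)
    bg = bg[np.isfinite(bg)]
    mu, sd = float(bg.mean()), float(bg.std(ddof=0))
    std = (raw - mu) / sd if sd > 0 else np.full_like(raw, np.nan)
    std_bg = (bg - mu) / sd if sd > 0 else bg
    p = np.array([rank_pvalue(x, std_bg) if np.isfinite(x) else np.nan
                  for x in std])
    return pd.DataFrame({
        "id": ies_by_pop["id"], "pos": ies_by_pop["pos"],
        "population": target, "ies": ies_by_pop[target],
        "raw": raw, "xp_rsb": std, "p": p,
        "neg_log10_p": -np.log10(p),
    })
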