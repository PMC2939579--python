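"""Site-frequency-spectrum diversity statistics, neutrality tests and
per-SNP AMOVA FST.

All SFS-based statistics take an unfolded spectrum: the derived-allele
count c (0 < c < n) of every segregating site in a sample of n
chromosomes.  Tajima's D follows Tajima (1989); Fu & Li's D, D*, F
follow Fu & Li (1993) and F* uses the corrected variance coefficients of
Simonsen, Churchill & Aquadro (1995) — the convention of standard
resequencing software, which reproduces published values where the
original misprinted F* coefficients do not.  Fay & Wu's H is reported
unnormalized (k − θ_H, Fay & Wu 2000).  Fu's Fs uses the exact Ewens
sampling distribution evaluated with a log-space Stirling-number
recurrence.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np


# ---------------------------------------------------------------------------
# containers

@dataclass
class SFSCounts:
    """Unfolded SFS: derived count per segregating site in n chromosomes."""

    n: int
    counts: np.ndarray
    L: float  # surveyed length in bp

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.n < 2:
            raise ValueError("need n >= 2 chromosomes")
        if np.any((self.counts <= 0) | (self.counts >= self.n)):
            raise ValueError("counts must satisfy 0 < c < n (segregating)")
        if self.L < len(self.counts):
            raise ValueError("surveyed length smaller than number of sites")

    @classmethod
    def from_counts(cls, counts, n: int, L: float) -> "SFSCounts":
        """Keep only segregating entries (drops fixed 0/n counts)."""
        c = np.asarray(counts, dtype=np.int64)
        return cls(n, c[(c > 0) & (c < n)], L)

    @classmethod
    def from_matrix(cls, matrix, L: float | None = None) -> "SFSCounts":
        c = matrix.derived_counts()
        n = matrix.n_chromosomes
        return cls.from_counts(c, n, L if L is not None else matrix.n_sites)


def derived_counts_from_daf(daf: float, two_n: int) -> int:
    """Nearest-integer derived count from a printed frequency.

    Ties round half up, so a frequency table printed to 2 decimals maps
    back onto the unique integer count that prints as that value.
    """
    if not 0.0 <= daf <= 1.0:
        raise ValueError("daf outside [0, 1]")
    if two_n <= 0:
        raise ValueError("two_n must be positive")
    return int(np.floor(daf * two_n + 0.5))


@dataclass(frozen=True)
class NeutralityConstants:
    """Sample-size-dependent coefficients for the neutrality tests."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float
    cn: float
    dn: float
    # Fu & Li variance coefficients (D, D*, F, F*; F* corrected)
    uD: float
    vD: float
    uDs: float
    vDs: float
    uF: float
    vF: float
    uFs: float
    vFs: float


@lru_cache(maxsize=None)
def neutrality_constants(n: int) -> NeutralityConstants:
    if n < 2:
        raise ValueError("need n >= 2")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    an1 = a1 + 1.0 / n
    # Tajima (1989)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    # Fu & Li (1993)
    if n > 2:
        cn = 2.0 * (n * a1 - 2 * (n - 1)) / ((n - 1) * (n - 2))
    else:
        cn = 1.0
    dn = cn + (n - 2) / (n - 1) ** 2 + (2.0 / (n - 1)) * (
        1.5 - (2 * an1 - 3) / (n - 2) - 1.0 / n) if n > 2 else 2.0
    vD = 1.0 + a1**2 / (a2 + a1**2) * (cn - (n + 1) / (n - 1))
    uD = a1 - 1.0 - vD
    vDs = ((n / (n - 1.0)) ** 2 * a2 + a1**2 * dn
           - 2.0 * n * a1 * (a1 + 1) / (n - 1.0) ** 2) / (a1**2 + a2)
    uDs = n / (n - 1.0) * (a1 - n / (n - 1.0)) - vDs
    vF = (cn + 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1)) - 2.0 / (n - 1)) / (a1**2 + a2)
    uF = (1.0 + (n + 1) / (3.0 * (n - 1))
          - 4.0 * (n + 1) / (n - 1) ** 2 * (an1 - 2.0 * n / (n + 1))) / a1 - vF
    vFs = ((2.0 * n**3 + 110 * n**2 - 255 * n + 153) / (9.0 * n**2 * (n - 1))
           + 2.0 * (n - 1) * a1 / n**2 - 8.0 * a2 / n) / (a1**2 + a2)
    uFs = ((4.0 * n**2 + 19 * n + 3 - 12 * (n + 1) * an1)
           / (3.0 * n * (n - 1))) / a1 - vFs
    return NeutralityConstants(n, a1, a2, b1, b2, c1, c2, e1, e2, cn, dn,
                               uD, vD, uDs, vDs, uF, vF, uFs, vFs)


# ---------------------------------------------------------------------------
# SFS statistics

def segregating_sites(sfs: SFSCounts) -> int:
    return int(len(sfs.counts))


def pairwise_diversity(sfs: SFSCounts) -> tuple[float, float]:
    """(k, π): mean pairwise differences and per-site nucleotide diversity."""
    if sfs.L == 0:
        raise ValueError("zero surveyed length")
    n = sfs.n
    c = sfs.counts.astype(float)
    k = float(np.sum(c * (n - c)) / (n * (n - 1) / 2.0))
    return k, k / sfs.L


def watterson_theta(sfs: SFSCounts) -> float:
    return segregating_sites(sfs) / neutrality_constants(sfs.n).a1


def tajimas_D(sfs: SFSCounts) -> float:
    """Tajima (1989) D; NaN when S = 0."""
    S = segregating_sites(sfs)
    if S == 0:
        return float("nan")
    k, _ = pairwise_diversity(sfs)
    cst = neutrality_constants(sfs.n)
    num = k - S / cst.a1
    if num == 0.0:  # exact at n=2, where k = S/a1 identically
        return 0.0
    var = cst.e1 * S + cst.e2 * S * (S - 1)
    return num / np.sqrt(var)


def fay_wu_H(sfs: SFSCounts) -> float:
    """Unnormalized Fay & Wu (2000) H = k − θ_H (requires polarized counts)."""
    n = sfs.n
    c = sfs.counts.astype(float)
    k, _ = pairwise_diversity(sfs)
    theta_h = float(np.sum(2.0 * c**2) / (n * (n - 1)))
    return k - theta_h


def singleton_counts(sfs: SFSCounts) -> tuple[int, int]:
    """(ηe, ηs): derived singletons and within-sample singletons
    (count 1 or n−1)."""
    c = sfs.counts
    eta_e = int(np.sum(c == 1))
    eta_s = int(np.sum((c == 1) | (c == sfs.n - 1)))
    return eta_e, eta_s


def fu_li_tests(sfs: SFSCounts) -> tuple[float, float, float, float]:
    """(D, D*, F, F*) of Fu & Li (1993), F* variance per Simonsen 1995.

    D and F use the outgroup-polarized derived singleton count ηe; the
    starred variants use within-sample singletons ηs.  NaN when S = 0.
    """
    S = segregating_sites(sfs)
    if S == 0:
        return (float("nan"),) * 4
    n = sfs.n
    eta = float(S)
    eta_e, eta_s = singleton_counts(sfs)
    k, _ = pairwise_diversity(sfs)
    cst = neutrality_constants(n)
    D = (eta - cst.a1 * eta_e) / np.sqrt(cst.uD * eta + cst.vD * eta**2)
    Ds = (n / (n - 1.0) * eta - cst.a1 * eta_s) / np.sqrt(
        cst.uDs * eta + cst.vDs * eta**2)
    F = (k - eta_e) / np.sqrt(cst.uF * eta + cst.vF * eta**2)
    Fs = (k - (n - 1.0) / n * eta_s) / np.sqrt(cst.uFs * eta + cst.vFs * eta**2)
    return float(D), float(Ds), float(F), float(Fs)


# ---------------------------------------------------------------------------
# Fu's Fs (Ewens sampling distribution)

@lru_cache(maxsize=None)
def _log_stirling_row(n: int) -> tuple[float, ...]:
    """log |s(n, k)| for k = 0..n (unsigned Stirling numbers, 1st kind)."""
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0
    for m in range(1, n + 1):
        new = np.full(n + 1, -np.inf)
        new[1:m + 1] = row[0:m]
        if m > 1:
            new[1:m] = np.logaddexp(new[1:m], np.log(m - 1) + row[1:m])
        row = new
    return tuple(row)


def ewens_k_pmf(n: int, theta: float) -> np.ndarray:
    """P(K = k | θ, n) for k = 0..n under the Ewens sampling formula."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    ls = np.array(_log_stirling_row(n))
    k = np.arange(n + 1)
    log_rising = float(np.sum(np.log(theta + np.arange(n))))
    return np.exp(ls + k * np.log(theta) - log_rising)


def fu_fs(k_obs: int, k_hat: float, n: int) -> float:
    """Fu's (1997) Fs = ln(S'/(1−S')), S' = P(K ≥ k_obs | θ = k_hat).

    Returns NaN when θ = 0 and signed infinity when S' degenerates.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if k_hat == 0:
        return float("nan")
    pmf = ewens_k_pmf(n, k_hat)
    s_prime = float(pmf[k_obs:].sum())
    complement = float(pmf[:k_obs].sum())  # stable 1 − S'
    if complement <= 0.0:
        return float("inf")
    if s_prime <= 0.0:
        return float("-inf")
    return float(np.log(s_prime / complement))


# ---------------------------------------------------------------------------
# haplotype summaries

def haplotype_counts(matrix) -> np.ndarray:
    """Multiplicity of each distinct haplotype (row) in the matrix."""
    matrix.require_complete()
    _, counts = np.unique(matrix.alleles, axis=0, return_counts=True)
    return counts


def haplotype_summary(matrix_or_counts) -> tuple[int, float]:
    """(K, Hd): distinct haplotypes and small-sample-corrected diversity."""
    if isinstance(matrix_or_counts, (list, tuple, np.ndarray)):
        counts = np.asarray(matrix_or_counts, dtype=float)
    else:
        counts = haplotype_counts(matrix_or_counts).astype(float)
    n = counts.sum()
    if n < 2:
        raise ValueError("need at least 2 chromosomes")
    p = counts / n
    hd = n / (n - 1.0) * (1.0 - float(np.sum(p**2)))
    return int(len(counts)), float(hd)


@dataclass
class DiversitySummary:
    n: int
    S: int
    eta_e: int
    eta_s: int
    k: float
    pi: float
    theta_w: float
    tajimas_D: float
    fu_li_D: float
    fu_li_D_star: float
    fu_li_F: float
    fu_li_F_star: float
    fay_wu_H: float
    K: int | None = None
    Hd: float | None = None
    fu_fs: float | None = None


def summarize(sfs: SFSCounts, matrix=None) -> DiversitySummary:
    """One-stop summary used by the ``divstats`` pipeline stage."""
    k, pi = pairwise_diversity(sfs)
    eta_e, eta_s = singleton_counts(sfs)
    d, ds, f, fs_star = fu_li_tests(sfs)
    K = Hd = fs = None
    if matrix is not None:
        K, Hd = haplotype_summary(matrix)
        fs = fu_fs(K, k, sfs.n)
    return DiversitySummary(
        n=sfs.n, S=segregating_sites(sfs), eta_e=eta_e, eta_s=eta_s,
        k=k, pi=pi, theta_w=watterson_theta(sfs),
        tajimas_D=tajimas_D(sfs), fu_li_D=d, fu_li_D_star=ds,
        fu_li_F=f, fu_li_F_star=fs_star, fay_wu_H=fay_wu_H(sfs),
        K=K, Hd=Hd, fu_fs=fs)


# ---------------------------------------------------------------------------
# AMOVA FST

@dataclass
class FstResult:
    msa: float
    msw: float
    n_c: float
    sigma_a2: float
    sigma_w2: float
    fst: float


def fst_amova(counts, sizes) -> FstResult:
    """Locus-by-locus AMOVA FST from one-way variance components.

    ``counts``: derived (or either) allele count per population;
    ``sizes``: chromosomes sampled per population.  The 0/1 allele
    indicator is the analysis variable, so FST = σa²/(σa²+σw²) with σw²
    the within-population mean square.  Returns FST = NaN when every
    population is fixed for the same allele (no variance to partition).
    """
    counts = np.asarray(counts, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    if len(counts) != len(sizes) or len(counts) < 2:
        raise ValueError("need counts and sizes for >= 2 populations")
    if np.any(sizes <= 0):
        raise ValueError("population sizes must be positive")
    r = len(sizes)
    N = sizes.sum()
    p = counts / sizes
    pbar = counts.sum() / N
    msa = float(np.sum(sizes * (p - pbar) ** 2) / (r - 1))
    msw = float(np.sum(sizes * p * (1 - p)) / (N - r))
    n_c = float((N - np.sum(sizes**2) / N) / (r - 1))
    sigma_a2 = (msa - msw) / n_c
    denom = sigma_a2 + msw
    fst = sigma_a2 / denom if denom != 0 else float("nan")
    return FstResult(msa, msw, n_c, sigma_a2, msw, fst)


# ---------------------------------------------------------------------------
# empirical critical values

def neutrality_critical_values(null: np.ndarray, alpha: float = 0.05,
                               two_sided: bool = True):
    """Empirical critical value(s) from simulated null draws.

    Two-sided (default): returns ``(lower, upper)`` at alpha/2 per tail,
    taken conservatively outward (lower tail rounds down the order
    statistic, upper tail rounds up).  One-sided: upper critical value
    at 1−alpha.  Warns (via ``warnings``) when the null has fewer draws
    than 1/alpha.
    """
    import warnings

    null = np.sort(np.asarray(null, dtype=float))
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if len(null) < 1.0 / alpha:
        warnings.warn("fewer null draws than 1/alpha; critical values unstable")
    if two_sided:
        lo = float(np.quantile(null, alpha / 2, method="lower"))
        hi = float(np.quantile(null, 1 - alpha / 2, method="higher"))
        return lo, hi
    return float(np.quantile(null, 1 - alpha, method="higher"))


def is_significant(observed: float, critical, two_sided: bool = True) -> bool:
    if two_sided:
        lo, hi = critical
        return bool(observed < lo or observed > hi)
    return bool(observed > critical)
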