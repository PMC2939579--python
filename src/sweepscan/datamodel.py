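"""Core containers for phased haplotype data.

All haplotype statistics in this package operate on a
:class:`HaplotypeMatrix` (phased chromosomes x polarized biallelic
sites), annotated by a :class:`SiteTable`.  Physical positions are
1-based; genomic windows are half-open ``[start, start+len)``.  Genetic
distances come from a :class:`GeneticMap` (piecewise-linear bp<->cM).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

REGIONS = ("SSAFR", "MENA", "EUR", "CSASIA", "EASIA", "OCE", "AME")


@dataclass
class SiteTable:
    """Per-site metadata for a set of biallelic variants.

    An insertion/deletion is coded as an ordinary biallelic site.
    ``polarized`` marks sites whose ancestral state is known; unfolded
    statistics (DAF, Fay & Wu's H, iHS) must exclude or refuse
    unpolarized sites.
    """

    chrom: np.ndarray
    pos: np.ndarray          # 1-based bp, strictly increasing per chrom
    ids: np.ndarray
    anc_allele: np.ndarray
    der_allele: np.ndarray
    polarized: np.ndarray    # bool

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ids = np.asarray(self.ids, dtype=object)
        self.anc_allele = np.asarray(self.anc_allele, dtype=object)
        self.der_allele = np.asarray(self.der_allele, dtype=object)
        self.polarized = np.asarray(self.polarized, dtype=bool)
        n = len(self.pos)
        for arr, name in ((self.chrom, "chrom"), (self.ids, "ids"),
                          (self.anc_allele, "anc_allele"),
                          (self.der_allele, "der_allele"),
                          (self.polarized, "polarized")):
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != pos length {n}")
        for c in np.unique(self.chrom.astype(str)):
            p = self.pos[self.chrom.astype(str) == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        if any(a == "" for a in self.anc_allele) or any(d == "" for d in self.der_allele):
            raise ValueError("empty allele string")

    def __len__(self) -> int:
        return len(self.pos)

    @classmethod
    def simple(cls, pos, ids=None, chrom="1", polarized=True) -> "SiteTable":
        """Build a table from positions alone, with placeholder alleles."""
        pos = np.asarray(pos, dtype=np.int64)
        n = len(pos)
        if ids is None:
            ids = np.array([f"snp{i + 1}" for i in range(n)], dtype=object)
        return cls(
            chrom=np.full(n, chrom, dtype=object),
            pos=pos,
            ids=np.asarray(ids, dtype=object),
            anc_allele=np.full(n, "A", dtype=object),
            der_allele=np.full(n, "G", dtype=object),
            polarized=np.full(n, bool(polarized)),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": self.chrom, "pos": self.pos, "id": self.ids,
            "anc_allele": self.anc_allele, "der_allele": self.der_allele,
            "polarized": self.polarized,
        })

    def take(self, idx) -> "SiteTable":
        idx = np.asarray(idx)
        return SiteTable(self.chrom[idx], self.pos[idx], self.ids[idx],
                         self.anc_allele[idx], self.der_allele[idx],
                         self.polarized[idx])


@dataclass
class HaplotypeMatrix:
    """Phased chromosomes x sites over {0, 1, MISSING}.

    0 = ancestral, 1 = derived at polarized sites; at unpolarized sites
    the 0/1 coding is arbitrary (reference/alternate).  For diploids the
    chromosome count is twice the individual count and chromosome ids
    carry ``_1``/``_2`` suffixes.
    """

    alleles: np.ndarray      # (n_chrom, n_sites) int8
    sample_ids: list[str]
    sites: SiteTable

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D (chromosomes x sites)")
        if self.alleles.shape[1] != len(self.sites):
            raise ValueError(
                f"{self.alleles.shape[1]} columns but {len(self.sites)} sites")
        if self.alleles.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length mismatch")
        bad = ~np.isin(self.alleles, (0, 1, MISSING))
        if bad.any():
            raise ValueError("alleles must be 0, 1 or MISSING")

    @property
    def n_chromosomes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def derived_counts(self) -> np.ndarray:
        """Derived-allele count per site, ignoring missing calls."""
        return (self.alleles == 1).sum(axis=0)

    def daf(self) -> np.ndarray:
        called = (self.alleles != MISSING).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(called > 0, self.derived_counts() / called, np.nan)

    def maf(self) -> np.ndarray:
        f = self.daf()
        return np.minimum(f, 1.0 - f)

    def require_complete(self, cols=None) -> None:
        sub = self.alleles if cols is None else self.alleles[:, cols]
        if (sub == MISSING).any():
            raise ValueError("missing calls in a span that requires complete data")

    def take_chromosomes(self, idx) -> "HaplotypeMatrix":
        idx = np.asarray(idx)
        return HaplotypeMatrix(self.alleles[idx],
                               [self.sample_ids[i] for i in idx], self.sites)

    def take_sites(self, idx) -> "HaplotypeMatrix":
        return HaplotypeMatrix(self.alleles[:, idx], list(self.sample_ids),
                               self.sites.take(idx))


@dataclass
class GeneticMap:
    """Monotone piecewise-linear bp -> cumulative cM interpolation."""

    pos_bp: np.ndarray
    cm: np.ndarray

    def __post_init__(self) -> None:
        self.pos_bp = np.asarray(self.pos_bp, dtype=float)
        self.cm = np.asarray(self.cm, dtype=float)
        if len(self.pos_bp) < 2:
            raise ValueError("a genetic map needs at least 2 anchors")
        if np.any(np.diff(self.pos_bp) <= 0):
            raise ValueError("anchor positions must be strictly increasing")
        if np.any(np.diff(self.cm) < 0):
            raise ValueError("anchor cM must be non-decreasing")

    @classmethod
    def uniform(cls, start_bp: float, end_bp: float,
                cm_per_mb: float = 1.0) -> "GeneticMap":
        total = (end_bp - start_bp) / 1e6 * cm_per_mb
        return cls(np.array([start_bp, end_bp]), np.array([0.0, total]))

    def interpolate(self, pos, extrapolate: bool = False):
        """cM at ``pos`` (scalar or array); linear between anchors."""
        pos = np.asarray(pos, dtype=float)
        if not extrapolate:
            if np.any(pos < self.pos_bp[0]) or np.any(pos > self.pos_bp[-1]):
                raise ValueError(
                    f"position outside map span "
                    f"[{self.pos_bp[0]:.0f}, {self.pos_bp[-1]:.0f}] "
                    "and extrapolation is disabled")
        out = np.interp(pos, self.pos_bp, self.cm)
        # linear extrapolation from the terminal segments
        if extrapolate:
            lo = pos < self.pos_bp[0]
            hi = pos > self.pos_bp[-1]
            s0 = (self.cm[1] - self.cm[0]) / (self.pos_bp[1] - self.pos_bp[0])
            s1 = (self.cm[-1] - self.cm[-2]) / (self.pos_bp[-1] - self.pos_bp[-2])
            out = np.where(lo, self.cm[0] + (pos - self.pos_bp[0]) * s0, out)
            out = np.where(hi, self.cm[-1] + (pos - self.pos_bp[-1]) * s1, out)
        return float(out) if out.ndim == 0 else out


@dataclass
class PopulationPanel:
    """Sample -> population -> geographic region assignment with coordinates.

    Coordinates are decimal degrees; ``two_n`` is the number of phased
    chromosomes sampled per population.
    """

    sample_population: dict[str, str]
    population_region: dict[str, str]
    latitude: dict[str, float] = field(default_factory=dict)
    longitude: dict[str, float] = field(default_factory=dict)
    two_n: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pop, lat in self.latitude.items():
            if abs(lat) > 90:
                raise ValueError(f"|latitude| > 90 for {pop}")
        for pop, lon in self.longitude.items():
            if abs(lon) > 180:
                raise ValueError(f"|longitude| > 180 for {pop}")

    @property
    def populations(self) -> list[str]:
        return sorted(set(self.sample_population.values()))

    def samples_of(self, population: str) -> list[str]:
        return [s for s, p in self.sample_population.items() if p == population]

    def chromosome_mask(self, sample_ids: list[str], population: str) -> np.ndarray:
        """Boolean mask over chromosome rows belonging to ``population``.

        Chromosome ids are ``sample`` or ``sample_1``/``sample_2``.
        """
        def base(cid: str) -> str:
            return cid.rsplit("_", 1)[0] if cid.rsplit("_", 1)[-1] in ("1", "2") else cid
        return np.array([self.sample_population.get(base(c)) == population
                         for c in sample_ids])


@dataclass
class ScanTable:
    """Per-SNP scan output: raw and standardized statistic, p and q."""

    frame: pd.DataFrame

    REQUIRED = ("id", "pos", "raw", "standardized", "p", "q", "population")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.frame.columns:
                raise ValueError(f"ScanTable missing column {col!r}")
        for col in ("p", "q"):
            v = self.frame[col].dropna()
            if ((v < 0) | (v > 1)).any():
                raise ValueError(f"{col} outside [0, 1]")
        if not self.frame["pos"].is_monotonic_increasing:
            self.frame = self.frame.sort_values("pos", kind="stable").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)
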