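"""Neutral coalescent simulator with recombination and demography, plus
a haplotype-copy sweep injector.

The simulator generates phased haplotypes under the standard neutral
coalescent with recombination (an ancestral-recombination-graph walk in
the style of Hudson's ms): lineages carry ancestral-material segments
tagged with the set of sample chromosomes they subtend; coalescence,
recombination and island-model migration compete as exponential events;
piecewise-constant population sizes, pastward splits and migration-rate
changes are applied as scheduled events.  Mutations follow the
infinite-sites model and are placed uniformly on branch length — either
Poisson with rate θ/2 per unit coalescent time, or exactly S mutations
when conditioning on the observed number of segregating sites (the
fixed-S null used for empirical critical values of the neutrality
tests).

Units: time in units of 2N0 generations; θ = 4N0·μ per locus;
ρ = 4N0·r per locus; population sizes are relative to N0.  Exponential
growth is approximated by an internal piecewise-constant staircase
(:func:`growth_staircase`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import HaplotypeMatrix, SiteTable


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class SizeChange:
    time: float
    pop: str
    size: float


@dataclass(frozen=True)
class Split:
    """Pastward merge: at ``time`` all lineages of ``derived`` move into
    ``ancestral`` and ``derived`` disappears."""

    time: float
    derived: str
    ancestral: str


@dataclass(frozen=True)
class MigrationChange:
    time: float
    rate: float


def growth_staircase(pop: str, t_start: float, t_end: float,
                     present_size: float, rate: float,
                     steps: int = 16) -> list[SizeChange]:
    """Approximate pastward-shrinking exponential growth
    (size(t) = present_size·exp(−rate·t)) by ``steps`` constant epochs."""
    ts = np.linspace(t_start, t_end, steps + 1)
    mids = 0.5 * (ts[:-1] + ts[1:])
    return [SizeChange(float(t0), pop, float(present_size * np.exp(-rate * tm)))
            for t0, tm in zip(ts[:-1], mids)]


@dataclass
class SimConfig:
    """Specification of one neutral simulation.

    ``samples`` maps population name to chromosome count (an int means a
    single population "pop0").  Exactly one of ``theta`` / ``fixed_s``
    must be set.  ``migration`` is the scaled island-model rate (total
    per-lineage out-rate M/2, split equally over other populations).
    """

    samples: dict[str, int] | int
    theta: float | None = None
    fixed_s: int | None = None
    rho: float = 0.0
    length_bp: int = 4007
    pop_sizes: dict[str, float] = field(default_factory=dict)
    events: list = field(default_factory=list)
    migration: float = 0.0
    seed: int | None = None

    def sample_dict(self) -> dict[str, int]:
        if isinstance(self.samples, int):
            return {"pop0": self.samples}
        return dict(self.samples)

    def validate(self) -> None:
        samples = self.sample_dict()
        if sum(samples.values()) < 2:
            raise ValueError("need at least 2 sampled chromosomes")
        if (self.theta is None) == (self.fixed_s is None):
            raise ValueError("set exactly one of theta / fixed_s")
        if self.theta is not None and self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.fixed_s is not None and self.fixed_s < 0:
            raise ValueError("fixed_s must be >= 0")
        if self.rho < 0 or self.migration < 0:
            raise ValueError("rates must be >= 0")
        times = [e.time for e in self.events]
        if any(t < 0 for t in times):
            raise ValueError("event times must be >= 0 (pastward)")


def demographic_preset(name: str, pop: str = "pop0") -> dict:
    """Rough continental demographic presets (bottleneck/growth), as
    keyword arguments for :class:`SimConfig`.

    These are simplified approximations of published human demographic
    calibrations — user-editable, not a restatement of any fitted model:
    Africans get recent two-fold growth; Europeans and East Asians get
    an out-of-Africa bottleneck followed by recovery and growth.
    """
    presets = {
        "african": {"pop_sizes": {pop: 2.0},
                    "events": [SizeChange(0.05, pop, 1.0)]},
        "european": {"pop_sizes": {pop: 1.5},
                     "events": [SizeChange(0.02, pop, 0.10),
                                SizeChange(0.035, pop, 1.0)]},
        "asian": {"pop_sizes": {pop: 1.5},
                  "events": [SizeChange(0.02, pop, 0.08),
                             SizeChange(0.035, pop, 1.0)]},
    }
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    return presets[name]


# ---------------------------------------------------------------------------
# ARG machinery

class _Lineage:
    __slots__ = ("pop", "birth", "segs")

    def __init__(self, pop: str, birth: float, segs: list):
        self.pop = pop
        self.birth = birth
        self.segs = segs  # list of (left, right, mask), 0 <= left < right <= 1

    @property
    def extent(self) -> float:
        return self.segs[-1][1] - self.segs[0][0]


def _merge_segments(a: list, b: list, full: int) -> list:
    """Union of two lineages' ancestral material; drops locally-fixed
    (full-mask) stretches, merges adjacent same-mask pieces."""
    pts = sorted({x for s in a + b for x in (s[0], s[1])})
    out = []
    for left, right in zip(pts, pts[1:]):
        m = 0
        for l, r, mask in a:
            if l <= left and right <= r:
                m |= mask
                break
        for l, r, mask in b:
            if l <= left and right <= r:
                m |= mask
                break
        if m == 0 or m == full:
            continue
        if out and out[-1][1] == left and out[-1][2] == m:
            out[-1] = (out[-1][0], right, m)
        else:
            out.append((left, right, m))
    return out


def _split_segments(segs: list, bp: float) -> tuple[list, list]:
    left, right = [], []
    for l, r, m in segs:
        if r <= bp:
            left.append((l, r, m))
        elif l >= bp:
            right.append((l, r, m))
        else:
            left.append((l, bp, m))
            right.append((bp, r, m))
    return left, right


def _run_arg(config: SimConfig, rng: np.random.Generator):
    """Run the coalescent; returns the list of branch pieces
    (left, right, mask, duration) available for mutations."""
    samples = config.sample_dict()
    n_total = sum(samples.values())
    full = (1 << n_total) - 1
    sizes = {p: 1.0 for p in samples}
    sizes.update(config.pop_sizes)
    migration = config.migration
    active_pops = set(samples)

    lineages: list[_Lineage] = []
    i = 0
    for pop, k in samples.items():
        for _ in range(k):
            lineages.append(_Lineage(pop, 0.0, [(0.0, 1.0, 1 << i)]))
            i += 1

    pieces: list[tuple[float, float, int, float]] = []

    def consume(lin: _Lineage, t: float) -> None:
        dur = t - lin.birth
        if dur > 0:
            for l, r, m in lin.segs:
                pieces.append((l, r, m, dur))

    events = sorted(config.events, key=lambda e: e.time)
    ei = 0
    t = 0.0
    while lineages:
        by_pop: dict[str, list[int]] = {}
        for idx, lin in enumerate(lineages):
            by_pop.setdefault(lin.pop, []).append(idx)
        coal_rates = {p: len(ix) * (len(ix) - 1) / 2.0 / sizes.get(p, 1.0)
                      for p, ix in by_pop.items()}
        rec_rate = (config.rho / 2.0) * sum(lin.extent for lin in lineages) \
            if config.rho > 0 else 0.0
        n_dest = len(active_pops) - 1
        mig_rate = (migration / 2.0) * len(lineages) if (migration > 0 and n_dest > 0) else 0.0
        total = sum(coal_rates.values()) + rec_rate + mig_rate
        if total == 0.0:
            if ei < len(events):
                t = events[ei].time
            else:
                raise ValueError(
                    "no possible event but uncoalesced lineages remain "
                    "(disconnected demography: zero migration between "
                    "populations that never merge)")
        else:
            dt = rng.exponential(1.0 / total)
            if ei < len(events) and t + dt >= events[ei].time:
                t = events[ei].time
            else:
                t += dt
                u = rng.uniform(0.0, total)
                acc = 0.0
                done = False
                for p, rate in coal_rates.items():
                    acc += rate
                    if u < acc:
                        i1, i2 = rng.choice(by_pop[p], size=2, replace=False)
                        a, b = lineages[i1], lineages[i2]
                        consume(a, t)
                        consume(b, t)
                        merged = _merge_segments(a.segs, b.segs, full)
                        for idx in sorted((i1, i2), reverse=True):
                            lineages.pop(idx)
                        if merged:
                            lineages.append(_Lineage(p, t, merged))
                        done = True
                        break
                if not done and u < acc + rec_rate:
                    w = np.array([lin.extent for lin in lineages])
                    idx = rng.choice(len(lineages), p=w / w.sum())
                    lin = lineages[idx]
                    lo, hi = lin.segs[0][0], lin.segs[-1][1]
                    bp = rng.uniform(lo, hi)
                    lseg, rseg = _split_segments(lin.segs, bp)
                    if lseg and rseg:
                        consume(lin, t)
                        lineages.pop(idx)
                        lineages.append(_Lineage(lin.pop, t, lseg))
                        lineages.append(_Lineage(lin.pop, t, rseg))
                    done = True
                elif not done:
                    idx = rng.integers(len(lineages))
                    lin = lineages[idx]
                    dests = sorted(active_pops - {lin.pop})
                    if dests:
                        lin.pop = dests[rng.integers(len(dests))]
                    done = True
                continue
        # scheduled event at time t
        while ei < len(events) and events[ei].time <= t:
            ev = events[ei]
            if isinstance(ev, SizeChange):
                sizes[ev.pop] = ev.size
            elif isinstance(ev, Split):
                for lin in lineages:
                    if lin.pop == ev.derived:
                        lin.pop = ev.ancestral
                active_pops.discard(ev.derived)
                active_pops.add(ev.ancestral)
            elif isinstance(ev, MigrationChange):
                migration = ev.rate
            else:
                raise TypeError(f"unknown event {ev!r}")
            ei += 1
    return pieces, n_total


def _place_mutations(pieces, n_total: int, config: SimConfig,
                     rng: np.random.Generator):
    w = np.array([(r - l) * dur for l, r, _, dur in pieces])
    W = w.sum()
    if config.fixed_s is not None:
        S = config.fixed_s
    else:
        S = int(rng.poisson(config.theta / 2.0 * W))
    if S == 0 or W == 0:
        return np.empty(0), np.empty((n_total, 0), dtype=np.int8)
    chosen = rng.choice(len(pieces), size=S, p=w / W, replace=True)
    us = np.array([pieces[i][0] + rng.uniform() * (pieces[i][1] - pieces[i][0])
                   for i in chosen])
    masks = np.array([pieces[i][2] for i in chosen], dtype=object)
    order = np.argsort(us)
    us, masks = us[order], masks[order]
    cols = np.zeros((n_total, S), dtype=np.int8)
    for j, m in enumerate(masks):
        for i in range(n_total):
            if (int(m) >> i) & 1:
                cols[i, j] = 1
    return us, cols


def simulate_neutral(config: SimConfig,
                     rng: np.random.Generator | None = None
                     ) -> tuple[SiteTable, HaplotypeMatrix]:
    """Simulate one neutral region; reproducible under ``config.seed``.

    In fixed-S mode exactly S segregating sites are returned on every
    run; in θ mode the count is Poisson on total branch length.  Site
    positions are uniform on the region and strictly increasing in bp.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pieces, n_total = _run_arg(config, rng)
    us, cols = _place_mutations(pieces, n_total, config, rng)
    # continuous [0,1) -> unique increasing 1-based bp
    pos = np.floor(us * config.length_bp).astype(np.int64) + 1
    for j in range(1, len(pos)):
        if pos[j] <= pos[j - 1]:
            pos[j] = pos[j - 1] + 1
    if len(pos) and pos[-1] > config.length_bp:
        raise ValueError("more segregating sites than base pairs")
    sites = SiteTable.simple(pos, ids=[str(p) for p in pos], chrom="sim")
    ids = []
    for pop, k in config.sample_dict().items():
        ids.extend(f"{pop}_c{j}" for j in range(k))
    return sites, HaplotypeMatrix(cols, ids, sites)


# ---------------------------------------------------------------------------
# sweep injection

@dataclass
class SweepSpec:
    """Positive-control sweep emulator parameters.

    A fraction ``frequency`` of chromosomes become carriers of a derived
    focal allele, and each carrier's flanking sequence is overwritten by
    one donor haplotype out to independent exponential breakpoints
    (mean ``extent_cm`` on each side), emulating the long shared
    haplotype of a recent sweep.  This is a deterministic homozygosity
    emulator, not a structured-coalescent sweep simulation.
    """

    position_bp: float
    frequency: float
    extent_cm: float

    def __post_init__(self) -> None:
        if not 0.0 < self.frequency < 1.0:
            raise ValueError("frequency must be in (0, 1)")
        if self.extent_cm <= 0:
            raise ValueError("extent must be positive")


def inject_sweep(matrix: HaplotypeMatrix, spec: SweepSpec, gmap,
                 rng: np.random.Generator | None = None,
                 seed: int | None = None) -> tuple[HaplotypeMatrix, int]:
    """Return a swept copy of ``matrix`` and the focal site index."""
    if rng is None:
        rng = np.random.default_rng(seed)
    pos = matrix.sites.pos
    if not pos[0] <= spec.position_bp <= pos[-1]:
        raise ValueError("focal position outside the region")
    focal = int(np.argmin(np.abs(pos - spec.position_bp)))
    n = matrix.n_chromosomes
    n_car = int(round(spec.frequency * n))
    if n_car < 2:
        raise ValueError("sweep would have fewer than 2 carriers")
    carriers = rng.choice(n, size=n_car, replace=False)
    donor = int(carriers[0])
    cm = gmap.interpolate(pos)
    out = matrix.alleles.copy()
    for c in carriers:
        if c == donor:
            continue
        left = rng.exponential(spec.extent_cm)
        right = rng.exponential(spec.extent_cm)
        span = (cm >= cm[focal] - left) & (cm <= cm[focal] + right)
        out[c, span] = matrix.alleles[donor, span]
    out[:, focal] = 0
    out[carriers, focal] = 1
    return HaplotypeMatrix(out, list(matrix.sample_ids), matrix.sites), focal


def simulate_background(config: SimConfig, n_regions: int,
                        seed: int | None = None) -> list:
    """Independent neutral regions for empirical background pools."""
    ss = np.random.SeedSequence(seed)
    out = []
    for child in ss.spawn(n_regions):
        rng = np.random.default_rng(child)
        out.append(simulate_neutral(config, rng=rng))
    return out
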