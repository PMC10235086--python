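"""Synthetic mock / auxin RNA-seq fragment datasets.

The generator emulates the statistical structure of a strand-specific,
rRNA-depleted, paired-end RNA-seq experiment on a budding-yeast Rio1
degron strain: three mock-treated and three auxin-treated (Rio1-depleted)
replicate libraries whose (peri)centromeric fragment content follows the
observed study conditions —

- cenRNA fragments in a 1:1 short:long mixture (log-normal lengths with
  medians 231 and 4458 nt), noncoding pericen fragments (median 225 nt)
  at ~390x the cen count, coding pericen fragments at ~10x the noncoding
  count;
- a mock termination-class composition of 48% FULL_CEN with the remainder
  split CDEI/CDEII/CDEIII proportionally to 12/24/17, shifting to 32%
  FULL_CEN under auxin with the deficit moving to CDEI;
- 79% of cen fragments initiating in the pericentromere, a plus-strand
  bias on 10 of 16 chromosomes, and auxin count multipliers of 2.3 (net,
  total cen), 1.9 (noncoding pericen), 1.0 (long cen and coding pericen);
- ~1e6 background fragments per library standing in for genome-wide
  library depth (the CPM denominator).

Placement is constructive: each fragment's interval is built so that the
classifier assigns its intended class (termination classes are anchored
on the CDE element boundaries), which tests assert.  Everything is
deterministic under a fixed seed; replicate streams derive child seeds
from (seed, condition, replicate) so replicates differ but runs reproduce.
"""

from __future__ import annotations

import dataclasses
import hashlib
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as cls
from .fragments import FRAME_COLUMNS, SampleSheet, write_fragments_frame
from .genome import (
    GenomeModel,
    OrfFeature,
    build_genome_model,
    write_genome_model,
)

__all__ = [
    "SimulationConfig",
    "SimulationError",
    "simulate_genome",
    "simulate_fragments",
    "simulate_experiment",
]

MOCK = "mock"
AUXIN = "auxin"
_COND_CODE = {MOCK: 0, AUXIN: 1}

# (name, length bp, mRNA copies per cell) of the calibration references
DEFAULT_REFERENCE_GENES = (
    ("DOA1", 2148, 2.6),
    ("KAP104", 2757, 5.0),
    ("POL1", 4407, 3.1),
    ("PDR5", 4536, 13.4),
)


class SimulationError(ValueError):
    pass


def _roman(i: int) -> str:
    vals = (1000, 900, 500, 400, 100, 90, 50, 40, 10, 9, 5, 4, 1)
    syms = ("M", "CM", "D", "CD", "C", "XC", "L", "XL", "X", "IX", "V", "IV", "I")
    out = []
    for v, s in zip(vals, syms):
        while i >= v:
            out.append(s)
            i -= v
    return "".join(out)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic experiment, with study-condition defaults."""

    seed: int = 1
    # genome geometry
    n_chromosomes: int = 16
    chromosome_length: int = 100_000
    window_bp: int = 500
    core_width_band: tuple[int, int] = (115, 119)   # sampled core widths, 117 +/- 2
    cde1_len: int = 8
    cde3_len: int = 25
    orf_count: int = 22
    orf_core_gap: int = 200     # no ORF closer than this to a core
    orf_length_range: tuple[int, int] = (300, 1500)
    # per-condition class abundances (mock baseline x scale, over all replicates)
    scale: int = 10
    cen_total: int = 42
    noncoding_pericen_total: int = 16_369
    coding_pericen_multiplier: float = 10.0
    background_fragments: int = 1_000_000   # per sample (library-depth filler)
    replicates: int = 3
    # cen structure
    short_cen_weight: float = 0.5           # mock short:long mixture
    length_threshold: int = 1000
    short_cen_median: float = 231.0
    short_cen_log_sd: float = 0.45
    long_cen_median: float = 4458.0
    long_cen_log_sd: float = 0.35
    noncoding_median: float = 225.0
    noncoding_log_sd: float = 0.45
    coding_median: float = 500.0
    coding_log_sd: float = 0.5
    background_median: float = 300.0
    background_log_sd: float = 0.5
    # termination-class composition
    term_full_mock: float = 0.48
    term_cde_weights: tuple[float, float, float] = (0.12, 0.24, 0.17)
    term_full_auxin: float = 0.32
    # initiation and strand structure
    pericen_init_prob: float = 0.79
    plus_dominant_chromosomes: int = 10
    plus_strand_prob: float = 0.7           # P(+) on plus-dominant chromosomes
    # auxin condition multipliers: the published count ratios (98/42 and
    # 30346/16369), which display as 2.3 and 1.9 at two significant figures
    auxin_cen_multiplier: float = 98 / 42           # net over total cen count
    auxin_long_cen_multiplier: float = 1.0
    auxin_noncoding_multiplier: float = 30346 / 16369
    auxin_coding_multiplier: float = 1.0
    # optional per-chromosome abundance weights (uniform when None)
    chrom_weights: tuple[float, ...] | None = None
    # reference-gene synthesis
    ref_read_density: float = 50.0          # reads per kb per molecule per cell

    def validate(self) -> None:
        probs = {
            "short_cen_weight": self.short_cen_weight,
            "term_full_mock": self.term_full_mock,
            "term_full_auxin": self.term_full_auxin,
            "pericen_init_prob": self.pericen_init_prob,
            "plus_strand_prob": self.plus_strand_prob,
        }
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise SimulationError(f"{name}={p} outside [0,1]")
        if min(self.term_cde_weights) < 0 or sum(self.term_cde_weights) <= 0:
            raise SimulationError("term_cde_weights must be non-negative, not all zero")
        for name in (
            "short_cen_median", "long_cen_median", "noncoding_median",
            "coding_median", "background_median",
        ):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be > 0")
        if self.replicates < 1:
            raise SimulationError("need at least one replicate")
        if self.n_chromosomes < 1:
            raise SimulationError("need at least one chromosome")
        if self.plus_dominant_chromosomes > self.n_chromosomes:
            raise SimulationError("plus_dominant_chromosomes exceeds n_chromosomes")
        lo, hi = self.core_width_band
        if not (0 < lo <= hi):
            raise SimulationError("invalid core_width_band")
        if hi < self.cde1_len + self.cde3_len + 1:
            raise SimulationError("core width band too small for the CDE layout")
        min_len = 4 * (self.window_bp + hi) + 2 * self.orf_length_range[1]
        if self.chromosome_length < max(min_len, 30_000):
            raise SimulationError(
                f"chromosome_length {self.chromosome_length} too short for the "
                f"window geometry and fragment length distributions"
            )
        if self.chrom_weights is not None:
            if len(self.chrom_weights) != self.n_chromosomes:
                raise SimulationError("chrom_weights length != n_chromosomes")
            if min(self.chrom_weights) < 0 or sum(self.chrom_weights) <= 0:
                raise SimulationError("invalid chrom_weights")
        # FULL_CEN fragments must be able to cover a core: the long-length
        # distribution always can; the short one can iff threshold > max width
        if self.length_threshold <= hi:
            raise SimulationError(
                "length_threshold must exceed the maximal core width, else a "
                "SHORT FULL_CEN fragment is infeasible"
            )

    def term_composition(self, condition: str) -> dict[str, float]:
        """Termination-class probabilities for a condition (sums to 1)."""
        w = np.asarray(self.term_cde_weights, dtype=float)
        cde_mock = w / w.sum() * (1.0 - self.term_full_mock)
        if condition == MOCK:
            full, cde = self.term_full_mock, cde_mock
        elif condition == AUXIN:
            # the FULL_CEN deficit moves to CDEI
            cde = cde_mock.copy()
            cde[0] += self.term_full_mock - self.term_full_auxin
            full = self.term_full_auxin
        else:
            raise SimulationError(f"unknown condition {condition!r}")
        comp = {
            cls.FULL_CEN: full,
            cls.CDEI: float(cde[0]),
            cls.CDEII: float(cde[1]),
            cls.CDEIII: float(cde[2]),
        }
        if min(comp.values()) < 0:
            raise SimulationError("termination composition has a negative component")
        return comp

    def condition_totals(self, condition: str) -> dict[str, int]:
        """Per-condition class totals (summed over replicates)."""
        cen_m = int(round(self.cen_total * self.scale))
        short_m = int(round(cen_m * self.short_cen_weight))
        long_m = cen_m - short_m
        nc_m = int(round(self.noncoding_pericen_total * self.scale))
        cod_m = int(round(nc_m * self.coding_pericen_multiplier))
        if condition == MOCK:
            return {"short_cen": short_m, "long_cen": long_m,
                    "noncoding": nc_m, "coding": cod_m}
        if condition == AUXIN:
            long_a = int(round(long_m * self.auxin_long_cen_multiplier))
            cen_a = int(round(cen_m * self.auxin_cen_multiplier))
            short_a = max(cen_a - long_a, 0)
            return {
                "short_cen": short_a,
                "long_cen": long_a,
                "noncoding": int(round(nc_m * self.auxin_noncoding_multiplier)),
                "coding": int(round(cod_m * self.auxin_coding_multiplier)),
            }
        raise SimulationError(f"unknown condition {condition!r}")

    # ---- serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        return d

    @classmethod
    def from_dict(cls_, d: dict) -> "SimulationConfig":
        fields = {f.name for f in dataclasses.fields(cls_)}
        unknown = set(d) - fields
        if unknown:
            raise SimulationError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = dict(d)
        for key, val in kwargs.items():
            if isinstance(val, list):
                kwargs[key] = tuple(val)
        cfg = cls_(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls_, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls_.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# genome simulation


def simulate_genome(config: SimulationConfig) -> GenomeModel:
    """One CEN core per chromosome plus pericen-window-intersecting ORFs.

    Core widths are drawn in the configured 117 +/- 2 band; exactly
    ``orf_count`` ORFs are placed so each intersects a pericen window while
    keeping at least ``orf_core_gap`` bp clear of every core.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 101])
    L = config.chromosome_length
    chroms = {f"chr{_roman(i + 1)}": L for i in range(config.n_chromosomes)}
    names = list(chroms)

    lo, hi = config.core_width_band
    cen_intervals: dict[str, tuple[int, int]] = {}
    for name in names:
        width = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(int(0.35 * L), int(0.65 * L)))
        cen_intervals[name] = (start, start + width)

    # all of a chromosome's pericen ORFs sit on one side of its core so the
    # opposite window always offers ORF-free room for noncoding fragments
    orf_side_up = {name: bool(rng.random() < 0.5) for name in names}
    orfs: list[OrfFeature] = []
    olo, ohi = config.orf_length_range
    for i in range(config.orf_count):
        chrom = names[i % len(names)]
        cs, ce = cen_intervals[chrom]
        length = int(rng.integers(olo, ohi + 1))
        gap = int(rng.integers(config.orf_core_gap, config.window_bp - 50))
        if orf_side_up[chrom]:
            end = cs - gap
            start = end - length
        else:
            start = ce + gap
            end = start + length
        strand = "+" if rng.random() < 0.5 else "-"
        orfs.append(
            OrfFeature(chrom=chrom, start=start, end=end, strand=strand,
                       id=f"ORF{i + 1:03d}")
        )

    return build_genome_model(
        chroms, cen_intervals, orfs,
        window_bp=config.window_bp,
        cde1_len=config.cde1_len, cde3_len=config.cde3_len,
        core_width_band=(lo - 2, hi + 2),
    )


# ---------------------------------------------------------------------------
# fragment placement helpers


def _chrom_probs(config: SimulationConfig) -> np.ndarray:
    if config.chrom_weights is None:
        return np.full(config.n_chromosomes, 1.0 / config.n_chromosomes)
    w = np.asarray(config.chrom_weights, dtype=float)
    return w / w.sum()


def _plus_prob_by_chrom(config: SimulationConfig) -> np.ndarray:
    """P(+ strand) per chromosome: the first ``plus_dominant_chromosomes``
    are plus-dominant, the rest minus-dominant."""
    p = np.full(config.n_chromosomes, 1.0 - config.plus_strand_prob)
    p[: config.plus_dominant_chromosomes] = config.plus_strand_prob
    return p


def _lognormal_lengths(
    rng: np.random.Generator, n: int, median: float, log_sd: float,
    lo: int | None = None, hi: int | None = None,
) -> np.ndarray:
    """Integer lengths from a log-normal with the given median, resampled
    (not clipped) into [lo, hi] so class boundaries are respected without
    distorting the interior of the distribution."""
    mu = np.log(median)
    out = np.rint(rng.lognormal(mu, log_sd, size=n)).astype(np.int64)
    out = np.maximum(out, 1)
    for _ in range(1000):
        bad = np.zeros(n, dtype=bool)
        if lo is not None:
            bad |= out < lo
        if hi is not None:
            bad |= out > hi
        k = int(bad.sum())
        if k == 0:
            return out
        redraw = np.rint(rng.lognormal(mu, log_sd, size=k)).astype(np.int64)
        out[bad] = np.maximum(redraw, 1)
    raise SimulationError(
        f"length resampling did not converge for median={median}, "
        f"bounds=({lo},{hi}); bounds are likely infeasible"
    )


def _ranged_int(rng: np.random.Generator, lo: int, hi: int) -> int:
    """Uniform integer in the inclusive range [lo, hi]."""
    return int(rng.integers(lo, hi + 1))


def _place_cen(core, strand: str, term: str, length: int, want_init: bool,
               rng: np.random.Generator) -> tuple[int, int]:
    """Choose a (start, end) realising the intended termination class.

    The termination class is always honoured; the pericen-initiation wish
    is honoured whenever the drawn length makes it geometrically possible.
    """
    s, e = core.start, core.end
    width = e - s
    if term == cls.FULL_CEN:
        if length < width:
            raise SimulationError("FULL_CEN fragment shorter than the core")
        slack = length - width
        if want_init and slack >= 1:
            u = _ranged_int(rng, 1, slack)
            start = s - u if strand == "+" else e + u - length
        else:
            start = s if strand == "+" else e - length
        return start, start + length

    elems = dict(zip((cls.CDEI, cls.CDEII, cls.CDEIII), core.elements))
    ts, te = elems[term]
    if strand == "+":
        # first choice: anchor the fragment end (termination boundary) in the
        # element, with the start placed per the initiation wish
        e_lo, e_hi = ts + 1, min(te, e - 1)
        if want_init:           # 5' (start) outside the core, upstream
            p_lo, p_hi = e_lo, min(e_hi, s + length - 1)
        else:                   # 5' inside the core, fragment shorter than core
            p_lo, p_hi = max(e_lo, s + length), e_hi
        if p_lo <= p_hi:
            end = _ranged_int(rng, p_lo, p_hi)
            return end - length, end
        if not want_init:
            # second choice: 5' (start) inside the element, running beyond the
            # core — the in-core start boundary then carries the termination
            a_lo, a_hi = max(ts, s + 1, e - length), te - 1
            if a_lo <= a_hi:
                start = _ranged_int(rng, a_lo, a_hi)
                return start, start + length
        # geometrically infeasible wish: keep the termination class
        end = _ranged_int(rng, e_lo, e_hi)
        return end - length, end
    else:
        # mirror image: the 3' boundary of a '-' fragment is its start
        s_lo, s_hi = max(ts, s + 1), te - 1
        if want_init:           # 5' (end-1) outside the core, downstream
            p_lo, p_hi = max(s_lo, e + 1 - length), s_hi
        else:                   # 5' inside the core, fragment shorter than core
            p_lo, p_hi = s_lo, min(s_hi, e - length)
        if p_lo <= p_hi:
            start = _ranged_int(rng, p_lo, p_hi)
            return start, start + length
        if not want_init:
            a_lo, a_hi = ts + 1, min(te, e - 1, s + length)
            if a_lo <= a_hi:
                end = _ranged_int(rng, a_lo, a_hi)
                return end - length, end
        start = _ranged_int(rng, s_lo, s_hi)
        return start, start + length


# ---------------------------------------------------------------------------
# per-class fragment blocks


def _gen_cen_block(
    config: SimulationConfig, model: GenomeModel, condition: str,
    n_short: int, n_long: int, rng: np.random.Generator,
) -> pd.DataFrame:
    n = n_short + n_long
    if n == 0:
        return pd.DataFrame(columns=FRAME_COLUMNS[:-1])
    names = list(model.chromosomes)
    p_chrom = _chrom_probs(config)
    p_plus = _plus_prob_by_chrom(config)
    comp = config.term_composition(condition)
    term_names = list(comp)
    term_p = np.array([comp[t] for t in term_names])

    chrom_idx = rng.choice(len(names), size=n, p=p_chrom)
    plus = rng.random(n) < p_plus[chrom_idx]
    terms = rng.choice(len(term_names), size=n, p=term_p)
    inits = rng.random(n) < config.pericen_init_prob
    is_short = np.zeros(n, dtype=bool)
    is_short[:n_short] = True

    starts = np.empty(n, dtype=np.int64)
    ends = np.empty(n, dtype=np.int64)
    mu_s, sd_s = np.log(config.short_cen_median), config.short_cen_log_sd
    mu_l, sd_l = np.log(config.long_cen_median), config.long_cen_log_sd
    thr = config.length_threshold
    for i in range(n):
        core = model.cores[names[chrom_idx[i]]]
        term = term_names[terms[i]]
        lo = core.width if term == cls.FULL_CEN else 1
        # keep long placements inside the chromosome
        hi_cap = min(core.start - 1, model.chromosomes[core.chrom] - core.end - 1)
        if is_short[i]:
            mu, sd, lo_b, hi_b = mu_s, sd_s, lo, thr - 1
        else:
            mu, sd, lo_b, hi_b = mu_l, sd_l, max(lo, thr), hi_cap
        length = 0
        for _ in range(10_000):
            length = max(int(round(rng.lognormal(mu, sd))), 1)
            if lo_b <= length <= hi_b:
                break
        else:
            raise SimulationError("cen length resampling did not converge")
        strand = "+" if plus[i] else "-"
        starts[i], ends[i] = _place_cen(core, strand, term, length, bool(inits[i]), rng)

    return pd.DataFrame(
        {
            "chrom": [names[i] for i in chrom_idx],
            "start": starts,
            "end": ends,
            "name": "cen",
            "score": 0,
            "strand": np.where(plus, "+", "-"),
        }
    )


def _gen_noncoding_block(
    config: SimulationConfig, model: GenomeModel, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    if n == 0:
        return pd.DataFrame(columns=FRAME_COLUMNS[:-1])
    names = list(model.chromosomes)
    chrom_idx = rng.choice(len(names), size=n, p=_chrom_probs(config))
    plus = rng.random(n) < _plus_prob_by_chrom(config)[chrom_idx]
    lengths = _lognormal_lengths(
        rng, n, config.noncoding_median, config.noncoding_log_sd, lo=30
    )
    up_side = rng.random(n) < 0.5

    starts = np.empty(n, dtype=np.int64)
    ends = np.empty(n, dtype=np.int64)
    for ci, name in enumerate(names):
        core = model.cores[name]
        win = model.windows[name]
        m = chrom_idx == ci
        if not m.any():
            continue
        idx = np.flatnonzero(m)
        orfs = [(o.start, o.end) for o in model.pericen_orfs(name)]
        li = lengths[idx]
        side = up_side[idx]
        s_arr = np.empty(len(idx), dtype=np.int64)
        e_arr = np.empty(len(idx), dtype=np.int64)
        todo = np.arange(len(idx))
        for _ in range(200):
            # up-side fragments end at or before the core start; down-side
            # fragments begin at or after the core end ("end at the border")
            k = len(todo)
            end_up = rng.integers(win.up[0] + 1, core.start + 1, size=k)
            start_dn = rng.integers(core.end, win.down[1], size=k)
            s_new = np.where(side[todo], end_up - li[todo], start_dn)
            e_new = np.where(side[todo], end_up, start_dn + li[todo])
            bad = np.zeros(k, dtype=bool)
            for os_, oe in orfs:
                bad |= (s_new < oe) & (e_new > os_)
            s_arr[todo], e_arr[todo] = s_new, e_new
            todo = todo[bad]
            if len(todo) == 0:
                break
            # a fragment longer than the ORF-free gap can never place on the
            # up side next to an up-side ORF; flip the stuck ones' side
            side[todo] = ~side[todo]
        else:
            raise SimulationError("noncoding pericen placement did not converge")
        starts[idx], ends[idx] = s_arr, e_arr

    return pd.DataFrame(
        {
            "chrom": [names[i] for i in chrom_idx],
            "start": starts,
            "end": ends,
            "name": "pnc",
            "score": 0,
            "strand": np.where(plus, "+", "-"),
        }
    )


def _gen_coding_block(
    config: SimulationConfig, model: GenomeModel, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    if n == 0:
        return pd.DataFrame(columns=FRAME_COLUMNS[:-1])
    orfs = model.pericen_orfs()
    if not orfs:
        raise SimulationError("no pericen-intersecting ORFs to draw coding fragments from")
    ostart = np.array([o.start for o in orfs])
    oend = np.array([o.end for o in orfs])
    ostrand = np.array([o.strand for o in orfs], dtype=object)
    ochrom = np.array([o.chrom for o in orfs], dtype=object)
    # the window each ORF intersects (ORFs sit on one side of the core)
    wlo = np.empty(len(orfs), dtype=np.int64)
    whi = np.empty(len(orfs), dtype=np.int64)
    for j, o in enumerate(orfs):
        win = model.windows[o.chrom]
        if o.start < win.up[1] and o.end > win.up[0]:
            wlo[j], whi[j] = win.up
        else:
            wlo[j], whi[j] = win.down

    pick = rng.integers(0, len(orfs), size=n)
    olen = oend[pick] - ostart[pick]
    lengths = _lognormal_lengths(rng, n, config.coding_median, config.coding_log_sd, lo=50)
    lengths = np.minimum(lengths, olen)
    # start range keeping the fragment inside its ORF and overlapping the window
    lo_arr = np.maximum(ostart[pick], wlo[pick] - lengths + 1)
    hi_arr = np.minimum(oend[pick] - lengths, whi[pick] - 1)
    u = rng.random(n)
    starts = (lo_arr + np.floor(u * (hi_arr - lo_arr + 1))).astype(np.int64)
    return pd.DataFrame(
        {
            "chrom": ochrom[pick],
            "start": starts,
            "end": starts + lengths,
            "name": "pc",
            "score": 0,
            "strand": ostrand[pick],
        }
    )


def _gen_background_block(
    config: SimulationConfig, model: GenomeModel, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    if n == 0:
        return pd.DataFrame(columns=FRAME_COLUMNS[:-1])
    names = list(model.chromosomes)
    clen = np.array([model.chromosomes[c] for c in names])
    span_lo = np.array([model.windows[c].span[0] for c in names])
    span_hi = np.array([model.windows[c].span[1] for c in names])

    chrom_idx = rng.integers(0, len(names), size=n)
    plus = rng.random(n) < 0.5
    lengths = _lognormal_lengths(
        rng, n, config.background_median, config.background_log_sd, lo=30,
        hi=int(clen.min() // 2),
    )
    starts = np.empty(n, dtype=np.int64)
    todo = np.arange(n)
    for _ in range(200):
        k = len(todo)
        ci = chrom_idx[todo]
        u = rng.random(k)
        s_new = np.floor(u * (clen[ci] - lengths[todo])).astype(np.int64)
        e_new = s_new + lengths[todo]
        bad = (s_new < span_hi[ci]) & (e_new > span_lo[ci])
        starts[todo] = s_new
        todo = todo[bad]
        if len(todo) == 0:
            break
    else:
        raise SimulationError("background placement did not converge")
    return pd.DataFrame(
        {
            "chrom": [names[i] for i in chrom_idx],
            "start": starts,
            "end": starts + lengths,
            "name": "bg",
            "score": 0,
            "strand": np.where(plus, "+", "-"),
        }
    )


# ---------------------------------------------------------------------------
# replicate / experiment assembly


def _replicate_counts(config: SimulationConfig, condition: str) -> dict[str, np.ndarray]:
    """Multinomial split of the condition totals over replicates.

    Drawn from a child seed of (seed, condition) only, so every replicate
    call sees the same split.
    """
    rng = np.random.default_rng([config.seed, 11, _COND_CODE[condition]])
    totals = config.condition_totals(condition)
    probs = np.full(config.replicates, 1.0 / config.replicates)
    return {k: rng.multinomial(v, probs) for k, v in totals.items()}


def sample_name(condition: str, replicate: int) -> str:
    return f"{condition}{replicate + 1}"


def simulate_fragments(
    config: SimulationConfig,
    model: GenomeModel,
    condition: str,
    replicate: int,
) -> tuple[pd.DataFrame, dict]:
    """One replicate library: fragment frame + its sample-sheet row.

    The frame carries cen, noncoding pericen, coding pericen and background
    blocks (in that fixed order); ``total_fragments`` in the sheet row is
    the full library size and is the CPM denominator downstream.
    """
    config.validate()
    if condition not in _COND_CODE:
        raise SimulationError(f"unknown condition {condition!r}")
    if not (0 <= replicate < config.replicates):
        raise SimulationError(f"replicate {replicate} outside 0..{config.replicates - 1}")
    counts = {k: int(v[replicate]) for k, v in _replicate_counts(config, condition).items()}
    rng = np.random.default_rng([config.seed, 13, _COND_CODE[condition], replicate])

    blocks = [
        _gen_cen_block(config, model, condition, counts["short_cen"],
                       counts["long_cen"], rng),
        _gen_noncoding_block(config, model, counts["noncoding"], rng),
        _gen_coding_block(config, model, counts["coding"], rng),
        _gen_background_block(config, model, config.background_fragments, rng),
    ]
    frame = pd.concat([b for b in blocks if len(b)], ignore_index=True) if any(
        len(b) for b in blocks
    ) else blocks[0]
    sample = sample_name(condition, replicate)
    frame["sample"] = sample
    row = {
        "sample": sample,
        "condition": condition,
        "replicate": replicate + 1,
        "total_fragments": int(len(frame)),
    }
    return frame, row


def _reference_tables(
    config: SimulationConfig, model: GenomeModel, samples: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reference-gene annotation + per-sample counts consistent with their
    copies-per-cell (counts ~ Poisson(density * copies * length))."""
    rng = np.random.default_rng([config.seed, 17])
    names = list(model.chromosomes)
    genes = []
    for i, (gid, length, copies) in enumerate(DEFAULT_REFERENCE_GENES):
        chrom = names[i % len(names)]
        start = 1000 + i * 10  # far from the mid-chromosome CEN cores
        genes.append(
            {"id": gid, "chrom": chrom, "start": start, "end": start + length,
             "copies_per_cell": copies}
        )
    gene_df = pd.DataFrame(genes)
    count_rows = []
    for sample in samples:
        for g in genes:
            lam = config.ref_read_density * g["copies_per_cell"] * (
                (g["end"] - g["start"]) / 1000.0
            )
            count_rows.append(
                {"sample": sample, "id": g["id"], "count": int(rng.poisson(lam))}
            )
    return gene_df, pd.DataFrame(count_rows)


def simulate_experiment(
    config: SimulationConfig, outdir: str | Path, overwrite: bool = False
) -> dict:
    """Full synthetic dataset on disk, consumable end-to-end by the CLI.

    Layout: ``genome/`` (chrom.sizes + BED annotation), ``fragments/``
    (one BED6 per sample), ``samples.tsv``, ``reference_genes.tsv``,
    ``reference_counts.tsv``, ``config.yaml``.
    """
    config.validate()
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()):
        if not overwrite:
            raise SimulationError(
                f"output directory {outdir} exists and is not empty; "
                "pass overwrite=True to replace it"
            )
        shutil.rmtree(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    model = simulate_genome(config)
    genome_paths = write_genome_model(model, outdir / "genome")

    frag_dir = outdir / "fragments"
    frag_dir.mkdir(exist_ok=True)
    rows = []
    frag_paths: dict[str, Path] = {}
    for condition in (MOCK, AUXIN):
        for rep in range(config.replicates):
            frame, row = simulate_fragments(config, model, condition, rep)
            path = frag_dir / f"{row['sample']}.bed"
            write_fragments_frame(frame, path)
            rows.append(row)
            frag_paths[row["sample"]] = path
    sheet = SampleSheet(pd.DataFrame(rows))
    sheet.to_tsv(outdir / "samples.tsv")

    gene_df, count_df = _reference_tables(config, model, sheet.samples)
    gene_df.to_csv(outdir / "reference_genes.tsv", sep="\t", index=False)
    count_df.to_csv(outdir / "reference_counts.tsv", sep="\t", index=False)
    config.to_yaml(outdir / "config.yaml")

    return {
        "model": model,
        "sheet": sheet,
        "genome_paths": genome_paths,
        "fragment_paths": frag_paths,
        "samples_path": outdir / "samples.tsv",
        "reference_genes_path": outdir / "reference_genes.tsv",
        "reference_counts_path": outdir / "reference_counts.tsv",
        "config_path": outdir / "config.yaml",
    }
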