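"""Assign every fragment to exactly one transcript class.

Classes follow the subtraction semantics of the original bedtools-based
extraction: a fragment overlapping the CEN core by >=1 bp is centromeric
(CEN, a cenRNA), regardless of any window overlap; a fragment overlapping
a pericentromeric window but *not* the core is pericentromeric, split into
coding (overlaps an ORF that itself intersects a pericen window) and
noncoding; everything else is OTHER.

CEN fragments additionally carry

- a termination class: FULL_CEN when the fragment covers the whole core,
  otherwise the CDE element (CDEI/CDEII/CDEIII) containing the fragment
  boundary that falls inside the core — when both boundaries fall inside,
  the 3' boundary with respect to the fragment strand decides;
- a length class: SHORT (< 1000 bp span) or LONG (>= 1000 bp);
- an initiation flag: whether the strand-aware 5' end lies outside the
  core (i.e. the transcript initiated in the flanking pericentromere);
- a side flag: which pericen window(s) the fragment touches.

Scalar (:func:`classify_fragment`) and vectorised (:func:`classify_frame`)
implementations share the same rules; tests hold them to each other and to
a brute-force oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fragments import FragmentRecord, SampleSheet
from .genome import CenCore, GenomeModel

__all__ = [
    "CEN", "PERICEN_NONCODING", "PERICEN_CODING", "OTHER",
    "FULL_CEN", "CDEI", "CDEII", "CDEIII", "NONE",
    "SHORT", "LONG",
    "ClassifiedFragment", "classify_fragment", "classify_frame",
    "length_class", "tally", "term_class_distribution",
]

# transcript classes
CEN = "CEN"
PERICEN_NONCODING = "PERICEN_NONCODING"
PERICEN_CODING = "PERICEN_CODING"
OTHER = "OTHER"

# termination classes
FULL_CEN = "FULL_CEN"
CDEI = "CDEI"
CDEII = "CDEII"
CDEIII = "CDEIII"
NONE = "NONE"
TERM_CLASSES = (FULL_CEN, CDEI, CDEII, CDEIII)

# length classes
SHORT = "SHORT"
LONG = "LONG"
DEFAULT_LENGTH_THRESHOLD = 1000

# sides
UP = "UP"
DOWN = "DOWN"
BOTH = "BOTH"

_CDE_NAMES = (CDEI, CDEII, CDEIII)


class ClassificationError(ValueError):
    pass


@dataclass(frozen=True)
class ClassifiedFragment:
    fragment: FragmentRecord
    tclass: str
    term_class: str = NONE
    length_class: str = NONE
    initiated_in_pericen: bool = False
    side: str = NONE


def length_class(length: int, threshold: int = DEFAULT_LENGTH_THRESHOLD) -> str:
    """SHORT iff span < threshold (default 1000 bp); exactly 1000 is LONG."""
    return SHORT if length < threshold else LONG


def _element_of(core: CenCore, pos: int) -> str:
    for name, (s, e) in zip(_CDE_NAMES, core.elements):
        if s <= pos < e:
            return name
    raise ClassificationError(f"position {pos} not inside core [{core.start},{core.end})")


def _overlap_len(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def classify_fragment(
    f: FragmentRecord,
    model: GenomeModel,
    length_threshold: int = DEFAULT_LENGTH_THRESHOLD,
    min_overlap: int = 1,
    coding_strand_matched: bool = False,
) -> ClassifiedFragment:
    """Classify one fragment against the genome model (scalar reference path)."""
    if f.chrom not in model.chromosomes:
        raise ClassificationError(f"fragment {f.name}: unknown chromosome {f.chrom!r}")
    core = model.cores.get(f.chrom)
    win = model.windows.get(f.chrom)
    if core is None or win is None:
        return ClassifiedFragment(fragment=f, tclass=OTHER)

    ov_core = _overlap_len(f.start, f.end, core.start, core.end) >= min_overlap
    ov_up = _overlap_len(f.start, f.end, *win.up) >= min_overlap
    ov_down = _overlap_len(f.start, f.end, *win.down) >= min_overlap
    side = BOTH if (ov_up and ov_down) else UP if ov_up else DOWN if ov_down else NONE

    if ov_core:
        term = _term_class(f, core)
        init = not (core.start <= f.five_prime < core.end)
        return ClassifiedFragment(
            fragment=f, tclass=CEN, term_class=term,
            length_class=length_class(f.length, length_threshold),
            initiated_in_pericen=init, side=side,
        )

    if ov_up or ov_down:
        coding = False
        for orf in model.pericen_orfs(f.chrom):
            if _overlap_len(f.start, f.end, orf.start, orf.end) >= min_overlap:
                if not coding_strand_matched or orf.strand == f.strand:
                    coding = True
                    break
        tclass = PERICEN_CODING if coding else PERICEN_NONCODING
        return ClassifiedFragment(fragment=f, tclass=tclass, side=side)

    return ClassifiedFragment(fragment=f, tclass=OTHER)


def _term_class(f: FragmentRecord, core: CenCore) -> str:
    if f.start <= core.start and f.end >= core.end:
        return FULL_CEN
    p_start, p_end = f.start, f.end - 1  # last covered base
    start_inside = core.start < f.start and f.start < core.end
    end_inside = f.end < core.end and p_end >= core.start
    if start_inside and end_inside:
        pos = p_end if f.strand == "+" else p_start  # 3' boundary decides
        return _element_of(core, pos)
    if start_inside:
        return _element_of(core, p_start)
    if end_inside:
        return _element_of(core, p_end)
    raise ClassificationError(
        f"fragment {f.name} [{f.start},{f.end}) overlaps core "
        f"[{core.start},{core.end}) but has no classifiable boundary"
    )


# ---------------------------------------------------------------------------
# vectorised path


def classify_frame(
    frame: pd.DataFrame,
    model: GenomeModel,
    length_threshold: int = DEFAULT_LENGTH_THRESHOLD,
    min_overlap: int = 1,
    coding_strand_matched: bool = False,
) -> pd.DataFrame:
    """Vectorised classification of a fragment DataFrame.

    Returns a copy with the added columns ``tclass, term_class,
    length_class, initiated_in_pericen, side``.  Rules are identical to
    :func:`classify_fragment` (asserted by tests on random fixtures).
    """
    unknown = set(frame["chrom"].unique()) - set(model.chromosomes)
    if unknown:
        raise ClassificationError(f"fragments on unknown chromosome(s): {sorted(unknown)}")

    out = frame.copy()
    n = len(out)
    tclass = np.full(n, OTHER, dtype=object)
    term = np.full(n, NONE, dtype=object)
    lclass = np.full(n, NONE, dtype=object)
    init = np.zeros(n, dtype=bool)
    side = np.full(n, NONE, dtype=object)

    start = out["start"].to_numpy()
    end = out["end"].to_numpy()
    plus = out["strand"].to_numpy() == "+"
    chroms = out["chrom"].to_numpy()

    for chrom in pd.unique(out["chrom"]):
        core = model.cores.get(chrom)
        win = model.windows.get(chrom)
        if core is None or win is None:
            continue
        m = chroms == chrom
        s, e = start[m], end[m]
        pl = plus[m]

        def ovlen(lo: int, hi: int) -> np.ndarray:
            return np.minimum(e, hi) - np.maximum(s, lo)

        ov_core = ovlen(core.start, core.end) >= min_overlap
        ov_up = ovlen(*win.up) >= min_overlap
        ov_down = ovlen(*win.down) >= min_overlap

        sd = np.full(m.sum(), NONE, dtype=object)
        sd[ov_up] = UP
        sd[ov_down] = DOWN
        sd[ov_up & ov_down] = BOTH
        side[m] = sd

        tc = np.full(m.sum(), OTHER, dtype=object)
        pericen = ~ov_core & (ov_up | ov_down)
        if pericen.any():
            coding = np.zeros(m.sum(), dtype=bool)
            for orf in model.pericen_orfs(chrom):
                hit = (np.minimum(e, orf.end) - np.maximum(s, orf.start)) >= min_overlap
                if coding_strand_matched:
                    hit &= pl == (orf.strand == "+")
                coding |= hit
            tc[pericen & coding] = PERICEN_CODING
            tc[pericen & ~coding] = PERICEN_NONCODING
        tc[ov_core] = CEN
        tclass[m] = tc

        # termination classes for CEN fragments
        full = ov_core & (s <= core.start) & (e >= core.end)
        p_end = e - 1
        start_in = ov_core & (s > core.start) & (s < core.end)
        end_in = ov_core & (e < core.end) & (p_end >= core.start)
        both = start_in & end_in
        use_end = (both & pl) | (end_in & ~start_in)
        use_start = (both & ~pl) | (start_in & ~end_in)

        bounds = np.array([core.cde1[1], core.cde2[1]])
        elem_names = np.array(_CDE_NAMES, dtype=object)
        tm = np.full(m.sum(), NONE, dtype=object)
        tm[use_start] = elem_names[np.searchsorted(bounds, s[use_start], side="right")]
        tm[use_end] = elem_names[np.searchsorted(bounds, p_end[use_end], side="right")]
        tm[full] = FULL_CEN
        term[m] = tm

        five = np.where(pl, s, p_end)
        ini = np.zeros(m.sum(), dtype=bool)
        ini[ov_core] = ~((five[ov_core] >= core.start) & (five[ov_core] < core.end))
        init[m] = ini

        lc = np.full(m.sum(), NONE, dtype=object)
        lc[ov_core] = np.where((e - s)[ov_core] < length_threshold, SHORT, LONG)
        lclass[m] = lc

    out["tclass"] = tclass
    out["term_class"] = term
    out["length_class"] = lclass
    out["initiated_in_pericen"] = init
    out["side"] = side
    return out


# ---------------------------------------------------------------------------
# tallies and distributions

TALLY_KEYS = ["sample", "chrom", "tclass", "strand", "length_class", "term_class"]


def tally(classified: pd.DataFrame, sheet: SampleSheet) -> pd.DataFrame:
    """Exact multiset count per (sample, chrom, tclass, strand, length/term class).

    Deterministic and order-independent; every sample present in the input
    must appear in the sheet.
    """
    unknown = set(classified["sample"].unique()) - set(sheet.samples)
    if unknown:
        raise ClassificationError(f"sample(s) not in sheet: {sorted(unknown)}")
    if classified.empty:
        return pd.DataFrame(columns=TALLY_KEYS + ["count"])
    t = (
        classified.groupby(TALLY_KEYS, observed=True, sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return t


def term_class_distribution(
    tally_frame: pd.DataFrame, condition: str, sheet: SampleSheet
) -> pd.DataFrame:
    """Per-termination-class fractions of CEN fragments, split by strand.

    Returns a tidy frame (term_class, strand, count, fraction); fractions
    over {FULL_CEN, CDEI, CDEII, CDEIII} x {+,-} sum to 1.
    """
    samples = set(sheet.samples_of(condition))
    if not samples:
        raise ClassificationError(f"no samples for condition {condition!r}")
    sub = tally_frame[
        (tally_frame["tclass"] == CEN) & tally_frame["sample"].isin(samples)
    ]
    total = int(sub["count"].sum())
    if total == 0:
        raise ClassificationError(f"zero CEN fragments for condition {condition!r}")
    grid = pd.MultiIndex.from_product(
        [TERM_CLASSES, ["+", "-"]], names=["term_class", "strand"]
    )
    counts = (
        sub.groupby(["term_class", "strand"], observed=True)["count"]
        .sum()
        .reindex(grid, fill_value=0)
        .rename("count")
        .reset_index()
    )
    counts["fraction"] = counts["count"] / total
    return counts
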