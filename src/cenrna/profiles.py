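"""CEN-anchored per-nucleotide coverage and start-site profiles.

Profiles are computed in centromere-anchored coordinates: offset 0 is the
first base of each chromosome's CEN core, negative offsets run into the
upstream pericen window, and offsets >= core width into the downstream
window.  Anchoring makes the sixteen chromosomes superposable, so a single
profile aggregates the whole genome.

Two modes exist: COVERAGE (each fragment increments every position it
covers inside the profiled window) and START_SITES (each fragment
increments only its strand-aware 5' end).  Raw per-sample integer counts
can be CPM-normalised — each sample scaled by 1e6 / total mapped fragments
— and aggregated per condition (sum by default, mean as in figure-style
renderings).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .classify import CEN, PERICEN_NONCODING
from .fragments import SampleSheet
from .genome import GenomeModel

__all__ = [
    "NucleotideProfile",
    "ProfileError",
    "coverage_profile",
    "start_site_profile",
    "cpm_normalise",
    "aggregate_conditions",
    "start_site_count",
    "profile_table",
]

COVERAGE = "COVERAGE"
START_SITES = "START_SITES"
RAW = "RAW"
CPM = "CPM"

DEFAULT_CLASSES = (CEN, PERICEN_NONCODING)


class ProfileError(ValueError):
    pass


@dataclass(frozen=True)
class NucleotideProfile:
    """Per-offset, per-strand counts keyed by sample (RAW) or condition (CPM).

    ``values`` maps (key, strand) -> float array aligned with ``offsets``;
    RAW arrays are integral.  ``offsets`` runs from -window_bp to
    max core width + window_bp - 1.
    """

    offsets: np.ndarray
    values: dict[tuple[str, str], np.ndarray]
    mode: str
    normalisation: str
    window_bp: int
    keyed_by: str  # "sample" | "condition"

    def total_mass(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def key_array(self, key: str, strand: str) -> np.ndarray:
        return self.values.get((key, strand), np.zeros_like(self.offsets, dtype=float))


def _window_bounds(model: GenomeModel, chrom: str) -> tuple[int, int, int]:
    """(region start, region end, anchor) of the profiled window on a chromosome."""
    core = model.cores[chrom]
    win = model.windows[chrom]
    return win.up[0], win.down[1], core.start


def _empty_values(samples, offsets) -> dict[tuple[str, str], np.ndarray]:
    return {
        (s, st): np.zeros(len(offsets), dtype=float)
        for s in samples
        for st in ("+", "-")
    }


def _check_geometry(model: GenomeModel, window_bp: int | None) -> None:
    if window_bp is not None and window_bp != model.window_bp:
        raise ProfileError(
            f"profile window_bp={window_bp} does not match the model's "
            f"{model.window_bp}; profiles must use the classification geometry"
        )


def _prepare(classified: pd.DataFrame, classes) -> pd.DataFrame:
    if "tclass" not in classified.columns:
        raise ProfileError("fragments must be classified before profiling")
    return classified[classified["tclass"].isin(classes)]


def coverage_profile(
    classified: pd.DataFrame,
    model: GenomeModel,
    sheet: SampleSheet,
    window_bp: int | None = None,
    classes: tuple[str, ...] = DEFAULT_CLASSES,
) -> NucleotideProfile:
    """Per-position fragment coverage, CEN-anchored, per sample and strand.

    The raw profile conserves mass: its total equals the summed per-fragment
    overlap lengths with the profiled windows.
    """
    _check_geometry(model, window_bp)
    W = model.window_bp
    offsets = np.arange(-W, model.max_core_width + W)
    sub = _prepare(classified, classes)
    values = _empty_values(sheet.samples, offsets)

    for (sample, strand, chrom), grp in sub.groupby(
        ["sample", "strand", "chrom"], observed=True
    ):
        if chrom not in model.cores:
            continue
        lo, hi, anchor = _window_bounds(model, chrom)
        s = np.maximum(grp["start"].to_numpy(), lo)
        e = np.minimum(grp["end"].to_numpy(), hi)
        keep = s < e
        s, e = s[keep] - anchor + W, e[keep] - anchor + W  # array indices
        diff = np.zeros(len(offsets) + 1, dtype=float)
        np.add.at(diff, s, 1.0)
        np.add.at(diff, e, -1.0)
        values[(sample, strand)] += np.cumsum(diff[:-1])

    return NucleotideProfile(
        offsets=offsets, values=values, mode=COVERAGE,
        normalisation=RAW, window_bp=W, keyed_by="sample",
    )


def start_site_profile(
    classified: pd.DataFrame,
    model: GenomeModel,
    sheet: SampleSheet,
    window_bp: int | None = None,
    classes: tuple[str, ...] = DEFAULT_CLASSES,
) -> NucleotideProfile:
    """Per-position counts of strand-aware fragment 5' ends.

    The 5' end of a '+' fragment is its leftmost base, of a '-' fragment
    its rightmost.  Raw mass equals the number of profiled fragments whose
    5' end lies inside the profiled window.
    """
    _check_geometry(model, window_bp)
    W = model.window_bp
    offsets = np.arange(-W, model.max_core_width + W)
    sub = _prepare(classified, classes)
    values = _empty_values(sheet.samples, offsets)

    for (sample, strand, chrom), grp in sub.groupby(
        ["sample", "strand", "chrom"], observed=True
    ):
        if chrom not in model.cores:
            continue
        lo, hi, anchor = _window_bounds(model, chrom)
        five = np.where(
            grp["strand"].to_numpy() == "+",
            grp["start"].to_numpy(),
            grp["end"].to_numpy() - 1,
        )
        keep = (five >= lo) & (five < hi)
        idx = five[keep] - anchor + W
        np.add.at(values[(sample, strand)], idx, 1.0)

    return NucleotideProfile(
        offsets=offsets, values=values, mode=START_SITES,
        normalisation=RAW, window_bp=W, keyed_by="sample",
    )


def cpm_normalise(
    profile: NucleotideProfile, sheet: SampleSheet, agg: str = "sum"
) -> NucleotideProfile:
    """CPM-normalise a RAW per-sample profile and aggregate per condition.

    Each sample's counts are scaled by 1e6 / total mapped fragments of that
    sample, then combined over the condition's replicates (``agg``: "sum",
    the tally default, or "mean", the figure-style rendering).  Normalising
    an already-CPM profile is an error.
    """
    if profile.normalisation != RAW or profile.keyed_by != "sample":
        raise ProfileError("cpm_normalise expects a RAW, sample-keyed profile")
    if agg not in ("sum", "mean"):
        raise ProfileError(f"unknown aggregation {agg!r}")
    values: dict[tuple[str, str], np.ndarray] = {}
    for condition in sheet.conditions:
        samples = sheet.samples_of(condition)
        for strand in ("+", "-"):
            acc = np.zeros(len(profile.offsets), dtype=float)
            for sample in samples:
                total = sheet.total_of(sample)
                if total == 0:
                    raise ProfileError(f"sample {sample!r} has total_fragments == 0")
                acc += profile.key_array(sample, strand) * (1e6 / total)
            if agg == "mean" and samples:
                acc /= len(samples)
            values[(condition, strand)] = acc
    return NucleotideProfile(
        offsets=profile.offsets, values=values, mode=profile.mode,
        normalisation=CPM, window_bp=profile.window_bp, keyed_by="condition",
    )


def aggregate_conditions(
    profile: NucleotideProfile, sheet: SampleSheet, agg: str = "sum"
) -> NucleotideProfile:
    """Aggregate a RAW per-sample profile to condition level without scaling."""
    if profile.keyed_by != "sample":
        raise ProfileError("expected a sample-keyed profile")
    values: dict[tuple[str, str], np.ndarray] = {}
    for condition in sheet.conditions:
        samples = sheet.samples_of(condition)
        for strand in ("+", "-"):
            acc = np.zeros(len(profile.offsets), dtype=float)
            for sample in samples:
                acc += profile.key_array(sample, strand)
            if agg == "mean" and samples:
                acc /= len(samples)
            values[(condition, strand)] = acc
    return replace(profile, values=values, keyed_by="condition")


def start_site_count(
    classified: pd.DataFrame, region: tuple[str, int, int]
) -> tuple[int, int]:
    """(distinct start positions, total 5' ends) within a genomic region.

    Counts strand-aware fragment 5' ends falling in ``region`` =
    (chrom, start, end), half-open.  Distinct positions are counted per
    strand (the same coordinate on opposite strands is two sites).
    """
    chrom, lo, hi = region
    sub = classified[classified["chrom"] == chrom]
    if sub.empty:
        return 0, 0
    five = np.where(
        sub["strand"].to_numpy() == "+",
        sub["start"].to_numpy(),
        sub["end"].to_numpy() - 1,
    )
    keep = (five >= lo) & (five < hi)
    if not keep.any():
        return 0, 0
    strands = sub["strand"].to_numpy()[keep]
    sites = set(zip(five[keep].tolist(), strands.tolist()))
    return len(sites), int(keep.sum())


def profile_table(*profiles: NucleotideProfile) -> pd.DataFrame:
    """Tidy export: one row per (offset, strand, key) with a column per profile.

    Profiles must share offsets; column names are ``{mode}_{normalisation}``
    lower-cased (e.g. coverage_raw, start_sites_cpm).
    """
    if not profiles:
        raise ProfileError("no profiles given")
    base = profiles[0]
    rows: dict[tuple, dict] = {}
    for prof in profiles:
        if len(prof.offsets) != len(base.offsets) or (prof.offsets != base.offsets).any():
            raise ProfileError("profiles have mismatched offset grids")
        col = f"{prof.mode}_{prof.normalisation}".lower()
        for (key, strand), arr in sorted(prof.values.items()):
            for off, v in zip(prof.offsets.tolist(), arr.tolist()):
                rows.setdefault((off, strand, key), {})[col] = v
    out = pd.DataFrame(
        [
            {"offset": off, "strand": strand, "key": key, **cols}
            for (off, strand, key), cols in sorted(rows.items())
        ]
    )
    return out
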