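"""Genomic geometry for (peri)centromere transcript analysis.

The classification of sequenced fragments into centromeric (cenRNA) and
pericentromeric (pericenRNA) classes depends on a small, rigid geometry:
each chromosome carries exactly one point-centromere core (CEN, ~117 bp),
partitioned left-to-right on the reference strand into the three centromere
DNA elements CDEI / CDEII / CDEIII, and flanked by a pericentromeric window
of ``window_bp`` (default 500) on each side.  This module loads that
geometry from plain-text annotation (chromosome sizes + BED intervals),
validates it, and exposes it as an immutable :class:`GenomeModel`.

All coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "CenCore",
    "PericenWindow",
    "OrfFeature",
    "GenomeModel",
    "GenomeModelError",
    "derive_cde_layout",
    "load_genome_model",
    "write_genome_model",
]

#: width band (inclusive) a CEN core must fall into; the point centromere
#: is 117 +/- 2 bp, validated with 2 bp of slack on either side by default.
DEFAULT_CORE_WIDTH_BAND = (113, 121)
DEFAULT_WINDOW_BP = 500
DEFAULT_CDE1_LEN = 8
DEFAULT_CDE3_LEN = 25

Interval = tuple[int, int]


class GenomeModelError(ValueError):
    """Raised when annotation violates the point-centromere geometry."""


def derive_cde_layout(
    start: int,
    end: int,
    cde1_len: int = DEFAULT_CDE1_LEN,
    cde3_len: int = DEFAULT_CDE3_LEN,
) -> tuple[Interval, Interval, Interval]:
    """Partition a CEN core into (CDEI, CDEII, CDEIII) sub-intervals.

    CDEI is the first ``cde1_len`` bp, CDEIII the last ``cde3_len`` bp, and
    CDEII the remainder, measured left-to-right on the reference strand.
    The partition is exact: the three intervals tile ``[start, end)``.

    Raises
    ------
    GenomeModelError
        If the core is too short to leave at least 1 bp for CDEII.
    """
    width = end - start
    if width < cde1_len + cde3_len + 1:
        raise GenomeModelError(
            f"CEN core [{start},{end}) of width {width} bp cannot hold "
            f"CDEI ({cde1_len} bp) + CDEIII ({cde3_len} bp) + >=1 bp CDEII"
        )
    cde1 = (start, start + cde1_len)
    cde3 = (end - cde3_len, end)
    cde2 = (cde1[1], cde3[0])
    return cde1, cde2, cde3


@dataclass(frozen=True)
class CenCore:
    """One point-centromere core with its CDE partition."""

    chrom: str
    start: int
    end: int
    cde1: Interval
    cde2: Interval
    cde3: Interval

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def elements(self) -> tuple[Interval, Interval, Interval]:
        return self.cde1, self.cde2, self.cde3

    def validate(self, chrom_length: int, width_band: Interval) -> None:
        if not (0 <= self.start < self.end <= chrom_length):
            raise GenomeModelError(
                f"CEN core [{self.start},{self.end}) outside chromosome "
                f"{self.chrom} of length {chrom_length}"
            )
        lo, hi = width_band
        if not (lo <= self.width <= hi):
            raise GenomeModelError(
                f"CEN core on {self.chrom} has width {self.width} bp, "
                f"outside the allowed band [{lo},{hi}]"
            )
        c1, c2, c3 = self.cde1, self.cde2, self.cde3
        ok = (
            c1[0] == self.start
            and c1[1] == c2[0]
            and c2[1] == c3[0]
            and c3[1] == self.end
            and c1[0] < c1[1] < c2[1] < c3[1]
        )
        if not ok:
            raise GenomeModelError(
                f"CDE sub-intervals {c1},{c2},{c3} do not tile the core "
                f"[{self.start},{self.end}) on {self.chrom}"
            )


@dataclass(frozen=True)
class PericenWindow:
    """The two pericentromeric flanks of one core, clipped at chromosome ends."""

    chrom: str
    up: Interval      # [core.start - W, core.start), clipped at 0
    down: Interval    # [core.end, core.end + W), clipped at chromosome length
    width: int        # the nominal (unclipped) W

    @property
    def span(self) -> Interval:
        """Full [up.start, down.end) extent: windows plus the core between them."""
        return (self.up[0], self.down[1])


@dataclass(frozen=True)
class OrfFeature:
    """A protein-coding feature; only those intersecting a pericen window matter."""

    chrom: str
    start: int
    end: int
    strand: str
    id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise GenomeModelError(f"ORF {self.id}: start {self.start} >= end {self.end}")
        if self.strand not in ("+", "-"):
            raise GenomeModelError(f"ORF {self.id}: invalid strand {self.strand!r}")


def _overlaps(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


@dataclass(frozen=True)
class GenomeModel:
    """Validated chromosome / CEN-core / pericen-window / ORF geometry.

    ``chromosomes`` maps name -> length; ``cores`` and ``windows`` are keyed
    by chromosome (exactly one core per chromosome); ``orfs`` is the full
    feature list, of which :meth:`pericen_orfs` returns the subset that
    intersects a pericentromeric window (the only ones used downstream).
    """

    chromosomes: dict[str, int]
    cores: dict[str, CenCore]
    windows: dict[str, PericenWindow]
    orfs: tuple[OrfFeature, ...]
    window_bp: int = DEFAULT_WINDOW_BP
    core_width_band: Interval = DEFAULT_CORE_WIDTH_BAND

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise GenomeModelError("empty chromosome set")
        for name, length in self.chromosomes.items():
            if length <= 0:
                raise GenomeModelError(f"chromosome {name} has non-positive length")
        for chrom, core in self.cores.items():
            if chrom not in self.chromosomes:
                raise GenomeModelError(f"CEN core on unknown chromosome {chrom}")
            core.validate(self.chromosomes[chrom], self.core_width_band)
            win = self.windows.get(chrom)
            if win is None:
                raise GenomeModelError(f"no pericen window for core on {chrom}")
            if win.up[1] != core.start or win.down[0] != core.end:
                raise GenomeModelError(
                    f"pericen window on {chrom} not anchored to its core"
                )
        for orf in self.orfs:
            if orf.chrom not in self.chromosomes:
                raise GenomeModelError(f"ORF {orf.id} on unknown chromosome {orf.chrom}")

    def pericen_orfs(self, chrom: str | None = None) -> tuple[OrfFeature, ...]:
        """ORFs residing entirely or partially within a pericen window."""
        out = []
        for orf in self.orfs:
            win = self.windows.get(orf.chrom)
            if win is None:
                continue
            if _overlaps((orf.start, orf.end), win.up) or _overlaps(
                (orf.start, orf.end), win.down
            ):
                if chrom is None or orf.chrom == chrom:
                    out.append(orf)
        return tuple(out)

    @property
    def max_core_width(self) -> int:
        return max(c.width for c in self.cores.values())


def _make_window(core: CenCore, window_bp: int, chrom_length: int) -> PericenWindow:
    up = (max(0, core.start - window_bp), core.start)
    down = (core.end, min(chrom_length, core.end + window_bp))
    return PericenWindow(chrom=core.chrom, up=up, down=down, width=window_bp)


def build_genome_model(
    chromosomes: dict[str, int],
    cen_intervals: dict[str, Interval],
    orfs: list[OrfFeature] | tuple[OrfFeature, ...] = (),
    cde_intervals: dict[str, tuple[Interval, Interval, Interval]] | None = None,
    window_bp: int = DEFAULT_WINDOW_BP,
    cde1_len: int = DEFAULT_CDE1_LEN,
    cde3_len: int = DEFAULT_CDE3_LEN,
    core_width_band: Interval = DEFAULT_CORE_WIDTH_BAND,
) -> GenomeModel:
    """Assemble a GenomeModel from in-memory pieces (the loaders call this)."""
    if window_bp <= 0:
        raise GenomeModelError(f"window_bp must be positive, got {window_bp}")
    cores: dict[str, CenCore] = {}
    windows: dict[str, PericenWindow] = {}
    for chrom, (start, end) in cen_intervals.items():
        if chrom not in chromosomes:
            raise GenomeModelError(f"CEN core on unknown chromosome {chrom}")
        if cde_intervals is not None and chrom in cde_intervals:
            cde1, cde2, cde3 = cde_intervals[chrom]
        else:
            cde1, cde2, cde3 = derive_cde_layout(start, end, cde1_len, cde3_len)
        core = CenCore(chrom=chrom, start=start, end=end, cde1=cde1, cde2=cde2, cde3=cde3)
        cores[chrom] = core
        windows[chrom] = _make_window(core, window_bp, chromosomes[chrom])
    kept: list[OrfFeature] = []
    for orf in orfs:
        if orf.chrom not in cores:
            warnings.warn(
                f"ORF {orf.id} on chromosome {orf.chrom} without a CEN core; kept",
                stacklevel=2,
            )
        kept.append(orf)
    return GenomeModel(
        chromosomes=dict(chromosomes),
        cores=cores,
        windows=windows,
        orfs=tuple(kept),
        window_bp=window_bp,
        core_width_band=tuple(core_width_band),
    )


# ---------------------------------------------------------------------------
# plain-text I/O


def _read_bed(path: str | Path, min_cols: int) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        dtype={0: str},
        names=["chrom", "start", "end", "name", "score", "strand"][: max(min_cols, 6)],
        usecols=range(6),
        engine="python",
    )
    if df.shape[0] and df["start"].isna().any():
        raise GenomeModelError(f"{path}: malformed BED (missing start/end fields)")
    return df


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], dtype={0: str})
    if df["chrom"].duplicated().any():
        dupes = df.loc[df["chrom"].duplicated(), "chrom"].tolist()
        raise GenomeModelError(f"duplicate chromosome names in sizes file: {dupes}")
    return dict(zip(df["chrom"], df["length"].astype(int)))


def load_genome_model(
    chrom_sizes: str | Path,
    cen_bed: str | Path,
    orf_bed: str | Path | None = None,
    cde_bed: str | Path | None = None,
    window_bp: int = DEFAULT_WINDOW_BP,
    cde1_len: int = DEFAULT_CDE1_LEN,
    cde3_len: int = DEFAULT_CDE3_LEN,
    core_width_band: Interval = DEFAULT_CORE_WIDTH_BAND,
) -> GenomeModel:
    """Load a GenomeModel from plain-text annotation files.

    Parameters
    ----------
    chrom_sizes : two-column tab-separated file (name, length).
    cen_bed : BED3+ with at most one CEN core record per chromosome.
    orf_bed : optional BED6 of protein-coding features (strand required).
    cde_bed : optional BED with named records ``CDEI``/``CDEII``/``CDEIII``
        per chromosome; when absent the canonical 8 / remainder / 25 bp
        layout is derived.
    """
    chroms = read_chrom_sizes(chrom_sizes)

    cen = pd.read_csv(
        cen_bed, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end"], usecols=[0, 1, 2], dtype={0: str},
    )
    if cen["chrom"].duplicated().any():
        dupes = sorted(cen.loc[cen["chrom"].duplicated(), "chrom"].unique())
        raise GenomeModelError(f"more than one CEN record on chromosome(s): {dupes}")
    cen_intervals = {
        r.chrom: (int(r.start), int(r.end)) for r in cen.itertuples(index=False)
    }

    cde_intervals = None
    if cde_bed is not None:
        cde = pd.read_csv(
            cde_bed, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "name"], usecols=[0, 1, 2, 3], dtype={0: str},
        )
        cde_intervals = {}
        for chrom, grp in cde.groupby("chrom", sort=False):
            by_name = {r.name: (int(r.start), int(r.end)) for r in grp.itertuples(index=False)}
            missing = {"CDEI", "CDEII", "CDEIII"} - set(by_name)
            if missing:
                raise GenomeModelError(f"{cde_bed}: {chrom} missing CDE record(s) {sorted(missing)}")
            cde_intervals[str(chrom)] = (by_name["CDEI"], by_name["CDEII"], by_name["CDEIII"])

    orfs: list[OrfFeature] = []
    if orf_bed is not None:
        odf = pd.read_csv(
            orf_bed, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "name", "score", "strand"],
            dtype={0: str, 3: str, 5: str},
        )
        for i, r in enumerate(odf.itertuples(index=False)):
            orfs.append(
                OrfFeature(
                    chrom=str(r.chrom), start=int(r.start), end=int(r.end),
                    strand=str(r.strand), id=str(r.name),
                )
            )

    return build_genome_model(
        chroms, cen_intervals, orfs, cde_intervals,
        window_bp=window_bp, cde1_len=cde1_len, cde3_len=cde3_len,
        core_width_band=core_width_band,
    )


def write_genome_model(model: GenomeModel, outdir: str | Path) -> dict[str, Path]:
    """Write the model back to (chrom.sizes, cen.bed, cde.bed, orfs.bed).

    Round-trips: reloading the written files yields an identical model.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "chrom_sizes": outdir / "chrom.sizes",
        "cen_bed": outdir / "cen.bed",
        "cde_bed": outdir / "cde.bed",
        "orf_bed": outdir / "orfs.bed",
    }
    with open(paths["chrom_sizes"], "w") as fh:
        for name, length in model.chromosomes.items():
            fh.write(f"{name}\t{length}\n")
    with open(paths["cen_bed"], "w") as fh:
        for chrom in model.chromosomes:
            core = model.cores.get(chrom)
            if core is not None:
                fh.write(f"{chrom}\t{core.start}\t{core.end}\n")
    with open(paths["cde_bed"], "w") as fh:
        for chrom in model.chromosomes:
            core = model.cores.get(chrom)
            if core is None:
                continue
            for name, (s, e) in zip(("CDEI", "CDEII", "CDEIII"), core.elements):
                fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")
    with open(paths["orf_bed"], "w") as fh:
        for orf in model.orfs:
            fh.write(f"{orf.chrom}\t{orf.start}\t{orf.end}\t{orf.id}\t0\t{orf.strand}\n")
    return paths
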