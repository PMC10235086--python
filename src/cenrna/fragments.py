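"""Strand-aware fragment records and their BED6 / SAM plumbing.

A *fragment* is the full genomic span of one sequenced cDNA read pair
(leftmost to rightmost aligned base of either mate); its width is the
fragment "length".  In intronless (peri)centromeric regions this span is
the transcript extent the pair was sequenced from, which is why read-pair
lengths of several kb are meaningful.  Fragments flow through the pipeline
either as scalar :class:`FragmentRecord` objects or, for bulk work, as a
pandas DataFrame with the BED6-derived columns
``chrom,start,end,name,score,strand,sample`` (:func:`read_fragments_frame`).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
import pyarrow as pa
import pyarrow.csv as pacsv

__all__ = [
    "FragmentRecord",
    "SampleSheet",
    "FragmentInputError",
    "read_fragments_bed",
    "read_fragments_frame",
    "write_fragments_bed",
    "write_fragments_frame",
    "fragments_from_sam",
    "frame_from_records",
]

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
FRAME_COLUMNS = BED6_COLUMNS + ["sample"]


class FragmentInputError(ValueError):
    """Malformed fragment input (BED line, SAM pairing, sample sheet)."""


@dataclass(frozen=True)
class FragmentRecord:
    """One strand-aware genomic interval for a sequenced cDNA fragment."""

    chrom: str
    start: int
    end: int
    strand: str
    sample: str | None = None
    name: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FragmentInputError(
                f"fragment {self.name}: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise FragmentInputError(
                f"fragment {self.name}: strand must be '+' or '-', got {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Position of the transcript 5' end: leftmost base on '+', rightmost on '-'."""
        return self.start if self.strand == "+" else self.end - 1


# ---------------------------------------------------------------------------
# sample sheet


class SampleSheet:
    """Maps samples to (condition, replicate) and to their CPM denominator.

    ``total_fragments`` is the number of *all* mapped fragments in the
    sample (library depth), not the number of (peri)cen fragments, and is
    the denominator of every CPM value downstream.
    """

    COLUMNS = ["sample", "condition", "replicate", "total_fragments"]

    def __init__(self, frame: pd.DataFrame) -> None:
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise FragmentInputError(f"sample sheet missing column(s) {sorted(missing)}")
        frame = frame[self.COLUMNS].copy()
        frame["replicate"] = frame["replicate"].astype(int)
        frame["total_fragments"] = frame["total_fragments"].astype(int)
        if frame["sample"].duplicated().any():
            raise FragmentInputError("duplicate sample identifiers in sample sheet")
        if frame.duplicated(subset=["condition", "replicate"]).any():
            raise FragmentInputError("duplicate (condition, replicate) pair in sample sheet")
        if (frame["total_fragments"] < 0).any():
            raise FragmentInputError("negative total_fragments in sample sheet")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample": str, "condition": str}))

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @property
    def samples(self) -> list[str]:
        return list(self.frame["sample"])

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.frame["condition"]))

    def condition_of(self, sample: str) -> str:
        row = self.frame.loc[self.frame["sample"] == sample]
        if row.empty:
            raise FragmentInputError(f"unknown sample {sample!r}")
        return str(row["condition"].iloc[0])

    def total_of(self, sample: str) -> int:
        row = self.frame.loc[self.frame["sample"] == sample]
        if row.empty:
            raise FragmentInputError(f"unknown sample {sample!r}")
        return int(row["total_fragments"].iloc[0])

    def samples_of(self, condition: str) -> list[str]:
        return list(self.frame.loc[self.frame["condition"] == condition, "sample"])


# ---------------------------------------------------------------------------
# BED6 I/O


def read_fragments_bed(path: str | Path, sample: str | None = None) -> Iterator[FragmentRecord]:
    """Stream FragmentRecords from a BED6 file, preserving order.

    The strand column is required; ``.`` is rejected because every
    downstream statistic (5' ends, strand splits) is strand-aware.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FragmentInputError(
                    f"{path}:{lineno}: expected >=6 tab-separated fields, got {len(fields)}"
                )
            chrom, start, end, name, _score, strand = fields[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FragmentInputError(f"{path}:{lineno}: non-integer coordinates") from exc
            if strand not in ("+", "-"):
                raise FragmentInputError(
                    f"{path}:{lineno}: strand must be '+' or '-', got {strand!r}"
                )
            try:
                yield FragmentRecord(
                    chrom=chrom, start=start_i, end=end_i, strand=strand,
                    sample=sample, name=name,
                )
            except FragmentInputError as exc:
                raise FragmentInputError(f"{path}:{lineno}: {exc}") from exc


def read_fragments_frame(path: str | Path, sample: str | None = None) -> pd.DataFrame:
    """Bulk BED6 reader returning the pipeline's fragment DataFrame."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", names=BED6_COLUMNS,
        dtype={"chrom": str, "name": str, "strand": str},
    )
    if df.empty:
        df = pd.DataFrame(
            {
                "chrom": pd.Series(dtype=str),
                "start": pd.Series(dtype=int),
                "end": pd.Series(dtype=int),
                "name": pd.Series(dtype=str),
                "score": pd.Series(dtype=int),
                "strand": pd.Series(dtype=str),
            }
        )
    else:
        bad = ~df["strand"].isin(["+", "-"])
        if bad.any():
            raise FragmentInputError(
                f"{path}: {int(bad.sum())} record(s) without a '+'/'-' strand"
            )
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        if (df["start"] >= df["end"]).any():
            raise FragmentInputError(f"{path}: record(s) with start >= end")
    df["sample"] = sample
    return df


def write_fragments_bed(
    fragments: Iterable[FragmentRecord], path: str | Path
) -> None:
    """Write records as BED6 (score 0); round-trips through read_fragments_bed."""
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.name}\t0\t{f.strand}\n")


def write_fragments_frame(frame: pd.DataFrame, path: str | Path) -> None:
    """Fast BED6 writer for the bulk fragment DataFrame (arrow CSV backend)."""
    out = frame[BED6_COLUMNS] if "sample" in frame.columns else frame
    table = pa.Table.from_pandas(out.reset_index(drop=True), preserve_index=False)
    pacsv.write_csv(
        table,
        str(path),
        write_options=pacsv.WriteOptions(
            include_header=False, delimiter="\t", quoting_style="none"
        ),
    )


def frame_from_records(records: Iterable[FragmentRecord]) -> pd.DataFrame:
    rows = [
        (f.chrom, f.start, f.end, f.name, 0, f.strand, f.sample) for f in records
    ]
    return pd.DataFrame(rows, columns=FRAME_COLUMNS)


# ---------------------------------------------------------------------------
# SAM / BAM input


def fragments_from_sam(
    path: str | Path,
    sample: str | None = None,
    library: str = "fr-firststrand",
) -> tuple[list[FragmentRecord], dict[str, int]]:
    """Derive fragment spans from paired-end alignments.

    Per properly paired (primary, mapped, same-chromosome) read pair, emits
    one FragmentRecord spanning the leftmost to rightmost aligned base of
    either mate.  Transcript strand follows the library protocol:

    - ``fr-firststrand`` (dUTP, the default): read 2 carries the transcript
      sense, so a pair whose read 1 aligns to '-' is a '+' fragment.
    - ``fr-secondstrand``: read 1 carries the sense.

    Pairs failing the preconditions are counted and skipped; the skip
    tallies are returned alongside the records.  The result is a pure
    function of the alignment multiset (record order does not matter).
    """
    import pysam

    if library not in ("fr-firststrand", "fr-secondstrand"):
        raise FragmentInputError(f"unknown library protocol {library!r}")

    skipped = {"unpaired": 0, "secondary": 0, "unmapped": 0, "different_chrom": 0,
               "mate_missing": 0}
    pending: dict[str, "pysam.AlignedSegment"] = {}
    records: list[FragmentRecord] = []

    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as af:
        for aln in af.fetch(until_eof=True):
            if not aln.is_paired:
                skipped["unpaired"] += 1
                continue
            if aln.is_secondary or aln.is_supplementary:
                skipped["secondary"] += 1
                continue
            if aln.is_unmapped or aln.mate_is_unmapped:
                skipped["unmapped"] += 1
                continue
            if aln.reference_id != aln.next_reference_id:
                # count each pair once, on its first-seen mate
                if aln.query_name not in pending:
                    pending[aln.query_name] = None  # type: ignore[assignment]
                    skipped["different_chrom"] += 1
                else:
                    pending.pop(aln.query_name)
                continue
            if aln.query_name not in pending:
                pending[aln.query_name] = aln
                continue
            mate = pending.pop(aln.query_name)
            if mate is None:  # partner of a cross-chromosome pair
                continue
            r1, r2 = (aln, mate) if aln.is_read1 else (mate, aln)
            start = min(r1.reference_start, r2.reference_start)
            end = max(r1.reference_end, r2.reference_end)
            if library == "fr-firststrand":
                strand = "+" if r1.is_reverse else "-"
            else:
                strand = "-" if r1.is_reverse else "+"
            records.append(
                FragmentRecord(
                    chrom=r1.reference_name, start=start, end=end,
                    strand=strand, sample=sample, name=r1.query_name,
                )
            )
    # mates never seen a second time
    skipped["mate_missing"] += sum(1 for v in pending.values() if v is not None)
    # order independence: emit a canonically sorted list
    records.sort(key=lambda f: (f.chrom, f.start, f.end, f.strand, f.name))
    return records, skipped
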