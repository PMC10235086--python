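"""Headline numbers: folds, class ratios, absolute abundance, ddCq.

Counts from the class tallies are turned into the condition-comparison
statistics the analysis reports: fold changes between auxin (Rio1-depleted)
and mock conditions per transcript class, the noncoding-pericen : cen ratio
per condition, molecules-per-cell calibration against reference genes of
known mRNA copy number, and 2^-ddCq relative quantification for qPCR
measurements.

All ratios are computed at full precision and *displayed* at two
significant figures (e.g. 16,369/42 = 389.7 prints as 390), which is the
rounding that reconciles every printed value; machine output always keeps
full precision alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import CEN, PERICEN_CODING, PERICEN_NONCODING, TALLY_KEYS
from .fragments import SampleSheet

__all__ = [
    "round_sig",
    "FoldRatio",
    "fold_ratio",
    "abundance_table",
    "class_ratio_report",
    "ReferenceGene",
    "MoleculesEstimate",
    "molecules_per_cell",
    "QpcrMeasurement",
    "DdcqResult",
    "ddcq_fold",
    "read_reference_genes",
]

DISPLAY_SIG_FIGS = 2


class QuantifyError(ValueError):
    pass


def round_sig(x: float, sig: int = DISPLAY_SIG_FIGS) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


@dataclass(frozen=True)
class FoldRatio:
    value: float      # exact quotient
    display: float    # rounded to 2 significant figures

    def __float__(self) -> float:
        return self.value


def fold_ratio(numerator: float, denominator: float, sig: int = DISPLAY_SIG_FIGS) -> FoldRatio:
    """Exact quotient with a 2-significant-figure display value."""
    if denominator == 0:
        raise QuantifyError("fold_ratio: zero denominator")
    value = numerator / denominator
    return FoldRatio(value=value, display=round_sig(value, sig))


# ---------------------------------------------------------------------------
# abundance table and ratio report


def abundance_table(tally_frame: pd.DataFrame, sheet: SampleSheet) -> pd.DataFrame:
    """Sum tallies to (condition, tclass, length_class) counts.

    The length_class split is kept only for CEN fragments (SHORT/LONG);
    the class-level total is the row with length_class == 'ALL'.
    """
    missing = set(TALLY_KEYS + ["count"]) - set(tally_frame.columns)
    if missing:
        raise QuantifyError(f"tally frame missing column(s) {sorted(missing)}")
    t = tally_frame.merge(
        sheet.frame[["sample", "condition"]], on="sample", how="left"
    )
    if t["condition"].isna().any():
        raise QuantifyError("tally contains samples absent from the sheet")
    total = (
        t.groupby(["condition", "tclass"], observed=True)["count"].sum().reset_index()
    )
    total["length_class"] = "ALL"
    split = (
        t[t["length_class"].isin(["SHORT", "LONG"])]
        .groupby(["condition", "tclass", "length_class"], observed=True)["count"]
        .sum()
        .reset_index()
    )
    out = pd.concat([total, split], ignore_index=True)
    return out[["condition", "tclass", "length_class", "count"]].sort_values(
        ["condition", "tclass", "length_class"]
    ).reset_index(drop=True)


def _lookup(ab: pd.DataFrame, condition: str, tclass: str, length_class: str = "ALL") -> int | None:
    row = ab[
        (ab["condition"] == condition)
        & (ab["tclass"] == tclass)
        & (ab["length_class"] == length_class)
    ]
    return int(row["count"].iloc[0]) if len(row) else None


def class_ratio_report(
    ab: pd.DataFrame,
    mock: str = "mock",
    auxin: str = "auxin",
) -> pd.DataFrame:
    """Per-condition class ratios and between-condition folds.

    Rows (where the needed counts exist; missing classes are skipped with a
    warning): noncoding-pericen:cen ratio per condition, coding:noncoding
    pericen ratio per condition, auxin/mock fold per class (with SHORT/LONG
    cen sub-rows), and the relative change of the pericen:cen ratio.
    Columns: metric, condition, numerator, denominator, value, display.
    """
    import warnings

    rows: list[dict] = []

    def emit(metric: str, condition: str, num: int | None, den: int | None) -> None:
        if num is None or den is None or den == 0:
            warnings.warn(
                f"{metric} ({condition}): missing or zero counts, row omitted",
                stacklevel=3,
            )
            return
        fr = fold_ratio(num, den)
        rows.append(
            {
                "metric": metric, "condition": condition,
                "numerator": num, "denominator": den,
                "value": fr.value, "display": fr.display,
            }
        )

    conditions = list(dict.fromkeys(ab["condition"]))
    for cond in conditions:
        emit(
            "pericen_noncoding_to_cen_ratio", cond,
            _lookup(ab, cond, PERICEN_NONCODING), _lookup(ab, cond, CEN),
        )
        emit(
            "pericen_coding_to_noncoding_ratio", cond,
            _lookup(ab, cond, PERICEN_CODING), _lookup(ab, cond, PERICEN_NONCODING),
        )
    if mock in conditions and auxin in conditions:
        for tclass in (CEN, PERICEN_NONCODING, PERICEN_CODING):
            emit(
                f"{tclass.lower()}_fold_auxin_over_mock", f"{auxin}/{mock}",
                _lookup(ab, auxin, tclass), _lookup(ab, mock, tclass),
            )
        for lclass in ("SHORT", "LONG"):
            emit(
                f"cen_{lclass.lower()}_fold_auxin_over_mock", f"{auxin}/{mock}",
                _lookup(ab, auxin, CEN, lclass), _lookup(ab, mock, CEN, lclass),
            )
        pn_m, c_m = _lookup(ab, mock, PERICEN_NONCODING), _lookup(ab, mock, CEN)
        pn_a, c_a = _lookup(ab, auxin, PERICEN_NONCODING), _lookup(ab, auxin, CEN)
        if None not in (pn_m, c_m, pn_a, c_a) and c_m and c_a and pn_m:
            fr = fold_ratio(pn_a / c_a, pn_m / c_m)
            rows.append(
                {
                    "metric": "pericen_to_cen_ratio_change", "condition": f"{auxin}/{mock}",
                    "numerator": pn_a / c_a, "denominator": pn_m / c_m,
                    "value": fr.value, "display": fr.display,
                }
            )
    return pd.DataFrame(
        rows, columns=["metric", "condition", "numerator", "denominator", "value", "display"]
    )


# ---------------------------------------------------------------------------
# molecules-per-cell calibration


@dataclass(frozen=True)
class ReferenceGene:
    """A gene of known absolute expression used to calibrate read counts."""

    id: str
    chrom: str
    start: int
    end: int
    copies_per_cell: float

    def __post_init__(self) -> None:
        if self.copies_per_cell <= 0:
            raise QuantifyError(f"reference {self.id}: copies_per_cell must be > 0")
        if self.start >= self.end:
            raise QuantifyError(f"reference {self.id}: start >= end")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MoleculesEstimate:
    value: float
    sem: float
    per_reference: tuple[float, ...]  # estimate implied by each reference alone


def molecules_per_cell(
    target_count: float,
    target_length: int,
    refs: list[tuple[ReferenceGene, int]],
    normalise_by_length: bool = True,
) -> MoleculesEstimate:
    """Absolute abundance (molecules per cell) of a target feature.

    Each reference i with ``count_i`` reads over ``length_i`` bp and
    ``copies_per_cell_i`` known molecules yields a calibration factor
    k_i = (count_i / length_i) / copies_per_cell_i — length-density-
    normalised reads per molecule per cell.  The estimate is
    (target_count / target_length) / mean(k_i); its SEM is propagated
    from the spread of the k_i across references.  The estimate is
    invariant under a common library-depth factor on every count.
    """
    if not refs:
        raise QuantifyError("molecules_per_cell: no reference genes")
    ks = []
    for ref, count in refs:
        if count < 0:
            raise QuantifyError(f"reference {ref.id}: negative count")
        dens = count / ref.length if normalise_by_length else float(count)
        ks.append(dens / ref.copies_per_cell)
    ks_arr = np.asarray(ks, dtype=float)
    if (ks_arr == 0).all():
        raise QuantifyError("molecules_per_cell: all reference counts are zero")
    k_mean = ks_arr.mean()
    target_dens = target_count / target_length if normalise_by_length else float(target_count)
    value = target_dens / k_mean
    if len(ks_arr) > 1:
        sem_k = ks_arr.std(ddof=1) / math.sqrt(len(ks_arr))
        sem = value * sem_k / k_mean  # first-order propagation through 1/mean(k)
    else:
        sem = float("nan")
    per_ref = tuple(target_dens / k if k > 0 else float("inf") for k in ks_arr)
    return MoleculesEstimate(value=value, sem=sem, per_reference=per_ref)


def read_reference_genes(path: str | Path) -> list[ReferenceGene]:
    """Tab-separated (id, chrom, start, end, copies_per_cell[, count])."""
    df = pd.read_csv(path, sep="\t")
    needed = {"id", "chrom", "start", "end", "copies_per_cell"}
    if not needed <= set(df.columns):
        raise QuantifyError(f"reference table missing column(s) {sorted(needed - set(df.columns))}")
    return [
        ReferenceGene(
            id=str(r.id), chrom=str(r.chrom), start=int(r.start), end=int(r.end),
            copies_per_cell=float(r.copies_per_cell),
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# ddCq relative quantification


@dataclass(frozen=True)
class QpcrMeasurement:
    """Cq quadruple for one target: target & reference genes, treated & control arms."""

    target: str
    cq_target_treated: float
    cq_reference_treated: float
    cq_target_control: float
    cq_reference_control: float
    validation_band: tuple[float, float] = (10.0, 40.0)

    def __post_init__(self) -> None:
        for name in (
            "cq_target_treated", "cq_reference_treated",
            "cq_target_control", "cq_reference_control",
        ):
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                raise QuantifyError(f"{self.target}: missing/non-finite {name}")
            lo, hi = self.validation_band
            if not (lo <= v <= hi):
                raise QuantifyError(
                    f"{self.target}: {name}={v} outside validation band [{lo},{hi}]"
                )


@dataclass(frozen=True)
class DdcqResult:
    ddcq: float
    fold: float       # 2 ** -ddCq
    log2_fold: float  # == -ddCq


def ddcq_fold(m: QpcrMeasurement) -> DdcqResult:
    """Comparative-Cq relative quantification: fold = 2^-ddCq.

    dCq = Cq_target - Cq_reference per arm; ddCq = dCq_treated - dCq_control.
    One cycle fewer to threshold (ddCq = -1) doubles relative expression.
    """
    dcq_treated = m.cq_target_treated - m.cq_reference_treated
    dcq_control = m.cq_target_control - m.cq_reference_control
    ddcq = dcq_treated - dcq_control
    return DdcqResult(ddcq=ddcq, fold=2.0 ** (-ddcq), log2_fold=-ddcq)
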