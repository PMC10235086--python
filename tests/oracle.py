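"""Brute-force, set-based classification oracle for small geometries.

Independent of the production code path: intervals are materialised as
Python position sets and every rule is evaluated by literal membership,
so agreement with the vectorised classifier is a meaningful check.
"""

from __future__ import annotations

from cenrna.genome import GenomeModel


def oracle_classify(
    chrom: str, start: int, end: int, strand: str, model: GenomeModel,
    length_threshold: int = 1000,
) -> dict:
    core = model.cores[chrom]
    win = model.windows[chrom]
    pos = set(range(start, end))
    core_pos = set(range(core.start, core.end))
    up_pos = set(range(*win.up))
    down_pos = set(range(*win.down))
    elems = {
        name: set(range(s, e))
        for name, (s, e) in zip(("CDEI", "CDEII", "CDEIII"), core.elements)
    }

    touches_up = bool(pos & up_pos)
    touches_down = bool(pos & down_pos)
    side = (
        "BOTH" if touches_up and touches_down
        else "UP" if touches_up
        else "DOWN" if touches_down
        else "NONE"
    )

    out = {
        "tclass": "OTHER", "term_class": "NONE", "length_class": "NONE",
        "initiated_in_pericen": False, "side": side,
    }

    if pos & core_pos:
        out["tclass"] = "CEN"
        out["length_class"] = "SHORT" if (end - start) < length_threshold else "LONG"
        five = start if strand == "+" else end - 1
        out["initiated_in_pericen"] = five not in core_pos
        if core_pos <= pos:
            out["term_class"] = "FULL_CEN"
        else:
            boundaries = []  # (which, element) of fragment boundaries inside core
            if start in core_pos and start != core.start:
                boundaries.append(("start", next(n for n, p in elems.items() if start in p)))
            if (end - 1) in core_pos and end < core.end:
                boundaries.append(("end", next(n for n, p in elems.items() if (end - 1) in p)))
            assert boundaries, "non-covering core overlap must leave a boundary inside"
            if len(boundaries) == 2:
                three_prime = "end" if strand == "+" else "start"
                out["term_class"] = dict(boundaries)[three_prime]
            else:
                out["term_class"] = boundaries[0][1]
        return out

    if touches_up or touches_down:
        coding = False
        for orf in model.orfs:
            if orf.chrom != chrom:
                continue
            orf_pos = set(range(orf.start, orf.end))
            if (orf_pos & up_pos or orf_pos & down_pos) and pos & orf_pos:
                coding = True
        out["tclass"] = "PERICEN_CODING" if coding else "PERICEN_NONCODING"
        return out

    return out
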