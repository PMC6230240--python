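"""Target-site-duplication detection from 30 bp element flanks.

A TSD call is a pair of near-identical copies, 6-15 bp long with at most
one mismatching nucleotide, sitting as a suffix window of the left flank
and a prefix window of the right flank. Annotated element boundaries are
imprecise, so small offsets between the element boundary and each copy are
tolerated. The right flank is taken after skipping a terminal poly-A run
of the element (Can-SINE poly-A tails sit between the element body and the
right TSD copy); for minus-strand elements the corresponding poly-T run at
the genomic start is skipped instead.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import GenomeAssembly, RepeatAnnotation
import pandas as pd


@dataclass
class TSDCall:
    found: bool
    length: int = 0
    left_copy: str = ""
    right_copy: str = ""
    mismatches: int = 0
    left_offset: int = 0
    right_offset: int = 0
    beyond_band: bool = False       # true extent exceeded the search band
    reason: str = ""


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def find_tsd(left_flank: str, right_flank: str, min_len: int = 6,
             max_len: int = 15, max_mismatch: int = 1,
             max_offset: int = 5) -> TSDCall:
    """Scan for a target site duplication between the two element flanks.

    Candidate left copies are suffix windows of ``left_flank`` and right
    copies prefix windows of ``right_flank``, at offsets 0..``max_offset``
    from the element boundary. Lengths are scanned from ``max_len`` down to
    ``min_len``; at equal length an exact copy beats a one-mismatch copy,
    then smaller combined offsets win (left offset breaking remaining
    ties). A winning full-band match is extended outward while both copies
    stay identical, so the reported length is the true extent (flagged when
    it exceeds the band).
    """
    left_flank = left_flank.upper()
    right_flank = right_flank.upper()
    if not left_flank or not right_flank:
        return TSDCall(found=False, reason="empty flank")
    best = None  # (length, -mismatches, -(lo+ro), -lo, -ro) maximised
    for length in range(max_len, min_len - 1, -1):
        for lo in range(0, max_offset + 1):
            if lo + length > len(left_flank):
                continue
            lstart = len(left_flank) - lo - length
            lcopy = left_flank[lstart:lstart + length]
            for ro in range(0, max_offset + 1):
                if ro + length > len(right_flank):
                    continue
                rcopy = right_flank[ro:ro + length]
                mm = _hamming(lcopy, rcopy)
                if mm <= max_mismatch:
                    key = (length, -mm, -(lo + ro), -lo, -ro)
                    if best is None or key > best[0]:
                        best = (key, lcopy, rcopy, mm, lo, ro)
        if best is not None and best[0][0] == length:
            break  # no longer candidate can appear at shorter lengths
    if best is None:
        return TSDCall(found=False, reason="no window within mismatch budget")
    key, lcopy, rcopy, mm, lo, ro = best
    length = key[0]

    # extend to the true extent: the front of both copies can grow while the
    # right offset absorbs it; the back can grow while the left offset does.
    lstart = len(left_flank) - lo - length
    front, back = 0, 0
    while (lstart - front > 0 and ro - front > 0
           and left_flank[lstart - front - 1] == right_flank[ro - front - 1]):
        front += 1
    lend = lstart + length
    while (lo - back > 0 and ro + length + back < len(right_flank)
           and lend + back < len(left_flank)
           and left_flank[lend + back] == right_flank[ro + length + back]):
        back += 1
    if front or back:
        lstart -= front
        length += front + back
        ro -= front
        lo -= back
        lcopy = left_flank[lstart:lstart + length]
        rcopy = right_flank[ro:ro + length]
    return TSDCall(found=True, length=length, left_copy=lcopy,
                   right_copy=rcopy, mismatches=mm, left_offset=lo,
                   right_offset=ro, beyond_band=length > max_len)


# ---------------------------------------------------------------------------
# flank extraction with poly-A handling
# ---------------------------------------------------------------------------

def _skip_tail_run(seq: str, pos: int, base: str, direction: int,
                   min_run: int = 5) -> int:
    """Skip a homopolymer run of ``base`` (allowing one other nucleotide)
    starting at ``pos`` going ``direction`` (+1 right, -1 left). Returns the
    new position; if the run is shorter than ``min_run`` the position is
    unchanged."""
    i = pos
    used_other = False
    run = 0
    last_good = pos
    while 0 <= i + (direction - 1) // 2 < len(seq):
        ch = seq[i] if direction > 0 else seq[i - 1]
        if ch == base:
            run += 1
            i += direction
            last_good = i
        elif not used_other:
            used_other = True
            i += direction
        else:
            break
    if run >= min_run:
        return last_good
    return pos


def extract_tsd_flanks(genome: GenomeAssembly, annotation: RepeatAnnotation,
                       window: int = 30, trim_tail: bool = True
                       ) -> tuple[str, str]:
    """30 bp flanks immediately adjacent to an element, with the poly-A
    (poly-T on minus strand) tail skipped so the right/left flank starts at
    the expected TSD copy."""
    seq = genome.sequences[annotation.scaffold]
    left_end, right_start = annotation.start, annotation.end
    if trim_tail:
        if annotation.strand == "+":
            right_start = _skip_tail_run(seq, right_start, "A", +1)
        else:
            left_end = _skip_tail_run(seq, left_end, "T", -1)
    left = seq[max(0, left_end - window):left_end]
    right = seq[right_start:right_start + window]
    return left, right


def scan_annotation(genome: GenomeAssembly, annotation: RepeatAnnotation,
                    window: int = 30, **scan_kwargs) -> TSDCall:
    """TSD call for one annotated element.

    Both the tail-trimmed and untrimmed flank extractions are scanned and
    the better call kept: trimming recovers TSDs hidden behind a poly-A
    tail, but can itself consume a TSD that genuinely starts with an A run.
    """
    calls = []
    for trim in (True, False):
        left, right = extract_tsd_flanks(genome, annotation, window, trim)
        calls.append(find_tsd(left, right, **scan_kwargs))
    calls.sort(key=lambda c: (c.found, c.length, -c.mismatches), reverse=True)
    return calls[0]


def tsd_report(genome: GenomeAssembly,
               annotations: list[RepeatAnnotation],
               window: int = 30, **scan_kwargs) -> pd.DataFrame:
    """Per-element TSD table: element_id, found, length, mismatches, copies
    and offsets."""
    rows = []
    for ann in annotations:
        call = scan_annotation(genome, ann, window, **scan_kwargs)
        rows.append({
            "element_id": ann.element_id, "family": ann.family,
            "found": call.found, "length": call.length,
            "mismatches": call.mismatches, "left_copy": call.left_copy,
            "right_copy": call.right_copy, "left_offset": call.left_offset,
            "right_offset": call.right_offset,
        })
    return pd.DataFrame(rows)


def tsd_positive_percentage(n_found: int, n_total: int) -> float:
    """Percentage of TSD-positive elements, reported to one decimal."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_found / n_total, 1)
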