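"""Presence/absence calling of element loci at orthologous positions.

For every candidate element the two 500 bp flanks are mapped into each
target genome: exact k-mer seeding, diagonal clustering, then gapped
alignment of the seeded window (a fast unit-cost pass, redone with an
affine-gap aligner when structural indels or masked runs are in play).
A locus is *absent* when both flanks map collinearly
with (near-)adjacent inner ends and no same-family annotation between
them; *present* when a same-family annotation covers at least half of the
inter-flank span; anything else is *unresolved* with a reason code.

Flank similarity is scored on syntenic blocks: contiguous alignment gap
runs of >= ``big_indel_min`` bp (structural indels — almost always a TE
present on one side only) are discounted from both the identity and the
coverage denominators, so a recent insertion sitting inside a flank does
not destroy the orthology signal of the rest of the flank. A paralogy
guard marks loci whose second-best hit is nearly as good as the best.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from Bio import Align

from ._seq import encode, revcomp
from .io import GenomeAssembly, RepeatAnnotation


# ---------------------------------------------------------------------------
# parameters and result types
# ---------------------------------------------------------------------------

@dataclass
class ScreenParams:
    flank_len: int = 500
    k: int = 13                   # seed k-mer size
    min_identity: float = 0.80
    min_coverage: float = 0.90
    empty_gap_max: int = 30       # bp of target between inner flank ends
    max_overlap: int = 50         # tolerated inner-end overlap (TSD remnants)
    big_indel_min: int = 40       # gap runs at least this long are structural
    min_aligned_bp: int = 100     # absolute floor on aligned flank bases
    min_segment_bp: int = 25      # terminal syntenic segments below this are
                                  # too short to anchor an orthology call
    paralog_margin: float = 0.02
    min_family_coverage: float = 0.5
    max_candidates: int = 5       # clusters evaluated per flank and strand
    diag_merge: int = 800         # max diagonal spread merged into one cluster
    pad: int = 80                 # window padding around seed extents


@dataclass
class LocusFlanks:
    locus_id: int | str
    family: str
    scaffold: str
    left_flank: str
    right_flank: str
    element_seq: str = ""
    left_truncated: bool = False
    right_truncated: bool = False
    # positions covered by other annotated repeats (seeding is restricted to
    # unmasked positions, like soft-masking before a similarity search)
    left_mask: np.ndarray | None = None
    right_mask: np.ndarray | None = None


@dataclass
class FlankHit:
    scaffold: str
    start: int
    end: int
    strand: str
    identity: float
    coverage: float
    matches: int


@dataclass
class FlankMapping:
    left: FlankHit | None = None
    right: FlankHit | None = None
    left_second_identity: float = 0.0
    right_second_identity: float = 0.0
    gap: int | None = None        # signed bp between inner mapped ends
    reason: str = ""              # why the gap is undefined, if it is


@dataclass
class OrthologCall:
    status: str                   # present | absent | unresolved
    reason: str = ""
    mapping: FlankMapping | None = None
    family_coverage: float = 0.0


# ---------------------------------------------------------------------------
# k-mer index over a target genome
# ---------------------------------------------------------------------------

class GenomeIndex:
    """Sorted-array index of all k-mers of a genome (2-bit encoded)."""

    def __init__(self, genome: GenomeAssembly, k: int = 13):
        if genome.total_bp == 0:
            raise ValueError("target genome is empty")
        if not 4 <= k <= 31:
            raise ValueError("k must be in [4, 31]")
        self.genome = genome
        self.k = k
        parts, offsets, names = [], [], []
        pos = 0
        sep = np.full(k, 4, dtype=np.uint8)   # N-run separator kills k-mers
        for name, seq in genome.sequences.items():
            names.append(name)
            offsets.append(pos)
            parts.append(encode(seq))
            pos += len(seq)
            parts.append(sep)
            pos += k
        self._codes = np.concatenate(parts)
        self._offsets = np.array(offsets)
        self._names = names
        self._lengths = [len(genome.sequences[n]) for n in names]
        kmers, valid = _rolling_kmers(self._codes, k)
        positions = np.flatnonzero(valid)
        kmers = kmers[positions]
        order = np.argsort(kmers, kind="stable")
        self._sorted_kmers = kmers[order]
        self._sorted_pos = positions[order].astype(np.int64)

    def locate(self, global_pos: int) -> tuple[str, int]:
        """Map a concatenated-genome position back to (scaffold, local)."""
        i = int(np.searchsorted(self._offsets, global_pos, side="right")) - 1
        return self._names[i], int(global_pos - self._offsets[i])

    def seed_hits(self, query: str) -> tuple[np.ndarray, np.ndarray]:
        """(query_pos, target_global_pos) for every exact k-mer match.

        K-mers containing N (including hard-masked repeat positions of a
        flank) never seed."""
        q = encode(query.upper())
        kmers, valid = _rolling_kmers(q, self.k)
        qpos = np.flatnonzero(valid)
        kmers = kmers[qpos]
        lo = np.searchsorted(self._sorted_kmers, kmers, side="left")
        hi = np.searchsorted(self._sorted_kmers, kmers, side="right")
        out_q, out_t = [], []
        for qp, a, b in zip(qpos, lo, hi):
            if b > a:
                out_t.append(self._sorted_pos[a:b])
                out_q.append(np.full(b - a, qp, dtype=np.int64))
        if not out_q:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        return np.concatenate(out_q), np.concatenate(out_t)


def _rolling_kmers(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    kmers = np.zeros(n, dtype=np.uint64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        window = codes[j:j + n]
        kmers = (kmers << np.uint64(2)) | (window & np.uint8(3)).astype(np.uint64)
        valid &= window < 4
    return kmers, valid


# ---------------------------------------------------------------------------
# flank extraction
# ---------------------------------------------------------------------------

def extract_flanks(genome: GenomeAssembly, annotation: RepeatAnnotation,
                   flank_len: int = 500,
                   repeat_mask: dict[str, np.ndarray] | None = None
                   ) -> LocusFlanks:
    """Flanks immediately adjacent to the element span on the genome forward
    strand, truncated (and flagged) at scaffold boundaries.

    ``repeat_mask`` optionally maps scaffold id to a boolean per-bp array of
    annotated-repeat positions; the corresponding flank sub-masks restrict
    seeding during mapping."""
    if annotation.scaffold not in genome.sequences:
        raise ValueError(f"scaffold {annotation.scaffold!r} not in genome")
    seq = genome.sequences[annotation.scaffold]
    if annotation.end > len(seq):
        raise ValueError("element span extends past scaffold end")
    ls = max(0, annotation.start - flank_len)
    left = seq[ls:annotation.start]
    right = seq[annotation.end:annotation.end + flank_len]
    left_mask = right_mask = None
    if repeat_mask is not None and annotation.scaffold in repeat_mask:
        m = repeat_mask[annotation.scaffold]
        left_mask = m[ls:annotation.start].copy()
        right_mask = m[annotation.end:annotation.end + flank_len].copy()
    return LocusFlanks(
        locus_id=annotation.element_id, family=annotation.family,
        scaffold=annotation.scaffold, left_flank=left, right_flank=right,
        element_seq=seq[annotation.start:annotation.end],
        left_truncated=len(left) < flank_len,
        right_truncated=len(right) < flank_len,
        left_mask=left_mask, right_mask=right_mask)


def build_repeat_mask(genome: GenomeAssembly,
                      annotations: list[RepeatAnnotation]
                      ) -> dict[str, np.ndarray]:
    """Boolean per-bp mask of annotated repeat fragments per scaffold."""
    mask = {name: np.zeros(len(seq), dtype=bool)
            for name, seq in genome.sequences.items()}
    for ann in annotations:
        if ann.scaffold in mask:
            for s, e in ann.fragment_spans:
                mask[ann.scaffold][s:e] = True
    return mask


# ---------------------------------------------------------------------------
# flank mapping
# ---------------------------------------------------------------------------

def _clusters(qpos: np.ndarray, tpos: np.ndarray, qlen: int, diag_merge: int
              ) -> list[tuple[int, int, int]]:
    """Group seed hits into candidate loci by diagonal proximity.

    Returns (n_seeds, window_start, window_end) per cluster, in global
    target coordinates, strongest first. Windows project the full query
    through the outermost seeds so edlib sees the complete locus."""
    if qpos.size == 0:
        return []
    diag = tpos - qpos
    order = np.argsort(diag, kind="stable")
    diag, qpos, tpos = diag[order], qpos[order], tpos[order]
    breaks = np.flatnonzero(np.diff(diag) > diag_merge)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks + 1, [diag.size]])
    out = []
    for s, e in zip(starts, ends):
        ws = int((tpos[s:e] - qpos[s:e]).min())
        we = int((tpos[s:e] + (qlen - qpos[s:e])).max())
        out.append((int(e - s), ws, we))
    out.sort(key=lambda c: -c[0])
    return out


def _window_aligner() -> Align.PairwiseAligner:
    # Long gap runs must out-compete "smearing" an absent element across
    # unrelated sequence as mismatches, so gap extension is cheap while
    # substitutions are expensive. End gaps of the target window are free
    # (the window is deliberately larger than the homologous stretch).
    aligner = Align.PairwiseAligner(
        mode="global", match_score=1.0, mismatch_score=-2.0,
        open_gap_score=-6.0, extend_gap_score=-0.05)
    # free end gaps on the first ("target") sequence row, i.e. unpenalised
    # window overhang; the attribute was renamed in recent Biopython
    if hasattr(aligner, "open_end_insertion_score"):
        aligner.open_end_insertion_score = 0.0
        aligner.extend_end_insertion_score = 0.0
    else:                                       # pragma: no cover
        aligner.target_end_open_gap_score = 0.0
        aligner.target_end_extend_gap_score = 0.0
    return aligner


_ALIGNER = _window_aligner()


def _score_alignment(query: str, window: str, params: ScreenParams):
    """Align the query into the window and score identity/coverage on
    syntenic blocks (long gap runs = structural indels are discounted).

    A unit-cost aligner (edlib, banded) is tried first; it is reliable when
    the query aligns cleanly, but it smears structural indels into
    mismatch tracts, so alignments with a high edit-distance ratio are
    redone with an affine-gap aligner whose cheap gap extension recovers
    long indels as single gap runs."""
    res = edlib.align(query, window, mode="HW", task="path")
    if res["editDistance"] < 0:
        return None
    n_masked = query.count("N")
    unmasked = max(len(query) - n_masked, 1)
    # the unit-cost path cannot prefer one long gap over a diagonal smear,
    # so queries with a sizeable masked run always take the affine aligner
    if (n_masked < params.big_indel_min
            and res["editDistance"] - n_masked <= 0.18 * unmasked):
        nice = edlib.getNiceAlignment(res, query, window)
        qa, ta = nice["query_aligned"], nice["target_aligned"]
        t_offset = res["locations"][0][0]
        return _score_columns(qa, ta, len(query), t_offset, params)
    try:
        aln = _ALIGNER.align(query, window)[0]
    except (ValueError, OverflowError):
        return None
    return _score_columns(aln[0], aln[1], len(query), 0, params)


def _score_columns(qa: str, ta: str, qlen: int, t_offset: int,
                   params: ScreenParams):
    n = len(qa)
    qarr = np.frombuffer(qa.encode(), dtype=np.uint8)
    tarr = np.frombuffer(ta.encode(), dtype=np.uint8)
    dash = ord("-")
    gap = (qarr == dash) | (tarr == dash)
    aligned_cols = np.flatnonzero(~gap)
    if aligned_cols.size == 0:
        return None
    # trim end gaps (the window deliberately exceeds the homologous stretch)
    lo, hi = aligned_cols[0], aligned_cols[-1] + 1
    big = np.zeros(n, dtype=bool)
    i = lo
    while i < hi:
        if gap[i]:
            j = i
            while j < hi and gap[j]:
                j += 1
            if j - i >= params.big_indel_min:
                big[i:j] = True
            i = j
        else:
            i += 1
    in_core = np.zeros(n, dtype=bool)
    in_core[lo:hi] = True

    # split the core into syntenic segments separated by big gap runs and
    # drop terminal segments that do not themselves look orthologous: they
    # are usually spurious extension across an empty insertion site
    boundaries = np.flatnonzero(np.diff(big[lo:hi].astype(np.int8))) + lo + 1
    edges = np.concatenate([[lo], boundaries, [hi]])
    segments = [(int(edges[i]), int(edges[i + 1]))
                for i in range(len(edges) - 1) if not big[edges[i]]]

    masked = qarr == ord("N")

    def seg_stats(s: int, e: int):
        cols = slice(s, e)
        bb = ~gap[cols] & ~masked[cols]
        m = int(np.count_nonzero(bb & (qarr[cols] == tarr[cols])))
        mm = int(np.count_nonzero(bb & (qarr[cols] != tarr[cols])))
        sg = int(np.count_nonzero(gap[cols] & ~masked[cols]))
        return m, mm, sg

    stats = [seg_stats(s, e) for s, e in segments]

    def seg_ok(i: int) -> bool:
        m, mm, sg = stats[i]
        if len(segments) == 1:
            # sole segment: the global thresholds judge it
            return (m + mm + sg) > 0 and m / (m + mm + sg) >= params.min_identity
        return (m + mm >= params.min_segment_bp
                and m / (m + mm + sg) >= params.min_identity)

    while segments and not seg_ok(0):
        segments.pop(0); stats.pop(0)
    while segments and not seg_ok(len(segments) - 1):
        segments.pop(); stats.pop()
    if not segments:
        return None
    kept = np.zeros(n, dtype=bool)
    for s, e in segments:
        kept[s:e] = True

    matches = sum(m for m, _, _ in stats)
    mismatches = sum(mm for _, mm, _ in stats)
    small_gap = sum(sg for _, _, sg in stats)
    q_discounted = int(np.count_nonzero((qarr != dash) & (~kept | masked)))
    denom = matches + mismatches + small_gap
    identity = matches / denom if denom else 0.0
    cov_denom = qlen - q_discounted
    coverage = (matches + mismatches) / cov_denom if cov_denom > 0 else 0.0
    # window coordinates of the outermost retained aligned bases
    keep_cols = np.flatnonzero(kept & ~gap & ~masked)
    if keep_cols.size == 0:
        return None
    tpos = np.cumsum(tarr != dash)
    start = t_offset + int(tpos[keep_cols[0]] - 1)
    end = t_offset + int(tpos[keep_cols[-1]])
    return identity, coverage, matches, start, end


def _map_one_flank(flank: str, index: GenomeIndex, params: ScreenParams,
                   mask: np.ndarray | None = None
                   ) -> tuple[FlankHit | None, float]:
    """Best passing hit for one flank plus the runner-up identity.

    Clusters from both strands are ranked together by seed support and the
    top few aligned. The best *passing* hit (most matched bases) wins; the
    runner-up identity reported for the paralogy guard considers only
    non-overlapping hits of comparable aligned mass, so a partial match to
    a repeat contained in the flank does not masquerade as a paralog of
    the whole flank."""
    if mask is not None and mask.any():
        # hard-mask annotated repeats: they seed nowhere and score as
        # neither identity nor coverage, so orthology rests on unique
        # sequence and an embedded SINE cannot align paralogously
        arr = np.frombuffer(flank.encode(), dtype=np.uint8).copy()
        arr[mask[:arr.size]] = ord("N")
        flank = arr.tobytes().decode("ascii")
    queries = {"+": flank, "-": revcomp(flank)}
    all_clusters: list[tuple[int, int, int, str]] = []
    for strand, query in queries.items():
        qpos, tpos = index.seed_hits(query)
        for n_seeds, ws, we in _clusters(qpos, tpos, len(query),
                                         params.diag_merge):
            all_clusters.append((n_seeds, ws, we, strand))
    all_clusters.sort(key=lambda c: -c[0])
    evaluated: list[FlankHit] = []
    for n_seeds, ws, we, strand in all_clusters[:params.max_candidates]:
        if n_seeds < 3 and evaluated:
            break
        query = queries[strand]
        ws = max(0, ws - params.pad)
        we = we + params.pad
        scaffold, local_ws = index.locate(ws)
        scaf_len = len(index.genome.sequences[scaffold])
        local_we = min(scaf_len, local_ws + (we - ws))
        window = index.genome.sequences[scaffold][local_ws:local_we]
        if not window:
            continue
        scored = _score_alignment(query, window, params)
        if scored is None:
            continue
        identity, coverage, matches, s, e = scored
        # hit coordinates are always on the forward strand of the target;
        # strand records which orientation of the flank matched
        evaluated.append(FlankHit(scaffold, local_ws + s, local_ws + e,
                                  strand, identity, coverage, matches))
    passing = [h for h in evaluated
               if h.identity >= params.min_identity
               and h.coverage >= params.min_coverage
               and h.matches >= params.min_aligned_bp]
    if not passing:
        return None, 0.0
    passing.sort(key=lambda h: (-h.matches, -h.identity))
    best = passing[0]
    second = 0.0
    for h in evaluated:
        if h is best:
            continue
        overlaps = (h.scaffold == best.scaffold
                    and min(h.end, best.end) > max(h.start, best.start))
        if not overlaps and h.matches >= 0.85 * best.matches:
            second = max(second, h.identity)
    return best, second


def map_flanks(flanks: LocusFlanks, index: GenomeIndex,
               params: ScreenParams | None = None) -> FlankMapping:
    """Map both flanks of a locus into a target genome and compute the
    signed inter-flank gap when both land collinearly."""
    params = params or ScreenParams()
    mapping = FlankMapping()
    if not flanks.left_flank or not flanks.right_flank:
        mapping.reason = "empty_flank"
        return mapping
    mapping.left, mapping.left_second_identity = _map_one_flank(
        flanks.left_flank, index, params, flanks.left_mask)
    mapping.right, mapping.right_second_identity = _map_one_flank(
        flanks.right_flank, index, params, flanks.right_mask)
    lt, rt = mapping.left, mapping.right
    if lt is None or rt is None:
        mapping.reason = ("left_unmapped" if lt is None else "right_unmapped")
        return mapping
    if lt.scaffold != rt.scaffold:
        mapping.reason = "discordant_scaffold"
        return mapping
    if lt.strand != rt.strand:
        mapping.reason = "discordant_strand"
        return mapping
    gap = (rt.start - lt.end) if lt.strand == "+" else (lt.start - rt.end)
    if gap < -params.max_overlap:
        mapping.reason = "discordant_order"
        return mapping
    mapping.gap = int(gap)
    return mapping


# ---------------------------------------------------------------------------
# presence / absence call
# ---------------------------------------------------------------------------

class AnnotationIndex:
    """Per-scaffold sorted fragment intervals for coverage queries."""

    def __init__(self, annotations: list[RepeatAnnotation]):
        self._frags: dict[str, list[tuple[int, int, str]]] = {}
        for ann in annotations:
            self._frags.setdefault(ann.scaffold, []).extend(
                (s, e, ann.family) for s, e in ann.fragment_spans)
        self._starts = {}
        for key in self._frags:
            self._frags[key].sort()
            self._starts[key] = [s for s, _, _ in self._frags[key]]

    def _covered_bp(self, scaffold: str, start: int, end: int,
                    family: str | None, invert: bool) -> int:
        """Union bp of [start, end) covered by fragments of ``family``
        (or, with ``invert``, of every other family)."""
        if end <= start or scaffold not in self._frags:
            return 0
        frags = self._frags[scaffold]
        # fragments are short; anything starting 50 kb back cannot overlap
        i = bisect_left(self._starts[scaffold], start - 50_000)
        intervals = []
        for s, e, fam in frags[i:]:
            if s >= end:
                break
            if family is not None and ((fam == family) == invert):
                continue
            lo, hi = max(s, start), min(e, end)
            if hi > lo:
                intervals.append((lo, hi))
        intervals.sort()
        covered, cur_lo, cur_hi = 0, None, None
        for lo, hi in intervals:
            if cur_hi is None or lo > cur_hi:
                if cur_hi is not None:
                    covered += cur_hi - cur_lo
                cur_lo, cur_hi = lo, hi
            else:
                cur_hi = max(cur_hi, hi)
        if cur_hi is not None:
            covered += cur_hi - cur_lo
        return covered

    def family_coverage(self, scaffold: str, start: int, end: int,
                        family: str) -> float:
        """Fraction of [start, end) covered by fragments of ``family``."""
        if end <= start:
            return 0.0
        return self._covered_bp(scaffold, start, end, family, False) / (end - start)

    def other_family_bp(self, scaffold: str, start: int, end: int,
                        family: str) -> int:
        """Union bp of [start, end) covered by fragments of other families."""
        return self._covered_bp(scaffold, start, end, family, True)


def call_presence(mapping: FlankMapping, annotation_index: AnnotationIndex,
                  family: str, params: ScreenParams | None = None
                  ) -> OrthologCall:
    """Classify one locus in one target genome as present/absent/unresolved."""
    params = params or ScreenParams()
    if mapping.gap is None:
        return OrthologCall("unresolved", mapping.reason or "unmapped", mapping)
    lt, rt = mapping.left, mapping.right
    margin = params.paralog_margin
    if (mapping.left_second_identity >= lt.identity - margin
            or mapping.right_second_identity >= rt.identity - margin):
        return OrthologCall("unresolved", "paralog_ambiguity", mapping)
    if lt.strand == "+":
        span = (lt.end, rt.start)
    else:
        span = (rt.end, lt.start)
    cov = annotation_index.family_coverage(lt.scaffold, span[0], span[1], family)
    if cov >= params.min_family_coverage:
        return OrthologCall("present", "family_annotation_in_span", mapping, cov)
    # bp of the inter-flank span explained by annotated repeats of *other*
    # families does not argue for presence of this element
    explained = annotation_index.other_family_bp(lt.scaffold, span[0],
                                                 span[1], family)
    if mapping.gap - explained <= params.empty_gap_max:
        if cov > 0.0:
            return OrthologCall("unresolved", "annotation_in_small_gap",
                                mapping, cov)
        return OrthologCall("absent", "empty_site", mapping, cov)
    return OrthologCall("unresolved", "gap_unexplained", mapping, cov)


# ---------------------------------------------------------------------------
# lineage-specific screen
# ---------------------------------------------------------------------------

@dataclass
class LineageScreenResult:
    specific: list
    ambiguous: list                # (locus_id, species, reason)
    calls: dict                    # species -> {locus_id: OrthologCall}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for species, calls in self.calls.items():
            for locus, call in calls.items():
                gap = call.mapping.gap if call.mapping else None
                rows.append({"locus_id": locus, "species": species,
                             "status": call.status, "reason": call.reason,
                             "gap": -10**9 if gap is None else gap,
                             "family_coverage": round(call.family_coverage, 3)})
        return pd.DataFrame(rows)


def find_lineage_specific(calls_by_species: dict[str, dict],
                          focal_species: str) -> LineageScreenResult:
    """Loci absent in *all* non-focal species are lineage specific; loci with
    any unresolved call are excluded and reported separately."""
    if not calls_by_species:
        raise ValueError("no target species calls supplied")
    loci = None
    for species, calls in calls_by_species.items():
        if species == focal_species:
            raise ValueError("calls must be for non-focal species only")
        ids = set(calls)
        loci = ids if loci is None else loci & ids
    specific, ambiguous = [], []
    for locus in sorted(loci, key=str):
        statuses = {sp: calls_by_species[sp][locus] for sp in calls_by_species}
        if any(c.status == "unresolved" for c in statuses.values()):
            for sp, c in statuses.items():
                if c.status == "unresolved":
                    ambiguous.append((locus, sp, c.reason))
            continue
        if all(c.status == "absent" for c in statuses.values()):
            specific.append(locus)
    return LineageScreenResult(specific, ambiguous, calls_by_species)


def screen_lineage_specific(focal_genome: GenomeAssembly,
                            candidates: list[RepeatAnnotation],
                            target_genomes: dict[str, GenomeAssembly],
                            target_annotations: dict[str, list[RepeatAnnotation]],
                            params: ScreenParams | None = None,
                            focal_species: str = "focal",
                            focal_annotations: list[RepeatAnnotation] | None = None
                            ) -> LineageScreenResult:
    """Run the whole screen: flank extraction (with repeat-masked seeding
    when the focal annotation set is supplied), mapping into every target,
    presence calling, and the all-absent intersection."""
    params = params or ScreenParams()
    repeat_mask = (build_repeat_mask(focal_genome, focal_annotations)
                   if focal_annotations else None)
    flank_cache = [extract_flanks(focal_genome, ann, params.flank_len,
                                  repeat_mask) for ann in candidates]
    calls_by_species: dict[str, dict] = {}
    for species, target in target_genomes.items():
        index = GenomeIndex(target, params.k)
        ann_index = AnnotationIndex(target_annotations.get(species, []))
        calls = {}
        for ann, flanks in zip(candidates, flank_cache):
            mapping = map_flanks(flanks, index, params)
            calls[ann.element_id] = call_presence(mapping, ann_index,
                                                  ann.family, params)
        calls_by_species[species] = calls
    return find_lineage_specific(calls_by_species, focal_species)
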