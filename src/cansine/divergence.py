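"""Element-to-consensus alignment, CpG-aware divergence, young-element
filters and genome-wide TE summary statistics.

Divergence is the mismatch proportion over substitution columns only (gap
columns excluded), which tracks RepeatMasker's mismatch-based divergence;
a Kimura two-parameter mode is available since RepeatMasker's
calcDivergence uses it. CpG stratification is consensus-driven: a column
is CpG when its consensus base participates in a CG dinucleotide of the
ungapped consensus, because the ancestral state is what determines
hypermutability.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align

from ._seq import cpg_sites
from .io import RepeatAnnotation


@dataclass
class AlignmentScoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0


@dataclass
class ElementAlignment:
    """A global element-vs-consensus alignment with per-column annotation.

    ``column_class`` uses M (match), X (mismatch), I (insertion in the
    element relative to the consensus) and D (deletion). ``cpg`` flags
    columns whose consensus base is part of a CG dinucleotide of the
    ungapped consensus; it depends on the consensus only.
    """

    aligned_element: str
    aligned_consensus: str
    column_class: np.ndarray
    cpg: np.ndarray
    element_id: int | str = ""
    family: str = ""
    score: float = 0.0

    def ungapped_element(self) -> str:
        return self.aligned_element.replace("-", "")

    def ungapped_consensus(self) -> str:
        return self.aligned_consensus.replace("-", "")


def _make_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    return Align.PairwiseAligner(
        mode="global",
        match_score=scoring.match,
        mismatch_score=scoring.mismatch,
        open_gap_score=scoring.gap_open,
        extend_gap_score=scoring.gap_extend,
    )


def align_to_consensus(element_seq: str, consensus_seq: str,
                       scoring: AlignmentScoring | None = None,
                       element_id: int | str = "",
                       family: str = "") -> ElementAlignment:
    """Optimal global alignment of an element against its consensus.

    Affine gap penalties (default +1/-1, open -4, extend -1). Ties are
    broken deterministically by taking the aligner's canonical first
    traceback. Elements must be pre-oriented to the consensus strand by the
    caller (a reverse-complement element aligns with a poor score).
    """
    if not element_seq or not consensus_seq:
        raise ValueError("sequences must be non-empty")
    scoring = scoring or AlignmentScoring()
    aligner = _make_aligner(scoring)
    alignments = aligner.align(element_seq.upper(), consensus_seq.upper())
    aln = alignments[0]
    a_el, a_co = aln[0], aln[1]

    n = len(a_el)
    classes = np.empty(n, dtype="U1")
    cpg = np.zeros(n, dtype=bool)
    cons_cpg = cpg_sites(consensus_seq.upper())
    ci = 0
    for i, (e, c) in enumerate(zip(a_el, a_co)):
        if c == "-":
            classes[i] = "I"
        elif e == "-":
            classes[i] = "D"
            cpg[i] = cons_cpg[ci]
            ci += 1
        else:
            classes[i] = "M" if e == c else "X"
            cpg[i] = cons_cpg[ci]
            ci += 1
    return ElementAlignment(a_el, a_co, classes, cpg, element_id, family,
                            score=float(aln.score))


@dataclass
class DivergenceEstimate:
    overall: float
    cpg: float
    non_cpg: float
    counts: dict[str, int]
    mode: str
    defined: bool = True


def _kimura2p(transitions: int, transversions: int, sites: int) -> float:
    if sites == 0:
        return math.nan
    p = transitions / sites
    q = transversions / sites
    arg = (1.0 - 2.0 * p - q) * math.sqrt(max(1.0 - 2.0 * q, 0.0))
    if arg <= 0:
        return math.inf
    return -0.5 * math.log(arg)


_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def compute_divergence(alignment: ElementAlignment,
                       mode: str = "raw") -> DivergenceEstimate:
    """Divergence over substitution columns, overall and stratified by the
    CpG flag. ``raw`` is the mismatch proportion; ``kimura2p`` applies the
    two-parameter correction to the same columns. An alignment with no
    substitution columns yields NaN divergences flagged undefined."""
    if mode not in ("raw", "kimura2p"):
        raise ValueError(f"unknown divergence mode {mode!r}")
    sub = (alignment.column_class == "M") | (alignment.column_class == "X")
    counts = {"matched": 0, "mismatched": 0,
              "matched_cpg": 0, "mismatched_cpg": 0,
              "transitions": 0, "transversions": 0,
              "transitions_cpg": 0, "transversions_cpg": 0}
    for i in np.flatnonzero(sub):
        e, c = alignment.aligned_element[i], alignment.aligned_consensus[i]
        is_cpg = bool(alignment.cpg[i])
        if e == c:
            counts["matched"] += 1
            if is_cpg:
                counts["matched_cpg"] += 1
        else:
            counts["mismatched"] += 1
            kind = "transitions" if (c, e) in _TRANSITIONS else "transversions"
            counts[kind] += 1
            if is_cpg:
                counts["mismatched_cpg"] += 1
                counts[kind + "_cpg"] += 1

    n_all = counts["matched"] + counts["mismatched"]
    n_cpg = counts["matched_cpg"] + counts["mismatched_cpg"]
    n_non = n_all - n_cpg

    def frac(mis: int, n: int) -> float:
        return mis / n if n else math.nan

    if mode == "raw":
        overall = frac(counts["mismatched"], n_all)
        cpg = frac(counts["mismatched_cpg"], n_cpg)
        non = frac(counts["mismatched"] - counts["mismatched_cpg"], n_non)
    else:
        overall = _kimura2p(counts["transitions"], counts["transversions"], n_all)
        cpg = _kimura2p(counts["transitions_cpg"], counts["transversions_cpg"], n_cpg)
        non = _kimura2p(counts["transitions"] - counts["transitions_cpg"],
                        counts["transversions"] - counts["transversions_cpg"], n_non)
    return DivergenceEstimate(overall, cpg, non, counts, mode, defined=n_all > 0)


# ---------------------------------------------------------------------------
# young-element filter
# ---------------------------------------------------------------------------

def select_young_elements(annotations: list[RepeatAnnotation], family: str,
                          min_len_bp: int, max_div_pct: float
                          ) -> list[RepeatAnnotation]:
    """Keep annotations of ``family`` with total fragment length
    >= ``min_len_bp`` and divergence <= ``max_div_pct`` (boundaries
    inclusive). Order-preserving and idempotent."""
    if min_len_bp < 0 or max_div_pct < 0:
        raise ValueError("thresholds must be >= 0")
    if not any(a.family == family for a in annotations):
        warnings.warn(f"no annotations of family {family!r}", stacklevel=2)
        return []
    return [a for a in annotations
            if a.family == family
            and a.length >= min_len_bp
            and a.divergence_pct <= max_div_pct]


# ---------------------------------------------------------------------------
# genome-wide summary
# ---------------------------------------------------------------------------

@dataclass
class TESummary:
    by_family: pd.DataFrame
    by_class: pd.DataFrame
    histogram: pd.DataFrame
    genome_size_bp: int

    def write(self, prefix) -> None:
        self.by_family.to_csv(f"{prefix}_by_family.tsv", sep="\t", index=False)
        self.by_class.to_csv(f"{prefix}_by_class.tsv", sep="\t", index=False)
        self.histogram.to_csv(f"{prefix}_divergence_hist.tsv", sep="\t", index=False)


def summarize_te_content(annotations: list[RepeatAnnotation],
                         genome_size_bp: int,
                         deduplicate: bool = False) -> TESummary:
    """Per-family and per-class counts, bp totals, genome percentages and
    mean divergences, plus a divergence histogram (1% bins over 0-50%) per
    class — the repeat-landscape analogue.

    ``deduplicate`` collapses exactly-identical (scaffold, span, family)
    annotations before counting; the default keeps everything.
    """
    if genome_size_bp <= 0:
        raise ValueError("genome size must be positive")
    cols = ["family", "classification", "te_class", "length", "divergence"]
    if deduplicate:
        seen, uniq = set(), []
        for a in annotations:
            key = (a.scaffold, a.start, a.end, a.family)
            if key not in seen:
                seen.add(key)
                uniq.append(a)
        annotations = uniq
    rows = [(a.family, a.classification, a.te_class, a.length, a.divergence_pct)
            for a in annotations]
    df = pd.DataFrame(rows, columns=cols)

    def agg(group_col: str) -> pd.DataFrame:
        if df.empty:
            return pd.DataFrame(columns=[group_col, "count", "total_bp",
                                         "genome_pct", "mean_divergence"])
        g = df.groupby(group_col).agg(
            count=("length", "size"), total_bp=("length", "sum"),
            mean_divergence=("divergence", "mean")).reset_index()
        g["genome_pct"] = 100.0 * g["total_bp"] / genome_size_bp
        return g[[group_col, "count", "total_bp", "genome_pct", "mean_divergence"]]

    if df.empty:
        hist = pd.DataFrame(columns=["bin_lower", "te_class", "bp"])
    else:
        df["bin"] = np.clip(np.floor(df["divergence"]), 0, 50).astype(int)
        hist = (df.groupby(["bin", "te_class"])["length"].sum()
                .rename("bp").reset_index()
                .rename(columns={"bin": "bin_lower"}))
        hist = hist[hist["bin_lower"] < 51]
    return TESummary(agg("family"), agg("te_class"), hist, genome_size_bp)
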