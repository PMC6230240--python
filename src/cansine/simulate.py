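"""Synthetic multi-species genomes with planted, fully-recorded SINE histories.

The simulator evolves an ancestral random genome down a dated 4-taxon
species tree under a two-rate substitution model (background vs CpG sites)
and plants SINE insertions as a Poisson process inside each subfamily's
activity window. Every insertion copies a per-subfamily source sequence,
optionally 5'-truncated, extended with a (CT)n microsatellite run and a
poly-A tail, flanked by an 8-15 bp target site duplication, and may nest
inside an earlier element. The full history (who carries what, where, when,
which TSD, nested into whom) is recorded so downstream stages can be scored
against planted truth.

Background indels, recombination and selection are deliberately absent:
the only structural events are TE insertions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _seq
from .io import ConsensusLibrary, Fragment, GenomeAssembly, RepeatAnnotation


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

@dataclass
class SpeciesTree:
    """A rooted, dated tree. Node ages are in My before present (leaves = 0).

    ``stem_start`` is the age at which the simulated ancestor begins to
    evolve above the root split, so that insertions older than the root
    can be planted (they end up shared by every leaf).
    """

    node_age: dict[str, float]
    children: dict[str, list[str]]
    root: str
    stem_start: float

    def leaves(self) -> list[str]:
        return [n for n in self.node_age if n not in self.children]

    def leaves_below(self, node: str) -> frozenset[str]:
        if node not in self.children:
            return frozenset([node])
        out: set[str] = set()
        for child in self.children[node]:
            out |= self.leaves_below(child)
        return frozenset(out)

    @property
    def depth(self) -> float:
        return self.stem_start

    def validate(self) -> None:
        for parent, kids in self.children.items():
            for k in kids:
                if self.node_age[k] >= self.node_age[parent]:
                    raise ValueError(f"child {k} not younger than parent {parent}")
        if self.stem_start < self.node_age[self.root]:
            raise ValueError("stem_start must predate the root split")


def caniformia_tree() -> SpeciesTree:
    """Default 4-taxon caniform topology: (((panda, polar_bear), ferret), dog).

    Ages follow the usual molecular dates for these lineages: dog split
    ~46 Mya, mustelid split ~38 Mya, panda-polar bear split 15.5 Mya.
    The ancestral stem starts at 60 Mya so truly ancient, universally
    shared insertions can be planted.
    """
    return SpeciesTree(
        node_age={"caniformia": 46.0, "arctoidea": 38.0, "bears": 15.5,
                  "panda": 0.0, "polar_bear": 0.0, "ferret": 0.0, "dog": 0.0},
        children={"caniformia": ["dog", "arctoidea"],
                  "arctoidea": ["ferret", "bears"],
                  "bears": ["panda", "polar_bear"]},
        root="caniformia",
        stem_start=60.0,
    )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SubfamilyModel:
    """Study conditions for one simulated SINE subfamily.

    ``window`` is the activity interval in Mya (older bound first);
    ``lineages`` optionally restricts activity to particular branches,
    identified by the branch's child node name; ``label`` is the family
    name written into the emitted annotations (a derived subfamily can be
    annotated under its parent's label, emulating a consensus library that
    does not know it yet).
    """

    name: str
    source: str
    window: tuple[float, float]
    rate: float                       # insertions / My on each active branch
    tsd_range: tuple[int, int] = (8, 15)
    polya_range: tuple[int, int] = (8, 25)
    ct_range: tuple[int, int] = (3, 10)
    truncation_prob: float = 0.1
    nesting_allowed: bool = True
    lineages: frozenset[str] | None = None
    label: str | None = None
    classification: str = "SINE/Can"

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("insertion rate must be >= 0")
        if self.window[0] < self.window[1]:
            raise ValueError("activity window must be (older, younger)")
        lo, hi = self.tsd_range
        if not (1 <= lo <= hi):
            raise ValueError("bad TSD length range")

    @property
    def family_label(self) -> str:
        return self.label or self.name


@dataclass
class SimulationConfig:
    seed: int = 0
    tree: SpeciesTree = field(default_factory=caniformia_tree)
    genome_length: int = 2_000_000
    background_rate: float = 0.0013   # substitutions / site / My
    cpg_rate: float = 0.0104          # substitutions / site / My at CpG sites
    # mammalian genomes are strongly CpG-depleted (observed/expected ~0.2)
    # because of historical CpG deamination; the ancestral background
    # emulates that. SINE source sequences stay CpG-normal: young elements
    # are CpG-rich, which is what makes CpG-aware dating informative.
    cpg_depletion: float = 0.8
    subfamilies: list[SubfamilyModel] = field(default_factory=list)

    def validate(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.background_rate < 0 or self.cpg_rate < 0:
            raise ValueError("substitution rates must be >= 0")
        self.tree.validate()
        for sf in self.subfamilies:
            if sf.window[0] > self.tree.depth:
                raise ValueError(
                    f"subfamily {sf.name}: window predates tree stem")


def default_subfamilies(rng: np.random.Generator) -> list[SubfamilyModel]:
    """The default planted subfamilies.

    Four subfamilies emulate the layered history seen in caniform genomes:
    an ancient universally shared family, a mid-aged family, a recent
    bear-lineage family, and a derived subfamily carrying four diagnostic
    non-CpG mutations that is annotated under its parent's label (so
    subfamily discovery has something real to find). Rates are chosen for
    statistical power at the 2 Mb default genome size.
    """
    src_a = _seq.random_dna(230, rng)
    src_b = _seq.random_dna(215, rng)
    src_c = _seq.random_dna(210, rng)
    src_cnew = _derive_source(src_c, n_mutations=4, rng=rng)
    return [
        SubfamilyModel("CanSINE_A", src_a, (58.0, 46.0), rate=11.0,
                       truncation_prob=0.10),
        SubfamilyModel("CanSINE_B", src_b, (44.0, 24.0), rate=4.0,
                       truncation_prob=0.10),
        SubfamilyModel("CanSINE_C", src_c, (20.0, 0.0), rate=6.0,
                       truncation_prob=0.05,
                       lineages=frozenset({"bears", "panda", "polar_bear"})),
        SubfamilyModel("CanSINE_Cnew", src_cnew, (15.5, 0.0), rate=10.0,
                       truncation_prob=0.05, label="CanSINE_C",
                       lineages=frozenset({"panda", "polar_bear"})),
    ]


def _derive_source(parent: str, n_mutations: int, rng: np.random.Generator) -> str:
    """Derive a child source sequence differing at diagnostic non-CpG sites."""
    codes = _seq.encode(parent)
    eligible = np.flatnonzero(~_seq.cpg_mask(codes))
    # keep diagnostics away from the ends so truncation rarely removes them
    eligible = eligible[(eligible > 20) & (eligible < len(codes) - 20)]
    sites = rng.choice(eligible, size=n_mutations, replace=False)
    for s in sites:
        codes[s] = (codes[s] + 1 + rng.integers(0, 3)) % 4
    return _seq.decode(codes)


def default_config(seed: int = 0, genome_length: int = 2_000_000) -> SimulationConfig:
    """Default study conditions at the requested genome size.

    Insertion rates scale linearly with genome length so that repeat
    density — the quantity the downstream stages are sensitive to — is the
    same at every size; the reference density is set at 2 Mb."""
    rng = np.random.default_rng(seed)
    subfamilies = default_subfamilies(rng)
    scale = genome_length / 2_000_000
    for sf in subfamilies:
        sf.rate *= scale
    return SimulationConfig(seed=seed, genome_length=genome_length,
                            subfamilies=subfamilies)


# ---------------------------------------------------------------------------
# substitution model
# ---------------------------------------------------------------------------

def _mutate_codes(codes: np.ndarray, duration_my: float, background_rate: float,
                  cpg_rate: float, rng: np.random.Generator) -> None:
    """In-place two-rate substitution over one time interval.

    A site is CpG if it lies in a CG dinucleotide of the sequence at the
    *start* of the interval. Substitution probability is 1-exp(-r*t) and the
    target base is uniform over the three alternatives. N sites are inert.
    """
    if duration_my < 0:
        raise ValueError("duration must be >= 0")
    if duration_my == 0 or (background_rate == 0 and cpg_rate == 0):
        return
    is_cpg = _seq.cpg_mask(codes)
    p_bg = -math.expm1(-background_rate * duration_my)
    p_cpg = -math.expm1(-cpg_rate * duration_my)
    p = np.where(is_cpg, p_cpg, p_bg)
    hit = (rng.random(codes.size) < p) & (codes < 4)
    n = int(hit.sum())
    if n:
        codes[hit] = (codes[hit] + 1 + rng.integers(0, 3, n, dtype=np.uint8)) % 4


def _deplete_cpg(codes: np.ndarray, depletion: float,
                 rng: np.random.Generator) -> None:
    """Rewrite a fraction of CG dinucleotides to their deamination products
    (CG -> TG or CA), emulating the CpG depletion of mammalian genomes."""
    if depletion <= 0:
        return
    pair = np.flatnonzero((codes[:-1] == _seq.C) & (codes[1:] == _seq.G))
    hit = pair[rng.random(pair.size) < depletion]
    to_tg = rng.random(hit.size) < 0.5
    codes[hit[to_tg]] = _seq.T
    codes[hit[~to_tg] + 1] = _seq.A


def mutate_sequence(seq: str, duration_my: float, background_rate: float,
                    cpg_rate: float, rng: np.random.Generator) -> str:
    """Substitute a DNA string under the two-rate (CpG / non-CpG) model."""
    codes = _seq.encode(seq)
    _mutate_codes(codes, duration_my, background_rate, cpg_rate, rng)
    return _seq.decode(codes)


# ---------------------------------------------------------------------------
# insertion machinery
# ---------------------------------------------------------------------------

@dataclass
class PlantResult:
    sequence: str
    tsd: str
    tsd_len: int
    shrunk: bool


def plant_insertion(scaffold_seq: str, site: int, element_seq: str,
                    tsd_len: int) -> PlantResult:
    """Insert an element at ``site`` with a target site duplication.

    The TSD is the ``tsd_len`` bases immediately 5' of the site; the result
    is ``prefix + element + TSD + suffix`` (the prefix already ends with the
    first TSD copy). Near the scaffold start the TSD shrinks to the bases
    available and the result is flagged.
    """
    if not 0 <= site <= len(scaffold_seq):
        raise ValueError(f"site {site} outside scaffold of length {len(scaffold_seq)}")
    if tsd_len < 0:
        raise ValueError("tsd_len must be >= 0")
    eff = min(tsd_len, site)
    tsd = scaffold_seq[site - eff:site]
    new = scaffold_seq[:site] + element_seq + tsd + scaffold_seq[site:]
    return PlantResult(new, tsd, eff, eff < tsd_len)


# ---------------------------------------------------------------------------
# truth bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class InsertionRecord:
    uid: int
    subfamily: str
    label: str
    branch: str                      # child node of the branch carrying it
    time_my: float
    species: frozenset[str]
    strand: str
    tsd: str
    tsd_len: int
    tsd_shrunk: bool
    truncated: bool
    trunc_bp: int
    nested_into: int | None
    positions: dict[str, tuple[str, int, int]] = field(default_factory=dict)


@dataclass
class SimulationTruth:
    insertions: dict[int, InsertionRecord] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.insertions.values():
            rows.append({
                "uid": rec.uid, "subfamily": rec.subfamily, "label": rec.label,
                "branch": rec.branch, "time_my": round(rec.time_my, 4),
                "species": ",".join(sorted(rec.species)),
                "strand": rec.strand, "tsd": rec.tsd, "tsd_len": rec.tsd_len,
                "tsd_shrunk": rec.tsd_shrunk, "truncated": rec.truncated,
                "trunc_bp": rec.trunc_bp,
                "nested_into": -1 if rec.nested_into is None else rec.nested_into,
            })
        return pd.DataFrame(rows)

    def branch_activity(self) -> pd.DataFrame:
        df = self.to_frame()
        if df.empty:
            return df
        return (df.groupby(["branch", "subfamily"]).size()
                .rename("insertions").reset_index())

    def nesting_counts(self, species: str | None = None) -> pd.DataFrame:
        """Truth outer-family x inner-family nesting count matrix."""
        pairs: dict[tuple[str, str], int] = {}
        for rec in self.insertions.values():
            if rec.nested_into is None:
                continue
            if species is not None and species not in rec.species:
                continue
            outer = self.insertions[rec.nested_into]
            key = (outer.label, rec.label)
            pairs[key] = pairs.get(key, 0) + 1
        labels = sorted({l for k in pairs for l in k})
        mat = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
        for (o, i), n in pairs.items():
            mat.loc[o, i] = n
        return mat


# ---------------------------------------------------------------------------
# lineage state and the tree walk
# ---------------------------------------------------------------------------

@dataclass
class _LiveElement:
    uid: int
    subfamily: SubfamilyModel
    strand: str
    copy: np.ndarray                     # inserted bases, genome orientation
    trunc: int
    fragments: list[list[int]]           # [start, end) genome coords
    offsets: list[int]                   # element-internal offset per fragment
    tsd_spans: list[list[int]]

    def clone(self) -> "_LiveElement":
        return _LiveElement(self.uid, self.subfamily, self.strand, self.copy,
                            self.trunc, [f[:] for f in self.fragments],
                            self.offsets[:], [t[:] for t in self.tsd_spans])


class _LineageState:
    def __init__(self, seq: np.ndarray):
        self.seq = seq
        self.elements: list[_LiveElement] = []

    def clone(self) -> "_LineageState":
        st = _LineageState(self.seq.copy())
        st.elements = [e.clone() for e in self.elements]
        return st


def _make_element_copy(sf: SubfamilyModel, rng: np.random.Generator
                       ) -> tuple[np.ndarray, str, int]:
    """Build one fresh element copy: truncated core + (CT)n + poly-A, on a
    random strand. Returns (codes in genome orientation, strand, trunc_bp)."""
    core = _seq.encode(sf.source)
    trunc = 0
    if rng.random() < sf.truncation_prob:
        trunc = int(rng.integers(0, len(core) // 2 + 1))
    ct = np.tile(np.array([_seq.C, _seq.T], dtype=np.uint8),
                 int(rng.integers(sf.ct_range[0], sf.ct_range[1] + 1)))
    polya = np.full(int(rng.integers(sf.polya_range[0], sf.polya_range[1] + 1)),
                    _seq.A, dtype=np.uint8)
    elem = np.concatenate([core[trunc:], ct, polya])
    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "-":
        elem = _seq.revcomp_codes(elem)
    return elem, strand, trunc


def _choose_site(state: _LineageState, sf: SubfamilyModel,
                 rng: np.random.Generator) -> tuple[int, int | None]:
    """Pick an insertion site. Sites inside a TSD of a previous insertion are
    resampled (keeps planted TSDs recoverable); sites inside an existing
    element are resampled when the subfamily does not nest."""
    for _ in range(200):
        site = int(rng.integers(0, state.seq.size + 1))
        host = None
        host_span = None
        blocked = False
        for el in state.elements:
            for s, e in el.tsd_spans:
                if s < site < e:
                    blocked = True
                    break
            if blocked:
                break
            # the host is the innermost element whose span contains the
            # site: directly interrupted when a fragment contains it, or
            # landing inside an existing interruption otherwise
            span = (el.fragments[0][0], el.fragments[-1][1])
            if span[0] < site < span[1]:
                if host is None or span[1] - span[0] < host_span:
                    host, host_span = el, span[1] - span[0]
        if blocked:
            continue
        if host is not None and not sf.nesting_allowed:
            continue
        return site, (host.uid if host is not None else None)
    raise RuntimeError("could not place insertion after 200 attempts")


def _insert(state: _LineageState, sf: SubfamilyModel, time_my: float,
            branch_child: str, tree: SpeciesTree, truth: SimulationTruth,
            uid: int, rng: np.random.Generator) -> None:
    elem, strand, trunc = _make_element_copy(sf, rng)
    site, host_uid = _choose_site(state, sf, rng)
    tsd_len = int(rng.integers(sf.tsd_range[0], sf.tsd_range[1] + 1))
    eff = min(tsd_len, site)
    tsd_codes = state.seq[site - eff:site].copy()
    le = elem.size
    shift = le + eff

    state.seq = np.concatenate([state.seq[:site], elem, tsd_codes,
                                state.seq[site:]])

    for el in state.elements:
        new_frags, new_offs = [], []
        for (fs, fe), off in zip(el.fragments, el.offsets):
            if fe <= site:
                new_frags.append([fs, fe]); new_offs.append(off)
            elif fs >= site:
                new_frags.append([fs + shift, fe + shift]); new_offs.append(off)
            else:  # split by the new insertion
                new_frags.append([fs, site]); new_offs.append(off)
                new_frags.append([site + shift, fe + shift])
                new_offs.append(off + (site - fs))
        el.fragments, el.offsets = new_frags, new_offs
        el.tsd_spans = [[s + shift, e + shift] if s >= site else [s, e]
                        for s, e in el.tsd_spans]

    state.elements.append(_LiveElement(
        uid=uid, subfamily=sf, strand=strand, copy=elem, trunc=trunc,
        fragments=[[site, site + le]], offsets=[0],
        tsd_spans=[[site - eff, site], [site + le, site + le + eff]]))

    truth.insertions[uid] = InsertionRecord(
        uid=uid, subfamily=sf.name, label=sf.family_label,
        branch=branch_child, time_my=time_my,
        species=tree.leaves_below(branch_child), strand=strand,
        tsd=_seq.decode(tsd_codes), tsd_len=eff, tsd_shrunk=eff < tsd_len,
        truncated=trunc > 0, trunc_bp=trunc, nested_into=host_uid)


def _branch_events(cfg: SimulationConfig, branch_child: str, t_start: float,
                   t_end: float, rng: np.random.Generator
                   ) -> list[tuple[float, SubfamilyModel]]:
    events: list[tuple[float, SubfamilyModel]] = []
    for sf in cfg.subfamilies:
        if sf.lineages is not None and branch_child not in sf.lineages:
            continue
        hi = min(t_start, sf.window[0])
        lo = max(t_end, sf.window[1])
        if hi <= lo:
            continue
        n = int(rng.poisson(sf.rate * (hi - lo)))
        for t in rng.uniform(lo, hi, n):
            events.append((float(t), sf))
    events.sort(key=lambda e: (-e[0], e[1].name))
    return events


@dataclass
class SimulationResult:
    assemblies: dict[str, GenomeAssembly]
    annotations: dict[str, list[RepeatAnnotation]]
    truth: SimulationTruth
    library: ConsensusLibrary
    config: SimulationConfig


def simulate_caniform_genomes(config: SimulationConfig) -> SimulationResult:
    """Run the forward simulation and return genomes, exact truth-derived
    annotations per species, and the complete insertion history."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = SimulationTruth()
    uid_counter = [0]

    ancestral = rng.integers(0, 4, config.genome_length, dtype=np.uint8)
    _deplete_cpg(ancestral, config.cpg_depletion, rng)
    root_state = _LineageState(ancestral)

    assemblies: dict[str, GenomeAssembly] = {}
    annotations: dict[str, list[RepeatAnnotation]] = {}
    tree = config.tree

    def evolve(state: _LineageState, child: str, t_start: float) -> None:
        t_end = tree.node_age[child]
        t_cur = t_start
        for t, sf in _branch_events(config, child, t_start, t_end, rng):
            _mutate_codes(state.seq, t_cur - t, config.background_rate,
                          config.cpg_rate, rng)
            _insert(state, sf, t, child, tree, truth, uid_counter[0], rng)
            uid_counter[0] += 1
            t_cur = t
        _mutate_codes(state.seq, t_cur - t_end, config.background_rate,
                      config.cpg_rate, rng)
        if child in tree.children:
            for grandchild in tree.children[child]:
                evolve(state.clone(), grandchild, t_end)
        else:
            _emit_leaf(state, child)

    def _emit_leaf(state: _LineageState, species: str) -> None:
        scaffold = f"{species}_scaf1"
        assemblies[species] = GenomeAssembly(
            {scaffold: _seq.decode(state.seq)}, species_label=species)
        anns = []
        for el in state.elements:
            anns.append(_element_annotation(el, state.seq, scaffold))
            rec = truth.insertions[el.uid]
            rec.positions[species] = (scaffold, el.fragments[0][0],
                                      el.fragments[-1][1])
        anns.sort(key=lambda a: a.start)
        annotations[species] = anns

    evolve(root_state, tree.root, tree.stem_start)
    # walk children of root explicitly happens inside evolve via recursion

    library = ConsensusLibrary(
        {sf.name: sf.source for sf in config.subfamilies},
        {sf.name: sf.classification for sf in config.subfamilies})
    return SimulationResult(assemblies, annotations, truth, library, config)


def _element_annotation(el: _LiveElement, seq: np.ndarray,
                        scaffold: str) -> RepeatAnnotation:
    """Truth-derived annotation: the divergence written out is the true
    element-vs-inserted-copy mismatch percentage, decoupling the simulator
    from the divergence estimator under test."""
    sf = el.subfamily
    lcopy = el.copy.size
    frags = []
    for (fs, fe), off in zip(el.fragments, el.offsets):
        cur = seq[fs:fe]
        orig = el.copy[off:off + (fe - fs)]
        div = float(np.mean(cur != orig)) * 100.0 if fe > fs else 0.0
        if el.strand == "+":
            cs, ce = el.trunc + off, el.trunc + off + (fe - fs)
        else:
            # consensus coordinates run antiparallel to the genome on '-'
            cs = el.trunc + (lcopy - (off + (fe - fs)))
            ce = el.trunc + (lcopy - off)
        frags.append(Fragment(fs, fe, cs, ce, 0, round(div, 2), 0.0, 0.0,
                              score=1000))
    total = sum(f.end - f.start for f in frags)
    wdiv = sum(f.divergence_pct * (f.end - f.start) for f in frags) / total
    return RepeatAnnotation(
        scaffold=scaffold, start=el.fragments[0][0], end=el.fragments[-1][1],
        strand=el.strand, family=sf.family_label,
        classification=sf.classification,
        consensus_start=min(f.cons_start for f in frags),
        consensus_end=max(f.cons_end for f in frags),
        divergence_pct=round(wdiv, 4), element_id=el.uid, fragments=frags)


# ---------------------------------------------------------------------------
# focused cohort generators (building blocks for targeted experiments)
# ---------------------------------------------------------------------------

def simulate_aged_cohort(source: str, age_my: float, n_elements: int,
                         rng: np.random.Generator,
                         background_rate: float = 0.0013,
                         cpg_rate: float = 0.0104) -> list[str]:
    """A cohort of element copies all inserted ``age_my`` ago: each is the
    source sequence aged independently under the two-rate model."""
    return [mutate_sequence(source, age_my, background_rate, cpg_rate, rng)
            for _ in range(n_elements)]


def simulate_subfamily_cohort(n_elements: int, n_diagnostic: int,
                              noise: float, rng: np.random.Generator,
                              template_length: int = 200,
                              proportions: tuple[float, float] = (0.5, 0.5),
                              ) -> tuple[list[str], list[int], str, list[int]]:
    """Two element sources differing at diagnostic non-CpG columns, with
    uniform per-site noise. Returns (elements, true source index per element,
    template sequence, diagnostic column list)."""
    template = _seq.random_dna(template_length, rng)
    derived = _derive_source(template, n_diagnostic, rng)
    diag_cols = [i for i, (a, b) in enumerate(zip(template, derived)) if a != b]
    elements, labels = [], []
    for i in range(n_elements):
        src = template if rng.random() < proportions[0] else derived
        codes = _seq.encode(src)
        hit = rng.random(codes.size) < noise
        nh = int(hit.sum())
        if nh:
            codes[hit] = (codes[hit] + 1 + rng.integers(0, 3, nh, dtype=np.uint8)) % 4
        elements.append(_seq.decode(codes))
        labels.append(0 if src is template else 1)
    return elements, labels, template, diag_cols


def simulate_tsd_loci(n_loci: int, age_my: float, rng: np.random.Generator,
                      element_core: str | None = None,
                      flank_bp: int = 60,
                      tsd_range: tuple[int, int] = (8, 15),
                      background_rate: float = 0.0013,
                      cpg_rate: float = 0.0104):
    """Independent single-element loci with planted TSDs, then aged.

    Returns a list of dicts with the locus sequence, element span after
    aging (coordinates are unchanged by substitutions) and the planted TSD.
    """
    if element_core is None:
        element_core = _seq.random_dna(160, rng)
    loci = []
    for _ in range(n_loci):
        background = _seq.random_dna(2 * flank_bp, rng)
        polya = "A" * int(rng.integers(8, 20))
        elem = element_core + polya
        tsd_len = int(rng.integers(tsd_range[0], tsd_range[1] + 1))
        site = flank_bp
        planted = plant_insertion(background, site, elem, tsd_len)
        aged = mutate_sequence(planted.sequence, age_my, background_rate,
                               cpg_rate, rng)
        loci.append({
            "sequence": aged,
            "element_start": site,
            "element_end": site + len(elem),
            "tsd": planted.tsd,
            "tsd_len": planted.tsd_len,
        })
    return loci


def simulate_nested_counts(peaks_my: list[float], sds_my: list[float],
                           n_per_family: int, rng: np.random.Generator,
                           element_bp: int = 250, genome_bp: int = 2_000_000,
                           names: list[str] | None = None) -> pd.DataFrame:
    """Draw a family-into-family nesting count matrix from Gaussian activity.

    Each element has an insertion time drawn from its family's Gaussian
    activity curve; processing events oldest-first, a new element lands
    inside an already-present family f with probability (accumulated bp of
    f)/genome_bp. Rows are outer families, columns inner families.
    """
    n_fam = len(peaks_my)
    names = names or [f"fam{i}" for i in range(n_fam)]
    events = []
    for f in range(n_fam):
        for t in rng.normal(peaks_my[f], sds_my[f], n_per_family):
            events.append((float(t), f))
    events.sort(key=lambda e: -e[0])  # oldest first
    present = np.zeros(n_fam, dtype=float)
    counts = np.zeros((n_fam, n_fam), dtype=int)
    for _, fam in events:
        p = present * element_bp / genome_bp
        u = rng.random()
        acc = 0.0
        for f in range(n_fam):
            acc += p[f]
            if u < acc:
                counts[f, fam] += 1
                break
        present[fam] += 1
    return pd.DataFrame(counts, index=names, columns=names)
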