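"""End-to-end orchestration of the analysis stages behind one config.

A run is a pure function of (inputs, parameters, seed): the manifest
records a hash of the parameters and of every output file, so identical
config+seed reruns are byte-identical and verifiably so.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import dating, divergence, ortholog, simulate, subfamily, tsd
from .io import (GenomeAssembly, read_consensus_library, read_fasta,
                 parse_repeatmasker_out, write_fasta, write_intervals,
                 write_repeatmasker_out)

__version__ = "0.1.0"


@dataclass
class YoungFilter:
    family: str = "CanSINE_C"
    min_len_bp: int = 150
    max_div_pct: float = 10.0


@dataclass
class PipelineConfig:
    """All stage parameters in one place.

    Defaults are the standard operating point of the method: 500 bp
    flanks, identity >= 0.80, coverage >= 0.90, TSD search band 6-15 bp
    with one mismatch, minimum subfamily size 10, substitution rates
    0.0013/0.0104 per site per My, TinT minimum repeat extension 4.
    """

    seed: int = 0
    output_dir: str = "cansine_out"
    # simulated-mode inputs
    simulate: bool = True
    genome_length: int = 2_000_000
    # real-mode inputs
    focal_species: str = "panda"
    genome_paths: dict = field(default_factory=dict)        # species -> FASTA
    annotation_paths: dict = field(default_factory=dict)    # species -> .out
    consensus_library_path: str = ""
    # stage parameters
    young: YoungFilter = field(default_factory=YoungFilter)
    flank_len: int = 500
    min_identity: float = 0.80
    min_coverage: float = 0.90
    empty_gap_max: int = 30
    seed_k: int = 13
    tsd_min_len: int = 6
    tsd_max_len: int = 15
    tsd_max_mismatch: int = 1
    coseg_min_size: int = 10
    coseg_exclude_cpg: bool = True
    rate_non_cpg: float = 0.0013
    rate_cpg: float = 0.0104
    tint_min_extension: int = 4

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        young = YoungFilter(**data.pop("young", {}))
        cfg = cls(**data)
        cfg.young = young
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


def validate_config(config: PipelineConfig) -> list[str]:
    """Empty list iff every invariant holds; each problem names the field
    and the violated rule."""
    problems = []
    for name in ("min_identity", "min_coverage"):
        v = getattr(config, name)
        if not 0.0 <= v <= 1.0:
            problems.append(f"{name}: fraction out of range [0,1]: {v}")
    if config.tsd_min_len > config.tsd_max_len:
        problems.append(f"tsd band: min>max ({config.tsd_min_len}>"
                        f"{config.tsd_max_len})")
    if config.tsd_min_len < 1:
        problems.append("tsd_min_len: must be >= 1")
    if config.flank_len < 0:
        problems.append("flank_len: must be >= 0")
    if config.genome_length <= 0:
        problems.append("genome_length: must be positive")
    if config.coseg_min_size < 2:
        problems.append("coseg_min_size: must be >= 2")
    if config.rate_non_cpg <= 0 or config.rate_cpg <= 0:
        problems.append("substitution rates: must be > 0")
    if config.tint_min_extension < 1:
        problems.append("tint_min_extension: must be >= 1")
    if config.young.min_len_bp < 0 or config.young.max_div_pct < 0:
        problems.append("young filter: thresholds must be >= 0")
    if not config.simulate:
        for species, path in {**config.genome_paths}.items():
            if not Path(path).exists():
                problems.append(f"genome_paths[{species}]: missing file {path}")
        for species, path in {**config.annotation_paths}.items():
            if not Path(path).exists():
                problems.append(f"annotation_paths[{species}]: missing file {path}")
        if not config.genome_paths:
            problems.append("genome_paths: required when simulate is false")
        if config.focal_species not in config.genome_paths and config.genome_paths:
            problems.append(f"focal_species: {config.focal_species!r} has no genome")
    return problems


@dataclass
class ReportBundle:
    output_dir: Path
    manifest: dict
    summary: str


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every stage and write all reports under ``output_dir``."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary_lines = [f"cansine pipeline v{__version__} (seed {config.seed})"]

    # --- inputs -----------------------------------------------------------
    if config.simulate:
        sim_cfg = simulate.default_config(config.seed, config.genome_length)
        sim = simulate.simulate_caniform_genomes(sim_cfg)
        assemblies, annotations = sim.assemblies, sim.annotations
        library = sim.library
        focal = config.focal_species
        for species, asm in assemblies.items():
            write_fasta(asm.sequences, out / f"{species}.fa")
            write_repeatmasker_out(annotations[species], out / f"{species}.out")
        sim.truth.to_frame().to_csv(out / "truth.tsv", sep="\t", index=False)
        summary_lines.append(
            f"simulated {len(assemblies)} genomes of "
            f"{config.genome_length} bp; {len(sim.truth.insertions)} "
            "insertions planted")
    else:
        assemblies = {sp: read_fasta(p, sp)
                      for sp, p in config.genome_paths.items()}
        annotations = {sp: parse_repeatmasker_out(p)
                       for sp, p in config.annotation_paths.items()}
        library = (read_consensus_library(config.consensus_library_path)
                   if config.consensus_library_path else None)
        focal = config.focal_species
        sim = None

    focal_genome = assemblies[focal]
    focal_anns = annotations[focal]

    # --- genome-wide summary ---------------------------------------------
    for species, anns in annotations.items():
        summ = divergence.summarize_te_content(anns, assemblies[species].total_bp)
        summ.write(out / f"{species}_te")
        write_intervals(anns, out / f"{species}_repeats.bed", "BED")
    summary_lines.append(f"TE summaries written for {len(annotations)} species")

    # --- young elements and the lineage-specific screen -------------------
    young = divergence.select_young_elements(
        focal_anns, config.young.family, config.young.min_len_bp,
        config.young.max_div_pct)
    params = ortholog.ScreenParams(
        flank_len=config.flank_len, k=config.seed_k,
        min_identity=config.min_identity, min_coverage=config.min_coverage,
        empty_gap_max=config.empty_gap_max)
    targets = {sp: asm for sp, asm in assemblies.items() if sp != focal}
    screen = ortholog.screen_lineage_specific(
        focal_genome, young, targets,
        {sp: annotations[sp] for sp in targets}, params, focal,
        focal_annotations=focal_anns)
    screen.to_frame().to_csv(out / "ortholog_calls.tsv", sep="\t", index=False)
    specific_ids = set(screen.specific)
    specific_anns = [a for a in young if a.element_id in specific_ids]
    with open(out / "lineage_specific.tsv", "w") as fh:
        fh.write("locus_id\n")
        for locus in screen.specific:
            fh.write(f"{locus}\n")
    with open(out / "ambiguous_loci.tsv", "w") as fh:
        fh.write("locus_id\tspecies\treason\n")
        for locus, sp, reason in screen.ambiguous:
            fh.write(f"{locus}\t{sp}\t{reason}\n")
    summary_lines.append(
        f"{len(young)} young {config.young.family} candidates; "
        f"{len(screen.specific)} {focal}-specific; "
        f"{len(set(l for l, _, _ in screen.ambiguous))} ambiguous")

    # --- TSD scan ----------------------------------------------------------
    tsd_df = tsd.tsd_report(focal_genome, specific_anns or young,
                            min_len=config.tsd_min_len,
                            max_len=config.tsd_max_len,
                            max_mismatch=config.tsd_max_mismatch)
    tsd_df.to_csv(out / "tsd_report.tsv", sep="\t", index=False)
    if len(tsd_df):
        pct = tsd.tsd_positive_percentage(int(tsd_df["found"].sum()), len(tsd_df))
        summary_lines.append(
            f"TSDs: {int(tsd_df['found'].sum())} of {len(tsd_df)} "
            f"elements ({pct}%)")

    # --- subfamily discovery and network -----------------------------------
    template = None
    if library is not None and config.young.family in library:
        template = library[config.young.family]
    elif library is not None and len(library.sequences):
        template = next(iter(library.sequences.values()))
    subfams = []
    if template is not None and specific_anns:
        elems = []
        for ann in specific_anns:
            seq = focal_genome.sequences[ann.scaffold][ann.start:ann.end]
            if ann.strand == "-":
                from ._seq import revcomp
                seq = revcomp(seq)
            elems.append((ann.element_id, seq))
        matrix = subfamily.build_mutation_matrix(elems, template)
        subfams = subfamily.detect_subfamilies(
            matrix, min_size=config.coseg_min_size,
            exclude_cpg=config.coseg_exclude_cpg)
        with open(out / "subfamilies.tsv", "w") as fh:
            fh.write("subfamily\tsize\tn_diagnostics\tdiagnostics\tmembers\n")
            for i, sf in enumerate(subfams):
                diags = ",".join(f"{c}{s}" for c, s in sf.diagnostics)
                members = ",".join(str(m) for m in sf.members)
                fh.write(f"sf{i}\t{sf.size}\t{len(sf.diagnostics)}\t"
                         f"{diags}\t{members}\n")
        write_fasta({f"sf{i}": sf.consensus for i, sf in enumerate(subfams)},
                    out / "subfamily_consensus.fa")
        aligned = {f"sf{i}": "".join(subfamily._STATES[c]
                                     for c in sf.consensus_row)
                   for i, sf in enumerate(subfams)}
        aligned["template"] = template.upper()
        try:
            net = subfamily.median_joining_network(
                aligned, exclude_cpg=config.coseg_exclude_cpg,
                cpg_reference=template.upper())
            net.write_graphml(out / "consensus_network.graphml")
            net.write_rdf(out / "consensus_network.rdf")
        except ValueError:
            pass
        summary_lines.append(f"{len(subfams)} subfamilies discovered "
                             f"among {matrix.n_elements} elements")

        # --- ages ------------------------------------------------------
        # each subfamily is dated against its own reconstructed consensus:
        # against the parent template, a derived subfamily's diagnostic
        # mutations would masquerade as age
        age_cfg = dating.AgeConfig(config.rate_non_cpg, config.rate_cpg)
        with open(out / "subfamily_ages.tsv", "w") as fh:
            fh.write("subfamily\tsize\td_non_cpg\td_cpg\tage_non_cpg_my\t"
                     "age_cpg_my\tage_mean_my\n")
            member_seq = dict(elems)
            for i, sf in enumerate(subfams):
                divs = []
                for m in sf.members:
                    aln = divergence.align_to_consensus(member_seq[m],
                                                        sf.consensus)
                    divs.append(divergence.compute_divergence(aln))
                est = dating.pooled_age_estimate(divs, age_cfg)
                fh.write(f"sf{i}\t{sf.size}\t{est.divergence_non_cpg:.4f}\t"
                         f"{est.divergence_cpg:.4f}\t{est.age_non_cpg_my:.2f}\t"
                         f"{est.age_cpg_my:.2f}\t{est.age_mean_my:.2f}\n")

    # --- TinT ---------------------------------------------------------------
    tint = dating.detect_nested_insertions(focal_anns,
                                           config.tint_min_extension)
    tint.counts.to_csv(out / "tint_matrix.tsv", sep="\t")
    try:
        activity = dating.estimate_activity_periods(tint, seed=config.seed)
        dating.activity_table(activity).to_csv(out / "activity.tsv", sep="\t",
                                               index=False)
        order = [e.family for e in sorted(activity, key=lambda e: e.mu)]
        summary_lines.append("TinT activity order (old->young): "
                             + " -> ".join(order))
    except ValueError as exc:
        summary_lines.append(f"TinT activity fit skipped: {exc}")

    # --- manifest -----------------------------------------------------------
    param_hash = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest()
    files = sorted(p for p in out.iterdir()
                   if p.is_file() and p.name not in ("manifest.json", "summary.txt"))
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameter_hash": param_hash,
        "files": {p.name: _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    summary = "\n".join(summary_lines) + "\n"
    (out / "summary.txt").write_text(summary)
    return ReportBundle(out, manifest, summary)
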