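"""End-to-end orchestration: experiment-design expansion and cohort runs.

A *design* lists strain groups (ploidy, chromosome topology, Cre-variant /
inducer-dose labels mapped to an event-rate parameter) with the number of
independent inductions and colonies picked per induction; expanding it gives
one manifest row — and one derived random seed — per simulated strain.  The
pipeline then runs, per strain: recombination simulation -> read simulation
-> QC -> junction calling -> depth/copy-number estimation -> structure
reconstruction -> event classification, and aggregates cohort summaries,
writing deterministic TSV outputs plus a JSON run log.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._mapper import KmerMapper
from .junctions import CallerConfig, call_pipeline, novel_junction_keys, \
    reference_mapper
from .landscape import summarize_cohort, summary_table
from .reads import GenomeSource, QCConfig, ReadSimConfig, emit_reads, \
    qc_filter
from .reconstruct import classify_events, estimate_copy_number, \
    baseline_exclusions, reconstruct_structure, retention_rate, segment_depth
from .refmodel import SegmentedReference, load_reference, random_reference
from .scramble import RearrangementEvent, SignedStructure, SimConfig, \
    diploid_genome, ground_truth_table, simulate_strain, structure_string


class PipelineError(RuntimeError):
    pass


@dataclass
class GroupSpec:
    """One experimental group of the design."""

    label: str
    ploidy: str = "haploid"
    topology: str = "linear"
    cre_variant: str = "Cre_UAG14"
    dose: str = "1mM"
    n_inductions: int = 30
    colonies_per_induction: int = 2
    event_rate: float = 4.0           # Poisson mean events per strain

    def __post_init__(self) -> None:
        if self.n_inductions < 1 or self.colonies_per_induction < 1:
            raise PipelineError("induction/colony counts must be positive")


@dataclass
class DesignSpec:
    groups: list[GroupSpec]
    master_seed: int = 0

    def __post_init__(self) -> None:
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise PipelineError("duplicate group labels in design")


def derive_seed(master_seed: int, group: str, induction: int,
                colony: int) -> int:
    """Stable per-strain seed: first 4 bytes of
    sha256(f"{master_seed}:{group}:{induction}:{colony}") mod 2^31."""
    h = hashlib.sha256(
        f"{master_seed}:{group}:{induction}:{colony}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def expand_design(design: DesignSpec) -> pd.DataFrame:
    """Expand a design into the per-strain run manifest.

    Rows = sum over groups of inductions x colonies; seeds derive from the
    master seed and are guaranteed distinct (hash collisions are bumped
    deterministically).
    """
    rows = []
    used: set[int] = set()
    for g in design.groups:
        for i in range(1, g.n_inductions + 1):
            for c in range(1, g.colonies_per_induction + 1):
                seed = derive_seed(design.master_seed, g.label, i, c)
                while seed in used:
                    seed = (seed + 1) % (2 ** 31)
                used.add(seed)
                rows.append({"strain_id": f"{g.label}_i{i:02d}_c{c}",
                             "group": g.label, "induction": i,
                             "colony": c, "seed": seed})
    manifest = pd.DataFrame(rows)
    expected = sum(g.n_inductions * g.colonies_per_induction
                   for g in design.groups)
    assert len(manifest) == expected
    return manifest


# ---------------------------------------------------------------------------
# config handling
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def reference_from_config(cfg: dict, topology: str | None = None
                          ) -> SegmentedReference:
    ref_cfg = dict(cfg.get("reference", {}))
    if topology is not None:
        ref_cfg["topology"] = topology
    if "fasta" in ref_cfg:
        return load_reference(ref_cfg["fasta"], ref_cfg["loxp_bed"],
                              ref_cfg.get("essential_bed"),
                              tuple(ref_cfg["centromere"]),
                              ref_cfg.get("topology", "linear"))
    return random_reference(
        n_segments=ref_cfg.get("n_segments", 12),
        mean_segment_len=ref_cfg.get("mean_segment_len", 1500),
        topology=ref_cfg.get("topology", "linear"),
        seed=ref_cfg.get("seed", 0))


def design_from_config(cfg: dict, master_seed: int | None = None
                       ) -> DesignSpec:
    d = cfg.get("design", {})
    groups = [GroupSpec(**g) for g in d.get("groups", [])]
    seed = master_seed if master_seed is not None else d.get("master_seed", 0)
    return DesignSpec(groups, seed)


# ---------------------------------------------------------------------------
# single-strain processing
# ---------------------------------------------------------------------------

@dataclass
class StrainResult:
    strain_id: str
    group: str
    truth_events: list[RearrangementEvent]
    truth_structure: object
    detected_events: list[RearrangementEvent]
    structures: list
    status: str
    copies: np.ndarray
    retention: float
    junctions: pd.DataFrame
    caller_stats: dict
    truth_novel: set = field(default_factory=set)
    detected_novel: set = field(default_factory=set)


def process_strain(ref: SegmentedReference, strain_id: str, group: GroupSpec,
                   seed: int, cfg: dict,
                   shared: dict) -> StrainResult:
    """Run the full per-strain pipeline (simulate -> reads -> call ->
    reconstruct -> classify)."""
    sim_cfg = SimConfig(
        n_events=group.event_rate, poisson=True,
        type_probs=tuple(cfg.get("simulate", {}).get(
            "type_probs", (1 / 3, 1 / 3, 1 / 3))),
        ploidy=group.ploidy,
        max_resample=cfg.get("simulate", {}).get("max_resample", 200),
        seed=seed)
    truth = simulate_strain(ref, sim_cfg)

    reads_cfg_d = cfg.get("reads", {})
    read_cfg = ReadSimConfig(
        read_len=reads_cfg_d.get("read_len", 100),
        mean_depth=reads_cfg_d.get("mean_depth", 100.0),
        insert_mean=reads_cfg_d.get("insert_mean", 300),
        insert_sd=reads_cfg_d.get("insert_sd", 30.0),
        error_rate=reads_cfg_d.get("error_rate", 0.001),
        seed=(seed + 1) % (2 ** 31))
    circular = ref.topology == "circular"
    native_seq = None
    if group.ploidy == "diploid":
        syn, native_seq, _snps = diploid_genome(
            ref, truth.structure,
            snp_density=cfg.get("diploid", {}).get("snp_density", 0.01),
            seed=shared["native_seed"])
        genomes = [GenomeSource("syn", syn, 1.0, circular),
                   GenomeSource("native", native_seq, 1.0, circular)]
    else:
        genomes = [GenomeSource("syn", truth.structure.sequence(ref), 1.0,
                                circular)]
    pairs = emit_reads(genomes, read_cfg)
    pairs, _qc = qc_filter(pairs, QCConfig(**cfg.get("qc", {})))

    caller_cfg = CallerConfig(**cfg.get("caller", {}))
    extra = [native_seq] if native_seq else []
    mapper = shared.get("mapper")
    if native_seq is not None:
        mapper = shared.get("diploid_mapper")
    junctions, stats = call_pipeline(pairs, ref, caller_cfg,
                                     extra_ref_seqs=extra, mapper=mapper)
    depths = segment_depth(
        pairs, ref, native_seq=native_seq,
        mapper=shared.get("depth_mapper"),
        native_mapper=shared.get("native_depth_mapper"))
    profile = estimate_copy_number(
        depths, exclude=baseline_exclusions(ref, junctions),
        anchor_index=ref.centromere_id() - 1)
    structures, status, _diag = reconstruct_structure(
        junctions, profile.copies, ref)
    # events come from the walk-invariant junction/copy signature, never
    # from one arbitrarily chosen walk of an ambiguous reconstruction
    detected = classify_events(ref, junction_df=junctions,
                               copies=profile.copies)
    truth_novel = {j for j in _structure_novel(ref, truth.structure)}
    detected_novel = novel_junction_keys(junctions)
    return StrainResult(
        strain_id=strain_id, group=group.label,
        truth_events=truth.events, truth_structure=truth.structure,
        detected_events=detected, structures=structures, status=status,
        copies=profile.copies,
        retention=retention_rate(profile.copies, ref),
        junctions=junctions, caller_stats=stats,
        truth_novel=truth_novel, detected_novel=detected_novel)


def _structure_novel(ref, structure):
    from .reconstruct import _structure_junctions
    return _structure_junctions(structure) - ref.parental_junctions()


# ---------------------------------------------------------------------------
# cohort run
# ---------------------------------------------------------------------------

def run_pipeline(cfg: dict, outdir, master_seed: int | None = None,
                 write_reads: bool = False) -> dict:
    """Execute a whole design and write deterministic outputs.

    Writes per-cohort TSVs (ground-truth events, called events, junctions,
    copy numbers, structures, summaries) and ``run_log.json`` under
    ``outdir``; returns the in-memory results keyed by strain id.  Reruns
    with the same config and master seed are byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = design_from_config(cfg, master_seed)
    manifest = expand_design(design)
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)

    groups = {g.label: g for g in design.groups}
    topologies = {g.topology for g in design.groups}
    refs = {t: reference_from_config(cfg, topology=t) for t in topologies}
    shared_by_topo = {}
    for t, ref in refs.items():
        m = reference_mapper(ref)
        shared_by_topo[t] = {
            "mapper": m,
            "depth_mapper": m,
            "native_seed": design.master_seed,
        }

    results: dict[str, StrainResult] = {}
    truth_rows, called_rows, junc_rows, copy_rows, struct_rows = \
        [], [], [], [], []
    for row in manifest.itertuples():
        group = groups[row.group]
        ref = refs[group.topology]
        shared = shared_by_topo[group.topology]
        if group.ploidy == "diploid" and "native_depth_mapper" not in shared:
            _syn, native_seq, _ = diploid_genome(
                ref, SignedStructure.reference(ref),
                snp_density=cfg.get("diploid", {}).get("snp_density", 0.01),
                seed=shared["native_seed"])
            ext = native_seq + native_seq[:99] \
                if ref.topology == "circular" else native_seq
            shared["native_depth_mapper"] = KmerMapper([ext])
            shared["diploid_mapper"] = reference_mapper(ref, [ext])
        try:
            res = process_strain(ref, row.strain_id, group, int(row.seed),
                                 cfg, shared)
        except Exception as exc:          # noqa: BLE001 - report stage+strain
            raise PipelineError(
                f"strain {row.strain_id}: {exc}") from exc
        results[row.strain_id] = res
        truth_rows.extend(ground_truth_table(row.strain_id,
                                             res.truth_events))
        for ev in res.detected_events:
            called_rows.append({
                "strain_id": row.strain_id, "type": ev.type,
                "segments": ",".join(map(str, ev.segments)),
                "loxp_loci": f"{ev.loci[0]},{ev.loci[1]}"})
        for r in res.junctions.itertuples(index=False):
            junc_rows.append({"strain_id": row.strain_id,
                              **r._asdict()})
        copy_rows.append({"strain_id": row.strain_id,
                          **{f"seg{i + 1}": int(c)
                             for i, c in enumerate(res.copies)}})
        struct_rows.append({
            "strain_id": row.strain_id, "status": res.status,
            "structure": structure_string(res.structures[0])
            if res.structures else "",
            "truth_structure": structure_string(res.truth_structure),
            "retention": f"{res.retention:.2f}"})
        if write_reads:
            pass   # FASTQ export is handled by the CLI `simulate` command

    for name, rows in (("ground_truth_events", truth_rows),
                       ("called_events", called_rows),
                       ("junctions", junc_rows),
                       ("copy_numbers", copy_rows),
                       ("structures", struct_rows)):
        pd.DataFrame(rows).to_csv(outdir / f"{name}.tsv", sep="\t",
                                  index=False)

    # cohort summaries per group, from *called* events
    summaries = []
    for label, g in groups.items():
        ids = [s for s in results if results[s].group == label]
        ref = refs[g.topology]
        summary = summarize_cohort(
            {s: results[s].detected_events for s in ids}, ref,
            retention={s: results[s].retention for s in ids})
        summaries.append(summary_table(summary, label))
    pd.concat(summaries, ignore_index=True).to_csv(
        outdir / "cohort_summary.tsv", sep="\t", index=False)

    # ground-truth agreement metrics
    tp = sum(len(r.truth_novel & r.detected_novel) for r in results.values())
    fp = sum(len(r.detected_novel - r.truth_novel) for r in results.values())
    fn = sum(len(r.truth_novel - r.detected_novel) for r in results.values())
    exact = sum(
        classify_events(refs[groups[r.group].topology],
                        structure=r.truth_structure) == r.detected_events
        for r in results.values())
    log = {
        "version": __version__,
        "master_seed": design.master_seed,
        "n_strains": len(results),
        "junction_precision": tp / (tp + fp) if tp + fp else 1.0,
        "junction_recall": tp / (tp + fn) if tp + fn else 1.0,
        "event_list_exact_fraction": exact / len(results) if results else 0,
        "statuses": {s: sum(1 for r in results.values() if r.status == s)
                     for s in ("unique", "ambiguous", "inconsistent")},
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return {"results": results, "manifest": manifest, "log": log,
            "refs": refs}
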