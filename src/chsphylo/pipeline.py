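"""End-to-end pipeline: simulate -> scan -> trim -> trees -> classify ->
HGT -> recombination.

Every stage reads and writes standard formats in a single output directory,
so any stage can be rerun or inspected in isolation; a run report reconciles
sequence counts across stages.  All coordinates written are 0-based,
half-open.  Deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .chimera import detect_chimera, locate_breakpoint, write_chimera_reports
from .classify import (DEFAULT_SUPPORT_MIN, define_classes,
                       read_class_proposals, write_class_definitions)
from .hgt import (DEFAULT_STEP, DEFAULT_WINDOW, DEFAULT_Z_MIN, HgtCall,
                  combine_evidence, detect_cotransfer,
                  detect_incongruent_leaves, gc_anomaly, gc_windows,
                  write_hgt_calls)
from .io import (Alignment, NeighborhoodTable, read_alignment, read_fasta,
                 read_taxon_map, write_alignment, write_newick)
from .motifs import (QXXXY, build_pssm, calibrate_threshold,
                     detect_motif_duplication, filter_candidates, pssm_scan)
from .phylo import bootstrap_support, flag_long_branches, root_by_outgroup
from .simulate import OUTGROUP_GROUP, EventRates, FixtureConfig, emit_fixture
from .trim import trim_alignment, write_index_map

ALL_STAGES = ("simulate", "scan", "trim", "tree", "classify", "hgt", "recomb")


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class PipelineConfig:
    """Pipeline parameters; printed defaults follow the study conventions:
    100 bootstrap replicates, support threshold 60, G+C windows of 1000 bp
    at a 30 bp step, |z| >= 2 composition anomaly."""

    out_dir: str = "chsphylo_out"
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    # simulate
    fixture: FixtureConfig = field(default_factory=lambda: FixtureConfig(
        rates=EventRates(duplication_rate=0.6, loss_rate=0.15),
        n_forced_hgt=3, n_recombinants=1, n_decayed=3))
    # scan
    pssm_block_width: int = 40
    pssm_pseudocount: float = 1.0
    pssm_calibration_shuffles: int = 1000
    # trim
    score_cutoff: float = 0.5
    gap_cutoff: float = 0.5
    smoothing_window: int = 3
    trim_mode: str = "entropy"
    # tree
    bootstrap_reps: int = 100
    corrections: tuple[str, str] = ("p", "poisson")
    k_long_branch: float = 4.0
    # classify / hgt / recomb
    support_min: int = DEFAULT_SUPPORT_MIN
    class_proposals: str | None = None  # TSV path; simulated truth if None
    gc_window: int = DEFAULT_WINDOW
    gc_step: int = DEFAULT_STEP
    z_min: float = DEFAULT_Z_MIN
    jaccard_min: float = 0.5
    # sequences to drop before tree inference (e.g. chimeras flagged by a
    # previous run's recomb stage, or long-branch leaves)
    exclude: tuple[str, ...] = ()
    # non-simulated inputs (used when the simulate stage is disabled)
    proteins: str | None = None
    alignment: str | None = None
    taxon_map: str | None = None

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages {sorted(unknown)}")
        if not 0 <= self.score_cutoff <= 1 or not 0 <= self.gap_cutoff <= 1:
            raise ConfigError("trim cutoffs must be in [0,1]")
        if not 0 <= self.support_min <= 100:
            raise ConfigError("support_min must be in [0,100]")
        if self.bootstrap_reps < 1:
            raise ConfigError("bootstrap_reps must be >= 1")
        if self.gc_window < 1 or self.gc_step < 1:
            raise ConfigError("gc window/step must be >= 1")
        if not 0 <= self.jaccard_min <= 1:
            raise ConfigError("jaccard_min must be in [0,1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fixture_raw = raw.pop("fixture", None)
        cfg = cls(**raw)
        if fixture_raw:
            rates = EventRates(**fixture_raw.pop("rates", {}))
            cfg.fixture = FixtureConfig(rates=rates, **fixture_raw)
        if isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        return cfg


@dataclass
class RunReport:
    config: dict[str, Any]
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)
    wall_time_s: float = 0.0
    version: str = ""

    def validate_counts(self) -> None:
        """Counts must reconcile across consecutive stages."""
        s = self.stages
        if "scan" in s:
            if s["scan"]["kept"] + s["scan"]["dubious"] != s["scan"]["scanned"]:
                raise AssertionError("scan counts do not reconcile")
        if "trim" in s and "scan" in s:
            expect = (s["scan"]["kept"] + s["trim"].get("outgroup", 0)
                      - s["trim"].get("excluded", 0))
            if s["trim"]["sequences"] != expect:
                raise AssertionError("trim input != scan kept + outgroup "
                                     "- excluded")

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"version": self.version, "wall_time_s": self.wall_time_s,
                       "stages": self.stages, "config": self.config},
                      fh, indent=2, default=str)
            fh.write("\n")


def run_pipeline(config: PipelineConfig) -> RunReport:
    config.validate()
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=asdict(config), version=__version__)
    rng = np.random.default_rng(config.seed)
    seeds = {name: int(s) for name, s in
             zip(ALL_STAGES, rng.integers(2 ** 31, size=len(ALL_STAGES)))}

    dataset = None
    if "simulate" in config.stages:
        dataset = emit_fixture(config.fixture, seeds["simulate"], out)
        report.stages["simulate"] = {
            "genes": len(dataset.genes),
            "events": len(dataset.events),
            "hgt_events": sum(e.kind == "hgt" for e in dataset.events),
        }

    # resolve inputs
    def need(path: str | None, stage: str, what: str) -> Path:
        if path is None:
            raise ConfigError(f"stage {stage!r} needs {what} "
                              "(enable simulate or provide the path)")
        return Path(path)

    if dataset is not None:
        proteins = {g.gene_id: g.protein for g in dataset.genes}
        aln = dataset.alignment
        taxon_map = dataset.taxon_map
    else:
        proteins = aln = taxon_map = None
        if any(s in config.stages for s in ALL_STAGES[1:]):
            proteins = read_fasta(need(config.proteins, "scan", "proteins"))
            aln = read_alignment(need(config.alignment, "trim", "alignment"))
            taxon_map = read_taxon_map(need(config.taxon_map, "tree",
                                            "taxon map"))
    groups = ({sid: grp for sid, (_t, grp) in taxon_map.items()}
              if taxon_map else {})
    outgroup_ids = sorted(sid for sid, g in groups.items()
                          if g == OUTGROUP_GROUP)

    kept_ids = sorted(proteins) if proteins else []
    if "scan" in config.stages:
        kept_ids = _stage_scan(config, proteins, aln, outgroup_ids, out,
                               seeds["scan"], report)

    trimmed = None
    if "trim" in config.stages:
        ids = [i for i in aln.ids
               if (i in set(kept_ids) or i in outgroup_ids)
               and i not in set(config.exclude)]
        sub = aln.subset(ids)
        trimmed, index_map = trim_alignment(
            sub, config.score_cutoff, config.gap_cutoff,
            config.smoothing_window, mode=config.trim_mode)
        write_alignment(trimmed, out / "trimmed_alignment.fasta")
        write_index_map(index_map, out / "trimmed_columns.tsv")
        n_excluded = len(set(kept_ids) & set(config.exclude) & set(aln.ids))
        report.stages["trim"] = {"sequences": trimmed.n_rows,
                                 "outgroup": len([i for i in ids
                                                  if i in outgroup_ids]),
                                 "excluded": n_excluded,
                                 "columns_in": sub.width,
                                 "columns_kept": trimmed.width}

    trees = {}
    if "tree" in config.stages:
        if trimmed is None:
            raise ConfigError("stage 'tree' needs the trim stage output")
        for k, corr in enumerate(config.corrections):
            tree = bootstrap_support(trimmed, n_reps=config.bootstrap_reps,
                                     correction=corr, seed=seeds["tree"] + k)
            if outgroup_ids:
                present = [i for i in outgroup_ids if i in trimmed.ids]
                if present:
                    tree = root_by_outgroup(tree, present)
            trees[corr] = tree
            write_newick(tree, out / f"tree_{corr}.nwk")
        long_branches = flag_long_branches(trees[config.corrections[0]],
                                           k=config.k_long_branch)
        report.stages["tree"] = {
            "corrections": list(config.corrections),
            "bootstrap_reps": config.bootstrap_reps,
            "long_branch_flags": long_branches,
            "discarded_replicates": {
                c: getattr(t, "discarded_replicates", 0)
                for c, t in trees.items()},
        }

    if "classify" in config.stages and trees:
        if config.class_proposals:
            proposals = read_class_proposals(config.class_proposals)
        elif dataset is not None:
            proposals = {}
            in_tree = set(trimmed.ids)
            for g in dataset.genes:
                if g.true_class and g.gene_id in in_tree:
                    proposals.setdefault(g.true_class, set()).add(g.gene_id)
        else:
            proposals = {}
        accepted, rejected = define_classes(
            trees[config.corrections[0]], trees[config.corrections[1]],
            proposals, support_min=config.support_min)
        write_class_definitions(accepted, out / "classes.tsv")
        report.stages["classify"] = {
            "proposed": len(proposals), "accepted": len(accepted),
            "rejected": [{"class": n, "reason": r} for n, r in rejected]}

    if "hgt" in config.stages and trees:
        calls = _stage_hgt(config, dataset, trees[config.corrections[0]],
                           groups, out)
        report.stages["hgt"] = {
            "calls_strong": sum(c.verdict == "strong" for c in calls),
            "calls_weak": sum(c.verdict == "weak" for c in calls),
            "evaluated": len(calls)}

    if "recomb" in config.stages:
        reports = _stage_recomb(config, proteins, aln, groups, outgroup_ids,
                                out, seeds["recomb"])
        report.stages["recomb"] = {
            "queries": len(reports),
            "chimeric": sum(r.chimeric for r in reports)}

    report.wall_time_s = round(time.time() - t0, 3)
    report.validate_counts()
    report.write(out / "run_report.json")
    return report


def _stage_scan(config, proteins, aln, outgroup_ids, out, seed, report):
    from .io import CodingGene
    ids = sorted(proteins)
    # PSSM from the most conserved block of the reference alignment
    ref = aln.subset([i for i in aln.ids if i not in outgroup_ids])
    pssm = _block_pssm(ref, config.pssm_block_width, config.pssm_pseudocount)
    longest = max(proteins.values(), key=len)
    pssm.threshold = calibrate_threshold(
        pssm, longest, n_shuffles=config.pssm_calibration_shuffles, seed=seed)
    pssm.write(out / "pssm.txt")
    hits = {i: pssm_scan(pssm, proteins[i]) for i in ids}
    candidates = [i for i in ids if hits[i] and i not in outgroup_ids]
    genes = [CodingGene(gene_id=i, taxon=i.split("|")[0], protein=proteins[i])
             for i in candidates]
    kept, dubious = filter_candidates(genes)
    with open(out / "scan_results.tsv", "w") as fh:
        fh.write("seq_id\tpssm_hits\tbest_score\tmotifs_complete\n")
        kept_ids = {g.gene_id for g in kept}
        for i in candidates:
            best = f"{hits[i][0][1]:.2f}" if hits[i] else ""
            fh.write(f"{i}\t{len(hits[i])}\t{best}\t{int(i in kept_ids)}\n")
    report.stages["scan"] = {"scanned": len(candidates),
                             "kept": len(kept), "dubious": len(dubious),
                             "pssm_threshold": round(pssm.threshold, 3)}
    return [g.gene_id for g in kept]


def _block_pssm(ref: Alignment, width: int, pseudocount: float):
    from .trim import score_columns
    scores = score_columns(ref, mode="similarity")
    if ref.width <= width:
        best = 0
        width = ref.width
    else:
        sums = np.convolve(scores, np.ones(width), mode="valid")
        best = int(np.argmax(sums))
    block = ref.columns(range(best, best + width))
    return build_pssm(block, pseudocount=pseudocount)


def _stage_hgt(config, dataset, tree, groups, out):
    ignore = {OUTGROUP_GROUP, "recombinant"}
    in_tree = {lf.taxon.label for lf in tree.leaf_node_iter()}
    leaf_groups = {lb: groups[lb] for lb in in_tree}
    incongruent = detect_incongruent_leaves(
        tree, leaf_groups, support_min=config.support_min,
        ignore_groups=ignore)
    inc_by_id = {leaf: (host, foreign, sup)
                 for leaf, host, foreign, sup in incongruent}

    records: dict[str, HgtCall] = {
        sid: HgtCall(seq_id=sid) for sid in sorted(in_tree)
        if groups.get(sid) not in ignore}
    for sid, (host, foreign, sup) in inc_by_id.items():
        if sid in records:
            records[sid].incongruent = True
            records[sid].foreign_group = foreign
            records[sid].incongruence_support = sup

    if dataset is not None:
        backgrounds = {genome: gc_windows(seq, config.gc_window, config.gc_step)
                       for genome, seq in dataset.contexts.items()}
        for g in dataset.genes:
            if g.gene_id not in records or g.cds is None:
                continue
            bg = backgrounds.get(g.taxon)
            if bg is None or not bg.values:
                continue
            z, flag = gc_anomaly(g.cds, bg, z_min=config.z_min)
            records[g.gene_id].composition_z = z
            records[g.gene_id].composition_flag = flag
        nb = dataset.neighborhoods
        focal = [gid for gid in nb.gene_ids if gid in records]
        taxon_groups = {t: grp for _sid, (t, grp) in dataset.taxon_map.items()}
        cotransfer = detect_cotransfer(nb, taxon_groups, focal,
                                       jaccard_min=config.jaccard_min)
        for grp in cotransfer:
            for gid in grp.gene_ids:
                if gid in records:
                    records[gid].synteny_flag = True
                    records[gid].synteny_partners = grp.genomes

    calls = combine_evidence(list(records.values()))
    write_hgt_calls(calls, out / "hgt_calls.tsv")
    return calls


def _stage_recomb(config, proteins, aln, groups, outgroup_ids, out, seed):
    reports = []
    ignore = {OUTGROUP_GROUP, "recombinant"}
    in_aln = set(aln.ids)
    for sid in sorted(proteins):
        if sid not in in_aln:
            continue
        if len(detect_motif_duplication(proteins[sid], QXXXY)) < 2:
            continue
        row = aln.row(sid)
        bp = locate_breakpoint(row, QXXXY, pair="closest")
        if bp is None:
            continue
        refs = {i: groups[i] for i in aln.ids
                if i != sid and groups.get(i) not in ignore
                and i in groups}
        if len(set(refs.values())) < 2:
            continue
        sub_ids = [i for i in aln.ids
                   if i in refs or i == sid or i in outgroup_ids]
        sub = aln.subset(sub_ids)
        try:
            rep = detect_chimera(sub, sid, refs, bp,
                                 support_min=config.support_min,
                                 outgroup=[i for i in outgroup_ids
                                           if i in sub_ids],
                                 n_reps=config.bootstrap_reps, seed=seed)
        except ValueError:
            continue
        reports.append(rep)
    write_chimera_reports(reports, out / "chimera_reports.tsv")
    return reports
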