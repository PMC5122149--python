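"""End-to-end validation metrics computed by running the package.

Each function here builds simulated inputs with known ground truth, runs
the corresponding inference chain, and measures recovery.  The test suite
asserts thresholds on these numbers and the reproduction script reports
them; nothing here is used by the inference code itself.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np

from .chimera import detect_chimera, locate_breakpoint
from .classify import define_classes
from .hgt import (HgtCall, combine_evidence, detect_cotransfer,
                  detect_incongruent_leaves, gc_anomaly, gc_windows)
from .motifs import filter_candidates
from .oracles import (all_unrooted_topologies, min_ols_topology,
                      near_additive_matrix, patristic_matrix,
                      random_unrooted_tree)
from .phylo import (DistanceMatrix, bootstrap_support, nj_tree, rf_distance,
                    root_by_outgroup)
from .pipeline import PipelineConfig, run_pipeline
from .simulate import (OUTGROUP_GROUP, FixtureConfig, SimulatedDataset,
                       generate_class_dataset, generate_dataset,
                       make_recombinant_aligned)


def nj_additive_recovery(n_trials: int = 100, seed: int = 0) -> dict:
    """Fraction of tree-derived additive matrices from which NJ recovers
    the generating topology exactly (RF distance 0)."""
    rng = np.random.default_rng(seed)
    ok = 0
    for _ in range(n_trials):
        n = int(rng.integers(4, 13))
        labels = [f"L{i:02d}" for i in range(n)]
        gen = random_unrooted_tree(labels, rng)
        D = patristic_matrix(gen, labels)
        ok += rf_distance(nj_tree(DistanceMatrix(labels, D)), gen) == 0
    return {"rate": ok / n_trials, "n": n_trials}


def nj_ols_agreement(n_trials: int = 100, seed: int = 0) -> dict:
    """Fraction of near-additive 6-taxon matrices on which NJ's topology
    equals the exhaustive minimum-OLS topology over all 105 trees."""
    rng = np.random.default_rng(seed)
    labels = [f"L{i}" for i in range(6)]
    topologies = all_unrooted_topologies(labels)
    ok = 0
    for _ in range(n_trials):
        D, _gen = near_additive_matrix(labels, rng)
        nj = nj_tree(DistanceMatrix(labels, D))
        best = min_ols_topology(labels, D, topologies)
        ok += rf_distance(nj, best) == 0
    return {"rate": ok / n_trials, "n": n_trials}


def gc_window_oracle(n_cases: int = 25, seed: int = 0) -> dict:
    """Exact agreement of the sliding-window G+C profile with a brute-force
    per-window counter, plus the window-count law at the 1000/30 defaults."""
    rng = np.random.default_rng(seed)
    mismatches = 0
    checked = 0
    for _ in range(n_cases):
        L = int(rng.integers(1000, 4000))
        seq = "".join(rng.choice(list("ACGTN"), L))
        prof = gc_windows(seq)  # window=1000, step=30
        if len(prof.starts) != (L - 1000) // 30 + 1:
            mismatches += 1
        for s, v in zip(prof.starts, prof.values):
            win = seq[s:s + 1000]
            gc = sum(c in "GC" for c in win)
            tot = sum(c in "ACGT" for c in win)
            checked += 1
            if abs(v - gc / tot) > 1e-12:
                mismatches += 1
    return {"mismatches": mismatches, "windows_checked": checked,
            "n": n_cases}


def motif_filter_recovery(seed: int = 0, ks=(0, 3, 10)) -> dict:
    """For fixtures with k motif-decayed genes, the filter must mark exactly
    those k as dubious.  Returns the total misclassification count."""
    rng = np.random.default_rng(seed)
    errors = 0
    total = 0
    for k in ks:
        cfg = FixtureConfig(n_decayed=k, n_forced_hgt=0, n_recombinants=0)
        ds = generate_dataset(cfg, int(rng.integers(2 ** 31)))
        genes = [g for g in ds.genes if not g.taxon.startswith("outg")]
        _kept, dubious = filter_candidates(genes)
        got = {g.gene_id for g in dubious}
        errors += len(got ^ ds.decayed_ids)
        total += len(genes)
    return {"errors": errors, "genes_checked": total, "n": len(ks)}


def evaluate_hgt_calls(ds: SimulatedDataset, seed: int,
                       support_min: int = 60, z_min: float = 2.0,
                       jaccard_min: float = 0.5,
                       n_bootstrap: int = 100) -> list[HgtCall]:
    """Run the three evidence lines on one dataset and combine them."""
    tree = root_by_outgroup(
        bootstrap_support(ds.alignment, n_bootstrap, "p", seed=seed),
        ds.outgroup_ids)
    groups = {sid: grp for sid, (_t, grp) in ds.taxon_map.items()}
    leaf_groups = {lf.taxon.label: groups[lf.taxon.label]
                   for lf in tree.leaf_node_iter()}
    incongruent = detect_incongruent_leaves(
        tree, leaf_groups, support_min=support_min,
        ignore_groups={OUTGROUP_GROUP})
    records = {sid: HgtCall(seq_id=sid) for sid in sorted(leaf_groups)
               if leaf_groups[sid] != OUTGROUP_GROUP}
    for leaf, _host, foreign, sup in incongruent:
        records[leaf].incongruent = True
        records[leaf].foreign_group = foreign
        records[leaf].incongruence_support = sup
    backgrounds = {genome: gc_windows(seq)
                   for genome, seq in ds.contexts.items()}
    for g in ds.genes:
        if g.gene_id not in records or g.cds is None:
            continue
        bg = backgrounds.get(g.taxon)
        if bg is None or not bg.values:
            continue
        z, flag = gc_anomaly(g.cds, bg, z_min=z_min)
        records[g.gene_id].composition_z = z
        records[g.gene_id].composition_flag = flag
    taxon_groups = {t: grp for _s, (t, grp) in ds.taxon_map.items()}
    comps = detect_cotransfer(ds.neighborhoods, taxon_groups,
                              [gid for gid in ds.neighborhoods.gene_ids
                               if gid in records],
                              jaccard_min=jaccard_min)
    for comp in comps:
        for gid in comp.gene_ids:
            if gid in records:
                records[gid].synteny_flag = True
                records[gid].synteny_partners = comp.genomes
    return combine_evidence(list(records.values()))


def hgt_recovery(n_replicates: int = 20, seed: int = 0,
                 n_bootstrap: int = 100) -> dict:
    """Recall/precision of strong combined calls against the event log over
    replicate simulations with 3 planted recent transfers each."""
    rng = np.random.default_rng(seed)
    tp = fp = fn = 0
    all_strong_reps = 0
    for _ in range(n_replicates):
        s = int(rng.integers(2 ** 31))
        ds = generate_dataset(FixtureConfig(n_forced_hgt=3), s)
        calls = evaluate_hgt_calls(ds, seed=s % (2 ** 31 - 1) + 1,
                                   n_bootstrap=n_bootstrap)
        strong = {c.seq_id for c in calls if c.verdict == "strong"}
        truth = ds.hgt_gene_ids
        tp += len(strong & truth)
        fp += len(strong - truth)
        fn += len(truth - strong)
        all_strong_reps += truth <= strong
    return {"recall": tp / (tp + fn) if tp + fn else 0.0,
            "precision": tp / (tp + fp) if tp + fp else 0.0,
            "replicates_all_strong": all_strong_reps,
            "n": n_replicates}


def chimera_recovery(seed: int = 0, n_chimeras: int = 10,
                     n_controls: int = 10, n_bootstrap: int = 100) -> dict:
    """Verdict accuracy over planted chimeras and non-recombinant controls
    (controls counted correct only with a negative verdict)."""
    rng = np.random.default_rng(seed)
    ds = generate_class_dataset(FixtureConfig(), int(rng.integers(2 ** 31)),
                                n_classes=2, within_depth=0.1,
                                between_stem=0.2)
    groups = {g.gene_id: g.true_class for g in ds.genes if g.true_class}
    c1 = sorted(g for g, c in groups.items() if c == "C1")
    c2 = sorted(g for g, c in groups.items() if c == "C2")
    correct = 0
    false_pos = 0
    for i in range(n_chimeras):
        aln2, _chim = make_recombinant_aligned(
            ds.alignment, c2[i % len(c2)], c1[(i + 1) % len(c1)],
            new_id=f"q{i}|chim")
        bp = locate_breakpoint(aln2.row(f"q{i}|chim"), pair="closest")
        rep = detect_chimera(aln2, f"q{i}|chim", groups, bp,
                             outgroup=ds.outgroup_ids,
                             n_reps=n_bootstrap,
                             seed=int(rng.integers(2 ** 31)))
        correct += rep.chimeric
    controls = (c1 + c2)[:n_controls]
    mid = ds.alignment.width // 2
    for q in controls:
        refs = {g: c for g, c in groups.items() if g != q}
        rep = detect_chimera(ds.alignment, q, refs, mid,
                             outgroup=ds.outgroup_ids,
                             n_reps=n_bootstrap,
                             seed=int(rng.integers(2 ** 31)))
        correct += not rep.chimeric
        false_pos += rep.chimeric
    return {"accuracy": correct / (n_chimeras + n_controls),
            "false_positives": false_pos,
            "n": n_chimeras + n_controls}


def class_concordance(n_replicates: int = 20, seed: int = 0,
                      n_bootstrap: int = 100) -> dict:
    """Fraction of replicate simulations in which all 3 planted classes are
    accepted as well-supported monophyletic groups under both distance
    settings."""
    rng = np.random.default_rng(seed)
    ok = 0
    for _ in range(n_replicates):
        s = int(rng.integers(2 ** 31))
        ds = generate_class_dataset(FixtureConfig(), s, n_classes=3,
                                    within_depth=0.05, between_stem=0.2)
        truth: dict[str, set[str]] = {}
        for g in ds.genes:
            if g.true_class:
                truth.setdefault(g.true_class, set()).add(g.gene_id)
        trees = []
        for k, corr in enumerate(("p", "poisson")):
            t = bootstrap_support(ds.alignment, n_bootstrap, corr,
                                  seed=(s + k) % (2 ** 31))
            trees.append(root_by_outgroup(t, ds.outgroup_ids))
        accepted, _rejected = define_classes(trees[0], trees[1], truth,
                                             support_min=60)
        ok += len(accepted) == len(truth)
    return {"rate": ok / n_replicates, "n": n_replicates}


def pipeline_determinism(seed: int = 0, work_dir: str | Path = None) -> dict:
    """Byte-identity of every artifact across two full pipeline runs with
    the same seed (the run report is compared without its wall time)."""
    import tempfile
    base = Path(work_dir) if work_dir else Path(tempfile.mkdtemp())
    sums = []
    reports = []
    for run in (1, 2):
        out = base / f"run{run}"
        report = run_pipeline(PipelineConfig(out_dir=str(out), seed=seed))
        reports.append(report.stages)
        sums.append({p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                     for p in sorted(out.iterdir())
                     if p.name != "run_report.json"})
    identical = sums[0] == sums[1] and reports[0] == reports[1]
    return {"identical": float(identical), "n_files": len(sums[0])}
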