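"""Configuration-driven orchestration of the two reconstruction tracks.

The pipeline reads a YAML/JSON config (or a :class:`PipelineConfig` built in
code), runs the thermometer track and/or the gene-content track (with the
clustering front end when only a hit table is given), writes TSV/JSON
outputs under the configured directory and returns a machine-readable run
report.  Identical config + seeds produce byte-identical outputs.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import famclust, genefam_bd, thermometer
from .phylo_core import (
    Tree,
    parse_newick,
    assign_internal_labels,
    read_node_label_map,
)

__all__ = ["PipelineConfig", "run_thermometer", "run_gene_content", "run_all"]


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; file paths may be None for unused tracks."""

    tree: str | None = None
    alignment: str | None = None
    stem_annotations: str | None = None
    ogt_table: str | None = None
    hits: str | None = None
    lengths: str | None = None
    seq2genome: str | None = None
    occurrence_matrix: str | None = None
    node_labels: str | None = None
    outdir: str = "ancrec_out"
    # thresholds / sizes (defaults: posterior threshold 0.5, 100 replicates)
    tau: float = 0.5
    cmax: int = 10
    replicates: int = 100
    min_identity: float = 35.0
    min_coverage: float = 0.70
    max_evalue: float = 1e-4
    consensus_fraction: float = 1.0
    seed: int = 0
    fit_multi_start: int = 3
    fit_duplication: bool = True
    run_thermometer_track: bool = True
    run_gene_content_track: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self, *, need_thermometer: bool, need_content: bool) -> None:
        if not 0 < self.tau < 1:
            raise ValueError("tau must be in (0, 1)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        missing = []
        if self.tree is None:
            missing.append("tree")
        if need_thermometer:
            for key in ("alignment", "ogt_table"):
                if getattr(self, key) is None:
                    missing.append(key)
        if need_content and self.occurrence_matrix is None:
            for key in ("hits", "lengths", "seq2genome"):
                if getattr(self, key) is None:
                    missing.append(key)
        if missing:
            raise ValueError(f"config missing required fields: {missing}")
        for key in (
            "tree", "alignment", "stem_annotations", "ogt_table", "hits",
            "lengths", "seq2genome", "occurrence_matrix", "node_labels",
        ):
            val = getattr(self, key)
            if val is not None and not Path(val).exists():
                raise FileNotFoundError(f"{key}: no such file: {val}")


def _load_tree(config: PipelineConfig) -> Tree:
    tree = parse_newick(Path(config.tree).read_text())
    label_map = (
        read_node_label_map(config.node_labels) if config.node_labels else None
    )
    assign_internal_labels(tree, label_map)
    return tree


def _node_name(tree: Tree, nid: int) -> str:
    return tree.nodes[nid].label or f"node{nid}"


def run_thermometer(config: PipelineConfig, log: list[str] | None = None) -> dict:
    """Thermometer track: calibration, model fit, ancestral OGTs with CIs."""
    config.validate(need_thermometer=True, need_content=False)
    log = log if log is not None else []
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree = _load_tree(config)
    aln = thermometer.read_fasta_alignment(config.alignment)
    if config.stem_annotations:
        positions = thermometer.read_stem_annotations(config.stem_annotations)
        aln.stem_mask = thermometer.build_stem_mask(
            aln, positions, consensus_fraction=config.consensus_fraction
        )
    else:
        aln.stem_mask = np.ones(aln.length, dtype=bool)
        log.append("no stem annotations given; all columns treated as stem")
    ogt = thermometer.read_ogt_table(config.ogt_table)
    no_ogt = sorted(set(aln.labels) - set(ogt))
    if no_ogt:
        log.append(f"taxa without OGT (used for ASR, not calibration): {no_ogt}")
    fit_config = thermometer.FitConfig(
        multi_start=config.fit_multi_start, seed=config.seed
    )
    sub, calib, model, reps, estimates, dropped = thermometer.run_thermometer_track(
        tree, aln, ogt, R=config.replicates, seed=config.seed, fit_config=fit_config
    )
    for taxon in dropped:
        log.append(f"pruned taxon without 16S sequence: {taxon}")
    if not model.converged:
        log.append("model fit did not satisfy the convergence criterion")

    with open(outdir / "calibration.json", "w") as fh:
        json.dump(calib.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    rows = [
        {
            "node": _node_name(sub, e.node_id),
            "ogt_point": round(e.point, 6),
            "ci_low": round(e.ci_low, 6),
            "ci_high": round(e.ci_high, 6),
        }
        for e in estimates
    ]
    pd.DataFrame(rows).to_csv(outdir / "ancestral_ogt.tsv", sep="\t", index=False)
    rep_rows = []
    for e in estimates:
        for r, v in enumerate(e.replicate_ogts):
            rep_rows.append((_node_name(sub, e.node_id), r, round(float(v), 6)))
    pd.DataFrame(rep_rows, columns=["node", "replicate", "ogt"]).to_csv(
        outdir / "ancestral_ogt_replicates.tsv", sep="\t", index=False
    )
    return {
        "stage": "thermometer",
        "status": "ok" if model.converged else "convergence-warning",
        "n_taxa_model": sub.n_leaves(),
        "n_taxa_calibration": calib.n_taxa,
        "pruned_taxa": dropped,
        "calibration": calib.to_dict(),
        "model_loglik": model.loglik,
        "kappa": model.kappa,
        "theta_root": model.theta_root,
        "replicates": config.replicates,
        "seed": config.seed,
        "ancestral_ogt": rows,
    }


def run_gene_content(config: PipelineConfig, log: list[str] | None = None) -> dict:
    """Gene-content track; runs the clustering front end if only hits given."""
    config.validate(need_thermometer=False, need_content=True)
    log = log if log is not None else []
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree = _load_tree(config)

    if config.occurrence_matrix:
        matrix = pd.read_csv(config.occurrence_matrix, sep="\t", index_col=0)
    else:
        lengths = famclust.read_lengths(config.lengths)
        seq2genome = famclust.read_seq2genome(config.seq2genome)
        hits = famclust.read_hits(config.hits, lengths)
        th = famclust.FilterThresholds(
            config.min_identity, config.min_coverage, config.max_evalue
        )
        edges = famclust.filter_hits(hits, th)
        fams = famclust.cluster_families(sorted(lengths), edges)
        matrix = famclust.build_occurrence_matrix(fams, seq2genome)
        famclust.write_families(fams, outdir / "families.tsv")
        famclust.write_occurrence_matrix(matrix, outdir / "occurrence_matrix.tsv")
        log.append(f"clustered {len(fams.membership)} sequences into {fams.n_families} families")

    leaves = set(tree.leaf_labels())
    if leaves - set(matrix.index):
        raise ValueError(
            f"tree leaves absent from occurrence matrix: {sorted(leaves - set(matrix.index))}"
        )
    empty = matrix.columns[matrix.loc[sorted(leaves)].sum(axis=0) == 0]
    if len(empty):
        log.append(f"dropped {len(empty)} families observed in zero genomes")
        matrix = matrix.drop(columns=empty)
    over_cap = (matrix.loc[sorted(leaves)] > config.cmax).to_numpy().sum()
    if over_cap:
        log.append(f"{over_cap} observed counts exceed cmax={config.cmax}; truncated")

    fit_config = genefam_bd.BDFitConfig(
        cmax=config.cmax,
        seed=config.seed,
        fit_duplication=config.fit_duplication,
    )
    rates = genefam_bd.fit_rates(tree, matrix, fit_config)
    n_flagged = int((~rates["converged"]).sum())
    if n_flagged:
        log.append(f"{n_flagged} family fits flagged as non-converged")
    rates.reset_index().to_csv(
        outdir / "family_rates.tsv", sep="\t", index=False, float_format="%.6f"
    )

    leaves_ordered = tree.leaf_labels()
    posteriors: dict[str, dict[int, np.ndarray]] = {}
    event_frames = []
    for fam in matrix.columns:
        counts = {lab: int(matrix.loc[lab, fam]) for lab in leaves_ordered}
        fr = genefam_bd.BDRates(
            float(rates.loc[fam, "gain"]),
            float(rates.loc[fam, "dup"]),
            float(rates.loc[fam, "loss"]),
            config.cmax,
        )
        posteriors[fam] = genefam_bd.node_posteriors(tree, counts, fr)
        event_frames.append(
            genefam_bd.call_events(tree, counts, fr, tau=config.tau, family=fam)
        )
    events = pd.concat(event_frames, ignore_index=True)
    events_out = events.copy()
    events_out["parent"] = [_node_name(tree, int(p)) for p in events_out["parent"]]
    events_out["child"] = [_node_name(tree, int(c)) for c in events_out["child"]]
    # the written table keeps only non-negligible event probabilities; the
    # overwhelming majority of (family, branch) pairs carry ~0 on all four
    prob_cols = ["P_gain", "P_loss", "P_expand", "P_contract"]
    events_out = events_out[events_out[prob_cols].max(axis=1) >= 0.05]
    events_out.to_csv(
        outdir / "branch_events.tsv", sep="\t", index=False, float_format="%.6f"
    )

    content = genefam_bd.ancestral_content(posteriors, tau=config.tau)
    content_rows = []
    for nid in sorted(content):
        if tree.nodes[nid].is_leaf:
            continue
        g = content[nid]
        content_rows.append(
            {
                "node": _node_name(tree, nid),
                "n_present": len(g.present),
                "n_multicopy": len(g.multicopy),
                "families": ",".join(sorted(g.present)),
            }
        )
    pd.DataFrame(content_rows).to_csv(outdir / "node_content.tsv", sep="\t", index=False)

    grates = genefam_bd.gain_rates(events, tree)
    grates_out = grates.copy()
    grates_out["child"] = [_node_name(tree, int(c)) for c in grates_out["child"]]
    grates_out.to_csv(
        outdir / "gain_rates.tsv", sep="\t", index=False, float_format="%.6f"
    )
    defined = grates[grates["rate_defined"]]
    anc = defined[defined["branch_class"] == "ancestral"]["gain_rate"]
    term = defined[defined["branch_class"] == "terminal"]["gain_rate"]
    statistics: dict = {}
    if len(anc) >= 2 and len(term) >= 2:
        stat, p = genefam_bd.compare_gain_rates(list(anc), list(term), "rank-sum")
        statistics["gain_rate_ancestral_vs_terminal"] = {
            "method": "rank-sum",
            "statistic": stat,
            "p_value": p,
        }
    try:
        statistics["gains_vs_substitutions"] = genefam_bd.gains_vs_substitutions(
            events, tree, content
        )
    except ValueError as exc:
        statistics["gains_vs_substitutions"] = {"skipped": str(exc)}
    with open(outdir / "statistics.json", "w") as fh:
        json.dump(statistics, fh, indent=1, sort_keys=True, default=float)
        fh.write("\n")

    # per-ancestor summary (present / gained / lost), leafward branch view
    summary = []
    for row in content_rows:
        node = row["node"]
        sub_e = events_out[(events_out["child"] == node)]
        summary.append(
            {
                "node": node,
                "present": row["n_present"],
                "gained": int(sub_e["call_gain"].sum()),
                "lost": int(sub_e["call_loss"].sum()),
            }
        )
    return {
        "stage": "gene_content",
        "status": "ok" if n_flagged == 0 else "convergence-warning",
        "n_families": int(matrix.shape[1]),
        "n_genomes": int(matrix.shape[0]),
        "tau": config.tau,
        "cmax": config.cmax,
        "seed": config.seed,
        "ancestor_summary": summary,
        "statistics": statistics,
    }


def run_all(config: PipelineConfig) -> dict:
    """Run the enabled tracks; write report.json and run.log; return report."""
    t0 = time.monotonic()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    stages = []
    if config.run_thermometer_track:
        stages.append(run_thermometer(config, log))
    if config.run_gene_content_track:
        stages.append(run_gene_content(config, log))
    status = "ok"
    if any(s["status"] != "ok" for s in stages):
        status = "convergence-warning"
    report = {
        "version": __version__,
        "status": status,
        "config": asdict(config),
        "stages": stages,
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=float)
        fh.write("\n")
    log.append(f"wall_time_s={time.monotonic() - t0:.2f}")
    with open(outdir / "run.log", "w") as fh:
        fh.write("\n".join(log) + "\n")
    return report
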