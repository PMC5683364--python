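"""End-to-end orchestration of the family-characterization workflow.

Stage order mirrors the study: identification -> protein characterisation ->
Ka/Ks -> phylogenetic grouping -> duplication/fractionation -> gene structure
-> miRNA targets -> expression. Inputs not supplied in the config are
generated by the seeded synthetic-data module, so the default run is fully
self-contained and byte-reproducible for a fixed config.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import (evolution, expression, genestruct, mirna, patterns, phylo,
               physchem, simulate, seqio)

STAGES = ("identify", "physchem", "kaks", "groups", "duplication",
          "structure", "mirna", "expression")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    tandem_bp: int = 50_000
    mirna_cutoff: float = 3.0
    fpkm_threshold: float = 1.0
    alpha: float = 0.01
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES})
    inputs: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


_KNOWN_KEYS = {"outdir", "seed", "tandem_bp", "mirna_cutoff",
               "fpkm_threshold", "alpha", "stages", "inputs"}
_INPUT_KEYS = {"proteins", "cds", "transcripts", "gff3", "domains",
               "subgenome", "blocks", "mirnas", "fpkm", "ct"}


def validate_config(source: str | dict) -> PipelineConfig:
    """Parse and validate a YAML config (path or pre-parsed dict).

    Unknown keys produce warnings, not errors; bad thresholds and missing
    referenced files are errors (collected before any stage runs).
    """
    if isinstance(source, dict):
        raw = dict(source)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    errors: list[str] = []
    warnings = [f"unknown config key {k!r}" for k in raw
                if k not in _KNOWN_KEYS]
    if "outdir" not in raw:
        errors.append("missing required key 'outdir'")
    cfg = PipelineConfig(outdir=raw.get("outdir", "."),
                         seed=int(raw.get("seed", 0)),
                         warnings=warnings)
    for key in ("tandem_bp", "mirna_cutoff", "fpkm_threshold", "alpha"):
        if key in raw:
            val = float(raw[key])
            if val <= 0:
                errors.append(f"{key} must be positive, got {val}")
            setattr(cfg, key, int(val) if key == "tandem_bp" else val)
    for stage, flag in (raw.get("stages") or {}).items():
        if stage not in STAGES:
            warnings.append(f"unknown stage {stage!r}")
        else:
            cfg.stages[stage] = bool(flag)
    for name, path in (raw.get("inputs") or {}).items():
        if name not in _INPUT_KEYS:
            warnings.append(f"unknown input {name!r}")
            continue
        if not os.path.exists(path):
            errors.append(f"input {name!r}: no such file {path!r}")
        cfg.inputs[name] = path
    if errors:
        raise ConfigError("; ".join(errors))
    return cfg


def _read_domains(path: str) -> dict[str, seqio.DomainAnnotation]:
    table = pd.read_csv(path, sep="\t")
    out = {}
    for r in table.itertuples():
        labels = frozenset(str(r.domain_labels).split(",")) \
            if str(r.domain_labels) != "nan" else frozenset()
        out[str(r.protein_id)] = seqio.DomainAnnotation(
            str(r.protein_id), labels, getattr(r, "source", ""))
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all enabled stages; returns the manifest (also written to disk).

    Any stage failure aborts with the stage name; a ``<stage>.partial``
    marker is left next to the stage's outputs.
    """
    os.makedirs(cfg.outdir, exist_ok=True)
    sim_cfg = simulate.SimulationConfig(seed=cfg.seed)
    outputs: dict[str, str] = {}

    def out(name: str) -> str:
        path = os.path.join(cfg.outdir, name)
        outputs[name] = path
        return path

    # --- inputs: load if provided, else simulate ---
    if {"proteins", "domains"} <= set(cfg.inputs):
        proteins = seqio.read_fasta(cfg.inputs["proteins"], "protein")
        annotations = _read_domains(cfg.inputs["domains"])
        cds = (seqio.read_fasta(cfg.inputs["cds"], "DNA")
               if "cds" in cfg.inputs else [])
        models = (seqio.read_gff3(cfg.inputs["gff3"])
                  if "gff3" in cfg.inputs else [])
        subgenome = (pd.read_csv(cfg.inputs["subgenome"], sep="\t")
                     if "subgenome" in cfg.inputs else None)
        blocks = (pd.read_csv(cfg.inputs["blocks"], sep="\t")
                  if "blocks" in cfg.inputs else None)
    else:
        bundle = simulate.simulate_family_genome(sim_cfg)
        simulate.write_genome_bundle(bundle,
                                     os.path.join(cfg.outdir, "inputs"))
        proteins, cds = bundle.proteins, bundle.cds
        models, annotations = bundle.models, bundle.annotations
        subgenome, blocks = bundle.truth_subgenome, bundle.blocks

    def _stage(name: str):
        return cfg.stages.get(name, True)

    accepted_ids: set[str] = {p.id for p in proteins}
    current = "?"
    try:
        if _stage("identify"):
            current = "identify"
            results = patterns.classify_family(proteins, annotations)
            accepted_ids = {r.protein_id for r in results
                            if r.verdict == "accepted"}
            seqio.write_tsv_report(pd.DataFrame(
                [{"protein_id": r.protein_id, "verdict": r.verdict,
                  "reasons": ",".join(r.reasons)} for r in results]),
                out("identification.tsv"))
        accepted = [p for p in proteins if p.id in accepted_ids]

        if _stage("physchem"):
            current = "physchem"
            seqio.write_tsv_report(physchem.properties_table(accepted),
                                   out("physchem.tsv"))

        if _stage("kaks"):
            current = "kaks"
            pairs = simulate.simulate_codon_pairs(sim_cfg,
                                                  n_pairs_per_omega=3)
            rows = []
            for r in pairs.itertuples():
                res = evolution.nei_gojobori(
                    [r.cds_a[i:i + 3] for i in range(0, len(r.cds_a), 3)],
                    [r.cds_b[i:i + 3] for i in range(0, len(r.cds_b), 3)],
                    f"{r.pair_id}_a", f"{r.pair_id}_b")
                rows.append({"pair": r.pair_id, "true_omega": r.omega,
                             "KA": res.Ka, "KS": res.Ks,
                             "KA/KS": res.ratio,
                             "selection_class": res.selection_class})
            seqio.write_tsv_report(pd.DataFrame(rows), out("kaks.tsv"))

        if _stage("groups") and len(accepted) >= 3:
            current = "groups"
            # pairwise global alignments give p-distances without a joint
            # MSA; Biopython's C aligner keeps the all-vs-all pass fast
            from Bio import Align
            import numpy as np
            aligner = Align.PairwiseAligner()
            aligner.mode = "global"
            aligner.substitution_matrix = \
                evolution.substitution_matrices.load("BLOSUM62")
            aligner.open_gap_score = aligner.extend_gap_score = -8
            labels = [p.id for p in accepted]
            n = len(labels)
            d = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    aln = aligner.align(accepted[i].residues,
                                        accepted[j].residues)[0]
                    d[i, j] = d[j, i] = phylo.p_distance(str(aln[0]),
                                                         str(aln[1]))
            tree = phylo.neighbor_joining(phylo.DistanceMatrix(labels, d))
            with open(out("tree.newick"), "w") as fh:
                fh.write(tree.newick() + "\n")

        if _stage("duplication") and models:
            current = "duplication"
            calls = evolution.call_tandem(models, "CNGC")
            clusters = evolution.tandem_clusters(calls)
            rows = [{"gene_a": c.gene_a, "gene_b": c.gene_b, "kind": c.kind,
                     "distance_bp": c.distance_bp}
                    for c in calls if c.kind == "tandem"]
            if blocks is not None:
                rows += [{"gene_a": c.gene_a, "gene_b": c.gene_b,
                          "kind": c.kind, "distance_bp": None}
                         for c in evolution.segmental_calls(blocks)]
            seqio.write_tsv_report(pd.DataFrame(rows), out("duplications.tsv"))
            seqio.write_tsv_report(pd.DataFrame(
                [{"cluster": i + 1, "genes": ",".join(sorted(c))}
                 for i, c in enumerate(clusters)]), out("tandem_clusters.tsv"))
            if subgenome is not None:
                counts = evolution.summarize_fractionation(subgenome)
                seqio.write_tsv_report(pd.DataFrame(
                    [{"subgenome": k, "genes": v}
                     for k, v in counts.items()]), out("fractionation.tsv"))

        if _stage("structure") and models:
            current = "structure"
            totals, per_gene = genestruct.phase_census(models)
            seqio.write_tsv_report(per_gene, out("gene_structure.tsv"))
            seqio.write_tsv_report(pd.DataFrame(
                [{"phase": k, "introns": v}
                 for k, v in sorted(totals.items())]), out("intron_phases.tsv"))

        if _stage("mirna"):
            current = "mirna"
            mb = simulate.simulate_mirna_targets(sim_cfg,
                                                 cutoff=cfg.mirna_cutoff)
            reports = mirna.scan_all(mb.mirnas, mb.transcripts,
                                     cfg.mirna_cutoff)
            seqio.write_tsv_report(mirna.reports_to_table(reports),
                                   out("mirna_targets.tsv"))

        if _stage("expression"):
            current = "expression"
            eb = simulate.simulate_expression(sim_cfg)
            calls, per_tissue = expression.expressed_calls(
                eb.fpkm, cfg.fpkm_threshold)
            seqio.write_tsv_report(pd.DataFrame(
                {"gene_id": calls.index, "expressed": calls.values}),
                out("expressed_calls.tsv"))
            dendro = expression.hierarchical_cluster(
                expression.log_transform(eb.fpkm))
            with open(out("expression_dendrogram.newick"), "w") as fh:
                fh.write(dendro.newick + "\n")
            measurements = [
                expression.QpcrMeasurement(
                    str(r.gene), str(r.condition), int(r.replicate),
                    float(r.ct_target), float(r.ct_reference))
                for r in eb.ct_table.itertuples()]
            folds = expression.ddct_fold_change(measurements)
            seqio.write_tsv_report(pd.DataFrame(
                [{"gene": f.gene, "ddct": f.ddct,
                  "fold_change": f.fold_change,
                  "log2_ratio": f.log2_ratio} for f in folds]),
                out("qpcr_fold_changes.tsv"))
    except Exception as exc:  # noqa: BLE001 - abort with stage attribution
        marker = os.path.join(cfg.outdir, f"{current}.partial")
        with open(marker, "w") as fh:
            fh.write(str(exc) + "\n")
        raise PipelineError(current, exc) from exc

    from . import __version__
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {"tandem_bp": cfg.tandem_bp,
                       "mirna_cutoff": cfg.mirna_cutoff,
                       "fpkm_threshold": cfg.fpkm_threshold,
                       "alpha": cfg.alpha},
        "stages": {s: cfg.stages.get(s, True) for s in STAGES},
        "outputs": sorted(outputs),
    }
    with open(os.path.join(cfg.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
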