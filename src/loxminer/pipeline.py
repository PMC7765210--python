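"""Pipeline orchestration: runs the stages in dependency order and emits the
summary tables.

Stage order mirrors the analysis workflow: simulate (optional) -> identify
-> props -> compare -> structure -> duplication -> tree -> expression ->
report. Every stage communicates with the next only through the files it
writes under the run directory; rerunning with the same configuration and
seed reproduces every output byte for byte (the run log carries no wall
clock state).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    comparative_genomics as cg,
    expression_stats as es,
    family_identification as fi,
    io_formats as io,
    phylogeny as ph,
    protein_props as pp,
    synthetic_data as sd,
)

ALL_STAGES = ("simulate", "identify", "props", "compare", "structure",
              "duplication", "tree", "expression", "report")

_BLOCK_KEYS = {
    "simulation": set(f.name for f in dc_fields(sd.SimulationConfig)),
    "identify": {"min_lox_width", "match_prob"},
    "alignment": {"matrix_name", "gap_open", "gap_extend"},
    "duplication": {"tandem_min_identity", "window", "max_genes",
                    "segmental_min_similarity"},
    "tree": {"replicates", "model"},
    "expression": {"mc_draws", "control_condition", "control_timepoint",
                   "alpha"},
}


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""


@dataclass
class RunConfig:
    """Top-level run configuration; unknown keys are rejected on load."""

    outdir: str = "loxminer_run"
    seed: int = 0
    log_level: str = "INFO"
    stages: tuple = ALL_STAGES
    inputs: dict = field(default_factory=dict)   # paths when not simulating
    simulation: dict = field(default_factory=dict)
    identify: dict = field(default_factory=dict)
    alignment: dict = field(default_factory=dict)
    duplication: dict = field(default_factory=dict)
    tree: dict = field(default_factory=dict)
    expression: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for stage in self.stages:
            if stage not in ALL_STAGES:
                raise ValueError(f"unknown stage {stage!r}")
        for block, allowed in _BLOCK_KEYS.items():
            extra = set(getattr(self, block)) - allowed
            if extra:
                raise ValueError(
                    f"unknown keys in config block {block!r}: {sorted(extra)}"
                )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dc_fields(cls)}
        extra = set(raw) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def echo(self) -> str:
        payload = {f.name: getattr(self, f.name) for f in dc_fields(self)}
        payload["stages"] = list(self.stages)
        return yaml.safe_dump(payload, sort_keys=True)


def _parse_planted_folds(folds: dict) -> dict:
    """Accept ``{gene: {"condition@timepoint": fold}}`` (YAML-friendly) and
    return the tuple-keyed mapping the generator expects."""
    out = {}
    for gene, cells in folds.items():
        parsed = {}
        for key, fold in cells.items():
            if isinstance(key, tuple):
                parsed[key] = fold
            else:
                cond, tp = str(key).split("@")
                parsed[(cond, float(tp) if "." in tp else int(tp))] = fold
        out[gene] = parsed
    return out


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _characterize(members, proteins, models_by_id):
    """Fill the characterization columns (lengths, MW, pI) per member."""
    for m in members:
        protein = proteins.get(m.gene_id)
        model = models_by_id.get(m.gene_id)
        if protein is not None:
            m.protein_length = len(protein)
            m.orf_length = 3 * (len(protein) + 1)
            m.mw_kda = pp.molecular_weight_kda(protein)
            m.pi = round(pp.isoelectric_point(protein), 2)
        if model is not None:
            m.genomic_length = model.genomic_length
            m.orf_length = model.cds_length or m.orf_length
    return members


def build_family_report(members, models_by_id=None, structures=None,
                        duplications=None, tree=None, expression=None,
                        outdir=None) -> dict[str, Path]:
    """Write the family summary: gene table, domain table and a text digest.

    The gene table mirrors the standard characterization layout (gene,
    coordinates, genomic bp, ORF bp, protein aa, MW kDa, pI, subfamily); the
    domain table lists PLAT/LOX/5HIS intervals per bona fide member. Works
    with any subset of downstream results present.
    """
    outdir = Path(outdir or ".")
    outdir.mkdir(parents=True, exist_ok=True)
    models_by_id = models_by_id or {}

    gene_rows, domain_rows = [], []
    for m in members:
        if not m.bona_fide:
            continue
        model = models_by_id.get(m.gene_id)
        coords = (f"{model.start}:{model.end} ({model.strand})"
                  if model else "n/a")
        gene_rows.append({
            "gene": m.gene_id,
            "sequence_id": m.gene_id,
            "coordinates": coords,
            "genomic_bp": model.genomic_length if model else m.genomic_length,
            "orf_bp": m.orf_length,
            "protein_aa": m.protein_length,
            "mw_kda": m.mw_kda,
            "pi": m.pi,
            "subfamily": m.subfamily,
            "lox13_type": m.lox13_type,
        })
        for hit in m.domain_hits:
            domain_rows.append({
                "gene_id": m.gene_id, "domain": hit.motif,
                "aa_start": hit.aa_start, "aa_end": hit.aa_end,
                "source": "scan",
            })
    gene_cols = ["gene", "sequence_id", "coordinates", "genomic_bp", "orf_bp",
                 "protein_aa", "mw_kda", "pi", "subfamily", "lox13_type"]
    dom_cols = ["gene_id", "domain", "aa_start", "aa_end", "source"]
    paths = {
        "gene_table": outdir / "family_gene_table.tsv",
        "domain_table": outdir / "family_domain_table.tsv",
        "summary": outdir / "summary.txt",
    }
    io.write_tsv(pd.DataFrame(gene_rows, columns=gene_cols), paths["gene_table"])
    io.write_tsv(pd.DataFrame(domain_rows, columns=dom_cols), paths["domain_table"])

    counts: dict[str, int] = {}
    for row in gene_rows:
        counts[row["subfamily"]] = counts.get(row["subfamily"], 0) + 1
    ratio = fi.subfamily_ratio(counts)
    lines = [
        f"bona fide family members: {len(gene_rows)}",
        "subfamily counts: " + ", ".join(f"{k}={v}" for k, v in sorted(counts.items())),
        f"13-LOX : 9-LOX ratio: {'undefined' if ratio is None else f'{ratio:.2f}'}",
    ]
    if duplications is not None:
        tandem = [c for c in duplications if c.kind == "tandem"]
        seg = [c for c in duplications if c.kind == "segmental"]
        lines.append(f"tandem arrays: {len(tandem)} "
                     f"(sizes {sorted(len(c.members) for c in tandem)})")
        lines.append(f"segmental duplications: {len(seg)}")
    if tree is not None:
        lines.append(f"tree: {len(tree.taxa)} taxa, "
                     f"{'degenerate' if tree.degenerate else 'resolved'}")
    paths["summary"].write_text("\n".join(lines) + "\n")
    return paths


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    Raises :class:`StageError` naming the failing stage; outputs written by
    earlier stages are left in place.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"seed: {config.seed}", "config:"]
    log_lines += ["  " + line for line in config.echo().splitlines()]
    stages = set(config.stages)
    state: dict = {}

    def run_stage(name, fn):
        if name not in stages:
            return
        try:
            fn()
            log_lines.append(f"stage {name}: ok")
        except Exception as exc:
            log_lines.append(f"stage {name}: FAILED ({exc})")
            (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    # ---- simulate ---------------------------------------------------------
    def stage_simulate():
        params = dict(config.simulation)
        if "planted_fold_changes" in params:
            params["planted_fold_changes"] = _parse_planted_folds(
                params["planted_fold_changes"])
        sim = sd.SimulationConfig(seed=config.seed, **params)
        bundle = sd.generate_genome_bundle(sim)
        sd.write_bundle(bundle, outdir / "bundle")
        ct = sd.generate_ct_table(sim)
        io.write_tsv(ct, outdir / "bundle" / "ct_table.tsv", float_format="%.4f")
        state["bundle"] = bundle
        state["sim"] = sim

    run_stage("simulate", stage_simulate)

    # ---- load inputs ------------------------------------------------------
    if "bundle" in state:
        proteins = {r.id: r for r in state["bundle"].proteins}
        models = state["bundle"].genes
        cds = {r.id: r for r in state["bundle"].cds}
    else:
        proteins, models, cds = {}, [], {}
        if config.inputs.get("proteins"):
            proteins = {r.id: r for r in io.read_fasta(config.inputs["proteins"],
                                                       alphabet="protein")}
        if config.inputs.get("gff3"):
            models = io.read_gff3(config.inputs["gff3"])
        if config.inputs.get("cds"):
            cds = {r.id: r for r in io.read_fasta(config.inputs["cds"],
                                                  alphabet="nucleotide")}
    models_by_id = {m.gene_id: m for m in models}
    domains = None
    if config.inputs.get("domain_table"):
        domains = io.read_domain_table(config.inputs["domain_table"])

    # ---- identify ---------------------------------------------------------
    def stage_identify():
        if not proteins and domains is None:
            raise ValueError("no proteins or domain table to identify from")
        candidates = sorted(proteins) if proteins else sorted(
            domains["gene_id"].unique())
        motifs = fi.packaged_motifs(config.identify.get("match_prob", 0.7))
        members = fi.bona_fide_filter(
            candidates, proteins or None, domains, motifs,
            min_lox_width=config.identify.get(
                "min_lox_width", fi.DEFAULT_MIN_LOX_WIDTH))
        refs = sd.reference_panel()
        members = [
            fi.assign_subfamily(m, proteins[m.gene_id], refs)
            if m.bona_fide and m.gene_id in proteins else m
            for m in members
        ]
        state["members"] = members
        io.write_tsv(fi.rejection_report(members),
                     outdir / "rejection_report.tsv")
        # first cut of the family tables; later stages enrich and rewrite
        build_family_report(members, models_by_id, outdir=outdir)

    run_stage("identify", stage_identify)

    # ---- props ------------------------------------------------------------
    def stage_props():
        _characterize(state.get("members", []), proteins, models_by_id)

    run_stage("props", stage_props)

    def bona_fide():
        return [m for m in state.get("members", []) if m.bona_fide]

    # ---- compare ----------------------------------------------------------
    def stage_compare():
        ids = [m.gene_id for m in bona_fide() if m.gene_id in proteins]
        if len(ids) < 2:
            raise ValueError("need >= 2 bona fide members with sequences")
        protein_mat = cg.identity_matrix([proteins[i] for i in ids])
        state["protein_matrix"] = protein_mat
        io.write_tsv(protein_mat.identity.round(2).reset_index(names="gene"),
                     outdir / "protein_identity_matrix.tsv")
        if cds:
            cds_mat = cg.identity_matrix([cds[i] for i in ids if i in cds])
            io.write_tsv(cds_mat.identity.round(2).reset_index(names="gene"),
                         outdir / "cds_identity_matrix.tsv")

    run_stage("compare", stage_compare)

    # ---- structure --------------------------------------------------------
    def stage_structure():
        rows = []
        for m in bona_fide():
            model = models_by_id.get(m.gene_id)
            if model is None:
                continue
            s = cg.intron_phases(model)
            rows.append({
                "gene_id": s.gene_id,
                "exon_lengths": ",".join(map(str, s.exon_lengths)),
                "intron_lengths": ",".join(map(str, s.intron_lengths)),
                "intron_phases": ",".join(map(str, s.intron_phases)),
            })
        state["structures"] = rows
        io.write_tsv(pd.DataFrame(
            rows, columns=["gene_id", "exon_lengths", "intron_lengths",
                           "intron_phases"]),
            outdir / "gene_structures.tsv")

    run_stage("structure", stage_structure)

    # ---- duplication ------------------------------------------------------
    def stage_duplication():
        mat = state.get("protein_matrix")
        if mat is None:
            raise ValueError("duplication stage needs the compare stage")
        fam_models = [models_by_id[m.gene_id] for m in bona_fide()
                      if m.gene_id in models_by_id]
        calls = cg.detect_duplications(fam_models, mat, **config.duplication)
        state["duplications"] = calls
        io.write_tsv(pd.DataFrame(
            [{"kind": c.kind, "members": ",".join(c.members),
              "scaffold": c.scaffold, "span_bp": c.span,
              "supporting_identity": round(c.supporting_identity, 2)}
             for c in calls],
            columns=["kind", "members", "scaffold", "span_bp",
                     "supporting_identity"]),
            outdir / "duplications.tsv")

    run_stage("duplication", stage_duplication)

    # ---- tree -------------------------------------------------------------
    def stage_tree():
        ids = [m.gene_id for m in bona_fide() if m.gene_id in proteins]
        if len(ids) < 3:
            raise ValueError("tree stage needs >= 3 sequences")
        msa = ph.align_progressive([proteins[i] for i in ids])
        tree = ph.bootstrap_support(
            msa, model=config.tree.get("model", "poisson"),
            replicates=config.tree.get("replicates", 1000),
            seed=config.seed)
        state["tree"] = tree
        (outdir / "family_tree.nwk").write_text(
            tree.to_newick(with_supports=True) + "\n")

    run_stage("tree", stage_tree)

    # ---- expression -------------------------------------------------------
    def stage_expression():
        if "sim" in state:
            ct = sd.generate_ct_table(state["sim"])
            targets = [f"SpLOX{i + 1}"
                       for i in range(state["sim"].n_true_family)]
            references = list(state["sim"].reference_genes)
            control_condition = config.expression.get("control_condition",
                                                      "control")
        elif config.inputs.get("ct_table"):
            ct = io.read_ct_table(config.inputs["ct_table"])
            targets = sorted(set(ct["gene_id"]))
            references = config.expression.get("references", [])
            control_condition = config.expression.get("control_condition")
        else:
            raise ValueError("no Ct table available")
        table = es.expression_analysis(
            ct, targets, references,
            control_condition=control_condition,
            control_timepoint=config.expression.get("control_timepoint"),
            mc_draws=config.expression.get("mc_draws", 100_000),
            seed=config.seed)
        state["expression"] = table
        io.write_tsv(table.results.round(4), outdir / "expression_results.tsv",
                     float_format="%.4f")
        alpha = config.expression.get("alpha", 0.05)
        calls = []
        for gene, sub in table.results.groupby("gene_id"):
            rows = sub[~sub["is_control"]]
            if rows.empty or "dunnett_p" not in rows:
                continue
            label = es.classify_treatment_response(
                list(zip(rows["timepoint"], rows["fold"], rows["dunnett_p"])),
                alpha=alpha)
            calls.append({"gene_id": gene, "response": label})
        io.write_tsv(pd.DataFrame(calls, columns=["gene_id", "response"]),
                     outdir / "response_calls.tsv")

    run_stage("expression", stage_expression)

    # ---- report -----------------------------------------------------------
    def stage_report():
        build_family_report(
            state.get("members", []), models_by_id,
            structures=state.get("structures"),
            duplications=state.get("duplications"),
            tree=state.get("tree"),
            expression=state.get("expression"),
            outdir=outdir)

    run_stage("report", stage_report)

    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return outdir
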