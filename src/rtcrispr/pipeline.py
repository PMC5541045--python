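"""End-to-end orchestration: genomes in, classified loci and reports out.

Stages run in a fixed order: gene calling (or supplied GFF3) -> RT domain
detection -> dereplication -> array detection -> orientation cascade ->
cas annotation -> locus extraction and trimming -> fusion and subtype
classification -> tree building (or supplied Newick) -> clade assignment
and subclades -> consensus membership screening -> distribution table and
(when Cas1 sequences are available) an RT/Cas1 congruence report.  Every
stage logs record counts; identical config + seed gives byte-identical
outputs.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as rio
from .arrays import RepeatDB, detect_arrays, resolve_orientation
from .loci import (
    annotate_cas,
    call_orfs,
    classify_subtype,
    detect_fusion,
    extract_locus,
    tabulate_distribution,
)
from .phylo import (
    SupportTree,
    assign_clades,
    fit_clade_models,
    monophyly,
    read_leaf_metadata,
    screen_membership,
    split_subclades,
)
from .profiles import load_profiles, load_repeat_db
from .sequence import (
    ProteinRecord,
    dereplicate,
    find_domains,
    progressive_align,
)


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    genome_fasta: str
    out_dir: str
    gff3: str | None = None
    profiles_fasta: str | None = None
    repeat_db_tsv: str | None = None
    rt_tree_newick: str | None = None
    metadata_tsv: str | None = None
    identity_max: float = 85.0
    min_len: int = 200
    evalue_annot: float = 0.01
    evalue_subtype: float = 1e-6
    evalue_domain: float = 1e-6  # confident threshold for domain-architecture calls
    support_min: float = 0.92
    window_bp: int = 50_000
    gap_max_bp: int = 5_000
    array_link_bp: int = 1_000
    bootstrap_n: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "identity_max", "min_len", "evalue_annot", "evalue_subtype",
            "support_min", "window_bp", "gap_max_bp", "array_link_bp",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"threshold {name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def validate_paths(self) -> None:
        for name in ("genome_fasta", "gff3", "profiles_fasta", "repeat_db_tsv",
                     "rt_tree_newick", "metadata_tsv"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise ConfigError(f"{name} path does not exist: {value}")


class _StageLog:
    def __init__(self, log_path: Path):
        self.lines: list[str] = []
        self.log_path = log_path

    def stage(self, name: str, n_in: int, n_out: int, t0: float) -> None:
        wall = time.monotonic() - t0
        print(f"stage={name} n_in={n_in} n_out={n_out} wall={wall:.2f}s", file=sys.stderr)
        # the persisted log omits wall time so reruns are byte-identical
        self.lines.append(f"stage={name} n_in={n_in} n_out={n_out}")

    def flush(self) -> None:
        self.log_path.write_text("\n".join(self.lines) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write reports to ``config.out_dir``.

    Returns the run report as a dict (also written as JSON).
    """
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _StageLog(out / "run.log")
    report: dict = {"seed": config.seed, "stages": {}}

    def fail(stage: str, exc: Exception):
        log.flush()
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    contigs = dict(rio.read_fasta(config.genome_fasta))
    profiles = (
        rio.read_fasta(config.profiles_fasta)
        if config.profiles_fasta
        else load_profiles()
    )
    repeat_db = (
        RepeatDB.from_tsv(config.repeat_db_tsv)
        if config.repeat_db_tsv
        else load_repeat_db()
    )
    metadata = read_leaf_metadata(config.metadata_tsv) if config.metadata_tsv else {}

    # --- gene calling ------------------------------------------------------
    t0 = time.monotonic()
    try:
        if config.gff3:
            genes = rio.read_genes_gff3(config.gff3, contigs)
        else:
            genes = [
                g for cid, seq in sorted(contigs.items()) for g in call_orfs(seq, cid)
            ]
    except Exception as exc:  # pragma: no cover - defensive
        fail("gene_calling", exc)
    log.stage("gene_calling", len(contigs), len(genes), t0)

    # --- RT domain detection ----------------------------------------------
    t0 = time.monotonic()
    rt_profile = [p for p in profiles if p[0] == "RT"]
    fusion_profiles = [p for p in profiles if p[0] in ("RT", "cas1", "cas6")]
    rt_genes = []
    for g in genes:
        doms = find_domains(g.translation, rt_profile, max_evalue=config.evalue_domain)
        if doms:
            rt_genes.append(g)
    log.stage("rt_detection", len(genes), len(rt_genes), t0)

    # --- dereplication -----------------------------------------------------
    t0 = time.monotonic()
    rt_records = [
        ProteinRecord(f"{g.contig}:{g.locus_tag}", g.translation) for g in rt_genes
    ]
    reps = dereplicate(rt_records, config.identity_max, config.min_len)
    rep_ids = {r.id for r in reps}
    rt_reps = [
        g for g in rt_genes if f"{g.contig}:{g.locus_tag}" in rep_ids
    ]
    log.stage("dereplication", len(rt_genes), len(rt_reps), t0)

    # --- array detection and orientation ----------------------------------
    t0 = time.monotonic()
    arrays_by_contig: dict[str, list] = {}
    for cid in sorted(contigs):
        arrays_by_contig[cid] = detect_arrays(contigs[cid], cid)
    n_arrays = sum(len(v) for v in arrays_by_contig.values())
    log.stage("array_detection", len(contigs), n_arrays, t0)

    t0 = time.monotonic()
    oriented: dict[str, list] = {}
    first_pass: dict[str, list] = {}
    for cid, arrs in arrays_by_contig.items():
        first_pass[cid] = [
            resolve_orientation(a, contigs[cid], repeat_db, []) for a in arrs
        ]
    group = [
        a
        for arrs in first_pass.values()
        for a in arrs
        if a.orientation != "undetermined"
    ]
    for cid, arrs in first_pass.items():
        oriented[cid] = [
            a
            if a.orientation != "undetermined"
            else resolve_orientation(a, contigs[cid], repeat_db, group)
            for a in arrs
        ]
    all_arrays = [a for arrs in oriented.values() for a in arrs]
    n_oriented = sum(1 for a in all_arrays if a.orientation != "undetermined")
    log.stage("orientation", n_arrays, n_oriented, t0)

    # --- cas annotation ----------------------------------------------------
    t0 = time.monotonic()
    cas_hits = annotate_cas(genes, profiles)
    hits_by_contig: dict[str, list] = {}
    for h in cas_hits:
        hits_by_contig.setdefault(h.feature.contig, []).append(h)
    log.stage("cas_annotation", len(genes), len(cas_hits), t0)

    # --- locus extraction, fusion, subtype ---------------------------------
    t0 = time.monotonic()
    loci = []
    rt_id_of = {}
    for g in rt_reps:
        try:
            locus = extract_locus(
                g.contig,
                len(contigs[g.contig]),
                g,
                hits_by_contig.get(g.contig, []),
                oriented.get(g.contig, []),
                window=config.window_bp,
                gap_max=config.gap_max_bp,
                array_link=config.array_link_bp,
            )
            doms = find_domains(
                g.translation, fusion_profiles, max_evalue=config.evalue_domain
            )
            locus.fusion_class = detect_fusion(g, doms)
            locus.subtype = classify_subtype(locus)
            loci.append(locus)
            rt_id_of[id(locus)] = f"{g.contig}:{g.locus_tag}"
        except Exception as exc:
            fail("locus_extraction", exc)
    log.stage("locus_extraction", len(rt_reps), len(loci), t0)

    # --- tree + clades ------------------------------------------------------
    t0 = time.monotonic()
    partition = None
    if config.rt_tree_newick:
        stree = SupportTree.from_newick(Path(config.rt_tree_newick), metadata)
        partition = assign_clades(stree, config.support_min)
    elif len(rt_reps) >= 3:
        from .phylo import build_tree

        rt_named = sorted(
            (f"{g.contig}:{g.locus_tag}", g.translation) for g in rt_reps
        )
        rows = progressive_align([s for _n, s in rt_named])
        alignment = [(n, row) for (n, _s), row in zip(rt_named, rows)]
        tree_meta = {
            n: metadata.get(n, {"phylum": "", "crispr_associated": True})
            for n, _ in rt_named
        }
        stree = build_tree(
            alignment, bootstrap_n=config.bootstrap_n, seed=config.seed,
            metadata=tree_meta,
        )
        partition = assign_clades(stree, config.support_min)
    if partition is not None:
        partition = split_subclades(partition, support_min=config.support_min)
        for locus in loci:
            locus.clade = partition.label_of(rt_id_of[id(locus)])
    n_assigned = sum(1 for l in loci if l.clade != "unassigned")
    log.stage("clade_assignment", len(loci), n_assigned, t0)

    # --- membership screening ----------------------------------------------
    t0 = time.monotonic()
    screening_rows = []
    if partition is not None and partition.clades:
        members: dict[str, list[ProteinRecord]] = {}
        rt_seq_of = {f"{g.contig}:{g.locus_tag}": g.translation for g in rt_reps}
        for label, info in partition.clades.items():
            recs = [
                ProteinRecord(l, rt_seq_of[l]) for l in sorted(info.leaves)
                if l in rt_seq_of
            ]
            if recs:
                members[label] = recs
        if members:
            models = fit_clade_models(members)
            for g in rt_genes:
                label, ev = screen_membership(g.translation, models)
                screening_rows.append(
                    {
                        "rt": f"{g.contig}:{g.locus_tag}",
                        "clade": label or "none",
                        "evalue": ev,
                    }
                )
    log.stage("screening", len(rt_genes), len(screening_rows), t0)

    # --- congruence (RT clades vs Cas1 tree) --------------------------------
    t0 = time.monotonic()
    congruence = None
    cas1_seqs = _collect_cas1(loci, fusion_profiles, config.evalue_domain, rt_id_of)
    if partition is not None and len(cas1_seqs) >= 4:
        from .phylo import build_tree

        items = sorted(cas1_seqs.items())
        rows = progressive_align([s for _n, s in items])
        alignment = [(n, row) for (n, _s), row in zip(items, rows)]
        cas1_tree = build_tree(
            alignment, bootstrap_n=config.bootstrap_n, seed=config.seed
        )
        labels = {
            n: partition.labels.get(n, "unassigned")
            for n, _ in items
            if partition.labels.get(n, "unassigned") != "unassigned"
        }
        if labels:
            congruence = {
                label: {"monophyletic_in_cas1_tree": mono, "support": support}
                for label, (mono, support) in monophyly(cas1_tree, labels).items()
            }
    log.stage("congruence", len(cas1_seqs), len(congruence or {}), t0)

    # --- outputs ------------------------------------------------------------
    dist = tabulate_distribution(loci)
    rio.write_gff3(out / "features.gff3", genes, all_arrays)
    rio.arrays_table(all_arrays).to_csv(out / "arrays.tsv", sep="\t", index=False)
    rio.loci_table(loci).to_csv(out / "loci.tsv", sep="\t", index=False)
    dist.to_csv(out / "distribution.tsv", sep="\t")
    if partition is not None:
        pd.DataFrame(
            [
                {"leaf": leaf, "clade": partition.labels[leaf]}
                for leaf in sorted(partition.labels)
            ]
        ).to_csv(out / "partition.tsv", sep="\t", index=False)
    if screening_rows:
        pd.DataFrame(screening_rows).to_csv(out / "screening.tsv", sep="\t", index=False)

    report["stages"] = {
        fields["stage"]: {"n_in": int(fields["n_in"]), "n_out": int(fields["n_out"])}
        for fields in (dict(kv.split("=") for kv in line.split()) for line in log.lines)
    }
    report["n_loci"] = len(loci)
    report["n_arrays"] = len(all_arrays)
    report["n_rt_representatives"] = len(rt_reps)
    report["clades"] = sorted(partition.clades) if partition else []
    report["congruence"] = congruence
    (out / "run_report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    log.flush()
    return report


def _collect_cas1(loci, fusion_profiles, evalue, rt_id_of) -> dict[str, str]:
    """Cas1 sequence per locus: the Cas1 domain of a fused RT gene, or the
    translation of a separate cas1 gene in the locus."""
    out: dict[str, str] = {}
    for locus in loci:
        rid = rt_id_of[id(locus)]
        if locus.fusion_class in ("RT-Cas1", "Cas6-RT-Cas1"):
            doms = find_domains(
                locus.rt_feature.translation, fusion_profiles, max_evalue=evalue
            )
            cas1 = next((d for d in doms if d.family == "cas1"), None)
            if cas1 is not None:
                out[rid] = locus.rt_feature.translation[cas1.start - 1 : cas1.end]
        else:
            hit = next((h for h in locus.features if h.family == "cas1"), None)
            if hit is not None:
                out[rid] = hit.feature.translation
    return out
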