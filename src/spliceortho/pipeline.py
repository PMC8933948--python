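"""Orchestration of the full triplet analysis, and the command-line tool.

For each orthologous gene triplet: build structure models from the
annotation, run the three pairwise comparisons (both directions each),
unify block labels, predict transcripts, build and classify the
functional-site graph (retained / structurally orthologous), build the
transcript graph and extract CDS orthology groups (all-conserved /
single-copy verdicts), enumerate redundant-CDS sets, and tag predictions
with annotation/junction evidence.  Errors are attached to the triplet and
the run continues (per-triplet isolation).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import click

from . import evidence as ev
from .align import TripletComparison, compare_triplet
from .graphs import (
    CDSOrthologyGroup, build_site_graph, build_transcript_graph,
    classify_components, extract_groups, find_redundant_sets,
)
from .io_formats import (
    SpeciesData, export_sqlite, load_species, read_junctions,
    read_ortholog_map, write_models_tsv, write_predictions,
)
from .models import Config, DEFAULT_CONFIG, build_gene_model, \
    build_transcript_model
from .predict import predict_transcripts

__all__ = ["TripletResult", "TripletReport", "run_triplet", "run_analysis",
           "write_outputs", "cli"]

logger = logging.getLogger(__name__)


@dataclass
class TripletResult:
    triplet_id: str
    gene_ids: dict[str, str]  # species -> gene_id
    comparison: TripletComparison | None = None
    site_classes: list = field(default_factory=list)
    verdicts: dict = field(default_factory=dict)
    groups: list[CDSOrthologyGroup] = field(default_factory=list)
    redundant_sets: dict[str, list[list[str]]] = field(default_factory=dict)
    excluded_no_utr: dict[str, list[str]] = field(default_factory=dict)
    predictions: dict[str, list] = field(default_factory=dict)
    evidence: dict[str, ev.EvidenceTag] = field(default_factory=dict)
    error: str | None = None


@dataclass
class TripletReport:
    species: tuple[str, ...]
    triplets: list[TripletResult]
    summary: dict = field(default_factory=dict)


def run_triplet(species_data: dict[str, SpeciesData],
                triplets: list[tuple[str, ...]],
                junction_support: dict[str, dict] | None = None,
                annotations: dict[str, list] | None = None,
                config: Config = DEFAULT_CONFIG) -> TripletReport:
    """Run the full analysis over a list of gene triplets.

    ``species_data`` maps species name to its loaded annotation;
    ``junction_support`` maps species to ``{(seqname, start, end): reads}``;
    ``annotations`` maps species to ``[(set name, SpeciesData)]`` used for
    the *confirmed* evidence tag.
    """
    species = tuple(species_data)
    junction_support = junction_support or {}
    annotations = annotations or {}
    known_junctions = {sp: ev.known_junction_set(species_data[sp])
                       for sp in species}
    results: list[TripletResult] = []
    for triplet in triplets:
        triplet_id = "|".join(triplet)
        result = TripletResult(triplet_id, dict(zip(species, triplet)))
        try:
            _analyze(result, species_data, triplet, known_junctions,
                     junction_support, annotations, config)
        except Exception as exc:  # per-triplet isolation
            result.error = f"{type(exc).__name__}: {exc}"
            logger.warning("triplet %s failed: %s", triplet_id, result.error)
        results.append(result)
        if result.error is None:
            logger.info(
                "triplet %s retained=%s structural=%s all_conserved=%s "
                "single_copy=%s groups=%d predictions=%d", triplet_id,
                result.verdicts.get("retained"),
                result.verdicts.get("structurally_orthologous"),
                result.verdicts.get("all_conserved"),
                result.verdicts.get("single_copy"), len(result.groups),
                sum(len(v) for v in result.predictions.values()))
    report = TripletReport(species, results)
    report.summary = _summarize(report)
    return report


def _analyze(result: TripletResult, species_data, triplet,
             known_junctions, junction_support, annotations,
             config: Config) -> None:
    species = tuple(species_data)
    inputs = {}
    genes = {}
    for sp, gid in zip(species, triplet):
        gene_in = species_data[sp].genes.get(gid)
        if gene_in is None:
            raise KeyError(f"gene {gid} not found in {sp} annotation")
        inputs[sp] = gene_in
        tms = [build_transcript_model(rec, gene_in.locus, config)
               for rec in gene_in.records]
        genes[gid] = build_gene_model(tms, gene_in.locus, species=sp,
                                      strand=gene_in.strand, config=config)
    comparison = compare_triplet(genes, config)
    result.comparison = comparison
    result.predictions = predict_transcripts(comparison, config)

    sg = build_site_graph(comparison)
    result.site_classes, verdicts = classify_components(sg)
    tg = build_transcript_graph(comparison)
    result.groups, group_verdicts = extract_groups(tg, species)
    verdicts.update(group_verdicts)
    result.verdicts = verdicts

    for sp, gid in zip(species, triplet):
        sets, excluded = find_redundant_sets(comparison.genes[gid],
                                             inputs[sp].records)
        result.redundant_sets[sp] = sets
        result.excluded_no_utr[sp] = excluded
        tags = ev.assign_evidence(
            result.predictions.get(gid, []), inputs[sp],
            annotations.get(sp, []), known_junctions[sp],
            junction_support.get(sp, {}), config)
        result.evidence.update(tags)


def _summarize(report: TripletReport) -> dict:
    ok = [t for t in report.triplets if t.error is None]
    tags = {}
    for t in ok:
        for e in t.evidence.values():
            tags[e.tag] = tags.get(e.tag, 0) + 1
    summary = {
        "triplets": len(report.triplets),
        "errors": len(report.triplets) - len(ok),
        "retained": sum(t.verdicts.get("retained", False) for t in ok),
        "structurally_orthologous": sum(
            t.verdicts.get("structurally_orthologous", False) for t in ok),
        "all_conserved": sum(t.verdicts.get("all_conserved", False)
                             for t in ok),
        "single_copy": sum(t.verdicts.get("single_copy", False) for t in ok),
        "cds_orthology_groups": sum(len(t.groups) for t in ok),
        "predictions": {
            sp: sum(len(t.predictions.get(t.gene_ids.get(sp, ""), []))
                    for t in ok)
            for sp in report.species},
        "redundant_sets": {
            sp: sum(len(t.redundant_sets.get(sp, [])) for t in ok)
            for sp in report.species},
        "evidence_tags": tags,
    }
    return summary


# --------------------------------------------------------------------------
# file-level driver and outputs
# --------------------------------------------------------------------------

def run_analysis(species_files: dict[str, tuple],
                 ortholog_map_path,
                 junction_paths: dict[str, str] | None = None,
                 annotation_files: dict[str, list[tuple]] | None = None,
                 config: Config = DEFAULT_CONFIG
                 ) -> tuple[TripletReport, dict[str, SpeciesData]]:
    """Load everything from files and run the analysis.

    ``species_files``: species -> (gtf path, fasta path), in species-order
    precedence.  ``annotation_files``: species -> [(name, gtf, fasta)].
    """
    species_data = {sp: load_species(gtf, fasta, sp, config)
                    for sp, (gtf, fasta) in species_files.items()}
    map_species, triplets = read_ortholog_map(ortholog_map_path)
    if set(map_species) != set(species_data):
        raise ValueError(
            f"ortholog map species {map_species} do not match inputs "
            f"{sorted(species_data)}")
    # reorder triplet columns to the species_files order
    idx = [map_species.index(sp) for sp in species_data]
    triplets = [tuple(t[i] for i in idx) for t in triplets]
    for t in triplets:
        for sp, gid in zip(species_data, t):
            if gid not in species_data[sp].genes:
                raise ValueError(f"ortholog map gene {gid} missing from "
                                 f"{sp} annotation")
    support = {}
    for sp, path in (junction_paths or {}).items():
        rows = read_junctions(path)
        agg: dict[tuple, int] = {}
        for chrom, s, e, _strand, count in rows:
            key = (chrom, s, e)
            agg[key] = max(agg.get(key, 0), count)
        support[sp] = agg
    annotations = {}
    for sp, sets in (annotation_files or {}).items():
        annotations[sp] = [(name, load_species(gtf, fasta, sp, config))
                           for name, gtf, fasta in sets]
    report = run_triplet(species_data, triplets, support, annotations,
                         config)
    return report, species_data


def write_outputs(report: TripletReport, species_data, outdir,
                  stage: str = "run", sqlite: bool = False,
                  config: Config = DEFAULT_CONFIG) -> None:
    """Write stage-appropriate result files under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ok = [t for t in report.triplets if t.error is None]

    genes = [g for t in ok for g in t.comparison.genes.values()]
    write_models_tsv(outdir / "tokens.tsv", genes)
    if stage == "build":
        return

    with open(outdir / "orthologies.tsv", "w") as fh:
        fh.write("triplet_id\tgene_a\tgene_b\tkind\tlabel_a\tlabel_b\t"
                 "coords_a\tcoords_b\tidentity\tstatus_a\tstatus_b\n")
        for t in ok:
            for o in t.comparison.orthologies:
                a, b = o.token_a, o.token_b
                ident = "" if o.identity is None else f"{o.identity:.3f}"
                fh.write(f"{t.triplet_id}\t{a.gene_id}\t{b.gene_id}\t"
                         f"{a.kind}\t{a.label}\t{b.label}\t"
                         f"{a.start}-{a.end}\t{b.start}-{b.end}\t{ident}\t"
                         f"{a.status}\t{b.status}\n")
    if stage == "compare":
        return

    for sp in report.species:
        preds = []
        for t in ok:
            gid = t.gene_ids.get(sp, "")
            gene_in = species_data[sp].genes.get(gid)
            for pred in t.predictions.get(gid, []):
                tag = t.evidence.get(pred.transcript_id)
                preds.append((gene_in, pred, tag.tag if tag else ""))
        write_predictions(outdir / f"predicted_{sp}.gtf", preds,
                          config=config)
    if stage == "predict":
        return

    with open(outdir / "verdicts.tsv", "w") as fh:
        fh.write("triplet_id\tretained\tstructurally_orthologous\t"
                 "all_conserved\tsingle_copy\tgroups\terror\n")
        for t in report.triplets:
            v = t.verdicts
            fh.write(f"{t.triplet_id}\t{v.get('retained', '')}\t"
                     f"{v.get('structurally_orthologous', '')}\t"
                     f"{v.get('all_conserved', '')}\t"
                     f"{v.get('single_copy', '')}\t{len(t.groups)}\t"
                     f"{t.error or ''}\n")
    with open(outdir / "groups.tsv", "w") as fh:
        fh.write("triplet_id\tgroup_id\tmodel_string\tspecies\t"
                 "transcript_id\tstatus\tredundancy_size\n")
        for t in ok:
            for grp in t.groups:
                for sp in report.species:
                    for tid, status in grp.members.get(sp, []):
                        fh.write(f"{t.triplet_id}\t{grp.group_id}\t"
                                 f"{grp.model_string}\t{sp}\t{tid}\t{status}"
                                 f"\t{grp.redundancy.get(sp, 0)}\n")
    with open(outdir / "redundancy.tsv", "w") as fh:
        fh.write("triplet_id\tspecies\tset_index\ttranscript_id\n")
        for t in ok:
            for sp in report.species:
                for i, tids in enumerate(t.redundant_sets.get(sp, []), 1):
                    for tid in tids:
                        fh.write(f"{t.triplet_id}\t{sp}\t{i}\t{tid}\n")
    if stage == "graphs":
        return

    with open(outdir / "evidence.tsv", "w") as fh:
        fh.write("transcript_id\ttag\tdetail\n")
        for t in ok:
            for tid in sorted(t.evidence):
                e = t.evidence[tid]
                fh.write(f"{tid}\t{e.tag}\t{e.detail}\n")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(report.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if sqlite:
        export_sqlite(outdir / "transcript_ortho.sqlite", report)


# --------------------------------------------------------------------------
# command-line interface
# --------------------------------------------------------------------------

def _config_from(identity, site_context, min_reads, start_codons,
                 stop_in_cds, species: tuple[str, ...]) -> Config:
    return replace(
        DEFAULT_CONFIG,
        block_identity_threshold=identity,
        site_context=site_context,
        min_reads=min_reads,
        start_codons=tuple(start_codons.split(",")),
        stop_in_cds=stop_in_cds,
        species_order=species or DEFAULT_CONFIG.species_order,
    )


def _common(f):
    f = click.option("--identity", default=0.70, show_default=True,
                     help="block identity threshold")(f)
    f = click.option("--site-context", default=12, show_default=True,
                     help="site motif flanking context (nt)")(f)
    f = click.option("--min-reads", default=1, show_default=True,
                     help="reads required to support a junction")(f)
    f = click.option("--start-codons", default="ATG", show_default=True,
                     help="comma-separated start codon set")(f)
    f = click.option("--stop-in-cds", is_flag=True,
                     help="GTF CDS features include the stop codon")(f)
    f = click.option("--seed", default=0, show_default=True)(f)
    return f


def _inputs(f):
    f = click.option("--species", "species_", nargs=3, multiple=True,
                     required=True, metavar="NAME GTF FASTA",
                     help="one per species, in precedence order")(f)
    f = click.option("--orthologs", required=True,
                     type=click.Path(exists=True),
                     help="gene-triplet TSV")(f)
    f = click.option("--junctions", nargs=2, multiple=True,
                     metavar="NAME PATH", help="junction support per species")(f)
    f = click.option("--annotation", nargs=4, multiple=True,
                     metavar="SPECIES NAME GTF FASTA",
                     help="extra annotation set for confirmation")(f)
    f = click.option("--outdir", required=True, type=click.Path())(f)
    f = click.option("--sqlite", is_flag=True, help="export SQLite database")(f)
    return f


@click.group()
def cli():
    """Splicing-structure orthology analysis of orthologous gene triplets."""
    logging.basicConfig(level=logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")


def _run_stage(stage, species_, orthologs, junctions, annotation, outdir,
               sqlite, identity, site_context, min_reads, start_codons,
               stop_in_cds, seed):
    del seed  # the analysis itself is deterministic
    species_files = {name: (gtf, fasta) for name, gtf, fasta in species_}
    config = _config_from(identity, site_context, min_reads, start_codons,
                          stop_in_cds, tuple(species_files))
    junction_paths = {name: path for name, path in junctions}
    ann: dict[str, list[tuple]] = {}
    for sp, name, gtf, fasta in annotation:
        ann.setdefault(sp, []).append((name, gtf, fasta))
    report, species_data = run_analysis(species_files, orthologs,
                                        junction_paths, ann, config)
    write_outputs(report, species_data, outdir, stage=stage, sqlite=sqlite,
                  config=config)
    click.echo(json.dumps(report.summary, indent=2, sort_keys=True))


for _stage, _help in [
        ("build", "Build gene structure models and stop."),
        ("compare", "Models plus pairwise token orthologies."),
        ("predict", "Models, orthologies and predicted CDSs."),
        ("graphs", "Through site/transcript graphs and verdicts."),
        ("evidence", "Through evidence tagging."),
        ("run", "Full analysis (all outputs)."),
        ("export", "Full analysis plus SQLite export.")]:
    def _make(stage):
        @_common
        @_inputs
        def _cmd(species_, orthologs, junctions, annotation, outdir, sqlite,
                 identity, site_context, min_reads, start_codons,
                 stop_in_cds, seed):
            _run_stage("run" if stage == "export" else stage, species_,
                       orthologs, junctions, annotation, outdir,
                       sqlite or stage == "export", identity, site_context,
                       min_reads, start_codons, stop_in_cds, seed)
        _cmd.__doc__ = _help
        return _cmd
    cli.command(name=_stage)(_make(_stage))


@cli.command()
@click.option("--fixture", default="all", show_default=True,
              type=click.Choice(["fig1", "fig4", "fig5", "all"]))
@click.option("--outdir", required=True, type=click.Path())
@click.option("--seed", default=0, show_default=True)
@click.option("--support", default="all", show_default=True,
              type=click.Choice(["all", "known"]))
def simulate(fixture, outdir, seed, support):
    """Write synthetic tri-species fixtures (FASTA, GTF, junctions, map)."""
    from .synthetic import figure_fixtures, realize_many
    specs = figure_fixtures(seed)
    if fixture != "all":
        specs = {fixture: specs[fixture]}
    fx = realize_many(list(specs.values()), outdir, support=support)
    click.echo(f"wrote {', '.join(sorted(p.name for p in fx.gtf.values()))} "
               f"under {fx.outdir}")
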