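"""Readers and writers: GTF, FASTA, ortholog maps, junction files, tables.

Internal coordinates are 0-based half-open on the gene locus in
transcription orientation; GTF and junction files use 1-based inclusive
genomic coordinates on the forward genome strand.  Conversion is an exact
bijection given a gene's genomic span and strand, and minus-strand loci are
reverse-complemented at load so every downstream model reads 5'->3'.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

from .models import (
    Config,
    DEFAULT_CONFIG,
    InputError,
    TranscriptRecord,
    TranscriptModel,
    is_valid_cds,
)

__all__ = [
    "GeneInput",
    "SpeciesData",
    "genomic_to_local",
    "local_to_genomic",
    "load_species",
    "read_ortholog_map",
    "read_junctions",
    "write_junctions",
    "write_fasta",
    "write_gtf",
    "write_predictions",
    "write_models_tsv",
    "export_sqlite",
]


# --------------------------------------------------------------------------
# coordinate conversion
# --------------------------------------------------------------------------

def genomic_to_local(span: tuple[int, int], gene_span: tuple[int, int],
                     strand: str) -> tuple[int, int]:
    """1-based inclusive genomic interval -> 0-based half-open local interval."""
    gs, ge = span
    lo, hi = gene_span
    if strand == "+":
        return (gs - lo, ge - lo + 1)
    if strand == "-":
        return (hi - ge, hi - gs + 1)
    raise InputError(f"unknown strand {strand!r}")


def local_to_genomic(ival: tuple[int, int], gene_span: tuple[int, int],
                     strand: str) -> tuple[int, int]:
    """0-based half-open local interval -> 1-based inclusive genomic interval."""
    s, e = ival
    lo, hi = gene_span
    if strand == "+":
        return (lo + s, lo + e - 1)
    if strand == "-":
        return (hi - e + 1, hi - s)
    raise InputError(f"unknown strand {strand!r}")


# --------------------------------------------------------------------------
# species loading
# --------------------------------------------------------------------------

@dataclass
class GeneInput:
    """One gene locus: sequence, span, and its annotated transcripts."""

    gene_id: str
    species: str
    seqname: str
    strand: str
    span: tuple[int, int]  # 1-based inclusive genomic
    locus: str  # transcription orientation
    records: list[TranscriptRecord] = field(default_factory=list)

    def to_genomic(self, ival: tuple[int, int]) -> tuple[int, int]:
        return local_to_genomic(ival, self.span, self.strand)

    def to_local(self, span: tuple[int, int]) -> tuple[int, int]:
        return genomic_to_local(span, self.span, self.strand)


@dataclass
class SpeciesData:
    species: str
    genes: dict[str, GeneInput]
    #: per-transcript CDS validity failures: (gene_id, transcript_id, reason)
    cds_validity_report: list[tuple[str, str, str]] = field(default_factory=list)


_UTR5_FEATURES = ("five_prime_utr", "5UTR")
_UTR3_FEATURES = ("three_prime_utr", "3UTR")


def load_species(gtf_path, fasta_path, species: str = "",
                 config: Config = DEFAULT_CONFIG) -> SpeciesData:
    """Load one species' annotation and genome into per-gene inputs.

    Expects GTF CDS features with ``gene_id``/``transcript_id`` attributes
    (UTR features optional).  When the dialect excludes the stop codon from
    CDS features (``config.stop_in_cds`` false, the Ensembl convention) the
    last CDS exon is extended by three nucleotides so that assembled CDSs
    end with their stop trinucleotide.  Every transcript's assembled CDS is
    checked with :func:`is_valid_cds`; violations are reported in
    ``cds_validity_report``, not dropped.
    """
    seqs = {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(fasta_path), "fasta")}
    db = gffutils.create_db(str(gtf_path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique",
                            disable_infer_genes=True,
                            disable_infer_transcripts=True)

    per_gene: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("gene", "CDS", "stop_codon") \
                and feat.featuretype not in _UTR5_FEATURES + _UTR3_FEATURES:
            continue
        try:
            gid = feat.attributes["gene_id"][0]
        except KeyError:
            raise InputError(f"{feat.featuretype} feature without gene_id "
                             f"at {feat.seqid}:{feat.start}")
        if feat.strand not in "+-":
            raise InputError(f"{gid}: unknown strand {feat.strand!r}")
        g = per_gene.setdefault(gid, {
            "seqname": feat.seqid, "strand": feat.strand,
            "lo": feat.start, "hi": feat.end, "feats": []})
        g["lo"] = min(g["lo"], feat.start)
        g["hi"] = max(g["hi"], feat.end)
        if feat.featuretype != "gene":
            g["feats"].append(feat)

    genes: dict[str, GeneInput] = {}
    report: list[tuple[str, str, str]] = []
    for gid in sorted(per_gene):
        info = per_gene[gid]
        seq = seqs.get(info["seqname"])
        if seq is None or info["hi"] > len(seq):
            raise InputError(
                f"{gid}: no sequence for {info['seqname']}:"
                f"{info['lo']}-{info['hi']}")
        span = (info["lo"], info["hi"])
        locus = seq[span[0] - 1:span[1]]
        if info["strand"] == "-":
            locus = str(Seq(locus).reverse_complement())
        gene = GeneInput(gid, species, info["seqname"], info["strand"],
                         span, locus)

        by_tx: dict[str, dict] = {}
        for feat in info["feats"]:
            try:
                tid = feat.attributes["transcript_id"][0]
            except KeyError:
                raise InputError(f"{gid}: {feat.featuretype} feature without "
                                 "transcript_id")
            tx = by_tx.setdefault(tid, {"cds": [], "utr5": [], "utr3": []})
            ival = gene.to_local((feat.start, feat.end))
            if feat.featuretype == "CDS":
                tx["cds"].append(ival)
            elif feat.featuretype in _UTR5_FEATURES:
                tx["utr5"].append(ival)
            elif feat.featuretype in _UTR3_FEATURES:
                tx["utr3"].append(ival)
            # stop_codon features are implied by the extension below

        for tid in sorted(by_tx):
            tx = by_tx[tid]
            cds = sorted(tx["cds"])
            if not cds:
                continue
            if not config.stop_in_cds:
                last = cds[-1]
                if last[1] + 3 > len(locus):
                    raise InputError(
                        f"{gid}/{tid}: stop codon outside the gene locus")
                cds[-1] = (last[0], last[1] + 3)
            rec = TranscriptRecord(tid, gid, cds,
                                   sorted(tx["utr5"]), sorted(tx["utr3"]))
            gene.records.append(rec)
            assembled = "".join(locus[s:e] for s, e in cds)
            try:
                ok, reason = is_valid_cds(assembled, config)
            except Exception as exc:  # non-ACGT etc.
                ok, reason = False, str(exc)
            if not ok:
                report.append((gid, tid, reason))
        genes[gid] = gene
    return SpeciesData(species, genes, report)


# --------------------------------------------------------------------------
# ortholog map and junction files
# --------------------------------------------------------------------------

def read_ortholog_map(path) -> tuple[list[str], list[tuple[str, ...]]]:
    """Read a gene-triplet TSV: header of species names, one row per triplet.

    Gene IDs must be unique across the whole table (one-to-one orthology).
    """
    lines = [ln.rstrip("\n") for ln in open(path) if ln.strip()]
    if not lines:
        raise InputError("empty ortholog map")
    species = lines[0].split("\t")
    triplets: list[tuple[str, ...]] = []
    seen: set[str] = set()
    for ln in lines[1:]:
        ids = tuple(ln.split("\t"))
        if len(ids) != len(species):
            raise InputError(f"ortholog map row has {len(ids)} columns, "
                             f"expected {len(species)}: {ln!r}")
        for gid in ids:
            if gid in seen:
                raise InputError(f"duplicate gene id in ortholog map: {gid}")
            seen.add(gid)
        triplets.append(ids)
    return species, triplets


def read_junctions(path) -> list[tuple[str, int, int, str, int]]:
    """Read a splice-junction support file.

    Accepts the 5-column tab format ``chrom  intron_start  intron_end
    strand  read_count`` (1-based inclusive intron coordinates) or 6-column
    BED (0-based half-open, score column = read count).
    """
    out = []
    for lineno, ln in enumerate(open(path), 1):
        ln = ln.rstrip("\n")
        if not ln or ln.startswith(("#", "track")):
            continue
        parts = ln.split("\t")
        try:
            if len(parts) == 5:
                chrom, s, e, strand, count = parts
                out.append((chrom, int(s), int(e), strand, int(count)))
            elif len(parts) == 6:
                chrom, s, e, _name, score, strand = parts
                out.append((chrom, int(s) + 1, int(e), strand, int(score)))
            else:
                raise ValueError(f"{len(parts)} columns")
        except ValueError as exc:
            raise InputError(f"{path}:{lineno}: malformed junction line "
                             f"({exc}): {ln!r}")
    return out


def write_junctions(path, rows) -> None:
    with open(path, "w") as fh:
        for chrom, s, e, strand, count in rows:
            fh.write(f"{chrom}\t{s}\t{e}\t{strand}\t{count}\n")


# --------------------------------------------------------------------------
# FASTA / GTF writing
# --------------------------------------------------------------------------

def write_fasta(path, seqs: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def _gtf_attrs(pairs: list[tuple[str, str]]) -> str:
    return " ".join(f'{k} "{v}";' for k, v in pairs)


def write_gtf(path, rows: list[tuple]) -> None:
    """Write GTF rows: (seqname, source, feature, start, end, strand, frame, attrs)."""
    with open(path, "w") as fh:
        fh.write("##format: gtf\n")
        for seqname, source, feature, start, end, strand, frame, attrs in rows:
            fh.write(f"{seqname}\t{source}\t{feature}\t{start}\t{end}\t.\t"
                     f"{strand}\t{frame}\t{_gtf_attrs(attrs)}\n")


def transcript_gtf_rows(gene: GeneInput, model: TranscriptModel,
                        utr5=None, utr3=None, extra_attrs=None,
                        source: str = "spliceortho",
                        config: Config = DEFAULT_CONFIG) -> list[tuple]:
    """GTF rows for one transcript's coding exon chain (plus optional UTRs).

    When the dialect excludes the stop codon from CDS features, the last
    three coding nucleotides are emitted as a ``stop_codon`` feature.
    """
    attrs = [("gene_id", gene.gene_id), ("transcript_id", model.transcript_id)]
    if extra_attrs:
        attrs += list(extra_attrs)
    chain = list(model.exon_chain)
    rows = []
    stop_rows = []
    if not config.stop_in_cds:
        s, e = chain[-1]
        chain[-1] = (s, e - 3)
        gs, ge = gene.to_genomic((e - 3, e))
        stop_rows.append((gene.seqname, source, "stop_codon", gs, ge,
                          gene.strand, "0", attrs))
        if chain[-1][0] == chain[-1][1]:
            chain.pop()
    frames = []
    cum = 0
    for s, e in chain:
        frames.append((3 - cum % 3) % 3)
        cum += e - s
    for (s, e), frame in zip(chain, frames):
        gs, ge = gene.to_genomic((s, e))
        rows.append((gene.seqname, source, "CDS", gs, ge, gene.strand,
                     str(frame), attrs))
    rows += stop_rows
    for feature, ivals in (("five_prime_utr", utr5), ("three_prime_utr", utr3)):
        for ival in ivals or []:
            gs, ge = gene.to_genomic(ival)
            rows.append((gene.seqname, source, feature, gs, ge, gene.strand,
                         ".", attrs))
    # GTF rows sorted by forward-genome coordinate
    return sorted(rows, key=lambda r: (r[0], r[3], r[4]))


def write_predictions(path, predictions: list[tuple[GeneInput, TranscriptModel, str]],
                      config: Config = DEFAULT_CONFIG) -> None:
    """Write predicted transcripts as GTF CDS features.

    Each prediction carries ``status "predicted"``, its source-species set
    and, when available, its evidence tag as attributes.
    """
    rows: list[tuple] = []
    for gene, model, tag in predictions:
        extra = [("status", "predicted"),
                 ("sources", ",".join(model.sources))]
        if tag:
            extra.append(("evidence", tag))
        gene_rows = [(gene.seqname, "spliceortho", "gene", gene.span[0],
                      gene.span[1], gene.strand, ".",
                      [("gene_id", gene.gene_id)])]
        rows += gene_rows + transcript_gtf_rows(
            gene, model, extra_attrs=extra, config=config)
    seen = set()
    unique = []
    for r in rows:
        key = (r[0], r[2], r[3], r[4], tuple(r[7]))
        if key not in seen:
            seen.add(key)
            unique.append(r)
    write_gtf(path, unique)


# --------------------------------------------------------------------------
# result tables
# --------------------------------------------------------------------------

def write_models_tsv(path, genes) -> None:
    """Serialize gene models: one token per row."""
    with open(path, "w") as fh:
        fh.write("gene_id\ttoken_index\tkind\tlabel\tstart\tend\tmotif\t"
                 "status\tsource_species\n")
        for gene in genes:
            for i, tok in enumerate(gene.tokens):
                fh.write(f"{gene.gene_id}\t{i}\t{tok.kind}\t{tok.label}\t"
                         f"{tok.start}\t{tok.end}\t{tok.motif}\t{tok.status}\t"
                         f"{','.join(tok.sources)}\n")


def export_sqlite(path, report) -> None:
    """Export a triplet-analysis report to a simplified SQLite database.

    Tables: genes, transcripts, tokens, orthologies, groups.
    """
    con = sqlite3.connect(str(path))
    cur = con.cursor()
    cur.executescript("""
        DROP TABLE IF EXISTS genes;
        DROP TABLE IF EXISTS transcripts;
        DROP TABLE IF EXISTS tokens;
        DROP TABLE IF EXISTS orthologies;
        DROP TABLE IF EXISTS groups;
        CREATE TABLE genes (gene_id TEXT PRIMARY KEY, species TEXT,
            triplet_id TEXT, strand TEXT, model TEXT);
        CREATE TABLE transcripts (transcript_id TEXT, gene_id TEXT,
            status TEXT, model TEXT, sources TEXT, evidence TEXT);
        CREATE TABLE tokens (gene_id TEXT, token_index INTEGER, kind TEXT,
            label TEXT, start INTEGER, end INTEGER, motif TEXT, status TEXT);
        CREATE TABLE orthologies (gene_a TEXT, token_a TEXT, gene_b TEXT,
            token_b TEXT, kind TEXT, identity REAL);
        CREATE TABLE groups (group_id TEXT, triplet_id TEXT, model TEXT,
            species TEXT, transcript_id TEXT, status TEXT);
    """)
    for tr in report.triplets:
        if tr.error:
            continue
        cmp_ = tr.comparison
        for gene in cmp_.genes.values():
            cur.execute("INSERT INTO genes VALUES (?,?,?,?,?)",
                        (gene.gene_id, gene.species, tr.triplet_id,
                         gene.strand, gene.model_string))
            for i, tok in enumerate(gene.tokens):
                cur.execute("INSERT INTO tokens VALUES (?,?,?,?,?,?,?,?)",
                            (gene.gene_id, i, tok.kind, tok.label, tok.start,
                             tok.end, tok.motif, tok.status))
            for tm in gene.transcripts:
                etag = tr.evidence.get(tm.transcript_id)
                cur.execute("INSERT INTO transcripts VALUES (?,?,?,?,?,?)",
                            (tm.transcript_id, tm.gene_id, tm.status,
                             tm.model_string, ",".join(tm.sources),
                             etag.tag if etag else ""))
        for orth in cmp_.orthologies:
            cur.execute("INSERT INTO orthologies VALUES (?,?,?,?,?,?)",
                        (orth.token_a.gene_id, orth.token_a.symbol,
                         orth.token_b.gene_id, orth.token_b.symbol,
                         orth.token_a.kind, orth.identity))
        for grp in tr.groups:
            for species in sorted(grp.members):
                for tid, status in grp.members[species]:
                    cur.execute("INSERT INTO groups VALUES (?,?,?,?,?,?)",
                                (grp.group_id, tr.triplet_id,
                                 grp.model_string, species, tid, status))
    con.commit()
    con.close()
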