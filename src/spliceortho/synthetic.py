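"""Deterministic generator of tri-species gene fixtures.

A :class:`FixtureSpec` declares, per species, a gene grammar (the coding
structure physically present in the locus), the subset of transcript
structures that are *annotated* (known), UTR lengths per transcript, block
and intron lengths, and sequence identities.  :func:`realize` writes
standard FASTA, GTF (CDS + UTR features), an ortholog-map TSV and a
splice-junction support file, and returns the planted ground truth
(site positions, block intervals, transcript models) for every species.

Homologous coding blocks are generated from one ancestral sequence and
mutated per species to the requested identity; introns are mutated
independently to a (low) intron identity, so exonic sequence is conserved
while intronic sequence diverges.  Exact splice motifs (GT donors, AG
acceptors), ATG starts and TAA stops are planted at every declared site and
are never touched by mutation; coding blocks are stop-codon-free in frame
so that every declared transcript assembles into a valid CDS.  Equal seeds
give byte-identical output files.

The module also houses the worked-example fixtures used throughout the
documentation and tests: a triplet whose seven known
transcripts yield five predicted CDSs and four three-species CDS orthology
groups (``fig1``); a gene with redundant CDSs encoded by UTR variants
(``fig4``); and a triplet where one gene genuinely lacks a coding block, so
the corresponding CDS structure cannot be predicted there (``fig5``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io_formats import GeneInput, transcript_gtf_rows, write_fasta, \
    write_gtf, write_junctions
from .models import (
    ACCEPTOR, BLOCK, DONOR, START, STOP,
    Config, DEFAULT_CONFIG, InputError, TranscriptModel, parse_model_string,
)

__all__ = [
    "KnownTranscript",
    "FixtureSpec",
    "Fixture",
    "realize",
    "realize_many",
    "figure_fixtures",
    "random_fixture_spec",
]

_STOPS = ("TAA", "TAG", "TGA")
_SAFE_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS)


# --------------------------------------------------------------------------
# fixture specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class KnownTranscript:
    transcript_id: str
    model: str
    utr5: int = 15
    utr3: int = 18


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of one orthologous gene (triplet) fixture."""

    name: str
    master_grammar: str
    gene_grammar: dict[str, str]
    transcripts: dict[str, tuple[KnownTranscript, ...]]
    block_lengths: dict[str, int]
    intron_lengths: dict[str, int] = field(default_factory=dict)
    default_intron: int = 80
    block_identity: float = 1.0
    intron_identity: float = 0.4
    strand: dict[str, str] = field(default_factory=dict)
    flank: int = 40
    seed: int = 0

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.gene_grammar)

    def gene_id(self, sp: str) -> str:
        return f"{sp}_{self.name}"

    # -- structural derivation -------------------------------------------

    def master_blocks(self) -> list[str]:
        toks = parse_model_string(self.master_grammar)
        labels = [t.label for t in toks if t.kind == BLOCK]
        if len(set(labels)) != len(labels):
            raise InputError(f"{self.name}: repeated block in master grammar")
        return labels

    def site_attachment(self) -> tuple[dict, dict]:
        """Per master block: site symbols before (start/acceptor) and
        after (donor/stop) it."""
        toks = parse_model_string(self.master_grammar)
        before: dict[str, set[str]] = {}
        after: dict[str, set[str]] = {}
        pending: list[str] = []
        prev_block: str | None = None
        for t in toks:
            if t.kind == BLOCK:
                before.setdefault(t.label, set()).update(pending)
                after.setdefault(t.label, set())
                pending = []
                prev_block = t.label
            elif t.kind in (START, ACCEPTOR):
                pending.append(t.kind)
            else:  # donor, stop: attach to preceding block
                if prev_block is None:
                    raise InputError(
                        f"{self.name}: {t.kind} before any block in grammar")
                after[prev_block].add(t.kind)
        return before, after

    def adjacent_pairs(self) -> set[tuple[str, str]]:
        """Consecutive master blocks with no intron between them: some
        declared transcript places them in one exon."""
        blocks = self.master_blocks()
        consecutive = set(zip(blocks, blocks[1:]))
        adjacent: set[tuple[str, str]] = set()
        for txs in self.transcripts.values():
            for tx in txs:
                toks = parse_model_string(tx.model)
                for a, b in zip(toks, toks[1:]):
                    if a.kind == BLOCK and b.kind == BLOCK:
                        if (a.label, b.label) not in consecutive:
                            raise InputError(
                                f"{self.name}/{tx.transcript_id}: blocks "
                                f"{a.label}{b.label} adjacent in transcript "
                                "but not consecutive in the master grammar")
                        adjacent.add((a.label, b.label))
        return adjacent

    def species_blocks(self, sp: str) -> list[str]:
        toks = parse_model_string(self.gene_grammar[sp])
        present = [t.label for t in toks if t.kind == BLOCK]
        master = self.master_blocks()
        if any(b not in master for b in present):
            raise InputError(f"{self.name}/{sp}: block outside master grammar")
        return present

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        master = self.master_blocks()
        before, after = self.site_attachment()
        adjacent = self.adjacent_pairs()
        for label in master:
            n = self.block_lengths.get(label)
            if n is None:
                raise InputError(f"{self.name}: no length for block {label}")
            if n % 3 or n < 6:
                raise InputError(
                    f"{self.name}: block {label} length {n} is not a "
                    "positive multiple of three")
        for sp, txs in self.transcripts.items():
            if sp not in self.gene_grammar:
                raise InputError(f"{self.name}: transcripts for unknown "
                                 f"species {sp}")
            present = set(self.species_blocks(sp))
            for tx in txs:
                toks = parse_model_string(tx.model)
                labels = [t.label for t in toks if t.kind == BLOCK]
                missing = [b for b in labels if b not in present]
                if missing:
                    raise InputError(
                        f"{self.name}/{tx.transcript_id}: blocks {missing} "
                        f"absent from the {sp} gene")
                if sum(self.block_lengths[b] for b in labels) % 3:
                    raise InputError(
                        f"{self.name}/{tx.transcript_id}: CDS length not a "
                        "multiple of three")
                if STOP not in after.get(labels[-1], set()):
                    raise InputError(
                        f"{self.name}/{tx.transcript_id}: terminal block "
                        f"{labels[-1]} carries no stop codon")
                for lab in labels[:-1]:
                    if STOP in after.get(lab, set()):
                        raise InputError(
                            f"{self.name}/{tx.transcript_id}: stop-carrying "
                            f"block {lab} used internally")
        # conflicting boundary-motif constraints surface here
        self._forced_positions()
        for pair in adjacent:
            key = f"{pair[0]}|{pair[1]}"
            if self.intron_lengths.get(key, 0):
                raise InputError(
                    f"{self.name}: blocks {key} are exon-adjacent but have "
                    "a declared intron length")

    def _forced_positions(self) -> dict[str, dict[int, str]]:
        """Nucleotides pinned inside blocks by boundary motifs."""
        before, after = self.site_attachment()
        blocks = self.master_blocks()
        adjacent = self.adjacent_pairs()
        forced: dict[str, dict[int, str]] = {b: {} for b in blocks}

        def pin(label, pos, nt):
            old = forced[label].get(pos)
            if old is not None and old != nt:
                raise InputError(
                    f"{self.name}: conflicting motif constraints on block "
                    f"{label} position {pos} ({old} vs {nt})")
            forced[label][pos] = nt

        for i, label in enumerate(blocks):
            n = self.block_lengths[label]
            if START in before[label]:
                for k, nt in enumerate("ATG"):
                    pin(label, k, nt)
            if STOP in after[label]:
                for k, nt in enumerate("TAA"):
                    pin(label, n - 3 + k, nt)
            prev = blocks[i - 1] if i > 0 else None
            nxt = blocks[i + 1] if i + 1 < len(blocks) else None
            if ACCEPTOR in before[label] and prev is not None \
                    and (prev, label) in adjacent:
                m = self.block_lengths[prev]
                for k, nt in enumerate("CAG"):
                    pin(prev, m - 3 + k, nt)
            if DONOR in after[label] and nxt is not None \
                    and (label, nxt) in adjacent:
                for k, nt in enumerate("GT"):
                    pin(nxt, k, nt)
        return forced


# --------------------------------------------------------------------------
# sequence realization
# --------------------------------------------------------------------------

def _random_codons(rng, n: int) -> str:
    return "".join(rng.choice(_SAFE_CODONS) for _ in range(n // 3))


def _random_seq(rng, n: int) -> str:
    return "".join(rng.choice(("A", "C", "G", "T")) for _ in range(n))


def _mutate_block(rng, seq: str, identity: float, forced: dict[int, str]) -> str:
    out = list(seq)
    for i in range(len(out)):
        if i in forced or rng.random() >= (1.0 - identity):
            continue
        codon_start = (i // 3) * 3
        alternatives = [c for c in "ACGT" if c != out[i]]
        rng.shuffle(alternatives)
        for alt in alternatives:
            trial = list(out)
            trial[i] = alt
            if "".join(trial[codon_start:codon_start + 3]) not in _STOPS:
                out[i] = alt
                break
    return "".join(out)


def _mutate_plain(rng, seq: str, identity: float,
                  forced: dict[int, str]) -> str:
    out = list(seq)
    for i in range(len(out)):
        if i in forced or rng.random() >= (1.0 - identity):
            continue
        out[i] = rng.choice([c for c in "ACGT" if c != out[i]])
    return "".join(out)


def _model_exon_chain(model: str, coords: dict[str, tuple[int, int]],
                      name: str) -> list[tuple[int, int]]:
    """Exon intervals (stop codon included) of a transcript model realized
    on a locus with the given block coordinates."""
    toks = parse_model_string(model)
    exons: list[list[str]] = [[]]
    for t in toks:
        if t.kind == BLOCK:
            exons[-1].append(t.label)
        elif t.kind == DONOR:
            exons.append([])
    chain = []
    for ex in exons:
        if not ex:
            raise InputError(f"{name}: empty exon in model {model!r}")
        for a, b in zip(ex, ex[1:]):
            if coords[a][1] != coords[b][0]:
                raise InputError(
                    f"{name}: blocks {a}{b} of one exon are not adjacent "
                    "on the locus")
        chain.append((coords[ex[0]][0], coords[ex[-1]][1]))
    return chain


@dataclass
class _RealizedGene:
    species: str
    gene_id: str
    seqname: str
    strand: str
    locus: str  # transcription orientation
    coords: dict[str, tuple[int, int]]
    known: list[tuple[KnownTranscript, list[tuple[int, int]]]]
    planted_sites: set[tuple[str, int]]


def _realize_spec(spec: FixtureSpec) -> dict[str, _RealizedGene]:
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    blocks = spec.master_blocks()
    before, after = spec.site_attachment()
    adjacent = spec.adjacent_pairs()
    forced = spec._forced_positions()

    ancestral_blocks: dict[str, str] = {}
    for label in blocks:
        seq = list(_random_codons(rng, spec.block_lengths[label]))
        for pos, nt in forced[label].items():
            seq[pos] = nt
        ancestral_blocks[label] = "".join(seq)

    gaps: dict[tuple[str, str], tuple[str, dict[int, str]]] = {}
    for a, b in zip(blocks, blocks[1:]):
        if (a, b) in adjacent:
            continue
        n = spec.intron_lengths.get(f"{a}|{b}", spec.default_intron)
        seq = list(_random_seq(rng, n))
        pinned: dict[int, str] = {}
        if DONOR in after[a]:
            seq[0], seq[1] = "G", "T"
            pinned[0], pinned[1] = "G", "T"
        if ACCEPTOR in before[b]:
            seq[-2], seq[-1] = "A", "G"
            pinned[n - 2], pinned[n - 1] = "A", "G"
        gaps[(a, b)] = ("".join(seq), pinned)

    out: dict[str, _RealizedGene] = {}
    for sp in spec.species:
        sp_rng = np.random.default_rng([spec.seed, _stable_hash(sp)])
        present = set(spec.species_blocks(sp))
        parts: list[str] = [_random_seq(sp_rng, spec.flank)]
        coords: dict[str, tuple[int, int]] = {}
        pos = spec.flank
        for i, label in enumerate(blocks):
            if label in present:
                seq = _mutate_block(sp_rng, ancestral_blocks[label],
                                    spec.block_identity, forced[label])
                parts.append(seq)
                coords[label] = (pos, pos + len(seq))
                pos += len(seq)
            if i + 1 < len(blocks):
                gap = gaps.get((label, blocks[i + 1]))
                if gap is not None:
                    seq = _mutate_plain(sp_rng, gap[0], spec.intron_identity,
                                        gap[1])
                    parts.append(seq)
                    pos += len(seq)
        parts.append(_random_seq(sp_rng, spec.flank))
        locus = "".join(parts)

        planted: set[tuple[str, int]] = set()
        for label in blocks:
            if label not in present:
                continue
            s, e = coords[label]
            if START in before[label]:
                planted.add((START, s))
            if ACCEPTOR in before[label]:
                planted.add((ACCEPTOR, s))
            if DONOR in after[label]:
                planted.add((DONOR, e))
            if STOP in after[label]:
                planted.add((STOP, e))

        gid = spec.gene_id(sp)
        known = []
        for tx in spec.transcripts.get(sp, ()):
            chain = _model_exon_chain(tx.model, coords,
                                      f"{spec.name}/{tx.transcript_id}")
            known.append((tx, chain))
        out[sp] = _RealizedGene(sp, gid, f"{gid}_locus",
                                spec.strand.get(sp, "+"), locus, coords,
                                known, planted)
    return out


def _stable_hash(text: str) -> int:
    h = 2166136261
    for ch in text.encode():
        h = ((h ^ ch) * 16777619) % (2 ** 31)
    return h


# --------------------------------------------------------------------------
# file emission
# --------------------------------------------------------------------------

@dataclass
class Fixture:
    """Realized fixture: file paths plus planted ground truth."""

    outdir: Path
    species: tuple[str, ...]
    fasta: dict[str, Path]
    gtf: dict[str, Path]
    junctions: dict[str, Path]
    ortholog_map: Path
    #: (fixture name, species) -> _RealizedGene with planted truth
    genes: dict[tuple[str, str], _RealizedGene]


def realize_many(specs: list[FixtureSpec], outdir,
                 support: str = "all",
                 config: Config = DEFAULT_CONFIG) -> Fixture:
    """Realize several fixtures into one per-species FASTA/GTF/junction set.

    ``support`` selects which exon junctions receive read support:
    ``"all"`` covers every junction realizable from the union of declared
    transcript structures (in species where the blocks exist), ``"known"``
    only those of the species' own known transcripts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    all_species: list[str] = []
    for spec in specs:
        for sp in spec.species:
            if sp not in all_species:
                all_species.append(sp)

    fasta: dict[str, dict[str, str]] = {sp: {} for sp in all_species}
    gtf_rows: dict[str, list] = {sp: [] for sp in all_species}
    junc_rows: dict[str, list] = {sp: [] for sp in all_species}
    genes: dict[tuple[str, str], _RealizedGene] = {}
    map_rows: list[tuple[str, ...]] = []

    for spec in specs:
        realized = _realize_spec(spec)
        map_rows.append(tuple(realized[sp].gene_id for sp in all_species
                              if sp in realized))
        union_models: list[str] = []
        for sp in spec.species:
            for tx in spec.transcripts.get(sp, ()):
                if tx.model not in union_models:
                    union_models.append(tx.model)
        for sp in spec.species:
            rg = realized[sp]
            genes[(spec.name, sp)] = rg
            L = len(rg.locus)
            if rg.strand == "-":
                from Bio.Seq import Seq
                fasta[sp][rg.seqname] = str(Seq(rg.locus).reverse_complement())
            else:
                fasta[sp][rg.seqname] = rg.locus
            shim = GeneInput(rg.gene_id, sp, rg.seqname, rg.strand,
                             (1, L), rg.locus)
            gtf_rows[sp].append((rg.seqname, "spliceortho", "gene", 1, L,
                                 rg.strand, ".", [("gene_id", rg.gene_id)]))
            for tx, chain in rg.known:
                model = TranscriptModel(tx.transcript_id, rg.gene_id,
                                        list(chain))
                utr5 = [(chain[0][0] - tx.utr5, chain[0][0])] \
                    if tx.utr5 else None
                utr3 = [(chain[-1][1], chain[-1][1] + tx.utr3)] \
                    if tx.utr3 else None
                if utr5 and utr5[0][0] < 0:
                    raise InputError(f"{tx.transcript_id}: 5' UTR outside locus")
                if utr3 and utr3[0][1] > L:
                    raise InputError(f"{tx.transcript_id}: 3' UTR outside locus")
                gtf_rows[sp] += transcript_gtf_rows(
                    shim, model, utr5=utr5, utr3=utr3,
                    extra_attrs=[("status", "known")], config=config)
            # junction support
            if support == "known":
                models = [tx.model for tx in spec.transcripts.get(sp, ())]
            else:
                models = union_models
            seen = set()
            for idx, mstr in enumerate(models):
                toks = parse_model_string(mstr)
                if any(t.kind == BLOCK and t.label not in rg.coords
                       for t in toks):
                    continue
                chain = _model_exon_chain(mstr, rg.coords, spec.name)
                for d, a in zip([e for _s, e in chain[:-1]],
                                [s for s, _e in chain[1:]]):
                    gs, ge = shim.to_genomic((d, a))
                    key = (rg.seqname, gs, ge)
                    if key in seen:
                        continue
                    seen.add(key)
                    junc_rows[sp].append((rg.seqname, gs, ge, rg.strand,
                                          8 + (gs + idx) % 7))

    paths_fa, paths_gtf, paths_j = {}, {}, {}
    for sp in all_species:
        paths_fa[sp] = outdir / f"{sp}.fa"
        write_fasta(paths_fa[sp], fasta[sp])
        paths_gtf[sp] = outdir / f"{sp}.gtf"
        write_gtf(paths_gtf[sp], gtf_rows[sp])
        paths_j[sp] = outdir / f"{sp}.junctions.tab"
        write_junctions(paths_j[sp], sorted(junc_rows[sp]))
    map_path = outdir / "orthologs.tsv"
    with open(map_path, "w") as fh:
        fh.write("\t".join(all_species) + "\n")
        for row in map_rows:
            fh.write("\t".join(row) + "\n")
    return Fixture(outdir, tuple(all_species), paths_fa, paths_gtf,
                   paths_j, map_path, genes)


def realize(spec: FixtureSpec, outdir, support: str = "all",
            config: Config = DEFAULT_CONFIG) -> Fixture:
    """Realize one fixture (see :func:`realize_many`)."""
    return realize_many([spec], outdir, support=support, config=config)


# --------------------------------------------------------------------------
# the figure worked examples
# --------------------------------------------------------------------------

def figure_fixtures(seed: int = 0) -> dict[str, FixtureSpec]:
    """Named worked-example fixtures.

    ``fig1``: six blocks with alternative exon variants C/BC and F/EF;
    mouse knows all four CDS structures, human two (only the BC- and
    EF-containing forms, so its locus lacks annotation for the acceptors of
    C and of F), dog one -- its locus lacks annotation for block B, B's
    acceptor and F's acceptor.  The triplet yields five predicted CDSs (two
    in human, three in dog) and four three-species CDS orthology groups.

    ``fig4``: two CDS structures; one encoded by two human, two mouse and
    one dog known transcripts differing only in UTRs, the other by one
    transcript per species.

    ``fig5``: gene model ``[A<>B<>C]>D]``; the dog gene genuinely lacks
    block C (deleted from the sequence), so the C-containing CDS is
    predicted in human but cannot be predicted in dog.
    """
    s1 = "[A<>BC<>D<>EF]"
    s2 = "[A<>BC<>EF]"
    s3 = "[A<>C<>D<>EF]"
    s4 = "[A<>BC<>D<>F]"
    fig1 = FixtureSpec(
        name="fig1",
        master_grammar="[A<>B>C<>D<>E>F]",
        gene_grammar={sp: "[A<>B>C<>D<>E>F]"
                      for sp in ("human", "mouse", "dog")},
        transcripts={
            "mouse": (
                KnownTranscript("mouse_fig1_t1", s1, 15, 18),
                KnownTranscript("mouse_fig1_t2", s2, 12, 24),
                KnownTranscript("mouse_fig1_t3", s3, 21, 15),
                KnownTranscript("mouse_fig1_t4", s4, 18, 21),
            ),
            "human": (
                KnownTranscript("human_fig1_t1", s1, 24, 15),
                KnownTranscript("human_fig1_t2", s2, 15, 27),
            ),
            "dog": (
                KnownTranscript("dog_fig1_t1", s3, 12, 12),
            ),
        },
        block_lengths={"A": 24, "B": 18, "C": 27, "D": 21, "E": 18, "F": 24},
        intron_lengths={"A|B": 90, "C|D": 75, "D|E": 60},
        seed=seed,
    )

    r1 = "[A<>BC]"
    r2 = "[A<>C]"
    fig4 = FixtureSpec(
        name="fig4",
        master_grammar="[A<>B>C]",
        gene_grammar={sp: "[A<>B>C]" for sp in ("human", "mouse", "dog")},
        transcripts={
            "human": (
                KnownTranscript("human_fig4_t1", r1, 15, 21),
                KnownTranscript("human_fig4_t2", r1, 30, 33),
                KnownTranscript("human_fig4_t3", r2, 18, 15),
            ),
            "mouse": (
                KnownTranscript("mouse_fig4_t1", r1, 12, 18),
                KnownTranscript("mouse_fig4_t2", r1, 27, 30),
                KnownTranscript("mouse_fig4_t3", r2, 15, 12),
            ),
            "dog": (
                KnownTranscript("dog_fig4_t1", r1, 12, 15),
                KnownTranscript("dog_fig4_t2", r2, 18, 12),
            ),
        },
        block_lengths={"A": 24, "B": 18, "C": 27},
        intron_lengths={"A|B": 80},
        seed=seed + 1,
    )

    t_c = "[A<>B<>C]"
    t_d = "[A<>B<>D]"
    fig5 = FixtureSpec(
        name="fig5",
        master_grammar="[A<>B<>C]>D]",
        gene_grammar={
            "human": "[A<>B<>C]>D]",
            "mouse": "[A<>B<>C]>D]",
            "dog": "[A<>B<>D]",
        },
        transcripts={
            "mouse": (
                KnownTranscript("mouse_fig5_t1", t_c, 15, 18),
                KnownTranscript("mouse_fig5_t2", t_d, 21, 15),
            ),
            "human": (
                KnownTranscript("human_fig5_t1", t_d, 18, 12),
            ),
            "dog": (
                KnownTranscript("dog_fig5_t1", t_d, 12, 15),
            ),
        },
        block_lengths={"A": 24, "B": 21, "C": 27, "D": 24},
        intron_lengths={"A|B": 80, "B|C": 70, "C|D": 65},
        seed=seed + 2,
    )
    return {"fig1": fig1, "fig4": fig4, "fig5": fig5}


# --------------------------------------------------------------------------
# random fixtures for property tests
# --------------------------------------------------------------------------

def random_fixture_spec(seed: int,
                        species: tuple[str, ...] = ("human",),
                        block_identity: float = 1.0,
                        intron_identity: float = 0.4) -> FixtureSpec:
    """A random but always-valid single-gene fixture.

    Every transcript keeps the first (start-carrying) and last
    (stop-carrying) block; interior blocks are included at random, and
    consecutive blocks are exon-adjacent at random.  Identical structure is
    declared for every requested species.
    """
    rng = np.random.default_rng(seed)
    n_blocks = int(rng.integers(3, 7))
    labels = [chr(ord("A") + i) for i in range(n_blocks)]
    lengths = {lab: int(rng.integers(6, 11)) * 3 for lab in labels}
    adjacent = {(labels[i], labels[i + 1])
                for i in range(n_blocks - 1) if rng.random() < 0.3}

    # at most 2**(n_blocks - 2) distinct subsets exist (first/last fixed)
    n_tx = min(int(rng.integers(2, 5)), 2 ** (n_blocks - 2))
    subsets: list[tuple[str, ...]] = [tuple(labels)]
    attempts = 0
    while len(subsets) < n_tx and attempts < 200:
        attempts += 1
        keep = [labels[0]] + \
            [lab for lab in labels[1:-1] if rng.random() < 0.6] + [labels[-1]]
        if tuple(keep) not in subsets:
            subsets.append(tuple(keep))

    def model_for(subset: tuple[str, ...]) -> str:
        out = ["["]
        for i, lab in enumerate(subset):
            if i > 0:
                prev = subset[i - 1]
                if (prev, lab) not in adjacent:
                    out += ["<", ">"]
            out.append(lab)
        out.append("]")
        return "".join(out)

    models = [model_for(s) for s in subsets]
    # master grammar: union of the per-block site requirements
    before: dict[str, set[str]] = {lab: set() for lab in labels}
    after: dict[str, set[str]] = {lab: set() for lab in labels}
    before[labels[0]].add(START)
    after[labels[-1]].add(STOP)
    for subset in subsets:
        for i, lab in enumerate(subset):
            if i > 0:
                prev = subset[i - 1]
                if (prev, lab) not in adjacent:
                    after[prev].add(DONOR)
                    before[lab].add(ACCEPTOR)
    # exon-adjacent blocks skipped in some transcript need boundary sites
    for subset in subsets:
        for a, b in zip(labels, labels[1:]):
            if (a, b) in adjacent:
                if a in subset and b not in subset:
                    after[a].add(DONOR)
                if b in subset and a not in subset:
                    before[b].add(ACCEPTOR)

    sym = {START: "[", DONOR: "<", ACCEPTOR: ">", STOP: "]"}
    rank = {STOP: 0, DONOR: 1, ACCEPTOR: 2, START: 3}
    grammar = []
    for lab in labels:
        for kind in sorted(before[lab], key=rank.get):
            grammar.append(sym[kind])
        grammar.append(lab)
        for kind in sorted(after[lab], key=rank.get):
            grammar.append(sym[kind])
    grammar_str = "".join(grammar)

    txs = tuple(
        KnownTranscript(f"{{sp}}_rnd{seed}_t{i + 1}", m,
                        int(rng.integers(8, 25)), int(rng.integers(8, 25)))
        for i, m in enumerate(models))
    return FixtureSpec(
        name=f"rnd{seed}",
        master_grammar=grammar_str,
        gene_grammar={sp: grammar_str for sp in species},
        transcripts={sp: tuple(replace(t, transcript_id=t.transcript_id
                                       .format(sp=sp)) for t in txs)
                     for sp in species},
        block_lengths=lengths,
        intron_lengths={},
        default_intron=int(rng.integers(60, 100)),
        block_identity=block_identity,
        intron_identity=intron_identity,
        seed=seed,
    )
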