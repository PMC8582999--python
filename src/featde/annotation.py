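"""Flatten gene models into disjoint exon counting units.

Counting reads per exon requires non-overlapping units: the exons of a gene's
isoforms overlap each other, so within each gene the union of all exon
intervals is merged into maximal disjoint intervals ("exon-union" flattening),
numbered 5'→3' along the gene strand as ``<gene_id>:E001`` etc.  Genomic
regions claimed by more than one gene are reported (and can optionally be
excluded) so that no counting unit is ambiguous.

Coordinates are 1-based inclusive throughout (GTF convention).  Input gene
models can be built programmatically or read from GTF/GFF3 via
:func:`read_gene_models` (backed by gffutils).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "GeneModel",
    "FlattenedExonSet",
    "flatten_gene",
    "flatten_annotation",
    "read_gene_models",
    "write_flattened_gtf",
]


@dataclass
class GeneModel:
    """One gene: a chromosome, strand, and per-transcript exon interval lists."""

    gene_id: str
    chrom: str
    strand: str  # '+', '-' or '.'
    transcripts: list  # list of lists of (start, end), 1-based inclusive

    def __post_init__(self) -> None:
        for exons in self.transcripts:
            for start, end in exons:
                if start > end:
                    raise ValueError(
                        f"{self.gene_id}: exon has start {start} > end {end}"
                    )

    def all_exons(self) -> list:
        return [iv for exons in self.transcripts for iv in exons]


@dataclass
class FlattenedExonSet:
    """Disjoint, sorted counting units of one gene with 5'→3' unit IDs."""

    gene_id: str
    chrom: str
    strand: str
    units: list  # sorted disjoint (start, end)
    unit_ids: list
    #: per unit, the source exon intervals merged into it
    provenance: list = field(default_factory=list)

    def total_length(self) -> int:
        return sum(end - start + 1 for start, end in self.units)


def _merge_intervals(intervals):
    """Union-merge overlapping or bookended 1-based inclusive intervals.

    Returns (merged, provenance) where provenance[i] lists the source
    intervals contributing to merged[i].
    """
    if not intervals:
        return [], []
    ordered = sorted(intervals)
    merged = [list(ordered[0])]
    prov = [[ordered[0]]]
    for start, end in ordered[1:]:
        cur = merged[-1]
        if start <= cur[1] + 1:  # overlap or bookended
            cur[1] = max(cur[1], end)
            prov[-1].append((start, end))
        else:
            merged.append([start, end])
            prov.append([(start, end)])
    return [tuple(m) for m in merged], prov


def _number_units(gene_id, units, strand):
    # 5'→3': ascending coordinates on '+' (and unknown), descending on '-'
    order = range(len(units)) if strand != "-" else range(len(units) - 1, -1, -1)
    ids = [None] * len(units)
    for n, i in enumerate(order, start=1):
        ids[i] = f"{gene_id}:E{n:03d}"
    return ids


def flatten_gene(model: GeneModel) -> FlattenedExonSet:
    """Merge a gene's exon intervals into maximal disjoint counting units."""
    exons = model.all_exons()
    if not exons:
        raise ValueError(f"{model.gene_id}: gene model has no exons")
    merged, prov = _merge_intervals(exons)
    ids = _number_units(model.gene_id, merged, model.strand)
    return FlattenedExonSet(model.gene_id, model.chrom, model.strand,
                            merged, ids, prov)


def _subtract(intervals, cuts):
    """Remove the union of ``cuts`` from each interval (1-based inclusive)."""
    cuts, _ = _merge_intervals(cuts)
    out = []
    for start, end in intervals:
        pieces = [(start, end)]
        for cs, ce in cuts:
            next_pieces = []
            for ps, pe in pieces:
                if ce < ps or cs > pe:
                    next_pieces.append((ps, pe))
                    continue
                if ps < cs:
                    next_pieces.append((ps, cs - 1))
                if ce < pe:
                    next_pieces.append((ce + 1, pe))
            pieces = next_pieces
        out.extend(pieces)
    return sorted(out)


def flatten_annotation(models, exclude_overlaps: bool = False):
    """Flatten every gene and report genomic spans claimed by several genes.

    Returns ``(flattened, overlaps)`` where ``overlaps`` is a list of
    ``(chrom, start, end, [gene_ids])``.  With ``exclude_overlaps=True`` the
    shared spans are removed from the units of every affected gene (units are
    renumbered; genes left without units are dropped).
    """
    seen = set()
    for m in models:
        if m.gene_id in seen:
            raise ValueError(f"duplicate gene_id {m.gene_id!r}")
        seen.add(m.gene_id)

    flattened = [flatten_gene(m) for m in models]

    # Sweep per chromosome over unit boundaries, recording spans covered by
    # more than one distinct gene.
    overlaps = []
    by_chrom = {}
    for fs in flattened:
        by_chrom.setdefault(fs.chrom, []).extend(
            (start, end, fs.gene_id) for start, end in fs.units
        )
    for chrom, ivs in sorted(by_chrom.items()):
        events = []
        for start, end, gene in ivs:
            events.append((start, 0, gene))       # open (half-open at end+1)
            events.append((end + 1, 1, gene))     # close
        events.sort(key=lambda e: (e[0], e[1]))
        open_genes: dict = {}
        pos = None
        i = 0
        while i < len(events):
            at = events[i][0]
            if pos is not None and len(open_genes) > 1 and at > pos:
                overlaps.append((chrom, pos, at - 1, sorted(open_genes)))
            while i < len(events) and events[i][0] == at:
                _, kind, gene = events[i]
                if kind == 0:
                    open_genes[gene] = open_genes.get(gene, 0) + 1
                else:
                    open_genes[gene] -= 1
                    if open_genes[gene] == 0:
                        del open_genes[gene]
                i += 1
            pos = at

    if exclude_overlaps and overlaps:
        cuts_by_chrom = {}
        for chrom, start, end, _ in overlaps:
            cuts_by_chrom.setdefault(chrom, []).append((start, end))
        cleaned = []
        for fs in flattened:
            cuts = cuts_by_chrom.get(fs.chrom, [])
            units = _subtract(fs.units, cuts) if cuts else fs.units
            if not units:
                continue
            ids = _number_units(fs.gene_id, units, fs.strand)
            cleaned.append(FlattenedExonSet(fs.gene_id, fs.chrom, fs.strand,
                                            list(units), ids))
        flattened = cleaned

    return flattened, overlaps


def read_gene_models(path) -> list:
    """Read gene models from a GTF or GFF3 file (gffutils in-memory db).

    Exons are grouped by their ``gene_id`` attribute (GTF) or by walking the
    ``Parent`` chain to a gene feature (GFF3).  The strand and chromosome of a
    gene are taken from its exons and must agree.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="merge",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    genes: dict = {}
    for exon in db.features_of_type("exon"):
        if "gene_id" in exon.attributes:
            gene_id = exon.attributes["gene_id"][0]
        else:
            parents = [p.id for p in db.parents(exon, featuretype="gene")]
            if not parents:
                parents = [p.id for p in db.parents(exon)]
            if not parents:
                raise ValueError(f"exon at {exon.seqid}:{exon.start} has no gene")
            gene_id = parents[0]
        tx = exon.attributes.get("transcript_id", ["_tx"])[0]
        entry = genes.setdefault(gene_id, {"chrom": exon.seqid,
                                           "strand": exon.strand, "tx": {}})
        if entry["chrom"] != exon.seqid:
            raise ValueError(
                f"gene {gene_id}: exons on multiple chromosomes "
                f"({entry['chrom']} vs {exon.seqid})"
            )
        entry["tx"].setdefault(tx, []).append((exon.start, exon.end))
    return [
        GeneModel(gene_id, e["chrom"], e["strand"], list(e["tx"].values()))
        for gene_id, e in genes.items()
    ]


def write_flattened_gtf(flattened, path) -> None:
    """Write flattened counting units as GTF exon records."""
    with open(path, "w") as fh:
        for fs in flattened:
            for (start, end), unit_id in zip(fs.units, fs.unit_ids):
                attrs = (f'gene_id "{fs.gene_id}"; '
                         f'exon_id "{unit_id}";')
                fh.write("\t".join([
                    fs.chrom, "featde", "exon", str(start), str(end),
                    ".", fs.strand, ".", attrs,
                ]) + "\n")
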