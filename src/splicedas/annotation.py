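"""Transcript annotation model and GTF input/output.

Coordinates are stored 0-based half-open throughout the package; GTF I/O
converts from/to the 1-based inclusive convention of the format.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

Interval = tuple[int, int]


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


@dataclass
class Transcript:
    transcript_id: str
    exons: list[Interval]
    cds: Optional[Interval] = None

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def junctions(self) -> list[Interval]:
        """Intron coordinates (donor end, acceptor start) between consecutive exons."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    def validate(self) -> None:
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id}: no exons")
        for s, e in self.exons:
            if not (0 <= s < e):
                raise AnnotationError(
                    f"transcript {self.transcript_id}: bad exon interval [{s}, {e})"
                )
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: exons overlap or unsorted "
                    f"([{s1},{e1}) then [{s2},{e2}))"
                )
        if self.cds is not None:
            c0, c1 = self.cds
            if not (self.start <= c0 < c1 <= self.end):
                raise AnnotationError(
                    f"transcript {self.transcript_id}: CDS [{c0},{c1}) outside "
                    f"exonic span [{self.start},{self.end})"
                )


@dataclass
class GeneModel:
    gene_id: str
    chromosome: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)

    def validate(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"gene {self.gene_id}: strand must be + or -")
        for tx in self.transcripts:
            tx.validate()


@dataclass
class GenomeAnnotation:
    genes: list[GeneModel] = field(default_factory=list)

    def validate(self) -> None:
        for gene in self.genes:
            gene.validate()

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def chromosomes(self) -> set[str]:
        return {g.chromosome for g in self.genes}

    def transcripts(self) -> Iterable[tuple[GeneModel, Transcript]]:
        for g in self.genes:
            for tx in g.transcripts:
                yield g, tx


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_gtf(path: str) -> GenomeAnnotation:
    """Read exon (and optional CDS) features from a GTF file.

    Transcripts are assembled from features sharing a transcript_id; exons are
    sorted by start. CDS segments are merged into a single genomic interval.
    Raises :class:`AnnotationError` naming the offending line or transcript.
    """
    exons: dict[str, list[Interval]] = {}
    cds: dict[str, list[Interval]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tx -> (gene, chrom, strand)
    order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature not in ("exon", "CDS"):
                continue
            try:
                start = int(start_s) - 1  # GTF is 1-based inclusive
                end = int(end_s)
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: bad coordinates") from exc
            attributes = _parse_attributes(attrs)
            try:
                gene_id = attributes["gene_id"]
                tx_id = attributes["transcript_id"]
            except KeyError as exc:
                raise AnnotationError(
                    f"{path}:{lineno}: missing {exc.args[0]} attribute"
                ) from exc
            if tx_id not in meta:
                meta[tx_id] = (gene_id, chrom, strand)
                order.append(tx_id)
            elif meta[tx_id] != (gene_id, chrom, strand):
                raise AnnotationError(
                    f"{path}:{lineno}: transcript {tx_id} changes "
                    "gene/chromosome/strand"
                )
            if feature == "exon":
                exons.setdefault(tx_id, []).append((start, end))
            else:
                cds.setdefault(tx_id, []).append((start, end))

    genes: dict[str, GeneModel] = {}
    gene_order: list[str] = []
    for tx_id in order:
        gene_id, chrom, strand = meta[tx_id]
        tx_exons = sorted(exons.get(tx_id, []))
        tx_cds = None
        if tx_id in cds:
            segs = sorted(cds[tx_id])
            tx_cds = (segs[0][0], segs[-1][1])
        tx = Transcript(tx_id, tx_exons, tx_cds)
        tx.validate()
        if gene_id not in genes:
            genes[gene_id] = GeneModel(gene_id, chrom, strand)
            gene_order.append(gene_id)
        gene = genes[gene_id]
        if gene.chromosome != chrom or gene.strand != strand:
            raise AnnotationError(
                f"transcript {tx_id}: chromosome/strand differs from other "
                f"transcripts of gene {gene_id}"
            )
        gene.transcripts.append(tx)

    ann = GenomeAnnotation([genes[g] for g in gene_order])
    ann.validate()
    return ann


def write_gtf(annotation: GenomeAnnotation, path: str) -> None:
    """Write the annotation back out as GTF (exon and CDS features)."""
    with open(path, "w") as fh:
        for gene in annotation.genes:
            for tx in gene.transcripts:
                attrs = f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}";'
                for s, e in tx.exons:
                    fh.write(
                        "\t".join(
                            [
                                gene.chromosome,
                                "splicedas",
                                "exon",
                                str(s + 1),
                                str(e),
                                ".",
                                gene.strand,
                                ".",
                                attrs,
                            ]
                        )
                        + "\n"
                    )
                if tx.cds is not None:
                    c0, c1 = tx.cds
                    for s, e in tx.exons:
                        lo, hi = max(s, c0), min(e, c1)
                        if lo < hi:
                            fh.write(
                                "\t".join(
                                    [
                                        gene.chromosome,
                                        "splicedas",
                                        "CDS",
                                        str(lo + 1),
                                        str(hi),
                                        ".",
                                        gene.strand,
                                        "0",
                                        attrs,
                                    ]
                                )
                                + "\n"
                            )
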