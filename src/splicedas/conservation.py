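"""Cross-species splicing conservation.

Given differential-splicing results in two species (here generically "a" and
"b"; in the motivating application mouse and human), this module:

* maps genes through homology groups and tests whether differentially
  spliced genes overlap more than expected (one-sided Fisher exact test on
  the Venn counts against the homologous expressed background);
* extracts the two isoform sequences covering an exon-skipping event
  (upstream exon + variable exon + downstream exon vs upstream + downstream),
  translating in the annotated frame when the event lies inside the CDS of
  both isoforms;
* globally aligns the 2x2 cross-species isoform pairings and labels
  conservation: ``both`` (straight pairing, inc<->inc / exc<->exc),
  ``cross_matched`` (the inclusion isoform of one species matches the
  exclusion isoform of the other), ``partial`` or ``none``;
* calls PSI consistency: an event is conserved in the same isoform (Y) iff
  delta PSI has the same sign in both species AND the isoform-conservation
  label is ``both``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from scipy.stats import fisher_exact

from .annotation import GenomeAnnotation, Transcript
from .events import SpliceEvent

LABELS = ("both", "cross_matched", "partial", "none")


class HomologyMap:
    """Bidirectional gene lookup through homology groups."""

    def __init__(self, pairs: list[tuple[str, str, str]]):
        # (group_id, gene_a, gene_b)
        self._a2b: dict[str, str] = {}
        self._b2a: dict[str, str] = {}
        self._group: dict[str, str] = {}
        for group_id, ga, gb in pairs:
            if ga in self._a2b or gb in self._b2a:
                raise ValueError(
                    f"gene mapped to more than one homology group: {ga}/{gb}"
                )
            self._a2b[ga] = gb
            self._b2a[gb] = ga
            self._group[ga] = group_id
            self._group[gb] = group_id

    @classmethod
    def from_pairs(cls, pairs: list[tuple[str, str]]) -> "HomologyMap":
        return cls([(str(i), a, b) for i, (a, b) in enumerate(pairs)])

    @classmethod
    def read_homologene(
        cls, path: str, taxid_a: str = "10090", taxid_b: str = "9606"
    ) -> "HomologyMap":
        """Read a HomoloGene-format flat TSV:
        group_id, taxonomy_id, gene_id, gene_symbol[, ...]."""
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            dtype=str,
            usecols=[0, 1, 2, 3],
            names=["group", "taxid", "gene_id", "symbol"],
        )
        pairs = []
        for group, sub in df.groupby("group", sort=True):
            sym_a = sub.loc[sub["taxid"] == taxid_a, "symbol"]
            sym_b = sub.loc[sub["taxid"] == taxid_b, "symbol"]
            if len(sym_a) == 1 and len(sym_b) == 1:
                pairs.append((group, sym_a.iloc[0], sym_b.iloc[0]))
        return cls(pairs)

    def b_for_a(self, gene_a: str) -> Optional[str]:
        return self._a2b.get(gene_a)

    def a_for_b(self, gene_b: str) -> Optional[str]:
        return self._b2a.get(gene_b)

    def pairs(self) -> list[tuple[str, str]]:
        return sorted(self._a2b.items())


@dataclass
class VennCounts:
    both: int
    a_only: int
    b_only: int
    background_total: int

    def validate(self) -> None:
        if min(self.both, self.a_only, self.b_only, self.background_total) < 0:
            raise ValueError("Venn counts must be non-negative")
        if self.both + self.a_only + self.b_only > self.background_total:
            raise ValueError("Venn counts exceed background total")


@dataclass
class IsoformConservation:
    label: str
    identities: dict[str, float]  # keys inc_inc, exc_exc, inc_exc, exc_inc


@dataclass
class ConservedEventCall:
    gene_a: str
    gene_b: str
    dpsi_a: float
    dpsi_b: float
    label: str
    psi_consistent: str = ""

    def __post_init__(self):
        if not self.psi_consistent:
            self.psi_consistent = call_psi_consistency(
                self.dpsi_a, self.dpsi_b, self.label
            )


def overlap_enrichment(venn: VennCounts) -> tuple[float, float]:
    """One-sided (greater) Fisher exact test of shared differentially spliced
    homologous genes. Returns (sample odds ratio, p)."""
    venn.validate()
    neither = venn.background_total - venn.both - venn.a_only - venn.b_only
    table = [[venn.both, venn.a_only], [venn.b_only, neither]]
    odds, p = fisher_exact(table, alternative="greater")
    return float(odds), float(p)


def shared_gene_sets(
    das_genes_a: set[str],
    das_genes_b: set[str],
    homology: HomologyMap,
    expressed_a: set[str],
    expressed_b: set[str],
) -> VennCounts:
    """Venn counts at the homology-group level.

    Background = homology groups with both members expressed; genes in a DAS
    list missing from the expressed list are added with a warning.
    """
    for g in das_genes_a - expressed_a:
        warnings.warn(f"species-a DAS gene {g} not in expressed list; adding")
    for g in das_genes_b - expressed_b:
        warnings.warn(f"species-b DAS gene {g} not in expressed list; adding")
    expressed_a = expressed_a | das_genes_a
    expressed_b = expressed_b | das_genes_b

    background = 0
    both = a_only = b_only = 0
    for ga, gb in homology.pairs():
        if ga in expressed_a and gb in expressed_b:
            background += 1
            da = ga in das_genes_a
            db = gb in das_genes_b
            if da and db:
                both += 1
            elif da:
                a_only += 1
            elif db:
                b_only += 1
    return VennCounts(both, a_only, b_only, background)


def _spliced_offset(tx: Transcript, genomic_pos: int, strand: str) -> int:
    """Distance along the spliced transcript from the 5' CDS-containing end
    to a genomic position lying on an exon boundary set."""
    if strand == "+":
        off = 0
        for s, e in tx.exons:
            if genomic_pos <= s:
                break
            off += min(genomic_pos, e) - s
            if genomic_pos <= e:
                break
        return off
    off = 0
    for s, e in reversed(tx.exons):
        if genomic_pos >= e:
            break
        off += e - max(genomic_pos, s)
        if genomic_pos >= s:
            break
    return off


def _host_transcript(
    annotation: GenomeAnnotation, event: SpliceEvent, chain
) -> Optional[Transcript]:
    gene = annotation.gene(event.gene_id)
    for tx in gene.transcripts:
        idx = [tx.exons.index(iv) for iv in chain if iv in tx.exons]
        if len(idx) == len(chain) and idx == list(range(idx[0], idx[0] + len(chain))):
            return tx
    return None


def extract_isoform_sequences(
    event: SpliceEvent,
    genome: dict[str, str],
    annotation: GenomeAnnotation,
) -> tuple[str, str, str]:
    """Isoform sequences covering an exon-skipping event.

    Returns (inclusion_seq, exclusion_seq, alphabet). The inclusion sequence
    concatenates upstream + variable + downstream exons, the exclusion
    sequence upstream + downstream (reverse-complemented on the minus
    strand). If the event span lies within the annotated CDS of host
    transcripts for both chains, sequences are translated in the annotated
    frame (alphabet "protein"); an internal stop codon falls back to
    nucleotide with a warning.
    """
    if event.event_type != "ES":
        raise ValueError("isoform sequence extraction is defined for ES events")
    chrom_seq = genome.get(event.chromosome)
    if chrom_seq is None or event.end > len(chrom_seq):
        raise ValueError(
            f"event span {event.chromosome}:{event.start}-{event.end} "
            "outside genome sequence"
        )

    def chain_seq(chain) -> str:
        seq = "".join(chrom_seq[s:e] for s, e in chain)
        if event.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    inc_nt = chain_seq(event.inclusion_chain)
    exc_nt = chain_seq(event.exclusion_chain)

    host_inc = _host_transcript(annotation, event, event.inclusion_chain)
    host_exc = _host_transcript(annotation, event, event.exclusion_chain)
    coding = False
    frame = 0
    if host_inc is not None and host_exc is not None:
        if host_inc.cds is not None and host_exc.cds is not None:
            c0, c1 = host_inc.cds
            d0, d1 = host_exc.cds
            span = (event.start, event.end)
            if c0 <= span[0] and c1 >= span[1] and d0 <= span[0] and d1 >= span[1]:
                coding = True
                if event.strand == "+":
                    cds_start = c0
                    ev_5p = event.inclusion_chain[0][0]
                else:
                    cds_start = c1
                    ev_5p = event.inclusion_chain[-1][1]
                dist = abs(
                    _spliced_offset(host_inc, ev_5p, event.strand)
                    - _spliced_offset(host_inc, cds_start, event.strand)
                )
                frame = dist % 3

    if coding:
        def translate(nt: str) -> Optional[str]:
            trimmed = nt[(3 - frame) % 3 if frame else 0:]
            trimmed = trimmed[: len(trimmed) - len(trimmed) % 3]
            aa = str(Seq(trimmed).translate())
            if "*" in aa[:-1]:
                return None
            return aa.rstrip("*")

        inc_aa, exc_aa = translate(inc_nt), translate(exc_nt)
        if inc_aa and exc_aa:
            return inc_aa, exc_aa, "protein"
        warnings.warn(
            f"event {event.event_id}: internal stop in annotated frame; "
            "falling back to nucleotide"
        )
    return inc_nt, exc_nt, "nucleotide"


def _aligner(alphabet: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if alphabet == "protein":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    else:
        aligner.match_score = 2.0
        aligner.mismatch_score = -1.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    # identity is scored excluding terminal gaps, so leave end gaps free
    aligner.open_end_gap_score = 0.0
    aligner.extend_end_gap_score = 0.0
    return aligner


def alignment_identity(seq1: str, seq2: str, alphabet: str = "nucleotide") -> float:
    """Global-alignment identity: matches / aligned columns, terminal gap
    columns excluded; internal gap columns count as mismatches."""
    if not seq1 or not seq2:
        raise ValueError("cannot align an empty sequence")
    # canonical argument order: ties between equally optimal alignments would
    # otherwise make the identity depend on which species comes first
    if seq2 < seq1:
        seq1, seq2 = seq2, seq1
    aligner = _aligner(alphabet)
    aln = aligner.align(seq1, seq2)[0]
    row1, row2 = str(aln[0]), str(aln[1])
    start = max(len(row1) - len(row1.lstrip("-")), len(row2) - len(row2.lstrip("-")))
    end = len(row1) - max(
        len(row1) - len(row1.rstrip("-")), len(row2) - len(row2.rstrip("-"))
    )
    if end <= start:
        return 0.0
    matches = sum(
        1 for c1, c2 in zip(row1[start:end], row2[start:end]) if c1 == c2 and c1 != "-"
    )
    return matches / (end - start)


def match_isoforms(
    seqs_a: tuple[str, str],
    seqs_b: tuple[str, str],
    identity_threshold: float = 0.5,
    alphabet: str = "nucleotide",
) -> IsoformConservation:
    """Label cross-species isoform conservation from the 2x2 pairings.

    The pairing assignment (straight inc<->inc & exc<->exc vs crossed
    inc<->exc & exc<->inc) with the higher summed identity wins; the label is
    ``both``/``cross_matched`` when both identities of the winning assignment
    reach the threshold, ``partial`` when exactly one does, ``none``
    otherwise.
    """
    inc_a, exc_a = seqs_a
    inc_b, exc_b = seqs_b
    ids = {
        "inc_inc": alignment_identity(inc_a, inc_b, alphabet),
        "exc_exc": alignment_identity(exc_a, exc_b, alphabet),
        "inc_exc": alignment_identity(inc_a, exc_b, alphabet),
        "exc_inc": alignment_identity(exc_a, inc_b, alphabet),
    }
    straight = ids["inc_inc"] + ids["exc_exc"]
    crossed = ids["inc_exc"] + ids["exc_inc"]
    if straight >= crossed:
        pair_ids = (ids["inc_inc"], ids["exc_exc"])
        winner = "both"
    else:
        pair_ids = (ids["inc_exc"], ids["exc_inc"])
        winner = "cross_matched"
    n_pass = sum(1 for x in pair_ids if x >= identity_threshold)
    if n_pass == 2:
        label = winner
    elif n_pass == 1:
        label = "partial"
    else:
        label = "none"
    return IsoformConservation(label=label, identities=ids)


def call_psi_consistency(dpsi_a: float, dpsi_b: float, label: str) -> str:
    """Y iff delta PSI has the same (non-zero) sign in both species and the
    isoform-conservation label is 'both'."""
    if dpsi_a == 0 or dpsi_b == 0:
        return "N"
    same_sign = (dpsi_a > 0) == (dpsi_b > 0)
    return "Y" if (same_sign and label == "both") else "N"


def summarize_conserved(
    calls: list[ConservedEventCall], large_dpsi: float = 0.10
) -> tuple[int, int]:
    """(number of PSI-consistent events, number of those with |delta PSI|
    strictly above ``large_dpsi`` in both species)."""
    consistent = [c for c in calls if c.psi_consistent == "Y"]
    n_large = sum(
        1
        for c in consistent
        if abs(c.dpsi_a) > large_dpsi and abs(c.dpsi_b) > large_dpsi
    )
    return len(consistent), n_large


def conservation_table(calls: list[ConservedEventCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_a": c.gene_a,
                "gene_b": c.gene_b,
                "dpsi_a": c.dpsi_a,
                "dpsi_b": c.dpsi_b,
                "isoform_conservation": c.label,
                "psi_consistency": c.psi_consistent,
            }
            for c in calls
        ]
    )
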