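"""Enumeration of minimal alternative-splicing events from annotation.

Seven event types are recognised from pairwise transcript comparison within a
gene: exon skipping (ES), alternative 5'/3' splice sites (A5SS/A3SS),
mutually exclusive exons (ME), intron retention (IR) and alternative
first/last exons (AFE/ALE).

For ES/A5SS/A3SS/IR the *inclusion* chain is the longer isoform; for ME it is
the chain with the longer variable exon (tie: smaller genomic start); for
AFE/ALE it is the proximal isoform, i.e. the one whose variable exon lies
closer to the shared constitutive exon.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .annotation import GeneModel, GenomeAnnotation, Interval, Transcript

EVENT_TYPES = ("ES", "A5SS", "A3SS", "ME", "IR", "AFE", "ALE")


@dataclass(frozen=True)
class SpliceEvent:
    event_id: str
    gene_id: str
    event_type: str
    chromosome: str
    strand: str
    inclusion_chain: tuple[Interval, ...]
    exclusion_chain: tuple[Interval, ...]
    variable_regions: tuple[Interval, ...]

    @property
    def start(self) -> int:
        return min(self.inclusion_chain[0][0], self.exclusion_chain[0][0])

    @property
    def end(self) -> int:
        return max(self.inclusion_chain[-1][1], self.exclusion_chain[-1][1])


def _chain_str(chain: tuple[Interval, ...]) -> str:
    return ",".join(f"{s}-{e}" for s, e in chain)


def _parse_chain(text: str) -> tuple[Interval, ...]:
    return tuple(
        (int(part.split("-")[0]), int(part.split("-")[1]))
        for part in text.split(",")
    )


def _coverage(chain: tuple[Interval, ...]) -> set[Interval]:
    return set(chain)


def _symmetric_regions(
    inc: tuple[Interval, ...], exc: tuple[Interval, ...]
) -> tuple[Interval, ...]:
    """Genomic intervals covered by exactly one of the two chains."""
    points = sorted({p for s, e in inc + exc for p in (s, e)})
    regions: list[Interval] = []
    for lo, hi in zip(points, points[1:]):
        mid = (lo + hi) // 2
        in_inc = any(s <= mid < e for s, e in inc)
        in_exc = any(s <= mid < e for s, e in exc)
        if in_inc != in_exc:
            if regions and regions[-1][1] == lo:
                regions[-1] = (regions[-1][0], hi)
            else:
                regions.append((lo, hi))
    return tuple(regions)


def _make_event(
    gene: GeneModel,
    event_type: str,
    inclusion: tuple[Interval, ...],
    exclusion: tuple[Interval, ...],
) -> SpliceEvent:
    event_id = (
        f"{event_type}:{gene.chromosome}:{gene.strand}:"
        f"{_chain_str(inclusion)}|{_chain_str(exclusion)}"
    )
    return SpliceEvent(
        event_id=event_id,
        gene_id=gene.gene_id,
        event_type=event_type,
        chromosome=gene.chromosome,
        strand=gene.strand,
        inclusion_chain=inclusion,
        exclusion_chain=exclusion,
        variable_regions=_symmetric_regions(inclusion, exclusion),
    )


def _length(chain: tuple[Interval, ...]) -> int:
    return sum(e - s for s, e in chain)


def _pair_events(gene: GeneModel, a: Transcript, b: Transcript) -> list[SpliceEvent]:
    """Minimal events distinguishing one ordered transcript pair.

    Called for both orders of each pair; duplicates are removed upstream.
    """
    out: list[SpliceEvent] = []
    ea, eb = a.exons, b.exons
    set_b = set(eb)
    strand = gene.strand

    # --- ES / ME / IR: anchored on a consecutive exon pair (U, D) of b ---
    for j in range(len(eb) - 1):
        u, d = eb[j], eb[j + 1]
        if u in ea and d in ea:
            i_u, i_d = ea.index(u), ea.index(d)
            if i_d == i_u + 2:
                v = ea[i_u + 1]
                # ES: skipped exon v present only in a
                if v not in set_b:
                    out.append(_make_event(gene, "ES", (u, v, d), (u, d)))
        # IR: single exon of a spanning exactly [u.start, d.end)
        spanning = (u[0], d[1])
        if spanning in ea:
            out.append(_make_event(gene, "IR", (spanning,), (u, d)))

    # --- ME: both transcripts have U, V?, D with distinct middle exons ---
    for i in range(len(ea) - 2):
        u, v1, d = ea[i], ea[i + 1], ea[i + 2]
        if u in eb and d in eb:
            j_u, j_d = eb.index(u), eb.index(d)
            if j_d == j_u + 2:
                v2 = eb[j_u + 1]
                if v1 != v2 and (v1[1] <= v2[0] or v2[1] <= v1[0]):
                    len1, len2 = v1[1] - v1[0], v2[1] - v2[0]
                    if len1 > len2 or (len1 == len2 and v1[0] < v2[0]):
                        inc, exc = (u, v1, d), (u, v2, d)
                    else:
                        inc, exc = (u, v2, d), (u, v1, d)
                    out.append(_make_event(gene, "ME", inc, exc))

    # --- A5SS / A3SS: alternative donor/acceptor against a shared exon ---
    # Pattern 1: exons sharing a genomic start, differing ends, both spliced
    # to an identical downstream exon. Varying donor on '+' => A5SS.
    for i in range(len(ea) - 1):
        x, d = ea[i], ea[i + 1]
        for j in range(len(eb) - 1):
            y, d2 = eb[j], eb[j + 1]
            if d == d2 and x[0] == y[0] and x[1] != y[1]:
                long_x, short_x = (x, y) if x[1] > y[1] else (y, x)
                etype = "A5SS" if strand == "+" else "A3SS"
                out.append(_make_event(gene, etype, (long_x, d), (short_x, d)))
    # Pattern 2: shared upstream exon, following exons share an end but
    # differ at the start. Varying acceptor on '+' => A3SS.
    for i in range(1, len(ea)):
        u, x = ea[i - 1], ea[i]
        for j in range(1, len(eb)):
            u2, y = eb[j - 1], eb[j]
            if u == u2 and x[1] == y[1] and x[0] != y[0]:
                long_x, short_x = (x, y) if x[0] < y[0] else (y, x)
                etype = "A3SS" if strand == "+" else "A5SS"
                out.append(_make_event(gene, etype, (u, long_x), (u, short_x)))

    # --- AFE / ALE: distinct non-overlapping terminal exons spliced to a
    # shared constitutive exon ---
    def _terminal(tx: Transcript, which: str) -> tuple[Interval, Interval] | None:
        """(terminal exon, adjacent shared-candidate exon) in genomic order."""
        if len(tx.exons) < 2:
            return None
        first_is_5p = strand == "+"
        if which == "first":
            return (
                (tx.exons[0], tx.exons[1])
                if first_is_5p
                else (tx.exons[-1], tx.exons[-2])
            )
        return (
            (tx.exons[-1], tx.exons[-2])
            if first_is_5p
            else (tx.exons[0], tx.exons[1])
        )

    for which, etype in (("first", "AFE"), ("last", "ALE")):
        ta, tb = _terminal(a, which), _terminal(b, which)
        if ta is None or tb is None:
            continue
        (fa, ca), (fb, cb) = ta, tb
        if ca != cb or fa == fb:
            continue
        if not (fa[1] <= fb[0] or fb[1] <= fa[0]):  # must not overlap
            continue
        c = ca

        def _gap(f: Interval) -> int:
            return c[0] - f[1] if f[1] <= c[0] else f[0] - c[1]

        proximal, distal = (fa, fb) if _gap(fa) < _gap(fb) else (fb, fa)
        if _gap(fa) == _gap(fb):  # deterministic tie-break
            proximal, distal = (fa, fb) if fa[0] < fb[0] else (fb, fa)
        inc = tuple(sorted((proximal, c)))
        exc = tuple(sorted((distal, c)))
        out.append(_make_event(gene, etype, inc, exc))

    return out


def enumerate_events(annotation: GenomeAnnotation) -> list[SpliceEvent]:
    """Enumerate all minimal events across every gene, deduplicated and in
    deterministic (chromosome, start, type, id) order."""
    seen: dict[str, SpliceEvent] = {}
    for gene in annotation.genes:
        txs = gene.transcripts
        for i in range(len(txs)):
            for j in range(len(txs)):
                if i == j:
                    continue
                for ev in _pair_events(gene, txs[i], txs[j]):
                    seen.setdefault(ev.event_id, ev)
    return sorted(
        seen.values(), key=lambda e: (e.chromosome, e.start, e.event_type, e.event_id)
    )


def write_events_tsv(events: list[SpliceEvent], path: str) -> None:
    rows = [
        {
            "event_id": e.event_id,
            "gene_id": e.gene_id,
            "type": e.event_type,
            "chrom": e.chromosome,
            "strand": e.strand,
            "inclusion_chain": _chain_str(e.inclusion_chain),
            "exclusion_chain": _chain_str(e.exclusion_chain),
            "variable_region": _chain_str(e.variable_regions),
        }
        for e in events
    ]
    pd.DataFrame(
        rows,
        columns=[
            "event_id",
            "gene_id",
            "type",
            "chrom",
            "strand",
            "inclusion_chain",
            "exclusion_chain",
            "variable_region",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str) -> list[SpliceEvent]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    events = []
    for row in df.itertuples(index=False):
        events.append(
            SpliceEvent(
                event_id=row.event_id,
                gene_id=row.gene_id,
                event_type=row.type,
                chromosome=row.chrom,
                strand=row.strand,
                inclusion_chain=_parse_chain(row.inclusion_chain),
                exclusion_chain=_parse_chain(row.exclusion_chain),
                variable_regions=_parse_chain(row.variable_region),
            )
        )
    return events
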