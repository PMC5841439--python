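"""HTSeq-style exon/junction counting and event isoform-count assignment.

A read supports a junction (a, b) iff two consecutive aligned blocks end
exactly at a and start exactly at b; it contributes to a body interval iff at
least one block lies entirely within that interval. Each read is counted at
most once per feature. Junction matching is exact — no tolerance window —
so counts are aligner-independent.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .annotation import GenomeAnnotation, Interval
from .events import SpliceEvent

logger = logging.getLogger(__name__)


@dataclass
class AlignedRead:
    sample_id: str
    chromosome: str
    blocks: tuple[Interval, ...]

    def junctions(self) -> list[Interval]:
        return [
            (self.blocks[i][1], self.blocks[i + 1][0])
            for i in range(len(self.blocks) - 1)
        ]


def read_bed12(path: str, sample_id: str) -> list[AlignedRead]:
    """Parse a BED12 file into aligned reads (one read per line)."""
    reads: list[AlignedRead] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 needs 12 fields")
            chrom, start = f[0], int(f[1])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            blocks = tuple(
                (start + off, start + off + size) for off, size in zip(starts, sizes)
            )
            reads.append(AlignedRead(sample_id, chrom, blocks))
    return reads


def write_bed12(reads: Iterable[AlignedRead], path: str) -> None:
    with open(path, "w") as fh:
        for i, read in enumerate(reads):
            start = read.blocks[0][0]
            end = read.blocks[-1][1]
            sizes = ",".join(str(e - s) for s, e in read.blocks)
            offsets = ",".join(str(s - start) for s, e in read.blocks)
            fh.write(
                "\t".join(
                    [
                        read.chromosome,
                        str(start),
                        str(end),
                        f"read{i}",
                        "0",
                        "+",
                        str(start),
                        str(end),
                        "0",
                        str(len(read.blocks)),
                        sizes,
                        offsets,
                    ]
                )
                + "\n"
            )


@dataclass
class FeatureCounts:
    """Per-sample counts for body intervals, junctions and intron boundaries.

    ``boundary`` is keyed by intron (chrom, donor_end, acceptor_start) and
    counts single-block reads straddling either exon-intron boundary — the
    intron-retention evidence that neither a body nor a junction count sees.
    """

    body: dict[tuple[str, int, int], dict[str, int]] = field(default_factory=dict)
    junction: dict[tuple[str, int, int], dict[str, int]] = field(default_factory=dict)
    boundary: dict[tuple[str, int, int], dict[str, int]] = field(default_factory=dict)
    skipped_reads: int = 0

    def get_body(self, chrom: str, iv: Interval, sample: str) -> int:
        return self.body.get((chrom, iv[0], iv[1]), {}).get(sample, 0)

    def get_junction(self, chrom: str, a: int, b: int, sample: str) -> int:
        return self.junction.get((chrom, a, b), {}).get(sample, 0)

    def get_boundary(self, chrom: str, a: int, b: int, sample: str) -> int:
        return self.boundary.get((chrom, a, b), {}).get(sample, 0)


def _feature_index(
    annotation: GenomeAnnotation, events: Optional[list[SpliceEvent]]
) -> tuple[dict, dict, dict]:
    """Collect features to count: body intervals (annotated exons plus
    event-derived variable regions), junctions, and candidate introns."""
    body: dict[str, set[Interval]] = {}
    junctions: dict[str, set[Interval]] = {}
    introns: dict[str, set[Interval]] = {}
    for gene, tx in annotation.transcripts():
        body.setdefault(gene.chromosome, set()).update(tx.exons)
        jset = junctions.setdefault(gene.chromosome, set())
        iset = introns.setdefault(gene.chromosome, set())
        for jn in tx.junctions():
            jset.add(jn)
            iset.add(jn)
    if events:
        for ev in events:
            body.setdefault(ev.chromosome, set()).update(ev.variable_regions)
            body[ev.chromosome].update(ev.inclusion_chain)
            body[ev.chromosome].update(ev.exclusion_chain)
    return body, junctions, introns


def count_features(
    reads: Iterable[AlignedRead],
    annotation: GenomeAnnotation,
    events: Optional[list[SpliceEvent]] = None,
) -> FeatureCounts:
    """Count reads per body interval, junction and intron boundary.

    Passing ``events`` additionally indexes event variable regions (A5SS/A3SS
    extensions, retained introns) that are not annotated exons.
    """
    body_ivs, junc_ivs, intron_ivs = _feature_index(annotation, events)
    # sort body intervals by start for containment queries
    sorted_body = {
        chrom: sorted(ivs) for chrom, ivs in body_ivs.items()
    }
    starts = {chrom: [iv[0] for iv in ivs] for chrom, ivs in sorted_body.items()}
    chroms = annotation.chromosomes()

    fc = FeatureCounts()
    for read in reads:
        if read.chromosome not in chroms:
            fc.skipped_reads += 1
            continue
        chrom = read.chromosome
        hits_body: set[Interval] = set()
        hits_junc: set[Interval] = set()
        hits_bound: set[Interval] = set()
        read_juncs = set(read.junctions())
        for jn in read_juncs & junc_ivs.get(chrom, set()):
            hits_junc.add(jn)
        ivs = sorted_body.get(chrom, [])
        st = starts.get(chrom, [])
        for bs, be in read.blocks:
            # candidate intervals start at or before the block start
            k = bisect_right(st, bs)
            for iv in ivs[:k]:
                if iv[1] >= be:
                    hits_body.add(iv)
        if len(read.blocks) == 1:
            bs, be = read.blocks[0]
            for a, b in intron_ivs.get(chrom, set()):
                if bs < a < be or bs < b < be:
                    hits_bound.add((a, b))
        s = read.sample_id
        for iv in hits_body:
            fc.body.setdefault((chrom, iv[0], iv[1]), {}).setdefault(s, 0)
            fc.body[(chrom, iv[0], iv[1])][s] += 1
        for a, b in hits_junc:
            fc.junction.setdefault((chrom, a, b), {}).setdefault(s, 0)
            fc.junction[(chrom, a, b)][s] += 1
        for a, b in hits_bound:
            fc.boundary.setdefault((chrom, a, b), {}).setdefault(s, 0)
            fc.boundary[(chrom, a, b)][s] += 1
    if fc.skipped_reads:
        logger.warning("%d reads on unknown chromosomes skipped", fc.skipped_reads)
    return fc


def _shared_and_variable(
    ev: SpliceEvent,
) -> tuple[list[Interval], list[Interval], list[Interval]]:
    shared = [iv for iv in ev.inclusion_chain if iv in ev.exclusion_chain]
    var_inc = [iv for iv in ev.inclusion_chain if iv not in ev.exclusion_chain]
    var_exc = [iv for iv in ev.exclusion_chain if iv not in ev.inclusion_chain]
    return shared, var_inc, var_exc


def _chain_junctions(chain: tuple[Interval, ...]) -> list[Interval]:
    return [(chain[i][1], chain[i + 1][0]) for i in range(len(chain) - 1)]


def _event_counts_sample(ev: SpliceEvent, fc: FeatureCounts, s: str) -> tuple[int, int]:
    chrom = ev.chromosome
    t = ev.event_type
    if t in ("ES", "ME"):
        _, var_inc, var_exc = _shared_and_variable(ev)
        n_inc = sum(fc.get_junction(chrom, a, b, s) for a, b in _chain_junctions(ev.inclusion_chain))
        n_inc += sum(fc.get_body(chrom, iv, s) for iv in var_inc)
        if t == "ES":
            n_exc = sum(
                fc.get_junction(chrom, a, b, s)
                for a, b in _chain_junctions(ev.exclusion_chain)
            )
        else:
            n_exc = sum(
                fc.get_junction(chrom, a, b, s)
                for a, b in _chain_junctions(ev.exclusion_chain)
            ) + sum(fc.get_body(chrom, iv, s) for iv in var_exc)
        return n_inc, n_exc
    if t in ("A5SS", "A3SS"):
        ext = ev.variable_regions[0]
        n_inc = sum(
            fc.get_junction(chrom, a, b, s)
            for a, b in _chain_junctions(ev.inclusion_chain)
        ) + fc.get_body(chrom, ext, s)
        n_exc = sum(
            fc.get_junction(chrom, a, b, s)
            for a, b in _chain_junctions(ev.exclusion_chain)
        )
        return n_inc, n_exc
    if t == "IR":
        intron = ev.variable_regions[0]
        n_inc = fc.get_body(chrom, intron, s) + fc.get_boundary(
            chrom, intron[0], intron[1], s
        )
        n_exc = fc.get_junction(chrom, intron[0], intron[1], s)
        return n_inc, n_exc
    if t in ("AFE", "ALE"):
        _, var_inc, var_exc = _shared_and_variable(ev)
        n_inc = fc.get_body(chrom, var_inc[0], s) + sum(
            fc.get_junction(chrom, a, b, s)
            for a, b in _chain_junctions(ev.inclusion_chain)
        )
        n_exc = fc.get_body(chrom, var_exc[0], s) + sum(
            fc.get_junction(chrom, a, b, s)
            for a, b in _chain_junctions(ev.exclusion_chain)
        )
        return n_inc, n_exc
    raise ValueError(f"unknown event type {t}")


def assign_event_counts(
    events: list[SpliceEvent],
    feature_counts: FeatureCounts,
    samples: list[str],
    groups: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Build the per-event, per-sample isoform-support count table.

    Returns a tidy frame with columns event_id, sample_id, group, n_inc,
    n_exc; every (event, sample) pair is present, zeros allowed.
    """
    rows = []
    for ev in events:
        for s in samples:
            n_inc, n_exc = _event_counts_sample(ev, feature_counts, s)
            rows.append(
                {
                    "event_id": ev.event_id,
                    "sample_id": s,
                    "group": (groups or {}).get(s, ""),
                    "n_inc": n_inc,
                    "n_exc": n_exc,
                }
            )
    return pd.DataFrame(rows, columns=["event_id", "sample_id", "group", "n_inc", "n_exc"])


def write_counts_tsv(counts: pd.DataFrame, path: str) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"event_id": str, "sample_id": str, "group": str})
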