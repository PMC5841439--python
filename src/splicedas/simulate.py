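"""Synthetic two-species splicing study generator.

Everything downstream of read alignment can be exercised on fully in-silico
inputs with known ground truth: annotations carrying one planted event per
gene (one of the seven types), beta-binomial isoform counts with planted
differential events, reads drawn from isoform chains (BED12-compatible
blocks), a second species with sequence divergence and planted
conservation categories, splicing-factor perturbation datasets with planted
regulons, and flat term annotations with planted enriched terms.

All randomness flows through a numpy Generator seeded from
``SimulationConfig.seed``; a fixed seed reproduces every output byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from Bio.Seq import Seq

from .annotation import GeneModel, GenomeAnnotation, Interval, Transcript
from .conservation import HomologyMap
from .counting import AlignedRead
from .events import EVENT_TYPES, SpliceEvent, enumerate_events
from .signatures import PerturbationMeta

NUCLEOTIDES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    seed: int = 0
    events_per_type: int = 2
    samples_per_group: int = 3
    depth_mean: float = 200.0
    depth_dispersion: float = 0.05
    psi_low: float = 0.1
    psi_high: float = 0.9
    planted_fraction: float = 0.1
    delta_psi: float = 0.3
    theta: float = 50.0
    substitution_rate: float = 0.1
    conserved_fraction: float = 0.5
    cross_matched_fraction: float = 0.2
    n_sfs: int = 3
    regulon_size: int = 40
    signature_overlap: float = 0.3
    n_terms: int = 20
    genes_per_term: int = 15
    n_enriched_terms: int = 3
    read_length: int = 50

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TruthSet:
    """Planted ground truth accumulated across simulation stages."""

    events: pd.DataFrame = field(default_factory=pd.DataFrame)
    counts: pd.DataFrame = field(default_factory=pd.DataFrame)
    homology: pd.DataFrame = field(default_factory=pd.DataFrame)
    regulons: dict = field(default_factory=dict)
    enriched_terms: list = field(default_factory=list)


# --- gene geometry -----------------------------------------------------------

# plus-strand exon patterns per event type: (transcript exon lists, gene span)
def _gene_pattern(etype: str) -> tuple[list[list[Interval]], int]:
    if etype == "ES":
        u, v, d = (0, 120), (200, 280), (360, 480)
        return [[u, v, d], [u, d]], 480
    if etype == "A5SS":
        return [[(0, 160), (240, 360)], [(0, 100), (240, 360)]], 360
    if etype == "A3SS":
        u = (0, 120)
        return [[u, (200, 360)], [u, (260, 360)]], 360
    if etype == "ME":
        u, v1, v2, d = (0, 120), (180, 270), (320, 400), (460, 580)
        return [[u, v1, d], [u, v2, d]], 580
    if etype == "IR":
        return [[(0, 400)], [(0, 160), (240, 400)]], 400
    if etype == "AFE":
        c = (360, 480)
        return [[(200, 280), c], [(0, 80), c]], 480
    if etype == "ALE":
        c = (0, 120)
        return [[c, (200, 280)], [c, (400, 480)]], 480
    raise ValueError(f"unknown event type {etype}")


def _reflect(exons: list[Interval], span: int) -> list[Interval]:
    return sorted((span - e, span - s) for s, e in exons)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(NUCLEOTIDES[rng.integers(0, 4, size=length)])


def simulate_annotation(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    chrom: str = "chrS1",
    gene_prefix: str = "gA",
) -> tuple[GenomeAnnotation, dict[str, str], pd.DataFrame]:
    """Build an annotation with ``events_per_type`` genes per event type,
    each carrying two transcripts realising exactly one planted event.

    Returns (annotation, genome sequences, truth frame with one row per
    planted event: gene_id, event_type, strand).
    """
    rng = config.rng() if rng is None else rng
    genes: list[GeneModel] = []
    seq_parts: list[str] = []
    truth_rows = []
    offset = 0
    gap = 100
    idx = 0
    for etype in EVENT_TYPES:
        for _ in range(config.events_per_type):
            strand = "+" if idx % 2 == 0 else "-"
            tx_exons, span = _gene_pattern(etype)
            if strand == "-":
                tx_exons = [_reflect(ex, span) for ex in tx_exons]
            gene_id = f"{gene_prefix}_{etype}_{idx}"
            gene = GeneModel(gene_id, chrom, strand)
            for t, exons in enumerate(tx_exons):
                gene.transcripts.append(
                    Transcript(
                        f"{gene_id}.t{t}",
                        [(s + offset, e + offset) for s, e in sorted(exons)],
                    )
                )
            genes.append(gene)
            truth_rows.append(
                {"gene_id": gene_id, "event_type": etype, "strand": strand}
            )
            seq_parts.append(_random_sequence(rng, span + gap))
            offset += span + gap
            idx += 1
    annotation = GenomeAnnotation(genes)
    annotation.validate()
    genome = {chrom: "".join(seq_parts)}
    return annotation, genome, pd.DataFrame(truth_rows)


# --- count-level simulation --------------------------------------------------

def _nb_totals(
    rng: np.random.Generator, size: int, mean: float, dispersion: float
) -> np.ndarray:
    if dispersion <= 0:
        return np.full(size, int(round(mean)))
    r = 1.0 / dispersion
    p = r / (r + mean)
    return np.maximum(1, rng.negative_binomial(r, p, size=size))


def _betabin_draw(
    rng: np.random.Generator, totals: np.ndarray, p: float, theta: float
) -> np.ndarray:
    a, b = p * theta, (1.0 - p) * theta
    ps = rng.beta(a, b, size=len(totals))
    return rng.binomial(totals, ps)


def simulate_counts(
    config: SimulationConfig,
    event_ids: list[str],
    rng: Optional[np.random.Generator] = None,
    groups: tuple[str, str] = ("case", "control"),
    planted_signs: Optional[dict[str, int]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Beta-binomial event counts for a two-group design.

    A ``planted_fraction`` of events (or exactly the events given in
    ``planted_signs`` mapping event_id -> +1/-1) receive a case-group PSI
    shift of ``delta_psi``; PSIs are kept inside [0.02, 0.98] so boundary
    maximum-likelihood degeneracies cannot arise by construction.

    Returns (tidy counts frame, truth frame with p_case/p_control/is_das).
    """
    rng = config.rng() if rng is None else rng
    n = len(event_ids)
    if planted_signs is None:
        n_planted = int(round(config.planted_fraction * n))
        chosen = rng.choice(n, size=n_planted, replace=False) if n_planted else []
        signs = np.zeros(n, dtype=int)
        for i in chosen:
            signs[i] = 1 if rng.random() < 0.5 else -1
    else:
        signs = np.array([planted_signs.get(e, 0) for e in event_ids], dtype=int)

    case, control = groups
    samples = {
        case: [f"{case}{i+1}" for i in range(config.samples_per_group)],
        control: [f"{control}{i+1}" for i in range(config.samples_per_group)],
    }
    lo, hi = max(config.psi_low, 0.02), min(config.psi_high, 0.98)
    rows = []
    truth_rows = []
    for i, event_id in enumerate(event_ids):
        p0 = rng.uniform(lo, hi)
        if signs[i] != 0:
            # choose the shift direction the baseline has room for
            if signs[i] > 0 and p0 + config.delta_psi > 0.98:
                p0 = 0.98 - config.delta_psi
            if signs[i] < 0 and p0 - config.delta_psi < 0.02:
                p0 = 0.02 + config.delta_psi
            p_case = p0 + signs[i] * config.delta_psi
        else:
            p_case = p0
        for group, p in ((case, p_case), (control, p0)):
            totals = _nb_totals(
                rng, config.samples_per_group, config.depth_mean, config.depth_dispersion
            )
            incs = _betabin_draw(rng, totals, p, config.theta)
            for s, tot, k in zip(samples[group], totals, incs):
                rows.append(
                    {
                        "event_id": event_id,
                        "sample_id": s,
                        "group": group,
                        "n_inc": int(k),
                        "n_exc": int(tot - k),
                    }
                )
        truth_rows.append(
            {
                "event_id": event_id,
                "p_case": p_case,
                "p_control": p0,
                "is_das": bool(signs[i] != 0),
                "sign": int(signs[i]),
            }
        )
    counts = pd.DataFrame(rows, columns=["event_id", "sample_id", "group", "n_inc", "n_exc"])
    return counts, pd.DataFrame(truth_rows)


# --- read-level simulation ---------------------------------------------------

def _chain_window_blocks(
    chain: tuple[Interval, ...], start: int, length: int
) -> tuple[Interval, ...]:
    """Map a window [start, start+length) in spliced chain coordinates back
    to genomic blocks."""
    blocks = []
    remaining = length
    pos = start
    for s, e in chain:
        exon_len = e - s
        if pos >= exon_len:
            pos -= exon_len
            continue
        take = min(exon_len - pos, remaining)
        blocks.append((s + pos, s + pos + take))
        remaining -= take
        pos = 0
        if remaining == 0:
            break
    if remaining:
        raise ValueError("window extends past chain end")
    return tuple(blocks)


def simulate_reads(
    event: SpliceEvent,
    n_inc_reads: int,
    n_exc_reads: int,
    sample_id: str,
    rng: np.random.Generator,
    read_length: int = 50,
) -> list[AlignedRead]:
    """Draw reads uniformly along each isoform chain of one event."""
    reads = []
    for chain, n_reads in (
        (event.inclusion_chain, n_inc_reads),
        (event.exclusion_chain, n_exc_reads),
    ):
        spliced_len = sum(e - s for s, e in chain)
        if spliced_len < read_length:
            raise ValueError("chain shorter than the read length")
        starts = rng.integers(0, spliced_len - read_length + 1, size=n_reads)
        for s0 in starts:
            reads.append(
                AlignedRead(
                    sample_id,
                    event.chromosome,
                    _chain_window_blocks(chain, int(s0), read_length),
                )
            )
    return reads


# --- two-species conservation ------------------------------------------------

def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    if hit.any():
        # substitute with a uniformly random *different* base
        for i in np.nonzero(hit)[0]:
            choices = [b for b in "ACGT" if b != arr[i]]
            arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def simulate_two_species(
    config: SimulationConfig,
    annotation_a: GenomeAnnotation,
    genome_a: dict[str, str],
    rng: Optional[np.random.Generator] = None,
    chrom_b: str = "chrS2",
    gene_prefix: str = "gB",
) -> tuple[GenomeAnnotation, dict[str, str], HomologyMap, pd.DataFrame]:
    """Clone species A into a diverged species B with planted conservation.

    Every gene gets a homolog. ES genes are assigned a category:
    ``consistent`` (sequence cloned with substitutions, delta-PSI signs
    planted equal), ``cross_matched`` (species B's upstream exon absorbs the
    variable-exon sequence and B gains a novel variable exon, so B's
    exclusion isoform matches A's inclusion isoform), or ``independent``
    (cloned sequence, independent sign). Non-ES genes are plain clones.

    Returns (annotation_b, genome_b, homology map, truth frame with columns
    gene_a, gene_b, event_type, category, sign_a, sign_b).
    """
    rng = config.rng() if rng is None else rng
    events_a = enumerate_events(annotation_a)
    by_gene = {e.gene_id: e for e in events_a}

    genes_b: list[GeneModel] = []
    seq_parts: list[str] = []
    pairs: list[tuple[str, str]] = []
    truth_rows = []
    offset = 0
    gap = 100
    (chrom_a,) = genome_a.keys()

    for gi, gene in enumerate(annotation_a.genes):
        ev = by_gene.get(gene.gene_id)
        gene_b_id = f"{gene_prefix}_{gene.gene_id.split('_', 1)[1]}"
        gene_start = min(tx.start for tx in gene.transcripts)
        gene_end = max(tx.end for tx in gene.transcripts)
        locus_seq = genome_a[chrom_a][gene_start:gene_end]

        category = "clone"
        sign_a = 1 if rng.random() < 0.5 else -1
        sign_b = sign_a
        if ev is not None and ev.event_type == "ES":
            u = rng.random()
            if u < config.conserved_fraction:
                category = "consistent"
            elif u < config.conserved_fraction + config.cross_matched_fraction:
                category = "cross_matched"
            else:
                category = "independent"
                sign_b = 1 if rng.random() < 0.5 else -1

        if category == "cross_matched" and ev is not None:
            # Species B geometry: upstream exon absorbs A's variable exon,
            # novel variable exon W, downstream exon kept. Coordinates are
            # local to the new locus.
            u_iv, v_iv, d_iv = ev.inclusion_chain
            seq_u = genome_a[chrom_a][u_iv[0]:u_iv[1]]
            seq_v = genome_a[chrom_a][v_iv[0]:v_iv[1]]
            seq_d = genome_a[chrom_a][d_iv[0]:d_iv[1]]
            if gene.strand == "-":
                # species B is built on '+': use transcript-oriented sequences
                rc = lambda s: str(Seq(s).reverse_complement())
                seq_u, seq_v, seq_d = rc(seq_d), rc(seq_v), rc(seq_u)
            w_len = v_iv[1] - v_iv[0]
            lu = len(seq_u) + len(seq_v)
            up = (offset, offset + lu)
            w = (up[1] + 80, up[1] + 80 + w_len)
            dn = (w[1] + 80, w[1] + 80 + len(seq_d))
            locus = (
                _mutate(rng, seq_u + seq_v, config.substitution_rate)
                + _random_sequence(rng, 80)
                + _random_sequence(rng, w_len)
                + _random_sequence(rng, 80)
                + _mutate(rng, seq_d, config.substitution_rate)
            )
            gene_b = GeneModel(gene_b_id, chrom_b, "+")
            gene_b.transcripts = [
                Transcript(f"{gene_b_id}.t0", [up, w, dn]),
                Transcript(f"{gene_b_id}.t1", [up, dn]),
            ]
            span = dn[1] - offset
        else:
            locus = _mutate(rng, locus_seq, config.substitution_rate)
            gene_b = GeneModel(gene_b_id, chrom_b, gene.strand)
            shift = offset - gene_start
            gene_b.transcripts = [
                Transcript(
                    f"{gene_b_id}.t{t}",
                    [(s + shift, e + shift) for s, e in tx.exons],
                    None if tx.cds is None else (tx.cds[0] + shift, tx.cds[1] + shift),
                )
                for t, tx in enumerate(gene.transcripts)
            ]
            span = gene_end - gene_start

        genes_b.append(gene_b)
        seq_parts.append(locus + _random_sequence(rng, gap))
        pairs.append((gene.gene_id, gene_b_id))
        truth_rows.append(
            {
                "gene_a": gene.gene_id,
                "gene_b": gene_b_id,
                "event_type": "" if ev is None else ev.event_type,
                "category": category,
                "sign_a": sign_a,
                "sign_b": sign_b,
            }
        )
        offset += span + gap

    annotation_b = GenomeAnnotation(genes_b)
    annotation_b.validate()
    genome_b = {chrom_b: "".join(seq_parts)}
    return annotation_b, genome_b, HomologyMap.from_pairs(pairs), pd.DataFrame(truth_rows)


def write_homologene_tsv(
    homology: HomologyMap, path: str, taxid_a: str = "10090", taxid_b: str = "9606"
) -> None:
    with open(path, "w") as fh:
        for i, (ga, gb) in enumerate(homology.pairs()):
            fh.write(f"{i}\t{taxid_a}\t{2 * i}\t{ga}\n")
            fh.write(f"{i}\t{taxid_b}\t{2 * i + 1}\t{gb}\n")


# --- splicing-factor perturbations ------------------------------------------

def simulate_signature_pair(
    n_events: int,
    overlap: float,
    rng: np.random.Generator,
    frac_regulated: float = 0.4,
    background_rate: float = 0.02,
) -> tuple[pd.Series, pd.Series, list[str]]:
    """A perturbation signature and a disease signature sharing a planted
    fraction ``overlap`` of the perturbation's non-zero events (symbol-equal);
    remaining disease symbols are independent background.

    ``background_rate`` is the per-symbol probability of a spurious non-zero
    disease call; its default reflects what the count-level workflow emits,
    where non-planted symbols arise only from BH-controlled false
    discoveries (q < 0.05), i.e. a few percent of events at most.

    Returns (perturbation signature, disease signature, planted event ids).
    """
    events = [f"E{i}" for i in range(n_events)]
    n_reg = int(round(frac_regulated * n_events))
    reg_idx = rng.choice(n_events, size=n_reg, replace=False)
    psig = pd.Series("0", index=events, dtype=object)
    for i in reg_idx:
        psig.iloc[i] = "+" if rng.random() < 0.5 else "-"
    n_shared = int(round(overlap * n_reg))
    shared_idx = rng.choice(reg_idx, size=n_shared, replace=False)
    dsig = pd.Series("0", index=events, dtype=object)
    shared_set = set(int(i) for i in shared_idx)
    for i in range(n_events):
        if i in shared_set:
            dsig.iloc[i] = psig.iloc[i]
        else:
            u = rng.random()
            if u < background_rate:
                dsig.iloc[i] = "+"
            elif u < 2 * background_rate:
                dsig.iloc[i] = "-"
    return psig, dsig, [events[i] for i in sorted(shared_set)]


def simulate_sf_perturbations(
    config: SimulationConfig,
    event_ids: list[str],
    rng: Optional[np.random.Generator] = None,
    sf_names: Optional[list[str]] = None,
    sf_fold_change: float = 3.0,
) -> dict:
    """Per-SF perturbation count tables plus a disease dataset.

    SF regulons are disjoint random event subsets with signed effects. Each
    SF's perturbation dataset shifts its regulon's PSI according to the
    perturbation direction (KO/KD reverse OE); the disease dataset shifts a
    ``signature_overlap`` fraction of every regulon consistently with that
    SF's planted expression direction in disease. Expression matrices carry
    the SF genes with the planted fold changes.

    Returns a dict with keys: perturbations (dataset_id -> dict with meta,
    counts, expression), disease (counts, expression, directions), truth
    (sf -> {event_id: sign}).
    """
    rng = config.rng() if rng is None else rng
    sf_names = sf_names or [f"SF{i+1}" for i in range(config.n_sfs)]
    n_sf = len(sf_names)
    needed = n_sf * config.regulon_size
    if needed > len(event_ids):
        raise ValueError("not enough events for disjoint SF regulons")
    perm = rng.permutation(len(event_ids))
    directions = ["OE", "KO", "KD"]

    truth: dict[str, dict[str, int]] = {}
    perturbations: dict[str, dict] = {}
    disease_signs: dict[str, int] = {}
    sf_disease_dir: dict[str, str] = {}

    for i, sf in enumerate(sf_names):
        idx = perm[i * config.regulon_size : (i + 1) * config.regulon_size]
        regulon = {
            event_ids[j]: (1 if rng.random() < 0.5 else -1) for j in idx
        }
        truth[sf] = regulon
        direction = directions[i % len(directions)]
        # perturbation dataset: positively regulated events rise under OE,
        # fall under KD/KO
        flip = 1 if direction == "OE" else -1
        planted = {e: s * flip for e, s in regulon.items()}
        counts, _ = simulate_counts(
            config,
            event_ids,
            rng=rng,
            groups=("perturbed", "control"),
            planted_signs=planted,
        )
        expr = _expression_matrix(
            rng, sf_names, counts, sf, direction, sf_fold_change
        )
        perturbations[f"DS_{sf}"] = {
            "meta": PerturbationMeta(f"DS_{sf}", sf, direction),
            "counts": counts,
            "expression": expr,
        }
        # disease: the SF is up or down; the overlapping regulon fraction
        # moves consistently (SF up: positively regulated events up)
        d_dir = "up" if rng.random() < 0.5 else "down"
        sf_disease_dir[sf] = d_dir
        d_flip = 1 if d_dir == "up" else -1
        members = sorted(regulon)
        n_over = int(round(config.signature_overlap * len(members)))
        over = rng.choice(len(members), size=n_over, replace=False)
        for j in over:
            e = members[j]
            disease_signs[e] = regulon[e] * d_flip

    disease_counts, _ = simulate_counts(
        config,
        event_ids,
        rng=rng,
        groups=("case", "control"),
        planted_signs=disease_signs,
    )
    disease_expr = _disease_expression_matrix(
        rng, sf_names, disease_counts, sf_disease_dir, sf_fold_change
    )
    return {
        "perturbations": perturbations,
        "disease": {
            "counts": disease_counts,
            "expression": disease_expr,
            "sf_directions": sf_disease_dir,
        },
        "truth": truth,
    }


def _expression_matrix(
    rng: np.random.Generator,
    gene_names: list[str],
    counts: pd.DataFrame,
    perturbed_sf: str,
    direction: str,
    fold: float,
) -> pd.DataFrame:
    samples = sorted(counts["sample_id"].unique())
    base = rng.poisson(200, size=(len(gene_names) + 20, len(samples))).astype(float)
    genes = gene_names + [f"bg_gene{i}" for i in range(20)]
    df = pd.DataFrame(base, index=genes, columns=samples)
    perturbed_samples = sorted(
        counts.loc[counts["group"] == "perturbed", "sample_id"].unique()
    )
    factor = fold if direction == "OE" else 1.0 / fold
    df.loc[perturbed_sf, perturbed_samples] = (
        df.loc[perturbed_sf, perturbed_samples] * factor
    ).round()
    return df.astype(int)


def _disease_expression_matrix(
    rng: np.random.Generator,
    sf_names: list[str],
    counts: pd.DataFrame,
    sf_directions: dict[str, str],
    fold: float,
) -> pd.DataFrame:
    samples = sorted(counts["sample_id"].unique())
    base = rng.poisson(200, size=(len(sf_names) + 20, len(samples))).astype(float)
    genes = sf_names + [f"bg_gene{i}" for i in range(20)]
    df = pd.DataFrame(base, index=genes, columns=samples)
    case_samples = sorted(counts.loc[counts["group"] == "case", "sample_id"].unique())
    for sf, d in sf_directions.items():
        factor = fold if d == "up" else 1.0 / fold
        df.loc[sf, case_samples] = (df.loc[sf, case_samples] * factor).round()
    return df.astype(int)


# --- term annotations --------------------------------------------------------

def simulate_terms(
    config: SimulationConfig,
    genes: list[str],
    foreground: set[str],
    rng: Optional[np.random.Generator] = None,
) -> tuple[list, list[str]]:
    """Flat term annotations over ``genes``; the first ``n_enriched_terms``
    terms draw most of their genes from the foreground (planted enrichment),
    the rest are uniform background draws.

    Returns (terms, planted enriched term ids).
    """
    from .enrichment import TermAnnotation

    rng = config.rng() if rng is None else rng
    fg = sorted(foreground)
    bg = sorted(set(genes))
    terms = []
    enriched_ids = []
    for t in range(config.n_terms):
        term_id = f"T{t:04d}"
        enriched = t < config.n_enriched_terms
        members: set[str] = set()
        size = min(config.genes_per_term, len(bg))
        if enriched and fg:
            n_fg = min(len(fg), max(1, int(round(0.7 * size))))
            members.update(
                fg[i] for i in rng.choice(len(fg), size=n_fg, replace=False)
            )
            enriched_ids.append(term_id)
        while len(members) < size:
            members.add(bg[int(rng.integers(0, len(bg)))])
        terms.append(TermAnnotation(term_id, f"term {t}", members))
    return terms, enriched_ids
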