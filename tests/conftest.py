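import numpy as np
import pytest

from splicedas.annotation import GeneModel, GenomeAnnotation, Transcript


def make_gene(gene_id, chrom, strand, tx_exons, cds=None):
    gene = GeneModel(gene_id, chrom, strand)
    for i, exons in enumerate(tx_exons):
        gene.transcripts.append(
            Transcript(
                f"{gene_id}.t{i}",
                sorted(exons),
                None if cds is None else cds[i],
            )
        )
    return gene


def make_annotation(*genes):
    ann = GenomeAnnotation(list(genes))
    ann.validate()
    return ann


@pytest.fixture
def cassette_gene():
    """Canonical exon-skipping gene: U-V-D vs U-D on the plus strand."""
    u, v, d = (100, 200), (300, 380), (500, 600)
    return make_annotation(
        make_gene("gES", "chr1", "+", [[u, v, d], [u, d]])
    ), (u, v, d)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


# A four-transcript gene carrying one event of each of the seven types on
# disjoint regions separated by constitutive exons. Used by the enumeration
# tests, which compare against the hand enumeration of its transcript pairs.
SEVEN_TYPE_REGIONS = {
    "AFE": {"prox": (200, 280), "dist": (0, 80)},
    "K1": (400, 500),
    "ES": (560, 640),
    "K2": (700, 800),
    "A5SS": {"long": (860, 1000), "short": (860, 940)},
    "K3": (1100, 1200),
    "A3SS": {"long": (1260, 1400), "short": (1320, 1400)},
    "K4": (1500, 1600),
    "IR": {"u": (1660, 1740), "d": (1800, 1880), "retained": (1660, 1880)},
    "K5": (1940, 2040),
    "ME": {"v1": (2100, 2190), "v2": (2240, 2320)},
    "K6": (2380, 2480),
    "ALE": {"prox": (2540, 2620), "dist": (2700, 2780)},
}


def seven_type_gene(strand="+", chrom="chr7", gene_id="g7"):
    r = SEVEN_TYPE_REGIONS

    def tx(afe, es, a5, a3, ir, me, ale):
        exons = [r["AFE"][afe], r["K1"]]
        if es:
            exons.append(r["ES"])
        exons += [r["K2"], r["A5SS"][a5], r["K3"], r["A3SS"][a3], r["K4"]]
        exons += [r["IR"]["u"], r["IR"]["d"]] if ir == "spliced" else [r["IR"]["retained"]]
        exons += [r["K5"], r["ME"][me], r["K6"], r["ALE"][ale]]
        return exons

    transcripts = [
        tx("prox", True, "long", "long", "spliced", "v1", "prox"),
        tx("dist", False, "short", "short", "retained", "v2", "dist"),
        tx("prox", False, "long", "long", "spliced", "v2", "prox"),
        tx("dist", True, "short", "short", "spliced", "v1", "dist"),
    ]
    span = 2800
    if strand == "-":
        transcripts = [
            sorted((span - e, span - s) for s, e in exons) for exons in transcripts
        ]
    return make_annotation(make_gene(gene_id, chrom, strand, transcripts))
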