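"""End-to-end orchestration of the synthetic two-species splicing study.

The pipeline simulates a species-A (disease model) and species-B cohort with
planted ground truth, runs event enumeration, differential-splicing testing,
cross-species conservation, splicing-factor signature screening and term
enrichment, and writes every result as TSV plus a JSON manifest with content
hashes for reproducibility checks.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotation import write_gtf
from .conservation import (
    ConservedEventCall,
    HomologyMap,
    conservation_table,
    extract_isoform_sequences,
    match_isoforms,
    overlap_enrichment,
    shared_gene_sets,
    summarize_conserved,
)
from .counting import write_counts_tsv
from .dasmodel import call_das, run_das
from .enrichment import enrich, enrichment_table
from .events import enumerate_events, write_events_tsv
from .signatures import (
    compare_signatures,
    disease_signature,
    perturbation_signature,
    sf_direction,
)
from .simulate import (
    SimulationConfig,
    simulate_annotation,
    simulate_counts,
    simulate_sf_perturbations,
    simulate_terms,
    simulate_two_species,
    write_homologene_tsv,
)

logger = logging.getLogger("splicedas.pipeline")


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    dpsi_threshold: float = 0.05
    q_threshold: float = 0.05
    large_dpsi: float = 0.10
    identity_threshold: float = 0.5
    alpha: float = 0.05
    candidate_rule: str = "both"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    run_signatures: bool = True
    run_enrichment: bool = True

    def __post_init__(self):
        for name in ("dpsi_threshold", "q_threshold", "large_dpsi", "alpha"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} out of range: {v}")
        self.simulation.seed = self.seed


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_fasta(genome: dict[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on simulated data; returns the manifest dict."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    rng = np.random.default_rng(config.seed)
    outputs: list[Path] = []

    def save(df: pd.DataFrame, name: str) -> Path:
        path = outdir / name
        df.to_csv(path, sep="\t", index=False)
        outputs.append(path)
        return path

    logger.info("simulating species A")
    ann_a, genome_a, _ = simulate_annotation(sim, rng=rng, chrom="chrS1", gene_prefix="gA")
    events_a = enumerate_events(ann_a)
    write_gtf(ann_a, str(outdir / "species_a.gtf"))
    _write_fasta(genome_a, outdir / "species_a.fa")
    write_events_tsv(events_a, str(outdir / "events_a.tsv"))
    outputs += [outdir / "species_a.gtf", outdir / "species_a.fa", outdir / "events_a.tsv"]

    logger.info("simulating species B with planted conservation")
    ann_b, genome_b, homology, cons_truth = simulate_two_species(
        sim, ann_a, genome_a, rng=rng
    )
    events_b = enumerate_events(ann_b)
    write_gtf(ann_b, str(outdir / "species_b.gtf"))
    _write_fasta(genome_b, outdir / "species_b.fa")
    write_events_tsv(events_b, str(outdir / "events_b.tsv"))
    write_homologene_tsv(homology, str(outdir / "homologs.tsv"))
    outputs += [
        outdir / "species_b.gtf",
        outdir / "species_b.fa",
        outdir / "events_b.tsv",
        outdir / "homologs.tsv",
    ]

    logger.info("simulating counts and running the differential test")
    ev_by_gene_a = {e.gene_id: e for e in events_a}
    ev_by_gene_b = {e.gene_id: e for e in events_b}
    signs_a = {
        ev_by_gene_a[r.gene_a].event_id: int(r.sign_a)
        for r in cons_truth.itertuples(index=False)
        if r.gene_a in ev_by_gene_a
    }
    signs_b = {
        ev_by_gene_b[r.gene_b].event_id: int(r.sign_b)
        for r in cons_truth.itertuples(index=False)
        if r.gene_b in ev_by_gene_b
    }
    das_tables = {}
    for label, events, signs in (
        ("a", events_a, signs_a),
        ("b", events_b, signs_b),
    ):
        event_ids = [e.event_id for e in events]
        counts, _ = simulate_counts(sim, event_ids, rng=rng, planted_signs=signs)
        save(counts, f"counts_{label}.tsv")
        das = call_das(
            run_das(counts, "case", "control"),
            config.dpsi_threshold,
            config.q_threshold,
        )
        gene_of = {e.event_id: e.gene_id for e in events}
        type_of = {e.event_id: e.event_type for e in events}
        das.insert(1, "gene_id", das["event_id"].map(gene_of))
        das.insert(2, "type", das["event_id"].map(type_of))
        save(das, f"das_{label}.tsv")
        das_tables[label] = das

    logger.info("conservation analysis")
    das_a, das_b = das_tables["a"], das_tables["b"]
    sig_genes_a = set(das_a.loc[das_a["significant"], "gene_id"])
    sig_genes_b = set(das_b.loc[das_b["significant"], "gene_id"])
    venn = shared_gene_sets(
        sig_genes_a,
        sig_genes_b,
        homology,
        expressed_a={g.gene_id for g in ann_a.genes},
        expressed_b={g.gene_id for g in ann_b.genes},
    )
    odds, venn_p = overlap_enrichment(venn)
    calls = []
    for r in cons_truth.itertuples(index=False):
        if r.event_type != "ES":
            continue
        ev_a = ev_by_gene_a.get(r.gene_a)
        ev_b = ev_by_gene_b.get(r.gene_b)
        if ev_a is None or ev_b is None:
            continue
        row_a = das_a.loc[das_a["event_id"] == ev_a.event_id]
        row_b = das_b.loc[das_b["event_id"] == ev_b.event_id]
        if row_a.empty or row_b.empty:
            continue
        seqs_a = extract_isoform_sequences(ev_a, genome_a, ann_a)
        seqs_b = extract_isoform_sequences(ev_b, genome_b, ann_b)
        cons = match_isoforms(
            seqs_a[:2], seqs_b[:2], identity_threshold=config.identity_threshold
        )
        calls.append(
            ConservedEventCall(
                gene_a=r.gene_a,
                gene_b=r.gene_b,
                dpsi_a=float(row_a["delta_psi"].iloc[0]),
                dpsi_b=float(row_b["delta_psi"].iloc[0]),
                label=cons.label,
            )
        )
    save(conservation_table(calls), "conserved.tsv")
    n_consistent, n_large = summarize_conserved(calls, config.large_dpsi)

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "venn": {
            "both": venn.both,
            "a_only": venn.a_only,
            "b_only": venn.b_only,
            "background": venn.background_total,
            "odds_ratio": odds,
            "p": venn_p,
        },
        "conserved": {"n_consistent": n_consistent, "n_large_dpsi": n_large},
    }

    if config.run_signatures:
        logger.info("splicing-factor signature screen")
        event_ids_a = [e.event_id for e in events_a]
        n_sf = min(sim.n_sfs, max(1, len(event_ids_a) // max(sim.regulon_size, 1)))
        sim_sf = SimulationConfig(**{**sim.__dict__})
        sim_sf.n_sfs = n_sf
        sim_sf.regulon_size = min(sim.regulon_size, len(event_ids_a) // n_sf)
        sf_data = simulate_sf_perturbations(sim_sf, event_ids_a, rng=rng)
        disease = sf_data["disease"]
        disease_das = call_das(
            run_das(disease["counts"], "case", "control"),
            config.dpsi_threshold,
            config.q_threshold,
        )
        comp_rows = []
        for ds_id, ds in sf_data["perturbations"].items():
            pert_das = call_das(
                run_das(ds["counts"], "perturbed", "control"),
                config.dpsi_threshold,
                config.q_threshold,
            )
            psig = perturbation_signature(pert_das, ds["meta"])
            d_dir = sf_direction(
                disease["expression"],
                ds["meta"].sf_gene,
                case_samples=[c for c in disease["expression"].columns if c.startswith("case")],
                control_samples=[c for c in disease["expression"].columns if c.startswith("control")],
            )
            if d_dir == "undetermined":
                logger.info("SF %s direction undetermined; skipped", ds["meta"].sf_gene)
                continue
            dsig = disease_signature(disease_das, d_dir)
            res = compare_signatures(
                psig,
                dsig,
                sf_gene=ds["meta"].sf_gene,
                dataset_id=ds_id,
                alpha=config.alpha,
                rule=config.candidate_rule,
            )
            comp_rows.append(
                {
                    "sf_gene": res.sf_gene,
                    "dataset_id": res.dataset_id,
                    "n_pp": int(res.table.loc["+", "+"]),
                    "n_mm": int(res.table.loc["-", "-"]),
                    "p_pp": res.p_pp,
                    "p_mm": res.p_mm,
                    "candidate": res.candidate,
                }
            )
        save(pd.DataFrame(comp_rows), "sf_comparison.tsv")
        manifest["sf_candidates"] = sorted(
            {r["sf_gene"] for r in comp_rows if r["candidate"]}
        )

    if config.run_enrichment:
        logger.info("term enrichment of differentially spliced genes")
        background = {g.gene_id for g in ann_a.genes}
        foreground = sig_genes_a & background
        terms, planted = simulate_terms(sim, sorted(background), foreground, rng=rng)
        if foreground:
            results = enrich(foreground, background, terms)
            save(enrichment_table(results), "enrichment.tsv")
            manifest["enrichment"] = {
                "planted_terms": planted,
                "n_significant": int(sum(r.p < 0.05 for r in results)),
            }

    manifest["outputs"] = {
        str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(outputs))
    }
    manifest["runtime_seconds"] = round(time.time() - t0, 2)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline finished in %.1fs", manifest["runtime_seconds"])
    return manifest
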