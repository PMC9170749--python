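"""End-to-end orchestration: simulate -> profile -> discover -> conserve ->
express -> clusters -> pare, with plain-text intermediates and a run report.

Every stage writes inspectable TSV/FASTA/GFF3 intermediates under the output
directory and is re-runnable on its own from the library API; the report
records per-stage record counts, the global seed, and parameter provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from . import clusters as clusters_mod
from . import conservation, degradome, discovery, expression, profiling, synthetic
from .seqio import to_dna, write_fasta

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    outdir: str = "mirforge_run"
    seed: int = 1
    simulate: bool = True
    genome_fasta: Optional[str] = None  # required when simulate is False
    sim: synthetic.SimulationConfig = field(default_factory=synthetic.SimulationConfig)
    discovery: discovery.DiscoveryParams = field(default_factory=discovery.DiscoveryParams)
    stage_call: expression.StageCallParams = field(default_factory=expression.StageCallParams)
    cluster_max_gap: int = 3000
    degradome_params: degradome.DegradomeParams = field(
        default_factory=degradome.DegradomeParams)
    run_pare: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key: {key}")
            current = getattr(cfg, key)
            if dataclasses.is_dataclass(current) and isinstance(value, dict):
                setattr(cfg, key, dataclasses.replace(current, **value))
            else:
                setattr(cfg, key, value)
        return cfg

    def validate(self) -> None:
        if not self.simulate:
            if not self.genome_fasta:
                raise ValueError("genome_fasta is required when simulate is false")
            if not os.path.exists(self.genome_fasta):
                raise ValueError(f"genome_fasta not found: {self.genome_fasta}")
        self.sim.validate()


def run_all(config: RunConfig) -> Dict:
    """Execute the full pipeline; returns the run report dict."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: Dict = {"seed": config.seed, "stages": {}, "parameters": {
        "discovery": dataclasses.asdict(config.discovery),
        "stage_call": dataclasses.asdict(config.stage_call),
        "cluster_max_gap": config.cluster_max_gap,
    }}

    # -- simulate ----------------------------------------------------------
    sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
    genome, truth, contaminants = synthetic.plant_genome(sim_cfg)
    libraries, manifest = synthetic.simulate_reads(genome, truth, sim_cfg,
                                                   contaminants)
    write_fasta(out / "genome.fa", genome.items())
    write_fasta(out / "contaminants.fa",
                [(c.name, c.sequence) for c in contaminants])
    synthetic.write_truth_tsv(out / "truth.tsv", truth)
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    report["stages"]["simulate"] = {"hairpins": len(truth),
                                    "libraries": len(libraries)}

    # -- profile -----------------------------------------------------------
    collapsed_all = {lib: profiling.collapse_reads(reads, lib)
                     for lib, reads in libraries.items()}
    lib_sizes = {lib: sum(r.count for r in col)
                 for lib, col in collapsed_all.items()}
    profiles = [profiling.profile_library(col) for col in collapsed_all.values()]
    profiling.profiles_to_frame(profiles).to_csv(out / "profiles.tsv", sep="\t",
                                                 index=False)
    report["stages"]["profile"] = {
        "libraries": len(profiles),
        "pirna_fraction": {p.library_id: round(p.pirna_class_fraction, 4)
                           for p in profiles},
    }

    # -- discover ----------------------------------------------------------
    collapsed_mirna = {lib: profiling.length_filter(col)
                       for lib, col in collapsed_all.items()}
    contaminant_db = {c.name: c.sequence for c in contaminants}
    records = discovery.discover(collapsed_mirna, genome, config.discovery,
                                 contaminant_db=contaminant_db,
                                 lib_sizes=lib_sizes)
    discovery.write_gff3(records, out / "precursors.gff3")
    discovery.records_to_frame(records).to_csv(out / "precursors.tsv", sep="\t",
                                               index=False)
    write_fasta(out / "precursors.fa",
                [(r.name, r.candidate.precursor_seq) for r in records])
    with open(out / "precursors.dotbracket.txt", "w") as fh:
        for r in records:
            fh.write(f">{r.name}\n{r.candidate.precursor_seq}\n"
                     f"{r.candidate.structure}\n")
    report["stages"]["discover"] = {"records": len(records)}

    # -- conserve ----------------------------------------------------------
    sibling = synthetic.mutate_sibling(truth, sim_cfg.snp_rate, config.seed)
    ref_sets = {
        "sib": [conservation.MatureRef("sib", f"sib-{m.name}", m.sequence)
                for m in sibling],
    }
    queries = [(r.name, r.mature_seq) for r in records]
    conserved = (conservation.classify_conservation(queries, ref_sets)
                 if queries else pd.DataFrame())
    if len(conserved):
        conserved.to_csv(out / "conservation.tsv", sep="\t", index=False)
    snps = conservation.detect_snps(
        [conservation.MatureRef("dvv", h.name, h.mature_seq) for h in truth],
        ref_sets["sib"])
    pd.DataFrame(snps, columns=["name_a", "name_b", "position", "allele_a",
                                "allele_b"]).to_csv(out / "snps.tsv", sep="\t",
                                                    index=False)
    report["stages"]["conserve"] = {
        "conserved": int(conserved["conserved"].sum()) if len(conserved) else 0,
        "snps": len(snps)}

    # -- express -----------------------------------------------------------
    stages_by_lib = dict(zip(manifest["library_id"], manifest["stage"]))
    if records:
        cm = expression.count_mature(records, collapsed_mirna, genome,
                                     stages_by_lib, lib_sizes=lib_sizes)
        cm.to_tsv(out / "counts.tsv")
        stage_names = cm.stage_names()
        if "early_pupa" in stage_names and "late_pupa" in stage_names:
            cm, merged, n_de = expression.maybe_merge_stages(
                cm, "early_pupa", "late_pupa", "pupa", config.stage_call)
            report["stages"]["express_merge"] = {"merged": merged, "n_de": n_de}
        categories = expression.classify_expression(cm, config.stage_call)
        categories.to_csv(out / "expression_categories.tsv", sep="\t")
        cat_counts = categories.value_counts().to_dict()
    else:
        cm, categories, cat_counts = None, None, {}
    report["stages"]["express"] = {str(k): int(v) for k, v in cat_counts.items()}

    # -- clusters ----------------------------------------------------------
    annotations = [(r.name, r.contig_id, r.strand, *r.precursor_span)
                   for r in records]
    clusters = clusters_mod.scan_clusters(annotations, config.cluster_max_gap)
    clusters_mod.write_bed(clusters, out / "clusters.bed")
    report["stages"]["clusters"] = {"clusters": len(clusters)}

    # -- pare --------------------------------------------------------------
    if config.run_pare:
        transcripts, mirnas, pare_truth = synthetic.make_pare_dataset(
            seed=config.seed)
        tags = synthetic.simulate_pare(transcripts, pare_truth, seed=config.seed)
        profiles_by_lib = {"pare_1": degradome.map_tags(tags, transcripts)}
        dg_params = dataclasses.replace(config.degradome_params,
                                        seed=config.seed)
        hits, _ = degradome.call_targets(mirnas, transcripts, profiles_by_lib,
                                         dg_params)
        degradome.hits_to_frame(hits).to_csv(out / "pare_targets.tsv", sep="\t",
                                             index=False)
        report["stages"]["pare"] = {"targets": len(hits)}

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def fixture_report() -> Dict:
    """Summary statistics of the packaged conserved-miRNA table."""
    df = conservation.load_table1()
    spectrum = conservation.first_nt_spectrum(df["mature_seq"])
    return {
        "entries": int(len(df)),
        "families": int(df["family"].nunique()),
        "ncr_detected": int(df["ncr_flag"].sum()),
        "first_nt_spectrum": {b: round(f, 4) for b, f in spectrum.items()},
        "first_nt_au_fraction": round(spectrum["A"] + spectrum["U"], 4),
    }
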