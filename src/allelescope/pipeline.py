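"""End-to-end workflow: probe ranking, RFLP comparison, variant cataloging,
indel-marker genotyping with phenotype concordance, and motif scanning of
inserted promoter segments — one deterministic run with TSV outputs and a
JSON summary."""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .genemodel import AlleleSequence, GeneModel
from .motifs import DEFAULT_MOTIFS, scan
from .pcr import PrimerPair, ThresholdRule, concordance, genotype_panel
from .probe_match import rank_candidates
from .restriction import rflp_compare
from .variants import (annotate, call_variants, global_align, merge_complex,
                       protein_effect, write_catalog_tsv, write_catalog_vcf)

logger = logging.getLogger("allelescope")

SUMMARY_SCHEMA_VERSION = 1

__all__ = ["RunConfig", "run_full", "packaged_phenotype_table"]


def packaged_phenotype_table() -> pd.DataFrame:
    """The packaged soybean accession table (accession, db_phenotype,
    observed_phenotype) used for marker-phenotype concordance."""
    with resources.files("allelescope.data").joinpath(
            "phenotype_accessions.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


@dataclass
class RunConfig:
    """Validated inputs for a full run; recorded verbatim into the report."""

    reference: AlleleSequence
    alt: AlleleSequence
    model: GeneModel
    primer_pair: PrimerPair
    probe_interval_ref: tuple[int, int]
    probe_interval_alt: tuple[int, int]
    outdir: str
    enzyme_recognition: str = "GGCC"
    enzyme_cut_offset: int = 2
    merge_window: int = 10
    classification_rule: ThresholdRule = field(default_factory=ThresholdRule)
    motifs: tuple = DEFAULT_MOTIFS
    probe: str | None = None
    candidates: list | None = None
    min_identity: float = 75.0
    panel: list | None = None
    phenotypes: pd.DataFrame | None = None
    seed: int = 1

    def validate(self) -> None:
        for interval, allele in ((self.probe_interval_ref, self.reference),
                                 (self.probe_interval_alt, self.alt)):
            s, e = interval
            if not (1 <= s <= e <= len(allele.residues)):
                raise ValueError(f"probe interval {interval} outside {allele.name}")
        if self.merge_window < 0:
            raise ValueError("merge window must be >= 0")
        os.makedirs(self.outdir, exist_ok=True)


def run_full(config: RunConfig) -> dict:
    """Execute every stage in order and write one TSV per stage plus
    summary.json; returns the summary dict."""
    config.validate()
    out = config.outdir
    summary: dict = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "config": {
            "reference": config.reference.name, "alt": config.alt.name,
            "enzyme": f"{config.enzyme_recognition}:{config.enzyme_cut_offset}",
            "merge_window": config.merge_window, "seed": config.seed,
        },
    }

    if config.probe and config.candidates:
        logger.info("stage identify: ranking %d candidates", len(config.candidates))
        hits = rank_candidates(config.probe, config.candidates,
                               min_identity=config.min_identity)
        pd.DataFrame([h.__dict__ for h in hits]).to_csv(
            os.path.join(out, "identify.tsv"), sep="\t", index=False)
        summary["identify"] = {
            "n_hits": len(hits),
            "top": hits[0].candidate_id if hits else None,
            "top_identity": round(hits[0].percent_identity, 1) if hits else None,
        }

    logger.info("stage variants: aligning %s vs %s",
                config.reference.name, config.alt.name)
    aln = global_align(config.reference, config.alt)
    catalog = call_variants(aln, ref_allele=config.reference)
    catalog = merge_complex(catalog, window=config.merge_window)
    annotate(catalog, config.model)
    protein_effect(catalog, config.reference, config.alt, config.model)
    write_catalog_tsv(catalog, os.path.join(out, "variants.tsv"))
    write_catalog_vcf(catalog, os.path.join(out, "variants.vcf"))
    upstream_complex = [v for v in catalog
                        if v.vtype == "complex_indel" and v.feature == "upstream"]
    summary["variants"] = {
        "n_variants": len(catalog),
        "n_snv": len(catalog.of_type("snv")),
        "n_insertion": len(catalog.of_type("insertion")),
        "n_deletion": len(catalog.of_type("deletion")),
        "n_complex": len(catalog.of_type("complex_indel")),
        "net_upstream_indel": (upstream_complex[0].net_len
                               if upstream_complex else 0),
        "protein_effects": [
            {"position": v.position, "effect": f"{v.protein_effect[0]}"
             f"{v.protein_effect[1]}{v.protein_effect[2]}"}
            for v in catalog if isinstance(v.protein_effect, tuple)],
    }

    logger.info("stage rflp: %s digest", config.enzyme_recognition)
    rflp = rflp_compare(config.reference, config.alt,
                        recognition=config.enzyme_recognition,
                        probe_interval_a=config.probe_interval_ref,
                        probe_interval_b=config.probe_interval_alt,
                        cut_offset=config.enzyme_cut_offset, catalog=catalog)
    pd.DataFrame([
        {"allele": config.reference.name,
         "n_sites": len(rflp.digest_a.site_positions),
         "fragments": ",".join(map(str, rflp.digest_a.fragment_lengths)),
         "probe_fragments": ",".join(map(str, rflp.probe_lengths_a))},
        {"allele": config.alt.name,
         "n_sites": len(rflp.digest_b.site_positions),
         "fragments": ",".join(map(str, rflp.digest_b.fragment_lengths)),
         "probe_fragments": ",".join(map(str, rflp.probe_lengths_b))},
    ]).to_csv(os.path.join(out, "rflp.tsv"), sep="\t", index=False)
    summary["rflp"] = {
        "sites": [len(rflp.digest_a.site_positions),
                  len(rflp.digest_b.site_positions)],
        "probe_fragments_ref": list(rflp.probe_lengths_a),
        "probe_fragments_alt": list(rflp.probe_lengths_b),
        "lost_sites": len(rflp.sites_only_in_a),
        "attributed_to_snv": len(rflp.attributions),
    }

    if config.panel is not None:
        logger.info("stage genotype: panel of %d", len(config.panel))
        calls = genotype_panel(config.panel, config.primer_pair,
                               rule=config.classification_rule)
        pd.DataFrame([c.__dict__ for c in calls]).to_csv(
            os.path.join(out, "genotype.tsv"), sep="\t", index=False)
        counts = pd.Series([c.call for c in calls]).value_counts().to_dict()
        summary["genotype"] = {"calls": counts}
        if config.phenotypes is not None:
            report = concordance(calls, config.phenotypes)
            summary["concordance"] = {
                "db_conflicts": list(report.conflicts_db),
                "observed_conflicts": list(report.conflicts_observed),
                "excluded": list(report.excluded),
                "missing": list(report.missing),
            }

    inserted = [(f"insert_{v.position}", v.alt_allele) for v in catalog
                if v.vtype in ("insertion", "complex_indel") and v.alt_len >= 20]
    motif_rows = []
    for name, seq in inserted:
        for h in scan(seq, config.motifs):
            motif_rows.append({"segment": name, "motif": h.motif_name,
                               "pattern": h.pattern, "position": h.position,
                               "strand": h.strand, "matched": h.matched})
    pd.DataFrame(motif_rows).to_csv(os.path.join(out, "motifs.tsv"),
                                    sep="\t", index=False)
    summary["motifs"] = {
        "segments_scanned": len(inserted),
        "motifs_present": sorted({r["motif"] for r in motif_rows}),
    }

    with open(os.path.join(out, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
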