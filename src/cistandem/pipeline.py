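"""End-to-end orchestration: DE set calling -> promoter annotation ->
co-occurrence statistics -> motif homology (+ optional GSEA), from a single
configuration, with a machine-readable run report.

Every number in the report is re-derivable from the input files, the
configuration echo embedded in the report, and the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from . import cooccurrence as cc
from . import de_sets, gsea, motifs, promoters

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    kd_tables: list[str]
    ki_tables: list[str] = field(default_factory=list)
    tss_table: str = ""
    alu_track: str = ""
    alu_dialect: str = "bed"
    peak_track: str = ""
    peak_dialect: str = "narrowpeak"
    genome_fasta: str = ""
    transcript_fasta: str = ""
    gene_sets_gmt: str = ""
    promoter_up: int = 2500
    promoter_down: int = 500
    fdr_max: float = 0.05
    min_abs_log2fc: float = 0.0
    score_min: float = 0.8
    n_perm: int = 1000
    seed: int = 0
    out_dir: str = "cistandem_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        return cls(**raw)

    def echo(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write the RunReport + TSV intermediates."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "config": config.echo()}

    # --- de_sets ---------------------------------------------------------
    @_stage("desets")
    def stage_desets():
        kd = [de_sets.read_de_table(p) for p in config.kd_tables]
        ki = [de_sets.read_de_table(p) for p in config.ki_tables]
        catalog = de_sets.build_catalog(
            kd, ki, fdr_max=config.fdr_max, min_abs_log2fc=config.min_abs_log2fc
        )
        return kd, ki, catalog

    kd, ki, catalog = stage_desets()
    de_sets.write_catalog_json(catalog, out / "catalog.json")
    report["catalog_sizes"] = catalog.sizes()
    logger.info("desets: %s", report["catalog_sizes"])

    # --- promoter annotation --------------------------------------------
    @_stage("annotate")
    def stage_annotate():
        genes = promoters.read_tss_table(config.tss_table, dialect="bed6")
        alu = promoters.read_repeat_track(config.alu_track, dialect=config.alu_dialect)
        irf = promoters.read_peaks(config.peak_track, dialect=config.peak_dialect)
        anns = promoters.annotate_promoters(
            genes, alu, irf, up=config.promoter_up, down=config.promoter_down
        )
        return anns

    annotations = stage_annotate()
    promoters.write_annotations_tsv(annotations, out / "annotations.tsv")
    logger.info("annotate: %d promoters", len(annotations))

    # --- co-occurrence ---------------------------------------------------
    @_stage("cooccur")
    def stage_cooccur():
        window_cfg = {"promoter_up": config.promoter_up,
                      "promoter_down": config.promoter_down}
        core_anns = {g: annotations[g] for g in catalog.core_up if g in annotations}
        enr = cc.category_enrichment(core_anns, annotations, config=window_cfg)
        ranked = de_sets.rank_by_mean_fc(
            {g for g in catalog.gene_set_up if g in annotations}, kd
        )
        curve = cc.cumulative_curve(ranked, annotations)
        signature = cc.extract_signature(ranked, annotations)
        tandem = [annotations[g] for g in signature]
        topo = cc.topology_summary(tandem) if tandem else None
        return enr, curve, signature, topo

    enr, curve, signature, topo = stage_cooccur()
    cc.write_report_tsv(enr, out / "cooccurrence.tsv")
    cc.write_report_json(enr, out / "cooccurrence.json")
    cc.write_curve_tsv(curve, out / "cumulative_curve.tsv")
    report["cooccurrence"] = {
        "set_fractions": enr.set_fractions,
        "background_fractions": enr.background_fractions,
        "hypergeom_p": enr.hypergeom_p,
        "set_size": enr.set_size,
        "background_size": enr.background_size,
    }
    report["signature"] = signature
    report["cumulative_curve"] = {
        "k": curve.k_values,
        "frac_alu": curve.frac_alu_at_k,
        "frac_tandem": curve.frac_tandem_at_k,
    }
    if topo is not None:
        report["topology"] = {
            "median_irf_tss_distance": topo.median_irf_tss_distance,
            "median_alu_tss_distance": topo.median_alu_tss_distance,
            "frac_alu_upstream_of_tss": topo.frac_alu_upstream_of_tss,
            "frac_alu_upstream_of_irf": topo.frac_alu_upstream_of_irf,
            "spacing_range": [topo.spacing_min_observed, topo.spacing_max_observed],
        }

    # --- motif homology --------------------------------------------------
    if config.transcript_fasta:
        @_stage("motif")
        def stage_motif():
            transcript = next(iter(read_fasta(config.transcript_fasta).values()))
            alignments = {}
            if config.genome_fasta and signature:
                genome = read_fasta(config.genome_fasta)
                genes = {
                    g.gene_id: g
                    for g in promoters.read_tss_table(config.tss_table, dialect="bed6")
                }
                for gid in signature[:10]:
                    ann = annotations[gid]
                    gene = genes[gid]
                    for rel in ann.alu_elements[:1]:
                        iv = promoters.from_tss_relative(rel, gene)
                        seq = genome[gene.chrom][iv.start : iv.end]
                        if gene.strand == "-":
                            seq = motifs.revcomp(seq)
                        aln = motifs.align_motif_to_transcript(seq, transcript)
                        alignments[gid] = {
                            "transcript_offset": aln.transcript_offset,
                            "identity": aln.identity,
                            "strand": aln.strand,
                        }
            return alignments

        report["motif_homology"] = stage_motif()

    # --- optional preranked GSEA ----------------------------------------
    if config.gene_sets_gmt:
        @_stage("gsea")
        def stage_gsea():
            sets = gsea.read_gmt(config.gene_sets_gmt)
            profile = gsea.RankedProfile.from_table(kd[0])
            return gsea.run_gsea(
                profile, sets, n_perm=config.n_perm, seed=config.seed
            )

        gsea_df = stage_gsea()
        gsea_df.to_csv(out / "gsea.tsv", sep="\t", index=False)
        report["gsea"] = gsea_df.drop(columns=["undefined"]).to_dict("records")

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    return report
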