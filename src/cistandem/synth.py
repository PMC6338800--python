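"""Self-contained synthetic study generator with planted ground truth.

Emulates the statistical structure the analysis assumes: a small random
genome with strand-assigned, non-overlapping genes; a planted subset of
target genes whose promoters carry an Alu repeat and an IRF site in tandem
at an elevated rate (IRF proximal to the TSS, Alu upstream of it, spacing
uniform within a stated range); background promoters carrying the elements
at genome-like rates; perturbation DE tables in which targets respond
coherently (up under knockdown, down under overexpression); a lncRNA-analog
transcript embedding the same Alu consensus; and the small auxiliary tables
(isoform TPM, qPCR Ct) used by the quantification primitives.

Everything is drawn from a single seeded generator, so a fixed config gives
a byte-identical dataset.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .promoters import GeneModel, GenomicInterval, from_tss_relative

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# Fixed 300-base Alu-consensus analog shared between promoter plants and the
# synthetic transcript, so motif scanning and transcript homology line up.
ALU_CONSENSUS = "".join(
    "ACGT"[i] for i in np.random.default_rng(20_0331).integers(0, 4, 300)
)
# ISRE-like IRF site consensus (GAAA repeats on the reverse strand).
IRF_CONSENSUS = "TTTCACTTTCAC"

_ALU_FAMILIES = ("AluY", "AluJb", "AluSx")


class ConfigurationError(ValueError):
    """A synthetic-study configuration violates a placement constraint."""


@dataclass
class SynthConfig:
    """Study conditions for the synthetic dataset.

    The tandem rates default to the genome-scale values the analysis is
    meant to recover (0.55 in targets vs 0.38 in background) and the
    Alu-to-IRF spacing range defaults to 66-1973 bases.
    """

    n_chroms: int = 4
    chrom_len: int = 4_000_000
    n_genes: int = 1000
    n_targets: int = 100
    promoter_up: int = 2500
    promoter_down: int = 500
    p_tandem_target: float = 0.55
    p_tandem_background: float = 0.38
    p_alu_only_background: float = 0.30
    p_irf_only_background: float = 0.19
    spacing_min: int = 66
    spacing_max: int = 1973
    alu_len: int = 300
    irf_site_len: int = 12
    irf_tss_min: int = 20
    irf_tss_max: int = 160
    effect_mu: float = 2.0
    effect_sd: float = 0.3
    noise_sd: float = 0.2
    n_experiments_kd: int = 2
    n_experiments_ki: int = 1
    fdr_df: int = 10
    transcript_len: int = 1200
    transcript_alu_offset: int = 150
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "p_tandem_target": self.p_tandem_target,
            "p_tandem_background": self.p_tandem_background,
            "p_alu_only_background": self.p_alu_only_background,
            "p_irf_only_background": self.p_irf_only_background,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        if (self.p_tandem_background + self.p_alu_only_background
                + self.p_irf_only_background) > 1.0 + 1e-12:
            raise ConfigurationError("background category probabilities exceed 1")
        if self.spacing_min < 1 or self.spacing_min > self.spacing_max:
            raise ConfigurationError("need 1 <= spacing_min <= spacing_max")
        if self.n_targets > self.n_genes:
            raise ConfigurationError("n_targets cannot exceed n_genes")
        needed = self.alu_len + self.irf_site_len + self.spacing_min
        if self.promoter_up + self.promoter_down < needed:
            raise ConfigurationError(
                "promoter window shorter than alu_len + irf_site_len + spacing_min "
                f"({self.promoter_up + self.promoter_down} < {needed})"
            )
        deepest = (self.irf_tss_max + self.irf_site_len - 1
                   + self.spacing_max + self.alu_len)
        if deepest > self.promoter_up:
            raise ConfigurationError(
                "promoter_up too small for irf_tss_max + irf_site_len + "
                f"spacing_max + alu_len ({deepest} > {self.promoter_up})"
            )
        if not (0 <= self.transcript_alu_offset
                and self.transcript_alu_offset + self.alu_len <= self.transcript_len):
            raise ConfigurationError("Alu segment does not fit in the transcript")


@dataclass
class SyntheticDataset:
    """The generated study with its planted ground truth."""

    config: SynthConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    alu_track: list[GenomicInterval]
    irf_track: list[GenomicInterval]
    de_tables: dict[str, "np.ndarray | object"]  # experiment id -> DataFrame
    truth: dict
    transcript: str
    isoform_table: list[dict]
    ct_table: list[dict]


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _fit_motif(consensus: str, length: int) -> str:
    """Tile/trim a consensus to the requested element length."""
    reps = -(-length // len(consensus))
    return (consensus * reps)[:length]


def _place_genes(cfg: SynthConfig, rng: np.random.Generator) -> list[GeneModel]:
    """Non-overlapping TSS placement with promoter-window-sized separation.

    Uniform sorted positions with a minimum gap (offset trick), which keeps
    promoter windows collision-free without rejection loops.  The gap covers
    the worst strand pairing: a minus-strand gene's window reaches up to
    ``up`` bases downstream in genomic coordinates, so windows of adjacent
    genes on opposite strands only stay disjoint with a 2*max(up, down) gap.
    """
    if cfg.n_genes == 0:
        return []
    gap = 2 * max(cfg.promoter_up, cfg.promoter_down) + 2
    margin = gap  # keeps every window inside the chromosome on both strands
    per_chrom = np.full(cfg.n_chroms, cfg.n_genes // cfg.n_chroms)
    per_chrom[: cfg.n_genes % cfg.n_chroms] += 1
    genes: list[GeneModel] = []
    gid = 0
    width = len(str(cfg.n_genes))
    for c in range(cfg.n_chroms):
        n = int(per_chrom[c])
        if n == 0:
            continue
        usable = cfg.chrom_len - 2 * margin - (n - 1) * gap
        if usable < n:
            raise ConfigurationError(
                f"cannot place {n} genes on a {cfg.chrom_len}-base chromosome "
                f"with {gap}-base separation"
            )
        offsets = np.sort(rng.integers(0, usable, size=n))
        positions = margin + offsets + np.arange(n) * gap
        strands = rng.random(n) < 0.5
        for i in range(n):
            genes.append(
                GeneModel(
                    gene_id=f"g{gid:0{width}d}",
                    chrom=f"chr{c + 1}",
                    strand="+" if strands[i] else "-",
                    tss=int(positions[i]),
                )
            )
            gid += 1
    return genes


def _sample_category(cfg: SynthConfig, is_target: bool, rng: np.random.Generator) -> str:
    """Category draw; targets get the elevated tandem rate and fall back to
    the background-conditional split among the remaining categories."""
    p_both = cfg.p_tandem_target if is_target else cfg.p_tandem_background
    rest = 1.0 - cfg.p_tandem_background
    if rest <= 0:
        p_alu, p_irf = 0.0, 0.0
    else:
        scale = (1.0 - p_both) / rest
        p_alu = cfg.p_alu_only_background * scale
        p_irf = cfg.p_irf_only_background * scale
    u = rng.random()
    if u < p_both:
        return "both"
    if u < p_both + p_irf:
        return "irf_only"
    if u < p_both + p_irf + p_alu:
        return "alu_only"
    return "none"


def _plant_elements(
    cfg: SynthConfig, gene: GeneModel, category: str, rng: np.random.Generator
) -> tuple[GenomicInterval | None, GenomicInterval | None]:
    """TSS-relative placement in the transcription direction, then lifted to
    genomic coordinates strand-aware."""
    alu_rel = irf_rel = None
    if category in ("both", "irf_only"):
        d = int(rng.integers(cfg.irf_tss_min, cfg.irf_tss_max + 1))
        irf_rel = (-d - cfg.irf_site_len + 1, -d + 1)
    if category == "both":
        s = int(rng.integers(cfg.spacing_min, cfg.spacing_max + 1))
        alu_end = irf_rel[0] - s
        alu_rel = (alu_end - cfg.alu_len, alu_end)
    elif category == "alu_only":
        lo, hi = -cfg.promoter_up, cfg.promoter_down - cfg.alu_len
        start = int(rng.integers(lo, hi + 1))
        alu_rel = (start, start + cfg.alu_len)
    alu = from_tss_relative(alu_rel, gene) if alu_rel else None
    irf = from_tss_relative(irf_rel, gene) if irf_rel else None
    return alu, irf


def _embed(genome: dict[str, np.ndarray], iv: GenomicInterval, motif: str, strand: str) -> None:
    seq = motif if strand == "+" else _revcomp(motif)
    genome[iv.chrom][iv.start : iv.end] = np.frombuffer(seq.encode(), dtype=np.uint8)


def _de_table(
    cfg: SynthConfig,
    gene_ids: list[str],
    is_target: np.ndarray,
    sign: int,
    rng: np.random.Generator,
):
    """One perturbation DE table: targets get a coherent signed effect."""
    import pandas as pd
    from scipy import stats as sps

    n = len(gene_ids)
    effect = np.zeros(n)
    n_t = int(is_target.sum())
    if n_t:
        draws = cfg.effect_mu + cfg.effect_sd * rng.standard_normal(n_t)
        # Effects are magnitudes: redraw the (rare) non-positive tail so a
        # noiseless dataset is perfectly coherent.
        bad = draws <= 0
        while bad.any():
            draws[bad] = cfg.effect_mu + cfg.effect_sd * rng.standard_normal(bad.sum())
            bad = draws <= 0
        effect[is_target] = sign * draws
    log2fc = effect + cfg.noise_sd * rng.standard_normal(n)
    se = cfg.noise_sd if cfg.noise_sd > 0 else 0.25
    t = log2fc / se
    p = 2.0 * sps.t.sf(np.abs(t), df=cfg.fdr_df)
    fdr = sps.false_discovery_control(p) if n else p
    return pd.DataFrame(
        {"gene_id": gene_ids, "log2FC": log2fc, "t": t, "p": p, "FDR": fdr}
    )


def generate_dataset(config: SynthConfig) -> SyntheticDataset:
    """Generate the full synthetic study from a validated configuration."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = _place_genes(config, rng)
    genome = {
        f"chr{c + 1}": rng.integers(0, 4, size=config.chrom_len, dtype=np.uint8)
        for c in range(config.n_chroms)
    }
    for chrom in genome:
        genome[chrom] = _BASES[genome[chrom]]

    n = len(genes)
    target_idx = set(
        rng.choice(n, size=config.n_targets, replace=False).tolist()
    ) if config.n_targets else set()

    alu_track: list[GenomicInterval] = []
    irf_track: list[GenomicInterval] = []
    planted: dict[str, dict] = {}
    tandem_targets: list[str] = []
    alu_seq = _fit_motif(ALU_CONSENSUS, config.alu_len)
    irf_seq = _fit_motif(IRF_CONSENSUS, config.irf_site_len)

    for i, gene in enumerate(genes):
        category = _sample_category(config, i in target_idx, rng)
        alu, irf = _plant_elements(config, gene, category, rng)
        rec: dict = {"category": category, "alu": None, "irf": None}
        if alu is not None:
            family = _ALU_FAMILIES[int(rng.integers(len(_ALU_FAMILIES)))]
            alu = GenomicInterval(
                chrom=alu.chrom, start=alu.start, end=alu.end,
                strand=gene.strand, label=family,
            )
            alu_track.append(alu)
            _embed(genome, alu, alu_seq, gene.strand)
            rec["alu"] = [alu.start, alu.end]
        if irf is not None:
            irf = GenomicInterval(
                chrom=irf.chrom, start=irf.start, end=irf.end,
                strand=gene.strand, label="irf_evidence",
            )
            irf_track.append(irf)
            _embed(genome, irf, irf_seq, gene.strand)
            rec["irf"] = [irf.start, irf.end]
        planted[gene.gene_id] = rec
        if i in target_idx and category == "both":
            tandem_targets.append(gene.gene_id)

    genome_str = {chrom: arr.tobytes().decode() for chrom, arr in genome.items()}

    gene_ids = [g.gene_id for g in genes]
    is_target = np.array([i in target_idx for i in range(n)])
    de_tables = {}
    for k in range(config.n_experiments_kd):
        de_tables[f"kd_{k + 1}"] = _de_table(config, gene_ids, is_target, +1, rng)
    for k in range(config.n_experiments_ki):
        de_tables[f"ki_{k + 1}"] = _de_table(config, gene_ids, is_target, -1, rng)

    # lncRNA-analog transcript with the Alu consensus embedded.
    t_arr = _BASES[rng.integers(0, 4, size=config.transcript_len, dtype=np.uint8)]
    transcript = t_arr.tobytes().decode()
    off = config.transcript_alu_offset
    transcript = (
        transcript[:off]
        + _fit_motif(ALU_CONSENSUS, config.alu_len)
        + transcript[off + config.alu_len:]
    )

    # Isoform abundances: the miR-incompatible class dominates (~97.6%).
    isoform_table = []
    for sample in ("basal_1", "basal_2", "basal_3"):
        incompat = np.clip(rng.normal([60, 25, 10], 2.0), 0.1, None)
        compat = np.clip(rng.normal([1.6, 0.8], 0.15), 0.01, None)
        for j, tpm in enumerate(incompat):
            isoform_table.append(
                {"sample": sample, "isoform_id": f"iso_inc_{j + 1}",
                 "tpm": round(float(tpm), 3), "compatibility": "mir_incompatible"}
            )
        for j, tpm in enumerate(compat):
            isoform_table.append(
                {"sample": sample, "isoform_id": f"iso_com_{j + 1}",
                 "tpm": round(float(tpm), 3), "compatibility": "mir_compatible"}
            )

    # Ct table: a knockdown halves the target transcript (ddCt = +1 cycle).
    ct_table = []
    base = {("calibrator", "target"): 24.0, ("calibrator", "normalizer"): 18.0,
            ("knockdown", "target"): 25.0, ("knockdown", "normalizer"): 18.0}
    for (sample, assay), ct in base.items():
        for rep in range(3):
            ct_table.append(
                {"sample": sample, "assay": assay, "replicate": rep + 1,
                 "ct": round(float(ct + 0.05 * rng.standard_normal()), 3)}
            )

    truth = {
        "target_ids": sorted(gene_ids[i] for i in target_idx),
        "tandem_target_ids": sorted(tandem_targets),
        "planted_elements": planted,
        "transcript_alu_offset": config.transcript_alu_offset,
        "transcript_alu_len": config.alu_len,
    }
    return SyntheticDataset(
        config=config,
        genome=genome_str,
        genes=genes,
        alu_track=alu_track,
        irf_track=irf_track,
        de_tables=de_tables,
        truth=truth,
        transcript=transcript,
        isoform_table=isoform_table,
        ct_table=ct_table,
    )


# ---------------------------------------------------------------------------
# Writer
# ---------------------------------------------------------------------------

def write_dataset(ds: SyntheticDataset, directory) -> dict[str, str]:
    """Write the dataset as the standard text formats; returns the manifest.

    Emits genome FASTA, TSS BED6, the Alu track as BED and RepeatMasker
    ``.out``, IRF peaks as narrowPeak, per-experiment DE TSVs, transcript
    FASTA, isoform TPM TSV, Ct CSV and the truth JSON.  Every file
    round-trips through the package's own readers.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def reg(key: str, name: str) -> Path:
        manifest[key] = name
        return directory / name

    with open(reg("genome", "genome.fa"), "w") as fh:
        for chrom, seq in ds.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")

    with open(reg("tss", "genes.bed"), "w") as fh:
        for g in ds.genes:
            fh.write(f"{g.chrom}\t{g.tss}\t{g.tss + 1}\t{g.gene_id}\t0\t{g.strand}\n")

    with open(reg("alu_bed", "alu.bed"), "w") as fh:
        for iv in ds.alu_track:
            strand = iv.strand or "+"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\t0\t{strand}\n")

    with open(reg("alu_out", "alu.out"), "w") as fh:
        fh.write("   SW   perc perc perc  query     position in query    "
                 "matching against repeat\n")
        fh.write("score   div. del. ins.  sequence  begin end   (left)   "
                 "repeat    class/family  begin end (left) ID\n\n")
        for i, iv in enumerate(ds.alu_track, 1):
            strand = "C" if iv.strand == "-" else "+"
            fh.write(
                f"  500   10.0  0.0  0.0  {iv.chrom}  {iv.start + 1} {iv.end} "
                f"(0)  {strand}  {iv.label}  SINE/Alu  1 {iv.end - iv.start} (0) {i}\n"
            )

    with open(reg("irf_peaks", "irf.narrowPeak"), "w") as fh:
        for i, iv in enumerate(ds.irf_track, 1):
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak{i}\t500\t.\t"
                f"5.0\t-1\t-1\t{(iv.end - iv.start) // 2}\n"
            )

    for exp_id, table in ds.de_tables.items():
        table.to_csv(reg(f"de_{exp_id}", f"de_{exp_id}.tsv"), sep="\t", index=False)

    with open(reg("transcript", "transcript.fa"), "w") as fh:
        fh.write(">lnc_transcript\n")
        for i in range(0, len(ds.transcript), 80):
            fh.write(ds.transcript[i : i + 80] + "\n")

    with open(reg("isoforms", "isoforms.tsv"), "w") as fh:
        fh.write("sample\tisoform_id\ttpm\tcompatibility\n")
        for row in ds.isoform_table:
            fh.write(f"{row['sample']}\t{row['isoform_id']}\t{row['tpm']}\t"
                     f"{row['compatibility']}\n")

    with open(reg("ct", "ct.csv"), "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["sample", "assay", "replicate", "ct"])
        writer.writeheader()
        writer.writerows(ds.ct_table)

    with open(reg("truth", "truth.json"), "w") as fh:
        json.dump(ds.truth, fh, indent=1)

    with open(reg("config", "config.json"), "w") as fh:
        json.dump(asdict(ds.config), fh, indent=1)

    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
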