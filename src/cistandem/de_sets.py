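"""Regulated gene-set calling from perturbation differential-expression tables.

A regulator is perturbed in both directions — knockdown (KD) with independent
reagents and overexpression / knock-in (KI) — and each experiment yields a
per-gene DE table (log2 fold-change, moderated-t analog, FDR).  Genes
upregulated in every KD experiment form the "gene set up"; intersecting with
genes downregulated under overexpression gives the coherent "core up" set of
bona fide direct targets (and symmetrically for "dn").
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

DE_COLUMNS = {"gene_id": "gene_id", "log2FC": "log2FC", "t": "t", "p": "p", "FDR": "FDR"}


def read_de_table(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a DE TSV with columns gene_id, log2FC, t, p, FDR.

    ``column_map`` maps the canonical names to the file's actual headers.
    Duplicate gene ids are collapsed by keeping the record with the highest
    |t| (the probe-collapse rule used for arrays: most variable probe wins).
    """
    cmap = dict(DE_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t")
    missing = [v for v in cmap.values() if v not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing DE columns {missing}")
    df = df.rename(columns={v: k for k, v in cmap.items()})
    df = df.loc[df["t"].abs().sort_values(ascending=False).index]
    df = df.drop_duplicates(subset="gene_id", keep="first").reset_index(drop=True)
    return df


def select_regulated(
    table: pd.DataFrame,
    direction: str,
    fdr_max: float = 0.05,
    min_abs_log2fc: float = 0.0,
) -> set[str]:
    """Genes significantly regulated in one direction.

    Keeps genes with FDR <= ``fdr_max``, log2FC sign matching ``direction``
    ("up" or "down") and |log2FC| >= ``min_abs_log2fc``.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"unknown direction {direction!r}")
    if table["gene_id"].duplicated().any():
        raise ValueError("DE table has duplicate gene ids; collapse first")
    sig = table["FDR"] <= fdr_max
    if direction == "up":
        sign_ok = table["log2FC"] > 0
    else:
        sign_ok = table["log2FC"] < 0
    big = table["log2FC"].abs() >= min_abs_log2fc
    return set(table.loc[sig & sign_ok & big, "gene_id"])


@dataclass
class GeneSetCatalog:
    """Per-experiment regulated sets and their coherent intersections."""

    up_per_kd: list[set[str]]
    dn_per_kd: list[set[str]]
    gene_set_up: set[str]
    gene_set_dn: set[str]
    core_up: set[str]
    core_dn: set[str]
    has_ki: bool = True

    def sizes(self) -> dict[str, int]:
        return {
            "gene_set_up": len(self.gene_set_up),
            "gene_set_dn": len(self.gene_set_dn),
            "core_up": len(self.core_up),
            "core_dn": len(self.core_dn),
        }


def build_catalog(
    kd_tables: Sequence[pd.DataFrame],
    ki_tables: Sequence[pd.DataFrame] = (),
    fdr_max: float = 0.05,
    min_abs_log2fc: float = 0.0,
) -> GeneSetCatalog:
    """Build the coherent target catalog from KD and KI DE tables.

    gene_set_up = genes up in every KD table; core_up additionally down in
    every KI table (the coherent direct-target candidates); symmetric for dn.
    With no KI tables the core sets are flagged empty.
    """
    if len(kd_tables) == 0:
        raise ValueError("need at least one knockdown DE table")
    up_per_kd = [select_regulated(t, "up", fdr_max, min_abs_log2fc) for t in kd_tables]
    dn_per_kd = [select_regulated(t, "down", fdr_max, min_abs_log2fc) for t in kd_tables]
    gene_set_up = set.intersection(*up_per_kd)
    gene_set_dn = set.intersection(*dn_per_kd)
    if ki_tables:
        ki_dn = [select_regulated(t, "down", fdr_max, min_abs_log2fc) for t in ki_tables]
        ki_up = [select_regulated(t, "up", fdr_max, min_abs_log2fc) for t in ki_tables]
        core_up = gene_set_up & set.intersection(*ki_dn)
        core_dn = gene_set_dn & set.intersection(*ki_up)
        has_ki = True
    else:
        core_up, core_dn, has_ki = set(), set(), False
    return GeneSetCatalog(
        up_per_kd=up_per_kd,
        dn_per_kd=dn_per_kd,
        gene_set_up=gene_set_up,
        gene_set_dn=gene_set_dn,
        core_up=core_up,
        core_dn=core_dn,
        has_ki=has_ki,
    )


@dataclass(frozen=True)
class OverlapStats:
    size_a: int
    size_b: int
    intersection: int
    fraction_a: float
    fraction_b: float
    mean_fraction: float
    fisher_p: float


def overlap_stats(set_a: set, set_b: set, universe_size: int) -> OverlapStats:
    """Overlap fractions and a two-sided Fisher exact test for two gene sets.

    The 2x2 table is (in both, a only, b only, universe minus union);
    ``universe_size`` is the number of genes surviving the expression filter.
    """
    inter = len(set_a & set_b)
    union = len(set_a | set_b)
    if universe_size < union:
        raise ValueError(
            f"universe_size {universe_size} smaller than union size {union}"
        )
    return overlap_stats_from_counts(len(set_a), len(set_b), inter, universe_size)


def overlap_stats_from_counts(
    size_a: int, size_b: int, intersection: int, universe_size: int
) -> OverlapStats:
    """Overlap statistics from printed counts (no explicit membership lists)."""
    if intersection > min(size_a, size_b) or intersection < 0:
        raise ValueError("intersection must be within [0, min(|A|, |B|)]")
    union = size_a + size_b - intersection
    if universe_size < union:
        raise ValueError("universe smaller than union")
    frac_a = intersection / size_a if size_a else 0.0
    frac_b = intersection / size_b if size_b else 0.0
    table = np.array(
        [
            [intersection, size_a - intersection],
            [size_b - intersection, universe_size - union],
        ]
    )
    _, fisher_p = sps.fisher_exact(table, alternative="two-sided")
    return OverlapStats(
        size_a=size_a,
        size_b=size_b,
        intersection=intersection,
        fraction_a=frac_a,
        fraction_b=frac_b,
        mean_fraction=(frac_a + frac_b) / 2.0,
        fisher_p=float(fisher_p),
    )


def rank_by_mean_fc(genes: set[str], kd_tables: Sequence[pd.DataFrame]) -> list[str]:
    """Order genes by descending mean log2FC across KD tables.

    Ties broken lexicographically by gene id so the ranking is deterministic.
    """
    means: dict[str, float] = {}
    for gene in genes:
        vals = []
        for i, table in enumerate(kd_tables):
            hit = table.loc[table["gene_id"] == gene, "log2FC"]
            if hit.empty:
                raise ValueError(f"gene {gene!r} missing from KD table {i}")
            vals.append(float(hit.iloc[0]))
        means[gene] = float(np.mean(vals))
    return sorted(means, key=lambda g: (-means[g], g))


def write_catalog_json(catalog: GeneSetCatalog, path) -> None:
    payload = {
        "gene_set_up": sorted(catalog.gene_set_up),
        "gene_set_dn": sorted(catalog.gene_set_dn),
        "core_up": sorted(catalog.core_up),
        "core_dn": sorted(catalog.core_dn),
        "has_ki": catalog.has_ki,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def write_catalog_gmt(catalog: GeneSetCatalog, path) -> None:
    """One set per line: name, description, then member genes (GMT-like)."""
    with open(path, "w") as fh:
        for name in ("gene_set_up", "gene_set_dn", "core_up", "core_dn"):
            members = sorted(getattr(catalog, name))
            fh.write("\t".join([name, "cistandem"] + members) + "\n")
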