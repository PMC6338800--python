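"""Preranked gene-set enrichment on t-ranked differential-expression profiles.

Implements the weighted Kolmogorov-Smirnov running-sum enrichment score on a
preranked profile, gene-label permutation normalisation (NES) with
same-sign pooling, custom top-k signed set construction (e.g. top-100
luminal/basal genes), and the differential luminal-minus-basal NES used to
place a perturbation on the basal-luminal axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class RankedProfile:
    """Genes ordered by descending ranking statistic (moderated t)."""

    genes: list[str]
    stats: np.ndarray

    def __post_init__(self) -> None:
        self.stats = np.asarray(self.stats, dtype=float)
        if len(self.genes) != len(self.stats):
            raise ValueError("genes and stats must have equal length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("profile genes must be unique")
        if np.any(np.diff(self.stats) > 1e-12):
            raise ValueError("stats must be ordered non-increasing")

    @classmethod
    def from_table(cls, table: pd.DataFrame, stat_col: str = "t") -> "RankedProfile":
        df = table.sort_values(stat_col, ascending=False, kind="mergesort")
        return cls(genes=list(df["gene_id"]), stats=df[stat_col].to_numpy())

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ESResult:
    es: float
    nes: float | None = None
    p: float | None = None
    fdr: float | None = None
    running_sum: np.ndarray | None = None
    undefined: bool = False


def build_custom_sets(
    de_table: pd.DataFrame,
    n_top: int = 100,
    fdr_max: float = 0.05,
) -> tuple[list[str], list[str]]:
    """Top-k up and down gene sets among significant genes, selected by t.

    Among genes with FDR <= ``fdr_max``, the ``n_top`` with most positive t
    form the up set and the ``n_top`` with most negative t the down set;
    fewer are returned (with a warning) when fewer pass the filter.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    sig = de_table[de_table["FDR"] <= fdr_max]
    up = sig[sig["t"] > 0].sort_values("t", ascending=False, kind="mergesort")
    dn = sig[sig["t"] < 0].sort_values("t", ascending=True, kind="mergesort")
    up_set = list(up["gene_id"].head(n_top))
    dn_set = list(dn["gene_id"].head(n_top))
    if len(up_set) < n_top or len(dn_set) < n_top:
        import logging

        logging.getLogger(__name__).warning(
            "build_custom_sets: only %d up / %d down significant genes for n_top=%d",
            len(up_set), len(dn_set), n_top,
        )
    return up_set, dn_set


def _es_from_membership(
    stats: np.ndarray, member: np.ndarray, weight_exponent: float
) -> tuple[float, np.ndarray]:
    """Running sum and extreme deviation for a boolean membership vector."""
    N = len(stats)
    n_hit = int(member.sum())
    n_miss = N - n_hit
    weights = np.abs(stats) ** weight_exponent
    hit_w = np.where(member, weights, 0.0)
    total = hit_w.sum()
    if total == 0:
        # All member stats are zero: fall back to unweighted hit mass.
        hit_w = member.astype(float)
        total = hit_w.sum()
    steps = hit_w / total - np.where(member, 0.0, 1.0 / n_miss)
    running = np.cumsum(steps)
    idx = int(np.argmax(np.abs(running)))  # earliest position at ties
    return float(running[idx]), running


def enrichment_score(
    profile: RankedProfile,
    gene_set: Sequence[str],
    weight_exponent: float = 1.0,
) -> ESResult:
    """Weighted KS enrichment score of a gene set on a ranked profile.

    Hits increment the running sum by |t|^w normalised over set members,
    misses decrement by 1/(N - |S|); the ES is the running-sum value of
    maximal absolute deviation (earlier position wins a tie).
    """
    members = set(gene_set) & set(profile.genes)
    if not members:
        raise ValueError("gene set is disjoint from the profile")
    member = np.array([g in members for g in profile.genes])
    if member.all():
        raise ValueError("gene set covers the whole profile; no miss positions")
    es, running = _es_from_membership(profile.stats, member, weight_exponent)
    return ESResult(es=es, running_sum=running)


def nes_permutation(
    profile: RankedProfile,
    gene_set: Sequence[str],
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    weight_exponent: float = 1.0,
) -> ESResult:
    """Gene-label permutation NES and p-value for one set.

    Random same-size member subsets of the profile give the null ES
    distribution; NES = ES / mean(|null ES| of the same sign) and p is the
    fraction of same-sign null scores at least as extreme as the observed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = enrichment_score(profile, gene_set, weight_exponent)
    n_members = len(set(gene_set) & set(profile.genes))
    N = len(profile)
    null = np.empty(n_perm)
    member = np.zeros(N, dtype=bool)
    for i in range(n_perm):
        member[:] = False
        member[rng.choice(N, size=n_members, replace=False)] = True
        null[i], _ = _es_from_membership(profile.stats, member, weight_exponent)
    same_sign = null[np.sign(null) == np.sign(base.es)] if base.es != 0 else null
    if len(same_sign) == 0:
        return ESResult(es=base.es, running_sum=base.running_sum, undefined=True)
    nes = base.es / np.mean(np.abs(same_sign))
    p = float(np.mean(np.abs(same_sign) >= abs(base.es) - 1e-12))
    return ESResult(es=base.es, nes=float(nes), p=p, running_sum=base.running_sum)


def differential_nes(nes_luminal: float | None, nes_basal: float | None) -> float:
    """Luminal-minus-basal NES; positive means a luminal-shifted profile."""
    if nes_luminal is None or nes_basal is None:
        raise ValueError("differential NES undefined: an input NES is undefined")
    return nes_luminal - nes_basal


# ---------------------------------------------------------------------------
# Multi-set driver with pooled-null FDR
# ---------------------------------------------------------------------------

def run_gsea(
    profile: RankedProfile,
    gene_sets: dict[str, Sequence[str]],
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> pd.DataFrame:
    """NES/p/FDR for many sets with a same-sign pooled permutation null."""
    rng = np.random.default_rng(seed)
    rows = []
    pooled_null: list[np.ndarray] = []
    for name, genes in gene_sets.items():
        res = nes_permutation(profile, genes, n_perm=n_perm, seed=rng,
                              weight_exponent=weight_exponent)
        rows.append({"set": name, "es": res.es, "nes": res.nes, "p": res.p,
                     "undefined": res.undefined})
    df = pd.DataFrame(rows)
    # FDR: fraction of observed same-sign NES at least as extreme, q-style.
    nes_vals = df["nes"].to_numpy(dtype=float)
    fdrs = []
    for nes in nes_vals:
        if not np.isfinite(nes):
            fdrs.append(np.nan)
            continue
        same = nes_vals[np.isfinite(nes_vals) & (np.sign(nes_vals) == np.sign(nes))]
        fdrs.append(float(np.mean(np.abs(same) >= abs(nes))))
    df["fdr"] = fdrs
    return df


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from GMT (name, description, members...) lines."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def read_ranked_profile(path, stat_col: str = "t") -> RankedProfile:
    """Read a two-column ranked-profile TSV (gene_id, t)."""
    df = pd.read_csv(path, sep="\t")
    return RankedProfile.from_table(df, stat_col=stat_col)
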