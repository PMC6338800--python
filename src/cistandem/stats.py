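"""Statistical and quantification primitives shared across the analysis.

Hypergeometric over-representation tails, the Jonckheere-Terpstra ordered
trend test, ROC/AUC via the Mann-Whitney identity, comparative-Ct (ddCt)
qPCR quantification, occupancy ratios normalised to an unrelated genomic
region, subcellular fraction percentages and transcript-isoform fraction
summaries.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


# ---------------------------------------------------------------------------
# Set statistics
# ---------------------------------------------------------------------------

def hypergeom_tail(x: int, N: int, K: int, n: int) -> float:
    """One-sided over-representation p-value P(X >= x).

    X ~ Hypergeometric(N, K, n): drawing ``n`` genes without replacement from
    a universe of ``N`` of which ``K`` are annotated.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts N={N}, K={K}, n={n}")
    if not (0 <= x <= min(K, n)):
        raise ValueError(f"x={x} outside [0, min(K={K}, n={n})]")
    if x == 0:
        return 1.0
    return float(sps.hypergeom.sf(x - 1, N, K, n))


# ---------------------------------------------------------------------------
# Jonckheere-Terpstra ordered trend test
# ---------------------------------------------------------------------------

@dataclass
class JTResult:
    statistic: float
    z: float
    p: float
    method: str


def _jt_statistic(groups: Sequence[Sequence[float]]) -> float:
    jt = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            for a in groups[i]:
                for b in groups[j]:
                    if b > a:
                        jt += 1.0
                    elif b == a:
                        jt += 0.5
    return jt


def jonckheere_terpstra(
    groups: Sequence[Sequence[float]],
    alternative: str = "increasing",
    exact: bool = False,
) -> JTResult:
    """Jonckheere-Terpstra test for a monotone trend across ordered groups.

    The statistic sums pairwise Mann-Whitney counts over all ordered group
    pairs, ties counted 1/2.  The default p-value uses the normal
    approximation with the tie-corrected variance; ``exact=True`` enumerates
    every assignment of the pooled observations to the group sizes (only
    feasible for small samples, roughly n <= 12).

    ``alternative`` states the a-priori trend direction: "increasing" means
    later groups tend to have larger values.
    """
    if len(groups) < 2:
        raise ValueError("need at least two ordered groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be nonempty")
    if alternative not in ("increasing", "decreasing"):
        raise ValueError(f"unknown alternative {alternative!r}")

    groups = [list(map(float, g)) for g in groups]
    jt = _jt_statistic(groups)

    sizes = np.array([len(g) for g in groups], dtype=float)
    N = sizes.sum()
    pooled = list(itertools.chain.from_iterable(groups))
    ties = np.array(list(Counter(pooled).values()), dtype=float)

    mean = (N**2 - (sizes**2).sum()) / 4.0
    # Tie-corrected variance (three-term formula).
    t1 = (
        N * (N - 1) * (2 * N + 5)
        - (sizes * (sizes - 1) * (2 * sizes + 5)).sum()
        - (ties * (ties - 1) * (2 * ties + 5)).sum()
    ) / 72.0
    t2 = (
        (sizes * (sizes - 1) * (sizes - 2)).sum()
        * (ties * (ties - 1) * (ties - 2)).sum()
    ) / (36.0 * N * (N - 1) * (N - 2))
    t3 = ((sizes * (sizes - 1)).sum() * (ties * (ties - 1)).sum()) / (8.0 * N * (N - 1))
    var = t1 + t2 + t3

    if var <= 0:
        z = 0.0
    else:
        z = (jt - mean) / np.sqrt(var)

    if exact:
        p = _jt_exact_p(groups, jt, alternative)
        return JTResult(statistic=jt, z=z, p=p, method="exact")

    if alternative == "increasing":
        p = float(sps.norm.sf(z))
    else:
        p = float(sps.norm.cdf(z))
    return JTResult(statistic=jt, z=z, p=p, method="normal")


def _jt_exact_p(groups, observed_jt: float, alternative: str) -> float:
    """Exact permutation p by enumerating all group assignments of the pool."""
    pooled = list(itertools.chain.from_iterable(groups))
    sizes = [len(g) for g in groups]

    def assignments(values, sizes):
        if not sizes:
            yield []
            return
        k = sizes[0]
        idx = range(len(values))
        for combo in itertools.combinations(idx, k):
            chosen = [values[i] for i in combo]
            rest = [values[i] for i in idx if i not in set(combo)]
            for tail in assignments(rest, sizes[1:]):
                yield [chosen] + tail

    total = 0
    extreme = 0
    for assignment in assignments(pooled, sizes):
        jt = _jt_statistic(assignment)
        total += 1
        if alternative == "increasing":
            if jt >= observed_jt - 1e-9:
                extreme += 1
        else:
            if jt <= observed_jt + 1e-9:
                extreme += 1
    return extreme / total


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve as Mann-Whitney U / (n1 * n0), ties 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


# ---------------------------------------------------------------------------
# qPCR quantification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CtRecord:
    """Cycle-threshold replicates for one (sample, assay) pair."""

    sample: str
    assay: str
    ct_replicates: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.ct_replicates) == 0:
            raise ValueError("need at least one Ct replicate")
        if any(not np.isfinite(c) or c <= 0 for c in self.ct_replicates):
            raise ValueError("Ct values must be finite and positive")

    @property
    def mean_ct(self) -> float:
        return float(np.mean(self.ct_replicates))


def ddct_rq(
    target: CtRecord,
    normalizer: CtRecord,
    calibrator_target: CtRecord,
    calibrator_normalizer: CtRecord,
) -> float:
    """Relative quantity by the comparative-Ct method, RQ = 2**(-ddCt).

    dCt = Ct(target) - Ct(normalizer) within each sample; ddCt subtracts the
    calibrator sample's dCt.  Replicates are averaged before differencing and
    amplification efficiency is fixed at 2.
    """
    dct_sample = target.mean_ct - normalizer.mean_ct
    dct_calib = calibrator_target.mean_ct - calibrator_normalizer.mean_ct
    return float(2.0 ** (-(dct_sample - dct_calib)))


def normalized_occupancy_ratio(
    ab_locus: CtRecord,
    ctrl_locus: CtRecord,
    ab_unrelated: CtRecord,
    ctrl_unrelated: CtRecord,
) -> float:
    """ChIP/ChIRP enrichment at a locus normalised to an unrelated region.

    ratio = 2**-(Ct_ab - Ct_ctrl) at the locus divided by the same quantity
    at the unrelated genomic region.
    """
    locus = 2.0 ** (-(ab_locus.mean_ct - ctrl_locus.mean_ct))
    unrelated = 2.0 ** (-(ab_unrelated.mean_ct - ctrl_unrelated.mean_ct))
    return float(locus / unrelated)


def read_ct_table(path) -> list[CtRecord]:
    """Read a Ct CSV (sample, assay, replicate, ct) into grouped records."""
    df = pd.read_csv(path)
    required = {"sample", "assay", "ct"}
    if not required.issubset(df.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    records = []
    for (sample, assay), grp in df.groupby(["sample", "assay"], sort=False):
        records.append(
            CtRecord(sample=str(sample), assay=str(assay), ct_replicates=tuple(grp["ct"]))
        )
    return records


# ---------------------------------------------------------------------------
# Fractions
# ---------------------------------------------------------------------------

def fraction_partition(values: Sequence[float]) -> list[float]:
    """Percentages of a total across compartments (e.g. nuclear/cytoplasmic)."""
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0):
        raise ValueError("compartment values must be non-negative")
    total = arr.sum()
    if total == 0:
        raise ValueError("all compartment values are zero")
    return list(arr / total * 100.0)


@dataclass(frozen=True)
class IsoformRecord:
    isoform_id: str
    tpm: float
    compatibility: str  # "mir_compatible" | "mir_incompatible"

    def __post_init__(self) -> None:
        if self.tpm < 0:
            raise ValueError("tpm must be >= 0")


def isoform_fractions(
    records: Iterable[IsoformRecord],
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-isoform relative percentages and cumulative class percentages.

    Returns ``(per_isoform_pct, per_class_pct)`` for a single sample; use
    :func:`isoform_class_means` to average percentages across samples.
    """
    records = list(records)
    total = sum(r.tpm for r in records)
    if total <= 0:
        raise ValueError("total TPM must be > 0")
    per_isoform = {r.isoform_id: r.tpm / total * 100.0 for r in records}
    per_class: dict[str, float] = {}
    for r in records:
        per_class[r.compatibility] = per_class.get(r.compatibility, 0.0) + r.tpm / total * 100.0
    return per_isoform, per_class


def isoform_class_means(samples: Sequence[Sequence[IsoformRecord]]) -> dict[str, float]:
    """Mean per-sample class percentage across samples (arithmetic mean)."""
    per_sample = [isoform_fractions(s)[1] for s in samples]
    classes = sorted({c for d in per_sample for c in d})
    return {c: float(np.mean([d.get(c, 0.0) for d in per_sample])) for c in classes}


def read_isoform_table(path) -> dict[str, list[IsoformRecord]]:
    """Read an isoform TPM TSV (sample, isoform_id, tpm, compatibility)."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[IsoformRecord]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["sample"]), []).append(
            IsoformRecord(
                isoform_id=str(row["isoform_id"]),
                tpm=float(row["tpm"]),
                compatibility=str(row["compatibility"]),
            )
        )
    return out
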