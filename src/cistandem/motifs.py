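"""PWM scanning, motif-set enrichment and motif-to-transcript homology.

Position weight matrices (from JASPAR counts or MEME minimal text) are
scored as log-odds sums against a background base composition.  Promoter
motifs recovered from a target set can be mapped back onto the regulator's
transcript by ungapped best-window alignment — the operation that links a
promoter repeat element to the homologous segment carried by the lncRNA —
and an in-silico deletion reports which motifs a truncated transcript
construct loses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .stats import hypergeom_tail

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """Probability matrix over A/C/G/T with log-odds scoring.

    ``matrix`` has shape (length, 4) in base order ACGT and each row sums
    to 1 after pseudocount normalisation.
    """

    matrix: np.ndarray
    background: np.ndarray
    pseudocount: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (length, 4)")
        if not np.allclose(self.matrix.sum(axis=1), 1.0):
            raise ValueError("PWM rows must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    @property
    def log_odds(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log2(self.matrix) - np.log2(self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())


def pwm_from_counts(
    counts: Sequence[Sequence[float]] | np.ndarray,
    pseudocount: float = 0.5,
    background: Sequence[float] | None = None,
    name: str = "",
) -> PWM:
    """Build a PWM from a count matrix: p = (count + pc) / (total + 4 pc)."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 4:
        raise ValueError("counts must have shape (length, 4) in ACGT order")
    if counts.shape[0] < 1:
        raise ValueError("PWM needs at least one position")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    totals = counts.sum(axis=1, keepdims=True)
    if pseudocount == 0 and np.any(totals == 0):
        raise ValueError("all-zero count column with pseudocount 0")
    probs = (counts + pseudocount) / (totals + 4 * pseudocount)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    return PWM(matrix=probs, background=bg, pseudocount=pseudocount, name=name)


def pwm_from_consensus(consensus: str, strength: float = 0.97, name: str = "") -> PWM:
    """Near-deterministic PWM from a consensus string (for synthetic motifs)."""
    L = len(consensus)
    mat = np.full((L, 4), (1 - strength) / 3)
    for i, base in enumerate(consensus.upper()):
        mat[i, _BASE_INDEX[base]] = strength
    return PWM(matrix=mat, background=np.full(4, 0.25), name=name or consensus)


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    offset: int
    strand: str
    score: float
    identity: float


def _encode(seq: str) -> np.ndarray:
    """Map a sequence to ACGT indices; ambiguous bases become 4."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def scan_sequence(
    pwm: PWM,
    sequence: str,
    score_min: float = 0.8,
    both_strands: bool = True,
    sequence_id: str = "",
) -> list[MotifHit]:
    """All PWM hits scoring at least ``score_min`` x max achievable score.

    ``score_min`` is a fraction of the PWM's maximum log-odds score (0.8 by
    default).  Ambiguous bases (N) contribute 0 to the log-odds sum.  Hits
    are reported on both strands (minus-strand offsets refer to the forward
    sequence) and sorted by offset.
    """
    L = len(pwm)
    if len(sequence) < L:
        return []
    threshold = score_min * pwm.max_score
    lo = np.vstack([pwm.log_odds.T, np.zeros((1, L))])  # row 4: N scores 0
    hits: list[MotifHit] = []
    strands = ("+", "-") if both_strands else ("+",)
    for strand in strands:
        seq = sequence if strand == "+" else revcomp(sequence)
        enc = _encode(seq)
        n_off = len(seq) - L + 1
        windows = np.lib.stride_tricks.sliding_window_view(enc, L)
        scores = lo[windows, np.arange(L)].sum(axis=1)
        cons = np.array([_BASE_INDEX[b] for b in pwm.consensus])
        idents = (windows == cons).mean(axis=1)
        for off in np.nonzero(scores >= threshold - 1e-12)[0]:
            fwd_off = int(off) if strand == "+" else len(sequence) - L - int(off)
            hits.append(
                MotifHit(
                    sequence_id=sequence_id,
                    offset=fwd_off,
                    strand=strand,
                    score=float(scores[off]),
                    identity=float(idents[off]),
                )
            )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


@dataclass(frozen=True)
class MotifEnrichment:
    set_hits: int
    set_size: int
    background_hits: int
    background_size: int
    set_fraction: float
    background_fraction: float
    p: float


def motif_set_enrichment(
    pwm: PWM,
    set_sequences: dict[str, str],
    background_sequences: dict[str, str],
    score_min: float = 0.8,
) -> MotifEnrichment:
    """Over-representation of sequences carrying >= 1 PWM hit in a set.

    The set must be drawn from the background universe; the p-value is the
    one-sided hypergeometric tail on the count of hit-bearing sequences.
    """
    if not set_sequences or not background_sequences:
        raise ValueError("both sequence collections must be nonempty")
    missing = sorted(set(set_sequences) - set(background_sequences))
    if missing:
        raise ValueError(f"set sequences not in background: {missing[:10]}")
    has_hit = {
        sid: bool(scan_sequence(pwm, seq, score_min=score_min, sequence_id=sid))
        for sid, seq in background_sequences.items()
    }
    K = sum(has_hit.values())
    x = sum(has_hit[sid] for sid in set_sequences)
    N, n = len(background_sequences), len(set_sequences)
    return MotifEnrichment(
        set_hits=x,
        set_size=n,
        background_hits=K,
        background_size=N,
        set_fraction=x / n,
        background_fraction=K / N,
        p=hypergeom_tail(x, N, K, n),
    )


@dataclass(frozen=True)
class HomologyAlignment:
    transcript_offset: int
    length: int
    identity: float
    score: int
    strand: str


def align_motif_to_transcript(
    motif_consensus: str, transcript_sequence: str
) -> HomologyAlignment:
    """Best ungapped window of the motif on the transcript (both strands).

    Scored by match count over all offsets; ties resolved by smallest offset
    with the forward strand preferred at an exact tie.
    """
    motif = motif_consensus.upper()
    transcript = transcript_sequence.upper()
    if not motif or not transcript:
        raise ValueError("motif and transcript must be nonempty")
    L = len(motif)
    if L > len(transcript):
        raise ValueError("motif longer than transcript")
    enc_t = _encode(transcript)
    windows = np.lib.stride_tricks.sliding_window_view(enc_t, L)
    best = None
    for strand, m in (("+", motif), ("-", revcomp(motif))):
        enc_m = _encode(m)
        matches = (windows == enc_m).sum(axis=1)
        off = int(matches.argmax())  # argmax takes the smallest offset on ties
        score = int(matches[off])
        key = (-score, off, strand)  # "+" < "-" lexicographically
        if best is None or key < best[0]:
            best = (key, off, score, strand)
    _, off, score, strand = best
    return HomologyAlignment(
        transcript_offset=off,
        length=L,
        identity=score / L,
        score=score,
        strand=strand,
    )


def apply_deletion(
    transcript: str,
    deletion_interval: tuple[int, int],
    motif_set: Sequence[str],
) -> tuple[str, dict[str, bool]]:
    """Excise an interval from the transcript and report motifs lost.

    A motif is "lost" when its best alignment window on the intact
    transcript intersects the deleted interval (the construct analog of
    deleting the Alu module from the lncRNA).
    """
    a, b = deletion_interval
    if not (0 <= a <= b <= len(transcript)):
        raise ValueError(f"deletion interval ({a}, {b}) out of transcript bounds")
    deleted = transcript[:a] + transcript[b:]
    lost: dict[str, bool] = {}
    for motif in motif_set:
        aln = align_motif_to_transcript(motif, transcript)
        w0, w1 = aln.transcript_offset, aln.transcript_offset + aln.length
        lost[motif] = max(w0, a) < min(w1, b)
    return deleted, lost


# ---------------------------------------------------------------------------
# PWM readers / writers
# ---------------------------------------------------------------------------

def read_jaspar(path) -> list[PWM]:
    """Read PWMs from JASPAR count format (one or more motifs per file)."""
    pwms = []
    name = ""
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if rows:
                    pwms.append(_finish_jaspar(name, rows))
                    rows = {}
                name = line[1:].split()[0]
            else:
                base = line[0].upper()
                nums = line[line.index("[") + 1 : line.index("]")].split()
                rows[base] = [float(v) for v in nums]
    if rows:
        pwms.append(_finish_jaspar(name, rows))
    return pwms


def _finish_jaspar(name: str, rows: dict[str, list[float]]) -> PWM:
    counts = np.array([rows[b] for b in BASES]).T
    return pwm_from_counts(counts, name=name)


def read_meme(path) -> list[PWM]:
    """Read PWMs from MEME minimal text format (letter-probability matrices)."""
    pwms = []
    with open(path) as fh:
        lines = fh.readlines()
    bg = np.full(4, 0.25)
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            vals = lines[i + 1].split()
            bg = np.array([float(vals[k]) for k in (1, 3, 5, 7)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            name = line.split()[1]
            j = i + 1
            while j < len(lines) and not lines[j].strip().startswith("letter-probability"):
                j += 1
            rows = []
            j += 1
            while j < len(lines) and lines[j].strip() and not lines[j].startswith("MOTIF"):
                parts = lines[j].split()
                if len(parts) != 4:
                    break
                rows.append([float(v) for v in parts])
                j += 1
            mat = np.array(rows)
            mat = mat / mat.sum(axis=1, keepdims=True)
            pwms.append(PWM(matrix=mat, background=bg, name=name))
            i = j
            continue
        i += 1
    return pwms


def write_hits_tsv(hits: Sequence[MotifHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence_id\toffset\tstrand\tscore\tidentity\n")
        for h in hits:
            fh.write(f"{h.sequence_id}\t{h.offset}\t{h.strand}\t{h.score:.4f}\t{h.identity:.4f}\n")
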