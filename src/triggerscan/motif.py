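"""PWM log-odds scanning of allele-specific windows with empirical nulls.

A transcription-factor binding motif is scored against a sequence window by
sliding its log-odds matrix over every offset on both strands; the best
match score La is compared with the motif's maximum attainable score Lm and
with an empirical null distribution of best-match scores.  For motif length
N <= 6 the null enumerates all 4^N sequences exactly; longer motifs use
unique random sequences.  Allele-specific scans of the reference and minor
allele windows yield gain/loss calls at a strict tier (empirical P < 0.001
and La/Lm > 0.75) or a relaxed tier (P < 0.005, La/Lm > 0.6).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

log = logging.getLogger(__name__)

__all__ = [
    "PWM",
    "read_jaspar",
    "read_meme_minimal",
    "pwm_logodds",
    "MotifHit",
    "scan_window",
    "EmpiricalNull",
    "empirical_null",
    "allele_scan",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

TIERS = {"strict": (0.001, 0.75), "relaxed": (0.005, 0.6)}


@dataclass(frozen=True)
class PWM:
    """Position weight matrix: per-position base weights over A,C,G,T."""

    name: str
    matrix: np.ndarray  # (length, 4) non-negative counts or probabilities

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("PWM matrix must be (length, 4)")
        if (m < 0).any():
            raise ValueError("PWM weights must be non-negative")
        if (m.sum(axis=1) == 0).any():
            raise ValueError("PWM has an all-zero position")
        object.__setattr__(self, "matrix", m)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))


def read_jaspar(path) -> list[PWM]:
    """Read JASPAR-format count matrices."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
        return [PWM(name=m.name, matrix=np.array(
            [[m.counts[b][i] for b in _BASES] for i in range(m.length)]
        )) for m in parsed]


def read_meme_minimal(path) -> list[PWM]:
    """Read MEME minimal-format motifs (letter-probability matrices)."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "minimal")
        return [PWM(name=m.name, matrix=np.array(
            [[m.counts[b][i] for b in _BASES] for i in range(m.length)]
        )) for m in parsed]


def pwm_logodds(
    pwm: PWM,
    background: float | np.ndarray = 0.25,
    pseudocount_fraction: float = 0.01,
) -> tuple[np.ndarray, float]:
    """Log-odds matrix (bits) and the maximum attainable score Lm.

    Weights become probabilities with a pseudocount of
    ``pseudocount_fraction`` x the position's total weight (split evenly
    across bases), then log2(p / background); Lm is the sum of per-position
    maxima.
    """
    m = pwm.matrix
    totals = m.sum(axis=1, keepdims=True)
    pc = pseudocount_fraction * totals / 4.0
    probs = (m + pc) / (totals + 4.0 * pc)
    bg = np.broadcast_to(np.asarray(background, dtype=float), probs.shape)
    with np.errstate(divide="ignore"):  # zero prob with zero pseudocount -> -inf
        lo = np.log2(probs / bg)
    lm = float(lo.max(axis=1).sum())
    return lo, lm


@dataclass(frozen=True)
class MotifHit:
    pwm_name: str
    offset: int
    strand: str
    la: float
    lm: float

    @property
    def ratio(self) -> float:
        return self.la / self.lm if self.lm != 0 else float("nan")


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(b, -1) for b in seq.upper()], dtype=int)


def _score_offsets(lo: np.ndarray, enc: np.ndarray) -> np.ndarray:
    """Best-match machinery: La at every valid offset; N bases -> -inf."""
    n = lo.shape[0]
    n_off = len(enc) - n + 1
    scores = np.full(n_off, -np.inf)
    for off in range(n_off):
        window = enc[off : off + n]
        if (window < 0).any():
            continue  # ambiguous base: window skipped
        scores[off] = lo[np.arange(n), window].sum()
    return scores


def scan_window(
    pwm: PWM,
    sequence: str,
    strands: str = "both",
    background: float | np.ndarray = 0.25,
    pseudocount_fraction: float = 0.01,
) -> MotifHit | None:
    """Best log-odds match of a PWM in a sequence window.

    Slides over every offset; with ``strands="both"`` the reverse
    complement is scanned too and the overall best hit returned.  Returns
    ``None`` when the sequence is shorter than the motif or every window
    contains an ambiguous base.
    """
    if len(sequence) < len(pwm):
        log.warning("scan_window: sequence shorter than motif %s", pwm.name)
        return None
    lo, lm = pwm_logodds(pwm, background, pseudocount_fraction)
    best: MotifHit | None = None
    for strand in ("+", "-"):
        if strands == "both" or strands == strand:
            seq = (
                sequence
                if strand == "+"
                else sequence.translate(_COMPLEMENT)[::-1]
            )
            scores = _score_offsets(lo, _encode(seq))
            if np.all(np.isinf(scores)):
                continue
            off = int(np.argmax(scores))
            hit = MotifHit(pwm.name, off, strand, float(scores[off]), lm)
            if best is None or hit.la > best.la:
                best = hit
    return best


@dataclass
class EmpiricalNull:
    """Null distribution of best-match La scores for one PWM."""

    scores: np.ndarray
    exhaustive: bool

    def p_value(self, la: float) -> float:
        """Empirical P of a query La (add-one for sampled nulls)."""
        k = int((self.scores >= la).sum())
        if self.exhaustive:
            return k / len(self.scores)
        return (k + 1) / (len(self.scores) + 1)


def empirical_null(
    pwm: PWM,
    B: int = 10_000,
    seed: int = 0,
    background: float | np.ndarray = 0.25,
    pseudocount_fraction: float = 0.01,
) -> EmpiricalNull:
    """Null La distribution over length-N sequences.

    For N <= 6 (or whenever B >= 4^N) all 4^N sequences are enumerated
    exactly; otherwise ``B`` unique random sequences of length N are drawn
    with uniform base composition.  Scores are single-offset matches (the
    null sequences have the motif's own length), forward strand.
    """
    lo, _ = pwm_logodds(pwm, background, pseudocount_fraction)
    n = len(pwm)
    if n <= 6 or B >= 4**n:
        combos = np.array(list(product(range(4), repeat=n)), dtype=int)
        scores = lo[np.arange(n), combos].sum(axis=1)
        return EmpiricalNull(scores=scores, exhaustive=True)
    rng = np.random.default_rng(seed)
    seen: set[bytes] = set()
    rows = np.empty((B, n), dtype=int)
    i = 0
    while i < B:
        cand = rng.integers(0, 4, size=n)
        key = cand.tobytes()
        if key in seen:
            continue
        seen.add(key)
        rows[i] = cand
        i += 1
    scores = lo[np.arange(n), rows].sum(axis=1)
    return EmpiricalNull(scores=scores, exhaustive=False)


def allele_scan(
    pwms: list[PWM],
    ref_window: str,
    alt_window: str,
    tier: str = "strict",
    B: int = 10_000,
    seed: int = 0,
    background: float | np.ndarray = 0.25,
    pseudocount_fraction: float = 0.01,
) -> pd.DataFrame:
    """Allele-specific motif scan with tiered filtering and gain/loss calls.

    ``ref_window`` and ``alt_window`` are the variant's flanked sequences
    (identical except at the variant base).  A PWM is retained when it is
    significant (empirical P below the tier's cutoff) in at least one
    allele AND reaches the tier's La/Lm ratio in at least one allele.  The
    call is "gain" when only the minor-allele window passes both criteria
    itself, "loss" when only the reference does, "both" when both do, and
    "either" when the retention rule is met across alleles only jointly.
    """
    if len(ref_window) != len(alt_window):
        raise ValueError("allele windows must have equal length")
    if tier not in TIERS:
        raise ValueError(f"tier must be one of {sorted(TIERS)}")
    p_cut, ratio_cut = TIERS[tier]
    rows = []
    for i, pwm in enumerate(pwms):
        null = empirical_null(
            pwm, B=B, seed=seed + i, background=background,
            pseudocount_fraction=pseudocount_fraction,
        )
        hits = {}
        for allele, window in (("ancestral", ref_window), ("minor", alt_window)):
            hit = scan_window(
                pwm, window, background=background,
                pseudocount_fraction=pseudocount_fraction,
            )
            if hit is None:
                continue
            hits[allele] = (hit, null.p_value(hit.la))
        if not hits:
            continue
        sig_any = any(p < p_cut for _, p in hits.values())
        ratio_any = any(h.ratio > ratio_cut for h, _ in hits.values())
        retained = sig_any and ratio_any
        passes = {
            a: (p < p_cut and h.ratio > ratio_cut) for a, (h, p) in hits.items()
        }
        if not retained:
            call = "none"
        elif passes.get("minor") and not passes.get("ancestral"):
            call = "gain"
        elif passes.get("ancestral") and not passes.get("minor"):
            call = "loss"
        elif passes.get("minor") and passes.get("ancestral"):
            call = "both"
        else:
            call = "either"
        for allele, (hit, p) in hits.items():
            rows.append(
                {
                    "pwm": pwm.name,
                    "allele": allele,
                    "strand": hit.strand,
                    "offset": hit.offset,
                    "la": hit.la,
                    "lm": hit.lm,
                    "ratio": hit.ratio,
                    "empirical_p": p,
                    "tier": tier,
                    "retained": retained,
                    "call": call,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "pwm", "allele", "strand", "offset", "la", "lm", "ratio",
            "empirical_p", "tier", "retained", "call",
        ],
    )
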