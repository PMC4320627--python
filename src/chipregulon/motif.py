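"""Motif discovery and scanning around peak maxima.

Sequences of ``2*flank + 1`` bp centered on the top-ranked peak maxima are
searched for an over-represented motif with an expectation-maximization
algorithm under the OOPS model (exactly one motif occurrence per sequence,
on either strand, against a 0-order background estimated from the input
composition).  The result is a position weight matrix with per-column
information content (bits against the background) and a degenerate IUPAC
consensus — for the transcription factor this package was built around, an
imperfect palindrome of the TGTYN8RAC class.  IUPAC consensus patterns can
be scanned back over arbitrary sequence on both strands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from chipregulon.concordance import MergedPeak
from chipregulon.formats import ValidationError

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement; supports the full IUPAC alphabet."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class Motif:
    """A PWM with counts, information content and degenerate consensus."""

    counts: np.ndarray  # (width, 4) expected base counts
    pwm: np.ndarray  # (width, 4) column-stochastic
    background: np.ndarray  # length-4 distribution
    n_sites: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.pwm = np.asarray(self.pwm, dtype=float)
        if self.pwm.shape != self.counts.shape or self.pwm.shape[1] != 4:
            raise ValidationError("pwm/counts must be (width, 4)")
        if not np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("pwm columns must sum to 1")

    @property
    def width(self) -> int:
        return self.pwm.shape[0]

    @property
    def ic(self) -> np.ndarray:
        return information_content(self.pwm, self.background)

    def consensus_iupac(self, threshold: float = 0.85) -> str:
        return consensus_from_pwm(self.pwm, threshold)

    def to_meme_text(self, name: str = "motif1") -> str:
        """Minimal MEME motif format (position probability matrix)."""
        lines = [
            "MEME version 4", "",
            "ALPHABET= ACGT", "",
            "Background letter frequencies",
            " ".join(f"{b} {f:.4f}" for b, f in zip(BASES, self.background)), "",
            f"MOTIF {name}",
            f"letter-probability matrix: alength= 4 w= {self.width} "
            f"nsites= {self.n_sites}",
        ]
        for row in self.pwm:
            lines.append(" ".join(f"{p:.6f}" for p in row))
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    offset: int  # forward-strand 0-based start
    strand: str  # "+" | "-"
    matched_text: str  # as read on the hit strand
    score: float | None = None


@dataclass
class FlankSequence:
    sequence_id: str
    sequence: str
    peak_rank: int
    clamped: bool = False


# ---------------------------------------------------------------------------
# Extraction & partitioning
# ---------------------------------------------------------------------------

def extract_flanks(
    merged_peaks: Sequence[MergedPeak], genome_sequence: str, flank: int = 50
) -> list[FlankSequence]:
    """One ``2*flank + 1`` bp sequence per peak, centered on the peak maximum.

    Peaks closer than ``flank`` to a sequence end are clamped to the
    boundary (shorter sequence) and flagged.
    """
    if flank <= 0:
        raise ValidationError("flank must be positive")
    L = len(genome_sequence)
    out = []
    for mp in merged_peaks:
        c = mp.coordinate
        if not 0 <= c < L:
            raise ValidationError(f"peak coordinate {c} outside sequence [0, {L})")
        start, end = c - flank, c + flank + 1
        clamped = start < 0 or end > L
        start, end = max(0, start), min(L, end)
        out.append(FlankSequence(
            sequence_id=f"peak_{mp.overall_rank}",
            sequence=genome_sequence[start:end].upper(),
            peak_rank=mp.overall_rank,
            clamped=clamped,
        ))
    return out


def partition_ranked(
    sequences: Sequence[FlankSequence], top_n: int, partition_size: int
) -> list[list[FlankSequence]]:
    """Top ``top_n`` sequences in rank order, chunked into rank-contiguous sets.

    The published analysis took the 500 top-ranked peaks and partitioned
    them into sets of 50 to separate motifs of strong vs weak sites.
    """
    ranked = sorted(sequences, key=lambda s: s.peak_rank)[:top_n]
    return [ranked[i:i + partition_size]
            for i in range(0, len(ranked), partition_size)]


# ---------------------------------------------------------------------------
# EM (OOPS) discovery
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(b, -1) for b in seq.upper()], dtype=np.int64)


def _background_from(encoded: list[np.ndarray]) -> np.ndarray:
    counts = np.ones(4)  # +1 pseudocount
    for e in encoded:
        valid = e[e >= 0]
        counts += np.bincount(valid, minlength=4)
    return counts / counts.sum()


def em_discover(
    sequences: Iterable,
    width: int = 15,
    n_restarts: int = 10,
    rng_seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-4,
    pseudocount: float = 0.25,
) -> tuple[Motif, float]:
    """EM motif discovery, one occurrence per sequence, both strands.

    Each restart seeds the PWM from a random sequence window (70% weight on
    the observed base).  The E-step computes the posterior over (position,
    strand) per sequence; the M-step re-estimates the PWM from the expected
    base counts plus ``pseudocount`` per cell.  Iteration stops when the
    log-likelihood improves by less than ``tol``.  Returns the best motif
    over restarts and its final log-likelihood; deterministic for a fixed
    seed.

    With a pseudocount the M-step maximizes a Dirichlet-penalized (MAP)
    objective, so it is the penalized log-likelihood — data log-likelihood
    plus ``pseudocount * sum(log pwm)`` — that EM guarantees non-decreasing;
    that quantity is asserted monotone every iteration.
    """
    seqs = [s.sequence if hasattr(s, "sequence") else str(s) for s in sequences]
    if width < 4:
        raise ValidationError("width must be >= 4")
    if not seqs:
        raise ValidationError("no sequences")
    for s in seqs:
        if len(s) < width:
            raise ValidationError(f"sequence of length {len(s)} shorter than width")

    encoded = [_encode(s) for s in seqs]
    bg = _background_from(encoded)
    log_bg = np.log(bg)

    # Stack every (position, strand) window of every sequence into one array;
    # per-sequence posteriors are then segment reductions over this stack.
    windows: list[np.ndarray] = []
    bg_scores: list[np.ndarray] = []  # log background prob of each window
    for e in encoded:
        m = np.lib.stride_tricks.sliding_window_view(e, width)
        rc = 3 - m[:, ::-1]  # reverse complement of each window
        rc[m[:, ::-1] < 0] = -1
        both = np.concatenate([m, rc])  # (2*n_windows, width)
        windows.append(both)
        safe = np.where(both >= 0, both, 0)
        lb = log_bg[safe] * (both >= 0)  # unknown bases contribute 0
        bg_scores.append(lb.sum(axis=1))
    all_windows = np.concatenate(windows)
    all_valid = all_windows >= 0
    all_safe = np.where(all_valid, all_windows, 0)
    all_bg = np.concatenate(bg_scores)
    seg_sizes = np.array([len(w) for w in windows])
    seg_starts = np.concatenate([[0], np.cumsum(seg_sizes)[:-1]])
    seg_id = np.repeat(np.arange(len(windows)), seg_sizes)
    base_masks = [(all_windows == b).astype(float) for b in range(4)]

    rng = np.random.default_rng(rng_seed)
    # seed windows are drawn from a canonically ordered copy so the result
    # does not depend on the input order of the sequences
    canon = [encoded[i] for i in sorted(range(len(seqs)), key=lambda i: seqs[i])]
    best: tuple[float, Motif] | None = None
    for _ in range(max(1, n_restarts)):
        pwm = _seed_pwm(canon, width, bg, rng)
        ll_prev = obj_prev = -np.inf
        for _it in range(max_iter):
            log_pwm = np.log(pwm)
            # E-step (uniform prior over (position, strand) within a sequence)
            col_idx = np.arange(width)[None, :]
            lm = (log_pwm[col_idx, all_safe] * all_valid).sum(axis=1)
            log_odds = lm - all_bg
            seg_max = np.maximum.reduceat(log_odds, seg_starts)
            w = np.exp(log_odds - seg_max[seg_id])
            z = np.add.reduceat(w, seg_starts)
            ll = float((seg_max + np.log(z / seg_sizes)).sum())
            post = w / z[seg_id]
            post_counts = np.full((width, 4), pseudocount)
            for b in range(4):
                post_counts[:, b] += post @ base_masks[b]
            # background term is constant given bg; omit from the tracked LL
            obj = ll + pseudocount * log_pwm.sum()
            assert obj >= obj_prev - 1e-6, "EM penalized log-likelihood decreased"
            converged = obj - obj_prev < tol
            obj_prev, ll_prev = obj, ll
            # M-step
            pwm = post_counts / post_counts.sum(axis=1, keepdims=True)
            if converged:
                break
        counts = post_counts - pseudocount
        motif = Motif(counts=counts, pwm=pwm, background=bg, n_sites=len(seqs))
        if best is None or ll_prev > best[0]:
            best = (ll_prev, motif)
    assert best is not None
    return best[1], best[0]


def _seed_pwm(encoded: list[np.ndarray], width: int, bg: np.ndarray,
              rng: np.random.Generator) -> np.ndarray:
    """Seed from a random width-mer of the data: 70% on the observed base."""
    for _ in range(100):
        e = encoded[rng.integers(len(encoded))]
        if len(e) >= width:
            j = rng.integers(len(e) - width + 1)
            wmer = e[j:j + width]
            if (wmer >= 0).all():
                pwm = np.tile(bg * 0.3, (width, 1))
                pwm[np.arange(width), wmer] += 0.7
                return pwm / pwm.sum(axis=1, keepdims=True)
    return np.tile(bg, (width, 1))


# ---------------------------------------------------------------------------
# Information content & consensus
# ---------------------------------------------------------------------------

def information_content(pwm: np.ndarray, background=None) -> np.ndarray:
    """Per-column relative entropy in bits; 0*log(0) taken as 0.

    Against the uniform background this is ``2 + sum_b p*log2(p)``, the
    quantity that sets letter heights in a sequence logo.
    """
    pwm = np.asarray(pwm, dtype=float)
    q = np.full(4, 0.25) if background is None else np.asarray(background, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pwm * np.log2(pwm / q)
    return np.where(pwm > 0, terms, 0.0).sum(axis=1)


# IUPAC classes ordered by degeneracy (size), then alphabetically: the
# consensus picks the smallest class covering >= threshold of the column.
_CLASSES = sorted(IUPAC.items(), key=lambda kv: (len(kv[1]), kv[0]))


def consensus_from_pwm(pwm: np.ndarray, threshold: float = 0.85) -> str:
    """Smallest IUPAC degeneracy class reaching ``threshold`` per column.

    Ties within a size class go to the larger summed frequency, then to the
    lexicographically smallest base set (so an exact tie between e.g. ACG and
    ACT resolves to V); a class reaching the threshold exactly wins
    (>= rule).  Columns nothing smaller covers fall back to N.
    """
    if not 0.5 <= threshold < 1:
        raise ValidationError("threshold must be in [0.5, 1)")
    pwm = np.asarray(pwm, dtype=float)
    out = []
    for col in pwm:
        chosen = "N"
        for size in (1, 2, 3, 4):
            cands = [(code, bases, sum(col[_BASE_INDEX[b]] for b in bases))
                     for code, bases in _CLASSES if len(bases) == size]
            cands = [(c, bs, s) for c, bs, s in cands if s >= threshold - 1e-12]
            if cands:
                chosen = min(cands, key=lambda cs: (-cs[2], cs[1]))[0]
                break
        out.append(chosen)
    return "".join(out)


# ---------------------------------------------------------------------------
# IUPAC scanning
# ---------------------------------------------------------------------------

def scan_iupac(
    sequence: str,
    pattern: str,
    both_strands: bool = True,
    sequence_id: str = "",
) -> list[MotifHit]:
    """All matches of a degenerate IUPAC pattern, overlapping hits included.

    Matching is case-insensitive; any non-ACGT sequence base fails every
    pattern position except N.  Reverse-strand hits carry forward-strand
    offsets and the matched text as read on the reverse strand.
    """
    pattern = pattern.upper()
    for ch in pattern:
        if ch not in IUPAC:
            raise ValidationError(f"invalid IUPAC code {ch!r} in pattern")
    seq = sequence.upper()
    w = len(pattern)
    hits: list[MotifHit] = []
    if w == 0 or len(seq) < w:
        return hits

    def matches(sub: str, pat: str) -> bool:
        return all(p == "N" or s in IUPAC[p] for s, p in zip(sub, pat))

    rc_pattern = reverse_complement(pattern)
    for i in range(len(seq) - w + 1):
        sub = seq[i:i + w]
        if matches(sub, pattern):
            hits.append(MotifHit(sequence_id, i, "+", sub))
        if both_strands and matches(sub, rc_pattern):
            hits.append(MotifHit(sequence_id, i, "-", reverse_complement(sub)))
    return hits


def scan_many(sequences: Sequence[FlankSequence], pattern: str,
              both_strands: bool = True) -> list[MotifHit]:
    hits: list[MotifHit] = []
    for fs in sequences:
        hits.extend(scan_iupac(fs.sequence, pattern, both_strands, fs.sequence_id))
    return hits


def plot_logo(motif: Motif, path, threshold: float = 0.85) -> None:
    """Sequence-logo-style plot: stacked letters with column heights = IC bits."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ic = motif.ic
    fig, ax = plt.subplots(figsize=(0.5 * motif.width + 1, 2.5))
    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}
    for j in range(motif.width):
        y = 0.0
        order = np.argsort(motif.pwm[j])
        for b in order:
            h = motif.pwm[j, b] * ic[j]
            if h > 0.01:
                ax.text(j + 0.5, y + h / 2, BASES[b], ha="center", va="center",
                        fontsize=8 + 10 * h, color=colors[BASES[b]])
            y += h
    ax.set_xlim(0, motif.width)
    ax.set_ylim(0, 2)
    ax.set_ylabel("bits")
    ax.set_xticks(np.arange(motif.width) + 0.5,
                  list(motif.consensus_iupac(threshold)))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
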