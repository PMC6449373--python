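"""PWM motif scanning and Fisher-exact enrichment.

Motifs are JASPAR-format count matrices (parsed via Biopython).  Scanning
scores every position of both strands with a log-odds matrix against a
uniform 0.25 background; a window is a hit when its score reaches
``score_fraction`` of the maximum achievable score, a scale-free threshold.
Windows containing N are skipped.

Enrichment compares a foreground region set (e.g. top induced H3K27ac
regions) against a disjoint background: a region counts as hit when at
least one motif occurrence overlaps it, the 2x2 table goes through a
one-sided Fisher's exact test (enrichment direction), and raw p-values are
Bonferroni-corrected over the number of motifs tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import motifs as bio_motifs
from scipy.stats import fisher_exact

from .errors import InputError

__all__ = [
    "PWM",
    "MotifHit",
    "MotifHitSet",
    "EnrichmentResult",
    "load_jaspar",
    "write_jaspar",
    "scan_motif",
    "motif_enrichment",
    "shuffle_columns",
    "demo_motif_path",
]

_ALPHABET = "ACGT"
_COMPLEMENT = {0: 3, 1: 2, 2: 1, 3: 0}


@dataclass(frozen=True)
class PWM:
    """A position count matrix with a consensus and log-odds scoring.

    ``counts`` is a 4 x L array in A, C, G, T row order.  The default
    pseudocount 0.8 is split evenly over the uniform background before
    log-odds conversion.
    """

    motif_id: str
    name: str
    counts: np.ndarray
    pseudocount: float = 0.8

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise InputError(f"motif {self.motif_id}: counts must be 4 x L")
        if counts.shape[1] < 4:
            raise InputError(f"motif {self.motif_id}: length must be >= 4")
        if (counts < 0).any():
            raise InputError(f"motif {self.motif_id}: negative counts")
        if (counts.sum(axis=0) <= 0).any():
            raise InputError(f"motif {self.motif_id}: empty column")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(_ALPHABET[i] for i in self.counts.argmax(axis=0))

    def log_odds(self) -> np.ndarray:
        """4 x L log2-odds against a uniform background."""
        totals = self.counts.sum(axis=0)
        p = (self.counts + self.pseudocount * 0.25) / (totals + self.pseudocount)
        return np.log2(p / 0.25)

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=0).sum())

    def reverse_complement(self) -> "PWM":
        rc = self.counts[::-1, ::-1]
        return PWM(self.motif_id, self.name, rc, self.pseudocount)


@dataclass(frozen=True)
class MotifHit:
    start: int
    end: int
    strand: str
    score: float


@dataclass
class MotifHitSet:
    motif_id: str
    hits: list[MotifHit] = field(default_factory=list)

    def starts(self) -> np.ndarray:
        return np.array([h.start for h in self.hits], dtype=int)


@dataclass(frozen=True)
class EnrichmentResult:
    """One row of the enrichment table: the 2x2 counts and corrected p."""

    motif_id: str
    fg_hit: int
    fg_miss: int
    bg_hit: int
    bg_miss: int
    p_raw: float
    p_bonferroni: float
    enriched: bool


def load_jaspar(path: str | Path) -> list[PWM]:
    """Parse a JASPAR-format motif file into PWMs (A, C, G, T rows)."""
    path = Path(path)
    try:
        with open(path) as handle:
            records = bio_motifs.parse(handle, "jaspar")
            pwms = [
                PWM(
                    rec.matrix_id or rec.name,
                    rec.name,
                    np.array([rec.counts[base] for base in _ALPHABET], dtype=float),
                )
                for rec in records
            ]
    except InputError:
        raise
    except Exception as exc:  # Biopython raises bare exceptions on ragged rows
        raise InputError(f"failed to parse JASPAR file {path}: {exc}") from exc
    if not pwms:
        raise InputError(f"no motifs found in {path}")
    return pwms


def write_jaspar(pwms: Iterable[PWM], path: str | Path) -> None:
    """Write motifs in JASPAR bracket format (round-trips with load_jaspar)."""
    with open(path, "w") as out:
        for pwm in pwms:
            out.write(f">{pwm.motif_id} {pwm.name}\n")
            for row, base in zip(pwm.counts, _ALPHABET):
                cells = " ".join(f"{v:10.2f}" for v in row)
                out.write(f"{base}  [{cells} ]\n")


def demo_motif_path() -> Path:
    """Bundled synthetic demo motifs (RBPJ-style, HES-style, shuffled control)."""
    return Path(__file__).parent / "resources" / "demo_motifs.jaspar"


def shuffle_columns(pwm: PWM, order: Sequence[int] | None = None) -> PWM:
    """A column-permuted control motif with identical composition.

    With ``order=None`` a fixed reversal-interleave permutation is used, so
    the control is deterministic and never the identity for L >= 2.
    """

    L = pwm.length
    if order is None:
        order = list(range(1, L, 2)) + list(range(0, L, 2))[::-1]
    if sorted(order) != list(range(L)):
        raise InputError("order must be a permutation of the motif columns")
    return PWM(
        f"{pwm.motif_id}_shuf", f"{pwm.name}_shuffled", pwm.counts[:, list(order)],
        pwm.pseudocount,
    )


def _encode(sequence: str) -> np.ndarray:
    table = np.full(256, 5, dtype=np.int8)
    for i, b in enumerate(_ALPHABET + "N"):
        table[ord(b)] = i
        table[ord(b.lower())] = i
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    code = table[arr]
    if (code == 5).any():
        raise InputError("sequence must be over the alphabet {A, C, G, T, N}")
    return code


def _window_scores(code: np.ndarray, lods: np.ndarray) -> np.ndarray:
    """Score every window against a 4 x L log-odds matrix; N poisons a window."""
    L = lods.shape[1]
    n = code.size - L + 1
    padded = np.vstack([lods, np.full(L, -np.inf)])
    scores = np.zeros(n)
    for j in range(L):
        scores += padded[code[j : j + n], j]
    return scores


def scan_motif(sequence: str, pwm: PWM, score_fraction: float = 0.8) -> MotifHitSet:
    """All positions on both strands scoring >= score_fraction * max score.

    Hits are half-open intervals in forward-strand coordinates; the reverse
    strand is scanned by scoring the reverse-complement matrix at the same
    positions, so scanning the reverse complement of a sequence yields the
    mirrored hit set exactly.
    """

    if not 0 < score_fraction <= 1:
        raise InputError("score_fraction must be in (0, 1]")
    hitset = MotifHitSet(pwm.motif_id)
    L = pwm.length
    if len(sequence) < L:
        return hitset
    code = _encode(sequence)
    threshold = score_fraction * pwm.max_score()
    fwd = _window_scores(code, pwm.log_odds())
    rev = _window_scores(code, pwm.reverse_complement().log_odds())
    for strand, scores in (("+", fwd), ("-", rev)):
        for pos in np.flatnonzero(scores >= threshold):
            hitset.hits.append(MotifHit(int(pos), int(pos) + L, strand, float(scores[pos])))
    hitset.hits.sort(key=lambda h: (h.start, h.strand))
    return hitset


def _regions_hit(
    regions: Sequence[tuple[int, int]], hits: MotifHitSet
) -> int:
    if not hits.hits:
        return 0
    starts = np.array([h.start for h in hits.hits])
    ends = np.array([h.end for h in hits.hits])
    n = 0
    for s, e in regions:
        if bool(((starts < e) & (ends > s)).any()):
            n += 1
    return n


def motif_enrichment(
    fg: Sequence[tuple[int, int]],
    bg: Sequence[tuple[int, int]],
    hitsets: Sequence[MotifHitSet],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """One-sided Fisher enrichment of motif-hit regions, Bonferroni-corrected.

    ``fg`` and ``bg`` must be disjoint, non-empty interval sets on the same
    chromosome as the scanned sequence.  Results come back sorted by raw p.
    """

    if not fg or not bg:
        raise InputError("foreground and background sets must be non-empty")
    for s, e in fg:
        for s2, e2 in bg:
            if s < e2 and s2 < e:
                raise InputError(
                    f"foreground region ({s}, {e}) overlaps background ({s2}, {e2})"
                )
    m = len(hitsets)
    out = []
    for hs in hitsets:
        a = _regions_hit(fg, hs)
        c = _regions_hit(bg, hs)
        b = len(fg) - a
        d = len(bg) - c
        _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
        p_bonf = min(1.0, m * float(p))
        out.append(
            EnrichmentResult(hs.motif_id, a, b, c, d, float(p), p_bonf, p_bonf < alpha)
        )
    out.sort(key=lambda r: (r.p_raw, r.motif_id))
    return out
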