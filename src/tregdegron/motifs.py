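"""PWM scanning and peak-level motif enrichment.

Windows are scored as the log-odds sum log2((p_base + 1e-4) / bg_base) on
both strands; windows containing N are skipped. Enrichment of a motif in a
foreground peak set versus the remaining universe is a hypergeometric tail
test on peak-level presence/absence of at least one hit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .containers import FormatError

#: pseudo-probability added to PWM entries before taking log-odds
PWM_PSEUDO = 1e-4

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PWM:
    """Position weight matrix: 4 x width base probabilities plus background."""

    motif_id: str
    matrix: np.ndarray  # rows A, C, G, T
    background: np.ndarray  # length-4 base frequencies

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.shape[0] != 4:
            raise FormatError("PWM matrix must have 4 base rows (A, C, G, T)")
        if self.width < 4:
            raise FormatError("PWM width must be >= 4")
        colsums = self.matrix.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-6):
            j = int(np.argmax(~np.isclose(colsums, 1.0, atol=1e-6)))
            raise FormatError(
                f"PWM {self.motif_id!r} column {j} sums to {colsums[j]:.8f}, not 1"
            )
        if not np.allclose(self.background.sum(), 1.0, atol=1e-6):
            raise FormatError("PWM background frequencies must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def log_odds(self) -> np.ndarray:
        return np.log2((self.matrix + PWM_PSEUDO) / self.background[:, None])

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=0).sum())


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(b, 4) for b in seq.upper()], dtype=np.int8)


def _scan_one_strand(codes: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Scores of every window on one strand; NaN where the window holds an N."""
    w = lo.shape[1]
    n_win = codes.size - w + 1
    if n_win <= 0:
        return np.empty(0)
    scores = np.zeros(n_win)
    invalid = np.zeros(n_win, dtype=bool)
    for j in range(w):
        col = codes[j:j + n_win]
        bad = col == 4
        invalid |= bad
        scores += np.where(bad, 0.0, lo[np.minimum(col, 3), j])
    scores[invalid] = np.nan
    return scores


def pwm_scan(
    sequences: Dict[str, str], pwm: PWM, score_threshold: float
) -> pd.DataFrame:
    """All windows scoring >= threshold on either strand of each record.

    Offsets are 0-based positions of the window start on the forward
    strand; minus-strand hits report the forward-strand coordinates of the
    reverse-complemented window. Sequences shorter than the motif yield no
    hits for that record.
    """
    lo = pwm.log_odds()
    w = pwm.width
    rows = []
    for name, seq in sequences.items():
        if set(seq.upper()) - set("ACGTN"):
            raise FormatError(f"sequence {name!r} contains non-ACGTN characters")
        if len(seq) < w:
            continue
        fwd = _scan_one_strand(_encode(seq), lo)
        for off in np.flatnonzero(fwd >= score_threshold):
            rows.append((name, int(off), "+", float(fwd[off])))
        rc = seq.translate(_COMPLEMENT)[::-1]
        rev = _scan_one_strand(_encode(rc), lo)
        L = len(seq)
        for off in np.flatnonzero(rev >= score_threshold):
            rows.append((name, int(L - w - off), "-", float(rev[off])))
    hits = pd.DataFrame(rows, columns=["record", "offset", "strand", "score"])
    return hits.sort_values(["record", "offset", "strand"], kind="stable").reset_index(
        drop=True
    )


def motif_enrichment(
    hits: pd.DataFrame,
    foreground_peaks: Sequence[str],
    background_peaks: Sequence[str],
) -> Tuple[float, float]:
    """Hypergeometric enrichment of peak-level motif presence.

    ``foreground_peaks`` and ``background_peaks`` partition the peak
    universe. Returns (p, fold) where p is the upper hypergeometric tail
    for the number of foreground peaks containing >= 1 hit and fold is the
    ratio of foreground to background hit rates.
    """
    fg: Set[str] = set(foreground_peaks)
    bg: Set[str] = set(background_peaks)
    if not fg:
        raise FormatError("foreground peak set is empty")
    if fg & bg:
        raise FormatError("foreground and background peak sets must be disjoint")
    with_hit = set(hits["record"]) if len(hits) else set()

    M = len(fg) + len(bg)
    n = len(with_hit & (fg | bg))
    N = len(fg)
    k = len(with_hit & fg)
    p = float(stats.hypergeom.sf(k - 1, M, n, N))

    fg_rate = k / N
    bg_hits = len(with_hit & bg)
    bg_rate = bg_hits / len(bg) if bg else np.nan
    fold = fg_rate / bg_rate if bg_rate and bg_rate > 0 else np.inf
    return p, float(fold)


def motif_enrichment_table(
    sequences: Dict[str, str],
    pwms: Sequence[PWM],
    foreground_peaks: Sequence[str],
    background_peaks: Sequence[str],
    score_frac: float = 0.8,
) -> pd.DataFrame:
    """Scan every PWM at ``score_frac`` of its maximum score and rank by p."""
    rows = []
    for pwm in pwms:
        hits = pwm_scan(sequences, pwm, score_frac * pwm.max_score())
        p, fold = motif_enrichment(hits, foreground_peaks, background_peaks)
        rows.append((pwm.motif_id, p, fold, int(hits["record"].nunique())))
    out = pd.DataFrame(rows, columns=["motif_id", "p", "fold", "n_peaks_with_hit"])
    return out.sort_values(["p", "motif_id"], kind="stable").reset_index(drop=True)
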