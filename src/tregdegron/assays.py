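"""Suppression-assay and proliferation summary statistics.

The suppression readout divides responder T cells labelled with a dilution
dye: cells divided strictly more than ``min_generations`` times (default 4)
count as divided, and suppression of a Treg-containing well is the relative
drop of its divided fraction versus the no-Treg control,

    %Suppression(X) = 100 * (divided(noTreg) - divided(X)) / divided(noTreg).
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .containers import FormatError


def divided_fraction(generations: Sequence[int], min_generations: int = 4) -> float:
    """Fraction of cells divided strictly more than ``min_generations`` times."""
    gen = np.asarray(list(generations))
    if gen.size == 0:
        raise FormatError("empty generation list")
    if min_generations < 0:
        raise FormatError("min_generations must be >= 0")
    if np.any(gen < 0):
        raise FormatError("generation numbers must be >= 0")
    return float(np.mean(gen > min_generations))


def percent_suppression(divided_no_treg: float, divided_sample: float) -> float:
    """Relative reduction of the divided fraction versus the no-Treg control.

    May be negative when the sample divides more than the control. The
    statistic is invariant to scaling both arguments by the same factor.
    """
    if divided_no_treg <= 0:
        raise FormatError("%suppression is undefined when the control does not divide")
    return 100.0 * (divided_no_treg - divided_sample) / divided_no_treg


def suppression_curve(wells: pd.DataFrame) -> pd.DataFrame:
    """Per-condition mean %suppression from a well table.

    ``wells`` needs columns condition and divided_fraction, with a
    'noTreg' condition serving as the control.
    """
    if "noTreg" not in set(wells["condition"]):
        raise FormatError("well table needs a 'noTreg' control condition")
    control = float(wells.loc[wells["condition"] == "noTreg", "divided_fraction"].mean())
    rows = []
    for cond, sub in wells.groupby("condition", sort=False):
        vals = [percent_suppression(control, f) for f in sub["divided_fraction"]]
        rows.append((cond, float(np.mean(vals)), float(np.std(vals, ddof=0)), len(vals)))
    return pd.DataFrame(rows, columns=["condition", "percent_suppression", "sd", "n_wells"])


def positive_fraction(
    flags: Sequence[bool], confidence: float = 0.95
) -> Tuple[float, Tuple[float, float]]:
    """Proportion of positive flags with an exact Clopper-Pearson interval."""
    arr = np.asarray(list(flags), dtype=bool)
    n = arr.size
    if n == 0:
        raise FormatError("empty flag list")
    k = int(arr.sum())
    alpha = 1.0 - confidence
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return k / n, (lo, hi)
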