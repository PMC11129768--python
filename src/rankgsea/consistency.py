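"""Agreement between scoring methods via Kendall's coefficient of concordance.

For every pair of methods and every gene set, the two per-cell score
vectors are treated as two raters ranking the same cells and summarised
by Kendall's W in [0, 1] (1 = identical rankings; for two raters,
independent rankings give W near 0.5 and exact reversal gives 0).
Pair-level medians across gene sets and an overall median summarise the
report.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .scoring import ScoreMatrix

__all__ = ["kendall_w_pair", "concordance_report", "ConcordanceReport"]


def _tie_term(ranks: np.ndarray) -> float:
    _, counts = np.unique(ranks, return_counts=True)
    return float((counts**3 - counts).sum())


def kendall_w_pair(a, b) -> float:
    """Kendall's W for two raters over n >= 3 subjects, with tie correction.

    W = 12 S / (m^2 (n^3 - n) - m T) with m = 2, S the sum of squared
    deviations of the per-subject rank sums from their mean, and T the
    tie correction summed over both raters.  Returns NaN when both
    vectors are constant (W undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("expected two equal-length 1-D vectors of length >= 3")
    n = a.size
    ra, rb = rankdata(a), rankdata(b)
    t = _tie_term(ra) + _tie_term(rb)
    denom = 4 * (n**3 - n) - 2 * t
    if denom <= 0:
        return float("nan")
    s = float(((ra + rb - (ra + rb).mean()) ** 2).sum())
    return float(np.clip(12 * s / denom, 0.0, 1.0))


@dataclass
class ConcordanceReport:
    """Pairwise Kendall-W table plus pair medians and the overall median."""

    per_set: pd.DataFrame     # method_a, method_b, set_name, W
    pair_medians: pd.DataFrame  # method_a, method_b, median_W
    overall_median: float

    def write(self, per_set_path, summary_path) -> None:
        self.per_set.to_csv(per_set_path, sep="\t", index=False)
        self.pair_medians.to_csv(summary_path, sep="\t", index=False)


def concordance_report(scores: list[ScoreMatrix]) -> ConcordanceReport:
    """Kendall's W per (method pair, gene set) over cells, with medians.

    All score matrices must share their gene sets and cells; method pairs
    are enumerated in sorted name order for determinism.
    """
    if len(scores) < 2:
        raise ValueError("concordance requires at least two score matrices")
    by_method = {s.method: s.to_frame() for s in scores}
    first = next(iter(by_method.values()))
    sets = list(first.index)
    cells = list(first.columns)
    for method, frame in by_method.items():
        if list(frame.index) != sets or list(frame.columns) != cells:
            raise ValueError(f"score matrix {method!r} does not share sets/cells")
    rows = []
    for ma, mb in combinations(sorted(by_method), 2):
        fa, fb = by_method[ma], by_method[mb]
        for set_name in sets:
            w = kendall_w_pair(fa.loc[set_name].to_numpy(), fb.loc[set_name].to_numpy())
            rows.append((ma, mb, set_name, w))
    per_set = pd.DataFrame(rows, columns=["method_a", "method_b", "set_name", "W"])
    pair_medians = (per_set.groupby(["method_a", "method_b"], sort=True)["W"]
                    .median().reset_index().rename(columns={"W": "median_W"}))
    overall = float(np.nanmedian(per_set["W"])) if len(per_set) else float("nan")
    return ConcordanceReport(per_set, pair_medians, overall)
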