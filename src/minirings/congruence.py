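"""Agreement between the phylogenetic and structural accretion rankings.

Each dual-ranked subelement contributes one point: its phylogenetic rank
normalized by the scale maximum (39) and its structural onion-model rank
normalized by 27, both times 100.  A point is "congruent" (filled) when
the absolute normalized difference is strictly below 25; ties at exactly
25 are hollow.  The Pearson correlation over all dual-ranked points is
affine-invariant, so the normalization only matters for the filled
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fixtures import PHYL_RANK_MAX, STRU_RANK_MAX

__all__ = ["CongruenceReport", "method_congruence", "CONGRUENCE_THRESHOLD"]

CONGRUENCE_THRESHOLD = 25.0


@dataclass
class CongruenceReport:
    per_subelement: pd.DataFrame
    n_total: int
    n_filled: int
    r_all: float
    p_all: float
    r_filled: float

    @property
    def pct_congruent(self) -> float:
        return 100.0 * self.n_filled / self.n_total


def method_congruence(subelements: pd.DataFrame) -> CongruenceReport:
    """Compare the two rank scales over all dual-ranked subelements.

    ``subelements`` is the long-format fixture table (any organism subset;
    ranks are shared, so duplicates collapse).  Subelements missing either
    rank are excluded.  Raises when fewer than 3 dual-ranked subelements
    remain.
    """
    ranks = subelements.drop_duplicates("subelement")[
        ["subelement", "phyl_rank", "stru_rank"]
    ].dropna()
    n = len(ranks)
    if n < 3:
        raise ValueError(f"only {n} dual-ranked subelements; need at least 3")
    phyl = 100.0 * ranks["phyl_rank"].to_numpy() / PHYL_RANK_MAX
    stru = 100.0 * ranks["stru_rank"].to_numpy() / STRU_RANK_MAX
    filled = np.abs(phyl - stru) < CONGRUENCE_THRESHOLD
    r_all = stats.pearsonr(phyl, stru)
    r_filled = (
        float(stats.pearsonr(phyl[filled], stru[filled]).statistic)
        if filled.sum() >= 3
        else float("nan")
    )
    per = pd.DataFrame(
        {
            "subelement": ranks["subelement"].to_numpy(),
            "phyl_rank": ranks["phyl_rank"].to_numpy(),
            "stru_rank": ranks["stru_rank"].to_numpy(),
            "phyl_norm": phyl,
            "stru_norm": stru,
            "filled": filled,
        }
    )
    return CongruenceReport(
        per_subelement=per,
        n_total=n,
        n_filled=int(filled.sum()),
        r_all=float(r_all.statistic),
        p_all=float(r_all.pvalue),
        r_filled=r_filled,
    )
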