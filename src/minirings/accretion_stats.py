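"""Rank correlations (rH) between structure similarity and accretion order,
and the aggregate sign statistics.

For one (organism, ring, splicing) triple, rH is the Pearson correlation
between the (transformed) rS values of that ring structure against every
scored subelement of the organism and the subelements' accretion ranks —
one value for the phylogenetic ranks (rHphyl) and one for the structural
onion-model ranks (rHstru).  The working hypothesis expects negative rH:
similarity to a proto-tRNA-like reference should decay as subelements get
younger.

Aggregation pools the per-triple rH values three ways: per organism
(extrema and percent-negative over rings x splicings), per ring (percent
negative over organisms x splicings), and per splicing position (percent
negative over organisms x rings), each with a chi-square test of the sign
proportion against 50%.  No multiple-testing correction is applied
anywhere, matching the original analysis; reports note this.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AccretionResult",
    "AggregateReport",
    "compute_rh",
    "percent_negative",
    "chi_square_vs_half",
    "rh_table",
    "aggregate",
]


@dataclass(frozen=True)
class AccretionResult:
    organism: str
    ring_id: int
    splicing_position: int
    rh_phyl: float | None
    rh_stru: float | None
    n_phyl: int
    n_stru: int


@dataclass
class AggregateReport:
    per_organism: pd.DataFrame   # the published summary's shape
    per_ring: pd.DataFrame       # percent negative over pooled organisms x splicings
    per_splicing: pd.DataFrame   # percent negative over pooled organisms x rings
    notes: list[str] = field(default_factory=list)


def compute_rh(z_scores, ranks) -> tuple[float | None, int]:
    """Pearson correlation of z-scores with ranks over the pairwise-complete set.

    Entries where either the z or the rank is missing (None/NaN) are
    dropped pairwise.  Returns ``(r, n)``; fewer than 3 complete pairs
    yields ``(None, n)``.  Invariant under any positive affine rescaling
    of the ranks.
    """
    z = np.asarray([np.nan if v is None else v for v in z_scores], dtype=float)
    r = np.asarray([np.nan if v is None else v for v in ranks], dtype=float)
    m = np.isfinite(z) & np.isfinite(r)
    n = int(m.sum())
    if n < 3 or z[m].std() == 0.0 or r[m].std() == 0.0:
        return None, n
    return float(stats.pearsonr(z[m], r[m]).statistic), n


def percent_negative(values) -> tuple[float | None, dict[str, int]]:
    """100 x (#strictly negative / #defined); zero counts as non-negative.

    Undefined entries (None/NaN) are reported but excluded from both
    numerator and denominator.  An empty defined set yields ``None``.
    """
    arr = np.asarray([np.nan if v is None else v for v in values], dtype=float)
    defined = np.isfinite(arr)
    counts = {
        "n_total": int(arr.size),
        "n_defined": int(defined.sum()),
        "n_undefined": int((~defined).sum()),
        "n_negative": int((arr[defined] < 0).sum()),
    }
    if counts["n_defined"] == 0:
        return None, counts
    return 100.0 * counts["n_negative"] / counts["n_defined"], counts


def chi_square_vs_half(n_negative: int, n_total: int) -> tuple[float, float, bool]:
    """1-df goodness of fit of a sign split against 50/50.

    No continuity correction; two-sided p; significance flag at 0.05.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    res = stats.chisquare([n_negative, n_total - n_negative])
    return float(res.statistic), float(res.pvalue), bool(res.pvalue < 0.05)


def rh_table(
    ring_features: pd.DataFrame,
    subelements: pd.DataFrame,
    z_mode: str = "identity",
    organisms=None,
) -> pd.DataFrame:
    """All rH values for every (organism, ring, splicing) x rank-type.

    ``ring_features`` has columns ring_id, splicing, pct_stem, pct_eloop,
    pct_gc_stem, pct_gc_loop; ``subelements`` is the long-format fixture
    (or synthetic) table.  Subelements with incomplete or zero-variance
    feature vectors are excluded from the rS sample (reducing n, logged in
    the n columns); missing ranks drop pairwise per rank type.
    Deterministic: no randomness anywhere.
    """
    from .fixtures import FEATURE_COLUMNS
    from .similarity import rs_matrix, z_transform

    feats = list(FEATURE_COLUMNS)
    rows = []
    ring_mat = ring_features[feats].to_numpy(dtype=float)
    orgs = organisms or sorted(subelements["organism"].unique())
    for organism in orgs:
        sub = subelements[subelements["organism"] == organism]
        sub_mat = sub[feats].to_numpy(dtype=float)
        # degenerate subelement vectors (NaN or zero variance) never score
        usable = np.all(np.isfinite(sub_mat), axis=1)
        usable[usable] &= np.std(sub_mat[usable], axis=1) > 0
        R = rs_matrix(ring_mat, sub_mat[usable])
        Z = z_transform(R, z_mode)
        phyl = sub["phyl_rank"].to_numpy(dtype=float)[usable]
        stru = sub["stru_rank"].to_numpy(dtype=float)[usable]
        for k, (_, ringrow) in enumerate(ring_features.iterrows()):
            rhp, n_p = compute_rh(Z[k], phyl)
            rhs, n_s = compute_rh(Z[k], stru)
            rows.append(
                {
                    "organism": organism,
                    "ring_id": int(ringrow["ring_id"]),
                    "splicing": int(ringrow["splicing"]),
                    "rh_phyl": np.nan if rhp is None else rhp,
                    "rh_stru": np.nan if rhs is None else rhs,
                    "n_phyl": n_p,
                    "n_stru": n_s,
                }
            )
    return pd.DataFrame(rows)


def _cognate_for(annotations, ring_id: int) -> str | None:
    for a in annotations or ():
        if a.ring_id == ring_id:
            return a.cognate_aa
    return None


def aggregate(
    rh: pd.DataFrame,
    annotations=None,
    fixed_denominator: int | None = None,
) -> AggregateReport:
    """Pool the rH table into the three published summaries.

    ``fixed_denominator`` optionally forces the per-organism percent-
    negative denominator to the published fixed total (rings x splicings)
    instead of the defined count, for strict reproduction; undefined rH
    values are always reported separately and never counted as negative.
    """
    notes = ["No multiple-testing correction is applied (matching the source analysis)."]
    per_org = []
    for organism, grp in rh.groupby("organism", sort=True):
        for method in ("phyl", "stru"):
            vals = grp[f"rh_{method}"]
            pct, counts = percent_negative(vals)
            denom = fixed_denominator or counts["n_defined"]
            pct_out = None if denom == 0 else 100.0 * counts["n_negative"] / denom
            chi2 = p = sig = None
            if denom:
                chi2, p, sig = chi_square_vs_half(counts["n_negative"], denom)
            defined = vals.dropna()
            imin, imax = defined.idxmin(), defined.idxmax()
            per_org.append(
                {
                    "organism": organism,
                    "method": method,
                    "n_values": counts["n_defined"],
                    "n_undefined": counts["n_undefined"],
                    "min_rh_x100": 100.0 * defined.loc[imin],
                    "min_ring_id": int(grp.loc[imin, "ring_id"]),
                    "min_cognate": _cognate_for(annotations, int(grp.loc[imin, "ring_id"])),
                    "max_rh_x100": 100.0 * defined.loc[imax],
                    "max_ring_id": int(grp.loc[imax, "ring_id"]),
                    "max_cognate": _cognate_for(annotations, int(grp.loc[imax, "ring_id"])),
                    "pct_negative": pct_out,
                    "chi_square": chi2,
                    "p_value": p,
                    "significant": sig,
                }
            )
    per_ring = []
    for (ring_id,), grp in rh.groupby(["ring_id"], sort=True):
        row = {"ring_id": int(ring_id)}
        row["cognate"] = _cognate_for(annotations, int(ring_id))
        for a in annotations or ():
            if a.ring_id == ring_id:
                row["integration_order"] = a.integration_order
        for method in ("phyl", "stru"):
            pct, counts = percent_negative(grp[f"rh_{method}"])
            row[f"pct_negative_{method}"] = pct
            row[f"n_{method}"] = counts["n_defined"]
            row[f"n_undefined_{method}"] = counts["n_undefined"]
        per_ring.append(row)
    per_splicing = []
    for (pos,), grp in rh.groupby(["splicing"], sort=True):
        row = {"splicing": int(pos)}
        for method in ("phyl", "stru"):
            pct, counts = percent_negative(grp[f"rh_{method}"])
            row[f"pct_negative_{method}"] = pct
            row[f"n_{method}"] = counts["n_defined"]
            row[f"n_undefined_{method}"] = counts["n_undefined"]
        per_splicing.append(row)
    return AggregateReport(
        per_organism=pd.DataFrame(per_org),
        per_ring=pd.DataFrame(per_ring),
        per_splicing=pd.DataFrame(per_splicing),
        notes=notes,
    )
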