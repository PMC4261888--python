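"""Persistence of LD phase between two populations.

For marker pairs shared by two populations (after the group-wise marker
intersection), the Pearson correlation of signed r is computed within
half-open distance bins [lo, hi) of a fixed width (default 50 kb, spanning
0-5000 kb).  A high per-bin correlation means the more-frequent-than-
expected haplotype couples the same alleles in both populations at that
distance, i.e. marker-QTL phase transfers.

Bins with fewer than two joined pairs, or with zero variance in either
population, have no defined correlation and are reported as missing with a
reason — never as zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import StructuralError

__all__ = ["align_pairs", "persistence_curve", "evaluate_bin_widths"]

DEFAULT_WIDTHS = (10.0, 30.0, 50.0, 70.0, 100.0)


def align_pairs(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Inner-join two pair-LD tables on (snp_a, snp_b).

    Distances come from the shared map and must agree between the inputs.
    Returns columns snp_a, snp_b, distance_kb, r_signed_a, r_signed_b
    (plus r2_a / r2_b for downstream summaries).
    """
    cols = ["snp_a", "snp_b", "distance_kb", "r2", "r_signed"]
    joined = a[cols].merge(
        b[cols], on=["snp_a", "snp_b"], suffixes=("_a", "_b"), how="inner"
    )
    if len(joined) and not np.allclose(
        joined["distance_kb_a"], joined["distance_kb_b"], atol=1e-9
    ):
        raise StructuralError("pair tables disagree on inter-marker distances")
    joined = joined.rename(columns={"distance_kb_a": "distance_kb"}).drop(
        columns=["distance_kb_b"]
    )
    return joined


def persistence_curve(
    joined: pd.DataFrame, bin_width_kb: float = 50.0, max_kb: float = 5000.0
) -> pd.DataFrame:
    """Per-bin Pearson correlation of signed r between the two populations.

    A pair at distance d falls in bin floor(d / width) (half-open
    [lo, hi)); pairs at d >= max_kb are excluded.  Output columns: lo_kb,
    hi_kb, n_pairs, pearson_r, note (empty when defined).
    """
    if joined.empty:
        raise StructuralError("no joined pairs: cannot build a persistence curve")
    d = joined["distance_kb"].to_numpy(dtype=float)
    xa = joined["r_signed_a"].to_numpy(dtype=float)
    xb = joined["r_signed_b"].to_numpy(dtype=float)
    ok = ~(np.isnan(xa) | np.isnan(xb))
    n_bins = int(np.ceil(max_kb / bin_width_kb))
    rows = []
    idx = np.floor(d / bin_width_kb).astype(int)
    for b in range(n_bins):
        lo, hi = b * bin_width_kb, (b + 1) * bin_width_kb
        sel = ok & (idx == b) & (d < max_kb)
        ya, yb = xa[sel], xb[sel]
        note = ""
        r = np.nan
        if sel.sum() < 2:
            note = "fewer than 2 pairs"
        elif np.std(ya) == 0 or np.std(yb) == 0:
            note = "zero variance"
        else:
            r = float(np.corrcoef(ya, yb)[0, 1])
        rows.append(
            {"lo_kb": lo, "hi_kb": hi, "n_pairs": int(sel.sum()), "pearson_r": r,
             "note": note}
        )
    return pd.DataFrame(rows)


def evaluate_bin_widths(
    joined: pd.DataFrame, widths=DEFAULT_WIDTHS, max_kb: float = 5000.0
) -> pd.DataFrame:
    """Coefficient of variation of per-bin pair counts for candidate widths.

    Every bin inside [0, max_kb) counts, including empty ones; CV uses the
    sample standard deviation.  Lower CV means the bins hold more even pair
    counts, hence more comparable correlation estimates.
    """
    if joined.empty:
        raise StructuralError("no joined pairs: cannot evaluate bin widths")
    d = joined["distance_kb"].to_numpy(dtype=float)
    d = d[d < max_kb]
    rows = []
    for w in widths:
        n_bins = int(np.ceil(max_kb / w))
        counts = np.bincount(np.floor(d / w).astype(int), minlength=n_bins)[:n_bins]
        mean = counts.mean()
        sd = counts.std(ddof=1) if len(counts) > 1 else np.nan
        rows.append(
            {
                "bin_width_kb": w,
                "n_bins": n_bins,
                "mean_count": float(mean),
                "sd_count": float(sd),
                "cv": float(sd / mean) if mean > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)
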