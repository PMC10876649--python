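"""Scalar quantifications and nonparametric two-group comparison.

Covers region-stratified cellularity (nucleus counts and densities),
percent-area immunopositivity normalized to nuclei counts (DAB-style
chromogenic quantification), and the two-sided Mann-Whitney U test used for
every group comparison.  The Mann-Whitney exact path enumerates all
C(n1+n2, n1) group assignments of the pooled (tie-aware) values and defines
the two-sided p as the probability mass of assignments at least as far from
the null mean n1*n2/2 as the observed U — the reflection rule, which remains
correct under asymmetric tie distributions.  Samples beyond pooled n = 20
fall back to the normal approximation with tie and continuity corrections.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from skimage.filters import threshold_otsu

from .datatypes import LINING, REGION_NAMES, SUBLINING, ChannelImage, NucleusSet, RegionMask
from .errors import EmptyROIError, TilecyteError

EXACT_MAX_POOLED_N = 20


def cellularity(nuclei: NucleusSet, region_mask: RegionMask) -> pd.DataFrame:
    """Nucleus counts, areas and densities per region and in total.

    A nucleus belongs to the region at the pixel containing its centroid.
    Areas are in mm² (pixel count × pixel_size² / 1e6 for µm pixels);
    density is cells/mm².  A region with zero area is reported with NaN
    density.
    """
    px = nuclei.pixels()
    if len(px):
        codes = region_mask.labels[px[:, 0], px[:, 1]]
    else:
        codes = np.empty(0, dtype=int)
    rows = []
    strata = [(REGION_NAMES[LINING], LINING), (REGION_NAMES[SUBLINING], SUBLINING)]
    for name, code in strata:
        count = int(np.count_nonzero(codes == code))
        area_px = int(np.count_nonzero(region_mask.labels == code))
        area_mm2 = area_px * region_mask.pixel_size**2 / 1e6
        assert not (area_px == 0 and count > 0), "nuclei in a zero-area region"
        rows.append(
            {
                "region": name,
                "count": count,
                "area_mm2": area_mm2,
                "density_per_mm2": count / area_mm2 if area_mm2 > 0 else np.nan,
            }
        )
    total_area = sum(r["area_mm2"] for r in rows)
    rows.append(
        {
            "region": "total",
            "count": len(nuclei),
            "area_mm2": total_area,
            "density_per_mm2": len(nuclei) / total_area if total_area > 0 else np.nan,
        }
    )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ImmunopositivityResult:
    """Percent-area immunopositivity for one field of view."""

    percent_area_positive: float
    nuclei_count: int
    positive_area_per_nucleus: float | None  # µm²/nucleus; None when no nuclei
    threshold: float


def percent_area_positive(
    stain: ChannelImage,
    roi_mask: RegionMask,
    threshold: float | None = None,
    nuclei_count: int = 0,
) -> ImmunopositivityResult:
    """Fraction of ROI pixels above an intensity threshold.

    ``threshold=None`` selects Otsu's threshold over the ROI pixels.  The
    positive area is additionally normalized to the nuclei count of the
    field (µm²/nucleus) when that count is nonzero.
    """
    roi = roi_mask.roi
    if not roi.any():
        raise EmptyROIError("empty ROI: percent-area undefined")
    if stain.shape != roi.shape:
        raise ValueError("stain channel and ROI mask differ in shape")
    if nuclei_count < 0:
        raise ValueError("nuclei_count must be >= 0")
    vals = stain.values[roi]
    if threshold is None:
        if vals.max() == vals.min():
            raise TilecyteError("constant stain channel: supply an explicit threshold")
        threshold = float(threshold_otsu(vals))
    n_pos = int(np.count_nonzero(vals > threshold))
    percent = 100.0 * n_pos / vals.size
    per_nucleus = (
        n_pos * roi_mask.pixel_size**2 / nuclei_count if nuclei_count > 0 else None
    )
    return ImmunopositivityResult(percent, nuclei_count, per_nucleus, float(threshold))


@dataclass(frozen=True)
class GroupComparisonResult:
    """Two-sided Mann-Whitney comparison of one endpoint."""

    n1: int
    n2: int
    u_statistic: float
    p_value: float
    method: str  # "exact" | "normal_approximation"
    median_a: float
    median_b: float


def _u_from_ranks(rank_sum_a: float, n1: int) -> float:
    return rank_sum_a - n1 * (n1 + 1) / 2.0


def mann_whitney_u(a, b) -> GroupComparisonResult:
    """Two-sided Mann-Whitney U test.

    U (for sample ``a``) counts pairs with a_i > b_j, ties counting one
    half.  For pooled n ≤ 20 the two-sided p is exact: the fraction of all
    C(n1+n2, n1) assignments of the pooled values whose |U − n1·n2/2| is at
    least the observed deviation.  Larger samples use the normal
    approximation with tie correction and a 0.5 continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise TilecyteError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    u_obs = _u_from_ranks(ranks[:n1].sum(), n1)
    mu = n1 * n2 / 2.0

    if n1 + n2 <= EXACT_MAX_POOLED_N:
        idx = np.array(
            list(combinations(range(n1 + n2), n1)), dtype=np.intp
        )  # C(20,10) = 184756 at worst
        u_all = ranks[idx].sum(axis=1) - n1 * (n1 + 1) / 2.0
        obs_dev = abs(u_obs - mu)
        p = float(np.mean(np.abs(u_all - mu) >= obs_dev - 1e-12))
        method = "exact"
    else:
        n = n1 + n2
        _, t = np.unique(pooled, return_counts=True)
        tie_term = (t**3 - t).sum() / (n * (n - 1))
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if sigma2 <= 0:
            p = 1.0
        else:
            z = max(abs(u_obs - mu) - 0.5, 0.0) / np.sqrt(sigma2)
            p = min(1.0, 2.0 * float(norm.sf(z)))
        method = "normal_approximation"
    return GroupComparisonResult(
        n1=n1,
        n2=n2,
        u_statistic=float(u_obs),
        p_value=p,
        method=method,
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
    )


def compare_compositions(
    composition: pd.DataFrame,
    groups: tuple[str, str] | None = None,
    value_col: str = "proportion_pct",
    extra_endpoints: dict[str, tuple[list, list]] | None = None,
    adjust: bool = False,
) -> pd.DataFrame:
    """Mann-Whitney comparison of every (region, type) composition endpoint.

    ``composition`` needs columns ``sample, group, region, type`` and
    ``value_col`` with one row per sample × region × type.  ``groups``
    selects and orders the two groups (default: sorted unique; first group
    plays the role of sample ``a``).  ``extra_endpoints`` adds scalar
    endpoints (e.g. cellularity, percent-area) as name -> (values_a,
    values_b).  Unadjusted p-values are the primary output; ``adjust=True``
    appends a Benjamini-Hochberg column.
    """
    if groups is None:
        uniq = sorted(composition["group"].unique())
        if len(uniq) != 2:
            raise TilecyteError(f"need exactly two groups, found {uniq}")
        groups = (uniq[0], uniq[1])
    g1, g2 = groups

    rows = []
    for (region, ctype), grp in composition.groupby(["region", "type"], sort=True):
        a = grp.loc[grp["group"] == g1, value_col].to_numpy()
        b = grp.loc[grp["group"] == g2, value_col].to_numpy()
        if a.size == 0 or b.size == 0:
            raise TilecyteError(
                f"endpoint ({region}, {ctype}) lacks samples in one group"
            )
        res = mann_whitney_u(a, b)
        rows.append(
            {
                "endpoint": "composition",
                "region": region,
                "type": ctype,
                "n1": res.n1,
                "n2": res.n2,
                "U": res.u_statistic,
                "p": res.p_value,
                "method": res.method,
                "median_1": res.median_a,
                "median_2": res.median_b,
            }
        )
    for name, (a, b) in (extra_endpoints or {}).items():
        res = mann_whitney_u(a, b)
        rows.append(
            {
                "endpoint": name,
                "region": "",
                "type": "",
                "n1": res.n1,
                "n2": res.n2,
                "U": res.u_statistic,
                "p": res.p_value,
                "method": res.method,
                "median_1": res.median_a,
                "median_2": res.median_b,
            }
        )
    out = pd.DataFrame(rows)
    if adjust and len(out):
        from statsmodels.stats.multitest import multipletests

        out["p_bh"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


__all__ = [
    "cellularity",
    "percent_area_positive",
    "ImmunopositivityResult",
    "mann_whitney_u",
    "GroupComparisonResult",
    "compare_compositions",
    "EXACT_MAX_POOLED_N",
]
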