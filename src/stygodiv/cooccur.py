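"""Exact species-ASV co-occurrence tests and diversity correlations.

The co-occurrence test is the probabilistic (hypergeometric) model: given a
species occupying ``n1`` of ``N`` sites and an ASV occupying ``n2``, the
number of shared sites under random, independent placement follows the
hypergeometric distribution

    P(J = j) = C(n1, j) C(N - n1, n2 - j) / C(N, n2)

over the feasible range ``max(0, n1 + n2 - N) <= j <= min(n1, n2)``. The
one-tailed probabilities ``p_gt = P(J >= j_obs)`` and ``p_lt = P(J <= j_obs)``
classify a pair as a positive co-occurrence (observed together at more sites
than expected by chance, ``p_gt < alpha``) or a negative one (``p_lt <
alpha``). The test conditions on both margins, so it is exact and conservative
on the discrete support.

``pearson_log_correlation`` supports the effort-corrected diversity
comparisons: Pearson's r on (optionally log-transformed) per-site values, with
the two-sided p-value from the t statistic ``r sqrt((n-2) / (1-r^2))`` on
``n - 2`` degrees of freedom and the least-squares line on the transformed
scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .detection import DetectionMatrix
from .io_formats import ReadCountTable, ValidationError

__all__ = [
    "CooccurrenceTest",
    "CorrelationResult",
    "cooccur_exact_test",
    "asv_site_matrix",
    "screen_cooccurrences",
    "pearson_log_correlation",
    "richness_summary",
]


@dataclass(frozen=True)
class CooccurrenceTest:
    species_id: str
    asv_id: str
    N: int
    n1: int
    n2: int
    j_obs: int
    expected: float
    p_lt: float
    p_gt: float
    p_obs: float  # P(J = j_obs)
    classification: str  # positive | negative | none
    degenerate: bool = False

    def __post_init__(self) -> None:
        lo = max(0, self.n1 + self.n2 - self.N)
        hi = min(self.n1, self.n2)
        if not (lo <= self.j_obs <= hi):
            raise ValidationError(
                f"observed overlap {self.j_obs} outside feasible range "
                f"[{lo}, {hi}] for N={self.N}, n1={self.n1}, n2={self.n2}"
            )


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    slope: float
    intercept: float
    n: int
    transform_x: str
    transform_y: str


def cooccur_exact_test(
    vec_species: Sequence[bool] | np.ndarray,
    vec_asv: Sequence[bool] | np.ndarray,
    alpha: float = 0.05,
    species_id: str = "",
    asv_id: str = "",
) -> CooccurrenceTest:
    """Exact hypergeometric co-occurrence test for one species-ASV pair.

    Degenerate margins (a taxon present everywhere or nowhere) carry no
    information about association; such pairs are flagged and classified
    ``none``.
    """
    a = np.asarray(vec_species, dtype=bool)
    b = np.asarray(vec_asv, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("presence vectors must be 1-D and of equal length")
    N = int(a.size)
    if N < 2:
        raise ValidationError("need at least two sites")
    n1 = int(a.sum())
    n2 = int(b.sum())
    j_obs = int((a & b).sum())
    dist = stats.hypergeom(N, n1, n2)
    p_obs = float(dist.pmf(j_obs))
    p_gt = float(dist.sf(j_obs - 1))  # P(J >= j_obs)
    p_lt = float(dist.cdf(j_obs))  # P(J <= j_obs)
    degenerate = n1 in (0, N) or n2 in (0, N)
    if degenerate:
        classification = "none"
    elif p_gt < alpha:
        classification = "positive"
    elif p_lt < alpha:
        classification = "negative"
    else:
        classification = "none"
    return CooccurrenceTest(
        species_id=species_id,
        asv_id=asv_id,
        N=N,
        n1=n1,
        n2=n2,
        j_obs=j_obs,
        expected=n1 * n2 / N,
        p_lt=min(p_lt, 1.0),
        p_gt=min(p_gt, 1.0),
        p_obs=p_obs,
        classification=classification,
        degenerate=degenerate,
    )


def asv_site_matrix(table: ReadCountTable) -> pd.DataFrame:
    """Site x ASV presence: an ASV occupies a site iff it has at least one
    read in any used replicate of that site."""
    groups = table.site_groups
    sites = list(groups)
    data = {
        site: (table.counts[cols].sum(axis=1) > 0) for site, cols in groups.items()
    }
    return pd.DataFrame(data, index=table.counts.index, columns=sites).T


def screen_cooccurrences(
    species_mat: DetectionMatrix,
    asv_mat: pd.DataFrame,
    alpha: float = 0.05,
    min_asv_sites: int = 2,
    expected_min: float = 1.0,
    apply_expected_filter: bool = True,
) -> list[CooccurrenceTest]:
    """Test every (species, ASV) pair whose ASV occupies at least
    ``min_asv_sites`` sites.

    ``apply_expected_filter`` additionally skips pairs whose expected overlap
    ``n1 n2 / N`` falls below ``expected_min`` (the customary screen of
    probabilistic co-occurrence packages); switch it off to test everything.
    All species with at least one site are tested -- restricting the report to
    widespread species is a presentation choice, not a testing one.
    """
    if species_mat.present.size == 0 or asv_mat.size == 0:
        raise ValidationError("empty detection or ASV matrix")
    sites = list(species_mat.sites)
    if list(asv_mat.index) != sites:
        asv_mat = asv_mat.reindex(sites)
        if asv_mat.isna().any().any():
            raise ValidationError("ASV matrix does not cover the site universe")
    N = len(sites)
    out: list[CooccurrenceTest] = []
    asv_counts = asv_mat.sum(axis=0)
    for asv in asv_mat.columns:
        if asv_counts[asv] < min_asv_sites:
            continue
        b = asv_mat[asv].to_numpy(dtype=bool)
        for species in species_mat.species:
            a = species_mat.present[species].to_numpy(dtype=bool)
            n1 = int(a.sum())
            if n1 == 0:
                continue
            if apply_expected_filter and n1 * asv_counts[asv] / N < expected_min:
                continue
            out.append(
                cooccur_exact_test(
                    a, b, alpha=alpha, species_id=species, asv_id=asv
                )
            )
    return out


_TRANSFORMS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "identity": lambda x: x,
    "log": np.log,
    "log1p": np.log1p,
    "log10": np.log10,
}


def pearson_log_correlation(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    transform_x: str = "identity",
    transform_y: str = "identity",
) -> CorrelationResult:
    """Pearson correlation on transformed per-site values.

    Sites undefined under the chosen transform (log of a non-positive value)
    are dropped pairwise; at least three sites must remain. Zero variance in
    either variable is an error rather than a NaN.
    """
    for name in (transform_x, transform_y):
        if name not in _TRANSFORMS:
            raise ValidationError(
                f"unknown transform {name!r}; choose from {sorted(_TRANSFORMS)}"
            )
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValidationError("x and y must be 1-D and of equal length")
    with np.errstate(divide="ignore", invalid="ignore"):
        tx = _TRANSFORMS[transform_x](xv)
        ty = _TRANSFORMS[transform_y](yv)
    keep = np.isfinite(tx) & np.isfinite(ty)
    tx, ty = tx[keep], ty[keep]
    n = int(tx.size)
    if n < 3:
        raise ValidationError(f"only {n} defined points after transforms; need >= 3")
    if np.ptp(tx) == 0 or np.ptp(ty) == 0:
        raise ValidationError("zero variance in a transformed variable")
    r, p = stats.pearsonr(tx, ty)
    slope, intercept = np.polyfit(tx, ty, 1)
    return CorrelationResult(
        r=float(r),
        p_value=float(p),
        slope=float(slope),
        intercept=float(intercept),
        n=n,
        transform_x=transform_x,
        transform_y=transform_y,
    )


def richness_summary(
    detections: DetectionMatrix, table: ReadCountTable
) -> pd.DataFrame:
    """Per-site species richness, ASV richness (ASVs with >= 1 read at the
    site) and summed reads, with dataset-level mean/SD in ``DataFrame.attrs``.
    """
    groups = table.site_groups
    rows = []
    for site in detections.sites:
        cols = groups.get(site, [])
        if cols:
            site_counts = table.counts[cols].sum(axis=1)
            asv_richness = int((site_counts > 0).sum())
            read_total = int(site_counts.sum())
        else:
            asv_richness = 0
            read_total = 0
        rows.append(
            {
                "site_id": site,
                "species_richness": int(detections.present.loc[site].sum()),
                "asv_richness": asv_richness,
                "read_total": read_total,
            }
        )
    df = pd.DataFrame(rows).set_index("site_id")
    df.attrs["asv_richness_mean"] = float(df["asv_richness"].mean())
    df.attrs["asv_richness_sd"] = float(df["asv_richness"].std(ddof=1)) if len(df) > 1 else 0.0
    df.attrs["read_total_mean"] = float(df["read_total"].mean())
    df.attrs["read_total_sd"] = float(df["read_total"].std(ddof=1)) if len(df) > 1 else 0.0
    return df
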