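"""Compositional statistics for the three-part morphotype data.

Clump displacement volumes are turned into relative abundances (three-part
compositions), aggregated first by date and then by month, and mapped to
bivariate isometric log-ratio (ilr) coordinates so the non-independence of
the three proportions is respected.  Group differences between the two
sub-origins are tested with a PERMANOVA whose permutations respect the
sampling design: whole dates are reassigned between sub-origins and clumps
travel with their date (dates are the independent replicates).  Homogeneity
of multivariate dispersion is checked with a betadisper-style test
(distance to own-group centroid in principal-coordinate space, label
permutation).

The fixed ilr basis for composition p = (p1, p2, p3) over
(S. natans I, S. natans VIII, S. fluitans III) is

    z1 = (1/sqrt 2) ln(p1/p2),
    z2 = sqrt(2/3) ln( sqrt(p1 p2) / p3 ).

Zeros are first replaced multiplicatively (default 0.5% of unit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .permanova import PermanovaResult, permanova_oneway, squared_euclidean

__all__ = [
    "to_relative_abundance",
    "compositions_from_samples",
    "aggregate_date_then_month",
    "ilr_bivariate",
    "ilr_inverse",
    "alr_bivariate",
    "permanova_nested",
    "dispersion_homogeneity",
    "DispersionResult",
    "ternary_coords",
]

_MORPHO_COLS = ["vol_sni_ml", "vol_snviii_ml", "vol_sfiii_ml"]
_PROP_COLS = ["p_sni", "p_snviii", "p_sfiii"]


def to_relative_abundance(volumes) -> np.ndarray:
    """Proportions = volumes / total volume; accepts a MorphotypeSample or array.

    Raises ``ValueError`` when the total volume is zero.
    """
    v = volumes.volumes() if hasattr(volumes, "volumes") else np.asarray(volumes, dtype=float)
    if v.ndim == 1:
        total = v.sum()
        if total <= 0:
            raise ValueError("composition undefined: total volume is zero")
        return v / total
    totals = v.sum(axis=1, keepdims=True)
    if (totals <= 0).any():
        raise ValueError("composition undefined: a sample has zero total volume")
    return v / totals


def compositions_from_samples(samples) -> pd.DataFrame:
    """Table of per-clump compositions with date and clump id columns."""
    from .synthetic_data import samples_to_dataframe  # local import avoids a cycle

    df = samples if isinstance(samples, pd.DataFrame) else samples_to_dataframe(samples)
    props = to_relative_abundance(df[_MORPHO_COLS].to_numpy(float))
    out = df[["date", "clump_id"]].copy()
    out[_PROP_COLS] = props
    return out


def aggregate_date_then_month(samples) -> pd.DataFrame:
    """Two-stage arithmetic mean of compositions: within date, then within month.

    Every date carries equal weight in its month regardless of how many
    clumps it contributed; the monthly means are renormalized to sum to 1.
    Returns a table indexed by calendar month period.
    """
    comp = compositions_from_samples(samples)
    comp["date"] = pd.to_datetime(comp["date"])
    by_date = comp.groupby("date")[_PROP_COLS].mean()
    by_month = by_date.groupby(by_date.index.to_period("M")).mean()
    return by_month.div(by_month.sum(axis=1), axis=0)


def _replace_zeros(p: np.ndarray, delta: float) -> np.ndarray:
    """Multiplicative zero replacement: zeros -> delta, the rest rescaled."""
    p = np.atleast_2d(np.asarray(p, dtype=float))
    zeros = p <= 0
    k = zeros.sum(axis=1, keepdims=True)
    out = np.where(zeros, delta, p * (1.0 - k * delta))
    return out


def ilr_bivariate(comp, zero_replacement: float = 0.005) -> np.ndarray:
    """Isometric log-ratio coordinates of three-part compositions.

    Returns an (n, 2) array (or length-2 vector for a single composition)
    in the fixed basis documented at module level.
    """
    p = np.asarray(comp, dtype=float)
    single = p.ndim == 1
    p = _replace_zeros(p, zero_replacement)
    z1 = np.log(p[:, 0] / p[:, 1]) / np.sqrt(2.0)
    z2 = np.sqrt(2.0 / 3.0) * np.log(np.sqrt(p[:, 0] * p[:, 1]) / p[:, 2])
    z = np.column_stack([z1, z2])
    return z[0] if single else z


def ilr_inverse(coords) -> np.ndarray:
    """Composition corresponding to ilr coordinates (inverse of :func:`ilr_bivariate`)."""
    z = np.atleast_2d(np.asarray(coords, dtype=float))
    # log-contrasts: l1 - l2 = sqrt(2) z1 ; (l1 + l2)/2 - l3 = sqrt(3/2) z2
    l3 = np.zeros(len(z))
    half_sum = np.sqrt(1.5) * z[:, 1]
    diff = np.sqrt(2.0) * z[:, 0]
    l1 = half_sum + diff / 2.0
    l2 = half_sum - diff / 2.0
    logs = np.column_stack([l1, l2, l3])
    p = np.exp(logs - logs.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    return p[0] if np.asarray(coords).ndim == 1 else p


def alr_bivariate(comp, zero_replacement: float = 0.005) -> np.ndarray:
    """Additive log-ratio alternative: (ln p1/p3, ln p2/p3)."""
    p = np.asarray(comp, dtype=float)
    single = p.ndim == 1
    p = _replace_zeros(p, zero_replacement)
    z = np.column_stack([np.log(p[:, 0] / p[:, 2]), np.log(p[:, 1] / p[:, 2])])
    return z[0] if single else z


def permanova_nested(
    response: np.ndarray,
    suborigin_of_sample,
    date_of_sample,
    n_perm: int = 9999,
    seed: int = 0,
    *,
    exhaustive: bool = False,
    scheme: str = "nested",
) -> PermanovaResult:
    """PERMANOVA of the bivariate response on sub-origin with date-nested permutations.

    ``response`` is the (n, 2) ilr coordinate matrix (Euclidean distances);
    ``date_of_sample`` assigns each clump to its collection date and
    ``suborigin_of_sample`` each clump to the sub-origin of its date.
    Permutations reassign whole dates between sub-origins preserving group
    sizes (``scheme='free'`` gives ordinary sample-level permutation).
    """
    d2 = squared_euclidean(np.asarray(response, dtype=float))
    dates = np.asarray(date_of_sample) if scheme == "nested" else None
    return permanova_oneway(
        d2,
        np.asarray(suborigin_of_sample),
        date_of_sample=dates,
        n_perm=n_perm,
        seed=seed,
        exhaustive=exhaustive,
        factor_name="suborigin",
    )


@dataclass(frozen=True)
class DispersionResult:
    """Betadisper-style homogeneity of multivariate dispersion."""

    group_mean_distance: dict
    f_statistic: float
    p_value: float
    n_perm: int


def _pcoa_distances_to_centroid(d2: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Distance of each point to its own group centroid in PCoA space.

    Follows the betadisper construction: principal-coordinate embedding of
    the distance matrix keeping negative-eigenvalue axes as imaginary parts
    (their squared distances subtract).  For Euclidean input this equals the
    plain distance to the group centroid.
    """
    n = len(labels)
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j
    vals, vecs = linalg.eigh(g)
    pos = vals > 1e-10
    neg = vals < -1e-10
    coords_pos = vecs[:, pos] * np.sqrt(vals[pos])
    coords_neg = vecs[:, neg] * np.sqrt(-vals[neg])
    dist2 = np.zeros(n)
    for grp in np.unique(labels):
        m = labels == grp
        dp = coords_pos[m] - coords_pos[m].mean(axis=0)
        dn = coords_neg[m] - coords_neg[m].mean(axis=0) if neg.any() else 0.0
        d2g = (dp**2).sum(axis=1) - ((dn**2).sum(axis=1) if neg.any() else 0.0)
        dist2[m] = np.maximum(d2g, 0.0)
    return np.sqrt(dist2)


def _anova_f(x: np.ndarray, labels: np.ndarray) -> float:
    groups = np.unique(labels)
    n, a = len(x), len(groups)
    grand = x.mean()
    ssb = sum(len(x[labels == g]) * (x[labels == g].mean() - grand) ** 2 for g in groups)
    ssw = sum(((x[labels == g] - x[labels == g].mean()) ** 2).sum() for g in groups)
    if ssw <= 0:
        return 0.0 if ssb <= 0 else np.inf
    return (ssb / (a - 1)) / (ssw / (n - a))


def dispersion_homogeneity(response: np.ndarray, groups, n_perm: int = 999, seed: int = 0) -> DispersionResult:
    """Test equality of multivariate dispersion between groups.

    Distances to own-group centroids are computed once; the permutation test
    shuffles group labels over those fixed distances (as in vegan's
    ``permutest.betadisper``).
    """
    labels = np.asarray(groups)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 groups with >= 2 members each")
    d2 = squared_euclidean(np.asarray(response, dtype=float))
    dist = _pcoa_distances_to_centroid(d2, labels)
    f_obs = _anova_f(dist, labels)
    rng = np.random.default_rng(np.random.Philox(key=seed))
    count = 0
    for _ in range(n_perm):
        if _anova_f(dist, rng.permutation(labels)) >= f_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return DispersionResult(
        group_mean_distance={str(g): float(dist[labels == g].mean()) for g in uniq},
        f_statistic=f_obs,
        p_value=p,
        n_perm=n_perm,
    )


def ternary_coords(comp) -> np.ndarray:
    """Barycentric -> Cartesian ternary plot coordinates.

    Vertex order (SNI, SNVIII, SFIII): the SNI vertex maps to (0, 0), SNVIII
    to (1, 0) and SFIII to (1/2, sqrt(3)/2) — an equilateral triangle of
    side 1.  x = p2 + p3/2, y = (sqrt 3 / 2) p3.
    """
    p = np.asarray(comp, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    xy = np.column_stack([p[:, 1] + p[:, 2] / 2.0, np.sqrt(3.0) / 2.0 * p[:, 2]])
    return xy[0] if single else xy


def ternary_plot(compositions, labels=None, ax=None, **scatter_kw):
    """Scatter three-part compositions inside the unit ternary triangle."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4.6))
    tri = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2], [0, 0]])
    ax.plot(tri[:, 0], tri[:, 1], color="k", lw=1)
    xy = np.atleast_2d(ternary_coords(compositions))
    if labels is None:
        ax.scatter(xy[:, 0], xy[:, 1], **scatter_kw)
    else:
        labels = np.asarray(labels)
        for g in np.unique(labels):
            m = labels == g
            ax.scatter(xy[m, 0], xy[m, 1], label=str(g), **scatter_kw)
        ax.legend(frameon=False, fontsize=8)
    for txt, pos in zip(("SNI", "SNVIII", "SFIII"), tri[:3]):
        ax.annotate(txt, pos, textcoords="offset points", xytext=(0, -12 if pos[1] == 0 else 6), ha="center")
    ax.set_aspect("equal")
    ax.axis("off")
    return ax
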