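"""Distance-based permutational MANOVA engines.

Two engines are provided, both authored here rather than delegated, because
the permutation schemes are the scientifically load-bearing part:

* a one-way engine on a squared-distance matrix with either a *nested*
  scheme — whole dates are reassigned between groups and samples move with
  their date, so dates (not samples) are the independent replicates — or
  free sample-level permutation;
* a sequential (Type I) multi-factor engine on Euclidean response
  coordinates with free row permutation, used for the two-factor
  environmental test.

For Euclidean distances the coordinate formulation is algebraically
identical to McArdle–Anderson partitioning of the Gower-centred distance
matrix; the one-way engine works on arbitrary squared distances.
P-values use the add-one rule p = (#{F_perm >= F_obs} + 1) / (n_perm + 1);
exhaustive enumeration over all distinct date-label assignments is used when
requested (p is then the exact proportion over all assignments).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

__all__ = [
    "PermanovaTerm",
    "PermanovaResult",
    "squared_euclidean",
    "pseudo_f_oneway",
    "permanova_oneway",
    "permanova_factorial",
]


@dataclass(frozen=True)
class PermanovaTerm:
    term: str
    df: int
    ss: float
    pseudo_f: float | None
    p_value: float | None
    rank: int | None = None  # #permuted statistics >= observed


@dataclass(frozen=True)
class PermanovaResult:
    """Partitioned sums of squares, pseudo-F per term, and permutation p-values."""

    terms: tuple
    residual_df: int
    residual_ss: float
    total_ss: float
    n_obs: int
    n_perm: int
    scheme: str

    def __post_init__(self) -> None:
        df_sum = sum(t.df for t in self.terms) + self.residual_df
        if df_sum != self.n_obs - 1:
            raise ValueError(f"degrees of freedom {df_sum} != n - 1 = {self.n_obs - 1}")

    def term(self, name: str) -> PermanovaTerm:
        for t in self.terms:
            if t.term == name:
                return t
        raise KeyError(name)

    @property
    def pseudo_f(self) -> float:
        return self.terms[0].pseudo_f

    @property
    def p_value(self) -> float:
        return self.terms[0].p_value

    def to_dict(self) -> dict:
        return {
            "terms": [vars(t) for t in self.terms],
            "residual": {"df": self.residual_df, "ss": self.residual_ss},
            "total_ss": self.total_ss,
            "n_obs": self.n_obs,
            "n_perm": self.n_perm,
            "scheme": self.scheme,
        }


def squared_euclidean(response: np.ndarray) -> np.ndarray:
    """Squared Euclidean distance matrix of row vectors."""
    y = np.asarray(response, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    sq = (y**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * y @ y.T
    np.fill_diagonal(d2, 0.0)
    return np.maximum(d2, 0.0)


def _within_ss(d2: np.ndarray, membership: np.ndarray) -> np.ndarray:
    """Within-group SS for a stack of boolean membership matrices (n_perm, n)."""
    m = membership.astype(float)
    n_g = m.sum(axis=1)
    pair_sums = np.einsum("pi,pi->p", m @ d2, m)
    return pair_sums / (2.0 * np.maximum(n_g, 1.0))


def pseudo_f_oneway(d2: np.ndarray, labels: np.ndarray):
    """One-way pseudo-F from a squared-distance matrix.

    Returns (F, ss_between, ss_within, df_between, df_within); F is 0 when
    there is no between-group variation.
    """
    labels = np.asarray(labels)
    n = len(labels)
    groups = np.unique(labels)
    a = len(groups)
    if a < 2:
        raise ValueError("need at least two groups")
    ss_total = d2.sum() / (2.0 * n)
    ss_within = sum(float(_within_ss(d2, (labels == g)[None, :])[0]) for g in groups)
    ss_between = max(ss_total - ss_within, 0.0)
    df_b, df_w = a - 1, n - a
    if ss_within <= 0:
        f = 0.0 if ss_between <= 0 else np.inf
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
    return f, ss_between, ss_within, df_b, df_w


def _sample_membership(date_labels: np.ndarray, incidence: np.ndarray, group) -> np.ndarray:
    """(n_perm, n_samples) membership from (n_perm, n_dates) date labels."""
    return (date_labels == group).astype(float) @ incidence > 0.5


def permanova_oneway(
    d2: np.ndarray,
    group_of_sample: np.ndarray,
    *,
    date_of_sample: np.ndarray | None = None,
    n_perm: int = 9999,
    seed: int = 0,
    exhaustive: bool = False,
    factor_name: str = "group",
) -> PermanovaResult:
    """One-way PERMANOVA with nested (date-level) or free permutations.

    When ``date_of_sample`` is given, permutations reassign whole dates
    between groups preserving the observed number of dates per group
    (samples travel with their date); otherwise sample labels are permuted
    freely.  ``exhaustive=True`` enumerates all distinct date-to-group
    assignments (two groups only) instead of Monte-Carlo sampling.
    """
    group_of_sample = np.asarray(group_of_sample)
    n = len(group_of_sample)
    if d2.shape != (n, n):
        raise ValueError("distance matrix does not match the number of samples")

    if date_of_sample is None:
        date_of_sample = np.arange(n)
        scheme = "free"
    else:
        scheme = "nested(dates)"
    date_of_sample = np.asarray(date_of_sample)
    dates, date_idx = np.unique(date_of_sample, return_inverse=True)
    n_dates = len(dates)
    incidence = np.zeros((n_dates, n))
    incidence[date_idx, np.arange(n)] = 1.0

    # group of each date; verify nesting (one group per date)
    date_group = np.empty(n_dates, dtype=object)
    for k in range(n_dates):
        g = np.unique(group_of_sample[date_idx == k])
        if len(g) != 1:
            raise ValueError("samples from one date must share a group (nesting violated)")
        date_group[k] = g[0]
    groups = np.unique(group_of_sample)
    if any((date_group == g).sum() < 2 for g in groups) and scheme.startswith("nested"):
        raise ValueError("each sub-origin needs at least two dates as replicates")

    f_obs, ss_b, ss_w, df_b, df_w = pseudo_f_oneway(d2, group_of_sample)
    ss_total = d2.sum() / (2.0 * n)

    if exhaustive:
        if len(groups) != 2:
            raise ValueError("exhaustive enumeration implemented for two groups")
        n_a = int((date_group == groups[0]).sum())
        assigns = list(combinations(range(n_dates), n_a))
        perm_labels = np.full((len(assigns), n_dates), groups[1], dtype=object)
        for r, comb in enumerate(assigns):
            perm_labels[r, list(comb)] = groups[0]
        n_perm_eff = len(assigns)
    else:
        rng = np.random.default_rng(np.random.Philox(key=seed))
        perm_labels = np.stack([rng.permutation(date_group) for _ in range(n_perm)])
        n_perm_eff = n_perm

    ssw_perm = np.zeros(len(perm_labels))
    for g in groups:
        ssw_perm += _within_ss(d2, _sample_membership(perm_labels, incidence, g))
    ssb_perm = np.maximum(ss_total - ssw_perm, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = (ssb_perm / df_b) / (ssw_perm / df_w)
    f_perm = np.where(ssw_perm <= 0, np.where(ssb_perm <= 0, 0.0, np.inf), f_perm)

    rank = int(np.sum(f_perm >= f_obs - 1e-12))
    if exhaustive:
        p = rank / n_perm_eff  # observed assignment is one of the enumerated ones
    else:
        p = (rank + 1) / (n_perm_eff + 1)

    term = PermanovaTerm(factor_name, df_b, ss_b, f_obs, p, rank)
    return PermanovaResult(
        terms=(term,),
        residual_df=df_w,
        residual_ss=ss_w,
        total_ss=ss_total,
        n_obs=n,
        n_perm=n_perm_eff,
        scheme=("exhaustive-" if exhaustive else "") + scheme,
    )


def _hat(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(x)
    keep = np.abs(np.diag(r)) > 1e-10 * max(np.abs(np.diag(r)).max(), 1e-300)
    q = q[:, keep]
    return q @ q.T


def _dummies(values: np.ndarray) -> np.ndarray:
    levels = np.unique(values)
    return (values[:, None] == levels[None, 1:]).astype(float)  # drop first level


def permanova_factorial(
    response: np.ndarray,
    factors: dict,
    *,
    interaction: bool = True,
    n_perm: int = 9999,
    seed: int = 0,
) -> PermanovaResult:
    """Sequential (Type I) PERMANOVA on Euclidean response coordinates.

    Terms enter in the order of ``factors`` followed by their pairwise
    interaction; each term's SS is the increment in projected SS over the
    previous model.  Significance per term by free permutation of the
    response rows (add-one rule).
    """
    y = np.asarray(response, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n = y.shape[0]
    y = y - y.mean(axis=0)

    names = list(factors)
    blocks = [_dummies(np.asarray(factors[k])) for k in names]
    if interaction:
        if len(names) != 2:
            raise ValueError("interaction requires exactly two factors")
        inter = np.einsum("ni,nj->nij", blocks[0], blocks[1]).reshape(n, -1)
        blocks.append(inter)
        names.append(f"{names[0]}:{names[1]}")

    ones = np.ones((n, 1))
    hats = [_hat(ones)]
    x = ones
    for b in blocks:
        x = np.column_stack([x, b])
        hats.append(_hat(x))
    q_terms = [hats[k + 1] - hats[k] for k in range(len(blocks))]
    q_resid = np.eye(n) - hats[-1]
    dfs = [int(round(np.trace(q))) for q in q_terms]
    df_res = int(round(np.trace(q_resid)))
    if df_res <= 0:
        raise ValueError("model saturates the data; no residual degrees of freedom")

    def term_ss(yy):
        return [float((q @ yy) .ravel() @ (q @ yy).ravel()) for q in q_terms + [q_resid]]

    *ss_obs, ss_res = term_ss(y)
    f_obs = [(ss / df) / (ss_res / df_res) for ss, df in zip(ss_obs, dfs)]

    rng = np.random.default_rng(np.random.Philox(key=seed))
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    yp = y[perms]  # (n_perm, n, k)
    flat = yp.transpose(1, 0, 2).reshape(n, -1)  # (n, n_perm*k)

    def batched_ss(q):
        proj = q @ flat
        return (proj**2).reshape(n, n_perm, y.shape[1]).sum(axis=(0, 2))

    ss_perm = [batched_ss(q) for q in q_terms]
    ss_res_perm = batched_ss(q_resid)

    terms = []
    for name, df, ss, f, ssp in zip(names, dfs, ss_obs, f_obs, ss_perm):
        with np.errstate(divide="ignore", invalid="ignore"):
            f_perm = (ssp / df) / (ss_res_perm / df_res)
        rank = int(np.sum(f_perm >= f - 1e-12))
        p = (rank + 1) / (n_perm + 1)
        terms.append(PermanovaTerm(name, df, ss, f, p, rank))

    return PermanovaResult(
        terms=tuple(terms),
        residual_df=df_res,
        residual_ss=ss_res,
        total_ss=float((y**2).sum()),
        n_obs=n,
        n_perm=n_perm,
        scheme="free-rows-sequential",
    )
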