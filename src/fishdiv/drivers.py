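"""Mantel and partial Mantel permutation tests against environmental drivers.

Driver distance matrices are absolute per-site attribute differences
|x_i - x_j|; community matrices are the beta-diversity component matrices.
The Mantel statistic is the Spearman correlation between the lower-triangle
vectors of two matched distance matrices; its null distribution comes from
jointly permuting rows and columns (site labels) of one matrix.  The
one-tailed p-value uses the add-one rule

    p = (1 + #{permuted r >= observed r}) / (1 + n_perm)

so p is never zero and never below 1/(n_perm + 1).  The partial test
computes the rank-based first-order partial correlation

    r_ab.c = (r_ab - r_ac r_bc) / sqrt((1 - r_ac^2)(1 - r_bc^2))

and permutes the first matrix, recomputing the partial statistic each time.
Sites with a missing attribute are dropped per driver (pairwise-complete
testing), with the exclusion logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .checklist import SiteAttributes
from .errors import ValidationError

logger = logging.getLogger(__name__)

_EPS = 1e-12


def attribute_distance(attrs: SiteAttributes, attribute: str) -> pd.DataFrame:
    """|x_i - x_j| distance matrix for one driver; missing-value sites dropped."""
    if attribute not in attrs.frame.columns:
        raise ValidationError(f"unknown attribute {attribute!r}")
    col = attrs.frame[attribute]
    missing = col[col.isna()].index.tolist()
    if missing:
        logger.warning("attribute %r: dropping site(s) with missing values: %s",
                       attribute, missing)
    col = col.dropna()
    if len(col) < 2:
        raise ValidationError(f"attribute {attribute!r} has <2 sites with values")
    x = col.to_numpy(dtype=float)
    d = np.abs(x[:, None] - x[None, :])
    return pd.DataFrame(d, index=col.index, columns=col.index)


@dataclass(frozen=True)
class MantelResult:
    r: float
    p_value: float
    n_perm: int
    n_sites: int
    method: str = "spearman"
    alternative: str = "greater"
    partial_controlled: str | None = None
    seed: int | None = None


def _align(*mats: pd.DataFrame) -> list[np.ndarray]:
    common = mats[0].index
    for m in mats[1:]:
        common = common.intersection(m.index)
    if len(common) == 0:
        raise ValidationError("no common sites between distance matrices")
    dropped = set().union(*(set(m.index) for m in mats)) - set(common)
    if dropped:
        logger.warning("Mantel: dropping unmatched site(s): %s", sorted(dropped))
    return [m.loc[common, common].to_numpy(dtype=float) for m in mats], list(common)


def _check_square(m: np.ndarray) -> None:
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(m, m.T):
        raise ValidationError("distance matrix must be symmetric")


def _perm_triangles(m: np.ndarray, perms: np.ndarray, iu) -> np.ndarray:
    """Lower/upper-triangle vectors of m under each row+column permutation."""
    return m[perms[:, iu[0]], perms[:, iu[1]]]


def _row_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of x with the vector y."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    num = xc @ yc
    den = np.sqrt((xc ** 2).sum(axis=1) * (yc ** 2).sum())
    out = np.zeros(x.shape[0])
    np.divide(num, den, out=out, where=den > 0)
    return out


def mantel(m_a: pd.DataFrame, m_b: pd.DataFrame, n_perm: int = 9999,
           seed: int = 0, alternative: str = "greater") -> MantelResult:
    """Spearman Mantel test, permuting the site labels of ``m_b``."""
    (a, b), sites = _align(m_a, m_b)
    _check_square(a)
    _check_square(b)
    n = len(sites)
    if n < 4:
        raise ValidationError("Mantel test needs at least 4 matched sites")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    iu = np.triu_indices(n, k=1)
    ra = rankdata(a[iu])
    rb = rankdata(b[iu])
    r_obs = float(_row_pearson(rb[None, :], ra)[0])

    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)
    perm_vals = rankdata(_perm_triangles(b, perms, iu), axis=1)
    r_perm = _row_pearson(perm_vals, ra)
    p = _perm_pvalue(r_obs, r_perm, alternative)
    return MantelResult(r=r_obs, p_value=p, n_perm=n_perm, n_sites=n,
                        alternative=alternative, seed=seed)


def _perm_pvalue(r_obs: float, r_perm: np.ndarray, alternative: str) -> float:
    if alternative == "greater":
        k = int((r_perm >= r_obs - _EPS).sum())
    elif alternative == "less":
        k = int((r_perm <= r_obs + _EPS).sum())
    else:
        k = int((np.abs(r_perm) >= abs(r_obs) - _EPS).sum())
    return (1 + k) / (1 + len(r_perm))


def _partial_r(r_ab: np.ndarray, r_ac: np.ndarray, r_bc: float) -> np.ndarray:
    num = r_ab - r_ac * r_bc
    den = np.sqrt(np.maximum((1 - r_ac ** 2) * (1 - r_bc ** 2), 0.0))
    out = np.zeros_like(np.asarray(r_ab, dtype=float))
    ok = den > _EPS
    np.divide(num, den, out=out, where=ok)
    bad = ~ok & (np.abs(num) > 1e-8)
    if np.any(bad):
        raise ValidationError(
            "degenerate control: a control matrix is perfectly correlated "
            "with an input and does not fully explain it"
        )
    return out


def partial_mantel(m_a: pd.DataFrame, m_b: pd.DataFrame, m_c: pd.DataFrame,
                   n_perm: int = 9999, seed: int = 0,
                   alternative: str = "greater",
                   controlled_name: str | None = None) -> MantelResult:
    """Partial Mantel r_ab.c with permutation of ``m_a``'s site labels.

    When the control is identical to one of the inputs the partial
    correlation is the 0/0 form of a fully explained association and is
    returned as 0; a perfectly correlated control that leaves signal
    unexplained raises instead.
    """
    (a, b, c), sites = _align(m_a, m_b, m_c)
    for m in (a, b, c):
        _check_square(m)
    n = len(sites)
    if n < 5:
        raise ValidationError("partial Mantel needs at least 5 matched sites")
    iu = np.triu_indices(n, k=1)
    ra = rankdata(a[iu])
    rb = rankdata(b[iu])
    rc = rankdata(c[iu])
    r_ab = float(_row_pearson(ra[None, :], rb)[0])
    r_ac = float(_row_pearson(ra[None, :], rc)[0])
    r_bc = float(_row_pearson(rb[None, :], rc)[0])
    r_obs = float(_partial_r(np.array([r_ab]), np.array([r_ac]), r_bc)[0])

    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)
    pa = rankdata(_perm_triangles(a, perms, iu), axis=1)
    r_ab_p = _row_pearson(pa, rb)
    r_ac_p = _row_pearson(pa, rc)
    r_perm = _partial_r(r_ab_p, r_ac_p, r_bc)
    p = _perm_pvalue(r_obs, r_perm, alternative)
    return MantelResult(r=r_obs, p_value=p, n_perm=n_perm, n_sites=n,
                        alternative=alternative,
                        partial_controlled=controlled_name, seed=seed)


def mantel_grid(component_matrices: dict[str, pd.DataFrame],
                attrs: SiteAttributes, n_perm: int = 9999,
                seed: int = 0) -> pd.DataFrame:
    """Tidy (component, driver, r, p, ...) table over the full test grid."""
    rows = []
    ss = np.random.SeedSequence(seed)
    seeds = iter(ss.generate_state(len(component_matrices) * len(attrs.attributes)))
    for comp, cmat in component_matrices.items():
        for driver in attrs.attributes:
            dmat = attribute_distance(attrs, driver)
            res = mantel(cmat, dmat, n_perm=n_perm, seed=int(next(seeds)) % (2 ** 31))
            rows.append({"component": comp, "driver": driver, "r": res.r,
                         "p_value": res.p_value, "n_perm": res.n_perm,
                         "n_sites": res.n_sites,
                         "partial_controlled": ""})
    return pd.DataFrame(rows)
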