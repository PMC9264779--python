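"""Beta-diversity partitioning into turnover and nestedness (BAS framework).

For a pair of sites with a shared species, b exclusive to the first and c to
the second, total dissimilarity splits additively in two index families:

Sorensen family
    beta_sor = (b + c) / (2a + b + c)
    beta_sim = min(b, c) / (a + min(b, c))                  (turnover)
    beta_sne = [|b - c| / (2a + b + c)] * [a / (a + min(b, c))]   (nestedness)

Jaccard family
    beta_jac = (b + c) / (a + b + c)
    beta_jtu = 2 min(b, c) / (a + 2 min(b, c))              (replacement)
    beta_jne = [|b - c| / (a + b + c)] * [a / (a + 2 min(b, c))]

so beta_sor = beta_sim + beta_sne and beta_jac = beta_jtu + beta_jne hold as
identities.  Turnover is the richness-independent substitution of species;
nestedness is the part driven by poorer sites being subsets of richer ones.

The multiple-site statistics generalize the same split to n sites.  With
S_T the pooled richness, S_i per-site richness, and b_ij the number of
species of site i absent from site j,

    beta_SIM = Smin / [Smin + (sum S_i - S_T)]
    beta_SOR = (Smin + Smax) / [2 (sum S_i - S_T) + Smin + Smax]
    beta_SNE = beta_SOR - beta_SIM
    beta_JTU = 2 Smin / [2 Smin + (sum S_i - S_T)]
    beta_JAC = (Smin + Smax) / [(sum S_i - S_T) + Smin + Smax]
    beta_JNE = beta_JAC - beta_JTU

where Smin = sum over pairs of min(b_ij, b_ji) and Smax the analogue with
max.  For n = 2 every multi-site statistic reduces exactly to its pairwise
form (sum S_i - S_T = a).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .checklist import OccurrenceMatrix
from .errors import ValidationError

COMPONENTS = ("beta_sor", "beta_sim", "beta_sne", "beta_jac", "beta_jtu", "beta_jne")


class PairCounts(NamedTuple):
    a: int  # shared
    b: int  # only site 1
    c: int  # only site 2


def pair_counts(site_i, site_j) -> PairCounts:
    """Set-algebra counts (a, b, c) from two binary incidence vectors."""
    u = np.asarray(site_i, dtype=bool)
    v = np.asarray(site_j, dtype=bool)
    if u.shape != v.shape:
        raise ValidationError("incidence vectors differ in length")
    if not u.any() or not v.any():
        raise ValidationError("empty site in pair comparison")
    return PairCounts(int((u & v).sum()), int((u & ~v).sum()), int((~u & v).sum()))


def _safe_div(num, den):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.zeros(np.broadcast(num, den).shape)
    np.divide(num, den, out=out, where=den != 0)
    return out


def decompose_pair(pc: PairCounts) -> dict[str, float]:
    """All six pairwise components; 0/0 forms return 0 (identical sites)."""
    a, b, c = pc
    if a < 0 or b < 0 or c < 0 or (a + b == 0) or (a + c == 0):
        raise ValidationError(f"invalid pair counts {pc}")
    mn, df = min(b, c), abs(b - c)
    sor = _safe_div(b + c, 2 * a + b + c)
    sim = _safe_div(mn, a + mn)
    sne = _safe_div(df, 2 * a + b + c) * _safe_div(a, a + mn)
    jac = _safe_div(b + c, a + b + c)
    jtu = _safe_div(2 * mn, a + 2 * mn)
    jne = _safe_div(df, a + b + c) * _safe_div(a, a + 2 * mn)
    return {"beta_sor": float(sor), "beta_sim": float(sim), "beta_sne": float(sne),
            "beta_jac": float(jac), "beta_jtu": float(jtu), "beta_jne": float(jne)}


@dataclass
class PairwiseBetaMatrices:
    """Six symmetric site x site component matrices (zero diagonal)."""

    matrices: dict[str, pd.DataFrame]

    def __getitem__(self, key: str) -> pd.DataFrame:
        return self.matrices[key]

    @property
    def sites(self) -> list[str]:
        return list(next(iter(self.matrices.values())).index)


def _abc_matrices(x: np.ndarray):
    """Shared/exclusive count matrices from a (sites x species) bool array."""
    xf = x.astype(float)
    a = xf @ xf.T
    s = xf.sum(axis=1)
    b = s[:, None] - a
    return a, b, b.T, s


def pairwise_matrices(matrix: OccurrenceMatrix) -> PairwiseBetaMatrices:
    """Decompose every unordered site pair; vectorized over the pair grid."""
    x = matrix.values_sites_by_species().astype(bool)
    if x.shape[0] < 2:
        raise ValidationError("need at least 2 sites")
    if (~x.any(axis=1)).any():
        raise ValidationError("empty site in occurrence matrix")
    a, b, c, _ = _abc_matrices(x)
    mn = np.minimum(b, c)
    df = np.abs(b - c)
    comp = {
        "beta_sor": _safe_div(b + c, 2 * a + b + c),
        "beta_sim": _safe_div(mn, a + mn),
        "beta_sne": _safe_div(df, 2 * a + b + c) * _safe_div(a, a + mn),
        "beta_jac": _safe_div(b + c, a + b + c),
        "beta_jtu": _safe_div(2 * mn, a + 2 * mn),
        "beta_jne": _safe_div(df, a + b + c) * _safe_div(a, a + 2 * mn),
    }
    sites = matrix.sites
    out = {}
    for name, m in comp.items():
        np.fill_diagonal(m, 0.0)
        out[name] = pd.DataFrame(m, index=sites, columns=sites)
    return PairwiseBetaMatrices(out)


def site_summary(matrices: PairwiseBetaMatrices) -> pd.DataFrame:
    """Per-site mean +/- sample SD of that site's n-1 pairwise values.

    This reproduces the shape of a per-basin similarity table: each site is
    summarized by the distribution of its comparisons with every other site.
    With only two sites the SD is reported missing.
    """
    sites = matrices.sites
    n = len(sites)
    rows = {}
    for site in sites:
        row = {}
        for comp in COMPONENTS:
            vals = matrices[comp].loc[site].drop(labels=[site]).to_numpy()
            row[f"{comp}_mean"] = float(vals.mean())
            row[f"{comp}_sd"] = float(vals.std(ddof=1)) if n > 2 else np.nan
        rows[site] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "site"
    return out


@dataclass(frozen=True)
class MultiSiteBeta:
    beta_sor: float
    beta_sim: float
    beta_sne: float
    beta_jac: float
    beta_jtu: float
    beta_jne: float
    n_sites: int

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in COMPONENTS}


def multi_site(matrix: OccurrenceMatrix | np.ndarray) -> MultiSiteBeta:
    """Multiple-site turnover/nestedness decomposition over all sites."""
    if isinstance(matrix, OccurrenceMatrix):
        x = matrix.values_sites_by_species().astype(bool)
    else:
        x = np.asarray(matrix, dtype=bool)
    n = x.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 sites")
    if (~x.any(axis=1)).any():
        raise ValidationError("empty site in occurrence matrix")
    _, b, c, s = _abc_matrices(x)
    iu = np.triu_indices(n, k=1)
    smin = float(np.minimum(b, c)[iu].sum())
    smax = float(np.maximum(b, c)[iu].sum())
    core = float(s.sum() - x.any(axis=0).sum())  # sum S_i - S_T
    sim = _safe_div(smin, smin + core)
    sor = _safe_div(smin + smax, 2 * core + smin + smax)
    jtu = _safe_div(2 * smin, 2 * smin + core)
    jac = _safe_div(smin + smax, core + smin + smax)
    return MultiSiteBeta(
        beta_sor=float(sor), beta_sim=float(sim), beta_sne=float(sor - sim),
        beta_jac=float(jac), beta_jtu=float(jtu), beta_jne=float(jac - jtu),
        n_sites=n,
    )


def resample_multi_site(matrix: OccurrenceMatrix, n_resamples: int = 100,
                        subset_size: int | None = None, seed: int = 0) -> pd.DataFrame:
    """Mean +/- SD of the multi-site components over random site subsets.

    Default subset size is n_sites - 2.  This puts a spread on the
    multiple-site statistics, which are otherwise single numbers.
    """
    x = matrix.values_sites_by_species().astype(bool)
    n = x.shape[0]
    if subset_size is None:
        subset_size = max(2, n - 2)
    if not 2 <= subset_size <= n:
        raise ValidationError(f"subset_size must lie in [2, {n}]")
    rng = np.random.default_rng(seed)
    if subset_size == n:
        draws = [multi_site(x).as_dict()]
    else:
        draws = []
        for _ in range(n_resamples):
            idx = rng.choice(n, size=subset_size, replace=False)
            draws.append(multi_site(x[idx]).as_dict())
    frame = pd.DataFrame(draws)
    out = pd.DataFrame({"mean": frame.mean(),
                        "sd": frame.std(ddof=1) if len(frame) > 1 else 0.0})
    out.index.name = "component"
    return out
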