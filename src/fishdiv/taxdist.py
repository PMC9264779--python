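"""Average taxonomic distinctness (Delta+), its variation (Lambda+), and the
randomization confidence funnel.

For a presence-only assemblage of S species, every unordered species pair
(i, j) receives a path-length weight w_ij set by the lowest taxonomic rank
the two share.  With the six-rank hierarchy species < genus < family <
order < class < phylum and an equal step per rank ascended, the weights are

    same genus 16.667, same family 33.333, same order 50.000,
    same class 66.667, same phylum 83.333

(the published three-decimal values are used verbatim).  Then

    Delta+  = mean of w_ij over the S(S-1)/2 pairs,
    Lambda+ = population variance of w_ij about Delta+ over those pairs.

Departure of a site from the master checklist is judged against a
randomization funnel: for each subset size m, ``n_draws`` uniform
without-replacement subsets of the master list give an expected mean and
empirical 2.5/97.5 percentile limits; a site below the lower limit is
taxonomically impoverished relative to the pool (degraded), one within the
funnel is consistent with a random draw.  Delta+ is exactly unbiased under
uniform subsetting (every pair is equally likely), which the test suite
verifies by exhaustive enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .checklist import Checklist, OccurrenceMatrix
from .errors import ValidationError

#: rank ascents: 1 = same genus ... 5 = same phylum, 6 = different phyla
_DEFAULT_WEIGHTS = (0.0, 16.667, 33.333, 50.000, 66.667, 83.333, 100.0)


@dataclass(frozen=True)
class PathWeightScheme:
    """Weights per number of ranks ascended to the lowest shared rank.

    ``weights[d]`` is the weight of a pair whose lowest shared rank is d
    steps above species (0 = identical species, 1 = same genus, ...,
    5 = same phylum, 6 = not even the same phylum).
    """

    weights: tuple[float, ...] = _DEFAULT_WEIGHTS

    def __post_init__(self):
        if len(self.weights) != 7 or any(
                b <= a for a, b in zip(self.weights, self.weights[1:])):
            raise ValidationError("weights must be 7 strictly increasing values")

    @classmethod
    def from_step(cls, step: float) -> "PathWeightScheme":
        return cls(tuple(step * d for d in range(7)))

    @property
    def max_weight(self) -> float:
        return self.weights[-1]


DEFAULT_SCHEME = PathWeightScheme()


def weight_matrix(checklist: Checklist, species=None,
                  scheme: PathWeightScheme = DEFAULT_SCHEME) -> np.ndarray:
    """Symmetric pairwise path-weight matrix over ``species`` (default: all)."""
    codes = checklist.lineage_codes(species)  # (n, 5): genus..phylum
    n = codes.shape[0]
    depth = np.full((n, n), 6, dtype=np.int8)
    # assign from coarsest to finest so the finest shared rank wins
    for level in range(4, -1, -1):  # 4 = phylum ... 0 = genus
        same = codes[:, level][:, None] == codes[:, level][None, :]
        depth[same] = level + 1
    np.fill_diagonal(depth, 0)
    return np.asarray(scheme.weights, dtype=float)[depth]


def pairwise_weight(sp_i: str, sp_j: str, checklist: Checklist,
                    scheme: PathWeightScheme = DEFAULT_SCHEME) -> float:
    """Path weight between two species (0 for a species with itself)."""
    if sp_i == sp_j:
        if sp_i not in checklist.frame.index:
            raise ValidationError(f"species not in checklist: {sp_i!r}")
        return 0.0
    w = weight_matrix(checklist, [sp_i, sp_j], scheme)
    return float(w[0, 1])


def _pair_stats(w: np.ndarray) -> tuple[float, float]:
    n = w.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = w[iu]
    delta = float(vals.mean())
    lam = float(((vals - delta) ** 2).mean())
    return delta, lam


@dataclass(frozen=True)
class TaxDistResult:
    delta_plus: float
    lambda_plus: float
    s: int


def delta_plus(assemblage, checklist: Checklist,
               scheme: PathWeightScheme = DEFAULT_SCHEME) -> float:
    """Mean pairwise path weight over all unordered pairs."""
    return tax_distinctness(assemblage, checklist, scheme).delta_plus


def lambda_plus(assemblage, checklist: Checklist,
                scheme: PathWeightScheme = DEFAULT_SCHEME) -> float:
    """Population variance of pairwise path weights about Delta+."""
    return tax_distinctness(assemblage, checklist, scheme).lambda_plus


def tax_distinctness(assemblage, checklist: Checklist,
                     scheme: PathWeightScheme = DEFAULT_SCHEME) -> TaxDistResult:
    species = list(assemblage)
    if len(species) < 2:
        raise ValidationError("Delta+/Lambda+ need at least 2 species")
    w = weight_matrix(checklist, species, scheme)
    d, l = _pair_stats(w)
    return TaxDistResult(delta_plus=d, lambda_plus=l, s=len(species))


# ---------------------------------------------------------------------------
# randomization funnel
# ---------------------------------------------------------------------------

@dataclass
class FunnelTable:
    """Expected mean and empirical 95% limits of Delta+/Lambda+ vs subset size."""

    table: pd.DataFrame          # columns: m, delta_mean/sd/lo/hi, lambda_...
    n_draws: int
    seed: int
    master_delta: float
    master_lambda: float
    s_master: int


def funnel(checklist: Checklist, sizes, n_draws: int = 10_000,
           seed: int = 0, scheme: PathWeightScheme = DEFAULT_SCHEME) -> FunnelTable:
    """Randomization funnel from the master checklist.

    For each m in ``sizes``, draws ``n_draws`` uniform subsets of size m
    without replacement and records the mean, SD, and empirical 2.5/97.5
    percentiles of Delta+ and Lambda+.  Subset sums are evaluated through
    indicator-matrix products, so the whole funnel for a few-hundred-species
    pool takes seconds.
    """
    s = len(checklist)
    sizes = sorted(set(int(m) for m in sizes))
    if any(m < 2 or m > s for m in sizes):
        raise ValidationError(f"subset sizes must lie in [2, {s}]")
    w = weight_matrix(checklist, None, scheme)
    w2 = w * w
    rng = np.random.default_rng(seed)
    master_d, master_l = _pair_stats(w)

    rows = []
    for m in sizes:
        # n_draws uniform m-subsets: first m columns of random permutations
        order = np.argsort(rng.random((n_draws, s)), axis=1)[:, :m]
        z = np.zeros((n_draws, s))
        np.put_along_axis(z, order, 1.0, axis=1)
        pairs = m * (m - 1) / 2
        s1 = np.einsum("dt,dt->d", z @ w, z) / 2.0
        s2 = np.einsum("dt,dt->d", z @ w2, z) / 2.0
        delta = s1 / pairs
        lam = s2 / pairs - delta ** 2
        rows.append({
            "m": m,
            "delta_mean": delta.mean(), "delta_sd": delta.std(ddof=1) if m < s else 0.0,
            "delta_lo": np.percentile(delta, 2.5), "delta_hi": np.percentile(delta, 97.5),
            "lambda_mean": lam.mean(), "lambda_sd": lam.std(ddof=1) if m < s else 0.0,
            "lambda_lo": np.percentile(lam, 2.5), "lambda_hi": np.percentile(lam, 97.5),
        })
    table = pd.DataFrame(rows)
    return FunnelTable(table=table, n_draws=n_draws, seed=seed,
                       master_delta=master_d, master_lambda=master_l, s_master=s)


def _interp(funnel_table: FunnelTable, col: str, m: float) -> float:
    t = funnel_table.table
    return float(np.interp(m, t["m"].to_numpy(), t[col].to_numpy()))


def classify_sites(funnel_table: FunnelTable, matrix: OccurrenceMatrix,
                   checklist: Checklist,
                   scheme: PathWeightScheme = DEFAULT_SCHEME) -> pd.DataFrame:
    """Observed per-site Delta+/Lambda+ against the funnel limits.

    Status per statistic: ``below`` / ``within`` / ``above`` the 95% limits
    (closed interval: a value exactly on a limit is within); sites with
    fewer than two species are ``unclassifiable``.  Limits at a site's
    richness are linearly interpolated between computed funnel sizes.
    """
    rows = []
    for site in matrix.sites:
        spp = list(matrix.site_species(site))
        m = len(spp)
        if m < 2:
            rows.append({"site": site, "m": m, "delta_plus": np.nan,
                         "delta_status": "unclassifiable",
                         "lambda_plus": np.nan,
                         "lambda_status": "unclassifiable"})
            continue
        res = tax_distinctness(spp, checklist, scheme)
        row = {"site": site, "m": m,
               "delta_plus": res.delta_plus, "lambda_plus": res.lambda_plus}
        for stat, value in (("delta", res.delta_plus), ("lambda", res.lambda_plus)):
            lo = _interp(funnel_table, f"{stat}_lo", m)
            hi = _interp(funnel_table, f"{stat}_hi", m)
            tol = 1e-9 * max(1.0, abs(hi), abs(lo))  # closed-interval limits
            if value < lo - tol:
                status = "below"
            elif value > hi + tol:
                status = "above"
            else:
                status = "within"
            row[f"{stat}_status"] = status
        rows.append(row)
    return pd.DataFrame(rows).set_index("site")
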