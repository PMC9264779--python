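"""Genus-family (G-F) diversity indices.

The G index is the Shannon entropy (natural log) of the partition of an
assemblage's species among genera,

    D_G = - sum_j (S_j / S) ln(S_j / S),

with S_j the species count of genus j and S the assemblage total.  The F
index sums, over families, the entropy of each family's species among its
genera,

    D_F = sum_k [ - sum_i (S_ki / S_k) ln(S_ki / S_k) ],

so a family containing a single genus contributes nothing.  The standardized
G-F index contrasts the two:

    D_GF = 1 - D_G / D_F,

defined as 0 when D_F = 0 (monogeneric families only).  All three are
presence-only statistics of a checklist; abundance never enters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .checklist import Checklist, OccurrenceMatrix
from .errors import ValidationError


@dataclass(frozen=True)
class GFResult:
    d_g: float
    d_f: float
    d_gf: float
    s_total: int
    p_genera: int
    m_families: int


def _entropy(counts: np.ndarray) -> float:
    """Shannon entropy in nats of a count vector."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def _assemblage_frame(assemblage: Sequence[str], checklist: Checklist) -> pd.DataFrame:
    species = list(assemblage)
    if not species:
        raise ValidationError("assemblage is empty")
    missing = [s for s in species if s not in checklist.frame.index]
    if missing:
        raise ValidationError(f"species not in checklist: {missing[:5]}")
    return checklist.frame.loc[species]


def g_index(assemblage: Sequence[str], checklist: Checklist) -> float:
    """Genus-level diversity D_G of an assemblage (nats)."""
    sub = _assemblage_frame(assemblage, checklist)
    return _entropy(sub.groupby("genus").size().to_numpy())


def f_index(assemblage: Sequence[str], checklist: Checklist) -> float:
    """Family-level diversity D_F: within-family genus entropies, summed."""
    sub = _assemblage_frame(assemblage, checklist)
    total = 0.0
    for _, fam in sub.groupby("family"):
        total += _entropy(fam.groupby("genus").size().to_numpy())
    return total


def gf_index(d_g: float, d_f: float) -> float:
    """Standardized G-F index 1 - D_G/D_F, with the degenerate case D_F=0 -> 0."""
    if d_g < 0 or d_f < 0:
        raise ValidationError("index inputs must be non-negative")
    if d_f == 0:
        return 0.0
    return 1.0 - d_g / d_f


def gf_result(assemblage: Sequence[str], checklist: Checklist) -> GFResult:
    sub = _assemblage_frame(assemblage, checklist)
    d_g = g_index(assemblage, checklist)
    d_f = f_index(assemblage, checklist)
    return GFResult(
        d_g=d_g,
        d_f=d_f,
        d_gf=gf_index(d_g, d_f),
        s_total=len(sub),
        p_genera=sub["genus"].nunique(),
        m_families=sub["family"].nunique(),
    )


def gf_per_site(matrix: OccurrenceMatrix, checklist: Checklist,
                pool_label: str = "ALL") -> pd.DataFrame:
    """One row of (D_G, D_F, D_GF, S, genera, families) per site + pool row.

    A site with fewer than one species is reported as a missing row.  The
    pool row is the union of all sites, labelled ``pool_label``.
    """
    rows = {}
    for site in matrix.sites:
        spp = list(matrix.site_species(site))
        if not spp:
            rows[site] = dict(d_g=np.nan, d_f=np.nan, d_gf=np.nan,
                              s_total=0, p_genera=0, m_families=0)
            continue
        r = gf_result(spp, checklist)
        rows[site] = r.__dict__
    pool = list(matrix.species)
    rows[pool_label] = gf_result(pool, checklist).__dict__
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "site"
    return out
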