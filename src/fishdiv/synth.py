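"""Synthetic checklists and occurrence matrices.

The study system is a set of river sub-basins sampled for a presence/absence
fish checklist: a species pool with a strongly skewed genus-size distribution
(a few very speciose genera, many monotypic ones) distributed over sites that
lie on a northwest-to-southeast gradient along which richness declines.
The generator reproduces exactly that structure so every downstream
statistic can be exercised, at any scale, without the original species list.

Three assembly regimes are available:

``nested``
    each site's assemblage is a subset of its richer neighbour's (a strict
    chain), the pure richness-difference end-member: spatial turnover is
    exactly zero;
``turnover``
    species occupy contiguous windows along the site gradient, so adjacent
    sites share species while distant sites do not — the replacement
    end-member;
``mixed``
    each species is assigned to one regime, turnover with probability
    ``theta``, giving an interpolation between the two.

Both constructions hit the requested per-site richness targets exactly, and
everything is reproducible from ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .checklist import Checklist, OccurrenceMatrix
from .errors import ConfigError

KNOWN_FLAGS = ("endemic", "cave", "threatened", "alien")

#: the 12 sub-basin codes, ordered richest (karst northwest) to poorest
GUANGXI_SITES = ("LGR", "LR", "HSR", "XZR", "ZR", "YR",
                 "XR", "YYR", "HR", "OR", "NLR", "BDR")


def guangxi_site_attributes():
    """The per-sub-basin hydrological/environmental driver table.

    River length (km), watershed area (km^2, one missing cell), average
    gradient (%), precipitation (mm), temperature (degC), annual runoff
    (1e8 m^3), and altitude (m) for the 12 sub-basins, shipped with the
    package as the driver input for Mantel tests.
    """
    import io
    from importlib.resources import files

    from .checklist import read_site_attributes
    text = (files("fishdiv") / "data" / "guangxi_site_attributes.csv").read_text()
    return read_site_attributes(io.StringIO(text))


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a synthetic study system.

    ``genus_size_skew`` is the success probability of the truncated geometric
    law used for genus sizes (smaller = more skew); ``largest_genus_min``
    optionally forces one hyper-diverse genus of at least that many species,
    mimicking a cave-adapted radiation. ``richness_range`` gives the poorest
    and richest site; per-site targets interpolate monotonically between the
    two along the gradient. ``flag_fractions`` gives the share of the pool
    carrying each non-endemic flag (the endemic flag is occupancy-derived,
    see :func:`generate_dataset`).
    """

    n_orders: int = 5
    n_families: int = 10
    n_genera: int = 30
    n_species: int = 80
    genus_size_skew: float = 0.35
    n_sites: int = 8
    richness_range: tuple[int, int] = (10, 40)
    assembly_mode: str = "mixed"
    theta: float = 0.8
    endemic_fraction: float | None = None
    seed: int = 0
    n_classes: int = 2
    n_phyla: int = 1
    largest_genus_min: int | None = None
    flag_fractions: tuple[tuple[str, float], ...] = ()
    site_names: tuple[str, ...] | None = None

    def validate(self) -> None:
        counts = (self.n_phyla, self.n_classes, self.n_orders,
                  self.n_families, self.n_genera, self.n_species)
        if any(c < 1 for c in counts):
            raise ConfigError("all taxon counts must be >= 1")
        if not (self.n_species >= self.n_genera >= self.n_families
                >= self.n_orders >= self.n_classes >= self.n_phyla):
            raise ConfigError(
                "counts must be nested: species >= genera >= families >= "
                "orders >= classes >= phyla"
            )
        lo, hi = self.richness_range
        if not (1 <= lo <= hi <= self.n_species):
            raise ConfigError("richness_range must satisfy 1 <= min <= max <= n_species")
        if self.assembly_mode not in ("nested", "turnover", "mixed"):
            raise ConfigError(f"unknown assembly_mode {self.assembly_mode!r}")
        if not 0.0 <= self.theta <= 1.0:
            raise ConfigError("theta must lie in [0, 1]")
        if self.n_sites < 1:
            raise ConfigError("n_sites must be >= 1")
        if not 0.0 < self.genus_size_skew < 1.0:
            raise ConfigError("genus_size_skew must lie in (0, 1)")
        if self.site_names is not None and len(self.site_names) != self.n_sites:
            raise ConfigError("site_names length must equal n_sites")


def guangxi_preset(seed: int = 2022) -> SyntheticConfig:
    """Config emulating the Guangxi freshwater-fish study system.

    380 species in 158 genera, 43 families, 17 orders; 12 sub-basins with
    richness falling monotonically from 185 (LGR-like) to 18 (BDR-like);
    one forced radiation of >= 30 congeners (a *Sinocyclocheilus*-like cave
    clade); mixed assembly dominated by turnover (theta = 0.75, calibrated
    by simulation: it is the admissible turnover weight whose multi-site
    turnover share of total dissimilarity comes closest to the
    replacement-dominated regime the system shows).  Flag
    fractions mirror the pool composition: 83/380 cave, 49/380 threatened,
    18/380 alien; endemics are the single-site species.
    """
    return SyntheticConfig(
        n_orders=17,
        n_families=43,
        n_genera=158,
        n_species=380,
        genus_size_skew=0.35,
        n_sites=12,
        richness_range=(18, 185),
        assembly_mode="mixed",
        theta=0.75,
        seed=seed,
        n_classes=2,
        n_phyla=1,
        largest_genus_min=30,
        flag_fractions=(("cave", 83 / 380), ("threatened", 49 / 380),
                        ("alien", 18 / 380)),
        site_names=GUANGXI_SITES,
    )


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

def _skewed_partition(n_items: int, n_bins: int, rng: np.random.Generator,
                      p: float, force_max: int | None = None) -> np.ndarray:
    """Partition ``n_items`` into ``n_bins`` positive parts, geometric-skewed.

    Draw truncated-geometric sizes, then adjust (decrement the largest /
    increment size-weighted) until the sum is exact, so the requested totals
    are hit exactly at every rank.
    """
    if n_bins > n_items:
        raise ConfigError(f"cannot split {n_items} items into {n_bins} non-empty bins")
    sizes = rng.geometric(p, size=n_bins).astype(np.int64)
    while sizes.sum() > n_items:
        k = int(np.argmax(sizes))
        if sizes[k] == 1:
            break
        excess = sizes.sum() - n_items
        sizes[k] -= min(excess, sizes[k] - 1)
    while sizes.sum() < n_items:
        # size-weighted growth keeps the distribution skewed
        k = rng.choice(n_bins, p=sizes / sizes.sum())
        sizes[k] += 1
    if force_max is not None:
        cap = n_items - (n_bins - 1)
        target = min(force_max, cap)
        k = int(np.argmax(sizes))
        while sizes[k] < target:
            j = int(np.argmax(np.where(np.arange(n_bins) == k, -1, sizes)))
            if sizes[j] <= 1:
                break
            sizes[j] -= 1
            sizes[k] += 1
    assert sizes.sum() == n_items and (sizes >= 1).all()
    return sizes


def generate_taxonomy(config: SyntheticConfig) -> Checklist:
    """Generate a checklist with exactly the requested counts at every rank."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    sp_per_genus = _skewed_partition(config.n_species, config.n_genera, rng,
                                     config.genus_size_skew,
                                     force_max=config.largest_genus_min)
    gen_per_family = _skewed_partition(config.n_genera, config.n_families, rng,
                                       config.genus_size_skew)
    fam_per_order = _skewed_partition(config.n_families, config.n_orders, rng, 0.5)
    ord_per_class = _skewed_partition(config.n_orders, config.n_classes, rng, 0.5)
    cls_per_phylum = _skewed_partition(config.n_classes, config.n_phyla, rng, 0.5)

    genus_of_species = np.repeat(np.arange(config.n_genera), sp_per_genus)
    family_of_genus = np.repeat(np.arange(config.n_families), gen_per_family)
    order_of_family = np.repeat(np.arange(config.n_orders), fam_per_order)
    class_of_order = np.repeat(np.arange(config.n_classes), ord_per_class)
    phylum_of_class = np.repeat(np.arange(config.n_phyla), cls_per_phylum)

    g = genus_of_species
    f = family_of_genus[g]
    o = order_of_family[f]
    c = class_of_order[o]
    p = phylum_of_class[c]

    order_idx = rng.permutation(config.n_species)  # shuffle checklist row order
    frame = pd.DataFrame({
        "species_id": [f"sp{i + 1:04d}" for i in range(config.n_species)],
        "genus": [f"G{k + 1:03d}" for k in g],
        "family": [f"F{k + 1:03d}" for k in f],
        "order": [f"O{k + 1:02d}" for k in o],
        "class": [f"C{k + 1:02d}" for k in c],
        "phylum": [f"P{k + 1:02d}" for k in p],
    }).iloc[order_idx].reset_index(drop=True)
    return Checklist(frame)


# ---------------------------------------------------------------------------
# occurrences
# ---------------------------------------------------------------------------

def _richness_targets(config: SyntheticConfig) -> np.ndarray:
    """Monotone non-increasing per-site richness, endpoints exact."""
    lo, hi = config.richness_range
    if config.n_sites == 1:
        return np.array([hi])
    t = np.linspace(hi, lo, config.n_sites)
    r = np.rint(t).astype(int)
    r[0], r[-1] = hi, lo
    return np.minimum.accumulate(r)  # guard against rounding bumps


def _nested_block(n_species: int, targets: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Strict nested chain: site k holds the top-targets[k] ranked species."""
    if targets.max(initial=0) > n_species:
        raise ConfigError("richness_range infeasible for n_species")
    rank = rng.permutation(n_species)
    m = np.zeros((len(targets), n_species), dtype=np.int8)
    for i, r in enumerate(targets):
        m[i, rank[:r]] = 1
    return m


def _turnover_block(n_species: int, targets: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Contiguous-window assembly hitting per-site richness exactly.

    Each species occupies a contiguous window of sites.  Windows are built
    from per-site start/end counts: the richness recurrence
    ``r_i = r_{i-1} + starts_i - ends_{i-1}`` fixes the minimum number of
    windows, and every extra species adds a (start at i, end at i-1) split
    that raises turnover without disturbing richness.
    """
    n_sites = len(targets)
    r_max = int(targets.max(initial=0))
    if r_max > n_species:
        raise ConfigError("richness_range infeasible for n_species")
    extras = n_species - int(targets[0])
    if extras > 0 and n_sites < 2:
        raise ConfigError("cannot place more species than max richness on one site")
    starts = np.zeros(n_sites, dtype=np.int64)
    ends = np.zeros(n_sites, dtype=np.int64)
    starts[0] = targets[0]
    for i in range(1, n_sites):
        d = int(targets[i]) - int(targets[i - 1])
        if d > 0:
            starts[i] += d
        else:
            ends[i - 1] += -d
    ends[-1] += int(targets[-1])
    if extras < 0:
        raise ConfigError("n_species below maximum site richness")
    for i in rng.integers(1, n_sites, size=extras):
        starts[i] += 1
        ends[i - 1] += 1
    start_sites = np.repeat(np.arange(n_sites), starts)
    end_sites = np.repeat(np.arange(n_sites), ends)
    # k-th smallest start pairs with k-th smallest end; positivity of the
    # running richness guarantees start <= end for every pair
    windows = list(zip(np.sort(start_sites), np.sort(end_sites)))
    rng.shuffle(windows)
    m = np.zeros((n_sites, n_species), dtype=np.int8)
    for j, (s, e) in enumerate(windows):
        m[s:e + 1, j] = 1
    assert (m.sum(axis=1) == targets).all()
    return m


def generate_occurrences(checklist: Checklist, config: SyntheticConfig) -> OccurrenceMatrix:
    """Binary site x species incidence on a 1-D gradient (site 1 richest)."""
    config.validate()
    n = len(checklist)
    if n != config.n_species:
        raise ConfigError("checklist size does not match config.n_species")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    targets = _richness_targets(config)

    if config.assembly_mode == "nested":
        m = _nested_block(n, targets, rng)
    elif config.assembly_mode == "turnover":
        m = _turnover_block(n, targets, rng)
    else:
        # split both the species pool and the per-site targets by theta
        t_targets = np.rint(config.theta * targets).astype(int)
        n_targets = targets - t_targets
        n_turn = max(int(t_targets[0]), round(config.theta * n))
        n_turn = min(n_turn, n - int(n_targets.max(initial=0)))
        if n_turn < t_targets.max(initial=0) or (n - n_turn) < n_targets.max(initial=0):
            raise ConfigError("richness_range infeasible under theta split")
        cols = rng.permutation(n)
        m = np.zeros((config.n_sites, n), dtype=np.int8)
        if n_turn:
            m[:, cols[:n_turn]] = _turnover_block(n_turn, t_targets, rng)
        if n - n_turn:
            m[:, cols[n_turn:]] = _nested_block(n - n_turn, n_targets, rng)

    site_names = (list(config.site_names) if config.site_names is not None
                  else [f"site{i + 1:02d}" for i in range(config.n_sites)])
    frame = pd.DataFrame(m.T, index=checklist.species.copy(), columns=site_names)
    # a nested chain can only record targets[0] species; pool species the
    # chain never places stay off the matrix (a pool may exceed the records)
    frame = frame.loc[frame.sum(axis=1) > 0]
    return OccurrenceMatrix(frame, checklist)


def generate_dataset(config: SyntheticConfig) -> tuple[Checklist, OccurrenceMatrix]:
    """Taxonomy + occurrences + flags in one call.

    The endemic flag goes to single-site species (or, when
    ``endemic_fraction`` is set, to that share of the pool ranked by
    occupancy); other flags are drawn at the configured fractions.
    """
    checklist = generate_taxonomy(config)
    matrix = generate_occurrences(checklist, config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))

    occ = matrix.occupancy()
    frame = checklist.frame.copy()
    if config.endemic_fraction is None:
        endemic = occ[occ == 1].index
    else:
        k = int(round(config.endemic_fraction * len(checklist)))
        jitter = pd.Series(rng.random(len(occ)), index=occ.index)
        endemic = (occ + jitter).sort_values().index[:k]
    frame["endemic"] = frame["species_id"].isin(endemic).astype(int)
    for flag, frac in config.flag_fractions:
        k = int(round(frac * len(checklist)))
        chosen = rng.choice(len(checklist), size=k, replace=False)
        col = np.zeros(len(checklist), dtype=int)
        col[chosen] = 1
        frame[flag] = col
    checklist = Checklist(frame.reset_index(drop=True))
    matrix = OccurrenceMatrix(matrix.frame, checklist)
    return checklist, matrix


def scaled_preset(scale: float = 0.25, seed: int = 2022) -> SyntheticConfig:
    """A smaller system with the preset's shape, for quick runs and tests."""
    full = guangxi_preset(seed)
    f = max(scale, 0.05)
    n_species = max(20, int(round(full.n_species * f)))
    n_genera = min(n_species, max(8, int(round(full.n_genera * f))))
    n_families = min(n_genera, max(4, int(round(full.n_families * f))))
    n_orders = min(n_families, max(3, int(round(full.n_orders * f))))
    hi = max(6, int(round(full.richness_range[1] * f)))
    lo = max(2, int(round(full.richness_range[0] * f)))
    return replace(full, n_species=n_species, n_genera=n_genera,
                   n_families=n_families, n_orders=n_orders,
                   richness_range=(min(lo, hi), hi), largest_genus_min=None)
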