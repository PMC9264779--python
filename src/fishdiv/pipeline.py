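"""End-to-end orchestration: three CSVs (or a synthetic preset) in, a bundle
of analysis tables out.

Stages, in order: composition summary -> G/F/G-F per site -> taxonomic
distinctness per site + randomization funnel + classification -> pairwise
and multi-site beta partitioning -> similarity clustering (Newick tree +
group cut) -> Mantel tests of components against drivers.  Every stochastic
stage draws its seed deterministically from the master seed, a manifest
records config, seeds, versions, and collected warnings, and site ordering
follows the occurrence file throughout, so a run is reproducible
byte-for-byte from its config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import beta as beta_mod
from . import community as cluster_mod
from . import gf as gf_mod
from . import drivers as mantel_mod
from . import taxdist as taxdist_mod
from .checklist import (Checklist, OccurrenceMatrix, SiteAttributes,
                        read_checklist, read_occurrences, read_site_attributes,
                        write_checklist, write_occurrences, write_site_attributes)
from .errors import ConfigError
from .synth import (SyntheticConfig, generate_dataset, guangxi_preset,
                    guangxi_site_attributes, scaled_preset)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    checklist_path: str | None = None
    occurrences_path: str | None = None
    site_attributes_path: str | None = None
    preset: str | None = None            # "guangxi" or "guangxi-small"
    weight_step: float | None = None     # None = published 3-decimal weights
    funnel_n_draws: int = 10_000
    funnel_sizes: tuple[int, ...] | None = None   # None = per-site richness
    cluster_metric: str = "jaccard"
    cluster_linkage: str = "average"
    cluster_cut: float = 0.5
    mantel_n_perm: int = 9999
    seed: int = 0
    outdir: str = "fishdiv_out"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_inputs(config: RunConfig):
    if config.preset is not None:
        if config.preset == "guangxi":
            syn = guangxi_preset(seed=config.seed)
        elif config.preset == "guangxi-small":
            syn = scaled_preset(seed=config.seed)
        else:
            raise ConfigError(f"unknown preset {config.preset!r}")
        checklist, matrix = generate_dataset(syn)
        if config.site_attributes_path:
            attrs = read_site_attributes(config.site_attributes_path,
                                         sites=matrix.sites)
        else:  # presets carry the published driver table for their 12 sites
            attrs = guangxi_site_attributes()
        return checklist, matrix, attrs
    if not config.checklist_path or not config.occurrences_path:
        raise ConfigError("need --checklist and --occurrences, or a preset")
    checklist = read_checklist(config.checklist_path)
    matrix = read_occurrences(config.occurrences_path, checklist)
    attrs = None
    if config.site_attributes_path:
        attrs = read_site_attributes(config.site_attributes_path,
                                     sites=matrix.sites)
    return checklist, matrix, attrs


def composition_summary(checklist: Checklist, matrix: OccurrenceMatrix) -> dict[str, pd.DataFrame]:
    """Counts and percentages by rank, flag, order, and site.

    Flag percentages use the total species count of the checklist as the
    denominator, rounded to 2 decimals; that convention is stated in the
    output header of the flags table.
    """
    counts = checklist.rank_counts()
    overview = pd.DataFrame([counts]).T.rename(columns={0: "count"})
    overview.index.name = "rank"

    total = len(checklist)
    flag_rows = []
    for flag in checklist.flag_columns:
        k = int(checklist.frame[flag].sum())
        flag_rows.append({"flag": flag, "count": k,
                          "pct_of_total_species": round(100.0 * k / total, 2)})
    flags = pd.DataFrame(flag_rows, columns=["flag", "count", "pct_of_total_species"])

    per_order = (checklist.frame.groupby("order")
                 .agg(species=("species_id", "size"),
                      genera=("genus", "nunique"),
                      families=("family", "nunique"))
                 .sort_values("species", ascending=False))

    site_rows = {}
    for site in matrix.sites:
        spp = matrix.site_species(site)
        sub = checklist.frame.loc[spp]
        site_rows[site] = {"species": len(spp),
                           "genera": sub["genus"].nunique(),
                           "families": sub["family"].nunique(),
                           "orders": sub["order"].nunique()}
    per_site = pd.DataFrame.from_dict(site_rows, orient="index")
    per_site.index.name = "site"
    return {"overview": overview, "flags": flags,
            "per_order": per_order, "per_site": per_site}


def run_all(config: RunConfig) -> dict:
    """Run every stage and write the output bundle under ``config.outdir``."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []

    handler = _CollectHandler(warnings)
    logging.getLogger("fishdiv").addHandler(handler)
    try:
        checklist, matrix, attrs = _load_inputs(config)
        scheme = (taxdist_mod.DEFAULT_SCHEME if config.weight_step is None
                  else taxdist_mod.PathWeightScheme.from_step(config.weight_step))
        ss = np.random.SeedSequence(config.seed)
        seed_funnel, seed_resample, seed_mantel = (
            int(s) % (2 ** 31) for s in ss.generate_state(3))

        logger.info("stage: composition")
        comp = composition_summary(checklist, matrix)
        for name, frame in comp.items():
            frame.to_csv(outdir / f"composition_{name}.csv")

        logger.info("stage: gf")
        gf_table = gf_mod.gf_per_site(matrix, checklist)
        gf_table.round(4).to_csv(outdir / "gf_indices.csv")

        logger.info("stage: taxdist")
        richness = matrix.richness()
        sizes = (config.funnel_sizes if config.funnel_sizes
                 else sorted(set(int(m) for m in richness if m >= 2)))
        fun = taxdist_mod.funnel(checklist, sizes, n_draws=config.funnel_n_draws,
                                 seed=seed_funnel, scheme=scheme)
        fun.table.round(6).to_csv(outdir / "taxdist_funnel.csv", index=False)
        taxdist_table = taxdist_mod.classify_sites(fun, matrix, checklist, scheme)
        taxdist_table.round(4).to_csv(outdir / "taxdist_sites.csv")

        logger.info("stage: beta")
        mats = beta_mod.pairwise_matrices(matrix)
        for name, m in mats.matrices.items():
            m.round(6).to_csv(outdir / f"beta_pairwise_{name}.csv")
        beta_sites = beta_mod.site_summary(mats)
        beta_sites.round(4).to_csv(outdir / "beta_site_summary.csv")
        total = beta_mod.multi_site(matrix)
        spread = beta_mod.resample_multi_site(matrix, seed=seed_resample)
        total_row = pd.DataFrame([total.as_dict()])
        total_row["n_sites"] = total.n_sites
        total_row.round(6).to_csv(outdir / "beta_multisite.csv", index=False)
        spread.round(6).to_csv(outdir / "beta_multisite_resampled.csv")

        logger.info("stage: cluster")
        sim = cluster_mod.similarity_matrix(matrix, metric=config.cluster_metric)
        dend = cluster_mod.cluster(sim, linkage=config.cluster_linkage)
        (outdir / "cluster_tree.nwk").write_text(cluster_mod.to_newick(dend) + "\n")
        groups = cluster_mod.cut_at(dend, config.cluster_cut)
        groups.rename_axis("site").to_csv(outdir / "cluster_groups.csv")

        mantel_table = None
        if attrs is not None:
            logger.info("stage: mantel")
            mantel_table = mantel_mod.mantel_grid(
                mats.matrices, attrs, n_perm=config.mantel_n_perm,
                seed=seed_mantel)
            mantel_table.round(6).to_csv(outdir / "mantel_results.csv", index=False)

        if config.preset is not None:  # echo synthetic inputs for reuse
            write_checklist(checklist, outdir / "input_checklist.csv")
            write_occurrences(matrix, outdir / "input_occurrences.csv")
            if attrs is not None:
                write_site_attributes(attrs, outdir / "input_site_attributes.csv")

        manifest = {
            "config": config.to_dict(),
            "seeds": {"funnel": seed_funnel, "resample": seed_resample,
                      "mantel": seed_mantel},
            "versions": _versions(),
            "counts": checklist.rank_counts(),
            "n_sites": matrix.n_sites,
            "warnings": list(dict.fromkeys(warnings)),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        logger.info("pipeline done in %.1f s", time.time() - t0)
        return {"composition": comp, "gf": gf_table, "funnel": fun,
                "taxdist_sites": taxdist_table, "beta": mats,
                "beta_site_summary": beta_sites, "multi_site": total,
                "multi_site_resampled": spread, "dendrogram": dend,
                "groups": groups, "mantel": mantel_table,
                "manifest": manifest}
    finally:
        logging.getLogger("fishdiv").removeHandler(handler)


class _CollectHandler(logging.Handler):
    def __init__(self, sink: list[str]):
        super().__init__(level=logging.WARNING)
        self.sink = sink

    def emit(self, record):
        self.sink.append(self.format(record))


def _versions() -> dict[str, str]:
    import importlib.metadata as md

    import scipy
    out = {"numpy": np.__version__, "scipy": scipy.__version__,
           "pandas": pd.__version__}
    try:
        out["fishdiv"] = md.version("fishdiv")
    except md.PackageNotFoundError:
        out["fishdiv"] = "unknown"
    return out
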