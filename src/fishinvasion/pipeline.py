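"""End-to-end pipeline: simulate -> metrics -> drivers -> BRT -> varpart/RDA.

Each stage is a thin orchestration over the library modules; every output
bundle records the global seed and config hash so a run can be reproduced
bit-identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, metrics, simulate
from .brt import BRTResult, run_brt_pipeline
from .config import PipelineConfig, config_hash, to_dict
from .rda import RDAResult, rda_axis_test, rda_fit
from .varpart import (
    PartitionResult,
    euler_venn_areas,
    partition_with_tests,
    vif_filter,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineReport:
    config: PipelineConfig
    config_hash: str
    sites: pd.DataFrame
    community: pd.DataFrame
    invasion: pd.DataFrame
    invasiveness: pd.DataFrame
    brt_overall: BRTResult | None = None
    brt_species: dict[str, BRTResult] = field(default_factory=dict)
    partition: PartitionResult | None = None
    rda: RDAResult | None = None
    rda_axis_F: np.ndarray | None = None
    rda_axis_p: np.ndarray | None = None


def simulate_dataset(config: PipelineConfig):
    """Generate the synthetic landscape, species pool and community."""
    sites = simulate.generate_landscape(config.landscape)
    pool = simulate.generate_species_pool(
        config.species.n_native,
        config.species.n_exotic,
        seed=config.species.seed,
        config=config.species,
        landscape=sites,
    )
    community = simulate.sample_communities(
        sites, pool, seed=config.community.seed, config=config.community
    )
    return sites, pool, community


def species_response_matrix(
    records: pd.DataFrame, species: list[str]
) -> pd.DataFrame:
    """Site x species matrix of relative abundance (share of site total)."""
    if "abundance" not in records.columns:
        records = metrics.add_abundance(records)
    totals = records.groupby("site_id")["abundance"].sum()
    wide = (
        records[records["species"].isin(species)]
        .pivot_table(
            index="site_id", columns="species", values="abundance", aggfunc="sum"
        )
        .reindex(columns=species)
        .fillna(0.0)
    )
    wide = wide.reindex(totals.index).fillna(0.0)
    denom = totals.replace(0, np.nan)
    return wide.div(denom, axis=0).fillna(0.0)


def run(config: PipelineConfig, out_dir: str | Path | None = None) -> PipelineReport:
    """Execute the full analysis on a simulated dataset.

    Stages: community simulation, invasion metrics, BRT on invasion degree
    (with the SAC protocol), BRT per top-N invasive species, VIF screening,
    4-group variation partitioning with permutation tests, and RDA of the
    top-N species with per-axis tests.
    """
    chash = config_hash(config)
    logger.info("pipeline run: seed=%d config=%s", config.seed, chash)
    sites, pool, community = simulate_dataset(config)
    community = metrics.add_abundance(community, config.moyle)
    invasion = metrics.invasion_degree_table(community)
    invasiveness = metrics.invasiveness_rank(community)

    # align response and drivers on sites with fish
    merged = sites.merge(invasion, on="site_id")
    ok = merged["invasion_degree"].notna()
    merged = merged[ok].reset_index(drop=True)
    driver_cols = [c for cols in config.driver_groups.values() for c in cols]
    X = merged[driver_cols]
    y = merged["invasion_degree"].to_numpy()
    coords = merged[["x_km", "y_km"]].to_numpy()

    report = PipelineReport(
        config=config,
        config_hash=chash,
        sites=sites,
        community=community,
        invasion=invasion,
        invasiveness=invasiveness,
    )

    report.brt_overall = run_brt_pipeline(X, y, coords, config.brt)

    top = invasiveness.head(config.top_n_species)["species"].tolist()
    resp = species_response_matrix(community, top).reindex(merged["site_id"]).fillna(0.0)
    for sp in top:
        y_sp = resp[sp].to_numpy()
        if np.ptp(y_sp) == 0:
            logger.warning("skipping %s: constant response", sp)
            continue
        report.brt_species[sp] = run_brt_pipeline(X, y_sp, coords, config.brt)

    # collinearity screening within groups, then varpart + RDA
    groups = {}
    for gname, cols in config.driver_groups.items():
        kept, _, dropped = vif_filter(merged[cols], config.varpart.vif_threshold)
        if dropped:
            logger.info("VIF screening dropped %s from %s", dropped, gname)
        groups[gname] = kept
    report.partition = partition_with_tests(
        y, groups, n_perm=config.varpart.n_perm_fraction, seed=config.varpart.seed
    )
    X_rda = pd.concat(groups.values(), axis=1)
    transform = "hellinger" if config.varpart.hellinger else None
    report.rda = rda_fit(
        resp, X_rda, scaling=config.varpart.rda_scaling, transform=transform
    )
    report.rda_axis_F, report.rda_axis_p = rda_axis_test(
        resp,
        X_rda,
        n_perm=config.varpart.n_perm_axis,
        seed=config.varpart.seed,
        transform=transform,
        max_axes=2,
    )

    if out_dir is not None:
        write_outputs(report, out_dir)
    return report


def write_outputs(report: PipelineReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_community_csv(report.community, out / "community.csv")
    report.invasion.to_csv(out / "invasion_degree.csv", index=False)
    report.invasiveness.to_csv(out / "invasiveness.csv", index=False)
    io.sites_to_geojson(report.sites, out / "sites.geojson")
    bundle: dict = {"seed": report.config.seed, "config_hash": report.config_hash}
    if report.brt_overall is not None:
        bundle["brt_overall"] = _brt_dict(report.brt_overall)
    bundle["brt_species"] = {
        sp: _brt_dict(r) for sp, r in report.brt_species.items()
    }
    if report.partition is not None:
        p = report.partition
        bundle["varpart"] = {
            "fractions": p.fractions.to_dict(),
            "residual": p.residual,
            "adj_r2_full": p.adj_r2_full,
            "unique_p": p.unique_p,
            "unique_F": p.unique_F,
        }
    if report.rda is not None:
        r = report.rda
        bundle["rda"] = {
            "eigenvalues": r.eigenvalues,
            "proportion": r.proportion,
            "adj_r2": r.adj_r2,
            "axis_F": report.rda_axis_F,
            "axis_p": report.rda_axis_p,
        }
        r.site_scores.to_csv(out / "rda_site_scores.csv")
        r.species_scores.to_csv(out / "rda_species_scores.csv")
        r.biplot_scores.to_csv(out / "rda_biplot_scores.csv")
    from . import plots  # deferred: pulls in matplotlib

    if report.brt_overall is not None:
        plots.vi_barplot(report.brt_overall, path=out / "brt_overall_vi.png")
    if report.rda is not None and report.rda.species_scores.shape[1] >= 2:
        plots.rda_biplot(report.rda, path=out / "rda_biplot.png")
    if report.partition is not None:
        io.write_json(
            {"areas": euler_venn_areas(report.partition)},
            out / "varpart_venn_areas.json",
        )
    bundle["config"] = to_dict(report.config)
    io.write_json(bundle, out / "report.json")
    logger.info("outputs written to %s", out)


def _brt_dict(res: BRTResult) -> dict:
    return {
        "selected_variables": res.selected_variables,
        "vi": res.vi.to_dict(),
        "direction": res.direction,
        "cv_r2": res.cv_r2,
        "sac_share": res.sac_share,
        "sac_deviance_share": res.sac_deviance_share,
        "moran_initial_I": None if res.moran_initial is None else res.moran_initial.I,
        "moran_initial_p": None
        if res.moran_initial is None
        else res.moran_initial.p_norm,
        "moran_final_I": None if res.moran_final is None else res.moran_final.I,
        "log": res.log,
    }
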