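"""Community-level invasion metrics.

From long-format survey records (site x species Moyle classes with origin and
body-size class) this module derives:

* body-mass-corrected abundance (Moyle class midpoint x size weight),
* per-site invasion degree — the share of community abundance contributed by
  exotic species, in [0, 1],
* per-species colonization (% of sampled sites occupied), prevalence (mean
  relative abundance % where present), and the invasiveness index
  ``colonization x prevalence`` with its descending ranking.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import MoyleWeightConfig

REQUIRED_COLUMNS = ("site_id", "species", "origin", "moyle_class", "body_size_class")


def moyle_to_abundance(
    moyle_class, body_size_class, weights: MoyleWeightConfig | None = None
):
    """Body-mass-corrected abundance = class midpoint x body-size weight.

    Accepts scalars or aligned array-likes; class 0 always maps to 0.
    """
    w = weights or MoyleWeightConfig()
    classes = np.atleast_1d(np.asarray(moyle_class))
    sizes = np.atleast_1d(np.asarray(body_size_class, dtype=object))
    if classes.shape != sizes.shape:
        sizes = np.broadcast_to(sizes, classes.shape)
    n_classes = len(w.class_midpoints) - 1
    if np.any((classes < 0) | (classes > n_classes)):
        raise ValueError(f"moyle_class must be in 0..{n_classes}")
    unknown = set(np.unique(sizes)) - set(w.size_weights)
    if unknown:
        raise ValueError(f"unknown body-size class(es): {sorted(unknown)}")
    midpoints = np.asarray(w.class_midpoints, dtype=float)[classes.astype(int)]
    size_w = np.array([w.size_weights[s] for s in sizes.ravel()]).reshape(sizes.shape)
    out = midpoints * size_w
    return float(out[0]) if np.isscalar(moyle_class) else out


def add_abundance(
    records: pd.DataFrame, weights: MoyleWeightConfig | None = None
) -> pd.DataFrame:
    """Return a copy of the records with an ``abundance`` column."""
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records missing columns: {missing}")
    out = records.copy()
    out["abundance"] = moyle_to_abundance(
        records["moyle_class"].to_numpy(),
        records["body_size_class"].to_numpy(),
        weights,
    )
    return out


def invasion_degree(site_records: pd.DataFrame) -> float:
    """Share of exotic abundance in one site's community, in [0, 1].

    NaN (missing, not zero) for a site with no fish at all.
    """
    total = site_records["abundance"].sum()
    if total <= 0:
        return float("nan")
    exotic = site_records.loc[site_records["origin"] == "exotic", "abundance"].sum()
    return float(exotic / total)


def invasion_degree_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-site invasion degree for all sites in the records."""
    if "abundance" not in records.columns:
        records = add_abundance(records)
    grouped = records.groupby("site_id", sort=True)
    rows = [
        {"site_id": site, "invasion_degree": invasion_degree(g)}
        for site, g in grouped
    ]
    return pd.DataFrame(rows)


def _presence_tables(records: pd.DataFrame):
    site_totals = records.groupby("site_id")["abundance"].sum()
    fish_sites = site_totals[site_totals > 0].index  # sites with any fish
    present = records[(records["abundance"] > 0)]
    return site_totals, fish_sites, present


def colonization_prevalence(
    records: pd.DataFrame, species: str
) -> tuple[float, float]:
    """(colonization %, prevalence %) of one species.

    colonization = 100 x occupied sites / total sampled sites (sites with no
    fish at all are excluded from the denominator); prevalence = mean over
    occupied sites of the species' share (%) of site abundance.  Prevalence is
    NaN when the species is absent everywhere.
    """
    if "abundance" not in records.columns:
        records = add_abundance(records)
    site_totals, fish_sites, present = _presence_tables(records)
    n_sites = len(fish_sites)
    if n_sites == 0:
        raise ValueError("no sampled sites with fish")
    sp = present[present["species"] == species]
    occupied = sp.groupby("site_id")["abundance"].sum()
    colonization = 100.0 * len(occupied) / n_sites
    if len(occupied) == 0:
        return 0.0, float("nan")
    shares = 100.0 * occupied / site_totals.loc[occupied.index]
    return float(colonization), float(shares.mean())


def invasiveness_index(colonization: float, prevalence: float) -> float:
    """Invasiveness = colonization x prevalence (both in %; index in [0, 10000])."""
    return colonization * prevalence


def invasiveness_rank(
    records: pd.DataFrame, exotic_species: list[str] | None = None
) -> pd.DataFrame:
    """Invasiveness table for the exotic species, ranked by descending index.

    Ties break by descending colonization, then species label.  Species absent
    everywhere get index 0 and rank last.
    """
    if "abundance" not in records.columns:
        records = add_abundance(records)
    if exotic_species is None:
        exotic_species = sorted(
            records.loc[records["origin"] == "exotic", "species"].unique()
        )
    if not exotic_species:
        raise ValueError("at least one exotic species is required")
    rows = []
    for sp in exotic_species:
        col, prev = colonization_prevalence(records, sp)
        idx = 0.0 if np.isnan(prev) else invasiveness_index(col, prev)
        rows.append(
            {
                "species": sp,
                "colonization": col,
                "prevalence": prev,
                "index": idx,
            }
        )
    table = pd.DataFrame(rows)
    table = table.sort_values(
        by=["index", "colonization", "species"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table
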