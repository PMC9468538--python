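"""Loaders for the printed-table fixtures shipped with the package.

The four tables distributed under ``mqtlhot/data`` carry the published study
summary, trait dictionary, the 20 selected hotspots with genetic and physical
CIs, and the per-hotspot syntenic target chromosomes.  They are small enough
to live in the package and let the selection rule and the summary code be
validated against real published rows without any download.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .hotspots import Hotspot, select_breeding
from .io_model import (
    TraitDictionary,
    count_trait_entries,
    load_studies,
    load_trait_dictionary,
    packaged_fixture,
)

__all__ = [
    "load_fixture_studies",
    "load_fixture_traits",
    "load_fixture_hotspots",
    "load_fixture_synteny",
    "paper_fixture_report",
]


def load_fixture_studies():
    return load_studies(packaged_fixture("studies_table1.tsv"))


def load_fixture_traits() -> TraitDictionary:
    return load_trait_dictionary(packaged_fixture("traits_table2.tsv"))


def load_fixture_hotspots() -> list[Hotspot]:
    """The 20 selected hotspots as :class:`Hotspot` objects.

    Member MTA ids are synthesized placeholders (the underlying per-MTA table
    is not published); counts, PVE means, traits and both physical CIs are the
    printed values.
    """
    df = pd.read_csv(packaged_fixture("hotspots_table3.tsv"), sep="\t", comment="#")
    out: list[Hotspot] = []
    for _, row in df.iterrows():
        n = int(row["n_mta"])
        out.append(
            Hotspot(
                hotspot_id=int(row["hotspot_id"]),
                chromosome=str(row["chromosome"]),
                ci_start_cM=float(row["ci_cm_start"]),
                ci_end_cM=float(row["ci_cm_end"]),
                member_ids=tuple(
                    f"h{row['hotspot_id']}_m{i + 1}" for i in range(n)
                ),
                traits=tuple(str(row["traits"]).split(",")),
                pve_mean=float(row["pve"]),
                physical_ci_Mb={
                    "Svevo": (
                        float(row["ci_svevo_start_mb"]),
                        float(row["ci_svevo_end_mb"]),
                    ),
                    "CS": (
                        float(row["ci_cs_start_mb"]),
                        float(row["ci_cs_end_mb"]),
                    ),
                },
            )
        )
    return out


def load_fixture_synteny() -> pd.DataFrame:
    df = pd.read_csv(packaged_fixture("synteny_table4.tsv"), sep="\t", comment="#")
    df["target_chromosomes"] = df["target_chromosomes"].map(
        lambda s: tuple(s.split(","))
    )
    return df


def paper_fixture_report() -> dict:
    """Recompute the fixture-level totals and the selection-rule outcome."""
    studies = load_fixture_studies()
    traits = load_fixture_traits()
    hotspots = load_fixture_hotspots()
    flagged = [select_breeding(h) for h in hotspots]
    synteny = load_fixture_synteny()
    pves = [h.pve_mean for h in hotspots if h.pve_mean is not None]
    return {
        "n_studies": len(studies),
        "total_genotypes": sum(s.size for s in studies),
        "n_mta_declared": sum(s.n_mta_declared for s in studies),
        "mean_mta_per_chromosome": round(sum(s.n_mta_declared for s in studies) / 14),
        "n_trait_entries": count_trait_entries(traits),
        "n_selected_hotspots": len(hotspots),
        "n_breeding": sum(h.is_breeding for h in flagged),
        "breeding_member_total": sum(h.n_mta for h in flagged if h.is_breeding),
        "breeding_pve_mean": round(sum(pves) / len(pves), 2),
        "n_hotspots_with_synteny": int(
            (synteny["target_chromosomes"].map(len) >= 1).sum()
        ),
    }
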