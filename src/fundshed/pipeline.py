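"""End-to-end orchestration: simulate → travel → allocate → access → classify.

One :func:`run_pipeline` call generates (or loads) a city, computes the
block-to-site walking-time matrix, allocates contract dollars to sites,
derives the three access measures, classifies tracts by hardship and
spending, and writes every stage's output plus a JSON manifest with
SHA-256 checksums. Re-running with the same config reproduces the stage
files byte for byte. :func:`build_report` renders the summary tables and
two figures from the stage outputs without recomputing anything.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import io as fio
from .access import access_2sfca, percent_with_access, supply_ratio
from .allocate import (
    allocate_all,
    container_funding,
    filter_contracts,
    funding_share_by_group,
)
from .classify import (
    TERCILE_LABELS,
    aggregate_to_tract,
    assign_spending_terciles,
    cross_classify,
    group_summary,
    hardship_index,
    tercile_classify,
)
from .errors import MissingStageError, SchemaError
from .synth import generate_scenario
from .travel import travel_time_matrix
from .types import Scenario, ScenarioConfig

logger = logging.getLogger(__name__)

STAGES = ("simulate", "travel", "allocate", "access", "classify")


@dataclass
class PipelineConfig:
    """Scenario parameters plus the analysis knobs of one run."""

    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    T: float = 30.0
    walk_speed_mph: float = 3.0
    hq_delivers: bool = True
    weighting: str = "unweighted"

    def validate(self) -> None:
        bad = []
        if self.T <= 0:
            bad.append("T")
        if self.walk_speed_mph <= 0:
            bad.append("walk_speed_mph")
        if self.weighting not in ("unweighted", "population"):
            bad.append("weighting")
        if bad:
            raise SchemaError(f"invalid analysis config keys: {bad}", bad)
        self.scenario.validate()

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario.to_dict(),
            "T": self.T,
            "walk_speed_mph": self.walk_speed_mph,
            "hq_delivers": self.hq_delivers,
            "weighting": self.weighting,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        scen = d.pop("scenario", {})
        known = {"T", "walk_speed_mph", "hq_delivers", "weighting"}
        stray = sorted(set(d) - known)
        if stray:
            raise SchemaError(f"unknown config keys: {stray}", stray)
        cfg = cls(scenario=ScenarioConfig.from_dict(scen), **d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise SchemaError("config must be a YAML mapping")
        return cls.from_dict(raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


@dataclass
class RunManifest:
    """Record of one pipeline run: config, per-stage files and checksums."""

    config: dict
    out_dir: str
    stages: dict[str, dict] = field(default_factory=dict)  # stage -> {file: sha256}
    warnings: dict[str, int] = field(default_factory=dict)

    def completed(self) -> list[str]:
        return [s for s in STAGES if s in self.stages]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"config": self.config, "out_dir": self.out_dir,
             "stages": self.stages, "warnings": self.warnings},
            indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        return cls(config=d["config"], out_dir=d["out_dir"],
                   stages=d["stages"], warnings=d["warnings"])


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _register(manifest: RunManifest, stage: str, out: Path, *names: str) -> None:
    manifest.stages[stage] = {n: _sha256(out / n) for n in names}


def run_pipeline(
    config: PipelineConfig | ScenarioConfig | str | Path,
    out_dir: str | Path,
    scenario: Scenario | None = None,
) -> RunManifest:
    """Execute all stages, writing outputs and a ``manifest.json``.

    ``config`` may be a :class:`PipelineConfig`, a bare
    :class:`ScenarioConfig` (default analysis knobs), or a path to a YAML
    file. A pre-built ``scenario`` skips generation (its config must
    match). On a stage failure the completed outputs and a partial
    manifest are preserved and the error re-raised.
    """
    if isinstance(config, (str, Path)):
        config = PipelineConfig.from_yaml(config)
    elif isinstance(config, ScenarioConfig):
        config = PipelineConfig(scenario=config)
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), out_dir=str(out))
    manifest_path = out / "manifest.json"

    try:
        # ---- simulate -------------------------------------------------
        scen = scenario if scenario is not None else generate_scenario(config.scenario)
        fio.write_network_geojson(scen.network, out / "network.geojson")
        fio.write_blocks_geojson(scen.blocks, scen.network, out / "blocks.geojson")
        fio.write_sites_geojson(scen.sites, scen.network, out / "sites.geojson")
        fio.write_tracts_csv(scen.tracts, out / "tracts.csv")
        fio.write_contracts_csv(scen.contracts, out / "contracts.csv")
        fio.write_config_yaml(scen.config, out / "scenario.yaml")
        _register(manifest, "simulate", out, "network.geojson", "blocks.geojson",
                  "sites.geojson", "tracts.csv", "contracts.csv", "scenario.yaml")
        logger.info("simulate: %d blocks, %d tracts, %d sites, %d contracts",
                    len(scen.blocks), len(scen.tracts), len(scen.sites),
                    len(scen.contracts))

        # ---- travel ---------------------------------------------------
        origins = {b.block_id: b.node_id for b in scen.blocks}
        dests = {s.site_id: s.node_id for s in scen.sites}
        matrix = travel_time_matrix(scen.network, origins, dests,
                                    config.walk_speed_mph)
        fio.write_matrix_csv(matrix, out / "matrix.csv.gz")
        _register(manifest, "travel", out, "matrix.csv.gz")
        n_unreach = int((~matrix.reachable).sum())
        manifest.warnings["unreachable_pairs"] = n_unreach
        logger.info("travel: %d x %d matrix, %d unreachable pairs",
                    len(origins), len(dests), n_unreach)

        # ---- allocate -------------------------------------------------
        by_provider: dict[str, list] = {}
        for s in scen.sites:
            by_provider.setdefault(s.provider_id, []).append(s)
        in_scope = filter_contracts(scen.contracts, by_provider)
        manifest.warnings["contracts_excluded"] = (
            len(scen.contracts) - len(in_scope)
        )
        allocations = allocate_all(in_scope, scen.sites, config.hq_delivers)
        fio.write_allocations_csv(allocations, out / "allocations.csv")

        # container funding per tract, both views
        site_area = _site_tract_membership(scen)
        tract_pop = _tract_populations(scen)
        cf_hq = container_funding(allocations, in_scope, scen.sites, site_area,
                                  "hq_only", tract_pop)
        cf_all = container_funding(allocations, in_scope, scen.sites, site_area,
                                   "all_sites", tract_pop)
        fio.write_area_funding_csv(cf_hq.areas, out / "area_funding_hq_only.csv")
        fio.write_area_funding_csv(cf_all.areas, out / "area_funding_all_sites.csv")
        manifest.warnings["sites_without_area"] = cf_all.skipped_sites
        _register(manifest, "allocate", out, "allocations.csv",
                  "area_funding_hq_only.csv", "area_funding_all_sites.csv")
        logger.info("allocate: %d in-scope contracts -> %d allocations",
                    len(in_scope), len(allocations))

        # ---- access ---------------------------------------------------
        from .allocate import site_supply as _site_supply

        supply = _site_supply(allocations)
        pops = scen.block_populations()
        ratios = supply_ratio(supply, matrix, pops, config.T)
        manifest.warnings["zero_demand_sites"] = sum(r.zero_demand for r in ratios)
        block_access = access_2sfca(ratios, matrix, config.T)
        pd.DataFrame(
            [{"block_id": b.block_id, "program_type": b.program_type,
              "a_2sfca": b.a_2sfca, "nearest_minutes": b.nearest_minutes,
              "n_within": b.n_within} for b in block_access]
        ).to_csv(out / "block_access.csv", index=False)
        manifest.warnings["blocks_unreachable"] = sum(
            1 for b in block_access if b.nearest_minutes is None
        )
        _register(manifest, "access", out, "block_access.csv")

        # ---- classify -------------------------------------------------
        idx = hardship_index({t.tract_id: t.components for t in scen.tracts})
        hardship = tercile_classify(idx)
        tract_access = aggregate_to_tract(
            block_access, scen.block_to_tract(), config.weighting, pops
        )
        assign_spending_terciles(tract_access)
        pd.DataFrame(
            [{"tract_id": t.tract_id, "hardship_index": idx[t.tract_id],
              "hardship_tercile": hardship[t.tract_id],
              "mean_a_2sfca": t.mean_a_2sfca,
              "mean_nearest_minutes": t.mean_nearest_minutes,
              "mean_n_within": t.mean_n_within,
              "percent_with_access": t.percent_with_access,
              "spending_tercile": t.spending_tercile}
             for t in tract_access]
        ).to_csv(out / "tract_table.csv", index=False)

        summary = group_summary(
            tract_access, hardship, cf_all.by_area(), tract_pop
        )
        summary.to_csv(out / "group_summary.csv")

        shares = pd.DataFrame({
            "hq_only": funding_share_by_group(cf_hq.areas, hardship),
            "all_sites": funding_share_by_group(cf_all.areas, hardship),
        }).reindex(list(TERCILE_LABELS))
        shares.index.name = "hardship"
        shares.to_csv(out / "funding_shares.csv")

        xtab = cross_classify(
            hardship, {t.tract_id: t.spending_tercile for t in tract_access}
        )
        xtab.to_csv(out / "cross_classification.csv")
        _register(manifest, "classify", out, "tract_table.csv",
                  "group_summary.csv", "funding_shares.csv",
                  "cross_classification.csv")
    finally:
        manifest.save(manifest_path)
        if len(manifest.completed()) < len(STAGES):
            logger.error("pipeline stopped after stages: %s", manifest.completed())
    return manifest


def _site_tract_membership(scen: Scenario) -> dict[str, str]:
    """Tract of each site: the tract owning a block on the site's node.

    Sites on nodes hosting no block are assigned the tract of the nearest
    block node (planar distance); synthetic sites always sit on block
    nodes so this fallback only fires for externally supplied data.
    """
    node_tract: dict[int, str] = {}
    for b in scen.blocks:
        node_tract.setdefault(b.node_id, b.tract_id)
    out = {}
    block_nodes = sorted(node_tract)
    for s in scen.sites:
        if s.node_id in node_tract:
            out[s.site_id] = node_tract[s.node_id]
        elif block_nodes:
            sx, sy = scen.network.coords(s.node_id)
            best = min(
                block_nodes,
                key=lambda n: (scen.network.coords(n)[0] - sx) ** 2
                + (scen.network.coords(n)[1] - sy) ** 2,
            )
            out[s.site_id] = node_tract[best]
    return out


def _tract_populations(scen: Scenario) -> dict[str, int]:
    pops: dict[str, int] = {}
    for b in scen.blocks:
        pops[b.tract_id] = pops.get(b.tract_id, 0) + b.population
    return pops


def build_report(manifest: RunManifest | str | Path, report_dir: str | Path | None = None):
    """Render the report tables and figures from a completed run.

    Reads only the stage CSVs (no recomputation): a funding-share table
    (hq_only vs all_sites × hardship group), a per-capita table, the
    group summaries and the hardship × spending cross-classification,
    plus a bar chart of the funding shares and boxplots of tract-level
    funded access by hardship group. Dollars are rounded to whole dollars
    and shares to one decimal at render time only.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(manifest, (str, Path)):
        p = Path(manifest)
        manifest = RunManifest.load(p if p.name.endswith(".json") else p / "manifest.json")
    missing = [s for s in STAGES if s not in manifest.stages]
    if missing:
        raise MissingStageError(f"manifest missing stages: {missing}")
    out = Path(manifest.out_dir)
    rep = Path(report_dir) if report_dir is not None else out / "report"
    rep.mkdir(parents=True, exist_ok=True)

    shares = pd.read_csv(out / "funding_shares.csv", index_col=0)
    shares.round(1).to_csv(rep / "funding_share_table.csv")

    summary = pd.read_csv(out / "group_summary.csv", index_col=0)
    percap_cols = [c for c in ("dollars", "population", "dollars_per_capita")
                   if c in summary.columns]
    percap = summary[percap_cols].copy()
    if "dollars" in percap:
        percap["dollars"] = percap["dollars"].round(0)
    if "dollars_per_capita" in percap:
        percap["dollars_per_capita"] = percap["dollars_per_capita"].round(2)
    percap.to_csv(rep / "per_capita_table.csv")
    summary.to_csv(rep / "group_summary_table.csv")

    xtab = pd.read_csv(out / "cross_classification.csv", index_col=0)
    xtab.to_csv(rep / "cross_classification_table.csv")

    # figure 1: funding share bars, hq_only vs all_sites
    fig, ax = plt.subplots(figsize=(6, 4))
    shares.plot.bar(ax=ax, rot=0)
    ax.set_ylabel("share of in-scope funding (%)")
    ax.set_xlabel("hardship tercile")
    ax.set_title("Funding share by hardship group: HQ-only vs all sites")
    fig.tight_layout()
    fig.savefig(rep / "funding_shares.png", dpi=120)
    plt.close(fig)

    # figure 2: tract-level funded access boxplots by hardship group
    tract = pd.read_csv(out / "tract_table.csv")
    fig, ax = plt.subplots(figsize=(6, 4))
    data = [tract.loc[tract["hardship_tercile"] == g, "mean_a_2sfca"]
            for g in TERCILE_LABELS]
    ax.boxplot(data, tick_labels=list(TERCILE_LABELS), showfliers=False)
    ax.set_ylabel("funded access A_i ($/person within 30-min walk)")
    ax.set_xlabel("hardship tercile")
    ax.set_title("Tract-mean funded access by hardship group")
    fig.tight_layout()
    fig.savefig(rep / "access_boxplots.png", dpi=120)
    plt.close(fig)

    return rep
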