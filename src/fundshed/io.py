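"""Readers and writers for the on-disk formats.

Spatial layers travel as GeoJSON FeatureCollections (Point nodes / blocks
/ sites, LineString edges with a ``length_m`` property); tabular data as
CSV via pandas; travel matrices as long-form CSV with an optional gzip
suffix; scenario configs as YAML. Coordinates are planar meters
throughout — no CRS handling is needed or attempted.
"""

from __future__ import annotations

import gzip
import json
import math
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .allocate import AreaFunding, SiteAllocation
from .errors import SchemaError
from .travel import TravelTimeMatrix
from .types import (
    HARDSHIP_COMPONENTS,
    CensusTract,
    Contract,
    HousingBlock,
    ProgramType,
    ScenarioConfig,
    ServiceSite,
    StreetNetwork,
)


def _feature(geometry: dict, properties: dict) -> dict:
    return {"type": "Feature", "geometry": geometry, "properties": properties}


def _collection(features: list[dict]) -> dict:
    return {"type": "FeatureCollection", "features": features}


def _write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, separators=(",", ":")) + "\n")


# ---------------------------------------------------------------- network

def write_network_geojson(network: StreetNetwork, path: str | Path) -> None:
    feats = []
    for n in network.nodes():
        x, y = network.coords(n)
        feats.append(_feature({"type": "Point", "coordinates": [x, y]},
                              {"kind": "node", "node_id": n}))
    for u, v, d in sorted(network.graph.edges(data=True),
                          key=lambda e: tuple(sorted(e[:2]))):
        a, b = sorted((u, v))
        feats.append(_feature(
            {"type": "LineString",
             "coordinates": [list(network.coords(a)), list(network.coords(b))]},
            {"kind": "edge", "node_a": a, "node_b": b,
             "length_m": float(d["length_m"])},
        ))
    _write_json(_collection(feats), path)


def read_network_geojson(path: str | Path) -> StreetNetwork:
    fc = json.loads(Path(path).read_text())
    g = nx.Graph()
    for f in fc["features"]:
        p = f.get("properties", {})
        if p.get("kind") == "node":
            x, y = f["geometry"]["coordinates"]
            g.add_node(p["node_id"], x=float(x), y=float(y))
    for f in fc["features"]:
        p = f.get("properties", {})
        if p.get("kind") == "edge":
            g.add_edge(p["node_a"], p["node_b"], length_m=float(p["length_m"]))
    return StreetNetwork(g)


# ----------------------------------------------------------- point layers

def write_blocks_geojson(
    blocks: Sequence[HousingBlock], network: StreetNetwork, path: str | Path
) -> None:
    feats = []
    for b in blocks:
        x, y = network.coords(b.node_id)
        feats.append(_feature(
            {"type": "Point", "coordinates": [x, y]},
            {"block_id": b.block_id, "node_id": b.node_id,
             "population": b.population, "tract_id": b.tract_id},
        ))
    _write_json(_collection(feats), path)


def read_blocks_geojson(path: str | Path) -> list[HousingBlock]:
    fc = json.loads(Path(path).read_text())
    return [
        HousingBlock(
            block_id=f["properties"]["block_id"],
            node_id=f["properties"]["node_id"],
            population=int(f["properties"]["population"]),
            tract_id=f["properties"].get("tract_id", ""),
        )
        for f in fc["features"]
    ]


def write_sites_geojson(
    sites: Sequence[ServiceSite], network: StreetNetwork, path: str | Path
) -> None:
    feats = []
    for s in sites:
        x, y = network.coords(s.node_id)
        props = {"site_id": s.site_id, "provider_id": s.provider_id,
                 "node_id": s.node_id, "is_headquarter": s.is_headquarter}
        if s.community_areas_served is not None:
            props["community_areas_served"] = "|".join(s.community_areas_served)
        feats.append(_feature({"type": "Point", "coordinates": [x, y]}, props))
    _write_json(_collection(feats), path)


def read_sites_geojson(path: str | Path) -> list[ServiceSite]:
    fc = json.loads(Path(path).read_text())
    out = []
    for f in fc["features"]:
        p = f["properties"]
        cas = p.get("community_areas_served")
        out.append(ServiceSite(
            site_id=p["site_id"], provider_id=p["provider_id"],
            node_id=p["node_id"], is_headquarter=bool(p["is_headquarter"]),
            community_areas_served=tuple(cas.split("|")) if cas else None,
        ))
    return out


# ------------------------------------------------------------- CSV tables

def write_tracts_csv(tracts: Sequence[CensusTract], path: str | Path) -> None:
    rows = []
    for t in tracts:
        row = {"tract_id": t.tract_id, "block_ids": "|".join(t.block_ids)}
        row.update({c: t.components[c] for c in HARDSHIP_COMPONENTS})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tracts_csv(path: str | Path) -> list[CensusTract]:
    df = pd.read_csv(path)
    return [
        CensusTract(
            tract_id=str(r["tract_id"]),
            block_ids=tuple(str(r["block_ids"]).split("|")),
            components={c: float(r[c]) for c in HARDSHIP_COMPONENTS},
        )
        for _, r in df.iterrows()
    ]


def _shares_to_str(shares: dict[str, float] | None) -> str:
    if shares is None:
        return ""
    return "|".join(f"{sid}:{frac!r}" for sid, frac in sorted(shares.items()))


def _shares_from_str(s: str) -> dict[str, float] | None:
    if not s or (isinstance(s, float) and math.isnan(s)):
        return None
    out = {}
    for part in str(s).split("|"):
        sid, frac = part.rsplit(":", 1)
        out[sid] = float(frac)
    return out


def write_contracts_csv(contracts: Sequence[Contract], path: str | Path) -> None:
    rows = [
        {"contract_id": c.contract_id, "provider_id": c.provider_id,
         "amount": c.amount, "program_type": c.program_type.value,
         "citywide": c.citywide, "site_shares": _shares_to_str(c.site_shares)}
        for c in contracts
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_contracts_csv(path: str | Path) -> list[Contract]:
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    return [
        Contract(
            contract_id=str(r["contract_id"]), provider_id=str(r["provider_id"]),
            amount=float(r["amount"]),
            program_type=ProgramType(r["program_type"]),
            site_shares=_shares_from_str(r["site_shares"]),
            citywide=str(r["citywide"]).lower() in ("true", "1"),
        )
        for _, r in df.iterrows()
    ]


def write_allocations_csv(
    allocations: Sequence[SiteAllocation], path: str | Path
) -> None:
    pd.DataFrame(
        [{"site_id": a.site_id, "contract_id": a.contract_id, "amount": a.amount}
         for a in allocations]
    ).to_csv(path, index=False)


def read_allocations_csv(path: str | Path) -> list[SiteAllocation]:
    df = pd.read_csv(path)
    return [
        SiteAllocation(site_id=str(r["site_id"]), contract_id=str(r["contract_id"]),
                       amount=float(r["amount"]))
        for _, r in df.iterrows()
    ]


def write_area_funding_csv(areas: Sequence[AreaFunding], path: str | Path) -> None:
    pd.DataFrame(
        [{"area_id": a.area_id, "dollars": a.dollars, "population": a.population,
          "dollars_per_capita": a.dollars_per_capita}
         for a in areas]
    ).to_csv(path, index=False)


# ----------------------------------------------------------- travel matrix

def write_matrix_csv(matrix: TravelTimeMatrix, path: str | Path) -> None:
    """Long-form (origin_id, dest_id, minutes, reachable); gzip if *.gz."""
    path = Path(path)
    lines = ["origin_id,dest_id,minutes,reachable"]
    for i, oid in enumerate(matrix.origin_ids):
        for j, did in enumerate(matrix.dest_ids):
            t = matrix.minutes[i, j]
            if math.isfinite(t):
                lines.append(f"{oid},{did},{float(t)!r},True")
            else:
                lines.append(f"{oid},{did},,False")
    data = ("\n".join(lines) + "\n").encode()
    if path.suffix == ".gz":
        # mtime=0 keeps the gzip container byte-reproducible across runs
        with open(path, "wb") as raw, gzip.GzipFile(
            fileobj=raw, mode="wb", mtime=0
        ) as fh:
            fh.write(data)
    else:
        path.write_bytes(data)


def read_matrix_csv(path: str | Path) -> TravelTimeMatrix:
    path = Path(path)
    # round_trip float parsing: times must survive write/read bit-exactly
    df = pd.read_csv(path, float_precision="round_trip")
    origin_ids = list(dict.fromkeys(df["origin_id"]))
    dest_ids = list(dict.fromkeys(df["dest_id"]))
    o_pos = {o: i for i, o in enumerate(origin_ids)}
    d_pos = {d: j for j, d in enumerate(dest_ids)}
    minutes = np.full((len(origin_ids), len(dest_ids)), math.inf)
    reach = df["reachable"].astype(bool).to_numpy()
    vals = df["minutes"].to_numpy()
    for k in range(len(df)):
        if reach[k]:
            minutes[o_pos[df["origin_id"].iat[k]], d_pos[df["dest_id"].iat[k]]] = vals[k]
    return TravelTimeMatrix(origin_ids=origin_ids, dest_ids=dest_ids, minutes=minutes)


# ----------------------------------------------------------------- config

def write_config_yaml(config: ScenarioConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def read_config_yaml(path: str | Path) -> ScenarioConfig:
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as e:
        raise SchemaError(f"config is not valid YAML: {e}") from e
    if not isinstance(raw, dict):
        raise SchemaError("config must be a YAML mapping")
    try:
        cfg = ScenarioConfig.from_dict(raw)
    except (TypeError, ValueError) as e:
        if isinstance(e, SchemaError):
            raise
        raise SchemaError(f"invalid config: {e}") from e
    return cfg
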