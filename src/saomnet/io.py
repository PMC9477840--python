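"""CSV input/output for village data.

Formats are deliberately plain: an actor table (one row per actor, with a
``label`` column, a ``household`` column and one column per covariate),
labelled square CSV matrices for dyadic covariates, and ``source,target``
edge lists for networks. Tie matrices must be explicit 0/1 — missing
entries are an error, never imputed.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from .network import (
    ActorCovariate,
    DirectedNetwork,
    DyadCovariate,
    HouseholdAssignment,
    VillageData,
)

__all__ = ["read_village", "write_village", "read_edge_list", "write_edge_list"]

_SYMMETRIC_DYADS = {"consanguineal", "affinal", "godparent", "infidelity", "distance"}
_BINARY_ACTOR_COVS = {"gender", "ethnicity"}


def read_edge_list(path: str, labels: list[str], observation_label: str = "") -> DirectedNetwork:
    """Read a ``source,target`` CSV edge list into a DirectedNetwork."""
    df = pd.read_csv(path, dtype=str)
    if not {"source", "target"} <= set(df.columns):
        raise ValueError(f"{path}: edge list needs 'source' and 'target' columns")
    index = {lab: k for k, lab in enumerate(labels)}
    n = len(labels)
    x = np.zeros((n, n), dtype=np.int8)
    for row, (s, t) in enumerate(zip(df["source"], df["target"]), start=2):
        if s not in index or t not in index:
            bad = s if s not in index else t
            raise ValueError(f"{path} row {row}: unknown actor identifier {bad!r}")
        if s == t:
            raise ValueError(f"{path} row {row}: self-tie {s!r} not allowed")
        x[index[s], index[t]] = 1
    return DirectedNetwork(x, list(labels), observation_label)


def write_edge_list(net: DirectedNetwork, path: str) -> None:
    src, dst = np.nonzero(net.ties)
    pd.DataFrame(
        {"source": [net.labels[i] for i in src], "target": [net.labels[j] for j in dst]}
    ).to_csv(path, index=False)


def _read_matrix(path: str, labels: list[str]) -> np.ndarray:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    missing = set(labels) - set(df.index)
    extra = set(df.index) - set(labels)
    if missing or extra:
        raise ValueError(
            f"{path}: actor set mismatch (missing {sorted(missing)}, unknown {sorted(extra)})"
        )
    df = df.loc[labels, labels]
    if df.isna().any().any():
        raise ValueError(f"{path}: missing entries are not allowed")
    return df.to_numpy(dtype=float)


def read_village(
    actor_table_path: str,
    dyad_matrix_paths: dict[str, str],
    edge_list_paths: dict[str, str],
    absent_actors: set[str] | None = None,
) -> VillageData:
    """Assemble a VillageData from CSV files.

    ``edge_list_paths`` may contain the keys ``giver``, ``receiver`` and
    ``verified``. Actor identifiers must be consistent across all files;
    unknown identifiers are a hard error naming the offender.
    """
    actors = pd.read_csv(actor_table_path, dtype={"label": str, "household": str})
    if "label" not in actors.columns or "household" not in actors.columns:
        raise ValueError(f"{actor_table_path}: needs 'label' and 'household' columns")
    labels = actors["label"].tolist()
    if len(set(labels)) != len(labels):
        raise ValueError(f"{actor_table_path}: duplicate actor labels")
    households = HouseholdAssignment(
        pd.factorize(actors["household"])[0]
    )
    # optional sidecar records which covariates are already standardised
    scaling = {}
    meta_path = os.path.join(os.path.dirname(actor_table_path), "covariate_meta.json")
    if os.path.exists(meta_path):
        with open(meta_path) as fh:
            scaling = json.load(fh)
    acov = {}
    for col in actors.columns:
        if col in ("label", "household"):
            continue
        vals = pd.to_numeric(actors[col], errors="raise").to_numpy(dtype=float)
        acov[col] = ActorCovariate(col, vals, scaling.get(col, "raw"))

    dcov = {}
    for name, path in dyad_matrix_paths.items():
        dcov[name] = DyadCovariate(name, _read_matrix(path, labels),
                                   symmetric=name in _SYMMETRIC_DYADS)

    nets: dict[str, DirectedNetwork | None] = {"giver": None, "receiver": None, "verified": None}
    for key, path in edge_list_paths.items():
        if key not in nets:
            raise ValueError(f"unknown edge list role {key!r}; use giver/receiver/verified")
        nets[key] = read_edge_list(path, labels)

    return VillageData(
        giver_reports=nets["giver"],
        receiver_reports=nets["receiver"],
        verified=nets["verified"],
        actor_covariates=acov,
        dyad_covariates=dcov,
        households=households,
        absent_actors=set(absent_actors or ()),
        labels=labels,
    )


def write_village(village: VillageData, directory: str) -> dict[str, object]:
    """Write a village to CSV files; returns the path arguments for read_village."""
    os.makedirs(directory, exist_ok=True)
    actors = pd.DataFrame({"label": village.labels})
    actors["household"] = [f"h{h}" for h in village.households.ids]
    for name, cov in village.actor_covariates.items():
        actors[name] = cov.values
    actor_path = os.path.join(directory, "actors.csv")
    actors.to_csv(actor_path, index=False)
    with open(os.path.join(directory, "covariate_meta.json"), "w") as fh:
        json.dump({name: cov.scaling for name, cov in village.actor_covariates.items()},
                  fh, indent=1)

    dyad_paths = {}
    for name, cov in village.dyad_covariates.items():
        path = os.path.join(directory, f"dyad_{name}.csv")
        pd.DataFrame(cov.values, index=village.labels, columns=village.labels).to_csv(path)
        dyad_paths[name] = path

    edge_paths = {}
    for key, net in (("giver", village.giver_reports),
                     ("receiver", village.receiver_reports),
                     ("verified", village.verified)):
        if net is not None:
            path = os.path.join(directory, f"edges_{key}.csv")
            write_edge_list(net, path)
            edge_paths[key] = path
    return {
        "actor_table_path": actor_path,
        "dyad_matrix_paths": dyad_paths,
        "edge_list_paths": edge_paths,
        "absent_actors": set(village.absent_actors),
    }
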