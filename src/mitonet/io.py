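"""Readers and writers for the pipeline's table dialects.

Every table is tab-delimited UTF-8 with a header row.  Readers validate
schemas strictly and report malformed rows with their line number (header
is line 1).  Dialects:

* abundance: ``protein_id, protein_ratio`` (+ optional ``regulation``)
* reference catalog: ``protein_id, set_name`` (set name ``CC`` reserved
  for the cellular-component annotation)
* links: ``protein_a, protein_b, confidence, channel``
* annotations: ``protein_id, term_id``
* expression: genes x samples intensity matrix with an identically shaped
  detection-p matrix (first column ``gene_id``)
* modules / profiles: long-format exports of the analysis results
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path
from typing import Dict, Mapping, Tuple

import pandas as pd

from .reliability import CHANNELS, ReferenceCatalog
from .synthworld import CC_SET_NAME, World, WorldConfig


def _read_tsv(path, expected_columns) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns)[: len(expected_columns)] != list(expected_columns):
        raise ValueError(
            f"{path}: expected columns {list(expected_columns)}, got {list(df.columns)}"
        )
    return df


def _reject(path, line_no: int, message: str):
    raise ValueError(f"{path}, line {line_no}: {message}")


def read_abundance(path) -> pd.DataFrame:
    """Read an abundance table; empty ratio fields become NaN (droppable)."""
    df = _read_tsv(path, ("protein_id", "protein_ratio"))
    ratios = []
    for i, raw in enumerate(df["protein_ratio"]):
        line = i + 2
        if raw == "":
            ratios.append(math.nan)
            continue
        try:
            value = float(raw)
        except ValueError:
            _reject(path, line, f"non-numeric protein_ratio {raw!r}")
        if not math.isfinite(value) or value <= 0:
            _reject(path, line, f"protein_ratio must be positive and finite, got {raw!r}")
        ratios.append(value)
    out = pd.DataFrame({"protein_id": df["protein_id"], "protein_ratio": ratios})
    if "regulation" in df.columns:
        out["regulation"] = df["regulation"]
    return out


def write_abundance(table: pd.DataFrame, path) -> None:
    cols = ["protein_id", "protein_ratio"]
    if "regulation" in table.columns:
        cols.append("regulation")
    table[cols].to_csv(path, sep="\t", index=False)


def read_catalog(path) -> ReferenceCatalog:
    df = _read_tsv(path, ("protein_id", "set_name"))
    cc = set()
    sets: Dict[str, set] = {}
    for i, (pid, name) in enumerate(zip(df["protein_id"], df["set_name"])):
        if not pid or not name:
            _reject(path, i + 2, "empty protein_id or set_name")
        if name == CC_SET_NAME:
            cc.add(pid)
        else:
            sets.setdefault(name, set()).add(pid)
    return ReferenceCatalog(
        cc_annotated=frozenset(cc),
        reference_sets={k: frozenset(v) for k, v in sorted(sets.items())},
    )


def write_catalog(catalog: ReferenceCatalog, path) -> None:
    rows = [(pid, CC_SET_NAME) for pid in sorted(catalog.cc_annotated)]
    for name in sorted(catalog.reference_sets):
        rows.extend((pid, name) for pid in sorted(catalog.reference_sets[name]))
    pd.DataFrame(rows, columns=["protein_id", "set_name"]).to_csv(
        path, sep="\t", index=False
    )


def read_links(path) -> pd.DataFrame:
    df = _read_tsv(path, ("protein_a", "protein_b", "confidence", "channel"))
    seen = set()
    confidences = []
    for i, (a, b, conf, channel) in enumerate(
        zip(df["protein_a"], df["protein_b"], df["confidence"], df["channel"])
    ):
        line = i + 2
        if a == b:
            _reject(path, line, f"self-link on {a!r}")
        try:
            value = float(conf)
        except ValueError:
            _reject(path, line, f"non-numeric confidence {conf!r}")
        if not (0.0 <= value <= 1.0):
            _reject(path, line, f"confidence {conf!r} outside [0, 1]")
        if channel not in CHANNELS:
            _reject(path, line, f"unknown channel {channel!r}")
        key = (min(a, b), max(a, b), channel)
        if key in seen:
            _reject(path, line, f"duplicate link {a!r}-{b!r} in channel {channel!r}")
        seen.add(key)
        confidences.append(value)
    out = df.copy()
    out["confidence"] = confidences
    return out


def write_links(links: pd.DataFrame, path) -> None:
    links[["protein_a", "protein_b", "confidence", "channel"]].to_csv(
        path, sep="\t", index=False
    )


def read_annotations(path) -> pd.DataFrame:
    df = _read_tsv(path, ("protein_id", "term_id"))
    for i, (pid, term) in enumerate(zip(df["protein_id"], df["term_id"])):
        if not pid or not term:
            _reject(path, i + 2, "empty protein_id or term_id")
    return df


def write_annotations(annotations: pd.DataFrame, path) -> None:
    annotations[["protein_id", "term_id"]].to_csv(path, sep="\t", index=False)


def _read_matrix(path, positive: bool) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.columns[0] != "gene_id":
        raise ValueError(f"{path}: first column must be gene_id")
    matrix = raw.set_index("gene_id")
    out = {}
    for col in matrix.columns:
        values = []
        for i, raw_value in enumerate(matrix[col]):
            line = i + 2
            try:
                value = float(raw_value)
            except ValueError:
                _reject(path, line, f"non-numeric value {raw_value!r} in column {col}")
            if positive and value <= 0:
                _reject(path, line, f"intensity must be positive, got {raw_value!r}")
            if not positive and not (0.0 <= value <= 1.0):
                _reject(path, line, f"detection p {raw_value!r} outside [0, 1]")
            values.append(value)
        out[col] = values
    result = pd.DataFrame(out, index=matrix.index)
    result.index.name = "gene_id"
    return result


def read_expression(matrix_path, detection_path) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Read intensity and detection-p matrices and check they align."""
    intensities = _read_matrix(matrix_path, positive=True)
    detection = _read_matrix(detection_path, positive=False)
    if not intensities.index.equals(detection.index) or list(
        intensities.columns
    ) != list(detection.columns):
        raise ValueError("intensity and detection-p matrices are not aligned")
    return intensities, detection


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index=True, index_label="gene_id")


def write_modules(modules, path) -> None:
    from .module_finder import modules_table

    modules_table(modules).to_csv(path, sep="\t", index=False)


def write_profiles(profiles: pd.DataFrame, path) -> None:
    profiles.to_csv(path, sep="\t", index=False)


def config_hash(config: WorldConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_world(world: World, outdir) -> Dict[str, str]:
    """Serialize a synthetic world to a directory; returns the manifest.

    Writes the five input tables, the planted truth, the condition map, and
    a ``manifest.json`` listing paths, the seed, and a config hash.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "abundance": "abundance.tsv",
        "catalog": "catalog.tsv",
        "links": "links.tsv",
        "annotations": "annotations.tsv",
        "intensities": "intensities.tsv",
        "detection_p": "detection_p.tsv",
        "truth": "truth.tsv",
    }
    write_abundance(world.abundance, outdir / paths["abundance"])
    write_catalog(world.catalog, outdir / paths["catalog"])
    write_links(world.links, outdir / paths["links"])
    write_annotations(world.annotations, outdir / paths["annotations"])
    write_matrix(world.intensities, outdir / paths["intensities"])
    write_matrix(world.detection_p, outdir / paths["detection_p"])
    world.truth.to_csv(outdir / paths["truth"], sep="\t", index=False)
    manifest = {
        "paths": paths,
        "seed": world.config.seed,
        "config_hash": config_hash(world.config),
        "config": dataclasses.asdict(world.config),
        "conditions": world.conditions,
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
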