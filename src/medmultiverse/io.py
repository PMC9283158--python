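"""Dataset/config readers, results writers, and run manifests."""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .engine import AnalysisConfig, MultiverseResult, default_config, summarize_verdicts

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"  # six significant digits everywhere, for byte-stable output


def read_dataset(
    path: str | Path,
    role_map: Mapping[str, str] | None = None,
    categorical_roles: Sequence[str] = (),
) -> pd.DataFrame:
    """Read a subject-per-row CSV and type-check the mapped columns.

    ``role_map`` maps role names (determinant, mediator, outcome,
    confounder names, ...) to column names; every mapped column must exist
    and, unless its role is listed in ``categorical_roles``, must be
    numeric.  Non-numeric values in a numeric role raise with the offending
    row indices.  Row count and per-column missingness are logged.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        header = next(csv.reader(fh))
    dupes = {c for c in header if header.count(c) > 1}
    if dupes:
        raise ValueError(f"duplicated column names in {path}: {sorted(dupes)}")

    frame = pd.read_csv(path)
    logger.info("read %d rows x %d columns from %s", *frame.shape, path)
    roles = dict(role_map or {})
    missing_cols = [c for c in roles.values() if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"mapped columns absent from {path}: {missing_cols}")

    categorical_cols = {roles[r] for r in categorical_roles if r in roles}
    for role, col in roles.items():
        if col in categorical_cols:
            continue
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[frame[col].notna() & coerced.isna()]
        if len(bad):
            raise ValueError(
                f"non-numeric values in numeric role {role!r} "
                f"(column {col!r}) at rows {list(bad[:10])}"
            )
        frame[col] = coerced
    for col in frame.columns:
        miss = float(frame[col].isna().mean())
        if miss > 0:
            logger.info("column %s: %.1f%% missing", col, 100 * miss)
    return frame


def missingness_report(frame: pd.DataFrame) -> dict[str, float]:
    """Per-column fraction of missing values."""
    return {col: float(frame[col].isna().mean()) for col in frame.columns}


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an analysis configuration from YAML or JSON.

    The file may override any :class:`AnalysisConfig` field; unspecified
    fields fall back to the synthetic-cohort defaults.  Lists are accepted
    for the confounder sets.
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = set(AnalysisConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
    for key in ("confounders_full", "confounders_hormonal"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return default_config(**raw)


@dataclass
class RunManifest:
    """Provenance record written next to every set of results."""

    manifest_id: str
    config_hash: str
    data_fingerprint: str
    seed: int
    software_version: str
    created: str
    n_universes: int = 0
    warning_count: int = 0
    extra: dict = field(default_factory=dict)


def _hash(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def data_fingerprint(frame: pd.DataFrame) -> str:
    """Shape/column/content digest of a dataset (NaN-stable)."""
    h = hashlib.sha256()
    h.update(repr(list(frame.columns)).encode())
    h.update(np.ascontiguousarray(frame.to_numpy(float)).tobytes())
    return h.hexdigest()[:16]


def build_manifest(
    result: MultiverseResult, data: pd.DataFrame
) -> RunManifest:
    config_hash = _hash(json.dumps(asdict(result.config), sort_keys=True, default=str))
    fingerprint = data_fingerprint(
        data.select_dtypes(include=[np.number])
    )
    warning_count = int((result.table["warning"].fillna("") != "").sum())
    return RunManifest(
        manifest_id=_hash(config_hash + fingerprint + str(result.config.seed)),
        config_hash=config_hash,
        data_fingerprint=fingerprint,
        seed=result.config.seed,
        software_version=__version__,
        created=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        n_universes=len(result.universes),
        warning_count=warning_count,
    )


def write_results(
    result: MultiverseResult,
    manifest: RunManifest,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write results.csv (long format, stable column order, 6-significant-
    digit floats), summary.json and manifest.json.  Reruns on identical
    inputs produce byte-identical results.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "results": out / "results.csv",
        "summary": out / "summary.json",
        "manifest": out / "manifest.json",
    }
    table = result.table
    if table.empty:
        logger.warning("empty multiverse result; writing header-only CSV")
        pd.DataFrame(columns=table.columns).to_csv(paths["results"], index=False)
    else:
        table.to_csv(paths["results"], index=False, float_format=FLOAT_FORMAT)

    summary = summarize_verdicts(result).as_dict() if not table.empty else {}
    summary["manifest_id"] = manifest.manifest_id
    paths["summary"].write_text(json.dumps(summary, indent=2, sort_keys=True))
    manifest_dict = asdict(manifest)
    paths["manifest"].write_text(json.dumps(manifest_dict, indent=2, sort_keys=True))
    return paths


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a results.csv written by :func:`write_results`."""
    return pd.read_csv(path)
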