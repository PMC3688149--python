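"""Shared fixtures: a tiny worked-example source and the full synthetic
pipeline (generated once per session, migrated and bridged)."""

from __future__ import annotations

import csv
import os
import random
from dataclasses import dataclass
from typing import Dict, List

import pytest
from hypothesis import HealthCheck, settings as hyp_settings

hyp_settings.register_profile(
    "deterministic",
    derandomize=True,
    database=None,
    suppress_health_check=[HealthCheck.too_slow],
)
hyp_settings.load_profile("deterministic")

from iptrans.bridge import BridgeView
from iptrans.cdbmodel import (
    ClinicalDatabaseModel,
    SourceColumn,
    SourceReader,
    SourceSchema,
    SourceTable,
)
from iptrans.etl import MigrationConfig
from iptrans.pipeline import run_migration
from iptrans.store import Store, init_store
from iptrans.synthdata import SynthSpec, default_config, generate_cdb


@pytest.fixture
def tmp_store(tmp_path) -> Store:
    store = init_store(str(tmp_path / "store.db"))
    yield store
    store.close()


def write_csv(path, header, rows) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(header)
        w.writerows(rows)


@dataclass
class TinySource:
    """The worked example: one patient with age/height/weight plus a
    three-drug prescription (Carboplatin with a dosage, Decadron,
    Furosemide)."""

    dir: str
    db_name: str
    config: MigrationConfig


@pytest.fixture
def tiny_source(tmp_path) -> TinySource:
    src = tmp_path / "cdb"
    src.mkdir()
    write_csv(
        src / "patient.csv",
        ["id", "age", "height", "weight"],
        [["9", "58", "1.72", "80.0"]],
    )
    write_csv(
        src / "prescription.csv",
        ["id", "patient_id", "drug", "dosage"],
        [
            ["1", "9", "Carboplatin", "50 mg"],
            ["2", "9", "Decadron", ""],
            ["3", "9", "Furosemide", ""],
        ],
    )
    return TinySource(
        dir=str(src),
        db_name="CDB",
        config=MigrationConfig(
            patient_table="patient",
            patient_fk={"prescription": "patient_id"},
            parent_columns={"prescription": {"dosage": "drug"}},
        ),
    )


@dataclass
class Pipeline:
    store: Store
    src_dir: str
    spec: SynthSpec
    manifest: Dict
    config: MigrationConfig
    model: ClinicalDatabaseModel
    views: List[BridgeView]
    reader: SourceReader


@pytest.fixture(scope="session")
def seed1(tmp_path_factory) -> Pipeline:
    """Seed-1 synthetic database (200 patients, null probability 0.2),
    fully migrated and bridged."""
    root = tmp_path_factory.mktemp("seed1")
    spec = SynthSpec(seed=1, n_patients=200, null_probability=0.2)
    src = str(root / "src")
    manifest = generate_cdb(spec, src)
    store = init_store(str(root / "store.db"))
    config = default_config()
    report = run_migration(store, src, "csv_dir", config, db_name=spec.db_name)
    yield Pipeline(
        store=store,
        src_dir=src,
        spec=spec,
        manifest=manifest,
        config=config,
        model=report.model,
        views=report.views,
        reader=SourceReader(src, "csv_dir"),
    )
    store.close()


# ---------------------------------------------------------------------------
# random schema generation shared by model/OBO tests


_DATATYPES = ("text", "integer", "decimal", "date", "boolean")


def random_schema(rng: random.Random, db_name: str = None) -> SourceSchema:
    db_name = db_name or f"db{rng.randint(0, 10**6)}"
    n_tables = rng.randint(1, 4)
    tnames = rng.sample(
        ["alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta"], n_tables
    )
    tables = []
    for tname in tnames:
        n_cols = rng.randint(1, 6)
        cnames = ["id"] + rng.sample(
            ["c1", "c2", "c3", "c4", "c5", "value", "label", "score"], n_cols - 1
        ) if n_cols > 1 else ["id"]
        cols = [SourceColumn(c, rng.choice(_DATATYPES)) for c in cnames]
        tables.append(SourceTable(tname, cols, "id"))
    return SourceSchema(db_name, tables)
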