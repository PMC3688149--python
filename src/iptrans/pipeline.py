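"""The four-step migration methodology, end to end.

1. create the clinical database model from the source schema;
2. store the model in the controlled-vocabulary tables;
3. run the ETL into the Clinical Module;
4. build the bridge layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

from .bridge import BridgeView, build_bridge
from .cdbmodel import (
    ClinicalDatabaseModel,
    SourceReader,
    build_model,
    extract_schema,
    load_model,
)
from .etl import MigrationConfig, MigrationReport, migrate
from .store import Store

STAGES = ("create_model", "store_model", "store_data", "build_bridge")


@dataclass
class PipelineReport:
    stages: List[str] = field(default_factory=list)
    model: Optional[ClinicalDatabaseModel] = None
    terms_loaded: int = 0
    migration: Optional[MigrationReport] = None
    views: List[BridgeView] = field(default_factory=list)


def run_migration(
    store: Store,
    source: str,
    kind: str,
    config: MigrationConfig,
    db_name: Optional[str] = None,
    materialize: bool = False,
    replace: bool = True,
) -> PipelineReport:
    """Execute the four methodology steps in order and report them."""
    report = PipelineReport()

    schema = extract_schema(source, kind, key_overrides=config.key_columns, db_name=db_name)
    report.model = build_model(schema)
    report.stages.append("create_model")

    load = load_model(store, report.model, replace=replace)
    report.terms_loaded = load.terms
    report.stages.append("store_model")

    reader = SourceReader(source, kind)
    report.migration = migrate(store, reader, report.model, config, replace=replace)
    report.stages.append("store_data")

    from .bridge import drop_bridge

    if replace:
        drop_bridge(store, report.model)
    report.views = build_bridge(store, report.model, config, materialize=materialize)
    report.stages.append("build_bridge")
    return report
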