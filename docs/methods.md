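# Methods

This note records the model, the procedural choices and the limits of
what the test suite demonstrates.

## The store

The store is a single SQLite file whose schema is written in portable
DDL (`iptrans.store.SCHEMA_DDL`), so a server RDBMS backend remains a
straightforward port. Three table groups coexist:

* **Controlled vocabulary** — `cv`, `cvterm`, `cvterm_relationship`,
  `cvtermprop`. Ontologies, legacy-database models and internal
  bookkeeping terms all live here; every typed row in the store
  references a `cvterm`.
* **Clinical module** — the seven tables `patient`, `patientprop`,
  `appointment`, `project_cdb`, `csd`, `csd_relationship`, `csdprop`,
  plus the `project` table they hang off. Facts that never change
  (sex, birthdate, address) go to `patientprop`; everything else
  patient-linked goes to `csd`; patient-independent reference data
  (drug catalogues, city lists) goes to `csdprop`.
* **Expression subset** — `biomaterial`, `biomaterialprop`, `assay`,
  `assay_biomaterial`, `expression_value`: the minimal complement
  needed to link a patient's sample to hybridizations and intensity
  values. It is deliberately small; platform metadata, channels and
  normalization are out of scope.

All EAV `value` columns are text. Datatype metadata (one of `text`,
`integer`, `decimal`, `date`, `boolean`) is annotated on the model's
column terms and drives three things: canonical rendering at load time
(integers without decimal point, decimals in shortest faithful form,
ISO-8601 dates, `true`/`false` booleans), CASTs in the bridge views so
numeric columns compare numerically, and operator type-checking in the
query planner (ordering operators are refused on non-orderable
attributes).

Uniqueness of `(entity, attribute, rank)` in the EAV tables is enforced
by the loaders and *audited* by `integrity_check` rather than declared
as UNIQUE constraints, so that a damaged store can still be opened and
reported on instead of failing at connection time. `rank` is 0-based.
`appointment` is implemented minimally (patient, ISO date): it is part
of the module's surface but no migration path targets it, because no
legacy-source classification rule for appointment-like tables is
defined here.

## Models of legacy databases

`extract_schema` supports three source kinds: a directory of CSV files
(RFC 4180, header row required), an embedded SQLite file (types read
from the DDL), and a SQL dump restricted to standard `CREATE TABLE` /
`INSERT` statements — vendor-specific syntax is rejected loudly rather
than half-parsed. CSV datatypes are inferred deterministically: a
column is integer / decimal / date / boolean iff *every* non-empty cell
parses as such, tested in that precedence, else text. No sampling, so
inference is reproducible.

`build_model` produces the three-level hierarchy with alphabetical
sibling order and identifiers `<db>:<7-digit ordinal>` assigned in
traversal order, making model construction a pure function of the
schema. Column terms are qualified `table.column` so two tables
sharing a column name cannot collide in the vocabulary, which is keyed
by `(cv, name)`. Key columns are included as terms but flagged
`is_key`: the ETL migrates them as system rows excluded from fact
counts, because an exact bridge-layer round trip needs the original
key values. The row-identifier heuristic (`id`, then `<table>_id`,
else the first column) can be overridden per table in the migration
config.

Models serialize as OBO 1.2 with `is_a` links and `property_value`
lines carrying the datatype and key flags; `read_obo ∘ write_obo` is
the identity on valid models (property-tested), and the writer's output
is cross-checked against an independent OBO parser in the tests.
Replacing a loaded model re-asserts it in place — terms shared with the
incoming model keep their surrogate ids so migrated facts stay valid;
deleting a term that still types stored facts fails loudly.

## Migration

The ETL walks tables in a fixed order (patient table, then other
patient-linked tables, then reference tables, each group
alphabetically; rows in source order), so re-running a migration yields
an identical store. Per table:

* patient table — one `patient` per row (key → `source_key`);
  configured stable columns → `patientprop`, the rest → rank-0 `csd`
  rows. Rows with NULL or duplicate keys are skipped and logged.
* other patient-linked tables — the configured patient foreign key
  resolves the patient; each row gets the next 0-based rank for that
  (patient, table); every non-NULL cell becomes one `csd` row at that
  rank. Declared child columns (e.g. `dosage → drug`) receive
  `parent_csd` pointing at the anchor cell's row; a NULL anchor is
  logged and the child stored parentless.
* reference tables — one `csdprop` row per non-NULL cell, the row
  group sharing the source-row ordinal as rank.

NULL cells produce no row (EAV sparsity); the bridge reinstates them.
Foreign keys into reference tables are stored verbatim as values, not
resolved to `csdprop` ids — the linkage mechanism between `csd` and
`csdprop` is left value-based by design, and bridge views re-join by
value. Cells that fail their declared datatype are stored as raw text
and logged as violations rather than dropped. A conservation law holds
on clean sources and is asserted on every synthetic fixture:

    csd_created + patientprops_created + cells_skipped_null
        + key/fk cells  =  total cells of patient-linked tables

Row groups are aligned by rank alone; no anchor record typed by the
table term is created. `parent_csd` is reserved for declared intra-row
dependencies, and `csd_relationship` is exposed (`attach_relationship`)
for cross-record links.

## Bridge layer

Each source table compiles to a view `bl_<db>_<table>` that pivots the
EAV rows back into the legacy shape by conditional aggregation
(`MAX(CASE WHEN type_id = … THEN value END)`) grouped by
(patient, rank) — one scan of `csd` per view regardless of column
count, instead of one self-join per column. The patient table pivots
`patientprop` and rank-0 `csd` rows keyed by `source_key`; reference
tables pivot `csdprop` by rank. `materialize=True` additionally writes
each view as a physical table (`<view>_mat`), trading redundancy for
speed; tests assert the two variants return identical row multisets.

Reconstructed rows are identified by the preserved legacy key column,
so no synthetic row-ordinal column is emitted; a keyless table would
fall back to the first column as its identifier. Round-trip
verification canonicalizes both sides per datatype and compares
multisets of rows, ignoring row and column order; the SQL pivot is also
checked against an in-memory pivot computed directly from the raw EAV
rows, independent of the SQL path.

## Mapping and querying

Only exact-match mapping relations are supported; one term maps to at
most one concept while a concept may be matched from many terms and
sources — the asymmetry that makes the reference ontology a mediated
schema. The constraint o ≤ r therefore holds by construction and is
property-tested under random add sequences. The reference ontology's
non-hierarchical relations are stored but take no part in translation
or querying. The shipped toy ontology (32 concepts, is_a structured)
exists so the package is exercisable offline; any OBO ontology loads in
its place, and it emulates none of a real ontology's breadth.

Concept-level predicates expand to their mapped source terms
(optionally including is_a descendants) *before* planning, so the
executor never consults the mapping environment. Execution follows the
split-query strategy; NOT complements against the queried clinical
database's patient set only, so multi-source stores cannot leak
patients across sources. Multivalued attributes qualify a patient if
ANY rank matches (the natural reading when one record is stored per
drug); a per-predicate ALL-ranks mode requires every non-NULL instance
to match and at least one to exist. Numeric comparisons CAST to REAL;
date comparisons rely on ISO-8601 lexicographic order; `contains` is
substring containment.

The integrated export emits one row per linked (patient, assay) pair.
A multivalued requested attribute contributes its lowest-rank value —
a deliberate simplification; use the bridge views when the full
multiplicity matters.

## Synthetic data

The generator emulates, at reduced scale, the structure of a clinical
research database: a 9-column demographics table mixing stable
socio-demographic columns with measurements, visit and diagnosis
tables with 1–3 and 1–2 rows per patient, a prescription table with
0–4 rows per patient whose dosage depends on its drug, and a
patient-independent drug catalogue. Defaults: 5 tables, 26 columns,
200 patients, null probability 0.2 per nullable cell — chosen to
exercise every migration device (rank groups, parent links, reference
tables, NULL reinstatement) while keeping the full
generate → migrate → bridge → verify cycle under a few seconds.
Dosages are generated only when their drug is present, mirroring real
prescriptions and keeping parent links well-defined. The group
attribute (sex) is never NULL so the expression generator always has
two levels.

Expression data: one biomaterial and one single-channel assay per
patient, 50 probes, independent Gaussian noise (SD 1) on log2
intensities around a baseline of 8, and a planted mean shift
(`effect_size`, default 1.0) on the first 10 probes between the two
group levels. No array effects, batch structure or correlation are
simulated — the artifact tests *linkage*, not normalization — so
passing tests show that clinical and expression data connect and
round-trip correctly, not that any statistical pipeline downstream
would behave well on real arrays.

All generation flows from one integer seed through Python's `random`;
identical seeds give byte-identical CSV/dump output. The manifest
records exact cell, NULL and per-patient row counts computed during
emission, serving as the independent oracle for the ETL conservation
law. (The SQLite copy is compared through extraction, not bytes, since
its file layout is library-dependent.)

## Numerical and degenerate-input choices

* Decimal canonical form is the shortest string that reads back as the
  same float (`repr`), with integral values rendered `N.0`;
  canonicalization is idempotent (property-tested).
* An empty CSV directory yields an empty schema; a model with no
  column terms reports depth < 3 rather than erroring, but `read_obo`
  rejects hierarchies that are not clean ≤3-level trees.
* Unknown patients, NULL keys, unparseable cells: logged as violations
  (TSV export) and skipped or stored-as-text; migration never aborts on
  data problems.
* `integrity_check` reports, never raises; cycles in `parent_csd`
  chains and `is_a` edges are detected by explicit traversal.

## Known limitations

Hospital operational workflows (billing, bed control, scheduling) are
out of scope, as are entity resolution across sources, automatic
schema matching, OWL serialization, HL7/DICOM interfaces and
anonymization. Virtual bridge views pivot on every query; for wide
tables under heavy read load, materialize them. The SQL-dump reader
supports only the standard CREATE TABLE / INSERT subset. Incremental
(delta) migration is not implemented: re-migration replaces the
database's clinical content wholesale.
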