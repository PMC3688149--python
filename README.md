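# iptrans

An ontology-typed Entity-Attribute-Value (EAV) store for clinical
research data, with a four-step methodology for migrating legacy
clinical databases into it, auto-generated *bridge views* that
reconstruct the legacy table shapes, exact-match mappings onto a common
reference ontology, and a bidirectional clinical ↔ gene-expression
query engine.

It is aimed at translational-research groups that hold patient data in
ad-hoc relational databases (demographics, visits, prescriptions,
diagnoses, reference tables) and expression data from microarray-style
assays, and want both integrated under one schema without breaking the
tools written against the original databases.

## The data model

Clinical facts are stored in a small relational schema inspired by the
modular, controlled-vocabulary-driven design used by genomic databases:
every stored datum is typed by a term of a controlled vocabulary
(`cv` / `cvterm`). The clinical portion consists of **seven tables** —
`patient`, `patientprop`, `appointment`, `project_cdb`, `csd`,
`csd_relationship`, `csdprop` — with `csd` (clinic-social data) holding
most facts as EAV triples:

    (entity, attribute, value) = (patient_id, type_id → cvterm, value)

Two devices disambiguate repeated and dependent facts:

* `rank` — repeated instances of the same attribute for one patient
  (e.g. three prescribed drugs) get ranks 0, 1, 2, …; all facts
  extracted from one source row share one rank;
* `parent_csd` — a dependent fact (a dosage) points at the fact it
  qualifies (its drug).

Each legacy database is described by a **three-level model**: a root
term (the database name), one term per table, one term per column
(annotated with its datatype and key flag). The model serializes as
OBO and is itself stored in the vocabulary tables, so every migrated
fact is typed by the model that describes its source.

Sources are integrated through an **ontological mapping environment**,
the 5-tuple (CRO, S_k, SM_k, M_k, m): a common reference ontology CRO,
source schemas S_k, their models SM_k with r terms each, per-source
sets M_k of exact-match relations m (at most one per term, so o ≤ r).
A concept-level query fans out through the mappings to every source
that stores the attribute.

Patient selection uses the split-query strategy for EAV stores: a
boolean expression is decomposed into one small single-attribute query
per predicate and the results are combined by set operations (AND →
intersection, OR → union, NOT → complement against the database's own
patient set). The clinical ↔ expression link is the biomaterial path:
patient → biomaterialprop → biomaterial → assay_biomaterial → assay.

## Worked example

One patient (legacy key 9, age 58, height 1.72, weight 80.0) with a
prescription of Carboplatin 50 mg, Decadron and Furosemide:

```sh
iptrans migrate --store store.db --source cdb --kind csv_dir \
    --config migration.yaml --db-name CDB --all
```

reports the four methodology stages and the migration counts:

```json
  "stages": ["create_model", "store_model", "store_data", "build_bridge"],
  "migration": {
    "patients_created": 1,
    "csd_created": 7,
    "cells_skipped_null": 2,
    ...
  }
```

`csd_created` is 7: age, height, weight, three drugs and one dosage —
every non-NULL, non-key cell became exactly one typed EAV row; the two
empty dosage cells produced no rows (`cells_skipped_null`). In the
`csd` table the three drugs share one `type_id` and are told apart by
`rank`, and the dosage row's `parent_csd` points at the Carboplatin
row:

```
(4, 1, 16, 'Carboplatin', 0, None)
(6, 1, 15, '50 mg',       0, 4)      ← parent_csd = 4
(7, 1, 16, 'Decadron',    1, None)
(9, 1, 16, 'Furosemide',  2, None)
```

The bridge view `bl_CDB_prescription` pivots those rows back into the
legacy shape, reinstating the NULL dosages:

```
dosage   drug         id  patient_id
'50 mg'  Carboplatin  1   9
NULL     Decadron     2   9
NULL     Furosemide   3   9
```

and a legacy-style query works against the store:

```sh
iptrans query --store store.db --db-name CDB \
    --expr '(eq CDB:prescription.drug Carboplatin)'
# -> {"patients": [1]}
```

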