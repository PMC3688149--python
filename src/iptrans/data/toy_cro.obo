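format-version: 1.2
ontology: toy_cro

[Term]
id: CRO:0000001
name: biomedical entity

[Term]
id: CRO:0000002
name: patient
is_a: CRO:0000001

[Term]
id: CRO:0000003
name: demographic attribute
is_a: CRO:0000001

[Term]
id: CRO:0000004
name: age
is_a: CRO:0000003

[Term]
id: CRO:0000005
name: sex
is_a: CRO:0000003

[Term]
id: CRO:0000006
name: birth date
is_a: CRO:0000003

[Term]
id: CRO:0000007
name: address
is_a: CRO:0000003

[Term]
id: CRO:0000008
name: city
is_a: CRO:0000003

[Term]
id: CRO:0000009
name: anthropometric attribute
is_a: CRO:0000001

[Term]
id: CRO:0000010
name: height
is_a: CRO:0000009

[Term]
id: CRO:0000011
name: weight
is_a: CRO:0000009

[Term]
id: CRO:0000012
name: clinical finding
is_a: CRO:0000001

[Term]
id: CRO:0000013
name: diagnosis
is_a: CRO:0000012

[Term]
id: CRO:0000014
name: diagnosis code
is_a: CRO:0000013

[Term]
id: CRO:0000015
name: disease severity
is_a: CRO:0000012

[Term]
id: CRO:0000016
name: vital sign
is_a: CRO:0000012

[Term]
id: CRO:0000017
name: systolic blood pressure
is_a: CRO:0000016

[Term]
id: CRO:0000018
name: heart rate
is_a: CRO:0000016

[Term]
id: CRO:0000019
name: tumor attribute
is_a: CRO:0000012

[Term]
id: CRO:0000020
name: tumor size
is_a: CRO:0000019

[Term]
id: CRO:0000021
name: tumor type
is_a: CRO:0000019

[Term]
id: CRO:0000022
name: treatment
is_a: CRO:0000001

[Term]
id: CRO:0000023
name: drug treatment
is_a: CRO:0000022

[Term]
id: CRO:0000024
name: drug
is_a: CRO:0000023

[Term]
id: CRO:0000025
name: dosage
is_a: CRO:0000023

[Term]
id: CRO:0000026
name: administration route
is_a: CRO:0000023

[Term]
id: CRO:0000027
name: clinical encounter
is_a: CRO:0000001

[Term]
id: CRO:0000028
name: encounter date
is_a: CRO:0000027

[Term]
id: CRO:0000029
name: clinical note
is_a: CRO:0000027

[Term]
id: CRO:0000030
name: biological material
is_a: CRO:0000001

[Term]
id: CRO:0000031
name: hybridization assay
is_a: CRO:0000001

[Term]
id: CRO:0000032
name: drug class
is_a: CRO:0000023

[Typedef]
id: part_of
name: part of

[Typedef]
id: has_participant
name: has participant
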