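# Organization-identifier patterns: kind<TAB>term.
# An org_type within a 10-token window of a language_pattern or
# target_population counts as one geographic/organization identifier.
language_pattern	lived in
language_pattern	lives in
language_pattern	lived at
language_pattern	come from
language_pattern	comes from
language_pattern	came from
language_pattern	moved to
language_pattern	grew up in
language_pattern	works at
language_pattern	worked at
language_pattern	attends
language_pattern	attended
language_pattern	enrolled at
language_pattern	enrolled in
language_pattern	stationed at
language_pattern	member of
language_pattern	volunteers at
language_pattern	stays at
org_type	school
org_type	schools
org_type	high school
org_type	elementary school
org_type	church
org_type	churches
org_type	parish
org_type	synagogue
org_type	mosque
org_type	temple
org_type	foster home
org_type	group home
org_type	orphanage
org_type	aid society
org_type	shelter
org_type	support center
org_type	support centre
org_type	community center
org_type	community centre
org_type	military base
org_type	regiment
org_type	battalion
org_type	garrison
org_type	university
org_type	college
org_type	academy
org_type	daycare
org_type	nursing home
org_type	retirement home
org_type	rehab center
org_type	rehab centre
target_population	youth
target_population	women
target_population	seniors
target_population	senior
target_population	children
target_population	veterans
target_population	teens
target_population	elderly
target_population	disabled
target_population	newcomers
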