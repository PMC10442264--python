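# External field-study inputs (not distributed)

The integration tests in `tests/test_acceptance.py` compare this package's
diagnostics against the dyadic half-weight-index matrices and survey data
published as supplementary material of the original Shark Bay field study.
Those tables are not redistributable here; to run the checks, transcribe
them into this directory as plain CSV:

| file                 | content                                              |
|----------------------|------------------------------------------------------|
| `hwi_pooled.csv`     | pooled 22-male HWI matrix (full study period)        |
| `hwi_T1.csv`         | 2009-2010 HWI matrix                                 |
| `hwi_T2.csv`         | 2011-2012 HWI matrix                                 |
| `hwi_T3.csv`         | 2013-2014 HWI matrix                                 |
| `field_surveys.csv`  | survey table (`survey_id,date,activity,members`)     |
| `field_registry.yaml`| alliance registry (see `alliancenet.survey_io`)      |

Matrix CSVs are square, with one header row and one index column of
individual codes (the format written by `AssociationMatrix.to_csv`).
When a file is absent the corresponding test is skipped.
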