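"""Audit the four-criterion stromal biomarker filter on a known fixture.

The engineered eight-protein fixture plants exactly three proteins
(B1-B3) that satisfy all criteria — stroma-unique, seen in over 80% of
patients, up-regulated in tumor stroma, abundant with enough peptide
support — and five that each fail exactly one gate.  The audit table
shows which criterion removed each candidate.
"""

import stromacomp as sc

stroma, epithelium, sheet, contrasts, _ = sc.biomarker_audit_fixture()
result = sc.select_biomarkers(stroma, epithelium, sheet, contrasts)

cols = ["stroma_unique", "patient_prevalence", "dep_up", "abundance_rank", "selected"]
print(result.audit[cols].replace({True: "pass", False: "FAIL"}))
print(f"\nselected panel: {sorted(result.panel)}")
# Each F-protein fails exactly the criterion it was built to fail; the
# final panel is the conjunction of all four criteria.
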