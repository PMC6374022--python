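"""Build the binary phenome matrix from raw ICD-9 records and a phecode map.

Demonstrates the mapping rules: repeated codes collapse to a single 1,
unmapped codes are dropped, and individuals with no mapped code at all are
excluded.
"""

import tempfile
from pathlib import Path

import genotopics as gt

with tempfile.TemporaryDirectory() as tmp:
    map_path = Path(tmp) / "phecode_map.csv"
    map_path.write_text(
        "icd9,phecode\n"
        "272.4,272.1\n"    # hyperlipidemia NEC -> Hyperlipidemia
        "272.0,272.1\n"    # hypercholesterolemia -> same phecode
        "401.9,401.1\n"    # hypertension NOS -> Essential hypertension
        "414.01,411.4\n"   # coronary atherosclerosis
    )
    pmap = gt.load_phecode_map(map_path)
print(f"phecode map: {len(pmap)} (icd, phecode) pairs")

records = [
    ("patient_A", "272.4"), ("patient_A", "272.0"), ("patient_A", "401.9"),
    ("patient_B", "414.01"),
    ("patient_C", "V70.0"),   # unmapped: patient_C carries nothing mappable
]
pm = gt.build_matrix(records, pmap)
print(f"matrix: {pm.shape[0]} individuals x {pm.shape[1]} phecodes")
print(f"individuals kept: {pm.individual_ids}  (patient_C dropped: no mapped code)")
print(f"phecodes (lexicographic): {pm.phecodes}")
print("X =")
print(pm.X.toarray())
print("note: patient_A's two hyperlipidemia codes collapse to a single 1")
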