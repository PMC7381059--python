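"""Generate a synthetic multi-site EMR cohort and inspect its identifier quality.

Creates 500 synthetic persons attending a default mix of clinics and
laboratories (with per-site Medicare missingness, typos, nicknames and
date errors), derives hashed linkage keys, and prints the per-site
availability of each key type. Sites that rarely record the Medicare
number are left with only key type 3, the name-based key.
"""

from privlink import CohortConfig, KeyGenConfig, generate_cohort, key_availability_summary
from privlink.pipeline import deid_table_to_records, make_deid_table

cohort = generate_cohort(CohortConfig(n_persons=500, rng_seed=11))
print(f"{len(cohort.identified)} records for {len(cohort.persons)} persons, "
      f"{len(cohort.tests)} test results\n")

deid = make_deid_table(cohort.identified, KeyGenConfig(secret_seed=b"example-seed"))
by_site: dict[str, list] = {}
for rec in deid_table_to_records(deid):
    by_site.setdefault(rec.site_id, []).append(rec.keyset)

table = key_availability_summary(by_site)
cols = ["site", "n_records", "no_keys_pct", "key1_pct", "key2_pct", "key3_pct", "key4_pct"]
print(table[cols].to_string(index=False))
print("\nEach *_pct column is the share of that site's records carrying the key type;")
print("lab2 blanks 97% of Medicare numbers, so its records rely on key type 3 alone.")
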