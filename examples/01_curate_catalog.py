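"""Curate a small presequence catalog.

Builds an in-memory catalog with duplicates, sub-threshold scores and a
Met-only entry, then applies the standard curation rules: keep records
with targeting score >= 0.3 and length >= 8, collapse duplicates to the
form identified most often (ties: the longer form), drop trivial
entries, and add one manually curated presequence.
"""

from mtscape import Catalog, PresequenceRecord, add_manual, curate

records = [
    PresequenceRecord("ATP5", "MLSRAVCGTSRQLAPVLGYLG", 0.95, 5),
    PresequenceRecord("ATP5", "MLSRAVCGTSRQLAPVLGYLGSRQ", 0.95, 2),  # rarer form
    PresequenceRecord("COX4", "MLSLRQSIRFFKPATRTLCSSR", 0.88, 3),
    PresequenceRecord("MAM33", "MFRTAVRSLLRSSQARLL", 0.12, 4),       # score too low
    PresequenceRecord("SOD1", "M", 0.80, 2),                          # bare initiator Met
    PresequenceRecord("MDL2", "MRLLSAS", 0.90, 1),                    # 7 residues, too short
]

catalog = Catalog(records)
curated = curate(catalog)
curated = add_manual(curated, PresequenceRecord("OXA1", "MFKLTSRLALSSRSILVRSIPVRFY", 0.71, 1))

print(f"input records:   {len(catalog)}")
print(f"curated records: {len(curated)}")
for key in ("dropped_no_score", "dropped_low_score", "dropped_short", "dropped_trivial"):
    print(f"  {key}: {curated.metadata.get(key, '0')}")
for rec in curated:
    print(f"  kept {rec.gene_id:6s} len={rec.length:3d} score={rec.targetp_score} source={rec.source}")

# ATP5's most-often-identified form survives deduplication; MAM33 fails the
# score filter; SOD1 and MDL2 fall below the length rules; OXA1 is appended
# with source="manual".
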