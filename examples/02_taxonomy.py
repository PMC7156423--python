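"""Resolve verbatim names against a registry and aggregate synonyms.

Three different spellings of one kelp collapse onto a single accepted
species; a misspelling and an uncertain taxon are removed.
"""

from marineqc import (
    OccurrenceRecord,
    RecordSet,
    TaxonRecord,
    TaxonRegistry,
    assign_group,
    resolve_name,
    standardize_records,
)
from marineqc.taxonomy import distinct_accepted_species

reg = TaxonRegistry()
reg.add(TaxonRecord(aphiaID=145724, scientificName="Laminaria digitata",
                    status="accepted", acceptedAphiaID=145724,
                    taxon_order="Laminariales", family="Laminariaceae",
                    genus="Laminaria"))
reg.add(TaxonRecord(aphiaID=145725, scientificName="Laminaria ensifolia",
                    status="unaccepted", acceptedAphiaID=145724))
reg.add(TaxonRecord(aphiaID=145726, scientificName="Laminaria dubitanda",
                    status="uncertain", acceptedAphiaID=145726))
reg.validate()

records = RecordSet(records=[
    OccurrenceRecord(id="1", name="Laminaria digitata"),
    OccurrenceRecord(id="2", name="laminaria   ensifolia"),   # synonym, messy case
    OccurrenceRecord(id="3", name="Laminaria digittata"),     # misspelled -> removed
    OccurrenceRecord(id="4", name="Laminaria dubitanda"),     # uncertain -> removed
])
out = standardize_records(records, reg)
print(out.provenance[-1])
print("accepted species in output:", distinct_accepted_species(out))
for r in out:
    print(f"  {r.id}: {r.name!r} -> {r.acceptedName} (aphiaID {r.acceptedAphiaID})")

t = resolve_name("Laminaria ensifolia", reg).taxon
print("ecological group of the accepted taxon:", assign_group(t).value)
# Both surviving records share one acceptedAphiaID; the kelp order
# Laminariales places the species in the kelp/fucoid group.
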