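"""Complete partial TM/TA/CO scorings under the lateral-medial dependency.

The tympanic middle ear is a chain: tympanic membrane (TM, lateral) sits on
the tympanic annulus (TA), which requires the columella (CO, medial). A
lateral structure can only occur where the medial one does, so partial
museum-style scorings can often be completed logically.
"""

from tmetrace import read_character_table
from tmetrace.characters import extract_binary

TABLE = """\
taxon	TM	TA	CO
Bufo_full_ear	1	?	?
Atelopus_no_annulus	?	0	?
Osornophryne_no_columella	?	?	0
Contradictory_scoring	1	?	0
"""

matrix, altered, report = read_character_table(TABLE)

print("completed rows (0 = absent, 1 = present, ? = unknown):")
for structure in ("TM", "TA", "CO"):
    print(f"  {structure}: {extract_binary(matrix, structure)}")
print(f"\nrows filled in by the rules: {[r.taxon for r in altered]}")
print(f"rows rejected as contradictory: {report}")
print(
    "\nTM present forced the full chain present; a missing annulus forces a"
    "\nmissing membrane but leaves the columella unknown (it can occur alone);"
    "\na missing columella forces complete earlessness. A membrane scored"
    "\npresent above an absent columella violates the dependency and is rejected."
)
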