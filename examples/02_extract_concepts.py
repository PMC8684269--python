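"""Extract patient-affirmation concepts from a few hand-written notes.

Shows the three extraction steps on real sentences: splitting into
sub-texts, four-way context classification, and exact most-precise
matching — negated and family-related findings never reach the stay set.
"""

from edlos import split_subtexts, classify_context, match_concepts, extract_stay_concepts
from edlos.config import DEFAULT_CUES
from edlos.thesaurus import Concept, ConceptThesaurus

thesaurus = ConceptThesaurus([
    Concept("root", None, "clinical finding"),
    Concept("pain", "root", "pain", frozenset({"dolor"})),
    Concept("abd-pain", "pain", "abdominal pain"),
    Concept("fever", "root", "fever", frozenset({"pyrexia"})),
    Concept("diabetes", "root", "diabetes"),
])
cues = DEFAULT_CUES["en"]

note = ("Diffuse abdominal pain since this morning. No fever. "
        "Mother has diabetes; patient anxious.")

print("sub-texts and their context:")
for sub in split_subtexts(note):
    label = classify_context(sub, cues)
    print(f"  {sub!r:55s} -> {label.subject}-{label.polarity} "
          f"matches={sorted(match_concepts(sub, thesaurus))}")

stay_concepts = extract_stay_concepts([{"sentences": [note]}], thesaurus, cues)
print("\nstay-level concept set:", sorted(stay_concepts))
# Only 'abd-pain' survives: 'pain' is its ancestor (less precise), fever is
# negated, and the diabetes mention is family context, so all are excluded.
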