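"""Collapse the packaged per-method link transcription into the relationship
table: lag classes, causal roles, and triangulated nature labels.

The packaged CSV transcribes the per-method significant links reported for
the three thalamic seeds (M-Tal, IL-Tal, MD-Tal) against the basal-ganglia
motor-circuit nuclei in two tasks.  Collapsing across methods yields 57
distinct relationships, 35 of them non-linear or complex (> 60%).
"""

import boldcausal as bc
from boldcausal.classify import nature_counts

links = bc.load_link_table()
records = bc.collapse_links(links)
counts = nature_counts(records)

print(f"per-method links transcribed: {len(links)}")
print(f"distinct relationships:       {counts['total']}")
print(f"  linear:     {counts['linear']}")
print(f"  non-linear: {counts['non_linear']}")
print(f"  complex:    {counts['complex']}")
print(f"non-linear or complex: {counts['non_linear_or_complex']} "
      f"({100 * counts['non_linear_fraction']:.1f}%)")

df = bc.records_to_frame(records)
print("\nM-Tal records (role mark: '*' seed causes, '<' seed responds):")
print(df[df.seed == "M-Tal"].to_string(index=False))
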