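"""Condense original mapping weights under the four rules.

One element column with weights 80, 52, 40, 8 is condensed by value
(symptom basis) and by ratio to the column maximum (element basis), at
both granularities.  Condensed weights live on a small ordinal scale
with a qualitative reading: 10 maximum correlation, 2 minimum.
"""

from syndel import CondenseRule, MappingMatrix, condense_matrix

matrix = MappingMatrix.from_long(
    [(1, 28, 80.0), (2, 28, 52.0), (3, 28, 40.0), (4, 28, 8.0)]
)

print("original :", [f"{v:g}" for v in matrix.weights[28]])
for name in ("symptom_normal", "symptom_fuzzy", "element_normal", "element_fuzzy"):
    condensed = condense_matrix(matrix, CondenseRule.from_name(name))
    print(f"{name:<15}:", [f"{v:g}" for v in condensed.weights[28]])

# symptom basis quantizes the raw values (80 -> 10, 8 -> 2); element
# basis quantizes ratios to the column max 80 (52/80 = 0.65 -> 10 under
# both granularities, 40/80 = 0.5 -> 6).  The weight ranking never inverts.
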