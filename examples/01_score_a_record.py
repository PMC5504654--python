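"""Score one answer record against a small mapping matrix.

Builds a 3-question knowledge base linking symptoms to three syndrome
elements, answers the questionnaire, and prints the quantitative value
of each element: the weighted sum of answer weight x mapping weight.
"""

from syndel import AnswerRecord, MappingMatrix, compute_element_values, load_registry

registry = load_registry()

# question 1 -> Dampness (e28, weight 40); question 2 -> Qi deficiency
# (e9, 25) and Spleen (e36, 30); question 3 -> Spleen (e36, 15)
matrix = MappingMatrix.from_long(
    [(1, 28, 40.0), (2, 9, 25.0), (2, 36, 30.0), (3, 36, 15.0)]
)

# A = severe/always (weight 1), B = 0.618, C = 0.382, D = none (0)
record = AnswerRecord("patient-1", "female", {1: "A", 2: "B", 3: "D"})

values = compute_element_values(record, matrix)
for idx in (28, 9, 36):
    element = registry[idx]
    print(f"{element.label:>4}  {element.name:<14} {values[idx]:7.3f}")

# e28 = 1.0 * 40 = 40; e9 = 0.618 * 25 = 15.45; e36 = 0.618 * 30 = 18.54
# (question 3 contributes nothing: answered D).  Larger value = stronger
# evidence for that element in this record.
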