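# syndel

Quantitative syndrome-element differentiation for inquiry-based
traditional Chinese medicine (TCM) diagnostics.

In TCM, a patient's health state is summarised by a *syndrome*, which
can be decomposed into atomic *syndrome elements* — disease locations
("Spleen", "Liver") and disease natures ("Dampness", "Qi deficiency").
`syndel` implements the inquiry arm of this decomposition as a
reusable engine for researchers working on computational TCM
diagnosis: it scores questionnaires into element values, coarsens the
underlying knowledge base onto interpretable ordinal weights, measures
how much that coarsening changes the diagnosis, and mines frequent
element combinations from a diagnosed cohort.

## The method

**Quantification.** A questionnaire of symptom questions (177 for men,
194 for women) is answered on a four-level scale A/B/C/D with weights
1 / 0.618 / 0.382 / 0. A mapping-weight matrix *W* (questions ×
47 elements, positive weights on a (0, 100) scale) encodes the
diagnostic knowledge base. The value of element *e* for a record is

    value(e) = Σ_q  answer_weight(q) · W[q, e]

over answered questions *q*; restricting the sum to severe answers
(level A, optionally A∪B) gives the *major* rather than *overall*
health state. Elements 7 (deficiency) and 8 (excess) are composite
judgements with no direct question mappings and are excluded from
scoring and evaluation, leaving 45 evaluable elements in 4
differentiation groups (eight-principle 6, disease-cause 7,
qi–blood–fluid–humor 16, visceral 16).

**Condensation.** Original weights are replaced by small ordinal
weights with qualitative TCM readings (10 = maximum correlation,
2 = minimum), under four rules crossing two bases — *symptom*
(quantize the raw value) and *element* (quantize the ratio of each
weight to its element column's maximum) — with two granularities —
*normal* ({2, 4, 6, 10}) and *fuzzy* ({2, 3, 4, 5, 6, 8, 10}, with
secondary levels near interval boundaries).

**Evaluation.** Element values are ranked within each group by *value
order* (8 highest … 1, from the ratio to the group maximum), each
order carrying a weight (1, 0.95, 0.9, 0.8, 0.7, 0.6, 0.4, 0.2).
Agreement between the original and condensed diagnoses is the matched
degree per group,

    MDG = (CG − Σ_mismatched SE_W) / CG,

and the integrated matched degree `MD = Σ MDG · CG / CT` with
CT = 45. Cohort results are binned into the standard percent bins
[95, 100], [90, 95), …, [0, 60).

**Knowledge discovery.** Each record's top-order elements become the
attributes of a formal context (records = objects); an *attribute
partial-ordered structure diagram* (APOSD) layers attributes by how
many records they cover, and root-to-layer-*k* chains are the cohort's
frequent element combinations.

The original knowledge base and clinical cohort are not publicly
deposited, so `syndel.synthdata` generates statistically shaped
synthetic matrices and cohorts for development and testing.

## Worked example

```python
from syndel import AnswerRecord, MappingMatrix, compute_element_values

matrix = MappingMatrix.from_long(
    [(1, 28, 40.0), (2, 9, 25.0), (2, 36, 30.0), (3, 36, 15.0)]
)
record = AnswerRecord("patient-1", "female", {1: "A", 2: "B", 3: "D"})
values = compute_element_values(record, matrix)
```

prints (via `python examples/01_score_a_record.py`):

```
 e28  Dampness        40.000
  e9  Qi deficiency   15.450
 e36  Spleen          18.540
```

Dampness scores 1.0 × 40 = 40 (severe answer, strong mapping), Qi
deficiency 0.618 × 25 = 15.45, Spleen 0.618 × 30 = 18.54 (question 3
was answered "none" and contributes nothing). Higher values mean
stronger evidence for that element in this record. The other scripts
in `examples/` walk through condensation, cohort-level agreement
evaluation, combination discovery, and the end-to-end pipeline.

A thin CLI mirrors the library:

```bash
syndel simulate matrix --n-questions 177 --seed 1 --out M.csv
syndel simulate cohort --n-records 670 --n-questions 177 --seed 2 --out R.csv
syndel condense --matrix M.csv --rule symptom_normal --out Mc.csv
syndel evaluate --records R.csv --original M.csv --condensed Mc.csv --report report.json
syndel run --outdir out --seed 42
```

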