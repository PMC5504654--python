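"""Discover frequent syndrome-element combinations with an APOSD.

Each diagnosed record contributes its top-order elements as attributes
of a formal context; the attribute partial-ordered structure diagram
then layers attributes by how many records they cover, and root-to-
layer-k chains are the cohort's common element combinations.
"""

from syndel import (
    CohortSpec,
    MatrixSpec,
    assign_value_orders,
    batch_quantify,
    build_context,
    export_diagram,
    extract_combinations,
    generate_aposd,
    generate_cohort,
    generate_matrix,
)

matrix = generate_matrix(MatrixSpec(n_questions=177, seed=1))
cohort = generate_cohort(CohortSpec(n_records=150, seed=3), list(range(1, 178)))

values = batch_quantify(cohort, matrix)
orders = [(v.record_id, assign_value_orders(v)) for v in values]
context = build_context(orders)
print(f"context: {len(context.objects)} records x {len(context.attributes)} elements")

tree = generate_aposd(context)
top = tree.root.children[0]
print(f"most common element: {top.attribute} covers {top.support} records")

print("\nfrequent chains (depth 2, support >= 5):")
for combo in extract_combinations(tree, depth=2, min_support=5):
    print(f"  {combo.label:<12} support {combo.support}")

# export_diagram(tree, "dot") renders the layered tree with Graphviz;
# chains read inner layer -> outer, most universal element first.
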