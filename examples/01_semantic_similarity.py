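"""Disease semantic similarity from a small hand-built disease DAG.

Builds a four-disease ontology (root R; R->A, R->B, B->C), prints each
term's contribution and the full similarity matrix. Rare terms carry
more weight, so C is closer to B (its parent) than to A.
"""

from irwrlda import DiseaseOntology, semantic_matrix, term_contribution

ont = DiseaseOntology(
    parents={
        "A": frozenset({"R"}),
        "B": frozenset({"R"}),
        "C": frozenset({"B"}),
    },
    diseases=("R", "A", "B", "C"),
)

print("term contributions (-log of DAG frequency):")
for term in sorted(ont.terms):
    print(f"  C({term}) = {term_contribution(ont, term):.4f}")

ss = semantic_matrix(ont, ["R", "A", "B", "C"])
print("\nsemantic similarity matrix SS:")
print(ss.round(4))

print(
    "\nSS(B, C) > SS(A, C): C sits below B, so they share the rare term B,"
    "\nwhile A and C share only the universal root R (zero contribution)."
)
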