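"""Tokenize a SMILES and list the attributes that carry correlation weights.

Every token ("SMILES atom") and every adjacent token pair becomes a
fixed-width 12-character attribute code; the hybrid configuration adds
Morgan extended-connectivity invariants of the hydrogen-suppressed graph.
"""

from mcqsar import FeatureConfig, extract_features, tokenize_smiles

smiles = "CC(=O)Oc1ccccc1"  # aspirin's ester fragment
tokens = tokenize_smiles(smiles)
print(f"SMILES : {smiles}")
print(f"tokens : {tokens}")

print("\nSMILES attributes (code -> multiplicity):")
for code, mult in sorted(extract_features(smiles).items()):
    print(f"  {code}  x{mult}")

hybrid = extract_features(smiles, FeatureConfig(graph_orders=frozenset({0, 1})))
graph_only = {c: m for c, m in hybrid.items() if c.startswith("EC")}
print("\ngraph invariants at Morgan orders 0-1 (vertex degree and its neighbour sum):")
for code, mult in sorted(graph_only.items()):
    print(f"  {code}  x{mult}")

# The multiset sizes follow the construction exactly: one atom code per
# token, one pair code per adjacent pair, one graph code per vertex per order.
print(f"\n{len(tokens)} tokens -> {len(tokens)} atom codes + {len(tokens) - 1} pair codes")
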