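"""Label positive and unlabeled genes from a typed knowledge graph.

Builds a tiny disease-compound-gene-ontology graph in memory, then runs
the two metapath selections: genes reached from the disease through a
compound become labeled positives; genes sharing an ontology term with
a positive form the unlabeled candidate pool.
"""

from pugene import KnowledgeGraph, build_pu_dataset, label_genes

kg = KnowledgeGraph()
for nid, ntype in [
    ("C0030567", "Disease"),            # query disease CUI
    ("CHEMBL25", "Compound"), ("CHEMBL112", "Compound"),
    ("SNCA", "Gene"), ("LRRK2", "Gene"), ("PRKN", "Gene"), ("GBA1", "Gene"),
    ("EFO:0001", "EFO"), ("EFO:0002", "EFO"),
]:
    kg.add_node(nid, ntype)

for u, v, rel in [
    ("C0030567", "CHEMBL25", "indication"),
    ("C0030567", "CHEMBL112", "indication"),
    ("CHEMBL25", "SNCA", "targets"),
    ("CHEMBL112", "LRRK2", "targets"),
    ("SNCA", "EFO:0001", "associated_with"),
    ("LRRK2", "EFO:0002", "associated_with"),
    ("PRKN", "EFO:0001", "associated_with"),
    ("GBA1", "EFO:0002", "associated_with"),
]:
    kg.add_edge(u, v, rel)

sets = label_genes(kg, ["C0030567"])
print("positive genes (Disease-Compound-Gene):", sets.positive_genes)
print("unlabeled genes (Gene-EFO-Gene):       ", sets.unlabeled_genes)
print("feature terms (bridging EFO nodes):    ", sets.feature_terms)

dataset = build_pu_dataset(kg, sets)
print("\nbinary feature matrix (rows = genes, cols = terms):")
print(dataset.X.toarray())
print("labels (1 = labeled positive, 0 = unlabeled):", dataset.y.tolist())
# Each 1 marks a gene-term edge; PRKN and GBA1 are candidates because
# they share a term with a positive, not because anything links them to
# the disease directly.
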