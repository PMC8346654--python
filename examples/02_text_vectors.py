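"""Preprocess caption text and build an embedding-mean document vector.

The pipeline substitutes named entities with generic concept terms,
lowercases, tokenizes, Porter-stems and removes stop words; the document
vector is the mean embedding of the distinct remaining tokens.
"""

import numpy as np

import figword as fw

ner = fw.NERSubstitutionMap({"Pax6": "gene", "Mus musculus": "species"})
text = "Pax6 expression in Mus musculus embryos"
tokens = fw.preprocess(text, ner)
print("raw text :", text)
print("tokens   :", list(tokens.tokens))
# Pax6 -> gene, the species name -> species, 'in' is a stop word, and
# the remaining words are stemmed (expression -> express)

# a tiny embedding table; real tables are 200-dimensional word2vec text
rng = np.random.default_rng(0)
table = fw.EmbeddingTable({t: rng.standard_normal(8) for t in tokens.tokens})
vec = fw.mean_embedding(tokens, table)
print("vector   :", np.round(vec, 3))
print("length   :", len(vec), "(= embedding dimension)")
# each distinct token contributes once, however often it occurs
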