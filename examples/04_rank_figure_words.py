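"""Find the Figure-words that most distinguish relevant publications.

Counts each figure's Figure-word per document class and ranks by the
pooled two-proportion z statistic; positive z = enriched among relevant
documents' figures.
"""

import figword as fw
from figword.experiments import ranking_config

# corpus where relevant papers favor fluorescence-microscopy panels
# (inclusion probability 0.6 vs 0.05), other panel types balanced
docs, _ = fw.generate_corpus(ranking_config(n_docs=300, seed=5))
counts = fw.count_figure_words(docs)
print(f"figures counted: {counts.n_rel} relevant, {counts.n_irr} irrelevant")

ranked = fw.rank_distinguishing(counts, top=5)
print(ranked.to_string(index=False))
# the fluorescence-only Figure-word (index 32) should top the |z|
# ranking; words that co-occur with fluorescence follow with smaller
# counts, and words crowded out of relevant papers get negative z
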