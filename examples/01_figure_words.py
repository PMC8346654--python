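"""Encode figures as Figure-words and a document as its d_IMG vector.

A Figure-word is an 11-bit indicator of which panel types co-occur in
one figure; a document's image representation marks which of the 2048
possible Figure-words appear among its figures.
"""

import figword as fw

taxonomy = fw.DEFAULT_TAXONOMY

word = fw.encode_figure(["Histogram", "Fluorescence microscopy"], taxonomy)
print("panel classes :", "Histogram + Fluorescence microscopy")
print("Figure-word   :", "<" + ",".join(map(str, word.bits)) + ">")
print("integer index :", fw.figure_word_index(word))
# bits 1 and 6 are set (positions of the two classes in the taxonomy);
# with position 1 as the least-significant bit the index is 2^0 + 2^5 = 33

doc = fw.DocumentRecord(
    doc_id="example",
    figures=[
        fw.FigureRecord(panel_labels=["Histogram"]),
        fw.FigureRecord(panel_labels=["Histogram", "Fluorescence microscopy"]),
        fw.FigureRecord(panel_labels=["Histogram"]),  # duplicate composition
    ],
)
vec = fw.document_image_vector(doc, taxonomy)
print("d_IMG indices :", sorted(vec.indices), "of", vec.size, "possible")
# three figures but only two distinct Figure-words: d_IMG is a set, so
# repeating a panel composition adds nothing
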