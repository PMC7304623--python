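"""Preprocess a report and featurize it three ways.

Shows the cleaning/phrase-merging pipeline on a dictated report, then the
bag-of-words counts, tf-idf weights and a summed document embedding for
the same text.
"""

import numpy as np

import radstroke as rs

text = (
    "There is loss of grey-white matter consistent with early ischemic stroke. "
    "Impression: There is an ischemic stroke in the MCA distribution."
)
doc = rs.preprocess_report(text, report_id="example")
print("Sentences of tokens:")
for sent in doc.sentences:
    print(" ", sent)

vocab = rs.fit_vocabulary([doc])
bow = rs.bow_vector(doc, vocab)
print("\nBag-of-words counts (nonzero):")
for tok, j in vocab.index.items():
    if bow[j]:
        print(f"  {tok:>16}: {int(bow[j])}")
print("-> 'stroke' and 'is' both occur twice; BOW treats them identically.")

corpus = [
    doc,
    rs.preprocess_report("There is no acute infarct.", report_id="b"),
    rs.preprocess_report("There is chronic small vessel disease.", report_id="c"),
]
vocab = rs.fit_vocabulary(corpus)
tfidf = rs.tfidf_transform([doc], vocab)
w = tfidf.values[0]
print("\ntf-idf weights: 'is' %.3f vs 'stroke' %.3f" % (
    w[vocab.index["is"]], w[vocab.index["stroke"]]))
print("-> the corpus-ubiquitous 'is' is down-weighted relative to 'stroke'.")

rng = np.random.default_rng(0)
emb = rs.EmbeddingFile(tokens=vocab.tokens, vectors=rng.normal(size=(len(vocab), 5)))
vec = rs.doc_embedding(doc, emb)
print("\nDocument embedding (sum of word vectors), first 5 dims:", np.round(vec, 3))
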