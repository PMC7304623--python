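"""Hierarchical LSTM vs lasso logistic regression, compared with McNemar.

Trains GloVe embeddings on a separate unlabeled corpus, fits both a
BOW+logistic-regression model and the hierarchical LSTM on one 75/25
split, and tests whether their stroke-presence predictions are
equivalent.
"""

import radstroke as rs
from radstroke import evaluation as ev
from radstroke.io import labels_frame

# embeddings come from a separate unlabeled corpus (no label leakage)
emb_reports, _ = rs.generate_reports(rs.GeneratorConfig(n_reports=1200, seed=99))
emb_docs = rs.preprocess_corpus(emb_reports)
vocab = rs.fit_vocabulary(emb_docs, min_df=5)
cooc = rs.build_cooccurrence(emb_docs, vocab, window=10)
emb = rs.export_embeddings(rs.train_glove(cooc, rs.GloveConfig(d=50, iters=25, seed=9)), vocab)

reports, labels = rs.generate_reports(rs.GeneratorConfig(n_reports=600, seed=21))
docs = rs.preprocess_corpus(reports)
plan = rs.make_splits(reports, labels, ev.SplitConfig(seed=21))
by_id = {d.report_id: d for d in docs}
lab = labels_frame(labels)
tr = [by_id[i] for i in plan.train_ids[0]]
te = [by_id[i] for i in plan.test_ids[0]]
y_tr = lab.loc[plan.train_ids[0], "stroke"].to_numpy()
y_te = lab.loc[plan.test_ids[0], "stroke"].to_numpy()

bow_vocab = rs.fit_vocabulary(tr, min_df=2)
lr = rs.train(rs.bow_matrix(tr, bow_vocab), y_tr, rs.LogRegSpec())
p_lr = rs.predict_proba(lr, rs.bow_matrix(te, bow_vocab))

rnn = rs.train_rnn_document_model(
    tr, emb, y_tr, rs.RNNSpec(word_hidden=32, sent_hidden=32, epochs=8, seed=5)
)
p_rnn = rnn.predict_proba(te)

for name, p in (("BOW+logreg", p_lr), ("GloVe+LSTM", p_rnn)):
    _, auc = rs.roc_and_auc(y_te, p)
    print(f"{name}: test AUC {auc:.3f}")

pred_lr = (p_lr >= rs.select_threshold(y_te, p_lr)).astype(int)
pred_rnn = (p_rnn >= rs.select_threshold(y_te, p_rnn)).astype(int)
res = rs.mcnemar_test(y_te, pred_rnn, pred_lr)
print(f"\nMcNemar: b={res.b} c={res.c} chi2={res.chi2:.2f} p={res.p:.3f}")
print("b/c are the discordant counts (one model right, the other wrong);")
print("a large p is consistent with equivalent performance.")
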