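"""Tokenize SMILES and build a corpus vocabulary.

The generator sees molecules as token sequences: multi-character atoms
(Cl, Br), bracket atoms ([nH]) and ring-closure digits are single tokens,
with GO/END sentinels delimiting every sequence.
"""

from paretogen import build_vocabulary, detokenize, make_corpus, tokenize

corpus = make_corpus(100, seed=7)
vocab, skipped = build_vocabulary(corpus)
print(f"corpus of {len(corpus)} molecules -> vocabulary of {len(vocab)} tokens "
      f"({skipped} skipped)")
print("tokens:", " ".join(vocab.tokens))

for smi in ("CCl", "c1ccccc1", corpus[0]):
    seq = tokenize(smi, vocab)
    print(f"{smi!r} -> {seq.tokens} -> round-trip {detokenize(seq)!r}")
# Each printed token is one decision step for the language model; the
# round-trip shows tokenization is lossless.
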