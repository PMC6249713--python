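"""Generate a synthetic bacteria-NER corpus and inspect what was planted.

The generator fills sentence templates with real Latin binomials (sometimes
abbreviated to genus initial + species), keeps the exact gold spans, and
writes standard two-column IOB2.
"""

from bacner import SynthConfig, generate_corpus, write_iob2

config = SynthConfig(n_sentences=8, seed=7)
corpus, gold = generate_corpus(config)

print(f"{len(corpus)} sentences, {corpus.n_tokens} tokens, {len(gold)} gold entities\n")
print(write_iob2(corpus).split("\n\n")[0])  # first sentence in IOB2
print("\ngold spans (sentence, [start, end), type):")
for span in sorted(gold):
    sent = corpus.sentences[span.sentence]
    mention = " ".join(sent.surfaces[span.start : span.end])
    print(f"  ({span.sentence}, [{span.start}, {span.end}), {span.type})  {mention!r}")

# Each span points at exactly the tokens of one planted bacteria name; B-BAC
# marks the first token, I-BAC the rest, O everything else.
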