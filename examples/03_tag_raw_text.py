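"""Tag a raw abstract: tokenize, Viterbi-decode, and list the entities found.

Prediction needs only the model file contents — templates and the name
dictionary travel inside the model.
"""

from bacner import generate_corpus, spans_from_tags, tokenize, train
from bacner.synth import SynthConfig

corpus, _ = generate_corpus(SynthConfig(n_sentences=150, seed=11))
model = train(corpus, max_iter=80)

abstract = (
    "Cultures of E. coli were grown overnight under anaerobic conditions. "
    "Treatment reduced colonization by Helicobacter pylori in the murine gut. "
    "The genome of Akkermansia muciniphila encodes numerous virulence factors."
)

for sent in tokenize(abstract):
    surfaces = [t.surface for t in sent]
    tags = model.predict(surfaces)
    for span in sorted(spans_from_tags(tags)):
        print(" ".join(surfaces[span.start : span.end]))

# Each printed line is one recognized bacteria mention, including the
# abbreviated writing "E. coli" of Escherichia coli.
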