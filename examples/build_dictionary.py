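"""Reduce MeSH headings to a filtered single-word dictionary.

Each multiword heading is split into lowercase tokens; duplicates, stop
words and words shorter than three characters are then removed and the
survivors sorted, giving the deterministic vocabulary that parameterizes
the latent-semantic engine.
"""

import literank as lr

headings = [
    lr.MeshHeading("Reproductive and Urinary Physiological Phenomena"),
    lr.MeshHeading("Stroke"),
    lr.MeshHeading("Heart-Assist Devices"),
    lr.MeshHeading("Vitamin B 12"),
]

for h in headings:
    print(f"{h.label!r:55s} -> {lr.tokenize_heading(h)}")

tokens = lr.build_vocabulary(headings)
dictionary = lr.filter_vocabulary(tokens)
print(f"\n{len(tokens)} raw tokens -> {len(dictionary)}-word dictionary:")
print(" ", ", ".join(dictionary.words))
# Note: 'and' (stop word) and 'b'/'12' (shorter than 3 characters) are
# gone; every surviving word is unique, lowercase and sorted.
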