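"""Marked-text span codec: bracket an entity, recover its offsets.

The model never emits character offsets; it echoes the observation with the
entity wrapped in square brackets, and offsets are recovered by locating
the brackets.  Discontinuous entities get one bracket pair per segment.
"""

from phenonorm import mark_text, parse_spans, recover_spans, serialize_spans

marked = "EYES: partial [synophrys], long lashes, horizontal slant"
text, spans = recover_spans(marked)
print(f"marked:   {marked}")
print(f"unmarked: {text}")
print(f"spans:    {serialize_spans(spans)}   -> {spans.extract(text)!r}")
# 14–23 selects "synophrys": 0-based start, exclusive end.

marked = "MOUTH: [normal] lips, [tongue], high palate"
text, spans = recover_spans(marked)
print(f"\ndisjoint: {serialize_spans(spans)} -> {spans.extract(text)!r}")
# Two segments, 7–13 and 20–26, read together as "normal tongue".

# The codec round-trips: marking those spans reproduces the marked string.
assert mark_text(text, spans) == marked
assert parse_spans(serialize_spans(spans)) == spans
print("\nround trip: mark_text(recover_spans(m)) == m  [ok]")
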