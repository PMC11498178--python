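# Methods

## Problem setting

Each input is one organ-system observation from a dysmorphology physical
examination: an upper-case header, a colon, then comma/semicolon-separated
findings. The task is to extract each *abnormal* key finding, with its
character span(s), and map it to a unique HPO concept. Findings may be
discontinuous (`MOUTH: [normal] lips, [tongue]`), modifier words ("mild",
"slightly", "prominent") are excluded from gold boundaries, and many
observations contain no findings at all.

## Pipeline model and assumptions

The pipeline delegates *recognition* to a chat LLM and keeps
*identification* rule-based. This rests on two assumptions about
generative models: they cannot be trusted to emit character offsets or
ontology identifiers (both hallucinate), but they can echo input text with
in-line markup and name concepts in natural language. Hence the response
contract: a pipe-delimited table of (preferred HPO term, observation text
with the entity bracketed), from which offsets are recovered
deterministically and concepts resolved by dictionary.

The backend is a one-method contract (`Prompt -> assistant text`). Every
offline path uses deterministic replay backends; the HTTP adapter for live
chat APIs is transport plumbing (temperature 0 by default, 3 attempts with
exponential backoff — a documented default, the underlying decoding
parameters are not part of the algorithm).

### Span recovery and discard rules

Unmarking is exact: each bracketed run becomes one segment with offsets
into the bracket-stripped string. A prediction is discarded (kept in the
output with a reason, but span-less) when brackets are unbalanced or
nested, when no brackets are present, when any offset would exceed the
original text, or when the unmarked echo differs from the original
(`text_mismatch`). One tolerance is applied before declaring a mismatch:
if the two strings differ only in whitespace runs, offsets are remapped
onto the original with a two-pointer walk. Anything further — typo repair,
fuzzy alignment — is deliberately rejected: an edited echo makes offsets
meaningless, and a discarded span can still contribute a concept through
the preferred-term step. Spans never silently shift.

### Dictionary normalization

Keys are built by case-folding, stripping punctuation at token edges,
stemming each token with a Porter-family English suffix stemmer, and
re-joining with single spaces. The stemmer is implemented in-package
(classic Porter, 1980 rules) and injectable; the dictionary logic never
depends on which Porter-family stemmer is plugged in. Key collisions are
resolved by source precedence *training surface > HPO preferred term > HPO
synonym* — task annotations define the behavior to match, so they outrank
ontology wording; same-precedence collisions keep the later entry and log
it. The exclusion list (modifier and unobservable concepts) is a required
user input, not a constant: its composition is task-specific and
distributed by task organizers, so the package takes a one-ID-per-line
file.

### Few-shot selection

Similarity is the cosine of mean token vectors. The token embedder is an
injected provider because the selection *algorithm* only needs "a fixed
vector per token"; which pretrained vectors to use is a deployment choice.
The default embedder derives a deterministic 64-dimensional Gaussian
vector from a hash of each token — shared tokens then dominate the cosine,
which preserves the algorithm's ranking structure offline and makes tests
reproducible across processes. It does not model true synonymy; with real
pretrained vectors the ranking improves but nothing else changes.
Negatives are ranked with the same similarity function as positives.
Top-k ties break by pool order (stable, reproducible); the final list is
shuffled by a seeded Fisher–Yates so category blocks form no positional
pattern. Shortfalls (a pool smaller than its quota) take all available and
log the gap.

The empty-response convention is a header-only table: the parser reads
"no data rows" as "no entities", and negative few-shot examples teach
exactly that format. This convention is a documented choice (configurable
at the parser level, which tolerates leading/trailing pipes and markdown
separator rows either way).

### Curation

Span-inconsistency detection groups annotated surfaces per concept and
flags pairs differing only by leading/trailing tokens from a configurable
modifier lexicon (defaults: mild, mildly, slight, slightly, prominent,
partial, partially, very, somewhat, borderline). Repair of span variants
is manual-map only — deciding the correct boundary needs the guideline,
not a heuristic. Concept-inconsistency detection flags case-folded
surfaces mapped to multiple IDs; repair is majority-vote (ties flagged,
untouched) or manual-map. Merge rules replace co-occurring concepts within
one observation by their combined concept, with span union and coalescing
of overlapping segments. Normal-polarity findings are dropped last; the
full pass is idempotent and never edits observation texts. The surface
form of a discontinuous annotation is its segment substrings joined by
single spaces, everywhere in the package.

### Evaluation

Matching is per observation and per concept, one-to-one. Within each
(observation, concept) group the maximum bipartite matching is computed by
augmenting paths — groups are tiny, and maximum matching makes counts
independent of prediction order and monotone in the match relation, so
TP(strict) ≤ TP(overlapping) ≤ TP(normalization-only) holds structurally.
Duplicate predictions are deduplicated first. Predictions without a
concept ID are excluded from scoring in every setting by default (a flag
counts them as FP in the span settings); predictions with an ID but
discarded spans participate everywhere — matchable in normalization-only,
unmatched in the span settings — so the prediction multiset is constant
across settings and F1 inherits the TP ordering.

## Synthetic data

The generator reproduces the structural statistics the pipeline exercises:
12% empty observations, a zero-truncated Poisson number of findings per
non-empty observation (rate 0.859, mean ≈ 1.49), 14% per-finding chance of
a discontinuous span (realized slightly lower, since one-word surfaces
cannot be split), 20 organ-system headers, 15% modifier injection (always
outside gold boundaries), 20% out-of-ontology paraphrase surfaces (forcing
the preferred-term step), and 10% normal-polarity findings (matching the
roughly one-in-ten share of normal annotations in comparable corpora) for
curation to drop. Concepts are adjective+noun phrases over disjoint stem
classes, so dictionary keys never collide across concepts and a dictionary
built from the ontology plus the corpus's own surfaces resolves 100% of
gold findings — the closed-world property behind the end-to-end F1 = 1.0
replay check. A per-organ tricky registry (5 examples each: disjoint span,
modifier exclusion, two header-annotation variants, and a combined case)
is generated alongside.

What the generator does *not* emulate: real clinical vocabulary breadth,
misspellings, abbreviation noise, or patient-level structure. Green
pipeline tests demonstrate that the machinery is correct, not that
extraction quality on real clinical text is high — the latter depends on
the live model and ontology coverage.

## Numerical and procedural choices

* Offsets are 0-based with exclusive end throughout; span strings render
  with an en dash (`14–23`) and parse with en dash or hyphen.
* Missing-value token `NA` (empty accepted on read); polarity markers `X`
  (normal) and `–`/`-` (abnormal).
* Entity-table rows serialize in ascending first-segment order; `|` inside
  a cell is replaced by `/` with a warning.
* Mock corruption modes are seeded per (seed, query), so corrupted runs
  are exactly reproducible.
* Test and acceptance problem sizes: unit corpora of 120–200 observations,
  the end-to-end replay check at 500, the codec round-trip at 10,000
  random pairs, and the degradation/monotonicity sweep over 100 corrupted
  runs of 30 observations each — sizes chosen so the structural properties
  they check are already stable.

## Known limitations

* No fuzzy re-alignment of model-edited echoes; such predictions lose
  their spans by design.
* The dictionary is exact-match after normalization — no embedding-based
  or approximate retrieval over HPO.
* Remote fine-tuning is an interface stub: the package exports the chat
  JSONL dataset but launching a job is provider-side.
* The ontology reader handles only minimal OBO (id/name/synonym) and
  tabular term lists; no is_a reasoning or cross-references.
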