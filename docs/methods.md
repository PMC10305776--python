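# Methods

## Problem setting

Deciding whether an acute ischaemic stroke patient can safely receive
thrombolysis requires checking a list of contraindications — recent major
surgery, anticoagulant medication, prior intracranial haemorrhage, and so on
— much of which lives in unstructured text: discharge letters, GP referrals,
clinic letters. `strokener` implements the machinery around clinical named
entity recognition (NER) for this task: an 86-entity inventory of
stroke-relevant concepts, span annotation I/O, a string-search baseline,
span-level evaluation, label-property statistics that explain per-label
performance, logit-averaging ensembling for token classifiers, and a
simulator that generates annotated letters so every computation is testable
without access to restricted clinical data.

## Entity inventory

The packaged ontology holds exactly 86 entities in five categories
(Diagnosis 44, Symptom 19, Social history 6, Medication 11, Treatment 6).
Canonical identifiers are lower-kebab-case of the display names (e.g.
`todds-paresis`, `functional-neurological-disorder`). Each entity carries a
seed list of surface forms — common abbreviations and clinical phrasings
(`SAH`, `LVSD`, `nuchal rigidity`, …) curated in this repository — used by
the simulator as sampling pools. Seeds are deliberately *not* lookup keys:
`lookup("SAH")` misses, because resolving free-text synonyms is an entity
linking problem the toolkit does not attempt. The thrombolysis eligibility
checklist is carried as display text with entity links for report grouping
only; no checklist question is ever answered, and numeric thresholds (BP,
platelets, glucose, INR) are not extracted.

## Spans, tokens and the IOB codec

Character offsets are 0-based half-open, the brat standoff convention; a
span's surface must equal its text slice. The tokenizer is deliberately
simple and deterministic: maximal alphanumeric runs are word tokens and
every other non-space character is a single-character token, so offsets are
always recoverable and `"BP 185/110."` splits into
`["BP","185","/","110","."]`. Case is preserved at this layer; the
dictionary and the name-regularity statistic lower-case downstream.

IOB encoding over N entity classes uses the 2N+1 tag space `{O} ∪ {B-e,
I-e}` with `O` first, then B/I pairs in ontology order. Edge rules:

- a span that starts or ends mid-token claims the whole token — the least
  destructive choice, since lenient evaluation tolerates boundary slack;
- overlapping gold spans with conflicting claims are rejected by default
  (the annotation scheme is flat); a `keep-longest` flag resolves them by
  giving longer spans priority;
- decoding is total: an orphan `I-e` is repaired to `B-e`, and maximal
  `B,I…I` runs become spans from the first token's start to the last
  token's end.

For collision-free, token-aligned spans, decode∘encode is the identity;
this is property-tested over simulator output.

## String-search baseline

The baseline compiles every normalized training surface form (lowercase,
whitespace collapsed) into a form→label map; a form observed under two or
more labels is ambiguous and dropped entirely, never majority-voted.
Prediction scans token positions left to right, trying the longest
candidate first; matches are anchored at token boundaries, so a form never
fires inside a word. Anchoring is a repo choice — pure substring search is
the plausible alternative — made because clinical shorthand makes mid-word
hits ("fall" inside "falls") clearly wrong.

## Evaluation

Strict matching requires identical (start, end, label); lenient matching
requires the same label and at least one shared character. Matching is
one-to-one and greedy by descending character overlap (ties: earlier gold
span, then earlier prediction). The cardinality of greedy matching is
checked against an exhaustive maximum bipartite matching oracle on all
small fixture documents; on well-separated spans (the realistic case) each
prediction overlaps at most one gold span and greedy is trivially optimal.

Conventions: precision (or recall) is 0 when its denominator is 0 while the
other side is non-empty; a label with neither gold nor predicted spans is
excluded from macro averaging, keeping macro scores comparable across
models. Micro metrics pool counts over labels and documents. Annotator
agreement is the same computation with the annotator as the prediction
side. The in-dict/out-dict diagnostic classes each gold test span by
whether its normalized surface occurred with the same label in training and
reports recall separately; an empty class reports `None`, never a number.
Note that the structural fact "string search has zero out-dict recall"
holds under strict matching; leniently, a hit on a seen sub-form inside an
unseen longer form still counts as overlap.

## Label properties

For each label with training spans:

- **frequency** `N` and `log10 N`;
- **name regularity** `(N − N_unique)/(N − 1)` over normalized surfaces;
  1 when every span is identical, 0 when all are distinct, 1 by convention
  at `N = 1`. The statistic is invariant to order and case and strictly
  decreases when a duplicate is replaced by a new unique form;
- **context regularity**: per mention, up to 5 tokens each side of the
  span; average the word embeddings of in-vocabulary context tokens
  (out-of-vocabulary tokens are skipped, not zero-filled, to avoid diluting
  the mean); L2-normalize; report the mean pairwise dot product over
  unordered mention pairs. Mentions with no usable context are skipped and
  counted; fewer than two usable mentions gives an undefined marker. Values
  are genuine cosines and are not clamped — embedding spaces with negative
  similarities can push the statistic below 0.

Embeddings are pluggable: any word2vec-format text table, or the packaged
deterministic hash-embedding table (a fixed pseudo-random unit vector per
word). The hash table carries no semantics; it exists so identical contexts
score exactly 1 and unrelated contexts score near 0, which is all the
synthetic-data tests require — conclusions about real distributional
similarity need a real embedding table.

The regression is ordinary least squares of per-label *lenient* F1 on
[log10 frequency, name regularity, context regularity] with intercept,
reporting β, classical standard errors, two-sided t-test p-values and r².
Labels with undefined predictors are dropped and reported; a rank-deficient
design raises rather than silently pseudo-inverting.

## Ensembling

Any object producing a (tokens × 2N+1) logit matrix over the shared tag
space can join an ensemble. Member logits are averaged elementwise —
deliberately *not* converted to probabilities first — so member confidence
carries weight: a strongly confident minority can outvote a lukewarm
majority, and rescaling one member's logits changes outcomes (both are
property-tested). At an exact tie of mean logits, `O` wins over entity
tags, a conservative choice favouring precision; otherwise the lowest tag
index wins. Decoded spans come from the same IOB repair path as any tag
sequence. A dictionary-backed classifier adapter (+confidence on matched
B/I tags, +confidence on `O` for unmatched tokens) realizes the contract so
ensembling is exercised end to end without a trained neural model; a logit
interchange TSV (offsets + 2N+1 scores per token row) lets externally
trained models join.

## The simulator

`generate_corpus` assembles letters from a header (document id, patient id,
document type), entity-bearing sentences instantiated from templates with a
`{E}` slot, and entity-free filler sentences. Defaults emulate the shape of
the clinical corpus this toolkit targets, scaled to desk speed: 200
patients, ~2.8 documents per patient (≈560 documents), 5,000 spans over the
full 86-label inventory with Zipf-tailed frequencies (exponent 1.1), a
document-type mix dominated by GP referrals, and per-label surface pools
from the ontology seeds. All randomness flows from a mandatory seed; the
same configuration is byte-identical across runs.

Two dials make the label-property statistics controllable: the per-label
surface-form pool size drives name regularity down as it grows, and the
per-label template pool size drives context regularity down as it grows.
Every packaged template keeps at least five tokens on each side of the
slot, so a mention's ±5-token context window never leaves its own sentence;
context regularity therefore depends only on the template subset, which
makes the monotone sweep deterministic.

The noise model applies, per span: deletion; boundary jitter by up to a
configured number of whole tokens per side (drawn from the non-zero grid,
clipped to the document, and constrained to keep overlap with the original
span — so lenient matching survives while strict matching breaks); label
confusion to a random other corpus label. Spurious spans annotate a random
1–2 token run that overlaps no existing span, with a random corpus label —
annotator noise cannot alter the letter text, so spurious *annotations* of
existing text are the faithful error mode. Deletion at rate d calibrates
agreement recall to ≈ 1 − d (binomial error), checked at d = 0.1 over
≥2,000 spans.

Patient-level splitting keeps all of a patient's documents on one side of
the train/test split and in one cross-validation fold; fold sizes differ by
at most one patient.

### What the simulator does and does not show

Generated letters have clinical *shape* (problem lists, medication lines,
referral phrasing) but template-bounded language: no negation, no
misspellings, no free word order, no cross-sentence discourse. Passing
tests therefore demonstrate that the statistics, codecs, matchers and the
ensemble behave exactly as specified on controlled data — they do not
certify extraction accuracy on real clinical text, which depends on a
trained token classifier supplied through the classifier contract.

## Problem sizes and numerical choices

Test corpora use 30–250 patients and 300–5,000 spans, sizes at which every
suite runs in seconds while binomial/chi-square checks have the power they
need. The regression recovery experiment uses 30 labels with synonym-pool
sizes cycling {1, 3, 9, 27, 81} and Zipf exponent 0.7 over 4,000 spans, so
that rare large-pool labels genuinely contain unseen test surfaces — the
mechanism that makes name regularity predictive of string-search F1
(measured β_name ≈ +0.3, p < 1e-4 at the packaged seed). Floating-point
comparisons in tests use exact equality only where arithmetic forces it
(limit cases, count ratios) and 1e-10 tolerances against the
normal-equations oracle otherwise.

## Known limitations

- Greedy one-to-one matching can undercount the optimal pairing on
  pathological nested-span configurations; the oracle-equivalence tests
  bound this on realistic data but it is not a theorem.
- The exponent-free reading of the name-regularity formula is a documented
  interpretation choice, forced by the statistic's stated limit behaviour.
- The dictionary baseline's boundary anchoring is one defensible reading of
  "exact string search"; substring semantics would change precision.
- Context regularity with hash embeddings measures template diversity, not
  semantics.
- No negation or temporality modifiers; checklist items are display-only.
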