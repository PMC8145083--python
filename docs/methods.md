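# Methods

This note records the modelling choices behind `kias`: what each stage
assumes, which parameters matter, what the synthetic corpus does and does
not emulate, and where the design was genuinely open.

## The summarization unit

The pipeline summarizes *templated statements*, not raw turns. Every
interviewer question is merged with the participant turns that follow it
and rendered as "participant was asked X, the participant said Y", with
second-person pronouns in X rewritten to third person (a fixed 6-entry
token table plus a 2-entry be-auxiliary inversion, "were you" → "they
were"). Templating serves two purposes: it keeps the question–answer
association explicit, and it lets graph-based ranking measure whether an
answer is lexically cohesive with its question — an incohesive pair
contributes a near-disjoint subgraph whose paths score poorly. Interviewer
turns with no answer yield empty-answer statements that are never counted
as clinical evidence but may survive pruning as context. Participant turns
before any question are dropped: the unit of analysis is the pair.

All text is lowercased and whitespace-normalized on entry; transcript
conventions for incomplete words (completion map) and unrecognizable
tokens (`xxx`) are applied at the same point, so every later stage sees
one canonical tokenization.

## Pruning as knowledge-based recall

A statement is evidence if it contains a depression-lexicon phrase
verbatim, or a bigram/trigram whose mean word vector has cosine ≥ τ with
some lexicon phrase's mean vector. Defaults: τ = 0.6 (recall-preferring; a
stricter τ trades recall for precision and pruning is monotone in it) and
context radius r = 1 (neighbors of a hit are kept because answers are
often anaphoric and need their surroundings to be interpretable). Pruning
deliberately operates on the combined statement, so a clinically relevant
question with a bland answer is retained. One occurrence of a phrase
suffices — there is no frequency requirement, which is precisely what
separates this filter from frequency-based extraction.

Semantic matching uses phrase vectors built as unweighted means of
in-vocabulary word vectors; out-of-vocabulary words are skipped and an
all-OOV n-gram simply cannot match semantically. One-word lexicon entries
are reachable through exact matching only.

## Retrofitting and the word semantic score

Word vectors are specialised to the lexicon by Faruqui-style retrofitting:
the lexicon induces an undirected graph (words sharing a phrase are
linked; head words of same-category phrases are linked, head = first
token), and vectors are updated synchronously for 10 Jacobi rounds with

    q_i ← (α·q̂_i + Σ_{j∈N(i)} β_ij·q_j) / (α + Σ_j β_ij),

α = 1 and β_ij = 1/degree(i). Words off the graph are untouched. The
synchronous rounds overshoot slightly before settling (the mean
linked-pair cosine is not monotone per round), but every depth leaves
linked pairs more similar than the raw embeddings; the tests assert that
sound version of the property.

WSS(w) is the maximum cosine of w's retrofitted vector with any lexicon
word, clamped to [0, 1] (negative similarities carry no clinical signal
and must not flip the sign of a probability boost); OOV words score 0.
WSS enters the scorer twice: it boosts trigram probabilities inside the
quality score, and it elevates TextRank importance to Imp·(1 + WSS) before
path informativeness is summed. The second route is what gives the
knowledge a real lever on selection: quality differences are O(10⁻³) per
word after length normalization, while importance elevation up to a factor
of 2 reliably steers the per-slice argmax toward lexicon-bearing paths.
Setting WSS ≡ 0 switches both routes off and yields the plain abstractive
baseline, bit for bit.

## Language model and quality

Q is computed from an ARPA back-off trigram model (log base 10; sentences
padded with `<s> <s>`; Katz back-off adds the skipped contexts' back-off
weights; OOV words and saturated terms sit at the floor, −10 log10). Each
word's probability is boosted multiplicatively by (1 + WSS) and capped at
1; the summed log probabilities are normalized by L·floor with L = the
path length (padded-context positions included, so single-word paths are
scoreable), giving LL_norm ∈ [0, 1] and Q = 1 − LL_norm. Whether the
underlying work normalized its log-likelihood to [0, 1] is not
reconstructable; this normalization is declared, configurable via
`log_floor`, and covered by ordering properties (bounds, monotonicity in
WSS and in trigram probability) rather than exact-value tests.

## Word graph, TextRank, and candidates

Statements are added to the slice graph as chains between dummy START/END
nodes. Content words merge across statements when their lowercase form
*and within-statement occurrence index* agree; without the occurrence
index, the template word "participant" (which occurs twice per statement)
would fold every chain into a cycle and no simple START→END path could
traverse a whole statement. Stopwords merge only under a guarded rule
(the neighboring context must already coincide), so function words do not
create spurious fusions. TextRank runs the damped update (d = 0.78,
initialized at 1, tolerance 1e−6, ≤ 100 iterations — the iteration is a
contraction since column sums of the transition matrix are ≤ 1) over the
full graph including dummies; dummies are excluded from the returned
scores. Path candidates are enumerated in ascending total edge cost with
cost(e) = 1/traversal_count(e) (Yen's algorithm), ties broken
lexicographically on the word sequence; K = 100 candidates per slice,
minimum path length 8 words (lowered to the shortest statement of the
slice when that is shorter, so every slice has at least one candidate and
each original statement remains recoverable as a candidate).

## Selection

With one selection per slice the binary program reduces to an argmax; the
ILP formulation is kept (and reconciled against the argmax with explicit
tie-breaks: fewer words first, then earlier candidate rank) because the
per-slice constraint is where inter-slice constraints such as redundancy
control would later attach. The objective's 1/|W(p)| factor is applied to
the *sum* I + Q; the worked two-candidate example is selected identically
under either reading of where the normalization binds.

## Baselines

SumBasic follows the standard formulation: P(w) = c(w)/N over the whole
input, sentence weight = mean word probability, pick the best-scoring
sentence containing the currently most probable word, then square the
probabilities of its words. Its default output length ceil(n/window)
matches the abstractive systems for fair comparison. AoES runs SumBasic
over the pruned statements (a flag switches to raw) and abstracts over the
kept fraction (default 0.5). All three baselines and the knowledge-infused
system share one pruned input per conversation.

## Synthetic corpus

The generator emulates the *structure* of Wizard-of-Oz diagnostic
interviews: 58 Q&A pairs by default, phase proportions (0.25, 0.55, 0.20)
for the neutral/clinical/cool-down arc, lexicon phrases planted in
clinical-phase answers at rate 0.3, anaphora at 0.1, disfluencies at 0.2.
Question and answer banks are small templates whose vocabulary is kept
disjoint from the lexicon's content words, so a zero planting rate yields
a transcript with provably zero lexicon matches. Planted and filler
answers are kept at comparable token lengths (4–6) so that the objective's
brevity pressure does not confound the knowledge-infusion effect — the
synthetic benchmark is a controlled experiment, not a language model of
patients. Toy embeddings are random unit vectors with same-category
content words placed within arcsin(0.2) of a shared anchor (pairwise
cosine ≥ 0.92 by construction; function words are never anchored, since
anchoring them would leak category similarity into every sentence). The
toy trigram model is an add-k MLE with proper Katz-style back-off weights,
written and re-read as ARPA losslessly.

What the corpus does **not** emulate: real lexical diversity, grammatical
errors, topic drift, rephrased repeated questions, or genuinely ambiguous
clinical language. Passing the recovery tests therefore shows that the
pipeline surfaces planted clinical content under controlled conditions; it
does not certify clinical validity on real interviews.

## Evaluation

The pruned conversation serves as the reference summary. FRE uses the
classic coefficients with a deterministic vowel-group syllable heuristic
(silent-e correction; at least one syllable per word) and counts sentences
at line breaks and terminal punctuation, so scores are reproducible bit
for bit. The LDA reference model is chosen by scanning topic counts
(default stride 2 over a configurable range; the cohort runs scan 2–12 to
keep desk-scale runtime) and keeping the highest C_V-style coherence,
computed from document-cooccurrence NPMI vectors with the one-set
segmentation. JSD is base-2 (bounded [0, 1]) between inferred topic
posteriors. Thematic overlap takes each text's dominant topics (posterior
above the uniform 1/k), unions their top-10 terms, and reports the share
of the reference's term set covered — a declared formulation, since none
is fixed by precedent. ROUGE-1/2 use clipped n-gram counts; ROUGE-L uses
the longest common subsequence; both report recall and F1 with the shared
tokenizer, no stemming and no stopword removal.

## Cohort sizes and determinism

The acceptance cohort is 20 interviews of 58 pairs — large enough for the
directional claims (retention, JSD, overlap) to be stable across seeds,
small enough to run in seconds. Every stochastic component (generator,
embeddings, LDA) draws from the single run seed; the pipeline core is
seed-free and deterministic, and each CLI run writes a manifest (config +
input hashes) sufficient to reproduce it.

## Known limitations

- Fusion can attach an answer to the wrong question when the graph merges
  through shared answer openers ("yeah …"); the knowledge boost reduces
  but does not eliminate this, mirroring the failure class the approach
  is known for.
- The per-slice candidate generator is cost-ranked Yen enumeration; it is
  deterministic but can omit long low-frequency fusions when K is small.
- WSS on arbitrary words has a noise floor (the maximum over many random
  cosines is positive), which slightly dilutes the contrast between
  clinical and non-clinical paths in high dimensions.
- The thematic-overlap and coherence formulations are reasonable defaults,
  not canonical definitions; comparisons across packages should use the
  same implementation on both sides.
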