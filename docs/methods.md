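# Methods

## The classification problem

A tail-anchored (TA) protein exposes one hydrophobic transmembrane domain
(TMD) of roughly 15–25 residues within ~30 residues of the C-terminus,
followed by a short hydrophilic tail, with no N-terminal signal sequence.
The confounders are membrane proteins that *do* carry a signal sequence:
single-pass proteins (SP), multi-pass proteins (MP), and soluble secreted
proteins with no TMD at all (NO).  `tahmm` separates TA sequences from
these classes with three generative models and two decision rules.

## Hidden Markov models

All models are discrete HMMs over the 20-letter amino-acid alphabet with
region-tagged states and *structural* transition sparsity: a transition
absent from the grammar has probability exactly zero and remains zero
through training.  There is no end state; the likelihood of a sequence
terminates by summing (forward) or maximising (Viterbi) over all states
at the last position, so the model can be truncated anywhere by the
sequence end.

**TA model** (reads C-to-N, so callers reverse the input): tail block of
2 or 4 states, each allowed to loop on itself, advance, or enter the TMD;
25 TMD states whose first 14 may only advance (exits to the cap are
allowed from state 15 on, bounding decoded TMD runs to 15–25 residues);
5 cap states (exit after any of them, runs 1–5); one self-looping
globular state.  Initial probability is 0.5 on the tail start and 0.5 on
the TMD start, so a protein whose TMD abuts the C-terminus needs no tail.
Starting at the C-terminus keeps the number of transitions before the
TMD small; a TMD reached only after hundreds of transitions would be
hard to detect.

**SP model** (reads N-to-C): a 40-state signal block — 10 basic-biased,
15 hydrophobic-biased, 15 polar-biased states mirroring the tripartite
organisation of real signal peptides — as a chain with exits to the
globular(1) state from state 15 on (decoded signals span 15–40 residues);
then globular(1) (self + exit), cap, TMD (as in the TA model) and a
terminal self-looping globular(2).  Initial probability is split 0.5/0.5
between signal start and globular(1), so unsignalled starts are
representable.

**MP model**: signal, globular, cap and TMD regions as in the SP model,
but the TMD exits into a 20-state loop chain (decoded loops span 1–20
residues, the observed length range of inter-TMD connectors); each loop
state may advance, re-enter the cap (next membrane pass) or fall into the
globular state (long connector), and the globular state can re-enter the
cap, so any number of passes can be threaded.

Notable grammar choices: the TMD always enters the cap (no TMD→globular
shortcut), the cap has minimum length 1, and the two TA tail variants
(2 and 4 states) are both trained — the TA likelihood is their maximum,
while decoding always uses the 2-state variant.  Emissions are untied:
every state trains its own emission row.

### Initial parameters

Transition rows start uniform over each state's allowed successors.
Emission rows start from a 70/30 rule over three residue classes that
partition the alphabet — basic {K, R, H}, hydrophobic {A, C, F, I, L, M,
V, W} (the Kyte–Doolittle-positive letters), hydrophilic (the remaining
nine) — with 70 % of the mass uniform on the region's favoured class
(tail/globular/loop/signal-polar: hydrophilic; TMD/signal-hydrophobic:
hydrophobic; cap/signal-basic: basic).  The 70/30 split is strong enough
to break the symmetry of EM (each region drifts toward its own residue
class) yet weak enough to be re-estimated freely.

### Numerics

All inference is in natural-log space with log-sum-exp; the per-position
recursions are numba kernels, and the expected transition counts of
Baum–Welch factor into one matrix product per sequence with per-position
normalisers.  There is no underflow for sequences of at least several
thousand residues (tested at 5,000 against a scaled linear-space
oracle at 1e-9 relative).  Every M-step adds a pseudocount of 1e-6 to
all 20 letters of each emission row and to the structurally allowed
transitions and initial states only, then renormalises; no residue ever
has exactly zero emission probability, and structural zeros are
preserved.  Baum–Welch stops when the relative increase of the total
log-likelihood falls below `tol` (default 1e-6) or after `max_iter`
(default 100) iterations.  Viterbi ties break toward the lowest state
index at every backtrack step, making decodes deterministic across
platforms.  Ambiguity codes (B, Z, X, U, O, J) are emitted with
probability 1/20 by every state of every model, so they shift all
likelihoods by the same constant and cannot influence a classification;
they are excluded from emission-count updates during training.

## Scores, thresholds and decision rules

For a sequence of length *L*, S_sp = (ln l_ta − ln l_sp)/L and
S_mp = (ln l_ta − ln l_mp)/L, positive meaning TA-like.  Dividing by *L*
removes the trivial proportionality of log-likelihoods to length.  The
likelihood is the Viterbi joint probability by default ("likelihood by
decoding"); a switch selects the forward likelihood instead — the two
are nearly identical in practice because one path dominates these
sparse grammars.

The score threshold minimises the balanced error rate over candidate
thresholds placed midway between adjacent distinct pooled scores (plus
±∞ sentinels); `score ≥ threshold` counts as positive, and BER ties
break toward the smallest candidate.  Thresholds are fitted separately
for the TA-vs-SP and TA-vs-MP score distributions; predictions against
MP, NO or pooled negatives use the MP threshold with S_mp, predictions
against SP use the SP threshold with S_sp.

The decoding rule accepts a sequence iff its TA-model Viterbi decode
contains a TMD segment of ≥15 residues and the C-terminal tail segment
is ≤30 residues; failures are reported as `no-TMD`, `tail-too-long`, or
`all-tail` (the decode never left the tail region — typical for
hydrophilic sequences).  A decode with no tail segment counts as tail
length 0.  The combined rule is the conjunction of the two; its
positives are by construction a subset of each rule's positives, so it
is always at least as specific.

## Training protocol

The TA model trains on reversed TA sequences; SP and MP models on their
own classes; NO sequences are never used for training (no NO model
exists).  For evaluation, per-sequence likelihoods follow a k-fold
protocol (default k = 5): the likelihood of a sequence under *its own*
class's model comes from a fold model that never saw it, while the other
two models are trained on their full datasets — only the own-model
likelihood risks overfitting, so only it needs cross-validation.  Fold
assignment sorts ids canonically, applies a seeded shuffle, then deals
round-robin, making the folds independent of input order.  Each fold
model restarts from the same initial topology parameters.

## The synthetic data generators

Curated datasets cannot be shipped, so labelled data come from
ground-truth region HMMs.  Emission profiles at difficulty 1.0:

| profile | used by | composition |
|---|---|---|
| hydrophobic-rich | TMD, signal hydrophobic core | 0.85 mass uniform on the 8 hydrophobic letters |
| hydrophilic-rich | tail, loop, signal polar block, SP/MP/NO bodies | 0.85 mass uniform on the 9 hydrophilic letters |
| basic-rich | cap, signal N-block | 0.60 mass uniform on K/R/H |
| background | TA globular body | Swiss-Prot-like average frequencies |

The asymmetry between the TA body (average composition) and the SP/MP/NO
bodies (polar-biased) mirrors real compartments: a TA protein's body
stays in the cytosol, while translocated and secreted domains are
measurably depleted in hydrophobics.  This compositional difference is
what allows the decoding rule to reject hydrophilic-bodied negatives by
an all-tail decode — exactly the behaviour the decoding rule's `all-tail`
failure class records.

Generator transition rows are the topology defaults except where a
uniform row would produce unrealistic region lengths in *sampled* data:
tail states dwell on themselves with probability 0.7 (mean tail ≈7
residues; real tails are mostly under 10), SP-globular(1) and
MP-globular states with probability 0.95 (extramembrane domains of tens
of residues rather than 2), and loop states advance with probability 0.8
(mean loop ≈5 residues).  Without these dwell terms the SP/MP generators
emit TMD-dense caricatures — 2-residue globular runs between membrane
passes — and no trained model can represent a realistic long-bodied
negative.  The model-side topologies are untouched; training re-estimates
all transition probabilities from data either way.

A `difficulty` knob interpolates every generator emission row linearly
toward the uniform distribution (1.0 = full separation, 0.0 = classes
indistinguishable), enabling graded-hardness experiments.

Record lengths follow a log-normal truncated to [50, 1000] with median
250 (the length range where TA proteins are abundant); TA records are
rejection-sampled until the truth contains a complete 15–25-residue TMD
within 30 residues of the C-terminus followed only by tail states.
Truth segments are the sampled state path mapped to regions, in N→C
0-based half-open coordinates, written to a side-car TSV.

What the generators do **not** emulate: annotation noise, homologous
families (every record is independent), positional composition gradients
within real domains, and the rare real TA proteins whose TMD sits far
from the C-terminus.  Passing tests on synthetic data therefore
demonstrate the correctness and internal consistency of the machinery —
not field performance on curated proteomes, which depends on real
training data.

## Problem sizes in the test and acceptance runs

Structural guarantees are verified over 500 TA-model and 200–500
MP-model decodes of random sequences (lengths 50–500 and 100–800);
parameter recovery trains on 500 generator samples at the default length
distribution; the end-to-end check trains on 80 sequences per modelled
class (Baum–Welch capped at 40 iterations, tol 1e-5, where the fit is
already converged for these data) and evaluates on held-out 100 TA vs
240 pooled negatives.  Parameter recovery is measured as the
occupancy-weighted mean hydrophobic emission mass of the TMD region —
the hydrophobic fraction of residues the region actually emits — because
the deep TMD states (reached only by the geometric tail of run lengths)
receive too little data for their individual rows to be identifiable.

## Known limitations

* Scores are relative likelihoods, not calibrated probabilities.
* The NO class has no dedicated model; non-membrane sequences are judged
  with the MP score, which is the weakest part of the discrimination.
* Sequences with strongly atypical body composition (e.g. Q-rich,
  low-hydrophobicity bodies) can score below threshold even with a
  correct C-terminal anchor; conversely the decoding rule alone accepts
  any sequence with a quasi-hydrophobic window near the C-terminus —
  the combination of both rules is what carries the specificity.
* Posterior (forward–backward) decoding, higher-order models and
  continuous emissions are out of scope.
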