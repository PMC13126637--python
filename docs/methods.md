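# Methods

## Transformation vocabulary

The generative alphabet is a fixed catalog of 33 actions over RDKit
molecular graphs: fragment operations (BRICS building-block attachment,
side-chain deletion/replacement, stereocenter reduction), functional-group
edits (aromatic decoration with −F/−Cl/−Br/−I/−CF₃/−NO₂/−SO₂CH₃ and their
deletion/replacement, halogenation/dehalogenation, nitration,
sulfonylation, polar and lipophilic group addition, polarity swaps, amine
methylation/demethylation), ring operations (saturation, aromatization,
expansion, contraction, fusion, chain cyclization), reaction-like edits
(alcohol oxidation, carbonyl reduction, ester hydrolysis, ester/amide
formation, phenol acetylation, deacetylation), a multi-rule bioisosteric
swap, CH₂-linker insertion/deletion, and STOP.

Site selection among eligible sites is uniform under the supplied seed.
One attempt is a fresh site/variant draw followed by full sanitization and
a canonical-SMILES round trip; after 20 failed attempts the action reports
`failed_validity`, which is distinct from `inapplicable` (no matching site
at all). All operators must preserve net formal charge except amine
methylation, which may quaternize a tertiary amine.

Decisions taken where the operator definitions left room:

- *Decoration bookkeeping.* A deletable aromatic decoration is recognized
  structurally (one of the seven tokens attached to an aromatic carbon),
  not through lineage memory, so externally supplied molecules are handled
  identically.
- *Halogenation and sulfonylation preferences* are implemented as strict
  tiers: aromatic C–H (resp. nucleophilic N–H) sites are used whenever any
  exist, otherwise the fallback tier.
- *Scaffold hopping* (`REPLACE_SIDECHAIN_CORE`) deletes a side chain first
  and attaches a library fragment at the vacated position.
- *Chain cyclization* measures the 3–10 separation in bonds along the
  shortest all-single-bond path between the two termini, inclusive.
- *Ring fusion* accepts chains of 3–5 atoms adjacent to a ring edge so the
  new fused ring has 5–7 members (the stated product sizes; a 2–4-atom
  chain would give 4–6-membered rings, which contradicts them).
- *Ester hydrolysis* of an acyclic ester yields two molecules; the larger
  organic fragment is kept. Lactones open in place.
- *Ester/amide formation* draws the alcohol/amine partner from
  hydroxyl-/amine-bearing fragments of the BRICS library when one is
  supplied, else from a small built-in set of common alcohols and amines.
- *Ring saturation* is restricted to aromatic rings not fused to another
  aromatic ring; saturating one ring of a fused aromatic system cannot
  produce a kekulizable molecule.
- *Catalog arithmetic.* The action head is fixed at 33 outputs. Polar and
  lipophilic group addition are separate actions, as are ester and amide
  formation. Terminal halogen exchange lives inside the bioisosteric-swap
  sub-rules (extended to all four halogens), and heteroatom
  methylation/ethylation is the N/O–H case of lipophilic group addition,
  whose site set is every C/N/O atom with an available hydrogen.
- *Stereocenter counting* includes unassigned potential centers, so the
  chirality-reduction operator cannot "succeed" by merely erasing a CIP
  label; its success condition is a strict decrease of this count.

## Fragment library

BRICS decomposition over a corpus, fragments capped at 10 heavy atoms
(attachment dummies excluded), ranked by occurrence, truncated to the top
0.1% of distinct fragments by default (minimum one). Ties at the cutoff
break by canonical-SMILES order so construction is deterministic. The
often-quoted library size of a few hundred fragments is a property of a
specific large corpus, not a constant; size scales with the corpus.
Attachment-point dummies are retained in storage and resolved to plain
single bonds on attachment; BRICS link-type compatibility is not enforced
at attach time.

## Policy and training

Input is the 2048-bit radius-2 Morgan fingerprint. Backbone: two ReLU
layers of width 512. Heads: action (three layers, width 512, 33 logits),
core fragment (three layers, width 256, one logit per library fragment),
decoration (three layers, width 256, 7 logits). Heads condition only on
the backbone features of the current state. Weights use fan-in (He)
initialization under a recorded seed; each head's final layer is scaled by
0.01 so the initial policy is near-uniform — the standard policy-gradient
choice, which matters at small training scale where there is little budget
to unlearn arbitrary initial preferences.

Sampling: temperature scaling is applied to the logits first, nucleus
truncation second (smallest descending-probability prefix with cumulative
mass ≥ top-p, renormalized). The log-probabilities entering the gradient
are taken under this truncated distribution — the law actually sampled
from. STOP is masked at the first step of every episode and the mask is
replicated at gradient time.

The REINFORCE loss per 15-episode batch is
`-mean[(R - b) * sum(log-probs)] - beta * mean-entropy`, gradients averaged
over the batch, clipped at global norm 1.0, applied with Adam (lr 1e-4).
Two deliberate choices:

- *Baseline.* One scalar EMA baseline (decay α = 0.9, initialized at 0) is
  held fixed across a source's 15 episodes and updated only after the
  batch. A per-source baseline reset to 0 was tried first and provides no
  variance reduction when curriculum sources rarely repeat; the running
  EMA is the reading consistent with both the batch-update rule and the
  purpose of baseline subtraction.
- *Entropy.* The entropy bonus is computed on the full softmax policy of
  all three heads (averaged over visited steps), not on the truncated
  sampling distribution. Truncated entropy collapses to zero — with a zero
  gradient — as soon as one outcome exceeds top-p, so it cannot prevent
  the positive-feedback collapse onto a single action; full-distribution
  entropy restores the intended exploration pressure (and was observed to
  do so).

Episodes credit the single terminal reward to every step's log-probability
(γ = 1; the reward is terminal by design, so this is the only consistent
episodic reading). Failed or inapplicable transformations consume a step
without changing the state and still contribute their log-probability, so
the policy learns to avoid inapplicable actions. Reward bounds:
[−0.05, 1.0].

Curriculum: epoch 0 trains on methane only; epoch *e* draws up to
`epoch_sample_size` sources uniformly without replacement from the unique
molecules generated at epoch *e* − 1 (5,000 at full scale; the test suite
uses 200 at 5 epochs, M = 1). The per-epoch CSV log records average
reward, mean Tanimoto similarity of generations to their sources, mean SA,
mean QED and mean trajectory length (transformation steps, excluding the
terminal STOP). Deployment variants M = 1, 2, 3 are three independent
trainings differing only in M.

## Genetic algorithm

Fitness is minimized. Single target: LE = DS/√(heavy atoms). Dual target:
harmonic mean of the two LEs when both are negative; any other sign
combination receives a +inf sentinel because a harmonic mean of mixed-sign
values is not order-consistent. The initial elite is the scored seed set;
hit-identification campaigns seed from methane. "Population size" for the
convergence rule is the number of new unique valid offspring produced in a
generation — the only per-generation size that can shrink as the
reachable chemistry saturates. Offspring generation follows the
10-offspring-per-elite-member reading, each offspring one independent
policy rollout of at most M steps. Scores are cached by canonical SMILES;
a molecule is never re-scored. A hard cap (default 1,000 generations)
bounds runaway runs and is logged when hit.

## Synthetic corpora and what the tests show

The fixture generator assembles molecules from scaffold and substituent
templates under a seed, standardizes them, and keeps those inside the
molecular-weight band (default 160–500 Da). A fixed anchor set guarantees
that every operator's precondition occurs in every corpus. These corpora
emulate the functional-group richness and size range of a cleaned
bioactivity extract; they do **not** reproduce real scaffold frequency
distributions, activity labels, or docking landscapes. Passing tests
therefore demonstrate the correctness of the machinery (operators,
estimator, selection, convergence logic) and the direction of the
policy-versus-random quality gap at miniature scale — not campaign-level
numbers, which additionally depend on a real docking engine and corpus.

Reference-ligand benchmarks: QED and SA of JWH-133 reproduce on the
neutral structure; the pentazocine QED value corresponds to its
protonated (ammonium) form, the state in which docking-prepared ligands
are evaluated at physiological pH, and that form is what the package
encodes for it. Mock docking scorers are deterministic composition/topology
functions on a kcal/mol-like scale — plumbing stand-ins, not chemistry.

## Numerical choices and limitations

- float64 throughout the network; gradients are exact (validated against
  central finite differences at 1e-4 relative tolerance).
- Nucleus truncation uses a stable descending sort; probability ties keep
  index order.
- KL divergence over the nine physicochemical descriptors uses Scott-rule
  histograms fitted on the parent set (shared support, capped at 200
  bins) with Laplace smoothing; count descriptors use smoothed empirical
  mass functions. Both the raw mean KL and the benchmark-style
  exp(−mean KL) aggregate are reported, since published values of this
  metric are typically the exponentiated form.
- Internal diversity is 1 − mean pairwise Tanimoto over unique molecules
  (the common convention).
- Miniature-scale training (5 epochs × 200 sources) learns a mostly
  state-independent action preference; some training seeds underlearn and
  stay near-uniform, in which case generations match the random baseline
  rather than beating it. Full-scale training (100 epochs × 5,000) is
  supported but not exercised by the test suite.
- The average-trajectory-length statistic excludes the terminal STOP step.
- Charged products other than quaternary ammonium are rejected; permanent
  cations already present in the input are preserved.
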