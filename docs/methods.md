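# Methods

This note documents the models, the deterministic rules that replace
manual curation, the simulator's assumptions, and the numerical choices —
in enough detail that a maintainer can predict what the code will do on an
input it has never seen.

## Discovery model

The two-pass search design assumes that every lineage worth reporting
retains a recognizable transposase in at least a few copies (first pass),
while most decayed or internally deleted copies do not (second pass, by
nucleotide similarity to the lineage consensus). Consequences: a lineage
represented **only** by transposase-free derivatives is invisible, and a
copy interrupted by an insertion longer than the 1000-bp merge distance is
reported as two copies. Both behaviors are intended.

**Protein pass.** Exact 4-mer amino-acid seeds on each of the six frames,
ungapped extension under BLOSUM62 with X-drop 30 (raw score; the value is
deliberately generous so that extensions survive local mismatch runs in
transposases ~25–30 % diverged from the panel query), reported when the
ungapped bit score (λ = 0.3176, K = 0.134) reaches 50. No E-values: a
score threshold is deterministic and database-size independent.

**Nucleotide pass.** Exact 20-mers seed diagonal-consistent candidate
regions (diagonal tolerance 50, chain gap 400); each candidate is
realigned with a gapped local aligner (match +1, mismatch −2, gap −2.5).
When a seed chain starts near a query terminus the realignment window is
widened to the query end, because a divergent terminal stretch may simply
lack exact words. Hits under 80 % identity or 100 nt are suppressed; the
100-nt floor means fragments of multiply-deleted copies can drop out,
which is the main (few-percent) loss mode in copy recovery.

## Identity and alignment conventions

Pairwise identity is matches / alignment columns excluding terminal-gap
columns, under a global aligner whose end gaps are nearly free (open −5,
extend −0.05): truncated copies do not pay for their missing ends, but a
terminal mismatch cannot be laundered into an end gap (otherwise AAAA vs
AAAT would read as 100 % identity over a 3-column overlap). Clustering and
flank comparison additionally divide by at least the shorter sequence
length ("coverage identity"), since with free end gaps two unrelated
sequences always share some lucky overlap at perfect identity.

Copy-vs-consensus alignment uses a stiff gap open (−24) with a soft extend
(−0.25) so that one biological deletion stays one gap block; with cheaper
opens the aligner splits long gaps around chance match islands and a
single ancestral deletion becomes two spurious breakpoints.

## Consensus and element ends

The relative-majority consensus ignores terminal gaps, emits (and drops) a
gap where the internal-gap count wins a column, and resolves ties by the
fixed priority A>C>G>T>gap. Because first-pass copies span only the
transposase homology, the per-cluster alignment includes each copy's
250-nt flanks; the element span inside that extended consensus is then
recovered by, in order of preference:

1. **conservation boundary** (clusters ≥ 8 rows): the span between the
   outermost 20-column windows whose winning base is carried by a strict
   majority of rows — per-copy random flanks, even A/T-biased ones (whose
   vote splits between A and T), cannot sustain it;
2. **TIR anchor**: the best inverted-repeat match between the two
   consensus ends (≥ 20 nt at ≥ 75 % identity), with the outer boundary
   anchored at the first run of six exact matches and the conserved TA
   target-site duplication stripped when present on both ends.

Both rules are deterministic stand-ins for the manual end curation a
human annotator would perform, and both leave a few nucleotides of
uncertainty. The final word belongs to the **TSD calibration**: every true
copy boundary sits immediately inside a duplicated TA, so each candidate
consensus-end offset (−8..+12) is scored by how well copies can place a
TSD-anchored boundary matching the implied terminal 16-mer; the consensus
is trimmed (or extended with the modal copy base) to the winning offset,
and each copy's interval is then snapped to the best TSD-compatible
position for the terminal k-mer (sides that do not reach the consensus
end — truncations — keep their alignment-driven boundary). On simulated
data this pins consensus ends exactly and per-copy intervals to within a
couple of nucleotides.

Clusters whose consensus matches an already-accepted lineage consensus at
the clustering threshold are absorbed into it (the deterministic
counterpart of merging over-split clusters by hand), and clusters whose
every recovered copy is claimed by an earlier lineage are dropped.

## Structural annotation

TIR presence ("paper" mode, the default) only asks whether the copy's
alignment reaches within 5 columns of the consensus terminus — mismatches
inside the TIR do not revoke the call; "strict" mode additionally demands
80 % identity over the terminal 30 nt. ORFs are the longest stop-free
codon run over the three forward frames (no ATG required: relic copies
keep a long frame with a degraded start); copies are potentially coding at
330–363 codons. Rearranged copies (3′ replaced by inverted 5′) are
detected by aligning the copy against the reverse-complemented consensus
5′ region (≥ 50 nt at ≥ 80 %, so an ordinary 30-nt TIR never triggers);
the junction is then refined by maximizing forward-match support before it
plus inverted-match support after it, which makes the constructed case
C[0:x]+revcomp(C[0:y]) exact. The breakpoint profile of a rearranged copy
is computed from its kept forward part only, and the inverted terminus
counts as its (long) right TIR.

MITE sublineages: candidates are clean copies < 1000 nt with both TIRs and
a non-empty signature; signatures match within ±5 nt per breakpoint,
grouping transitively; a group is accepted only if two members have
distinct flanks (< 0.90 coverage identity on at least one side), which is
what separates transposition from segmental duplication.

## Decay statistics

Per-copy divergence is (substitutions + internal-deletion events +
insertion events) / nucleotides aligned to the consensus; truncations stay
out of the numerator, insertions never enter the denominator, and
insertion runs > 1000 nt (nested elements) are not counted as events. At
the lineage level, deletion intervals and truncation boundaries identical
within ±5 nt across copies are counted once (they predate a
transposition); substitutions are summed per copy. The
deleted-nt-per-substitution ratio therefore estimates the generative
deletion load per unit substitution only when copies are largely
independent — the simulator's star-genealogy generator used for the
ratio-recovery study is calibrated accordingly (deletions drawn first,
substitutions applied to surviving sites, E[D] = r·d·L/(1+r·d)).

The insertion-site profile collapses the duplicated TA and reads %T/A at
offsets ±1..±5, compared with all genomic TA occurrences; per-position
information content is 2 − Shannon entropy (bits); trinucleotides are
tallied above count 5. KS p-values use the asymptotic Kolmogorov
distribution at the effective sample size with the standard
(√en + 0.12 + 0.11/√en) argument correction, which keeps the empirical
size at ~0.05 for n = 100.

## LTT dynamics

Trees: JC69 distances on shared non-gap sites (pairs under 50 shared sites
or at p ≥ 0.75 get the cap, 5.0), Saitou–Nei neighbor joining with
negative branches clamped to zero, rooting on the outgroup's pendant-edge
midpoint (outgroup = closest other lineage's consensus, pruned
afterwards; midpoint rooting when no other lineage exists). Node age =
mean node-to-descendant-tip path length (a lightweight clock smoothing;
"max" is available), leaves at age zero; for ultrametric trees both rules
equal the clock height. The LTT curve accumulates one event per internal
node (n − 1 for n leaves; the root counts as the first transposition, no
extra event is added beyond it) and integrates lineages-alive exactly
between node ages, so per-bin rates multiply back to n − 1.

Classification works on per-copy rates aggregated over thirds of the tree
depth (pseudo-count 0.5, because the near-root era holds well under one
expected event and a single stochastic node would otherwise dominate):
a decayed burst has ≥ 5 old events with r1 ≥ 3·r3 and ≥ 2·r2; an ongoing
burst has r3 ≥ 2·r1 and ≥ 2·r2; multiple bursts show an old burst
(≥ 3 events, r1 ≥ 2·r2) and a resurgence, both ≥ 3× the quietest interior
two-bin window (a fixed middle third would leak burst tails into the
lull); otherwise constant. Naive per-bin peak rules fail here for an
instructive reason: the null rate is estimated from the curve itself, so a
dominant recent burst self-normalizes to a relative rate near one while
suppressing everything older — the thirds contrasts are what remain
identifiable. These constants were fixed from pilot simulations (seeds
disjoint from any test seed) before the acceptance suite was run.

## Simulator

Discrete-time branching (default dt = 0.0025): each living copy transposes
with probability rate(age)·dt (the child snapshots the parent's *current*
sequence, so ancestral deletions are shared by descent), and accumulates
substitutions (Poisson per site), internal deletions and truncations
(geometric sizes), and small insertions as independent point processes.
A configured MITE-genesis event applies a fixed deletion or rearrangement
to one non-founder copy; only that copy's descendants carry the shortened
structure. Copies are placed at TA sites of the background genome weighted
by ∏(bias if A/T else 1−bias) over offsets ±1..±3 — with a uniform
background this makes the marginal A/T fraction at each biased offset
exactly the bias parameter — with the TA duplicated on insertion, a
minimum separation of 600 nt (no nested insertions arise), and random
strand. Segmental duplications copy an insertion with ~300 nt of each
flank to a new locus after placement. Identical config + seed gives
byte-identical outputs.

**Time units.** LineageSpec carries an explicit substitution rate; with
μ = 1 one simulation time unit is one expected substitution per site and
burst ages read directly in divergence units (the dynamics studies use
this). The bundled genome scenario instead sets μ = 0.3 so that a burst
0.25 time units before present leaves copies ~7–8 % diverged — old enough
to decay visibly, young enough that the 0.80 clustering threshold holds a
lineage together (at μ = 1 such copies would sit near 60 % pairwise
identity and no identity-based clustering could reunite them). Truth
tables record burst ages in divergence units (μ·age) so LTT output remains
directly comparable.

**Conditioning.** A pure birth process has enormous copy-number variance
(the founder's early luck dominates), and the analyses concern lineages
that actually amplified, so scenarios may condition on a copy-number
window, a minimum MITE count, or (for the ongoing scenario) a founder that
predates the burst; the simulator redraws with derived seeds until
satisfied. This is a statement about which histories are being studied,
not a tuning knob: the rates inside each draw are untouched.

**What the simulator does not emulate** — and hence what passing tests do
not show about real assemblies: sequencing/assembly error and collapsed
repeats, nested TE insertions, non-uniform background composition
(isochores, satellite), selection against insertions, within-population
polymorphism, and horizontal transfer between genomes. Real-data runs are
supported through the external-hits adapter and newick ingest, but the
recovery guarantees quoted by the tests are statements about the
simulator's conditions.

## Problem sizes

Defaults used by the test and acceptance studies, chosen as desk-scale
study conditions: the bundled scenario is 2 Mb with ~150–250 copies;
dynamics studies use 32–64+ leaves per tree (constant-rate linearity is
measured at ≥ 48 leaves, where the tree-noise floor sits just above the
0.98 R² line); insertion-site studies plant 6000 sites (at ±2 percentage
points, binomial noise alone needs thousands of sites, and the biased
study uses a 10 Mb background so the preferred site classes are not
depleted by without-replacement sampling); the search negative control
runs twenty 5-kb genomes against a 345-aa query with a full local-DP
oracle.

## Known limitations

Copies fragmented below the 100-nt hit floor on every segment are lost;
boundary accuracy degrades for truncated sides (no TSD anchor is required
there); consensus ends inherit ±1–2 nt of uncertainty when TIRs are
degraded and fewer than 8 copies exist; the subfamily call is
nearest-reference only (no phylogenetic placement); and the LTT time axis
is substitutions/site with no calendar calibration, so cross-lineage
comparisons assume comparable molecular clocks.
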