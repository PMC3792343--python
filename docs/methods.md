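# Methods

This note records the models, conventions, numerical choices, and known
limitations behind `targetlox`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Lox-site algebra

A lox site is decomposed as (left arm, linker, right arm) with per-arm
mutation state, a linker class label, and an orientation flag. Sites are
stored internally with the linker on its canonical class strand and the
orientation kept as metadata; this makes the arm-exchange rule of
recombination orientation-free:

    recombine(a, b) = (a.left + linker + b.right,  b.left + linker + a.right)

with arm states travelling with their arms. Activity is purely a
function of the arm states: a site with both arms mutant (lox72-type) is
invisible to Cre. Linker compatibility defaults to exact class identity;
a user-supplied matrix keyed on class pairs can override it, because
compatibility is a property of linker pairs, not something computed from
an alignment. When a 34-mer's linker matches more than one catalogue
class (impossible with the shipped catalogue, whose linkers and their
reverse complements are all distinct), parsing raises rather than
guessing.

The catalogue ships as a plain TSV
(`src/targetlox/data/lox_catalog.tsv`). The sequences follow the primary
literature on Cre arm and linker variants; all downstream algebra depends
only on the decomposition, not on the exact strings, so a user can swap
in their own catalogue file.

## Molecules, coordinates, and surgery

Coordinates are 0-based half-open on the reference strand everywhere.
Gene-relative 1-based positions (the `GENE.635s` convention, where the
number names the −1 base and insertion happens between the −1 and +1
bases) are converted at the naming layer only. Circular molecules are
stored as a linearized string; operations that care about the origin
(feature extraction, PCR, canonical hashing, adjacency of repeats)
handle the wrap explicitly, and molecule identity is defined by the
lexicographically least rotation of the sequence or its reverse
complement (Booth's algorithm), so a circle is the same molecule from
any starting point on either strand.

All sequence surgery (Cre events, host recombination, intron insertion)
runs through one parts-based assembler. Features are clipped to the
copied window; a partially copied lox feature is dropped (a partial site
is not a site), while a clipped intron feature keeps a record of which
slice of which scaffold survives, in scaffold-frame coordinates. That
record is what makes homology detection exact after arbitrary cutting
and flipping.

Intron scaffolds default to deterministic 1-kb synthetic stand-ins (one
per intron type, cargo cloning site at the midpoint, matching the
observation that an intron insertion enlarges a verification amplicon by
about 1 kb); real scaffold records can be substituted. Homology between
intron copies is decided by scaffold identity plus a minimum shared
scaffold range (default 200 nt, configurable) — the two supported intron
types are treated as having no usable mutual homology.

## Cre dynamics and closure

`cre_step` yields one successor per unordered pair of active,
linker-compatible sites: same-orientation intramolecular pairs excise
(the excised circle is retained in the state, since its site can
re-integrate — exactly the cut-and-paste mechanism; a flag models circle
loss instead), opposite-orientation pairs invert, and sites on two
circles fuse. Excision of a circle yields two circles; the larger
product keeps the chromosome identity. Every event conserves
double-stranded base content (A+T and G+C pools) — the invariant is
stated double-strandedly because inversion complements the inverted
segment.

`cre_closure` explores the reachable states breadth-first (default
bound 10,000 states; exceeding it is an explicit error) and reports the
terminal strongly connected components of the transition graph. A state
with no eligible pair is terminal outright; a set of states connected by
reversible flips but with no exit (entered through an irreversible
lox72-forming event) is one absorbing outcome, reported through its
lexicographically least member — a deterministic, rotation-independent
choice. `reversible` is true iff the initial configuration has a
predecessor in the graph.

The cut-and-paste pattern follows from three constraints: the cut must
stay reversible (neither excision product dead), the reinsertion must
form a lox72-type site, and the two wild-type-arm sites that necessarily
remain (arm counting: three sites carry only two mutant arms, and the
lock consumes both) must end up in opposing orientations so they can
only invert, never re-excise. The shipped plan builder uses lox66
upstream, loxP downstream, lox71 at the target in the opposite
orientation. Similarly, cassette exchange locks the cargo in the genome
only for one relative order of the two linker classes between genome and
plasmid; the builder uses that arrangement (genome loxm2/71 then lox66,
delivery loxm2/66 · cargo · lox71).

## Host recombination

Host (RecA-type) recombination between homologous intron scaffold copies
is modelled as a deterministic pass, not interleaved with Cre events,
because the cell applies it after the recombination products exist:
direct repeats collapse at an aligned crossover (deleting one repeat plus
the intervening sequence), inverted repeats separated by at most 100 nt
(i.e. flanking only a lox scar) are removed wholesale down to a 40-nt
scaffold remnant with no lox site (the "tens of base pairs" scar), and
separated inverted repeats invert reversibly. The 100-nt adjacency gap
and 40-nt remnant are configurable defaults.

Design classification uses the repeat geometry of the *uninduced* state:
a deletion can occur without Cre iff the two introns are homologous and
in direct orientation (their collapse mimics the deletion); an inversion
iff homologous and inverted; a cut-and-paste at most partially
(`"some"`) whenever any homologous pair exists. Inverted-repeat
formation is read from the simulated terminal states, not predicted from
a rule table. The twelve-design characterization panel in
`fixtures.rearrangement_panel` reconstructs each design's intron types
and orientations from its published qualitative outcome under this
geometry model; orientations are the reconstructed degree of freedom,
since they are not given in the main text.

## Verification PCR

Primers are the leftmost unique 20-mer within a 300-nt window flanking
each locus (uniqueness checked genome-wide on both strands by exact
match; fixture loci carry distinct 25-nt barcodes precisely so this
always succeeds). No thermodynamic screening is attempted, and in-silico
PCR is exact-match only with a 5-kb default product cap — off-target
"artifact bands" are out of model. Assay structure is fixed by the
operation: 3 assays for a deletion (two insertion bridges, one junction),
4 for an inversion (u-with-u and d-with-d across the new ends), 6 for a
cut-and-paste (three insertion bridges, one cut bridge, two paste
boundaries found by probing the simulated induced state). Expected band
tables are computed by running the PCR engine on the simulated W/U/I
states, with the host inverted-repeat removal applied to the induced
state, so a collapsed junction band is automatically smaller than the
uncollapsed prediction.

## Retargeting

The naming grammar `TYPE.GENE.POSITION{s|a}[.CARGO]` round-trips through
the parser/formatter. Candidate-site enumeration applies only a
template's hard constraints (fixed bases at relative positions) over a
−30..+15 recognition window on both strands; the published scoring
algorithms for ranking sites are deliberately not re-implemented — a
scorer hook accepts any callable. The default element ranges (EBS2/IBS2,
EBS1/IBS1, δ per intron type) are editable configuration. Retargeting
fragments rewrite each element to the reverse complement of its target
slice, carry the type's cloning ends (HindIII/BsrGI for the Ll.LtrB
type, AvaII/XbaI for the EcI5 type), and emit the type's assembly primer
set; fusion-PCR geometry is modelled as concatenation at the declared
junctions.

## Insert folding

Secondary structures are predicted by base-pair maximization (Nussinov
dynamic programming) over Watson–Crick plus GU pairs with a minimum
hairpin loop of 3 nt — a deliberate substitute for thermodynamic folding,
since only the presence and size of non-pairing regions matters for the
flexible/inflexible distinction. Traceback is deterministic: an interval
end is left unpaired when co-optimal, otherwise paired with its smallest
eligible 5′ partner. A hook accepts externally computed dot-bracket
structures for users who run a thermodynamic folder.

Flexibility scoring combines the unpaired fraction with the unpaired
count in the terminal 5-nt windows (the base of any stem). The
two-class call is "flexible" iff the two terminal windows together hold
at least 4 unpaired bases; the sum is used rather than a per-end cutoff
because co-optimal maximum-pairing structures shuffle slack between the
ends. Known limitation: maximum pairing overestimates pairing of
genuinely flexible purine-rich ends, so one of the shipped double-site
GAGAG inserts still folds fully paired at its ends and is called
inflexible; the monotone effect of GAGAG flanks on score and terminal
slack holds across the whole catalogue and is what the tests assert.

## Growth curves

The estimator follows the windowed-R² procedure exactly: per point, the
R² of the least-squares line through the 7-point window centred on it
(boundary points carry no value; a zero-variance window is assigned 0 so
flat stationary phases never qualify); per-point values averaged across
replicates; the longest contiguous run with averaged R² ≥ 0.99 is the
linear range, ties resolving to the earliest run; the same window is
used for all replicates. The slope of log2(OD600) versus minutes has
units of doublings per minute, so the doubling time is its reciprocal —
consistent with results in the tens of minutes — reported as mean ± SE
over the replicate set.

The synthetic generator emulates a plate-reader run: OD start 0.001,
560-s sampling, a sharp lag/exponential/stationary three-phase shape,
and multiplicative log-normal noise with per-replicate streams spawned
from one master seed. Defaults (60-min lag, stationary cap OD 1.0, 1%
noise, three replicates, 600-min duration giving 65 points) represent a
typical overnight run. It does not emulate smooth phase transitions,
instrument drift, evaporation, or replicate-correlated noise, so passing
recovery tests demonstrate estimator correctness under the stated noise
model, not robustness to every real plate-reader pathology.

## Problem sizes

Simulations in the tests and acceptance script run on 9–30-kb synthetic
chromosomes with 1-kb intron scaffolds, closure state spaces of at most a
few dozen states, PCR searches up to 10 kb, folds up to ~100 nt, and 100
growth-curve simulations per recovery check — sizes chosen so every
behaviour of interest (multi-step closures, origin-spanning amplicons,
repeat collapse) is exercised while the whole suite stays fast.

## Known limitations

- Recombination rates, insertion efficiencies, and biological stability
  of rearrangements are out of scope: the simulator predicts reachable
  sequence states and qualitative repeat behaviour, not viability.
- The state model carries one chromosome copy; transient heterozygous
  states (inverted and uninverted chromosomes in one cell) are not
  represented.
- Linear-by-circular and linear-by-linear Cre fusions are not modelled;
  intermolecular events require two circles.
- Exact-match PCR cannot produce the spurious bands a real gel may show.
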