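# Methods

## Scope and model of the device

The package implements the desk protocol for designing a conditional siRNA
(Cond-siRNA) riboswitch: a guide/core/sensor three-strand complex in which
the siRNA duplex (guide:core central 23-mer) is held inactive by a sensor
strand clamped across the core's two overhangs. A trigger mRNA bearing the
sensor's complement binds the free 3′ toehold of the sensor and removes it
by branch migration, liberating the Dicer substrate. Everything here is
sequence- and thermodynamics-level design; no cell biology, kinetics, or
3D structure is modeled.

Conventions: all sequences are RNA alphabet (T transcribed to U on ingest),
written 5′→3′; all coordinates are 1-based and inclusive.

## Construct geometry

* Guide pairing region fixed at 23 nt (the Dicer-substrate duplex), plus a
  3′ dinucleotide overhang (UU by default; deviations are reported as
  advisory warnings, not errors).
* A validated siRNA guide may be supplied without its overhang
  (extension + siRNA = 23 nt; the overhang is appended) or with it, as in a
  classic 21-mer (extension + siRNA = 25 nt; nothing appended). Both
  conventions appear in practice and the builder accepts either explicitly,
  rejecting any other total.
* When the 5′ extension is omitted it is auto-chosen from {G, C} to
  minimize the nearest-neighbor ΔG of the extended pairing duplex, ties
  resolved by enumeration order (G before C). A *supplied* extension must
  only be "GC-rich" — at least 3 of 4 bases G/C — because effective
  published extensions (e.g. CGAG) are not all-GC.
* The sensor is the reverse complement of the selected trigger window, so
  it can hybridize the trigger. Window lengths 31–33 give toeholds of 8–10
  nt beyond the fixed 23 core-paired bases; lengthening the window grows
  the toehold only, not the clamp.
* The core splits its sensor clamp floor(P/2)/ceil(P/2) for a pairing
  region P (11/12 at the default P = 23). The nick between the core's
  central and 3′ segments is recorded as the putative "middle toehold"
  locus; no structural claim is attached to it.
* Assembly asserts exactly three antiparallel duplexes, re-verifies
  Watson–Crick complementarity at every position, and checks that no
  position is claimed twice.

## Thermodynamic model

Perfect-duplex free energies use the RNA/RNA nearest-neighbor model at
37 °C: ΔG°37 = initiation + Σ dinucleotide stacks + a terminal penalty per
helix end closed by A·U. Parameters are the standard Xia et al. (1998)
Watson–Crick set (initiation +4.09 kcal/mol, terminal A·U +0.45 kcal/mol;
10 unique stacks expanded to all 16 steps by strand symmetry), shipped as a
versioned TSV asset; tests re-read the asset independently and hand-sum,
so the implementation is never compared against remembered constants. Only
perfect duplexes are scored — every designed duplex is perfect by
construction, so loops and bulges are out of scope, as are salt and
temperature corrections and partition-function ensembles. Because of that,
numerical equivalence with ensemble folding packages is neither expected
nor claimed; `duplex_dG` has a documented single-table interface so a
cross-check against an external tool can be bolted on where one is
installed.

The strand-displacement score is pure bookkeeping:
net ΔΔG = ΔG(trigger:sensor) − [ΔG(5′ clamp) + ΔG(3′ clamp)], negative
when opening the switch is favorable. For the worked example the value is
−25.67 kcal/mol with the shipped table.

Self-structure of candidate sensors is screened with a Nussinov
maximum-pairing dynamic program (Watson–Crick pairs, optional G·U wobble
off by default, minimum hairpin loop 3, deterministic 5′-most traceback).
A pair-count is used instead of an energy-based MFE because the screen
only needs a simple, exactly testable "is this strand nearly
unstructured?" signal. The count deliberately overstates real structure
(every admissible pair counts equally), which is why the fold ceiling
(default 6 pairs for a sensor-length strand) is advisory — it orders
survivors and raises a flag but never rejects: hard-filtering on it would
discard workable sensors, including the shipped worked example (9 max
pairs).

## Window screen

Windows of 31–33 nt are enumerated exhaustively; metrics are computed on
the strand that will be synthesized, the sensor (an option screens both
strands): GC fraction (bounds [0.45, 0.55], a concrete reading of "~50%"),
forbidden motifs GGGG and MMMM (M = A/U, all overlapping occurrences
reported), fold score, and off-target hits. Hard filters are GC bounds,
any motif hit, and any off-target hit when a background was screened;
survivors are ranked by |GC − 0.50|, then fold score, then 5′-most start —
an invented but documented and overridable policy, since only
"prioritized" is specified by the source protocol.

Off-target screening replaces a remote BLAST with an exact shared-k-mer
index (default k = 15) over a user-supplied background FASTA. Both the
sensor and its reverse complement are queried: a transcript carrying the
sensor's complement is a true hybridization off-target, and a transcript
carrying the sensor's own sequence marks a locus whose transcripts the
sensor family interacts with — this is also what makes the intended
trigger transcript itself register, so the id-exclusion rule has meaning.
The index is validated against a naive substring scan. Exact matching is
deliberate: deterministic, offline, and tunable via k; gapped or
mismatch-tolerant search is out of scope.

## Chemical modifications

Strand chemistry is per-residue sugar (ribose, 2′-O-methyl, LNA),
per-linkage backbone (phosphodiester, phosphorothioate), and terminal
conjugates (cholesterol-TEG, fluorophore), serialized in a vendor-style
notation (`m` = 2′-O-methyl, `+` = LNA, `*` = phosphorothioate linkage,
bracketed terminal tags) with a lossless parser. The three generation
presets (firstG: LNA + reduced phosphorothioate on the sensor toehold plus
an LNA at the middle-toehold locus; secondG: additionally 2′-O-methyl on
the guide; cholConj: additionally 3′ cholesterol-TEG on the sensor) ship
as editable YAML data. Their per-position defaults are **illustrative**:
the generations are specified qualitatively, so the presets encode the
pattern, not a validated synthesis recipe. The "middle toehold" is
interpreted as the sensor clamp base adjacent to the nick between the
core's central and 3′ segments — an interpretation, flagged as such.
Modification operations never alter the base sequence and preset
application is idempotent.

## Synthetic data

The fixture generator emulates only what the screen consumes: a trigger
transcript of configurable length and GC content (exact base composition,
then a seeded shuffle, so composition is on target and output is
byte-deterministic) with verbatim implanted windows, and decoy background
transcripts guaranteed k-mer-free against a protected sequence by
rejection sampling (unbiased composition; capped attempts with a clear
failure). It does not emulate expression levels, isoforms, UTR base
composition bias, or repeat structure — so a passing screen on fixtures
demonstrates algorithmic correctness (recovery of implanted windows,
zero/nonzero off-target counts by construction, determinism), not
performance on real transcriptomes.

## Problem sizes and determinism

Test and acceptance problem sizes are desk-scale: oracle equivalence on
~200+ random sequences of ≤ 12 nt for the fold screen, ~150 random
duplexes of ≤ 35 bp for the duplex model, screens over a 400-nt synthetic
trigger against 10 decoys of 300 nt. Every stochastic step takes an
explicit seed; identical configuration and seed reproduce every report
byte for byte, and the CLI embeds the effective configuration and tool
version in each report.

## Known limitations

* The thermodynamic model is a perfect-duplex nearest-neighbor sum at
  37 °C; no ensemble, kinetics, salt, or dangling-end terms.
* The fold screen counts pairs, it does not weigh energies.
* Off-target search is exact-match only; near-matches with mismatches or
  gaps are invisible below k consecutive identities.
* Modification presets are illustrative patterns, not validated chemistry.
* Sensors are assumed to act through simple toehold-initiated branch
  migration; no attempt is made to model partial displacement
  intermediates.
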