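# Methods

This note documents the models, numerical choices and limitations behind
`mthia`. The pipeline grades rare human 16S mt-rRNA variants by combining
population rarity, structural context on the mitoribosomal large subunit,
cross-kingdom conservation and a deterministic evidence rubric.

## Coordinate model

The 16S mt-rRNA is described in two numbering systems: residue indices in
the mature rRNA (1..1559) and rCRS m. coordinates. Over the whole gene the
two differ by a single constant, so `CoordinateMapper` stores one offset
and the inclusive gene span and maps bijectively inside it.
`calibrate_mapper` derives the offset from any set of double-numbered rows
and fails loudly, listing the offenders, if two rows disagree. Calibration
on the packaged table yields offset 1670 and span m.1671–3229. The mapper
is strictly positional: the rCRS placeholder base at m.3107 is counted like
any other position (the reference FASTA must retain its `N`), because the
constant offset empirically holds on curated pairings above m.3107.

Variant labels occur in five dialects (substitution, deletion, duplication,
insertion, homopolymer-run change), in either numbering, with en-dash or
hyphen ranges, mixed case for `del`/`Ins`/`dup`, optional whitespace around
`>`, `≥` for `>`, and occasional stray base letters between `m.` and the
position. The parser folds all of these; alleles are stored in the RNA
alphabet (T→U on ingest) and the original label is kept verbatim. A
homopolymer-run change (e.g. a 3T run becoming 4T) is its own event kind
rather than a normalized insertion, since the run edge carrying the extra
base is not well defined.

## Rarity filter

Each population sequence is globally aligned to the reference gene segment
(affine gap penalties: match +1, mismatch −1, gap open −5, gap extend −1).
Biopython's `PairwiseAligner` computes the optimal alignment; because its
tie-break among co-optimal gap placements is unspecified, a deterministic
post-pass shifts every gap run to its leftmost score-equivalent column, and
called indels are additionally left-normalized against the reference.
Homopolymer indels are therefore always reported at the run's 5′ edge.
Columns containing `N` in either row call nothing; ambiguity codes other
than `N` are rejected at ingest.

Counting distinguishes *total* appearances from *novel* ones: an appearance
is novel unless the carrying sequence is tagged `known_reporting_source`
(mechanizing the manual check that GenBank hits trace back to the
publications that reported the variant). The filter retains a variant iff
total ≤ 15 and novel = 0 — the boundary is inclusive at 15, so 16
appearances exclude.

The synthetic population generator plants variants at exact appearance
counts in a reference segment (default 2 kb, standing in for the 1.56 kb
gene; full 16.5 kb genomes add nothing to correctness testing). It is
deterministic under its seed, emits byte-stable FASTA plus a JSON
ground-truth sidecar, and refuses overlapping events in one sequence.
It does **not** emulate real mtDNA mutational spectra, phylogenetic
structure, sequencing error or alignment-breaking structural variation, so
green tests certify the counting/filter logic, not robustness to messy
real-world GenBank data.

## Structural context

**I/O.** PDB and mmCIF files are read through gemmi; only the first model
is used and altlocs resolve to the highest-occupancy conformer (first
listed on ties). A pre-scan rejects truncated ATOM/HETATM records with the
offending line number. Writers emit both formats; coordinates survive the
round trip to the formats' 3-decimal precision.

**Contacts.** All heavy-atom pairs between a residue and the rest of the
model strictly below the cutoff (default 3.0 Å — an atom pair at exactly
3.0 Å is not a contact), excluding intra-residue pairs and the covalent
O3′(i)–P(i+1) backbone link. The cutoff is a parameter, so looser screens
(e.g. 4 Å bridge checks) are the same code path.

**Base pairs.** Detection is geometric: candidate pairs from a C1′–C1′
neighbour search (≤ 12.5 Å); hydrogen bonds are base N/O donor–acceptor
pairs at 2.4–3.4 Å; coplanarity requires base-plane normals within 35° and
either base centre within 2.0 Å of the other's plane (this second gate is
what rejects stacked neighbours, whose atoms can satisfy the distance
window vertically). Canonical classes (cis Watson–Crick, wobble) need ≥ 2
bonds matching the canonical donor/acceptor pattern, antiparallel normals
and C1′–C1′ within 8.0–11.5 Å; reverse Hoogsteen is a WC-edge-to-
Hoogsteen-edge bond with parallel normals; sheared is the G·A
N3–N6/N2–N7 pattern; anything else hydrogen-bonded and coplanar is
`other_noncanonical`. All thresholds live in `PairCriteria` and are
configurable. Base-plane normals are computed by Newell's method over the
ordered ring perimeter with a per-base-type sign convention, so the normal
points off the same face of every base and the antiparallel test is
orientation-independent (an SVD normal would have an arbitrary sign).

**Glycosidic conformation.** χ is O4′–C1′–N9–C4 for purines and
O4′–C1′–N1–C2 for pyrimidines; syn iff χ ∈ [−90°, +90°]; missing atoms
yield `undetermined_conformation` rather than an error.

**Superposition.** Kabsch least-squares fit (SVD with determinant
correction, so the rotation is always proper) over an explicit atom
pairing, or over a pairing derived from a global alignment of chain
sequences for real structures. Pruning is iterative: after each fit the
single worst pair above the cutoff (default 2.0 Å) is removed and the fit
repeated until no pair exceeds the cutoff. One-at-a-time removal was
chosen over removing all offenders per sweep because a batch sweep can
discard the entire pairing when a few gross outliers drag the initial fit
away from the majority solution; on well-behaved pairings both schemes
converge to the same fixed point. Fewer than three surviving pairs raises
a degeneracy error. Residue equivalence across structures takes the
nearest C1′ to the transformed query C1′, unmapped beyond 4.0 Å.

**Conservation codes.** Interaction conservation across the five ribosomal
sources (bacterial, eukaryotic, archaeal, mammalian-mito, yeast-mito) is
rendered as `C` plus one glyph per source in b,e,a,m,M order: the source
letter when the interaction is observed, `+` when partners are present but
the interaction is unmodelled, `-` when a partner is absent, `?` when the
interaction is absent despite partners. With nothing observed the leading
`C` is dropped. Glyphs are ASCII.

**Synthetic duplexes.** Residues are built from in-plane standard
base-frame templates; the paired base is the template rotated 180° about
the frame's x axis, successive pairs are related by a 32.7°/residue twist
and 2.81 Å/residue rise about a displaced axis. Wobble partners apply an
in-plane shift of (2.176, 0.452, 0) Å realizing G O6–U N3 ≈ 2.9 Å and
G N1–U O2 ≈ 2.8 Å. O4′ is placed by internal coordinates at χ = −160°
(anti); each residue carries a phosphate from a fixed template and an O3′
1.6 Å from the next residue's phosphate. Limitations, deliberately
accepted: base planes are perpendicular to the helix axis (no inclination
or propeller twist), so the stacking separation equals the 2.81 Å rise —
tighter than real A-form stacking — and the backbone is a minimal
P/O3′/C1′/O4′ skeleton, not a full sugar-phosphate model. The duplexes
exercise the detector's criteria exactly as specified; passing tests
therefore certify the geometric rules, not performance on distorted
experimental models.

## Conservation index

C\_v = (2 − H)(1 − g), with H the Shannon entropy (bits, 0·log 0 ≡ 0) of
the non-gap base frequencies and g the gap fraction; a fully gapped column
scores 0. This reproduces the ceiling (2.000 for a gap-free invariant
column) and the qualitative ordering of published values; intermediate
published values depend on the original cross-kingdom alignment corpus and
are not reproduced. The entropy-to-score mapping is pluggable
(`conservation_index(column, score_fn=...)`) so an alternative published
definition can be swapped in without touching callers.

## Evidence rubric

`classify` is a total, deterministic priority function over five fields:
direct mitochondrial biochemistry → P; not placeable on the structure or
no heterologous data → und; direct heterologous mutagenesis at the residue
or its pairing partner supporting disruption/tolerance → E/N; indirect
heterologous evidence supporting disruption/tolerance → L/U; otherwise
NEE. The priority order resolves evidence conflicts (biochemistry on the
mitochondrial system itself outranks everything; direct heterologous data
outrank indirect). Profiles violating the invariant "direct heterologous
evidence implies heterologous data exist" are rejected. The packaged
64-row table encodes each variant's evidence profile as data transcribed
from the curated case narratives; the und/NEE boundary for placeable sites
in mito-specific regions follows the published assignment via the
placeable/heterologous flags.

## Reporting

Reports group rows in the published category order (NEE, U, und, L, E, P),
sort by rRNA position within groups, and carry printed labels verbatim
next to canonical machine labels. TSV output is byte-stable (fixed column
order, LF endings) and round-trips through the reader.

## Problem sizes

The default test suite and the acceptance script run entirely on packaged
or generated data: the 64-row table, duplexes of 4–30 base pairs (50
random duplexes in the geometry check), 500-point superpositions,
1,000 random alignment columns, and a seeded population of 100 × 2 kb
sequences. Checks against deposited ribosome structures (RMSD 0.700 Å for
the bacterial SSU pair, partner 1149 for residue 1169, bacterial
equivalent 562 for residue 173) need those files downloaded and are left
to the user via `mthia struct superpose` and `map_equivalent_residue`;
the printed atom-pair counts of the original superpositions are
tool-specific and are not asserted anywhere.
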