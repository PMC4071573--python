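# Methods

## Mass model

Species formulas are assembled as glycerol (C3H8O3) + head block + the free
fatty acids, minus one water per condensation (each ester bond to the
backbone, plus the head attachment, plus the inter-hexose bond of DGDG).
Head blocks, in free form: phosphocholine (PC/LPC), phosphoethanolamine
(PE), glycerophosphate (PG), inositol phosphate (PI), hexose ×1 (MGDG) / ×2
(DGDG), sulfoquinovose (SQDG); DAG/TAG carry none and a free fatty acid is
its own formula. This reproduces reference values such as PC 16:0/16:0 =
C40H80NO8P (733.5622 Da), SQDG 16:0/16:0 [M−H]⁻ = 793.514 and
LPC 16:0 = 495.332.

Atomic masses are hard-coded monoisotopic constants (C exactly 12,
H 1.0078250319, N 14.0030740, O 15.9949146, P 30.9737615, S 31.9720707,
Na 22.9897693) with the electron mass (0.00054858 Da) subtracted from
cations and added to anions. The electron correction matters at the printed
precision: it is what makes the phosphocholine fragment C5H15NO4P⁺ come out
at 184.0733 rather than 184.0739. Only charge ±1 is modeled; direct-infusion
glycerolipids are overwhelmingly singly charged.

Adduct defaults per scan channel: [M+H]⁺ for the 184.07 precursor-ion scan;
[M+H]⁺ and [M+Na]⁺ candidates for the 162 neutral-loss scan (the adduct that
carries the galactolipid signal under acidified infusion is not knowable a
priori, so both are indexed and the generator emits the protonated form);
[M−H]⁻ for negative Q1. All configurable per run.

## Candidate space and matching

The default acyl pool is {14:0, 16:0, 16:1, 16:2, 16:3, 18:1, 18:2, 18:3,
18:4, 20:4, 20:5, 22:6} — EPA, its C16/C18 precursors, and the minor chains
seen in diatom glycerolipids. Chains carry no double-bond positions; the
omega-3/omega-6 distinction is collapsed, and "20:5" denotes EPA by
convention. Diacyl enumeration yields n(n+1)/2 unordered multisets, triacyl
C(n+2,3).

Matching tolerance defaults to 0.01 Da (unit-resolution QTRAP regime).
Scan-mode gating admits only the classes a mode can see; within negative Q1
the classes separate by head-group mass. Every candidate within tolerance is
reported ranked by |error|, with ties broken lexicographically for
determinism; peaks with more than one candidate are flagged
`ambiguous_multi_candidate` and count toward profile totals only through
their best-ranked candidate. Note that compositions with equal totals (e.g.
PC 18:1_16:1 vs PC 18:2_16:0, both "34:2") are exactly isobaric and always
co-reported; because the profile is kept at (class, composition) granularity
this never inflates species counts.

The isotopic-overlap report flags candidate pairs in one detection mode
whose spacing is within a configurable window of two ¹³C–¹²C deltas
(2.00671 Da) — the M+2 of the more-saturated homologue lands on its
one-double-bond-fewer neighbour (spacing 2.01565, offset 8.9 mDa). Flags are
advisory; nothing is deleted, matching the bench-side remedy of fractionating
before infusion.

## Synthetic data

The generator exists so that the full pipeline is testable with known ground
truth. Packaged rosters mirror the published profile shape of the diatom
*Fistulifera solaris*: 14 PL species (11 PC + 2 PG + 1 PI, no PE) and 16 GL
species (8 MGDG + 5 DGDG + 3 SQDG), with every chloroplast-type lipid
(MGDG/DGDG/SQDG/PG/PI) carrying C16 at sn-2, C18 chains occurring only at PC
sn-2, and EPA-containing eukaryotic PCs holding EPA at sn-1 (including the
di-EPA PC). Exact chain identities within those constraints are this
package's choice (figure-level assignments are not machine-readable in the
source material); they were additionally chosen so that no two roster
species sharing a detection mode fall within 0.02 Da of each other at their
generation adducts, which keeps the zero-noise round trip exact at the
default tolerance. The rosters ship as TSVs under `src/diatomlipid/data/`.

Precursor scans place one peak per visible species at its exact adduct m/z
with intensity proportional to roster abundance (arbitrary units; no
ionization-efficiency model). Optional decoy peaks are drawn uniformly over
400–1000 m/z from a seeded generator, never within 0.05 Da of a true peak so
that decoys can only ever add false positives, not perturb true matches.
The optional isotope envelope is binomial in the carbon count
(p(¹³C) = 0.0107, depth M+2). Identical fixture + seed ⇒ byte-identical
files.

Product-ion scans emit one carboxylate per chain with
intensity(sn-2) = r × intensity(sn-1/sn-3), r = 2.0 by default, plus a small
head-group marker. This fragment-intensity convention is a package
convention, deliberately shared between generator and assigner (τ = 1.5 sits
below r = 2.0 with margin): published positional-assignment rules for these
instruments are qualitative, so the pair is internally consistent and both
knobs are exposed. Consequences of the synthetic design: passing round-trip
tests demonstrate the pipeline's correctness and determinism, not robustness
to real-world ionization suppression, in-source fragmentation, or
chromatographic artifacts, none of which are modeled.

## Positional and assembly calls

The most intense carboxylate's chain is placed sn-2 when its summed
intensity beats the runner-up chain's by ≥ τ; compositions whose chains are
all identical resolve by symmetry without ratios; a missing carboxylate
yields an ambiguous call with a note. Triacyl calls identify the sn-2 chain
only — sn-1 vs sn-3 is reported in canonical order, matching the
(sn-1/sn-2) granularity of direct-infusion profiling. Chain order of the
query never affects the call.

Assembly classification reads the sn-2 chain: ≤ C16 → prokaryotic
(chloroplast), C18/C20/C22 → eukaryotic (ER). The ≤16 cutoff is a design
choice for the minor C14 case (the chloroplast pathway exports acyls up to
C16); C22 is grouped with the eukaryotic side. Unresolved species are
ambiguous; lyso and free-acid species have no backbone signature and raise.

## Reaction network

States are (canonically sorted multiset of PC/LPC/DAG/TAG/FFA species,
set of acyl-CoA chains). The CoA side is a non-depleting reservoir — using
a CoA chain does not consume it — which keeps the state space finite and
matches the qualitative nature of the pathway scheme; PC/LPC/DAG/TAG/FFA
are stoichiometric. Acyl chains are conserved by every operator except the
two modifiers: ELO adds C2 to a CoA-bound chain (up to C22), DES adds one
double bond to a PC-bound chain (caps 18:4 and 20:5; other chain lengths are
not desaturase substrates here). PDAT and DGAT acylate sn-3 by default; the
sn-1 variant (DAG shifting to sn-2/sn-3) is behind a flag.

`find_routes` is a level-synchronous BFS with deterministic operator and
binding order that returns *all* distinct minimal step sequences, so
minimality claims are exact rather than heuristic; a configurable state cap
(default 200 000) turns runaway searches into an explicit error. The
acyl-editing route to DAG 20:5/16:1 is counted as three elementary steps
(PLA, LPCAT, PDCT) — the deacylation/reacylation pair is not merged into one
"editing" step — and the search also surfaces the equivalent shuttle that
releases the sn-2 chain directly to CoA via LPCAT's reverse reaction,
reported alongside it at the same length.

## Numerical and procedural choices

- Mass additivity holds to 1e−9 Da by construction (pure summation).
- Peak-list serialization: m/z at 4 decimals, intensity at 1; annotation
  tables sorted by (class, theoretical m/z) with explicit float formatting,
  so all outputs are byte-reproducible.
- Degenerate inputs: empty spectra annotate to empty lists; an empty
  annotation set resolves to an all-zero profile whose constraint checks are
  vacuously true; unsorted peak lists are sorted on load with a warning;
  malformed headers are format errors (CLI exit code 2).
- Problem sizes: the shipped pipelines run on the 30-species rosters and a
  702-entry candidate index; the complete simulate→annotate→routes chain
  finishes in a few seconds on one CPU.

## Known limitations

No quantification or intensity normalisation; no ether/odd-chain/oxidized
lipids or sphingolipids; no double-bond localisation or sn-1/sn-3
stereoresolution; isotope model truncated at M+2; galactosyltransfer onto
DAG is not simulated (DAG products are reported as available chloroplast
precursors only); reaction-network results are qualitative reachability
statements, not kinetics or flux.
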