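# diatomlipid

Shotgun-lipidomics tooling for the polar glycerolipids of oleaginous diatoms:
class-resolved annotation of direct-infusion ESI-MS peak lists, sn-positional
assignment from product-ion scans, prokaryotic/eukaryotic assembly
classification, and a reaction-network search for the PC-based acyl-editing
routes that move eicosapentaenoic acid (EPA, 20:5) into triacylglycerol (TAG).

It is written for people analysing triple-quadrupole (QTRAP-style)
direct-infusion scans of phospholipid (PL) and glycolipid (GL) fractions —
and for anyone who wants a fully synthetic, ground-truth-backed testbed for
that kind of pipeline, since every stage can be driven end to end without an
instrument.

## What it computes

**Annotation.** Candidate species are enumerated combinatorially from an acyl
pool (default: 14:0 … 22:6, twelve chains) and indexed by exact adduct m/z,
with monoisotopic masses built from elemental formulas (for example
PC 16:0/16:0 = C₄₀H₈₀NO₈P, [M+H]⁺ = 734.5694). Matching is class-gated by
scan mode, mirroring what each acquisition can see:

| scan | diagnostic | classes admitted |
|---|---|---|
| precursor-ion scan, positive | phosphocholine fragment, m/z 184.07 | PC |
| neutral-loss scan, positive | hexosyl loss, 162 Da | MGDG, DGDG |
| Q1 scan, negative | — (head-group mass separates classes) | SQDG, PG, PI, PE |

**Positional assignment.** In negative-mode product-ion scans each acyl chain
reports as its carboxylate anion [RCOO]⁻ (20:5 → 301.2173). The chain whose
carboxylate is most intense is placed at sn-2 (the backbone's center
position) when it beats the runner-up by a ratio threshold τ (default 1.5);
otherwise the call is ambiguous.

**Assembly classification.** A C16 (or shorter) acyl at sn-2 marks
chloroplast (prokaryotic-pathway) assembly; C18/C20/C22 at sn-2 marks ER
(eukaryotic-pathway) assembly.

**Route search.** A breadth-first search over a pool of PC/LPC/DAG/TAG/free
fatty acid species plus an acyl-CoA reservoir, under the acyl-editing
operators PLA, ACS, LPCAT (both directions), PDCT, PDAT, DGAT, ELO
(elongation, CoA-bound only) and DES (desaturation, PC-bound only), returns
every route of provably minimal length to a target species.

## Worked example

Simulate the packaged PL-fraction fixture, annotate it, and search for the
acyl-editing route to DAG 20:5/16:1:

```bash
diatomlipid simulate --fixture fsolaris_pl --seed 1 --out demo/scans
diatomlipid annotate --in demo/scans --out demo/ann
```

prints

```
total species: 14
  PC: 11  (PC 30:1, PC 32:0, PC 32:1, PC 36:5, PC 36:6, PC 38:6, PC 38:7, PC 38:8, PC 38:9, PC 40:10, PC 40:9)
  PG: 2  (PG 32:1, PG 36:5)
  PI: 1  (PI 32:1)
check c18_only_at_pc_sn2: pass
check pe_absent: pass
check sn2_c16_on_chloroplast_classes: pass
```

i.e. the 11 PC + 2 PG + 1 PI species planted by the fixture are all
recovered, no phosphatidylethanolamine is called, and the structural
constraints of the profile hold. Then

```bash
diatomlipid routes --preset dag-epa
```

reports `n_routes: 2`, both of length 3, one of them

```
PLA        PC 20:5/18:2            -> LPC 20:5 + FFA 18:2
LPCAT_fwd  LPC 20:5 + CoA 16:1     -> PC 20:5/16:1
PDCT       PC 20:5/16:1 + DAG 16:0/16:1 -> DAG 20:5/16:1 + PC 16:0/16:1
```

— deacylation/reacylation at sn-2 followed by a head-group swap, turning an
EPA-bearing eukaryotic PC and the predominant DAG 16:0/16:1 into the
EPA-containing prokaryotic-type DAG. The `pdat-tag` preset finds the
single-step PDAT conversion of PC 20:5/20:5 + DAG 16:0/16:1 into
TAG 16:0/16:1/20:5, and `epa-synthesis` returns a 7-step route from
PC 16:0/18:1 to an EPA-bearing PC in which every desaturation acts on a
PC-bound chain and the single C18→C20 elongation acts on acyl-CoA.

## Layout

- `src/diatomlipid/chem.py` — formulas, monoisotopic masses, adducts, diagnostics
- `src/diatomlipid/species.py` — candidate enumeration, sorted m/z index
- `src/diatomlipid/spectra_io.py` — peak-list TSV/MGF, annotation tables
- `src/diatomlipid/synthetic.py` — fixtures and synthetic scan generation
- `src/diatomlipid/annotation.py` — gated matching, overlap flags, profile report
- `src/diatomlipid/positional.py` — sn-1/sn-2(/sn-3) assignment
- `src/diatomlipid/pathway.py` — assembly calls and route search
- `src/diatomlipid/cli.py` — the `diatomlipid` command

See `docs/methods.md` for the model, conventions and limitations.
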