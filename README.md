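# condsirna

A design toolkit for **conditional siRNA (Cond-siRNA) riboswitch constructs**
— three-strand RNA devices whose silencing activity stays OFF until a chosen
trigger mRNA switches them ON by toehold-mediated strand displacement.

The shipped worked example is a cardiac construct: the trigger is the 3′ UTR
of *Nppa* (atrial natriuretic peptide, a stress biomarker), and the silencing
target is calcineurin A-α (*Ppp3ca*), a driver of pathological cardiac
hypertrophy. The toolkit is for nucleic-acid designers who want the whole
desk protocol — window screening, strand construction, thermodynamic
evaluation, off-target screening, and chemical-modification annotation — as
reproducible, offline code.

## The design in brief

A Cond-siRNA construct has three strands, written 5′→3′:

* **guide** — a validated siRNA guide against the target, 5′-extended with
  GC-rich bases to a 23-bp Dicer-substrate pairing region plus a 3′ UU
  overhang (25 nt total);
* **sensor** — the reverse complement of a 31–33-nt window of the trigger
  mRNA; its first 23 bases clamp the core, the remaining 8–10 bases are the
  exposed single-stranded **toehold**;
* **core** — `revcomp(sensor[1..11]) + revcomp(guide[1..23]) +
  revcomp(sensor[12..23])` (46 nt): a central 23-mer duplexed with the guide,
  flanked by 11-nt and 12-nt overhangs that clamp the sensor.

The trigger invades at the toehold and displaces the sensor by branch
migration; the net thermodynamic drive is

ΔΔG = ΔG(trigger:sensor) − [ΔG(sensor:core 5′ clamp) + ΔG(sensor:core 3′ clamp)]

with duplex free energies from the nearest-neighbor model
(ΔG°37 = initiation + Σ stacks + terminal A·U penalties, Xia/Turner RNA
parameters). Candidate windows are screened for ~50% GC, absence of GGGG and
MMMM (M = A/U) motifs on the synthesized sensor strand, low self-structure
(Nussinov maximum-pairing count), and zero exact shared k-mers (default
k = 15, both strands) with a background transcriptome.

## Worked example

```python
from condsirna import (normalize_to_rna, reverse_complement, build_sensor,
                       build_guide, build_core, assemble_construct,
                       verify_assembly, displacement_ddG)

sensor_seq = normalize_to_rna("CUUCACCACCU CUCAGUGGCAAU GCGACCAA", "sensor")
window = reverse_complement(sensor_seq, id="nppa_window")   # trigger segment

sensor = build_sensor(window)
guide = build_guide(normalize_to_rna("UGUUGUUUGGCUUUUCCUGUU", "sirna"),
                    extension="CGAG")
core = build_core(sensor, guide)
construct = assemble_construct(guide, sensor, core)
print(construct.stats)
score = displacement_ddG(construct, type("W", (), {"sequence": window})())
print(round(score.net_ddG, 2))
```

prints

```
{'duplex_lengths': [11, 23, 12], 'toehold': 'GCGACCAA', 'toehold_length': 8,
 'guide_overhang': 'UU', 'sensor_paired_bases': 23,
 'nick_positions_on_core': [11, 34]}
-25.67
```

i.e. the construct forms exactly the intended 11 + 23 + 12 bp duplexes, the
first 23 sensor bases are clamped with an 8-nt GCGACCAA toehold free, and
opening the switch is strongly downhill (net ΔΔG ≈ −25.7 kcal/mol): the
31-bp trigger:sensor duplex gained outweighs the two clamp duplexes lost.

The same pipeline is available from the shell:

```bash
condsirna screen --trigger trigger.fasta --background txome.fasta --out report
condsirna design --window <window-seq> --sirna UGUUGUUUGGCUUUUCCUGUU \
                 --extension CGAG --preset cholConj --out construct
condsirna evaluate construct.json
condsirna fixtures --seed 7 --implant 50:<window-seq> --out demo
```

## Layout

`src/condsirna/` — `seqcore` (alphabet, FASTA), `screen` (windows, k-mer
off-targets, ranking), `construct` (strand building and verification),
`thermo` (nearest-neighbor duplexes, Nussinov fold, displacement score),
`modifications` (LNA / 2′-O-methyl / phosphorothioate / conjugate
annotation with the firstG / secondG / cholConj presets), `fixtures`
(seeded synthetic data), `cli`. See `docs/methods.md` for models,
parameters, and design choices.
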